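"""Continuous-time Markov (Mk) models for discrete characters on trees.

Fits equal-rates (ER), symmetric (SYM), and all-rates-different (ARD) rate
matrices by maximum likelihood via Felsenstein pruning, selects the rate
structure by AICc, computes marginal/MAP ancestral states, and draws
stochastic character maps (joint node-state sampling plus
endpoint-conditioned within-branch histories via uniformization).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .phylo_io import (Node, Phylogeny, PhyloError, RegimePainting,
                       paint_from_node_states)
from .ou_engine import aicc as _aicc

__all__ = ["MkFit", "SimmapSample", "AncestralStates", "build_rate_matrix",
           "stationary_distribution", "mk_loglik", "fit_mk",
           "ancestral_states", "stochastic_maps", "STRUCTURES"]

STRUCTURES = ("ER", "SYM", "ARD")

RATE_BOUNDS = (1e-8, 1e3)   # per unit tree height


def n_free_rates(structure: str, k: int) -> int:
    if structure == "ER":
        return 1
    if structure == "SYM":
        return k * (k - 1) // 2
    if structure == "ARD":
        return k * (k - 1)
    raise PhyloError(f"unknown rate structure {structure!r}")


def build_rate_matrix(structure: str, rates: Sequence[float],
                      k: int) -> np.ndarray:
    """Assemble a k-state rate matrix Q from its free off-diagonal rates.

    Off-diagonal order: row-major over (i, j), i != j.  ER uses one rate for
    every transition; SYM fills the upper triangle row-major and mirrors it;
    ARD fills all off-diagonals row-major.  Rows sum to zero.
    """
    rates = np.asarray(rates, float)
    if (rates < 0).any():
        raise PhyloError("rates must be >= 0")
    if len(rates) != n_free_rates(structure, k):
        raise PhyloError(f"{structure} with {k} states needs "
                         f"{n_free_rates(structure, k)} rates, got {len(rates)}")
    Q = np.zeros((k, k))
    if structure == "ER":
        Q[:] = rates[0]
    elif structure == "SYM":
        idx = 0
        for i in range(k):
            for j in range(i + 1, k):
                Q[i, j] = Q[j, i] = rates[idx]
                idx += 1
    else:  # ARD
        idx = 0
        for i in range(k):
            for j in range(k):
                if i != j:
                    Q[i, j] = rates[idx]
                    idx += 1
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a rate matrix (left null vector)."""
    k = Q.shape[0]
    A = np.vstack([Q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    total = pi.sum()
    return pi / total if total > 0 else np.full(k, 1.0 / k)


def _resolve_root_prior(root_prior, Q: np.ndarray) -> np.ndarray:
    k = Q.shape[0]
    if isinstance(root_prior, str):
        if root_prior == "stationary":
            return stationary_distribution(Q)
        if root_prior == "flat":
            return np.full(k, 1.0 / k)
        raise PhyloError(f"unknown root prior {root_prior!r}")
    pi = np.asarray(root_prior, float)
    if pi.shape != (k,) or pi.min() < 0 or not np.isclose(pi.sum(), 1.0):
        raise PhyloError("root prior must be a probability vector")
    return pi


def _tip_state_indices(tree: Phylogeny, tip_states: Mapping[str, str],
                       states: Sequence[str]) -> dict[int, int]:
    lookup = {s: i for i, s in enumerate(states)}
    out = {}
    for t in tree.tips:
        if t.label not in tip_states:
            raise PhyloError(f"no state for tip {t.label!r}")
        st = str(tip_states[t.label])
        if st not in lookup:
            raise PhyloError(f"unknown state label {st!r} at tip {t.label!r}")
        out[t.index] = lookup[st]
    return out


def _branch_probs(tree: Phylogeny, Q: np.ndarray) -> dict[int, np.ndarray]:
    """Transition probability matrix for every non-root edge."""
    cache: dict[float, np.ndarray] = {}
    out = {}
    for n in tree.nodes:
        if n is tree.root:
            continue
        key = round(n.length, 15)
        if key not in cache:
            cache[key] = expm(Q * n.length)
        out[n.index] = cache[key]
    return out


def _partials(tree: Phylogeny, P: dict[int, np.ndarray],
              tip_idx: dict[int, int], k: int) -> np.ndarray:
    """Postorder conditional likelihoods L[node, state] (Felsenstein)."""
    L = np.zeros((len(tree.nodes), k))
    for n in tree.nodes:  # postorder
        if n.is_tip:
            L[n.index, tip_idx[n.index]] = 1.0
        else:
            vals = np.ones(k)
            for c in n.children:
                vals = vals * (P[c.index] @ L[c.index])
            L[n.index] = vals
    return L


def mk_loglik(tree: Phylogeny, tip_states: Mapping[str, str],
              structure: str, rates: Sequence[float],
              root_prior="stationary",
              states: Sequence[str] | None = None) -> float:
    """Pruning log-likelihood of tip states under an Mk model."""
    if states is None:
        states = sorted({str(v) for v in tip_states.values()})
    k = len(states)
    Q = build_rate_matrix(structure, rates, k)
    pi = _resolve_root_prior(root_prior, Q)
    tip_idx = _tip_state_indices(tree, tip_states, states)
    P = _branch_probs(tree, Q)
    L = _partials(tree, P, tip_idx, k)
    lik = float(pi @ L[tree.root.index])
    if lik <= 0:
        return -math.inf
    return math.log(lik)


@dataclass
class MkFit:
    """A fitted Mk model."""

    states: tuple[str, ...]
    structure: str
    rates: np.ndarray
    loglik: float
    aicc: float
    root_prior: np.ndarray
    root_prior_kind: str
    n_tips: int

    @property
    def Q(self) -> np.ndarray:
        return build_rate_matrix(self.structure, self.rates, len(self.states))

    def to_dict(self) -> dict:
        return {"states": list(self.states), "structure": self.structure,
                "rates": [float(r) for r in self.rates],
                "loglik": self.loglik, "aicc": self.aicc,
                "root_prior": [float(p) for p in self.root_prior]}


def fit_mk(tree: Phylogeny, tip_states: Mapping[str, str],
           structure: str = "auto", root_prior: str = "stationary",
           n_starts: int = 3) -> MkFit:
    """ML fit of an Mk model; ``structure="auto"`` picks the lowest AICc
    among ER, SYM, and ARD.

    Rates are optimized on the log scale within ``[1e-8, 1e3]`` per unit
    tree height with multiple starting points.
    """
    observed = sorted({str(v) for v in tip_states.values()})
    if len(observed) < 2:
        raise PhyloError(f"degenerate character: single observed state "
                         f"{observed}")
    if structure == "auto":
        fits = [fit_mk(tree, tip_states, s, root_prior, n_starts)
                for s in STRUCTURES]
        return min(fits, key=lambda f: f.aicc)
    if structure not in STRUCTURES:
        raise PhyloError(f"unknown rate structure {structure!r}")

    k = len(observed)
    m = n_free_rates(structure, k)
    tip_idx = _tip_state_indices(tree, tip_states, observed)
    lo, hi = math.log(RATE_BOUNDS[0]), math.log(RATE_BOUNDS[1])

    def neg_loglik(logr):
        rates = np.exp(logr)
        Q = build_rate_matrix(structure, rates, k)
        pi = _resolve_root_prior(root_prior, Q)
        P = _branch_probs(tree, Q)
        L = _partials(tree, P, tip_idx, k)
        lik = float(pi @ L[tree.root.index])
        return math.inf if lik <= 0 else -math.log(lik)

    # crude scale guess: transitions per unit height
    height = max(tree.height(), 1e-9)
    starts = [math.log(x / height) for x in (0.2, 1.0, 5.0)][:max(n_starts, 1)]
    best = None
    for s0 in starts:
        r = minimize(neg_loglik, np.full(m, s0), method="L-BFGS-B",
                     bounds=[(lo, hi)] * m)
        if best is None or r.fun < best.fun:
            best = r
    if best is None or not np.isfinite(best.fun):
        raise PhyloError("Mk optimization failed: "
                         + (best.message if best is not None else "no result"))
    rates = np.exp(best.x)
    lnl = -float(best.fun)
    Q = build_rate_matrix(structure, rates, k)
    return MkFit(states=tuple(observed), structure=structure, rates=rates,
                 loglik=lnl, aicc=_aicc(lnl, m, tree.n_tips),
                 root_prior=_resolve_root_prior(root_prior, Q),
                 root_prior_kind=root_prior, n_tips=tree.n_tips)


# ----------------------------------------------------------------------
# ancestral states
# ----------------------------------------------------------------------

@dataclass
class AncestralStates:
    """Marginal posteriors and MAP labels for every node."""

    marginals: pd.DataFrame          # rows: node index; columns: states
    map_states: dict[int, str]       # node index -> MAP label

    def node_state_map(self) -> dict[int, str]:
        return dict(self.map_states)


def ancestral_states(fit: MkFit, tree: Phylogeny,
                     tip_states: Mapping[str, str]) -> AncestralStates:
    """Marginal ancestral-state posteriors by inside-outside passes.

    MAP labels break ties lexicographically (and tips keep their observed
    state).  Marginals sum to one per node.
    """
    states = fit.states
    k = len(states)
    Q = fit.Q
    pi = fit.root_prior
    tip_idx = _tip_state_indices(tree, tip_states, states)
    P = _branch_probs(tree, Q)
    L = _partials(tree, P, tip_idx, k)

    # outside pass, preorder
    out = np.zeros((len(tree.nodes), k))
    out[tree.root.index] = pi
    order = [n for n in reversed(tree.nodes)]  # preorder-ish (root first)
    for n in order:
        if n.is_tip:
            continue
        msgs = {c.index: P[c.index] @ L[c.index] for c in n.children}
        for c in n.children:
            sib = np.ones(k)
            for b in n.children:
                if b is not c:
                    sib = sib * msgs[b.index]
            out[c.index] = (out[n.index] * sib) @ P[c.index]

    joint = out * L
    norm = joint.sum(axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    marg = joint / norm
    map_states = {}
    tie_logged = False
    for n in tree.nodes:
        if n.is_tip:
            map_states[n.index] = states[tip_idx[n.index]]
            continue
        row = marg[n.index]
        top = row.max()
        winners = [states[i] for i in range(k) if np.isclose(row[i], top)]
        if len(winners) > 1 and not tie_logged:
            warnings.warn("MAP tie at one or more nodes; broken "
                          "lexicographically", stacklevel=2)
            tie_logged = True
        map_states[n.index] = min(winners)
    return AncestralStates(
        marginals=pd.DataFrame(marg, columns=list(states)),
        map_states=map_states)


# ----------------------------------------------------------------------
# stochastic character mapping
# ----------------------------------------------------------------------

@dataclass
class SimmapSample:
    """One regime history drawn from the posterior given the tip data."""

    painting: RegimePainting
    node_states: dict[int, str]


def _sample_joint_states(tree: Phylogeny, P, L, pi, rng) -> dict[int, int]:
    """Sample node states jointly from P(states | tips) top-down."""
    idx: dict[int, int] = {}
    root = tree.root
    p = pi * L[root.index]
    p = p / p.sum()
    idx[root.index] = int(rng.choice(len(p), p=p))
    for n in reversed(tree.nodes):  # root first
        if n.index not in idx:
            continue
        for c in n.children:
            w = P[c.index][idx[n.index]] * L[c.index]
            w = w / w.sum()
            idx[c.index] = int(rng.choice(len(w), p=w))
    return idx


def _sample_branch_path(Q: np.ndarray, a: int, b: int, t: float,
                        rng, max_jumps: int = 1000) -> list[tuple[int, float]]:
    """Endpoint-conditioned CTMC path on [0, t] by uniformization.

    Returns ``(state, duration)`` segments from the parent end (state ``a``)
    to the child end (state ``b``); durations sum to ``t``.
    """
    if t <= 0:
        return [(b, 0.0)]
    k = Q.shape[0]
    mu = float(np.max(-np.diag(Q)))
    if mu <= 0:  # no movement possible
        return [(a, t)]
    R = np.eye(k) + Q / mu
    Pt = expm(Q * t)
    p_ab = Pt[a, b]
    if p_ab <= 0:
        raise PhyloError("impossible endpoint combination on branch")
    # sample the number of uniformized jumps
    u = rng.random()
    cum = 0.0
    Rpow = [np.eye(k)]
    n_jumps = None
    log_poisson = -mu * t
    poisson = math.exp(log_poisson)
    for n in range(max_jumps + 1):
        while len(Rpow) <= n:
            Rpow.append(Rpow[-1] @ R)
        term = poisson * Rpow[n][a, b] / p_ab
        cum += term
        if u <= cum:
            n_jumps = n
            break
        poisson *= mu * t / (n + 1)
    if n_jumps is None:
        n_jumps = max_jumps
    if n_jumps == 0:
        return [(a, t)]
    # jump-chain states conditioned on both endpoints
    while len(Rpow) <= n_jumps:
        Rpow.append(Rpow[-1] @ R)
    seq = [a]
    for i in range(1, n_jumps):
        prev = seq[-1]
        w = R[prev] * Rpow[n_jumps - i][:, b]
        total = w.sum()
        if total <= 0:
            w = R[prev].copy()
            total = w.sum()
        seq.append(int(rng.choice(k, p=w / total)))
    seq.append(b)
    times = np.sort(rng.random(n_jumps)) * t
    # build segments, dropping virtual (self) jumps
    segs: list[tuple[int, float]] = []
    prev_t = 0.0
    cur = a
    for st, tm in zip(seq[1:], times):
        if st != cur:
            segs.append((cur, tm - prev_t))
            prev_t = tm
            cur = st
    segs.append((cur, t - prev_t))
    if cur != b:  # should not happen
        raise PhyloError("uniformization path failed to hit endpoint")
    return segs


def stochastic_maps(fit: MkFit, tree: Phylogeny,
                    tip_states: Mapping[str, str], n_maps: int,
                    seed: int | np.random.Generator = 0) -> list[SimmapSample]:
    """Draw stochastic character maps under a fitted Mk model.

    Node states are sampled jointly from their conditional distribution
    given the tips; within-branch histories are endpoint-conditioned via
    uniformization.  Reproducible under a fixed seed.
    """
    if n_maps < 1:
        raise PhyloError("n_maps must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    states = fit.states
    Q = fit.Q
    tip_idx = _tip_state_indices(tree, tip_states, states)
    P = _branch_probs(tree, Q)
    L = _partials(tree, P, tip_idx, len(states))
    samples = []
    for _ in range(n_maps):
        node_idx = _sample_joint_states(tree, P, L, fit.root_prior, rng)
        segments = {}
        for n in tree.nodes:
            if n is tree.root:
                continue
            path = _sample_branch_path(Q, node_idx[n.parent.index],
                                       node_idx[n.index], n.length, rng)
            segments[n.index] = [(states[s], l) for s, l in path]
        painting = RegimePainting(segments, tuple(states))
        node_states = {i: states[s] for i, s in node_idx.items()}
        samples.append(SimmapSample(painting=painting,
                                    node_states=node_states))
    return samples


def map_painting(fit: MkFit, tree: Phylogeny,
                 tip_states: Mapping[str, str]) -> RegimePainting:
    """Painting from MAP ancestral states (child-state edge convention)."""
    anc = ancestral_states(fit, tree, tip_states)
    return paint_from_node_states(tree, anc.node_state_map())
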