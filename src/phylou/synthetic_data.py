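"""Simulators for trees, regimes, predictors, and responses.

These generate data with exactly the statistical structure the fitting
machinery assumes, and double as the Monte-Carlo oracle certifying the
analytic residual covariance in :mod:`phylou.ou_engine`.  All draws come
from a single :class:`numpy.random.Generator`, so a bundle regenerated with
the same seed is identical.

The response simulator uses exact branch-wise updating whenever the optimum
depends only on the painted regime, and fine-step Euler-Maruyama (with
Brownian-bridge interpolation of the predictor between node values) when the
optimum tracks a Brownian predictor.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .phylo_io import (Node, Phylogeny, PhyloError, RegimePainting,
                       SpeciesTable, bin_group_size, cross_paintings)
from .ou_engine import LN2, rho_factor

__all__ = ["ResponseConfig", "SimConfig", "SimBundle", "simulate_tree",
           "simulate_bm", "simulate_discrete", "simulate_response",
           "add_observation_error", "generate_study_like"]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


# ----------------------------------------------------------------------
# trees
# ----------------------------------------------------------------------

def simulate_tree(n_tips: int, seed=0) -> Phylogeny:
    """Pure-birth (Yule) tree conditioned on ``n_tips``, scaled to unit
    height; the raw height is kept as ``original_height``.

    The root splits at time zero; thereafter each of the k extant lineages
    splits at rate 1, and the tree is cut one exponential(n) waiting time
    after the last split.
    """
    if n_tips < 2:
        raise PhyloError("need at least 2 tips")
    rng = _rng(seed)
    root = Node()
    birth: dict[int, float] = {}
    active: list[Node] = []
    t = 0.0
    for _ in range(2):
        c = Node()
        root.children.append(c)
        active.append(c)
        birth[id(c)] = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        parent = active.pop(i)
        parent.length = t - birth[id(parent)]
        for _ in range(2):
            c = Node()
            parent.children.append(c)
            active.append(c)
            birth[id(c)] = t
    t_end = t + rng.exponential(1.0 / n_tips)
    for k, tip in enumerate(active):
        tip.length = t_end - birth[id(tip)]
        tip.label = f"t{k + 1}"
    raw = Phylogeny(root)
    for n in raw.nodes:
        if n is not raw.root:
            n.length /= t_end
    return Phylogeny(raw.root, original_height=t_end, scaled=True)


# ----------------------------------------------------------------------
# Brownian predictors
# ----------------------------------------------------------------------

def simulate_bm(tree: Phylogeny, sigma2: float, root: float, seed=0,
                size: int | None = None, return_nodes: bool = False):
    """Brownian motion on the tree: Gaussian increments with variance
    ``sigma2 * branch length``.

    Returns tip values as a Series (or a replicates-by-tips DataFrame when
    ``size`` is given); with ``return_nodes=True``, a dict mapping node
    index to value array instead.
    """
    if sigma2 < 0:
        raise PhyloError("sigma2 must be >= 0")
    rng = _rng(seed)
    m = 1 if size is None else int(size)
    vals: dict[int, np.ndarray] = {tree.root.index: np.full(m, float(root))}
    for n in reversed(tree.nodes):  # root first
        if n is tree.root:
            continue
        sd = math.sqrt(sigma2 * n.length)
        vals[n.index] = vals[n.parent.index] + rng.normal(0.0, sd, size=m) \
            if sd > 0 else vals[n.parent.index].copy()
    if return_nodes:
        return vals if size is not None else \
            {i: float(v[0]) for i, v in vals.items()}
    tips = np.column_stack([vals[t.index] for t in tree.tips])
    if size is None:
        return pd.Series(tips[0], index=tree.tip_labels)
    return pd.DataFrame(tips, columns=tree.tip_labels)


# ----------------------------------------------------------------------
# discrete characters
# ----------------------------------------------------------------------

def simulate_discrete(tree: Phylogeny, Q: np.ndarray,
                      states: Sequence[str], seed=0):
    """Gillespie simulation of a CTMC along every branch.

    The root state is drawn from the stationary distribution of ``Q``.
    Returns ``(tip_states, painting, node_states)`` where the painting is
    the true history.
    """
    from .mk_regimes import stationary_distribution

    rng = _rng(seed)
    Q = np.asarray(Q, float)
    k = Q.shape[0]
    if len(states) != k:
        raise PhyloError("states/Q size mismatch")
    pi = stationary_distribution(Q)
    node_state: dict[int, int] = {
        tree.root.index: int(rng.choice(k, p=pi))}
    segments: dict[int, list[tuple[str, float]]] = {}
    for n in reversed(tree.nodes):  # root first
        if n is tree.root:
            continue
        s = node_state[n.parent.index]
        remaining = n.length
        segs: list[tuple[str, float]] = []
        elapsed = 0.0
        while True:
            rate = -Q[s, s]
            if rate <= 0:
                break
            w = rng.exponential(1.0 / rate)
            if elapsed + w >= remaining:
                break
            elapsed += w
            segs.append((states[s], w))
            probs = Q[s].clip(min=0.0)
            probs[s] = 0.0
            probs = probs / probs.sum()
            s = int(rng.choice(k, p=probs))
        segs.append((states[s], remaining - elapsed))
        segments[n.index] = segs
        node_state[n.index] = s
    painting = RegimePainting(segments, tuple(states))
    tip_states = {t.label: states[node_state[t.index]] for t in tree.tips}
    node_states = {i: states[s] for i, s in node_state.items()}
    return tip_states, painting, node_states


# ----------------------------------------------------------------------
# response
# ----------------------------------------------------------------------

@dataclass
class ResponseConfig:
    """Generating parameters of the response process.

    ``t_half`` may be ``inf`` for the trend model, in which case
    ``regime_values`` are drift rates per unit tree height and ``v_y`` is
    the Brownian diffusion variance.  ``bm_slope`` is the optimal slope on
    the Brownian predictor for finite half-life, or the drift per unit of
    the predictor in the trend limit; ``direct_slope`` transfers changes of
    the direct predictor into the response instantaneously.
    """

    t_half: float = 1.0
    v_y: float = 0.1
    regime_values: dict[str, float] = field(default_factory=dict)
    direct_slope: float = 0.0
    bm_slope: float = 0.0
    root_value: float = 0.0
    euler_step: float = 1e-3

    @property
    def alpha(self) -> float:
        return 0.0 if math.isinf(self.t_half) else LN2 / self.t_half

    def evolutionary_slope(self, T: float = 1.0) -> float:
        """Slope of the response on the observed predictor implied by
        ``bm_slope`` (rho-attenuated for finite half-life)."""
        if self.bm_slope == 0:
            return 0.0
        if math.isinf(self.t_half):
            return self.bm_slope * T / 2.0
        return self.bm_slope * rho_factor(self.alpha, T)


def simulate_response(tree: Phylogeny, painting: RegimePainting,
                      config: ResponseConfig, seed=0,
                      x_nodes: Mapping[int, np.ndarray] | None = None,
                      g_nodes: Mapping[int, np.ndarray] | None = None,
                      g_sigma2: float | None = None,
                      size: int | None = None):
    """Simulate tip values of the response under the OU/trend model.

    With ``bm_slope == 0`` the process is advanced exactly segment by
    segment (the optimum is constant within a painted segment).  With a
    Brownian-predictor effect, the predictor path within each branch is a
    Brownian bridge between the supplied node values and the response is
    advanced by Euler-Maruyama with step ``config.euler_step``.

    Returns a Series (or replicates-by-tips DataFrame when ``size`` is
    given).  The direct effect adds ``direct_slope * (x_tip - x_root)``.
    """
    rng = _rng(seed)
    m = 1 if size is None else int(size)
    alpha = config.alpha
    trend = math.isinf(config.t_half)
    exact = config.bm_slope == 0
    if not exact and (g_nodes is None or g_sigma2 is None):
        raise PhyloError("bm_slope != 0 requires g_nodes and g_sigma2")

    def regval(regime: str) -> float:
        try:
            return float(config.regime_values[regime])
        except KeyError:
            raise PhyloError(f"no regime value for {regime!r}") from None

    def as_arr(v) -> np.ndarray:
        a = np.asarray(v, float)
        return np.full(m, float(a)) if a.ndim == 0 else a

    u: dict[int, np.ndarray] = {tree.root.index: np.full(m, config.root_value)}
    for n in reversed(tree.nodes):  # root first
        if n is tree.root:
            continue
        val = u[n.parent.index].copy()
        if exact:
            for regime, length in painting.segments[n.index]:
                if length <= 0:
                    continue
                theta = regval(regime)
                if trend:
                    val = val + theta * length \
                        + rng.normal(0.0, math.sqrt(config.v_y * length),
                                     size=m)
                else:
                    decay = math.exp(-alpha * length)
                    sd = math.sqrt(config.v_y * (1.0 - decay * decay))
                    val = val * decay + theta * (1.0 - decay) \
                        + rng.normal(0.0, sd, size=m)
        else:
            gp = as_arr(g_nodes[n.parent.index])
            gc = as_arr(g_nodes[n.index])
            length = n.length
            nsteps = max(1, int(math.ceil(length / config.euler_step)))
            dt = length / nsteps
            sigma_y = (math.sqrt(config.v_y) if trend
                       else math.sqrt(2.0 * alpha * config.v_y))
            z = gp.copy()
            elapsed = 0.0
            segs = painting.segments[n.index]
            seg_ends = np.cumsum([l for _, l in segs])
            si = 0
            for j in range(nsteps):
                while si < len(segs) - 1 and elapsed >= seg_ends[si] - 1e-12:
                    si += 1
                theta_r = regval(segs[si][0])
                if trend:
                    val = val + (theta_r + config.bm_slope * z) * dt \
                        + sigma_y * math.sqrt(dt) * rng.normal(size=m)
                else:
                    target = theta_r + config.bm_slope * z
                    val = val + (-alpha * (val - target)) * dt \
                        + sigma_y * math.sqrt(dt) * rng.normal(size=m)
                # exact Brownian-bridge step for the predictor
                rem = length - elapsed
                mean = z + (gc - z) * (dt / rem)
                bvar = g_sigma2 * dt * max(rem - dt, 0.0) / rem
                z = mean + (math.sqrt(bvar) * rng.normal(size=m)
                            if bvar > 0 else 0.0)
                elapsed += dt
        u[n.index] = val
    tips = np.column_stack([u[t.index] for t in tree.tips])
    if config.direct_slope != 0:
        if x_nodes is None:
            raise PhyloError("direct_slope != 0 requires x_nodes")
        x_root = as_arr(x_nodes[tree.root.index])
        x_tips = np.column_stack(
            [as_arr(x_nodes[t.index]) for t in tree.tips])
        tips = tips + config.direct_slope * (x_tips - x_root[:, None])
    if size is None:
        return pd.Series(tips[0], index=tree.tip_labels)
    return pd.DataFrame(tips, columns=tree.tip_labels)


# ----------------------------------------------------------------------
# observation error
# ----------------------------------------------------------------------

def add_observation_error(true_values: pd.Series,
                          n_per_species,
                          within_sd,
                          seed=0) -> tuple[pd.Series, pd.Series]:
    """Species-mean observation error from per-species sample sizes.

    Each observed mean is the average of ``n`` independent draws around the
    truth with standard deviation ``within_sd`` (drawn as a single Gaussian
    with sd ``within_sd / sqrt(n)``, which is the same distribution); the
    reported observation variance is the squared standard error
    ``within_sd**2 / n``.
    """
    rng = _rng(seed)
    idx = true_values.index
    n = pd.Series(n_per_species, index=idx) if np.isscalar(n_per_species) \
        else pd.Series(np.asarray(n_per_species), index=idx)
    sd = pd.Series(within_sd, index=idx) if np.isscalar(within_sd) \
        else pd.Series(np.asarray(within_sd), index=idx)
    if (n < 1).any():
        raise PhyloError("sample sizes must be >= 1")
    if (sd < 0).any():
        raise PhyloError("within-species SD must be >= 0")
    se = sd / np.sqrt(n.astype(float))
    observed = true_values + rng.normal(0.0, 1.0, size=len(idx)) * se
    return observed, se ** 2


# ----------------------------------------------------------------------
# study-like bundles
# ----------------------------------------------------------------------

@dataclass
class SimConfig:
    """Full generating configuration for a study-like bundle."""

    n_tips: int = 128
    seed: int = 0
    mk_factors: dict = field(default_factory=dict)   # name -> {states, q}
    bm_traits: dict = field(default_factory=dict)    # name -> {sigma2, root}
    response: ResponseConfig = field(default_factory=ResponseConfig)
    response_regime_factors: tuple[str, ...] = ()
    direct_trait: str = "log_mass"
    bm_trait: str = "log_group_size"
    n_obs_range: tuple[int, int] = (1, 30)
    within_sd_response: float = 0.15
    within_sd_direct: float = 0.1
    #: start the response at the optimum of the root's regime, matching the
    #: estimator's ancestral-state absorption (avoids a mean mismatch that
    #: would masquerade as faster adaptation)
    root_at_optimum: bool = True


@dataclass
class SimBundle:
    """A simulated dataset plus everything used to generate it."""

    tree: Phylogeny
    paintings: dict[str, RegimePainting]
    node_states: dict[str, dict[int, str]]
    table: SpeciesTable
    config: SimConfig
    true_values: dict[str, pd.Series] = field(default_factory=dict)

    def write(self, outdir: str | os.PathLike) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.tree.write(os.path.join(outdir, "tree.nwk"))
        for name, p in self.paintings.items():
            with open(os.path.join(outdir, f"painting_{name}.simmap.nwk"),
                      "w") as fh:
                fh.write(p.to_simmap_newick(self.tree) + "\n")
            p.to_edge_table(self.tree).to_csv(
                os.path.join(outdir, f"painting_{name}.csv"), index=False)
        self.table.to_csv(os.path.join(outdir, "data.csv"))
        cfg = asdict(self.config)
        cfg["response"]["t_half"] = (
            "inf" if math.isinf(self.config.response.t_half)
            else self.config.response.t_half)
        with open(os.path.join(outdir, "config.yaml"), "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)


_PRESET_MATING = ("harem_polygyny", "monogamy", "polyandry",
                  "polygynandry", "spatial_polygyny")
_PRESET_SOCIAL = ("solitary", "pair_living", "unimale", "multimale")

_MATING_EFFECT = {"harem_polygyny": 0.5, "monogamy": 0.3, "polyandry": -0.8,
                  "polygynandry": 0.9, "spatial_polygyny": 0.0}


def _preset_primate(n_tips: int, seed: int) -> SimConfig:
    # half-life 2.63 tree heights, Vy 0.18, direct slope 0.56, and
    # an evolutionary group-size slope of about -0.04; regime optima are
    # scaled so the implied trends (alpha * theta contrasts) are of order
    # 1 log unit per tree height
    t_half = 2.63
    alpha = LN2 / t_half
    diet = ("folivorous", "nonfolivorous")
    regime_values = {}
    for d in diet:
        for ms in _PRESET_MATING:
            trend = -1.1 + _MATING_EFFECT[ms]
            if d == "folivorous":
                trend -= 0.8
            regime_values[f"{d}:{ms}"] = trend / alpha
    return SimConfig(
        n_tips=n_tips, seed=seed,
        mk_factors={
            "diet": {"states": diet, "q": 0.5},
            "mating_system": {"states": _PRESET_MATING, "q": 0.5},
            "activity_period": {"states": ("diurnal", "nocturnal"),
                                "q": 0.3},
            "social_system": {"states": _PRESET_SOCIAL, "q": 0.4},
        },
        bm_traits={"log_mass": {"sigma2": 1.0, "root": 8.0},
                   "log_group_size": {"sigma2": 1.5, "root": 1.5}},
        response=ResponseConfig(t_half=t_half, v_y=0.18,
                                regime_values=regime_values,
                                direct_slope=0.56, bm_slope=-0.33,
                                root_value=3.4),
        response_regime_factors=("diet", "mating_system"),
    )


def generate_study_like(preset: str = "primate", n_tips: int = 128,
                        seed: int = 0,
                        config: SimConfig | None = None) -> SimBundle:
    """Generate a bundle emulating the structure of the study data:
    crossed discrete factors, Brownian body mass and group size, an OU
    response with a direct body-mass effect, and species-mean observation
    error from per-species sample sizes.
    """
    if config is None:
        if preset != "primate":
            raise PhyloError(f"unknown preset {preset!r}")
        config = _preset_primate(n_tips, seed)
    rng = _rng(config.seed if config.seed is not None else seed)
    tree = simulate_tree(config.n_tips, rng)
    paintings: dict[str, RegimePainting] = {}
    node_states: dict[str, dict[int, str]] = {}
    tip_state_cols: dict[str, dict[str, str]] = {}
    for name, fac in config.mk_factors.items():
        states = tuple(fac["states"])
        k = len(states)
        q = float(fac["q"])
        Q = np.full((k, k), q)
        np.fill_diagonal(Q, -(k - 1) * q)
        tips, painting, nstates = simulate_discrete(tree, Q, states, rng)
        paintings[name] = painting
        node_states[name] = nstates
        tip_state_cols[name] = tips
    combined = None
    for name in config.response_regime_factors:
        combined = paintings[name] if combined is None else \
            cross_paintings(combined, paintings[name], tree)
    if combined is not None:
        paintings["+".join(config.response_regime_factors)] = combined
        if config.root_at_optimum:
            root_state = ":".join(
                node_states[f][tree.root.index]
                for f in config.response_regime_factors)
            config.response.root_value = \
                config.response.regime_values[root_state]

    bm_nodes = {}
    for name, tr in config.bm_traits.items():
        bm_nodes[name] = simulate_bm(tree, tr["sigma2"], tr["root"], rng,
                                     return_nodes=True)
    x_nodes = bm_nodes.get(config.direct_trait)
    g_nodes = bm_nodes.get(config.bm_trait)
    g_sigma2 = config.bm_traits.get(config.bm_trait, {}).get("sigma2")
    y_true = simulate_response(
        tree, combined, config.response, rng,
        x_nodes=x_nodes, g_nodes=g_nodes, g_sigma2=g_sigma2)

    x_true = pd.Series({t.label: x_nodes[t.index] for t in tree.tips}) \
        if x_nodes else None
    g_tips = pd.Series({t.label: g_nodes[t.index] for t in tree.tips}) \
        if g_nodes else None

    n_obs = pd.Series(
        rng.integers(config.n_obs_range[0], config.n_obs_range[1] + 1,
                     size=tree.n_tips), index=tree.tip_labels)
    y_obs, y_var = add_observation_error(
        y_true, n_obs, config.within_sd_response, rng)
    x_obs, x_var = add_observation_error(
        x_true, n_obs, config.within_sd_direct, rng)

    diet_tip = tip_state_cols.get("diet", {})
    rows = []
    for lb in tree.tip_labels:
        d = diet_tip.get(lb, "nonfolivorous")
        if d == "folivorous":
            veg = rng.uniform(45, 75)
            rest = 100 - veg
            shares = rng.dirichlet([2, 2, 1])
            fauna, repro, exud = shares * rest
        else:
            repro = rng.uniform(45, 75)
            rest = 100 - repro
            shares = rng.dirichlet([2, 2, 1])
            fauna, veg, exud = shares * rest
        rows.append({
            "species": lb,
            "log_ecv": float(y_obs[lb]), "log_ecv_var": float(y_var[lb]),
            "log_mass": float(x_obs[lb]), "log_mass_var": float(x_var[lb]),
            "log_group_size": float(g_tips[lb]) if g_tips is not None
            else np.nan,
            "pct_fauna": float(fauna), "pct_plant_repro": float(repro),
            "pct_plant_veg": float(veg), "pct_exudate": float(exud),
            "mating_system": tip_state_cols["mating_system"][lb],
            "social_system": tip_state_cols["social_system"][lb],
            "activity_period": tip_state_cols["activity_period"][lb],
            "strict_folivore": bool(d == "folivorous"
                                    and rng.random() < 0.7),
            "n_observations": int(n_obs[lb]),
        })
    df = pd.DataFrame(rows)
    df["group_size_category"] = [bin_group_size(math.exp(g))
                                 for g in df["log_group_size"]]
    table = SpeciesTable(df)
    return SimBundle(tree=tree, paintings=paintings, node_states=node_states,
                     table=table, config=config,
                     true_values={"log_ecv": y_true, "log_mass": x_true,
                                  "log_group_size": g_tips})
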