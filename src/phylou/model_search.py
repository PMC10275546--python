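"""Exhaustive AICc model search over admissible predictor combinations.

Candidate predictors are enumerated as subsets of a pool, minus any subset
containing two or more members of an exclusion set (mutually incompatible
predictors, e.g. alternative codings of sociality).  Every candidate keeps
the direct-effect body-mass term, and the allometric-only baseline (the
empty subset) is always included.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .phylo_io import Phylogeny, PhyloError, RegimePainting, SpeciesTable
from .ou_engine import (FitResult, GridConfig, ModelSpec, model_metrics,
                        profile_fit)

__all__ = ["SearchPlan", "enumerate_models", "build_specs", "rank_models",
           "run_search"]


@dataclass
class SearchPlan:
    pool: tuple[str, ...]
    exclusions: tuple[frozenset, ...]
    subsets: list[tuple[str, ...]]


def enumerate_models(pool: Sequence[str],
                     exclusions: Iterable[Iterable[str]] = ()) -> SearchPlan:
    """All subsets of the pool minus those hitting an exclusion set.

    A subset is excluded when it contains two or more members of any single
    exclusion set.  The empty subset (allometric baseline) is always first;
    enumeration order is deterministic (by size, then lexicographic).
    """
    if not pool:
        raise PhyloError("empty predictor pool")
    if len(set(pool)) != len(pool):
        raise PhyloError("duplicate predictors in pool")
    excl = []
    for ex in exclusions:
        ex = list(ex)
        if len(ex) != len(set(ex)):
            raise PhyloError(f"contradictory exclusion set {ex}: "
                             "a predictor cannot be excluded with itself")
        if len(ex) < 2:
            raise PhyloError(f"exclusion set needs >= 2 members: {ex}")
        excl.append(frozenset(ex))
    items = sorted(pool)
    subsets = []
    for r in range(len(items) + 1):
        for combo in combinations(items, r):
            cs = set(combo)
            if any(len(cs & ex) >= 2 for ex in excl):
                continue
            subsets.append(tuple(combo))
    return SearchPlan(pool=tuple(items), exclusions=tuple(excl),
                      subsets=subsets)


def build_specs(plan: SearchPlan,
                regime_paintings: Mapping[str, RegimePainting],
                bm_columns: Sequence[str] = (),
                response: str = "log_ecv",
                direct: Sequence[str] = ("log_mass",)) -> list[ModelSpec]:
    """Turn enumerated subsets into fittable ModelSpecs.

    Pool members that have a painting become regime factors (crossed
    automatically when several appear together); members listed in
    ``bm_columns`` become Brownian predictors.
    """
    specs = []
    for subset in plan.subsets:
        regimes = {}
        bm = []
        for name in subset:
            if name in regime_paintings:
                regimes[name] = regime_paintings[name]
            elif name in bm_columns:
                bm.append(name)
            else:
                raise PhyloError(f"pool member {name!r} has neither a "
                                 f"painting nor a bm column")
        specs.append(ModelSpec(response=response, direct=tuple(direct),
                               bm=tuple(bm), regimes=regimes,
                               name=" + ".join(subset) if subset
                               else "allometric"))
    return specs


def rank_models(fits: Sequence[FitResult],
                baseline: FitResult | None = None) -> pd.DataFrame:
    """AICc ranking table, ascending; ties broken by fewer parameters.

    Delta columns are reported both against the best model and against the
    allometric-only baseline (taken as the fit named "allometric" if not
    given explicitly).
    """
    if not fits:
        raise PhyloError("no fits to rank")
    if baseline is None:
        named = [f for f in fits if f.spec.name == "allometric"]
        baseline = named[0] if named else None
    rows = []
    for f in fits:
        row = {"model": f.spec.name, "kind": f.kind, "k": f.k, "n": f.n,
               "loglik": f.loglik, "aicc": f.aicc,
               "t_half": f.t_half, "v_y": f.v_y,
               "r_squared": f.r_squared}
        if baseline is not None and f.n == baseline.n:
            m = model_metrics(f, baseline)
            row["residual_r_squared"] = m["residual_r_squared"]
            row["delta_aicc_baseline"] = m["delta_aicc"]
        rows.append(row)
    out = pd.DataFrame(rows).sort_values(
        ["aicc", "k", "model"], kind="mergesort").reset_index(drop=True)
    out["delta_aicc_best"] = out["aicc"] - out["aicc"].iloc[0]
    return out


def run_search(tree: Phylogeny, table: SpeciesTable,
               plan: SearchPlan,
               regime_paintings: Mapping[str, RegimePainting],
               bm_columns: Sequence[str] = (),
               response: str = "log_ecv",
               direct: Sequence[str] = ("log_mass",),
               grid: GridConfig | None = None):
    """Fit every admissible model and rank by AICc.

    Returns ``(table, fits)``; models whose design is aliased on the given
    paintings are flagged in the table rather than fitted.
    """
    specs = build_specs(plan, regime_paintings, bm_columns, response, direct)
    fits, failed = [], []
    for spec in specs:
        try:
            fits.append(profile_fit(spec, tree, table, grid))
        except Exception as exc:  # aliased/degenerate candidates are flagged
            failed.append({"model": spec.name, "error": str(exc)})
    ranked = rank_models(fits)
    if failed:
        ranked.attrs["failed"] = failed
    return ranked, fits
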