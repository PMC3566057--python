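"""Disparity through time (DTT) and the morphological disparity index (MDI).

The observed curve plots, against relative node age (root = 0, tips = 1),
the average relative disparity of the lineages alive just after each node:
each lineage crossing that time contributes the disparity of its terminal
descendants divided by the disparity of the whole tree. The curve starts at
1 at the root and is anchored at 0 at the tips.

Disparity of a set of taxa is the mean squared pairwise difference of their
trait values (mean absolute difference available as an option). The null
model is unconstrained Brownian motion on the same tree at the ML rate of
the observed data; MDI is the signed area between the observed curve and
the pointwise median of the null curves — positive when disparity is
concentrated within subclades (niche evolution), negative when it sits
among subclades (niche conservatism).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phylo import CladeMap, Phylogeny
from .niche_history import bm_ancestral_ml
from .pno import PNOProfile, pno_weighted_mean, sample_pno

__all__ = [
    "DTTCurve",
    "DTTNull",
    "MDIResult",
    "clade_disparity",
    "relative_disparity_curve",
    "simulate_bm_null",
    "mdi",
    "clade_dtt",
    "DisparityThroughTime",
    "DTTResults",
    "dtt_pipeline",
]


# -- disparity --------------------------------------------------------------

def _pairwise_disparity(X: np.ndarray, metric: str = "squared") -> np.ndarray:
    """Mean pairwise disparity along the last axis of a 2-D array.

    ``squared``: mean squared difference over unordered pairs, which equals
    twice the sample variance; ``absolute``: mean absolute difference.
    Columns of size 1 give 0.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[1]
    if n < 2:
        return np.zeros(X.shape[0])
    if metric == "squared":
        return 2.0 * X.var(axis=1, ddof=1)
    if metric == "absolute":
        # sorted-sum identity: sum_{i<j} (x_(j) - x_(i)) = sum_i (2i - n + 1) x_(i)
        S = np.sort(X, axis=1)
        coef = 2.0 * np.arange(n) - (n - 1)
        return (S @ coef) / (n * (n - 1) / 2.0)
    raise ValueError(f"unknown metric {metric!r}")


def clade_disparity(
    values: Mapping[str, float],
    taxa_subset: Sequence[str] | None = None,
    metric: str = "squared",
) -> float:
    """Disparity of a set of taxa; a single taxon has disparity 0."""
    if taxa_subset is None:
        taxa_subset = list(values)
    if len(taxa_subset) < 1:
        raise ValueError("need at least 1 taxon")
    unknown = [t for t in taxa_subset if t not in values]
    if unknown:
        raise KeyError(f"unknown taxa {unknown}")
    arr = np.array([float(values[t]) for t in taxa_subset])
    return float(_pairwise_disparity(arr[None, :], metric)[0])


# -- curve ------------------------------------------------------------------

@dataclass(frozen=True)
class DTTCurve:
    """Observed relative disparity vs relative time (root 0, tips 1)."""

    times: np.ndarray  # strictly increasing, [0, ..., 1]
    disparity: np.ndarray
    variable: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.disparity, dtype=float)
        if t.shape != d.shape or t.ndim != 1:
            raise ValueError("times/disparity shape mismatch")
        if not (np.diff(t) > 0).all():
            raise ValueError("times must be strictly increasing")


class _DTTStructure:
    """Tree-only part of the DTT computation, reusable across trait sets:
    relative node times and, per time, the tip-index sets of the lineages
    alive just after it."""

    def __init__(self, tree: Phylogeny):
        H = tree.height
        internal = tree.internal_nodes()
        heights = sorted({float(tree.heights[i]) for i in internal})
        if heights[0] != 0.0:
            raise AssertionError("root height must be 0")
        self.rel_times = np.array([h / H for h in heights] + [1.0])
        all_tips = np.arange(tree.n_tips)
        self.lineages: list[list[np.ndarray]] = [[all_tips]]
        non_root = [i for i in range(tree.n_nodes) if tree.parent[i] >= 0]
        for h in heights[1:]:
            crossing = [
                c
                for c in non_root
                if tree.heights[tree.parent[c]] <= h and tree.heights[c] > h
            ]
            self.lineages.append([tree.tips_below(c) for c in crossing])

    def curves(self, X: np.ndarray, metric: str = "squared") -> np.ndarray:
        """Relative-disparity curves for each row of tip values X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        total = _pairwise_disparity(X, metric)
        if (total <= 0).any():
            raise ValueError("degenerate trait: total disparity is zero")
        out = np.empty((X.shape[0], self.rel_times.size))
        out[:, 0] = 1.0
        for k, subsets in enumerate(self.lineages[1:], start=1):
            acc = np.zeros(X.shape[0])
            for idx in subsets:
                if idx.size > 1:
                    acc += _pairwise_disparity(X[:, idx], metric)
            out[:, k] = acc / (len(subsets) * total)
        out[:, -1] = 0.0
        return out


def relative_disparity_curve(
    tree: Phylogeny, tip_values, metric: str = "squared", variable: str = ""
) -> DTTCurve:
    """Observed DTT curve: 1 at the root, 0 at the tips.

    ``tip_values`` is a mapping label -> value or an array in tip order.
    All-equal tip values are an error ("degenerate trait").
    """
    x = _tip_array(tree, tip_values)
    structure = _DTTStructure(tree)
    vals = structure.curves(x[None, :], metric)[0]
    return DTTCurve(times=structure.rel_times, disparity=vals, variable=variable)


def _tip_array(tree: Phylogeny, tip_values) -> np.ndarray:
    if isinstance(tip_values, Mapping):
        missing = [l for l in tree.tip_labels if l not in tip_values]
        if missing:
            raise ValueError(f"missing tip values for {missing}")
        return np.array([float(tip_values[l]) for l in tree.tip_labels])
    arr = np.asarray(tip_values, dtype=float)
    if arr.shape != (tree.n_tips,):
        raise ValueError(f"expected {tree.n_tips} tip values")
    return arr


# -- null model -------------------------------------------------------------

@dataclass
class DTTNull:
    """Brownian-motion null: one curve per simulation plus pointwise median."""

    times: np.ndarray
    curves: np.ndarray  # (n_sim, n_times)
    sigma2: float

    @property
    def median(self) -> np.ndarray:
        return np.median(self.curves, axis=0)

    def quantile(self, q: float) -> np.ndarray:
        return np.quantile(self.curves, q, axis=0)


def _simulate_bm_tips(
    tree: Phylogeny, sigma2: float, z0: float, n_sim: int, rng: np.random.Generator
) -> np.ndarray:
    vals = np.zeros((tree.n_nodes, n_sim))
    vals[tree.root] = z0
    for i in tree.preorder():
        if i == tree.root:
            continue
        t = tree.branch_lengths[i]
        vals[i] = vals[tree.parent[i]] + rng.standard_normal(n_sim) * np.sqrt(
            sigma2 * t
        )
    return vals[: tree.n_tips].T  # (n_sim, n_tips)


def simulate_bm_null(
    tree: Phylogeny,
    tip_values,
    n_sim: int = 1000,
    seed: int | np.random.Generator = 0,
    metric: str = "squared",
) -> DTTNull:
    """Unconstrained BM null: rate and root estimated from the observed tips
    by ML, traits re-simulated on the same tree, curves evaluated at the
    observed node times."""
    if n_sim < 1:
        raise ValueError("n_sim must be at least 1")
    x = _tip_array(tree, tip_values)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate trait: total disparity is zero")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    _, params = bm_ancestral_ml(tree, x)
    structure = _DTTStructure(tree)
    X = _simulate_bm_tips(tree, params.sigma2, params.z0, n_sim, rng)
    # guard against the measure-zero event of a constant simulated dataset
    degenerate = np.isclose(X.var(axis=1), 0.0)
    while degenerate.any():
        X[degenerate] = _simulate_bm_tips(
            tree, params.sigma2, params.z0, int(degenerate.sum()), rng
        )
        degenerate = np.isclose(X.var(axis=1), 0.0)
    curves = structure.curves(X, metric)
    return DTTNull(times=structure.rel_times, curves=curves, sigma2=params.sigma2)


# -- MDI --------------------------------------------------------------------

@dataclass(frozen=True)
class MDIResult:
    """Signed area between observed and null-median DTT curves."""

    mdi: float
    scope: str = "all"
    variable: str = ""
    n_sim: int = 0


def mdi(
    observed_curve: DTTCurve,
    null_median_curve: np.ndarray | DTTNull,
    scope: str = "all",
    n_sim: int = 0,
) -> MDIResult:
    """Trapezoid integral over relative time of (observed - null median)."""
    if isinstance(null_median_curve, DTTNull):
        if not np.array_equal(observed_curve.times, null_median_curve.times):
            raise ValueError("observed and null curves are on different time grids")
        n_sim = null_median_curve.curves.shape[0]
        med = null_median_curve.median
    else:
        med = np.asarray(null_median_curve, dtype=float)
        if med.shape != observed_curve.times.shape:
            raise ValueError("observed and null curves are on different time grids")
    area = float(
        np.trapezoid(observed_curve.disparity - med, observed_curve.times)
    )
    return MDIResult(
        mdi=area, scope=scope, variable=observed_curve.variable, n_sim=n_sim
    )


# -- model object -----------------------------------------------------------

class DisparityThroughTime:
    """DTT analysis of one trait on a tree, optionally per clade.

    ``fit`` runs the observed curve, the BM null and the MDI for the whole
    tree and for each clade with at least ``min_clade_tips`` members
    (smaller clades are skipped with a warning).
    """

    def __init__(
        self,
        tree: Phylogeny,
        tip_values,
        clade_map: CladeMap | None = None,
        metric: str = "squared",
        variable: str = "",
    ):
        self.tree = tree
        self.tip_values = _tip_array(tree, tip_values)
        self.clade_map = clade_map
        if clade_map is not None:
            clade_map.validate(tree)
        self.metric = metric
        self.variable = variable

    def fit(
        self,
        n_sim: int = 1000,
        seed: int | np.random.Generator = 0,
        min_clade_tips: int = 3,
    ) -> "DTTResults":
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        observed = relative_disparity_curve(
            self.tree, self.tip_values, self.metric, variable=self.variable
        )
        null = simulate_bm_null(
            self.tree, self.tip_values, n_sim, rng, self.metric
        )
        overall = mdi(observed, null, scope="all")
        clade_results: dict[str, DTTResults] = {}
        if self.clade_map is not None:
            values = dict(zip(self.tree.tip_labels, self.tip_values))
            for clade in self.clade_map.clades:
                members = self.clade_map.members(clade)
                if len(members) < min_clade_tips:
                    warnings.warn(
                        f"clade {clade!r} has {len(members)} tips "
                        f"(< {min_clade_tips}); skipping its DTT",
                        stacklevel=2,
                    )
                    continue
                subtree = self.tree.extract(members)
                sub_values = np.array(
                    [values[l] for l in subtree.tip_labels]
                )
                sub = DisparityThroughTime(
                    subtree, sub_values, metric=self.metric, variable=self.variable
                )
                clade_results[clade] = sub.fit(n_sim=n_sim, seed=rng)
        return DTTResults(
            observed=observed,
            null=null,
            mdi_result=MDIResult(
                overall.mdi, scope="all", variable=self.variable, n_sim=n_sim
            ),
            clade_results=clade_results,
        )


@dataclass
class DTTResults:
    observed: DTTCurve
    null: DTTNull
    mdi_result: MDIResult
    clade_results: dict[str, "DTTResults"] = field(default_factory=dict)
    draw_mdis: np.ndarray | None = None  # per-PNO-draw MDIs ("draws" mode)

    @property
    def mdi(self) -> float:
        return self.mdi_result.mdi

    def mdi_table(self) -> pd.DataFrame:
        rows = [
            {
                "variable": self.mdi_result.variable,
                "scope": "all",
                "mdi": self.mdi,
                "n_sim": self.mdi_result.n_sim,
            }
        ]
        for clade, res in self.clade_results.items():
            rows.append(
                {
                    "variable": res.mdi_result.variable,
                    "scope": clade,
                    "mdi": res.mdi,
                    "n_sim": self.mdi_result.n_sim,
                }
            )
        return pd.DataFrame(rows)

    def curve_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.observed.times,
                "observed": self.observed.disparity,
                "null_median": self.null.median,
                "null_q05": self.null.quantile(0.05),
                "null_q95": self.null.quantile(0.95),
            }
        )

    def summary(self) -> str:
        lines = [
            f"Disparity through time: {self.mdi_result.variable or '<trait>'}",
            f"null simulations: {self.null.curves.shape[0]}   "
            f"BM rate: {self.null.sigma2:.6g}",
            f"MDI (all taxa): {self.mdi:+.4f}",
        ]
        for clade, res in self.clade_results.items():
            lines.append(f"MDI ({clade}): {res.mdi:+.4f}")
        return "\n".join(lines)


def clade_dtt(
    tree: Phylogeny,
    clade_map: CladeMap,
    tip_values,
    n_sim: int = 1000,
    seed: int | np.random.Generator = 0,
    metric: str = "squared",
    min_clade_tips: int = 3,
) -> dict[str, MDIResult]:
    """Per-clade MDI: each clade's subtree (re-rooted at its MRCA, branch
    lengths preserved, its own relative time scale) gets the full
    DTT + null + MDI treatment."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = (
        dict(tip_values)
        if isinstance(tip_values, Mapping)
        else dict(zip(tree.tip_labels, np.asarray(tip_values, dtype=float)))
    )
    clade_map.validate(tree)
    out: dict[str, MDIResult] = {}
    for clade in clade_map.clades:
        members = clade_map.members(clade)
        if len(members) < min_clade_tips:
            warnings.warn(
                f"clade {clade!r} has {len(members)} tips (< {min_clade_tips}); skipped",
                stacklevel=2,
            )
            continue
        subtree = tree.extract(members)
        sub_vals = np.array([values[l] for l in subtree.tip_labels])
        observed = relative_disparity_curve(subtree, sub_vals, metric)
        null = simulate_bm_null(subtree, sub_vals, n_sim, rng, metric)
        out[clade] = mdi(observed, null, scope=clade, n_sim=n_sim)
    return out


def dtt_pipeline(
    tree: Phylogeny,
    pno_profiles: Mapping[str, Mapping[str, PNOProfile]],
    clade_map: CladeMap | None = None,
    n_sim: int = 1000,
    seed: int | np.random.Generator = 0,
    metric: str = "squared",
    mode: str = "mean",
    n_draws: int = 100,
) -> dict[str, DTTResults]:
    """Run DTT for every variable.

    ``pno_profiles`` maps variable -> species -> profile. In ``mean`` mode
    (default) each species' trait value is its suitability-weighted PNO
    mean. In ``draws`` mode the whole-tree MDI is additionally computed for
    ``n_draws`` replicate PNO draws; the per-draw MDIs are attached to the
    results as ``draw_mdis``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    results: dict[str, DTTResults] = {}
    for variable in pno_profiles:
        profiles = pno_profiles[variable]
        tip_values = {
            sp: pno_weighted_mean(profiles[sp]) for sp in tree.tip_labels
        }
        model = DisparityThroughTime(
            tree, tip_values, clade_map=clade_map, metric=metric, variable=variable
        )
        res = model.fit(n_sim=n_sim, seed=rng)
        if mode == "draws":
            structure = _DTTStructure(tree)
            draws = np.empty((n_draws, tree.n_tips))
            for t, sp in enumerate(tree.tip_labels):
                draws[:, t] = sample_pno(profiles[sp], n_draws, rng)
            curves = structure.curves(draws, metric)
            med = res.null.median
            res.draw_mdis = np.trapezoid(curves - med, structure.rel_times, axis=1)
        elif mode != "mean":
            raise ValueError(f"unknown mode {mode!r}")
        results[variable] = res
    return results
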