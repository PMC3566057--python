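"""History of climatic tolerances: Brownian-motion ancestral reconstruction.

Internal-node values of each climate variable are estimated by maximum
likelihood under Brownian motion on the time-calibrated tree. The estimates
are the Gaussian conditional expectations given the tip values, computed by
a two-pass message-passing (pruning) algorithm; the root estimate equals the
GLS generalized mean under the phylogenetic covariance, and the BM rate is
the ML estimate (residual sum of standardized contrasts divided by n).

Uncertainty in the tip values themselves — a species' climatic tolerance is
a distribution, not a point — is propagated by repeating the reconstruction
over replicate draws from each species' PNO profile and summarizing each
node by the mean and the 80% central density across draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phylo import Phylogeny
from .pno import PNOProfile, sample_pno

__all__ = [
    "BMParams",
    "bm_ancestral_ml",
    "central_density",
    "reconstruct_history",
    "AncestralReconstruction",
]


@dataclass(frozen=True)
class BMParams:
    """Brownian-motion parameters: rate (units^2/Myr) and root state."""

    sigma2: float
    z0: float

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be nonnegative")


def _as_tip_array(tree: Phylogeny, tip_values) -> np.ndarray:
    if isinstance(tip_values, Mapping):
        missing = [l for l in tree.tip_labels if l not in tip_values]
        if missing:
            raise ValueError(f"missing tip values for {missing}")
        extra = set(tip_values) - set(tree.tip_labels)
        if extra:
            raise ValueError(f"tip values for unknown taxa {sorted(extra)}")
        arr = np.array([float(tip_values[l]) for l in tree.tip_labels])
    else:
        arr = np.asarray(tip_values, dtype=float)
        if arr.shape != (tree.n_tips,):
            raise ValueError(
                f"expected {tree.n_tips} tip values, got shape {arr.shape}"
            )
    if not np.isfinite(arr).all():
        raise ValueError("tip values must be finite")
    return arr


def bm_ancestral_ml(
    tree: Phylogeny, tip_values
) -> tuple[np.ndarray, BMParams]:
    """ML ancestral states under Brownian motion.

    Parameters
    ----------
    tip_values : mapping label -> value, or array in ``tree.tip_labels`` order

    Returns
    -------
    estimates : array over all nodes (tips carry their observed values)
    params : :class:`BMParams` with the ML rate and the root (GLS) state

    The upward pass combines child messages by precision (Felsenstein
    pruning); the downward pass sends each node the information from the
    rest of the tree; a node's estimate is the precision-weighted fusion of
    the two, which is the exact GLS/conditional-expectation solution.
    """
    x = _as_tip_array(tree, tip_values)
    n = tree.n_tips
    n_nodes = tree.n_nodes
    up_mean = np.zeros(n_nodes)
    up_var = np.zeros(n_nodes)  # in branch-length units; sigma2 cancels
    contrasts_ss = 0.0
    for i in tree.postorder():
        ch = tree.children[i]
        if not ch:
            up_mean[i] = x[i]
            up_var[i] = 0.0
            continue
        c1, c2 = ch
        v1 = up_var[c1] + tree.branch_lengths[c1]
        v2 = up_var[c2] + tree.branch_lengths[c2]
        if v1 <= 0 and v2 <= 0:
            up_mean[i] = 0.5 * (up_mean[c1] + up_mean[c2])
            up_var[i] = 0.0
        else:
            up_mean[i] = (up_mean[c1] * v2 + up_mean[c2] * v1) / (v1 + v2)
            up_var[i] = v1 * v2 / (v1 + v2)
        contrasts_ss += (up_mean[c1] - up_mean[c2]) ** 2 / (v1 + v2)

    # downward messages: (mean, var) of the information reaching the node
    # from outside its subtree, measured at the node itself
    down_mean = np.zeros(n_nodes)
    down_var = np.full(n_nodes, np.inf)
    estimates = np.empty(n_nodes)
    for i in tree.preorder():
        ch = tree.children[i]
        if i == tree.root:
            estimates[i] = up_mean[i]
        else:
            dm, dv = down_mean[i], down_var[i]
            if not ch:
                estimates[i] = x[i]
            else:
                um, uv = up_mean[i], up_var[i]
                if np.isinf(dv):
                    estimates[i] = um
                else:
                    w = dv / (uv + dv)
                    estimates[i] = w * um + (1 - w) * dm
        for c in ch:
            sib = ch[0] if ch[1] == c else ch[1]
            sm = up_mean[sib]
            sv = up_var[sib] + tree.branch_lengths[sib]
            if i == tree.root or np.isinf(down_var[i]):
                comb_m, comb_v = sm, sv
            else:
                pv = down_var[i]
                comb_v = sv * pv / (sv + pv)
                comb_m = (sm * pv + down_mean[i] * sv) / (sv + pv)
            down_mean[c] = comb_m
            down_var[c] = comb_v + tree.branch_lengths[c]
    sigma2 = contrasts_ss / n
    return estimates, BMParams(sigma2=float(sigma2), z0=float(estimates[tree.root]))


def central_density(
    values: Sequence[float] | np.ndarray, mass: float = 0.8
) -> tuple[float, float, float]:
    """Empirical central-density interval and the mean of the values in it.

    Returns (low, high, mean_within) where low/high are the (1-mass)/2 and
    1-(1-mass)/2 quantiles.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    alpha = (1.0 - mass) / 2.0
    low, high = np.quantile(values, [alpha, 1.0 - alpha])
    inside = values[(values >= low) & (values <= high)]
    return float(low), float(high), float(inside.mean())


@dataclass
class AncestralReconstruction:
    """Per-variable reconstruction across replicate PNO draws.

    ``node_draws`` has one row per draw and one column per internal node (in
    ``node_ids`` order); summaries are the mean across draws and the central
    density interval at the configured mass.
    """

    variable: str
    node_ids: np.ndarray
    node_draws: np.ndarray  # (n_draws, n_internal)
    tip_draws: np.ndarray  # (n_draws, n_tips)
    sigma2_draws: np.ndarray  # (n_draws,)
    heights: np.ndarray  # node heights (Myr) for the internal nodes
    mass: float = 0.8

    @property
    def n_draws(self) -> int:
        return self.node_draws.shape[0]

    @property
    def root_draws(self) -> np.ndarray:
        return self.node_draws[:, -1]  # root is the last internal node id

    def summarize(self) -> pd.DataFrame:
        rows = []
        for k, node in enumerate(self.node_ids):
            lo, hi, mean_in = central_density(self.node_draws[:, k], self.mass)
            rows.append(
                {
                    "node": int(node),
                    "height": float(self.heights[k]),
                    "mean": float(self.node_draws[:, k].mean()),
                    f"low{int(self.mass * 100)}": lo,
                    f"high{int(self.mass * 100)}": hi,
                    "mean_within": mean_in,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.summarize()
        lines = [
            f"Brownian-motion niche history: {self.variable}",
            f"draws: {self.n_draws}   central density mass: {self.mass:g}",
            f"mean BM rate across draws: {self.sigma2_draws.mean():.6g}",
            df.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


def reconstruct_history(
    tree: Phylogeny,
    pno_profiles: Mapping[str, PNOProfile],
    n_draws: int = 100,
    seed: int | np.random.Generator = 0,
    mass: float = 0.8,
) -> AncestralReconstruction:
    """Reconstruct one variable's history over replicate PNO draws.

    For each draw, one value per species is sampled from its PNO profile and
    the BM ancestral states are estimated; node summaries are taken across
    draws. All profiles must describe the same variable.
    """
    missing = [l for l in tree.tip_labels if l not in pno_profiles]
    if missing:
        raise ValueError(f"missing PNO profiles for {missing}")
    variables = {p.variable for p in pno_profiles.values()}
    if len(variables) != 1:
        raise ValueError(f"profiles mix variables: {sorted(variables)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_tips = tree.n_tips
    tip_draws = np.empty((n_draws, n_tips))
    for t, label in enumerate(tree.tip_labels):
        tip_draws[:, t] = sample_pno(pno_profiles[label], n_draws, rng)
    internal = [i for i in tree.internal_nodes()]
    internal = sorted(internal)
    node_draws = np.empty((n_draws, len(internal)))
    sigma2 = np.empty(n_draws)
    for d in range(n_draws):
        est, params = bm_ancestral_ml(tree, tip_draws[d])
        node_draws[d] = est[internal]
        sigma2[d] = params.sigma2
    return AncestralReconstruction(
        variable=next(iter(variables)),
        node_ids=np.array(internal),
        node_draws=node_draws,
        tip_draws=tip_draws,
        sigma2_draws=sigma2,
        heights=tree.heights[internal],
        mass=mass,
    )
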