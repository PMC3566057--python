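"""Presence-background ecological niche models.

A minimal MaxEnt-style Gibbs model: over the background cells, the species'
distribution is P(i) = exp(lambda . f(i)) / Z with linear and quadratic
features of each climate variable, fitted by maximizing the L1-penalized
presence log-likelihood

    l(lambda) = mean_presences lambda . f(x)  -  log Z  -  beta * ||lambda||_1 .

The fitted surface is exported in the RAW convention (weights summing to 1
over all valid study cells), which is what the overlap and predicted-niche-
occupancy math consumes. Exact MaxEnt feature classes (hinge, product,
threshold) and logistic/cloglog transforms are out of scope.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely
from scipy.special import logsumexp, softmax
from scipy.stats import rankdata
from shapely.geometry import MultiPoint, Polygon

from .occurrences import OccurrenceSet, MIN_POINTS
from .rasters import GridSpec, Raster, RasterStack
from .surfaces import SuitabilitySurface

__all__ = [
    "ENMSettings",
    "BackgroundSample",
    "FeatureMatrix",
    "MaxEnt",
    "MaxEntResults",
    "EvaluationReport",
    "BinarySurface",
    "minimum_convex_polygon",
    "build_background",
    "build_features",
    "split_train_test",
    "fit_maxent",
    "evaluate_auc",
    "crossvalidate",
    "fit_species_model",
    "variable_contribution",
    "select_top_variables",
    "binarize_mtp",
    "stack_richness",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ENMSettings:
    """Model settings shared across species."""

    beta: float = 0.1  # L1 regularization strength
    max_iter: int = 5000
    tol: float = 1e-6
    background_n: int = 10000
    train_fraction: float = 0.8
    cv_max_points: int = 12  # use cross-validation up to this many points
    replicates: int = 20


# -- geometry and sampling --------------------------------------------------

def minimum_convex_polygon(points: Sequence[tuple[float, float]]) -> Polygon:
    """Convex hull of the pooled occurrence points of all species.

    Raises if fewer than 3 points or all points collinear (the hull would be
    degenerate); callers must widen the data instead.
    """
    pts = list(points)
    if len(pts) < 3:
        raise ValueError("minimum convex polygon needs at least 3 points")
    hull = MultiPoint(pts).convex_hull
    if not isinstance(hull, Polygon):
        raise ValueError("all points are collinear; cannot form a polygon")
    return hull


@dataclass
class BackgroundSample:
    """Cells available to the model as background (pseudo-absence) points."""

    cells: np.ndarray  # (n, 2) int array of (row, col)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=int).reshape(-1, 2)
        if self.cells.shape[0] == 0:
            raise ValueError("empty background sample")

    def __len__(self) -> int:
        return self.cells.shape[0]


def build_background(
    polygon: Polygon,
    raster_stack: RasterStack,
    n_background: int = 10000,
    seed: int | np.random.Generator = 0,
) -> BackgroundSample:
    """Uniform sample (without replacement) of valid cells whose centers fall
    inside the polygon. If fewer eligible cells exist than requested, all are
    used and a warning is logged."""
    if n_background < 1:
        raise ValueError("n_background must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spec = raster_stack.spec
    mask = raster_stack.valid_mask
    xs, ys = spec.cell_centers()
    inside = shapely.covers(polygon, shapely.points(xs.ravel(), ys.ravel())).reshape(
        mask.shape
    )
    eligible = np.argwhere(mask & inside)
    if eligible.shape[0] == 0:
        raise ValueError("no valid cells inside the background polygon")
    if eligible.shape[0] < n_background:
        logger.warning(
            "only %d eligible background cells (requested %d); using all",
            eligible.shape[0],
            n_background,
        )
        return BackgroundSample(eligible)
    pick = rng.choice(eligible.shape[0], size=n_background, replace=False)
    return BackgroundSample(eligible[np.sort(pick)])


def split_train_test(
    occurrences: OccurrenceSet,
    fraction: float = 0.8,
    seed: int | np.random.Generator = 0,
) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Random disjoint train/test partition with |train| = round(fraction*n),
    clamped so both sides keep at least one point."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = len(occurrences)
    if n < 2:
        raise ValueError("need at least 2 points to split")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_train = int(round(fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    order = rng.permutation(n)
    pts = occurrences.points
    train = [pts[i] for i in sorted(order[:n_train])]
    test = [pts[i] for i in sorted(order[n_train:])]
    return (
        OccurrenceSet(occurrences.species, train),
        OccurrenceSet(occurrences.species, test),
    )


# -- features ---------------------------------------------------------------

class FeatureMatrix:
    """Standardized linear + quadratic features of each climate variable.

    One row per valid cell of the stack; standardization moments are computed
    on the background sample only (the model's reference distribution).
    Degenerate features (zero variance on the background) are zeroed out and
    flagged; the fit warns about and ignores them.
    """

    def __init__(self, raster_stack: RasterStack, background: BackgroundSample):
        spec = raster_stack.spec
        mask = raster_stack.valid_mask
        flat_valid = np.flatnonzero(mask.ravel())
        self.spec = spec
        self.valid_mask = mask
        self.cell_rows = np.full(spec.n_rows * spec.n_cols, -1, dtype=int)
        self.cell_rows[flat_valid] = np.arange(flat_valid.size)
        self.variables = list(raster_stack.names)
        n_vars = len(self.variables)
        bg_rows = self.cell_rows[
            np.asarray(background.cells, dtype=int)[:, 0] * spec.n_cols
            + np.asarray(background.cells, dtype=int)[:, 1]
        ]
        if (bg_rows < 0).any():
            raise ValueError("background contains invalid cells")
        # linear feature: z = (x - mean) / sd; quadratic feature: z^2,
        # restandardized — keeps both on comparable scales so one penalty
        # strength treats them evenly
        self.matrix = np.empty((flat_valid.size, 2 * n_vars))
        self.lin_mean = np.empty(n_vars)
        self.lin_sd = np.empty(n_vars)
        self.quad_mean = np.empty(n_vars)
        self.quad_sd = np.empty(n_vars)
        self.degenerate = np.zeros(2 * n_vars, dtype=bool)
        for v, layer in enumerate(raster_stack):
            x = layer.values.ravel()[flat_valid]
            m, s = x[bg_rows].mean(), x[bg_rows].std()
            self.lin_mean[v], self.lin_sd[v] = m, s
            if s == 0:
                self.degenerate[2 * v : 2 * v + 2] = True
                self.lin_sd[v] = 1.0
                self.quad_mean[v], self.quad_sd[v] = 0.0, 1.0
                self.matrix[:, 2 * v : 2 * v + 2] = 0.0
                continue
            z = (x - m) / s
            z2 = z ** 2
            mq, sq = z2[bg_rows].mean(), z2[bg_rows].std()
            self.quad_mean[v] = mq
            self.matrix[:, 2 * v] = z
            if sq == 0:
                self.degenerate[2 * v + 1] = True
                self.quad_sd[v] = 1.0
                self.matrix[:, 2 * v + 1] = 0.0
            else:
                self.quad_sd[v] = sq
                self.matrix[:, 2 * v + 1] = (z2 - mq) / sq
        if not np.isfinite(self.matrix).all():
            raise ValueError("non-finite feature values")
        self.feature_names = []
        for name in self.variables:
            self.feature_names.extend([name, f"{name}^2"])

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def rows_for_cells(self, cells: np.ndarray) -> np.ndarray:
        cells = np.asarray(cells, dtype=int).reshape(-1, 2)
        flat = cells[:, 0] * self.spec.n_cols + cells[:, 1]
        rows = self.cell_rows[flat]
        if (rows < 0).any():
            bad = cells[rows < 0]
            raise ValueError(f"cells on invalid grid locations: {bad.tolist()[:5]}")
        return rows

    def rows_for_points(self, points: Sequence[tuple[float, float]]) -> np.ndarray:
        cells = np.array([self.spec.cell_of(x, y) for x, y in points], dtype=int)
        return self.rows_for_cells(cells)


def build_features(
    raster_stack: RasterStack, background: BackgroundSample
) -> FeatureMatrix:
    return FeatureMatrix(raster_stack, background)


# -- the model --------------------------------------------------------------

class MaxEnt:
    """Presence-background Gibbs model for one species.

    Parameters
    ----------
    presences : OccurrenceSet or (n, 2) array of cells
        Training presence localities (snapped to grid cells).
    background : BackgroundSample
        Cells defining the model's reference distribution.
    features : FeatureMatrix
        Shared feature matrix over all valid study cells.
    """

    def __init__(
        self,
        presences: OccurrenceSet | np.ndarray,
        background: BackgroundSample,
        features: FeatureMatrix,
        species: str | None = None,
    ):
        if isinstance(presences, OccurrenceSet):
            self.presence_rows = features.rows_for_points(presences.points)
            species = species if species is not None else presences.species
        else:
            self.presence_rows = features.rows_for_cells(presences)
        if self.presence_rows.size < 2:
            raise ValueError("need at least 2 training presences")
        self.background = background
        self.features = features
        self.background_rows = features.rows_for_cells(background.cells)
        self.species = species or ""

    # penalized objective pieces
    def _objective(self, lam: np.ndarray, beta: float) -> float:
        Xp = self.features.matrix[self.presence_rows]
        Xb = self.features.matrix[self.background_rows]
        ll = float(np.mean(Xp @ lam)) - float(logsumexp(Xb @ lam))
        return ll - beta * float(np.abs(lam).sum())

    def fit(
        self,
        beta: float = 0.1,
        max_iter: int = 5000,
        tol: float = 1e-6,
        relax: bool = False,
    ) -> "MaxEntResults":
        """Maximize the penalized presence log-likelihood by proximal
        gradient ascent with step halving.

        Convergence is declared when the gradient-mapping sup-norm drops
        below ``tol``; otherwise the iteration cap is reached (logged).

        ``relax=True`` adds a relaxed refit: after the L1 solution selects
        the active features, those features are refitted without penalty
        (L-BFGS on the smooth likelihood). The L1 penalty's additive
        shrinkage biases weight ratios, so response-curve quantities such
        as :meth:`MaxEntResults.quadratic_optimum` are better read from a
        relaxed fit; predicted surfaces normally use the penalized fit.
        """
        if self.features.degenerate.any():
            bad = [
                n
                for n, d in zip(self.features.feature_names, self.features.degenerate)
                if d
            ]
            warnings.warn(f"dropping zero-variance features: {bad}", stacklevel=2)
        Xp = self.features.matrix[self.presence_rows]
        Xb = self.features.matrix[self.background_rows]
        pbar = Xp.mean(axis=0)
        lam = np.zeros(self.features.n_features)
        obj = self._objective(lam, beta)
        if not np.isfinite(obj):
            raise ValueError("non-finite objective at start")
        history = [obj]
        step = 1.0
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            scores = Xb @ lam
            q = softmax(scores)
            grad = pbar - q @ Xb
            while True:
                lam_new = _soft_threshold(lam + step * grad, step * beta)
                lam_new[self.features.degenerate] = 0.0
                obj_new = self._objective(lam_new, beta)
                if np.isfinite(obj_new) and obj_new >= obj - 1e-12:
                    break
                step *= 0.5
                if step < 1e-14:
                    lam_new, obj_new = lam, obj
                    break
            gap = float(np.max(np.abs(lam_new - lam))) / step
            lam, obj = lam_new, max(obj_new, obj)
            history.append(obj)
            step = min(step * 1.2, 16.0)
            if gap < tol:
                converged = True
                break
        if not converged:
            logger.info(
                "maxent fit for %r hit the iteration cap (%d) without converging",
                self.species,
                max_iter,
            )
        if not np.isfinite(obj):
            raise ValueError("non-finite objective")
        if relax:
            # a variable is active if either of its features survived the
            # penalty; both features of an active variable are refitted so
            # that response curves are not distorted by selection
            nonzero = lam != 0
            active = np.zeros_like(nonzero)
            for v in range(len(self.features.variables)):
                if nonzero[2 * v] or nonzero[2 * v + 1]:
                    active[2 * v : 2 * v + 2] = True
            active &= ~self.features.degenerate
            if active.any():
                # history keeps the (monotone) penalized path; the relaxed
                # solution optimizes the smooth likelihood instead
                lam = self._relaxed_refit(lam, active)
        return MaxEntResults(
            model=self,
            params=lam,
            beta=beta,
            converged=converged,
            n_iter=n_iter,
            objective_path=np.array(history),
        )

    def _relaxed_refit(self, lam: np.ndarray, active: np.ndarray) -> np.ndarray:
        from scipy.optimize import minimize

        Xp = self.features.matrix[self.presence_rows][:, active]
        Xb = self.features.matrix[self.background_rows][:, active]
        pbar = Xp.mean(axis=0)

        def neg(la):
            scores = Xb @ la
            m = scores.max()
            lz = m + np.log(np.exp(scores - m).sum())
            q = softmax(scores)
            return -(pbar @ la - lz), -(pbar - q @ Xb)

        res = minimize(neg, lam[active], jac=True, method="L-BFGS-B")
        out = lam.copy()
        out[active] = res.x
        return out


def _soft_threshold(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


@dataclass
class MaxEntResults:
    """Fitted feature weights plus diagnostics for one species' model."""

    model: MaxEnt
    params: np.ndarray
    beta: float
    converged: bool
    n_iter: int
    objective_path: np.ndarray

    @property
    def species(self) -> str:
        return self.model.species

    @property
    def feature_names(self) -> list[str]:
        return self.model.features.feature_names

    def predict_raw(self) -> SuitabilitySurface:
        """RAW suitability surface: p_i proportional to exp(lambda . f(i))
        over all valid study cells, normalized to unit mass."""
        return predict_raw_from_params(
            self.params, self.model.features, species=self.species
        )

    def quadratic_optimum(self, variable: str) -> float:
        """Implied response optimum of one variable in variable units.

        The exponent in the standardized variable z is the parabola
        lam_lin * z + lam_quad * (z^2 - mq) / sq, so the optimum sits at
        z* = -lam_lin * sq / (2 * lam_quad), mapped back to variable units.
        Requires a concave response (lam_quad < 0).
        """
        feats = self.model.features
        v = feats.variables.index(variable)
        lam_lin = self.params[2 * v]
        lam_quad = self.params[2 * v + 1]
        if lam_quad >= 0:
            raise ValueError(
                f"response to {variable!r} is not concave (quadratic weight >= 0)"
            )
        z_opt = -lam_lin * feats.quad_sd[v] / (2.0 * lam_quad)
        return float(feats.lin_mean[v] + feats.lin_sd[v] * z_opt)

    def summary(self) -> str:
        lines = [
            "MaxEnt presence-background model",
            "=" * 40,
            f"species:          {self.species or '<unnamed>'}",
            f"presences:        {self.model.presence_rows.size}",
            f"background cells: {len(self.model.background)}",
            f"beta (L1):        {self.beta:g}",
            f"iterations:       {self.n_iter}"
            + ("" if self.converged else " (iteration cap reached)"),
            f"penalized loglik: {self.objective_path[-1]:.6f}",
            "-" * 40,
            f"{'feature':<16}{'weight':>12}",
        ]
        for name, w in zip(self.feature_names, self.params):
            lines.append(f"{name:<16}{w:>12.5f}")
        return "\n".join(lines)


def predict_raw_from_params(
    params: np.ndarray, features: FeatureMatrix, species: str = ""
) -> SuitabilitySurface:
    scores = features.matrix @ params
    scores -= scores.max()  # overflow guard
    raw_valid = np.exp(scores)
    raw = np.zeros(features.spec.n_rows * features.spec.n_cols)
    raw[np.flatnonzero(features.valid_mask.ravel())] = raw_valid
    return SuitabilitySurface.from_unnormalized(
        features.spec,
        raw.reshape(features.spec.n_rows, features.spec.n_cols),
        features.valid_mask,
        species=species,
    )


def fit_maxent(
    train_presences: OccurrenceSet | np.ndarray,
    background: BackgroundSample,
    feature_matrix: FeatureMatrix,
    beta: float = 0.1,
    max_iter: int = 5000,
    tol: float = 1e-6,
    species: str | None = None,
) -> MaxEntResults:
    """Functional wrapper around :class:`MaxEnt` + ``fit``."""
    return MaxEnt(train_presences, background, feature_matrix, species=species).fit(
        beta=beta, max_iter=max_iter, tol=tol
    )


# -- evaluation -------------------------------------------------------------

def evaluate_auc(
    surface: SuitabilitySurface,
    test_presences: OccurrenceSet | np.ndarray,
    background: BackgroundSample,
) -> float:
    """Rank-based (Mann-Whitney) AUC of presence vs background suitability,
    with mid-ranks for ties."""
    if isinstance(test_presences, OccurrenceSet):
        if len(test_presences) < 1:
            raise ValueError("need at least 1 test presence")
        cells = np.array(
            [surface.spec.cell_of(x, y) for x, y in test_presences.points], dtype=int
        )
    else:
        cells = np.asarray(test_presences, dtype=int).reshape(-1, 2)
        if cells.shape[0] < 1:
            raise ValueError("need at least 1 test presence")
    if len(background) < 1:
        raise ValueError("empty background")
    w = surface.weights
    pres = w[cells[:, 0], cells[:, 1]]
    bg = w[background.cells[:, 0], background.cells[:, 1]]
    ranks = rankdata(np.concatenate([pres, bg]))
    n_p, n_b = pres.size, bg.size
    return float((ranks[:n_p].sum() - n_p * (n_p + 1) / 2) / (n_p * n_b))


@dataclass
class EvaluationReport:
    """Per-species model evaluation mirroring the input-summary table:
    point counts, AUC, and per-variable percent contributions."""

    species: str
    n_points: int
    n_train: int
    n_test: int
    auc: float
    replicates: int = 1
    contributions: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.contributions is not None:
            total = sum(self.contributions.values())
            if abs(total - 100.0) > 0.01:
                raise ValueError(f"contributions sum to {total}, expected 100")
            if any(v < 0 for v in self.contributions.values()):
                raise ValueError("negative contribution")


def crossvalidate(
    occurrences: OccurrenceSet,
    background: BackgroundSample,
    features: FeatureMatrix,
    k: int | None = None,
    beta: float = 0.1,
    max_iter: int = 5000,
    seed: int | np.random.Generator = 0,
) -> tuple[SuitabilitySurface, EvaluationReport]:
    """k-fold cross-validation: per-fold fit and held-out AUC; the final
    surface is the cell-wise mean of the fold surfaces, renormalized.

    ``k=None`` selects leave-one-out for small samples (n <= 12) and 5-fold
    otherwise.
    """
    n = len(occurrences)
    if k is None:
        k = n if n <= 12 else 5
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} points")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    pts = occurrences.points
    weights = np.zeros((features.spec.n_rows, features.spec.n_cols))
    aucs = []
    for fold in folds:
        test_idx = set(int(i) for i in fold)
        train = OccurrenceSet(
            occurrences.species, [pts[i] for i in range(n) if i not in test_idx]
        )
        test = OccurrenceSet(occurrences.species, [pts[i] for i in sorted(test_idx)])
        res = fit_maxent(
            train, background, features, beta=beta, max_iter=max_iter
        )
        surf = res.predict_raw()
        aucs.append(evaluate_auc(surf, test, background))
        weights += surf.weights
    final = SuitabilitySurface.from_unnormalized(
        features.spec, weights, features.valid_mask, species=occurrences.species
    )
    report = EvaluationReport(
        species=occurrences.species,
        n_points=n,
        n_train=n - len(folds[0]),
        n_test=len(folds[0]),
        auc=float(np.mean(aucs)),
        replicates=k,
    )
    return final, report


def fit_species_model(
    occurrences: OccurrenceSet,
    background: BackgroundSample,
    features: FeatureMatrix,
    settings: ENMSettings = ENMSettings(),
    seed: int | np.random.Generator = 0,
) -> tuple[SuitabilitySurface, EvaluationReport, MaxEntResults]:
    """Fit one species the way the study protocol prescribes.

    Species with up to ``settings.cv_max_points`` points are cross-validated
    (leave-one-out); larger samples are averaged over ``settings.replicates``
    re-seeded 80/20 train/test fits (cell-wise mean surface, renormalized,
    mean AUC). Returns the averaged surface, the evaluation report, and a
    final model fitted on all points (used for variable contributions).
    """
    n = len(occurrences)
    if n < MIN_POINTS:
        raise ValueError(
            f"{occurrences.species!r} has {n} spatially unique points; "
            f"at least {MIN_POINTS} are required"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n <= settings.cv_max_points:
        surface, report = crossvalidate(
            occurrences,
            background,
            features,
            k=None,
            beta=settings.beta,
            max_iter=settings.max_iter,
            seed=rng,
        )
    else:
        weights = np.zeros((features.spec.n_rows, features.spec.n_cols))
        aucs = []
        n_train = n_test = 0
        for _ in range(settings.replicates):
            train, test = split_train_test(
                occurrences, settings.train_fraction, rng
            )
            res = fit_maxent(
                train,
                background,
                features,
                beta=settings.beta,
                max_iter=settings.max_iter,
            )
            surf = res.predict_raw()
            aucs.append(evaluate_auc(surf, test, background))
            weights += surf.weights
            n_train, n_test = len(train), len(test)
        surface = SuitabilitySurface.from_unnormalized(
            features.spec, weights, features.valid_mask, species=occurrences.species
        )
        report = EvaluationReport(
            species=occurrences.species,
            n_points=n,
            n_train=n_train,
            n_test=n_test,
            auc=float(np.mean(aucs)),
            replicates=settings.replicates,
        )
    final = fit_maxent(
        occurrences,
        background,
        features,
        beta=settings.beta,
        max_iter=settings.max_iter,
    )
    return surface, report, final


def variable_contribution(
    results: MaxEntResults,
    test_presences: OccurrenceSet | np.ndarray,
    n_permutations: int = 10,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """Permutation importance as percent contribution per variable.

    For each variable, both of its features are permuted together across all
    valid cells and the AUC drop (against the model's background) is averaged
    over permutations, floored at zero, then normalized to sum to 100.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    feats = results.model.features
    background = results.model.background
    base_surface = results.predict_raw()
    base_auc = evaluate_auc(base_surface, test_presences, background)
    drops = np.zeros(len(feats.variables))
    matrix = feats.matrix
    for v in range(len(feats.variables)):
        cols = [2 * v, 2 * v + 1]
        if np.all(results.params[cols] == 0):
            continue  # variable absent from the model: exact zero
        for _ in range(n_permutations):
            perm = rng.permutation(matrix.shape[0])
            saved = matrix[:, cols].copy()
            matrix[:, cols] = matrix[perm][:, cols]
            try:
                surf = predict_raw_from_params(
                    results.params, feats, species=results.species
                )
                drops[v] += base_auc - evaluate_auc(surf, test_presences, background)
            finally:
                matrix[:, cols] = saved
        drops[v] /= n_permutations
    drops = np.maximum(drops, 0.0)
    total = drops.sum()
    if total == 0:
        # completely uninformative model: spread evenly so the report still
        # satisfies the sum-to-100 contract
        pct = np.full(drops.size, 100.0 / drops.size)
    else:
        pct = 100.0 * drops / total
    return dict(zip(feats.variables, pct.tolist()))


def select_top_variables(
    reports: Sequence[EvaluationReport], n_keep: int = 10
) -> list[str]:
    """Variables ranked by mean percent contribution across species; ties
    break alphabetically (logged)."""
    if not reports:
        raise ValueError("no reports")
    tables = [r.contributions for r in reports if r.contributions is not None]
    if not tables:
        raise ValueError("reports carry no contributions")
    variables = sorted(tables[0])
    if n_keep > len(variables):
        raise ValueError(f"n_keep={n_keep} exceeds {len(variables)} variables")
    means = {v: float(np.mean([t[v] for t in tables])) for v in variables}
    ranked = sorted(variables, key=lambda v: (-means[v], v))
    vals = sorted(means.values(), reverse=True)
    if len(set(vals)) < len(vals):
        logger.info("ties in mean contribution broken alphabetically")
    return ranked[:n_keep]


# -- binary maps ------------------------------------------------------------

@dataclass
class BinarySurface:
    """Thresholded presence/absence map and the threshold that produced it."""

    spec: GridSpec
    mask: np.ndarray
    threshold: float
    species: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.spec.n_rows, self.spec.n_cols):
            raise ValueError("mask shape does not match grid")


def binarize_mtp(
    surface: SuitabilitySurface,
    training_presences: OccurrenceSet | np.ndarray,
) -> BinarySurface:
    """Minimum-training-presence binary map: threshold at the lowest
    suitability observed at any training presence cell."""
    if isinstance(training_presences, OccurrenceSet):
        cells = np.array(
            [surface.spec.cell_of(x, y) for x, y in training_presences.points],
            dtype=int,
        )
    else:
        cells = np.asarray(training_presences, dtype=int).reshape(-1, 2)
    if cells.shape[0] < 1:
        raise ValueError("need at least 1 training presence")
    if not surface.valid_mask[cells[:, 0], cells[:, 1]].all():
        raise ValueError("training presence on an invalid cell")
    threshold = float(surface.weights[cells[:, 0], cells[:, 1]].min())
    mask = (surface.weights >= threshold) & surface.valid_mask
    return BinarySurface(surface.spec, mask, threshold, species=surface.species)


def stack_richness(binary_surfaces: Sequence[BinarySurface]) -> Raster:
    """Species-richness map: per cell, the number of species predicted
    present across the binary maps."""
    surfaces = list(binary_surfaces)
    if not surfaces:
        raise ValueError("no binary surfaces")
    spec = surfaces[0].spec
    for s in surfaces[1:]:
        if s.spec != spec:
            raise ValueError("binary surfaces are not co-registered")
    counts = np.zeros((spec.n_rows, spec.n_cols))
    for s in surfaces:
        counts += s.mask
    return Raster(spec, counts, name="richness")
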