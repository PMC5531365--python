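"""Partial credit model (PCM) calibration by joint maximum likelihood.

The PCM is the polytomous Rasch model of Masters: for an item with step
thresholds ``delta_1 .. delta_m`` the probability that a person with measure
``theta`` responds in category ``k`` (``k = 0 .. m``) is

    P_k(theta) = exp( sum_{j<=k} (theta - delta_j) ) / gamma(theta)

with the empty sum equal to 0 and ``gamma`` the normalizing constant.  Both
person measures and step thresholds live on the logit scale.

Estimation is alternating per-parameter Newton-Raphson joint maximum
likelihood (JMLE): person measures solve the raw-score equations, step
thresholds solve the category-threshold score equations, iterated until both
score residuals and parameter changes are below tolerance.  Persons may be
anchored (fixed) at supplied measures, which turns the fit into a pure item
calibration; without anchors the mean item location is constrained to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MISSING",
    "ResponseMatrix",
    "PCMParameters",
    "FitStatistics",
    "ResidualPCA",
    "TestInformation",
    "EstimationError",
    "category_probabilities",
    "item_information",
    "expected_score",
    "test_information",
    "fit_jmle",
    "fit_statistics",
    "residual_pca",
]

#: Sentinel for a missing response in an integer response matrix.
MISSING = -1

# JMLE convergence: max absolute score residual, max parameter change (logits),
# outer iteration cap.
SCORE_TOL = 0.01
CHANGE_TOL = 0.001
MAX_ITER = 200

# Extreme (zero / perfect) raw scores have no finite JMLE estimate; they are
# assigned the measure whose expected score sits this many score units inside
# the boundary.
EXTREME_ADJUST = 0.3


class EstimationError(RuntimeError):
    """Raised when JMLE cannot produce finite estimates (e.g. all-extreme data)."""


@dataclass
class ResponseMatrix:
    """Persons x items ordinal responses with consecutive category codes.

    Parameters
    ----------
    responses:
        Integer array (n_persons, n_items); category codes ``0..m_i`` per
        item, ``MISSING`` (-1) for absent cells.  Raw instrument codes that
        skip integers (e.g. a 0/2/4 scale) must be mapped to consecutive
        codes before construction.
    item_ids:
        Ordered item labels.
    m:
        Per-item top category index (number of steps).
    """

    responses: np.ndarray
    item_ids: list[str]
    m: np.ndarray

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=int)
        self.m = np.asarray(self.m, dtype=int)
        self.item_ids = list(self.item_ids)
        if self.responses.ndim != 2:
            raise ValueError("responses must be 2-D (persons x items)")
        n, k = self.responses.shape
        if k != len(self.item_ids) or k != self.m.size:
            raise ValueError("item_ids and m must match the number of columns")
        if np.any(self.m < 1):
            raise ValueError("every item needs at least one step (m >= 1)")
        obs = self.responses != MISSING
        if np.any((self.responses < MISSING) | (obs & (self.responses > self.m))):
            raise ValueError("observed responses must satisfy 0 <= r <= m_i")
        if (obs.any(axis=1).sum() < 2) or (obs.any(axis=0).sum() < 2):
            raise ValueError("need at least 2 persons and 2 items with data")

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where a response is observed."""
        return self.responses != MISSING


@dataclass
class PCMParameters:
    """Fitted PCM parameters on the logit scale.

    ``delta[i]`` holds item i's step thresholds (length ``m_i`` after any
    category collapsing); ``theta[n]`` the person measures.  ``category_maps``
    records, per item, the raw-category -> estimation-category mapping applied
    when intermediate categories were unobserved (identity when none).
    """

    delta: list[np.ndarray]
    theta: np.ndarray
    item_ids: list[str]
    anchored_persons: frozenset[int] = field(default_factory=frozenset)
    extreme_persons: frozenset[int] = field(default_factory=frozenset)
    category_maps: list[np.ndarray] | None = None

    @property
    def item_location(self) -> np.ndarray:
        """Mean of the step thresholds per item (item difficulty)."""
        return np.array([float(np.mean(d)) for d in self.delta])

    def delta_for(self, item_id: str) -> np.ndarray:
        return self.delta[self.item_ids.index(item_id)]


@dataclass
class FitStatistics:
    """Infit/outfit mean-square statistics (expectation 1 under the model)."""

    item_infit: np.ndarray
    item_outfit: np.ndarray
    person_infit: np.ndarray
    person_outfit: np.ndarray
    n_excluded_observations: int = 0


@dataclass
class ResidualPCA:
    """Eigenstructure of the item-by-item standardized-residual correlations."""

    eigenvalues: np.ndarray
    first_contrast_loadings: np.ndarray
    item_ids: list[str]


@dataclass
class TestInformation:
    """A test (summed) information curve over a theta grid."""

    theta_grid: np.ndarray
    curve: np.ndarray
    theta_star: float


def _check_finite(theta, delta) -> None:
    if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(delta))):
        raise ValueError("theta and delta must be finite")


def category_probabilities(theta, delta_i) -> np.ndarray:
    """PCM category probabilities for one item.

    Parameters
    ----------
    theta:
        Person measure(s) in logits; scalar or 1-D array of length n.
    delta_i:
        The item's step thresholds ``delta_1 .. delta_m`` in logits.

    Returns
    -------
    Probability vector of length ``m+1`` (or array ``(n, m+1)``), each entry
    in (0, 1), summing to 1.
    """
    delta_i = np.atleast_1d(np.asarray(delta_i, dtype=float))
    _check_finite(theta, delta_i)
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    m = delta_i.size
    k = np.arange(m + 1)
    # log numerator of P_k: k*theta - cumulative sum of thresholds
    cum = np.concatenate(([0.0], np.cumsum(delta_i)))
    logits = theta_arr[:, None] * k[None, :] - cum[None, :]
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    if np.isscalar(theta) or np.asarray(theta).ndim == 0:
        return p[0]
    return p


def expected_score(theta, delta_i):
    """E[X | theta] for one item — the item characteristic curve."""
    p = category_probabilities(theta, delta_i)
    k = np.arange(p.shape[-1])
    return p @ k


def item_information(theta, delta_i):
    """Fisher information of one PCM item at ``theta`` (logit^-2).

    For the PCM this equals the model variance of the category score,
    ``E[X^2] - E[X]^2``, which is also the slope of the item characteristic
    curve dE[X]/dtheta.
    """
    p = category_probabilities(theta, delta_i)
    k = np.arange(p.shape[-1])
    ex = p @ k
    ex2 = p @ (k**2)
    return ex2 - ex**2


def test_information(
    params: PCMParameters,
    theta_grid: np.ndarray | None = None,
    items: list[str] | None = None,
) -> TestInformation:
    """Summed information curve of an item subset, with its peak location.

    The curve is the pointwise sum of the item information functions over
    ``items`` (default: all items); ``theta_star`` is the grid point where it
    is maximal (lowest such point on ties).
    """
    if theta_grid is None:
        theta_grid = np.arange(-6.0, 6.0 + 1e-9, 0.01)
    theta_grid = np.asarray(theta_grid, dtype=float)
    if theta_grid.size < 2 or np.any(np.diff(theta_grid) <= 0):
        raise ValueError("theta_grid must be strictly increasing")
    if items is None:
        items = list(params.item_ids)
    if not items:
        raise ValueError("item subset must be non-empty")
    curve = np.zeros_like(theta_grid)
    for item_id in items:
        curve += item_information(theta_grid, params.delta_for(item_id))
    theta_star = float(theta_grid[int(np.argmax(curve))])
    return TestInformation(theta_grid=theta_grid, curve=curve, theta_star=theta_star)


# ---------------------------------------------------------------------------
# JMLE estimation
# ---------------------------------------------------------------------------


def _collapse_categories(data: ResponseMatrix):
    """Map unobserved intermediate/extreme categories out of each item.

    Returns collapsed integer responses, new per-item m, and per-item raw ->
    estimation category maps (length ``m_i + 1`` each).
    """
    resp = data.responses.copy()
    new_m = np.zeros(data.n_items, dtype=int)
    maps: list[np.ndarray] = []
    for i in range(data.n_items):
        col = resp[:, i]
        obs = col != MISSING
        counts = np.bincount(col[obs], minlength=data.m[i] + 1)
        observed_cats = np.flatnonzero(counts > 0)
        if observed_cats.size < 2:
            raise EstimationError(
                f"item {data.item_ids[i]!r} has fewer than 2 observed categories; "
                "its thresholds are inestimable"
            )
        # rank of each observed category becomes its estimation code
        cmap = np.zeros(data.m[i] + 1, dtype=int)
        rank = {int(c): r for r, c in enumerate(observed_cats)}
        prev = 0
        for c in range(data.m[i] + 1):
            if int(c) in rank:
                prev = rank[int(c)]
            cmap[c] = prev
        maps.append(cmap)
        col[obs] = cmap[col[obs]]
        new_m[i] = observed_cats.size - 1
    return resp, new_m, maps


def _item_score_residuals(resp_col, theta, delta, mask):
    """Observed-minus-expected counts at/above each step for one item."""
    p = category_probabilities(theta[mask], delta)
    m = delta.size
    surv = np.cumsum(p[:, ::-1], axis=1)[:, ::-1]  # S_k = P(X >= k)
    obs = resp_col[mask]
    g = np.empty(m)
    h = np.empty(m)
    for j in range(1, m + 1):
        s_j = surv[:, j]
        g[j - 1] = float(np.sum(obs >= j) - np.sum(s_j))
        h[j - 1] = float(np.sum(s_j * (s_j - 1.0)))  # d(expected)/d(delta_j)
    return g, h


def _theta_for_score(target, deltas, lo=-12.0, hi=12.0):
    """Solve E[total score | theta] = target by bisection over the items."""

    def total(th):
        return sum(expected_score(th, d) for d in deltas)

    f_lo, f_hi = total(lo) - target, total(hi) - target
    if f_lo > 0 or f_hi < 0:
        raise EstimationError("target score outside the achievable range")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if total(mid) - target < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def fit_jmle(
    data: ResponseMatrix,
    anchors: dict[int, float] | None = None,
) -> PCMParameters:
    """Joint maximum likelihood PCM calibration.

    Alternates damped Newton-Raphson updates of free person measures and of
    each step threshold until the maximum absolute score residual falls below
    0.01 and the largest parameter change below 0.001 logits (at most 200
    outer iterations).  Persons listed in ``anchors`` keep their supplied
    measure exactly and only contribute to item estimation.  Without anchors
    the mean item location is centered at zero.

    Persons with all-minimum or all-maximum observed responses have no finite
    estimate; they are excluded from estimation and afterwards assigned the
    measure whose expected raw score lies ``EXTREME_ADJUST`` score units
    inside the boundary.  Items with unobserved categories are collapsed
    (``category_maps`` records the mapping).
    """
    anchors = dict(anchors) if anchors else {}
    for n_idx, val in anchors.items():
        if not math.isfinite(val):
            raise ValueError("anchored theta values must be finite")
        if not 0 <= n_idx < data.n_persons:
            raise IndexError(f"anchor index {n_idx} out of range")

    resp, m, cmaps = _collapse_categories(data)
    n, k = resp.shape
    mask = resp != MISSING
    max_row = np.where(mask, m[None, :], 0).sum(axis=1)
    raw = np.where(mask, np.maximum(resp, 0), 0).sum(axis=1)

    anchored = frozenset(anchors)
    extreme = frozenset(
        int(i)
        for i in np.flatnonzero((raw == 0) | (raw == max_row))
        if i not in anchored
    )
    free = np.array(
        [i for i in range(n) if i not in anchored and i not in extreme], dtype=int
    )
    if free.size == 0 and not anchored:
        raise EstimationError("all persons have extreme scores; nothing to estimate")

    # estimation subset: anchored + free persons
    est_mask = np.zeros(n, dtype=bool)
    est_mask[free] = True
    est_mask[list(anchored)] = True

    theta = np.zeros(n)
    for i, val in anchors.items():
        theta[i] = val
    with np.errstate(divide="ignore"):
        p0 = np.clip(raw[free] / np.maximum(max_row[free], 1), 0.01, 0.99)
        theta[free] = np.log(p0 / (1 - p0))
    delta = [np.zeros(mi) for mi in m]

    for _ in range(MAX_ITER):
        max_resid = 0.0
        max_change = 0.0

        # --- person updates (vectorized over free persons) ---
        if free.size:
            ex = np.zeros(free.size)
            info = np.zeros(free.size)
            th = theta[free]
            for i in range(k):
                sub = mask[free, i]
                if not sub.any():
                    continue
                p = category_probabilities(th[sub], delta[i])
                cats = np.arange(m[i] + 1)
                e = p @ cats
                ex_i = np.zeros(free.size)
                info_i = np.zeros(free.size)
                ex_i[sub] = e
                info_i[sub] = p @ (cats**2) - e**2
                ex += ex_i
                info += info_i
            resid = raw[free] - ex
            step = np.clip(resid / np.maximum(info, 1e-10), -1.0, 1.0)
            theta[free] = th + step
            max_resid = max(max_resid, float(np.abs(resid).max()))
            max_change = max(max_change, float(np.abs(step).max()))

        # --- item updates (per-parameter Newton) ---
        for i in range(k):
            sub = mask[:, i] & est_mask
            g, h = _item_score_residuals(resp[:, i], theta, delta[i], sub)
            step = np.clip(g / np.minimum(h, -1e-10), -1.0, 1.0)
            delta[i] = delta[i] + step
            max_resid = max(max_resid, float(np.abs(g).max()))
            max_change = max(max_change, float(np.abs(step).max()))

        # --- centering (only when nothing is anchored) ---
        if not anchored:
            shift = float(np.mean([np.mean(d) for d in delta]))
            delta = [d - shift for d in delta]
            theta[free] -= shift

        if max_resid < SCORE_TOL and max_change < CHANGE_TOL:
            break

    # extreme persons: extrapolated measures EXTREME_ADJUST inside the boundary
    for i in extreme:
        deltas_i = [delta[j] for j in range(k) if mask[i, j]]
        target = EXTREME_ADJUST if raw[i] == 0 else max_row[i] - EXTREME_ADJUST
        theta[i] = _theta_for_score(target, deltas_i)

    for i, val in anchors.items():
        theta[i] = val  # bit-for-bit

    if not np.all([np.all(np.isfinite(d)) for d in delta]):
        raise EstimationError("item estimation diverged")

    return PCMParameters(
        delta=delta,
        theta=theta,
        item_ids=list(data.item_ids),
        anchored_persons=anchored,
        extreme_persons=extreme,
        category_maps=cmaps,
    )


def _residual_arrays(data: ResponseMatrix, params: PCMParameters):
    """Observed score, expectation and model variance per cell (NaN = missing)."""
    resp, m, _ = _collapse_categories(data)
    n, k = resp.shape
    x = np.where(resp == MISSING, np.nan, resp).astype(float)
    ex = np.full((n, k), np.nan)
    var = np.full((n, k), np.nan)
    for i in range(k):
        p = category_probabilities(params.theta, params.delta[i])
        cats = np.arange(params.delta[i].size + 1)
        e = p @ cats
        v = p @ (cats**2) - e**2
        obs = ~np.isnan(x[:, i])
        ex[obs, i] = e[obs]
        var[obs, i] = v[obs]
    return x, ex, var


def fit_statistics(
    data: ResponseMatrix, params: PCMParameters, var_floor: float = 1e-10
) -> FitStatistics:
    """Infit/outfit mean squares per item and per person.

    outfit: unweighted mean of squared standardized residuals
    ``(x - E)^2 / Var``; infit: information-weighted, ``sum (x-E)^2 / sum
    Var``.  Observations whose model variance is below ``var_floor`` (the
    model is certain, the residual undefined) are excluded and counted.
    """
    x, ex, var = _residual_arrays(data, params)
    sq = (x - ex) ** 2
    ok = ~np.isnan(x) & (var > var_floor)
    n_excl = int((~np.isnan(x)).sum() - ok.sum())
    z2 = np.where(ok, sq / np.where(ok, var, 1.0), np.nan)
    sqm = np.where(ok, sq, np.nan)
    varm = np.where(ok, var, np.nan)

    with np.errstate(invalid="ignore"):
        item_outfit = np.nanmean(z2, axis=0)
        person_outfit = np.nanmean(z2, axis=1)
        item_infit = np.nansum(sqm, axis=0) / np.nansum(varm, axis=0)
        person_infit = np.nansum(sqm, axis=1) / np.nansum(varm, axis=1)
    return FitStatistics(
        item_infit=item_infit,
        item_outfit=item_outfit,
        person_infit=person_infit,
        person_outfit=person_outfit,
        n_excluded_observations=n_excl,
    )


def residual_pca(data: ResponseMatrix, params: PCMParameters) -> ResidualPCA:
    """PCA of standardized response residuals (Rasch first-contrast analysis).

    Eigendecomposition of the item-by-item Pearson correlation matrix of the
    standardized residuals ``(x - E)/sqrt(Var)``; pairwise-complete over
    missing cells.  The first contrast's loadings are the leading eigenvector
    scaled by the square root of its eigenvalue.
    """
    if data.n_persons < data.n_items:
        raise ValueError("need at least as many persons as items for residual PCA")
    x, ex, var = _residual_arrays(data, params)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - ex) / np.sqrt(var)
    import pandas as pd

    corr = pd.DataFrame(z, columns=params.item_ids).corr().to_numpy()
    if np.any(np.isnan(corr)):
        raise EstimationError("residual correlations undefined (degenerate residuals)")
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    first = evecs[:, order[0]]
    # sign convention: largest-magnitude loading positive
    if first[np.argmax(np.abs(first))] < 0:
        first = -first
    return ResidualPCA(
        eigenvalues=evals,
        first_contrast_loadings=first * math.sqrt(max(evals[0], 0.0)),
        item_ids=list(params.item_ids),
    )
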