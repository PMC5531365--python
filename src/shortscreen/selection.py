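"""Four short-form item-selection methods for ordinal screening instruments.

Given a calibrated 8-item instrument and a binary diagnosis, each method
nominates a k-item subset (k=3 by default):

* ``select_tcc`` — match the full form's test-information peak: among all
  k-subsets, pick the one whose summed information peaks closest to the full
  form's peak location theta*.
* ``select_rasch_regression`` — anchor every person's measure at their
  diagnosis value (0/1 logits), recalibrate the items, and keep the k items
  with the best fit (infit/outfit nearest 1), using residual-PCA loadings as
  the secondary criterion.
* ``select_stepwise_logistic`` — forward stepwise logistic regression (score
  test entry at p < 0.05; Wald, likelihood-ratio or conditional removal at
  p > 0.10), keeping the first k entries.
* ``select_stepwise_dfa`` — stepwise linear discriminant analysis minimizing
  Wilks' lambda (F-to-enter 3.84, F-to-remove 2.71), keeping the first k.

All methods are deterministic given the data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .pcm import (
    PCMParameters,
    ResponseMatrix,
    fit_jmle,
    fit_statistics,
    residual_pca,
    test_information,
)

__all__ = [
    "SelectionResult",
    "select_tcc",
    "select_rasch_regression",
    "select_stepwise_logistic",
    "select_stepwise_dfa",
]

ENTRY_P = 0.05
REMOVAL_P = 0.10
F_TO_ENTER = 3.84
F_TO_REMOVE = 2.71
RIDGE_PENALTY = 1e-4


@dataclass
class SelectionResult:
    """A selected item subset with per-step diagnostics."""

    method: str
    items: list[str]
    trace: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.items)) != len(self.items):
            raise ValueError("selected items must be distinct")


# ---------------------------------------------------------------------------
# Information-peak (test characteristic curve) method
# ---------------------------------------------------------------------------


def select_tcc(
    params: PCMParameters,
    k: int = 3,
    theta_grid: np.ndarray | None = None,
    criterion: str = "peak",
) -> SelectionResult:
    """Pick the k items whose summed information best mirrors the full form.

    Default criterion ``"peak"``: minimize |theta*_subset - theta*_full|,
    ties broken by larger subset information at theta*_full, then by item
    order.  Alternative criterion ``"integral"``: minimize the integrated
    absolute difference between the subset curve and the full curve scaled
    by k/n_items.  Exhaustive over all C(n_items, k) subsets (n_items <= 12),
    greedy beyond that.
    """
    ids = list(params.item_ids)
    if k > len(ids):
        raise ValueError(f"cannot select {k} items from {len(ids)}")
    if criterion not in {"peak", "integral"}:
        raise ValueError("criterion must be 'peak' or 'integral'")

    full = test_information(params, theta_grid, items=ids)
    grid = full.theta_grid
    star_idx = int(np.argmax(full.curve))
    item_curves = {
        item: np.asarray(test_information(params, grid, items=[item]).curve)
        for item in ids
    }

    def criterion_tuple(subset: tuple[str, ...]):
        curve = sum(item_curves[i] for i in subset)
        peak = float(grid[int(np.argmax(curve))])
        if criterion == "peak":
            primary = abs(peak - full.theta_star)
        else:
            target = full.curve * (len(subset) / len(ids))
            primary = float(np.trapezoid(np.abs(curve - target), grid))
        return primary, -float(curve[star_idx]), peak

    if len(ids) <= 12:
        candidates = list(itertools.combinations(ids, k))
    else:  # greedy forward: grow the subset by best marginal criterion
        chosen: list[str] = []
        while len(chosen) < k:
            best = min(
                (c for c in ids if c not in chosen),
                key=lambda c: criterion_tuple(tuple(chosen + [c]))[:2],
            )
            chosen.append(best)
        candidates = [tuple(chosen)]

    trace = []
    best_subset, best_key = None, None
    for subset in candidates:
        primary, neg_info, peak = criterion_tuple(subset)
        key = (primary, neg_info, tuple(ids.index(i) for i in subset))
        trace.append(
            {
                "items": list(subset),
                "criterion": primary,
                "peak_theta": peak,
                "info_at_full_peak": -neg_info,
            }
        )
        if best_key is None or key < best_key:
            best_subset, best_key = subset, key

    trace.insert(0, {"theta_star_full": full.theta_star, "criterion": criterion})
    return SelectionResult(method="tcc", items=list(best_subset), trace=trace)


# ---------------------------------------------------------------------------
# Rasch regression (diagnosis-anchored calibration)
# ---------------------------------------------------------------------------


def select_rasch_regression(
    data: ResponseMatrix, diagnosis, k: int = 3
) -> SelectionResult:
    """Anchor person measures at the 0/1 diagnosis and keep the best-fitting items.

    Every person's measure is fixed at their diagnosis value (0 or 1 logits)
    and the items recalibrated; items are ranked by |infit-1| + |outfit-1|
    (ascending), then by the magnitude of their first-contrast residual-PCA
    loading (small = unidimensional), then by item order.
    """
    diagnosis = np.asarray(diagnosis, dtype=float)
    if diagnosis.size != data.n_persons:
        raise ValueError("diagnosis must align with persons")
    if np.unique(diagnosis).size < 2:
        raise ValueError("diagnosis is constant; no discrimination possible")
    if k > data.n_items:
        raise ValueError(f"cannot select {k} items from {data.n_items}")

    anchors = {i: float(diagnosis[i]) for i in range(data.n_persons)}
    params = fit_jmle(data, anchors=anchors)
    fit = fit_statistics(data, params)
    pca = residual_pca(data, params)

    misfit = np.abs(fit.item_infit - 1.0) + np.abs(fit.item_outfit - 1.0)
    loading = np.abs(pca.first_contrast_loadings)
    order = sorted(range(data.n_items), key=lambda i: (misfit[i], loading[i], i))
    trace = [
        {
            "item": data.item_ids[i],
            "rank": r + 1,
            "infit": float(fit.item_infit[i]),
            "outfit": float(fit.item_outfit[i]),
            "misfit": float(misfit[i]),
            "first_contrast_loading": float(pca.first_contrast_loadings[i]),
        }
        for r, i in enumerate(order)
    ]
    items = sorted((data.item_ids[i] for i in order[:k]), key=data.item_ids.index)
    return SelectionResult(method="rasch_regression", items=items, trace=trace)


# ---------------------------------------------------------------------------
# Forward stepwise logistic regression
# ---------------------------------------------------------------------------


def _logit_fit(y, X):
    """Binomial GLM fit with a small-ridge fallback under separation."""
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        with np.errstate(all="ignore"):
            res = model.fit(maxiter=200)
        if np.all(np.isfinite(res.bse)) and np.abs(res.params).max() < 30:
            return res, False
    except Exception:
        pass
    reg = model.fit_regularized(alpha=RIDGE_PENALTY, L1_wt=0.0, maxiter=500)
    # re-wrap at the ridge solution so llf / score_test / pvalues exist
    with np.errstate(all="ignore"):
        res = model.fit(start_params=np.asarray(reg.params), maxiter=0)
    return res, True


def _design(data: ResponseMatrix, items: list[str]) -> np.ndarray:
    cols = [data.item_ids.index(i) for i in items]
    X = data.responses[:, cols].astype(float)
    return np.column_stack([np.ones(data.n_persons), X])


def select_stepwise_logistic(
    data: ResponseMatrix,
    diagnosis,
    criterion: str = "wald",
    k: int = 3,
) -> SelectionResult:
    """Forward stepwise logistic regression on item scores.

    Entry: Rao score test of each candidate given the current model, best
    candidate enters while p < 0.05.  After each entry, included items are
    re-tested for removal (p > 0.10) by the named criterion: ``wald`` (z
    test), ``lr`` (likelihood ratio against the refitted reduced model), or
    ``conditional`` (likelihood ratio against a one-step approximation of
    the reduced fit).  Stops after k entries or when no candidate qualifies.
    """
    if criterion not in {"wald", "lr", "conditional"}:
        raise ValueError("criterion must be one of wald/lr/conditional")
    y = np.asarray(diagnosis, dtype=float)
    if y.size != data.n_persons:
        raise ValueError("diagnosis must align with persons")
    if k > data.n_items:
        raise ValueError(f"cannot select {k} items from {data.n_items}")

    included: list[str] = []
    trace: list[dict] = []
    from scipy import stats

    def reduced_loglike(items_subset, start_params=None):
        Xr = _design(data, items_subset)
        if criterion == "conditional" and start_params is not None:
            # one-step IRLS from the full model's estimates with the column cut
            model = sm.GLM(y, Xr, family=sm.families.Binomial())
            res = model.fit(start_params=start_params, maxiter=1)
            return res.llf
        res, _ = _logit_fit(y, Xr)
        return res.llf

    while len(included) < k:
        base_X = _design(data, included)
        base_res, ridged = _logit_fit(y, base_X)
        best_item, best_p, best_stat = None, None, None
        for cand in data.item_ids:
            if cand in included:
                continue
            extra = data.responses[:, data.item_ids.index(cand)].astype(float)
            if np.unique(extra).size < 2:
                continue
            try:
                stat, p, _ = base_res.score_test(exog_extra=extra[:, None])
                stat, p = float(np.squeeze(stat)), float(np.squeeze(p))
            except Exception:
                continue
            if best_p is None or p < best_p or (p == best_p and stat > best_stat):
                best_item, best_p, best_stat = cand, p, stat
        if best_item is None or best_p >= ENTRY_P:
            break
        included.append(best_item)
        trace.append(
            {
                "step": len(trace) + 1,
                "action": "enter",
                "item": best_item,
                "score_stat": best_stat,
                "p": best_p,
                "ridged": ridged,
            }
        )

        # removal phase
        changed = True
        while changed and included:
            changed = False
            full_res, ridged = _logit_fit(y, _design(data, included))
            worst_item, worst_p = None, None
            for j, item in enumerate(included):
                if criterion == "wald":
                    p = float(full_res.pvalues[j + 1])  # +1: intercept first
                else:
                    others = [it for it in included if it != item]
                    start = np.delete(np.asarray(full_res.params), j + 1)
                    ll0 = reduced_loglike(others, start)
                    lr = max(0.0, 2.0 * (full_res.llf - ll0))
                    p = float(stats.chi2.sf(lr, df=1))
                if worst_p is None or p > worst_p:
                    worst_item, worst_p = item, p
            if worst_p is not None and worst_p > REMOVAL_P:
                included.remove(worst_item)
                changed = True
                trace.append(
                    {
                        "step": len(trace) + 1,
                        "action": "remove",
                        "item": worst_item,
                        "p": worst_p,
                        "ridged": ridged,
                    }
                )
    items = sorted(included, key=data.item_ids.index)
    return SelectionResult(
        method=f"stepwise_logistic_{criterion}", items=items, trace=trace
    )


# ---------------------------------------------------------------------------
# Stepwise discriminant function analysis
# ---------------------------------------------------------------------------


def _wilks_lambda(X: np.ndarray, y: np.ndarray, cols: list[int]) -> float:
    """Wilks' lambda det(W)/det(T) for the selected columns, two groups."""
    Z = X[:, cols]
    total = Z - Z.mean(axis=0)
    T = total.T @ total
    W = np.zeros_like(T)
    for g in (0, 1):
        Zg = Z[y == g]
        cg = Zg - Zg.mean(axis=0)
        W += cg.T @ cg
    detT = np.linalg.det(T)
    if abs(detT) < 1e-300:
        raise np.linalg.LinAlgError("singular total SSCP")
    return float(np.linalg.det(W) / detT)


def select_stepwise_dfa(data: ResponseMatrix, diagnosis, k: int = 3) -> SelectionResult:
    """Stepwise two-group linear discriminant selection by Wilks' lambda.

    At each step the candidate minimizing the updated Wilks' lambda enters if
    its partial F-to-enter reaches 3.84; included variables with partial
    F-to-remove below 2.71 leave.  Candidates that would make the pooled
    SSCP singular are dropped (logged in the trace).  The first k entries
    are retained.
    """
    y = np.asarray(diagnosis, dtype=int)
    if y.size != data.n_persons:
        raise ValueError("diagnosis must align with persons")
    if np.unique(y).size < 2:
        raise ValueError("diagnosis is constant")
    if k > data.n_items:
        raise ValueError(f"cannot select {k} items from {data.n_items}")

    X = data.responses.astype(float)
    n, g = data.n_persons, 2
    included: list[int] = []
    trace: list[dict] = []

    def partial_f(lam_small, lam_big, p_after):
        # F for the change in lambda when one variable is added to p_after-1
        df2 = n - g - p_after + 1
        if df2 <= 0 or lam_big <= 0:
            return 0.0
        return (lam_small / lam_big - 1.0) * df2 / (g - 1)

    while len(included) < k:
        lam_now = _wilks_lambda(X, y, included) if included else 1.0
        best_j, best_lam, best_f = None, None, None
        for j in range(data.n_items):
            if j in included or np.unique(X[:, j]).size < 2:
                continue
            try:
                lam = _wilks_lambda(X, y, included + [j])
            except np.linalg.LinAlgError:
                trace.append(
                    {"action": "skip_singular", "item": data.item_ids[j]}
                )
                continue
            if lam < 1e-12 or lam >= lam_now:  # tolerance guard (collinearity)
                continue
            f = partial_f(lam_now, lam, len(included) + 1)
            if best_f is None or f > best_f:
                best_j, best_lam, best_f = j, lam, f
        if best_j is None or best_f < F_TO_ENTER:
            break
        included.append(best_j)
        trace.append(
            {
                "step": len(trace) + 1,
                "action": "enter",
                "item": data.item_ids[best_j],
                "wilks_lambda": best_lam,
                "F": best_f,
            }
        )
        # removal
        changed = True
        while changed and len(included) > 1:
            changed = False
            lam_full = _wilks_lambda(X, y, included)
            for j in list(included):
                rest = [c for c in included if c != j]
                lam_rest = _wilks_lambda(X, y, rest)
                f = partial_f(lam_rest, lam_full, len(included))
                if f < F_TO_REMOVE:
                    included.remove(j)
                    trace.append(
                        {
                            "step": len(trace) + 1,
                            "action": "remove",
                            "item": data.item_ids[j],
                            "F": f,
                        }
                    )
                    changed = True
                    break
    items = [data.item_ids[j] for j in sorted(included)]
    return SelectionResult(method="stepwise_dfa", items=items, trace=trace)
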