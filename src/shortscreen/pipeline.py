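"""End-to-end study pipeline: descriptives, calibration, selection, validation.

``run_study`` reproduces the whole short-form construction workflow on one or
more cohorts (CSV files or synthetic cohort specs): descriptive statistics
and internal consistency, partial-credit calibration, the four item-selection
methods, ROC/cut-point analysis of the full form and every candidate short
form, and the agreement/association block (kappa, percent agreement,
chi-square, Spearman, ANOVA by severity).  The result is a plain-dict report
that renders to JSON or markdown deterministically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics, selection, synth
from .metrics import ConfusionTable, round_half_away
from .pcm import MISSING, ResponseMatrix, fit_jmle
from .synth import (
    CUDIT_ITEM_IDS,
    FULL_FORM_CUT,
    ITEM8_RAW_CODES,
    SHORT_FORM_CUT,
    SHORT_FORM_ITEMS,
    CohortSpec,
    generate_cohort,
    score_cudit,
)

__all__ = ["StudyConfig", "CohortData", "read_cohort", "run_study", "render_report"]

log = logging.getLogger("shortscreen")

#: raw instrument code -> consecutive category code, per item
DEFAULT_CODE_MAPS = {
    **{f"item_{i}": {c: c for c in range(5)} for i in range(1, 8)},
    "item_8": {0: 0, 2: 1, 4: 2},
}
DEFAULT_M = {**{f"item_{i}": 4 for i in range(1, 8)}, "item_8": 2}

METHOD_FUNCS = {
    "rasch_regression": "rasch",
    "tcc": "tcc",
    "stepwise_logistic_wald": ("logistic", "wald"),
    "stepwise_logistic_lr": ("logistic", "lr"),
    "stepwise_logistic_conditional": ("logistic", "conditional"),
    "stepwise_dfa": "dfa",
}


@dataclass
class CohortData:
    """A loaded cohort: responses plus optional diagnosis/symptom columns."""

    responses: ResponseMatrix
    dsm_positive: np.ndarray | None = None
    symptom_count: np.ndarray | None = None


@dataclass
class StudyConfig:
    """Configuration of a full study run.

    ``cohorts`` maps sample name -> CSV path, CohortSpec, or CohortData.
    """

    cohorts: dict[str, object]
    cut_full: int = FULL_FORM_CUT
    cut_sf: int = SHORT_FORM_CUT
    k: int = 3
    methods: tuple[str, ...] = (
        "rasch_regression",
        "tcc",
        "stepwise_logistic_lr",
        "stepwise_dfa",
    )
    drop_item1_zero: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise ValueError("at least one cohort is required")
        if self.cut_full < 1 or self.cut_sf < 1 or self.k < 1:
            raise ValueError("cuts and k must be positive integers")
        unknown = set(self.methods) - set(METHOD_FUNCS)
        if unknown:
            raise ValueError(f"unknown selection methods: {sorted(unknown)}")


def read_cohort(path, code_maps: dict | None = None) -> CohortData:
    """Load a cohort CSV (one row per person, columns item_1..item_8).

    Raw instrument codes are mapped to consecutive categories via
    ``code_maps`` (default: identity for items 1-7, 0/2/4 -> 0/1/2 for item
    8); empty cells become missing responses.  Schema violations are
    collected and raised together with row numbers.
    """
    code_maps = code_maps or DEFAULT_CODE_MAPS
    df = pd.read_csv(path)
    errors: list[str] = []
    items = [c for c in CUDIT_ITEM_IDS if c in df.columns]
    if len(items) < 2:
        raise ValueError(f"{path}: expected item columns {CUDIT_ITEM_IDS}")
    extra = set(df.columns) - set(CUDIT_ITEM_IDS) - {"dsm_positive", "symptom_count"}
    if extra:
        errors.append(f"unknown columns: {sorted(extra)}")

    n = len(df)
    resp = np.full((n, len(items)), MISSING, dtype=int)
    for j, item in enumerate(items):
        cmap = code_maps[item]
        for row, val in enumerate(df[item]):
            if pd.isna(val):
                continue
            if float(val) != int(float(val)):
                errors.append(f"row {row}: non-integer response {val!r} for {item}")
                continue
            code = cmap.get(int(float(val)))
            if code is None:
                errors.append(f"row {row}: invalid code {int(float(val))} for {item}")
                continue
            resp[row, j] = code
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))

    matrix = ResponseMatrix(
        responses=resp, item_ids=items, m=np.array([DEFAULT_M[i] for i in items])
    )
    dsm = (
        df["dsm_positive"].to_numpy(dtype=int)
        if "dsm_positive" in df.columns
        else None
    )
    sym = (
        df["symptom_count"].to_numpy(dtype=int)
        if "symptom_count" in df.columns
        else None
    )
    return CohortData(responses=matrix, dsm_positive=dsm, symptom_count=sym)


def _load(source) -> CohortData:
    if isinstance(source, CohortData):
        return source
    if isinstance(source, CohortSpec):
        cohort = generate_cohort(source)
        return CohortData(
            responses=cohort.responses,
            dsm_positive=cohort.dsm_positive.astype(int),
            symptom_count=cohort.symptom_count,
        )
    return read_cohort(Path(source))


def _table(truth: np.ndarray, screen: np.ndarray) -> ConfusionTable:
    return ConfusionTable(
        tp=int(np.sum(truth & screen)),
        fn=int(np.sum(truth & ~screen)),
        fp=int(np.sum(~truth & screen)),
        tn=int(np.sum(~truth & ~screen)),
    )


def _agreement_block(truth, screen) -> dict:
    t = _table(truth, screen)
    se, sp = metrics.sensitivity_specificity(t)
    chi2, p = metrics.pearson_chi2(t)
    return {
        "table": {"tp": t.tp, "fn": t.fn, "fp": t.fp, "tn": t.tn},
        "kappa": metrics.cohens_kappa(t),
        "percent_agreement": metrics.percent_agreement(t),
        "chi2": chi2,
        "chi2_p": p,
        "sensitivity": se,
        "specificity": sp,
    }


def _roc_row(name, scores, labels, items, forced_cut=None) -> dict:
    roc = metrics.roc_analysis(scores, labels)
    cut = roc.optimal_cut if forced_cut is None else float(forced_cut)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    se = 100.0 * float(np.mean(scores[labels == 1] >= cut))
    sp = 100.0 * float(np.mean(scores[labels == 0] < cut))
    return {
        "name": name,
        "items": items,
        "cut": cut,
        "sensitivity": se,
        "specificity": sp,
        "auc": roc.auc,
        "auc_ci": list(roc.auc_ci),
        "youden_j": se + sp - 100.0,
    }


def _analyze_sample(name: str, cohort: CohortData, config: StudyConfig) -> dict:
    resp = cohort.responses
    n_in = resp.n_persons
    scores = score_cudit(resp)
    if cohort.dsm_positive is None:
        raise ValueError(f"cohort {name!r} has no dsm_positive column")
    dsm = cohort.dsm_positive.astype(bool)

    # ----- exclusions: incomplete full totals; optional item-1 zeros -----
    incomplete = scores["total"].isna().to_numpy()
    item1_zero = np.zeros(n_in, dtype=bool)
    if config.drop_item1_zero and "item_1" in resp.item_ids:
        item1_zero = resp.responses[:, resp.item_ids.index("item_1")] == 0
    excluded = incomplete | item1_zero
    analyzed = ~excluded
    n_analyzed = int(analyzed.sum())
    assert n_in - int(excluded.sum()) == n_analyzed
    log.info(
        "%s: %d persons in, %d incomplete, %d item-1 zero, %d analyzed",
        name, n_in, int(incomplete.sum()), int(item1_zero.sum()), n_analyzed,
    )

    # ----- descriptives (all persons; totals where computable) -----
    obs = resp.mask
    endorsement = {
        item: 100.0 * float(np.mean(resp.responses[obs[:, j], j] >= 1))
        for j, item in enumerate(resp.item_ids)
    }
    complete_raw = _raw_scores(resp)[~incomplete]
    descriptives = {
        "n": n_in,
        "prevalence_pct": 100.0 * float(np.mean(dsm)),
        "n_positive": int(dsm.sum()),
        "total_mean": float(scores["total"].dropna().mean()),
        "total_sd": float(scores["total"].dropna().std(ddof=1)),
        "alpha_full": metrics.cronbach_alpha(complete_raw),
        "endorsement_pct": endorsement,
        "exclusions": {
            "n_in": n_in,
            "incomplete_total": int(incomplete.sum()),
            "item1_zero": int(item1_zero.sum()),
            "n_analyzed": n_analyzed,
        },
    }

    # ----- calibration and selection (all persons with data) -----
    params = fit_jmle(resp)
    sub = _subset_cohort(cohort, analyzed)
    selections: dict[str, dict] = {}
    for method in config.methods:
        kind = METHOD_FUNCS[method]
        if kind == "tcc":
            res = selection.select_tcc(params, k=config.k)
        elif kind == "rasch":
            res = selection.select_rasch_regression(
                sub.responses, sub.dsm_positive, k=config.k
            )
        elif kind == "dfa":
            res = selection.select_stepwise_dfa(
                sub.responses, sub.dsm_positive, k=config.k
            )
        else:
            res = selection.select_stepwise_logistic(
                sub.responses, sub.dsm_positive, criterion=kind[1], k=config.k
            )
        selections[method] = {"items": res.items, "trace_steps": len(res.trace)}

    # ----- ROC rows (Table-2-like structure) -----
    sub_scores = score_cudit(sub.responses)
    y = sub.dsm_positive.astype(int)
    total = sub_scores["total"].to_numpy()
    rows = [
        _roc_row("full_standard_cut", total, y, resp.item_ids, forced_cut=config.cut_full),
        _roc_row("full_alternative_cut", total, y, resp.item_ids),
    ]
    for method in config.methods:
        items = selections[method]["items"]
        sf = _sum_items(sub.responses, items)
        rows.append(_roc_row(method, sf, y, items))

    # ----- agreement blocks for the canonical short form -----
    dsm_sub = y.astype(bool)
    full_pos = total >= config.cut_full
    sf_total = _sum_items(sub.responses, SHORT_FORM_ITEMS)
    sf_pos = sf_total >= config.cut_sf
    agreement = {
        "full_vs_dsm": _agreement_block(dsm_sub, full_pos),
        "sf_vs_dsm": _agreement_block(dsm_sub, sf_pos),
        "sf_vs_full": _agreement_block(full_pos, sf_pos),
        "sf_pos_rate_pct": 100.0 * float(np.mean(sf_pos)),
        "pct_full_pos_also_sf_pos": (
            100.0 * float(np.mean(sf_pos[full_pos])) if full_pos.any() else None
        ),
    }

    # ----- association block -----
    association: dict = {
        "spearman_sf_full": metrics.spearman_rho(sf_total, total),
        "alpha_sf": metrics.cronbach_alpha(
            _raw_scores(sub.responses, SHORT_FORM_ITEMS)
        ),
    }
    if cohort.symptom_count is not None:
        sym = cohort.symptom_count[analyzed]
        association["spearman_sf_symptoms"] = metrics.spearman_rho(sf_total, sym)
        sev = np.full(sym.shape, "none", dtype=object)
        sev[sym >= 2], sev[sym >= 4], sev[sym >= 6] = "mild", "moderate", "severe"
        if len(set(sev.tolist())) >= 2:
            f, df_, eta2, desc = metrics.oneway_anova_eta2(sf_total, sev)
            association["anova_sf_by_severity"] = {
                "F": f,
                "df": list(df_),
                "eta2": eta2,
                "groups": {g: {"n": d[0], "mean": d[1], "sd": d[2]} for g, d in desc.items()},
            }

    return {
        "descriptives": descriptives,
        "selection": selections,
        "roc_rows": rows,
        "agreement": agreement,
        "association": association,
    }


def _raw_scores(resp: ResponseMatrix, items: list[str] | None = None) -> np.ndarray:
    """Persons x items raw-code scores (NaN missing), item 8 back on 0/2/4."""
    items = items or resp.item_ids
    cols = [resp.item_ids.index(i) for i in items]
    raw = resp.responses[:, cols].astype(float)
    raw[resp.responses[:, cols] == MISSING] = np.nan
    if "item_8" in items:
        j = items.index("item_8")
        ok = ~np.isnan(raw[:, j])
        raw[ok, j] = ITEM8_RAW_CODES[raw[ok, j].astype(int)]
    return raw


def _sum_items(resp: ResponseMatrix, items: list[str]) -> np.ndarray:
    return _raw_scores(resp, items).sum(axis=1)


def _subset_cohort(cohort: CohortData, keep: np.ndarray) -> CohortData:
    resp = cohort.responses
    return CohortData(
        responses=ResponseMatrix(
            responses=resp.responses[keep],
            item_ids=resp.item_ids,
            m=resp.m,
        ),
        dsm_positive=cohort.dsm_positive[keep],
        symptom_count=(
            cohort.symptom_count[keep] if cohort.symptom_count is not None else None
        ),
    )


def run_study(config: StudyConfig) -> dict:
    """Run the full pipeline on every configured cohort.

    Returns a report dict: ``{"config": ..., "samples": {name: block}}``,
    a pure function of the inputs (deterministic given config).
    """
    report = {
        "config": {
            "cut_full": config.cut_full,
            "cut_sf": config.cut_sf,
            "k": config.k,
            "methods": list(config.methods),
            "drop_item1_zero": config.drop_item1_zero,
            "seed": config.seed,
        },
        "samples": {},
    }
    for name, source in config.cohorts.items():
        report["samples"][name] = _analyze_sample(name, _load(source), config)
    return report


def _fmt(x) -> str:
    if x is None:
        return "—"
    if isinstance(x, float):
        return f"{round_half_away(x, 2):.2f}"
    return str(x)


def render_report(report: dict, format: str = "json") -> str:
    """Render a study report as JSON (machine) or markdown (human).

    Markdown shows every statistic to 2 decimals (half away from zero) and
    appends a footnote on the chi-square degrees of freedom convention.
    """
    if format == "json":
        return json.dumps(report, indent=2, sort_keys=False, default=_json_default)
    if format != "markdown":
        raise ValueError("format must be 'json' or 'markdown'")

    lines: list[str] = ["# Short-form study report", ""]
    for name, block in report["samples"].items():
        d = block["descriptives"]
        lines += [
            f"## {name}",
            "",
            f"- persons: {d['n']} (analyzed: {d['exclusions']['n_analyzed']})",
            f"- diagnosis prevalence: {_fmt(d['prevalence_pct'])}% (n={d['n_positive']})",
            f"- full-form total: mean {_fmt(d['total_mean'])}, SD {_fmt(d['total_sd'])}",
            f"- Cronbach alpha (full form): {_fmt(d['alpha_full'])}",
            "",
            "| Method | Items | Cut | Sensitivity | Specificity | AUC | CI |",
            "|---|---|---|---|---|---|---|",
        ]
        for row in block["roc_rows"]:
            ci = f"{_fmt(row['auc_ci'][0])}–{_fmt(row['auc_ci'][1])}"
            items = ", ".join(i.removeprefix("item_") for i in row["items"])
            lines.append(
                f"| {row['name']} | {items} | {row['cut']:.0f} "
                f"| {_fmt(row['sensitivity'])} | {_fmt(row['specificity'])} "
                f"| {_fmt(row['auc'])} | {ci} |"
            )
        lines.append("")
        ag = block["agreement"]
        for key in ("full_vs_dsm", "sf_vs_dsm", "sf_vs_full"):
            b = ag[key]
            lines.append(
                f"- {key}: kappa {_fmt(b['kappa'])}, agreement "
                f"{_fmt(b['percent_agreement'])}%, chi2 {_fmt(b['chi2'])}"
            )
        assoc = block["association"]
        lines.append(
            f"- Spearman SF vs full: {_fmt(assoc['spearman_sf_full'])}; "
            f"alpha (SF): {_fmt(assoc['alpha_sf'])}"
        )
        if "anova_sf_by_severity" in assoc:
            a = assoc["anova_sf_by_severity"]
            lines.append(
                f"- ANOVA SF by severity: F({a['df'][0]}, {a['df'][1]}) = "
                f"{_fmt(a['F'])}, eta² = {_fmt(a['eta2'])}"
            )
        lines.append("")
    lines += [
        "---",
        "Note: chi-square statistics are Pearson statistics on 2×2 tables and are",
        "reported with df = 1 (reports elsewhere sometimes print df = 2 for the",
        "same tables; the statistic is identical).",
        "",
    ]
    return "\n".join(lines)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
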