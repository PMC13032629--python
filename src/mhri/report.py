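"""End-to-end cohort analysis: the full table bundle from one cohort frame.

Given a cohort (one row per eye), produces the study-style outputs:
group-comparison table, pre/post paired test, correlation table, post-VA
regression, anatomical and visual ROC tables, and the inter-rater agreement
summary. Anatomical analyses use all eyes; visual analyses are restricted to
eyes with successful closure. Every serialized output embeds the seed and a
config hash for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import prognostats as ps

logger = logging.getLogger("mhri")

ROC_SCORES = ("mhri", "mld_um")


def _roc_table(df: pd.DataFrame, labels: np.ndarray, seed: int) -> pd.DataFrame:
    rows = []
    for i, score in enumerate(ROC_SCORES):
        r = ps.roc_analysis(df[score].to_numpy(float), labels, seed=seed + i)
        rows.append({
            "parameter": score,
            "auc": r.auc,
            "auc_ci_low": r.auc_ci_low,
            "auc_ci_high": r.auc_ci_high,
            "cutoff": r.cutoff,
            "youden_j": r.youden_j,
            "sensitivity": r.sensitivity,
            "specificity": r.specificity,
            "direction": r.direction,
            "p_value": r.p_value,
            "n_positive": r.n_positive,
            "n_negative": r.n_negative,
        })
    return pd.DataFrame(rows)


def analyze_cohort(df: pd.DataFrame, seed: int = 0) -> dict:
    """Run every cohort statistic; returns a dict of DataFrames/dicts."""
    required = {"closure", "post_va_logmar", "pre_va_logmar", "mhri", "mld_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort is missing required columns: {sorted(missing)}")
    df = ps.classify_outcomes(df)
    closed = df[df["closure_success"]]
    logger.info("cohort: %d eyes in, %d closed (visual analyses)", len(df), len(closed))
    out: dict = {"n_eyes": len(df), "n_closed": len(closed), "seed": seed}

    # Table 2 analogue: closure success vs failure
    if df["closure"].nunique() == 2:
        out["group_comparison"] = ps.group_tests(df, grouping="closure")
    else:
        out["group_comparison"] = None
        logger.warning("single closure class: group comparison skipped")

    out["prepost_va"] = ps.paired_prepost_test(
        df["pre_va_logmar"], df["post_va_logmar"]
    )

    # Table 3 analogue: correlations with post-VA among closed eyes
    corr_rows = []
    for var in ("cri_max", "cri_mean", "pcri_min", "pcri_mean", "mhri", "mld_um",
                "pre_va_logmar", "age_years"):
        if var not in closed.columns:
            continue
        rho, p = ps.spearman(closed[var], closed["post_va_logmar"])
        corr_rows.append({"parameter": var, "spearman_rho": rho, "p_value": p, "n": len(closed)})
    out["correlations"] = pd.DataFrame(corr_rows)

    # Table 4 analogue: adjusted regression on closed eyes
    try:
        out["regression"] = ps.fit_postva_regression(df)
    except ValueError as exc:
        out["regression"] = None
        logger.warning("regression skipped: %s", exc)

    # Table 5 analogue: anatomical ROC over all eyes
    if df["closure_success"].nunique() == 2:
        out["roc_anatomical"] = _roc_table(df, df["closure_success"].to_numpy(bool), seed)
    else:
        out["roc_anatomical"] = None
        logger.warning("anatomical ROC skipped: only one closure class present")

    # Table 6 analogue: visual ROC among closed eyes only
    vs = closed["visual_success"].astype(bool).to_numpy()
    if 0 < vs.sum() < len(vs):
        out["roc_visual"] = _roc_table(closed, vs, seed + 100)
    else:
        out["roc_visual"] = None
        logger.warning("visual ROC skipped: only one visual-success class present")

    if {"rater1_mhri", "rater2_mhri"} <= set(df.columns):
        out["agreement"] = ps.rater_agreement(df["rater1_mhri"], df["rater2_mhri"])
        ba = ps.bland_altman(df["rater1_mhri"], df["rater2_mhri"])
        out["bland_altman_points"] = pd.DataFrame(
            {"mean": ba.means, "difference": ba.differences}
        )
    else:
        out["agreement"] = None

    out["visual_success_pct"] = (
        100.0 * float(np.mean(vs)) if len(vs) else float("nan")
    )
    out["closure_success_pct"] = 100.0 * float(df["closure_success"].mean())
    return out


def _meta(seed: int, df: pd.DataFrame) -> dict:
    h = hashlib.sha256(pd.util.hash_pandas_object(df, index=False).to_numpy().tobytes())
    return {"seed": seed, "cohort_hash": h.hexdigest()[:16], "n_rows": len(df)}


def write_report_bundle(results: dict, outdir: str | Path, df: pd.DataFrame, seed: int) -> list[Path]:
    """Serialize the analysis bundle as CSV/JSON files under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_df(name: str, obj) -> None:
        p = outdir / f"{name}.csv"
        obj.to_csv(p, index=False)
        written.append(p)

    meta = _meta(seed, df)
    for name, key in (
        ("table2_group_comparison", "group_comparison"),
        ("table3_correlations", "correlations"),
        ("table5_roc_anatomical", "roc_anatomical"),
        ("table6_roc_visual", "roc_visual"),
        ("bland_altman_points", "bland_altman_points"),
    ):
        if results.get(key) is not None:
            save_df(name, results[key])
    reg = results.get("regression")
    summary = {
        "metadata": meta,
        "n_eyes": results["n_eyes"],
        "n_closed": results["n_closed"],
        "closure_success_pct": results["closure_success_pct"],
        "visual_success_pct": results["visual_success_pct"],
        "prepost_va": results["prepost_va"],
        "regression": None
        if reg is None
        else {
            "n": reg.n,
            "r_squared": reg.r_squared,
            "intercept": reg.intercept,
            "predictors": {
                k: vars(v) for k, v in reg.predictors.items()
            },
        },
        "agreement": None
        if results.get("agreement") is None
        else vars(results["agreement"]),
        "skipped": [
            k for k in ("group_comparison", "roc_anatomical", "roc_visual", "regression")
            if results.get(k) is None
        ],
    }
    p = outdir / "table4_regression_and_summary.json"
    p.write_text(json.dumps(summary, indent=1, default=float))
    written.append(p)
    return written


def render_markdown_report(outdir: str | Path) -> Path:
    """Render a human-readable summary.md from a written report bundle."""
    outdir = Path(outdir)
    summary = json.loads((outdir / "table4_regression_and_summary.json").read_text())
    lines = ["# Cohort analysis report", ""]
    lines.append(f"- eyes analyzed: {summary['n_eyes']} ({summary['n_closed']} closed)")
    lines.append(f"- anatomical closure: {summary['closure_success_pct']:.2f}%")
    lines.append(f"- visual success among closed eyes: {summary['visual_success_pct']:.1f}%")
    pp = summary["prepost_va"]
    lines.append(f"- pre vs post VA: {pp['test']}, p = {pp['p_value']:.3g}")
    if summary["agreement"]:
        a = summary["agreement"]
        lines.append(
            f"- inter-rater MHRI: ICC {a['icc_value']:.3f} ({a['icc_model_label']}), "
            f"bias {a['bias']:.4f}, LOA [{a['loa_low']:.4f}, {a['loa_high']:.4f}]"
        )
    for name, title in (
        ("table5_roc_anatomical", "ROC — anatomical closure"),
        ("table6_roc_visual", "ROC — visual success (closed eyes)"),
    ):
        path = outdir / f"{name}.csv"
        if path.exists():
            t = pd.read_csv(path)
            lines.append("")
            lines.append(f"## {title}")
            for _, r in t.iterrows():
                lines.append(
                    f"- {r['parameter']}: AUC {100 * r['auc']:.1f}% "
                    f"(95% CI {100 * r['auc_ci_low']:.0f}–{100 * r['auc_ci_high']:.0f}%), "
                    f"cutoff {r['cutoff']:.2f} (positive if {r['direction']}), "
                    f"J {r['youden_j']:.2f}, sens {100 * r['sensitivity']:.1f}%, "
                    f"spec {100 * r['specificity']:.1f}%"
                )
    if summary["skipped"]:
        lines.append("")
        lines.append(f"Skipped (degenerate input): {', '.join(summary['skipped'])}")
    out = outdir / "summary.md"
    out.write_text("\n".join(lines) + "\n")
    return out
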