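#!/usr/bin/env python
"""ROC/Youden cutoffs for anatomical and visual success, plus rater agreement.

Reads results/cohort.csv; writes the ROC tables, the Bland-Altman points and
optional figures under results/tables/, and renders summary.md.
"""

import argparse
from pathlib import Path

import pandas as pd

from mhri import cohort as ch
from mhri import prognostats as ps
from mhri import report as rp


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/tables"))
    ap.add_argument("--figures", action="store_true", help="also write SVG figures")
    args = ap.parse_args()

    df = ch.read_cohort_csv(args.cohort)
    results = rp.analyze_cohort(df, seed=args.seed)
    rp.write_report_bundle(results, args.outdir, df, args.seed)

    for key, title in (("roc_anatomical", "anatomical closure"),
                       ("roc_visual", "visual success (closed eyes)")):
        table = results[key]
        if table is None:
            print(f"{title}: skipped (single class)")
            continue
        for _, r in table.iterrows():
            print(
                f"{title} — {r.parameter}: AUC {100 * r.auc:.1f}% "
                f"(CI {100 * r.auc_ci_low:.0f}–{100 * r.auc_ci_high:.0f}%), "
                f"cutoff {r.cutoff:.2f} ({r.direction} predicts positive), "
                f"J {r.youden_j:.2f}, sens {100 * r.sensitivity:.0f}%, "
                f"spec {100 * r.specificity:.0f}%"
            )
    agr = results["agreement"]
    if agr is not None:
        print(
            f"inter-rater MHRI: ICC {agr.icc_value:.3f}, bias {agr.bias:+.4f}, "
            f"LOA [{agr.loa_low:.4f}, {agr.loa_high:.4f}]"
        )

    if args.figures:
        from mhri import plots as pl

        labelled = ps.classify_outcomes(df)
        if results["roc_anatomical"] is not None:
            pl.plot_roc({"MHRI": df.mhri, "MLD": df.mld_um},
                        labelled.closure_success, args.outdir / "fig_roc_anatomical.svg")
        if agr is not None:
            ba = ps.bland_altman(df.rater1_mhri, df.rater2_mhri)
            pl.plot_bland_altman(ba, args.outdir / "fig_bland_altman.svg")
        print(f"figures -> {args.outdir}")

    print(str(rp.render_markdown_report(args.outdir)))


if __name__ == "__main__":
    main()
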