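"""Optional figures: ROC curves and the Bland-Altman scatter."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from sklearn.metrics import roc_curve

from .prognostats import BlandAltmanResult


def plot_roc(scores_by_name: dict[str, np.ndarray], labels, path: str | Path) -> Path:
    """One ROC figure with a curve per score (auto-oriented to AUC >= 0.5)."""
    from sklearn.metrics import roc_auc_score

    labels = np.asarray(labels, dtype=bool)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for name, s in scores_by_name.items():
        s = np.asarray(s, dtype=float)
        if roc_auc_score(labels, s) < 0.5:
            s = -s
        fpr, tpr, _ = roc_curve(labels, s)
        ax.plot(fpr, tpr, label=f"{name} (AUC {roc_auc_score(labels, s):.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_bland_altman(ba: BlandAltmanResult, path: str | Path) -> Path:
    """Difference-vs-mean scatter with bias and 95% limits of agreement."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ba.means, ba.differences, s=14, alpha=0.7)
    for y, style in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(y, color="tab:red", linestyle=style, lw=1)
    ax.set_xlabel("mean of raters")
    ax.set_ylabel("difference (rater 1 - rater 2)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
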