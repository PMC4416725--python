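"""Optional matplotlib figures: ROC curves and cumulative-risk KM curves."""

from __future__ import annotations

from typing import Mapping


def _axes():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_roc(curves: Mapping[str, "RocCurve"], path) -> None:
    """Overlay ROC curves (one per model) and save to ``path``."""
    plt = _axes()
    fig, ax = plt.subplots(figsize=(5, 5))
    for label, curve in curves.items():
        ax.plot(curve.fpr, curve.tpr, label=f"{label} (AUC={curve.auc:.3f})")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_cumulative_risk(curves: Mapping[str, "KMCurve"], path) -> None:
    """Kaplan-Meier curves drawn as cumulative risk (1 - S) by onset age."""
    plt = _axes()
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        ax.step(curve.times, curve.cumulative_risk(), where="post", label=label)
    ax.set_xlabel("age of onset (years)")
    ax.set_ylabel("cumulative risk")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
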