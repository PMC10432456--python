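"""Basic figure analogues rendered from a written report directory.

Six plots mirror the standard comparison views: per-protein accuracy
distributions, pairwise accuracy correlations, combined-vs-individual
accuracy, per-class accuracy, agreement-category accuracy/proportion, and
confidence-vs-RSA profiles.  Styling is deliberately minimal.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .pipeline import COMBINED_MODEL_ID


def render_report_plots(report_dir: str | Path, outdir: str | Path | None = None) -> list[Path]:
    """Render the six figure analogues; returns the written paths."""
    report_dir = Path(report_dir)
    outdir = report_dir / "plots" if outdir is None else Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    required = [
        "per_protein_accuracy.tsv",
        "correlations.tsv",
        "class_accuracy.tsv",
        "agreement.tsv",
    ]
    missing = [f for f in required if not (report_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete report directory, missing {missing}")

    acc = pd.read_csv(report_dir / "per_protein_accuracy.tsv", sep="\t", index_col=0)
    corr = pd.read_csv(report_dir / "correlations.tsv", sep="\t")
    cls = pd.read_csv(report_dir / "class_accuracy.tsv", sep="\t")
    agreement = pd.read_csv(report_dir / "agreement.tsv", sep="\t")
    written: list[Path] = []

    base_models = [m for m in acc.columns if m != COMBINED_MODEL_ID]

    # 1: per-protein accuracy distributions of the base models
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.violinplot([acc[m] for m in base_models], showmeans=True)
    ax.set_xticks(range(1, len(base_models) + 1), base_models)
    ax.set_ylabel("per-protein accuracy")
    written.append(_save(fig, outdir / "per_protein_accuracy.png"))

    # 2: pairwise correlation bar chart
    fig, ax = plt.subplots(figsize=(6, 4))
    labels = corr["model_a"] + " / " + corr["model_b"]
    ax.bar(labels, corr["r"])
    ax.set_ylabel("Pearson r of per-protein accuracy")
    ax.tick_params(axis="x", rotation=45)
    written.append(_save(fig, outdir / "accuracy_correlations.png"))

    # 3: combined model vs individual means
    fig, ax = plt.subplots(figsize=(6, 4))
    if COMBINED_MODEL_ID in acc.columns:
        ax.violinplot([acc[COMBINED_MODEL_ID]], showmeans=True)
        for m in base_models:
            ax.axhline(acc[m].mean(), ls="--", lw=1, label=m)
        ax.legend(fontsize=7)
        ax.set_ylabel("per-protein accuracy (combined)")
    else:
        ax.text(0.5, 0.5, "no combined model in report", ha="center")
    written.append(_save(fig, outdir / "combined_accuracy.png"))

    # 4: per-class accuracy grouped bars
    fig, ax = plt.subplots(figsize=(7, 4))
    classes = sorted(cls["aa_class"].unique())
    models = list(cls["model_id"].unique())
    width = 0.8 / len(models)
    for j, m in enumerate(models):
        sub = cls[cls["model_id"] == m].set_index("aa_class")["accuracy"]
        ax.bar(
            np.arange(len(classes)) + j * width,
            [sub.get(c, np.nan) for c in classes],
            width=width,
            label=m,
        )
    ax.set_xticks(np.arange(len(classes)) + 0.4, classes)
    ax.set_ylabel("accuracy")
    ax.legend(fontsize=7)
    written.append(_save(fig, outdir / "class_accuracy.png"))

    # 5: agreement categories (accuracy + proportion)
    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    present = agreement.dropna(subset=["accuracy"])
    axes[0].bar(present["category"], present["accuracy"])
    axes[0].set_ylabel("accuracy")
    axes[1].bar(agreement["category"], agreement["proportion"])
    axes[1].set_ylabel("proportion of sites")
    empties = agreement.loc[agreement["n_sites"] == 0, "category"].tolist()
    if empties:
        axes[0].set_title(f"absent categories: {', '.join(empties)}", fontsize=8)
    for ax in axes:
        ax.tick_params(axis="x", rotation=45)
    written.append(_save(fig, outdir / "agreement.png"))

    # 6: mean confidence vs RSA per model
    fig, ax = plt.subplots(figsize=(6, 4))
    for path in sorted(report_dir.glob("rsa_mean_confidence_*.tsv")):
        mc = pd.read_csv(path, sep="\t")
        model = path.stem.replace("rsa_mean_confidence_", "")
        mid = (mc["rsa_lo"] + mc["rsa_hi"]) / 2
        ax.plot(mid, mc["mean_confidence"], label=model, lw=1)
    ax.axvline(0.2, color="k", ls=":", lw=1)
    ax.set_xlabel("RSA")
    ax.set_ylabel("mean confidence")
    ax.legend(fontsize=7)
    written.append(_save(fig, outdir / "confidence_vs_rsa.png"))

    return written


def _save(fig, path: Path) -> Path:
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
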