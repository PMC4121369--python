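"""Optional diagnostic figures (matplotlib, Agg backend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def baf_histogram(baf, path, bins: int = 50, title: str = "B-allele frequency"):
    """Per-sample BAF histogram; bands appear as distinct peaks."""
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.hist(baf, bins=bins, range=(0, 1), color="steelblue")
    ax.set_xlabel("B-allele frequency")
    ax.set_ylabel("SNPs")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def repeat_boxplot(records, index_sample, path):
    """Box plots of repeat-element methylation per tissue x assay with the
    index sample marked."""
    groups = list(records.groupby(["tissue", "assay"], sort=True))
    fig, axes = plt.subplots(1, max(len(groups), 1), figsize=(3 * max(len(groups), 1), 3.2))
    if len(groups) == 1:
        axes = [axes]
    for ax, ((tissue, assay), group) in zip(axes, groups):
        ref = group.loc[group["sample_id"] != index_sample, "mean_methylation"]
        ax.boxplot([ref], tick_labels=[f"{tissue}\n{assay}"])
        idx = group.loc[group["sample_id"] == index_sample, "mean_methylation"]
        if len(idx):
            ax.plot([1], [float(idx.iloc[0])], "r*", markersize=12, label="index")
        ax.set_ylabel("% methylation")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
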