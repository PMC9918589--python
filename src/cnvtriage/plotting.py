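"""Static evidence plots: binned depth/MQ panel and anomalous-read panel.

These are file-output equivalents of an interactive review interface —
one PNG per CNV, with the proband's binned depth, the optional reference
overlay, the CNV boundaries, and anomalous reads drawn as horizontal
segments colour-coded by category (inward insert outliers red, outward
blue, same-direction cyan, split purple).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .evidence import EvidenceProfile

__all__ = ["plot_evidence_panel", "CATEGORY_COLOURS"]

CATEGORY_COLOURS = {
    "inward_insert_outlier": "tab:red",
    "outward": "tab:blue",
    "same_direction": "tab:cyan",
    "split": "tab:purple",
}


def plot_evidence_panel(
    evidence: EvidenceProfile,
    out_png: str | Path,
    reference_bins=None,
) -> Path:
    cnv = evidence.cnv
    fig, (ax_depth, ax_mq, ax_reads) = plt.subplots(
        3, 1, figsize=(10, 8), sharex=True,
        gridspec_kw={"height_ratios": [3, 2, 3]},
    )
    mids = [(b.interval.start + b.interval.end) / 2 for b in evidence.bins]
    ax_depth.plot(mids, [b.mean_depth for b in evidence.bins], lw=0.8, label="sample")
    if reference_bins is not None:
        ax_depth.plot(
            mids, [b.mean_depth for b in reference_bins],
            lw=0.8, alpha=0.6, label="reference",
        )
        ax_depth.legend(fontsize=8)
    for i in evidence.reference_flagged_bins:
        ax_depth.axvspan(
            evidence.bins[i].interval.start, evidence.bins[i].interval.end,
            color="grey", alpha=0.3,
        )
    ax_depth.set_ylabel("mean depth")
    title = f"{cnv.name()}  depth ratio={evidence.depth_ratio:.2f}" if evidence.depth_ratio else cnv.name()
    ax_depth.set_title(f"{title}  q={evidence.quality_score:.2f}", fontsize=10)

    ax_mq.plot(mids, [b.mean_mq if b.mean_mq is not None else float("nan") for b in evidence.bins], lw=0.8)
    ax_mq.set_ylabel("mean MQ")

    for y, read in enumerate(evidence.anomalous_reads):
        left = min(read.start, read.mate_start or read.start)
        right = max(read.end, (read.mate_start or read.start) + (read.end - read.start))
        ax_reads.hlines(y, left, right, colors=CATEGORY_COLOURS[read.category],
                        lw=1.5 if read.supports_cnv else 0.5)
    ax_reads.set_ylabel("anomalous reads")
    ax_reads.set_xlabel(f"{cnv.chrom} position (bp)")

    for ax in (ax_depth, ax_mq, ax_reads):
        ax.axvline(cnv.start, color="k", ls="--", lw=0.8)
        ax.axvline(cnv.end, color="k", ls="--", lw=0.8)

    out_png = Path(out_png)
    out_png.parent.mkdir(parents=True, exist_ok=True)
    fig.tight_layout()
    fig.savefig(out_png, dpi=110)
    plt.close(fig)
    return out_png
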