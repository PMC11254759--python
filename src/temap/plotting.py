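"""Minimal Manhattan-style rendering of a binned insertion-site track."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .insertion_seq import BinTrack


def manhattan_plot(
    track: BinTrack,
    path: str | Path,
    guide_rpm: float = 10_000.0,
    target_bins: Optional[set[tuple[str, int]]] = None,
    title: str = "insertion sites",
) -> None:
    """Scatter bin RPM along concatenated reference coordinates, with a
    dashed guide line at ``guide_rpm`` and target-locus bins highlighted."""
    target_bins = target_bins or set()
    refs = sorted({ref for ref, _ in track.raw})
    offsets = {}
    cursor = 0
    spans = {}
    for ref in refs:
        bins = [b for r, b in track.raw if r == ref]
        span = (max(bins) + 2) * track.bin_size if bins else track.bin_size
        offsets[ref] = cursor
        spans[ref] = span
        cursor += span
    fig, ax = plt.subplots(figsize=(9, 3))
    for i, ref in enumerate(refs):
        xs, ys, txs, tys = [], [], [], []
        for (r, b), _ in track.raw.items():
            if r != ref:
                continue
            x = offsets[ref] + b * track.bin_size
            y = track.rpm((r, b))
            if (r, b) in target_bins:
                txs.append(x)
                tys.append(y)
            else:
                xs.append(x)
                ys.append(y)
        ax.scatter(xs, ys, s=6, color=["#4477aa", "#66ccee"][i % 2], label=ref)
        if txs:
            ax.scatter(txs, tys, s=18, color="#cc3311", marker="v", label=f"{ref} target")
    ax.axhline(guide_rpm, linestyle="--", color="black", linewidth=0.8)
    ax.set_yscale("symlog", linthresh=1)
    ax.set_xlabel("genome position (concatenated)")
    ax.set_ylabel("RPM")
    ax.set_title(title)
    ax.legend(fontsize=6, ncol=max(len(refs) // 2, 1))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
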