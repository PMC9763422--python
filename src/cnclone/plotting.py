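"""Heatmap export of copy-number profiles."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .genome import BinnedGenome

__all__ = ["heatmap_export"]


def heatmap_export(profiles, genome: BinnedGenome, path, vcenter: float = 2.0) -> None:
    """Write a per-cluster (or per-cell) copy-number heatmap image.

    Rows are profiles (cluster means, cell rows, ...), columns genome bins
    in order, diverging colours centred on the diploid state: blue below
    ``vcenter`` copies (loss), red above (gain).
    """
    rows, labels = [], []
    for p in profiles:
        rows.append(np.asarray(getattr(p, "mean_cn", p), dtype=float))
        labels.append(getattr(p, "label", None))
    X = np.vstack(rows)
    if X.shape[1] != genome.n_bins:
        raise ValueError("profiles do not match the genome bin count")

    fig, ax = plt.subplots(figsize=(10, 0.5 + 0.35 * X.shape[0]))
    span = max(abs(X - vcenter).max(), 1.0)
    im = ax.imshow(
        X,
        aspect="auto",
        cmap="coolwarm",
        vmin=vcenter - span,
        vmax=vcenter + span,
        interpolation="nearest",
    )
    bounds = [sl.start for sl in genome.chromosome_slices().values()]
    for b in bounds[1:]:
        ax.axvline(b - 0.5, color="k", lw=0.4)
    ax.set_xticks(
        [ (sl.start + sl.stop) / 2 for sl in genome.chromosome_slices().values() ],
        list(genome.chromosome_slices().keys()),
        rotation=90,
        fontsize=7,
    )
    if any(l is not None for l in labels):
        ax.set_yticks(range(X.shape[0]), [l or "" for l in labels], fontsize=7)
    fig.colorbar(im, ax=ax, label="copy number")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
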