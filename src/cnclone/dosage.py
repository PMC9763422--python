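"""Gene-dosage analysis: does copy number translate to expression?

Expression is normalized to RPKM, the per-gene expression fold change
between two samples is averaged within 1 Mb windows, the copy-number ratio
between the samples is taken per window from their bulk profiles, and the
two tracks are correlated (Pearson). A positive correlation indicates a
gene-dosage effect: regions gained in one sample are transcribed more.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cnmatrix import BulkCnProfile
from .genome import BinnedGenome

__all__ = [
    "CorrelationResult",
    "rpkm",
    "binned_log2fc",
    "binned_log2cnv",
    "make_dosage_table",
    "dosage_correlation",
    "ranked_gene_list",
]

GENE_COLUMNS = ("gene_id", "chrom", "start", "end", "length_kb")


@dataclass
class CorrelationResult:
    """Pearson correlation between log2CNV and binned log2FC."""

    r: float
    p: float
    n: int

    def to_json(self, path=None) -> str:
        text = json.dumps({"r": self.r, "p": self.p, "n": self.n}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def rpkm(counts, gene_length_kb, total_reads_millions: float) -> np.ndarray:
    """Reads per kilobase per million mapped reads.

    Each gene's read count is divided by the sample's total read count in
    millions and by the gene length in kilobases.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(gene_length_kb, dtype=float)
    if total_reads_millions <= 0:
        raise ValueError("total read count must be positive")
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    return counts / total_reads_millions / lengths


def _rpkm_columns(genes: pd.DataFrame, sample: str) -> pd.Series:
    """RPKM for one sample, computed from counts if not precomputed."""
    col = f"rpkm_{sample}"
    if col in genes.columns:
        return genes[col].astype(float)
    ccol = f"count_{sample}"
    if ccol not in genes.columns:
        raise ValueError(f"gene table has neither {col!r} nor {ccol!r}")
    total = genes[ccol].sum() / 1e6
    return pd.Series(
        rpkm(genes[ccol].to_numpy(), genes["length_kb"].to_numpy(), total),
        index=genes.index,
    )


def _gene_bins(genes: pd.DataFrame, genome: BinnedGenome) -> np.ndarray:
    bins = np.empty(len(genes), dtype=np.int64)
    for i, row in enumerate(genes.itertuples()):
        try:
            bins[i] = genome.bin_index_of(str(row.chrom), int(row.start))
        except ValueError:
            raise ValueError(
                f"gene {row.gene_id!r} at {row.chrom}:{row.start} lies "
                "outside the binned genome"
            ) from None
    return bins


def binned_log2fc(
    genes: pd.DataFrame,
    sample_a: str,
    sample_b: str,
    genome: BinnedGenome,
    pseudocount: float = 0.1,
) -> np.ndarray:
    """Per-bin mean log2 expression fold change (A over B).

    Each gene contributes ``log2((rpkm_A + pc) / (rpkm_B + pc))`` to the bin
    containing its start coordinate; bins without genes are NaN (the
    explicit missing marker, dropped before correlation).
    """
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValueError(f"gene table is missing columns {missing}")
    a = _rpkm_columns(genes, sample_a).to_numpy()
    b = _rpkm_columns(genes, sample_b).to_numpy()
    fc = np.log2((a + pseudocount) / (b + pseudocount))
    bins = _gene_bins(genes, genome)
    sums = np.bincount(bins, weights=fc, minlength=genome.n_bins)
    counts = np.bincount(bins, minlength=genome.n_bins)
    out = np.full(genome.n_bins, np.nan)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    return out


def binned_log2cnv(cn_a, cn_b, epsilon: float = 0.1) -> np.ndarray:
    """Per-bin log2 copy-number ratio, ``log2((A + eps) / (B + eps))``.

    ``eps`` guards fully lost (zero-copy) regions.
    """
    a = cn_a.values if isinstance(cn_a, BulkCnProfile) else np.asarray(cn_a, float)
    b = cn_b.values if isinstance(cn_b, BulkCnProfile) else np.asarray(cn_b, float)
    if a.shape != b.shape:
        raise ValueError(f"profile lengths differ: {a.size} vs {b.size}")
    return np.log2((a + epsilon) / (b + epsilon))


def make_dosage_table(
    genes: pd.DataFrame,
    sample_a: str,
    sample_b: str,
    cn_a,
    cn_b,
    genome: BinnedGenome,
    pseudocount: float = 0.1,
    epsilon: float = 0.1,
) -> pd.DataFrame:
    """Combine the two 1 Mb tracks into one per-bin table.

    Columns: chrom, start, end, log2fc, log2cnv, n_genes. Bins without
    genes carry NaN in log2fc.
    """
    fc = binned_log2fc(genes, sample_a, sample_b, genome, pseudocount)
    cnv = binned_log2cnv(cn_a, cn_b, epsilon)
    n_genes = np.bincount(_gene_bins(genes, genome), minlength=genome.n_bins)
    return pd.DataFrame(
        {
            "chrom": genome.chromosomes,
            "start": genome.starts,
            "end": genome.ends,
            "log2fc": fc,
            "log2cnv": cnv,
            "n_genes": n_genes,
        }
    )


def dosage_correlation(table) -> CorrelationResult:
    """Pearson correlation of log2CNV vs binned log2FC.

    ``table`` is the frame from :func:`make_dosage_table` or any pair of
    arrays ``(log2cnv, log2fc)``. Bins missing in either track are dropped
    pairwise; the two-sided p-value uses the t transform with n-2 df.
    """
    if isinstance(table, pd.DataFrame):
        x = table["log2cnv"].to_numpy(float)
        y = table["log2fc"].to_numpy(float)
    else:
        x, y = (np.asarray(v, dtype=float) for v in table)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need at least 3 usable bins, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: a track has zero variance")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=int(x.size))


def ranked_gene_list(
    genes: pd.DataFrame,
    sample_a: str,
    sample_b: str,
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Two-column (gene, log2FC) ranking for pre-ranked GSEA tools."""
    a = _rpkm_columns(genes, sample_a).to_numpy()
    b = _rpkm_columns(genes, sample_b).to_numpy()
    fc = np.log2((a + pseudocount) / (b + pseudocount))
    out = pd.DataFrame({"gene": genes["gene_id"], "log2fc": fc})
    return out.sort_values("log2fc", ascending=False).reset_index(drop=True)
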