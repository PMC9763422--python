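"""Copy-number containers and basic summaries.

Holds per-cell binned copy-number matrices (cells x bins), bulk per-sample
profiles, and averaged cluster profiles, together with the summaries the
analysis reports: population-averaged profiles, the chromosome-count
estimate (sum over chromosomes of the mean copy number of that chromosome's
bins), and clonal proportions as percentages of cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BinnedGenome

__all__ = [
    "CellCnMatrix",
    "BulkCnProfile",
    "ClusterProfile",
    "read_cell_matrix",
    "write_cell_matrix",
    "read_bulk_profile",
    "write_bulk_profile",
    "average_profile",
    "estimate_chromosome_number",
    "proportion_of",
    "round_half_up",
]


@dataclass
class CellCnMatrix:
    """Cells x bins copy-number calls for one sample/passage.

    ``values[i, j]`` is the copy-number call of cell ``cell_ids[i]`` in bin
    ``j`` of ``genome``. Calls may be integer states or real-valued.
    """

    genome: BinnedGenome
    cell_ids: list
    values: np.ndarray
    passage_label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = list(self.cell_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x bins matrix")
        if self.values.shape[0] != len(self.cell_ids):
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {self.values.shape[0]} rows"
            )
        if self.values.shape[1] != self.genome.n_bins:
            raise ValueError(
                f"matrix has {self.values.shape[1]} bin columns, genome has "
                f"{self.genome.n_bins} bins"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("copy-number calls must be finite (no missing bins)")
        if np.any(self.values < 0):
            raise ValueError("copy-number calls must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def row(self, cell_id) -> np.ndarray:
        return self.values[self.cell_ids.index(cell_id)]


@dataclass
class BulkCnProfile:
    """A per-bin copy-number profile for one bulk sample."""

    genome: BinnedGenome
    values: np.ndarray
    sample_label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != self.genome.n_bins:
            raise ValueError(
                f"profile length {self.values.size} != {self.genome.n_bins} bins"
            )
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("profile values must be finite and non-negative")


def round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with halves rounded up (2.5 -> 3)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


@dataclass
class ClusterProfile:
    """Averaged copy-number profile of one cell cluster.

    ``state_cn`` is the integerized profile (round half-up of ``mean_cn``)
    used as the character states of the parsimony analysis;
    ``chromosome_estimate`` is the chromosome-count estimate of ``mean_cn``.
    """

    cluster_id: int
    cell_count: int
    mean_cn: np.ndarray
    state_cn: np.ndarray
    chromosome_estimate: float
    passage_label: str = ""
    genome: BinnedGenome | None = field(default=None, repr=False)

    def __post_init__(self):
        self.mean_cn = np.asarray(self.mean_cn, dtype=float)
        self.state_cn = np.asarray(self.state_cn, dtype=np.int64)
        if self.cell_count < 1:
            raise ValueError("cluster must contain at least one cell")
        if self.mean_cn.shape != self.state_cn.shape:
            raise ValueError("mean_cn and state_cn must have equal length")
        if np.any(self.state_cn < 0):
            raise ValueError("integer states must be non-negative")

    @property
    def label(self) -> str:
        if self.passage_label:
            return f"{self.passage_label}_C{self.cluster_id}"
        return f"C{self.cluster_id}"


# ---------------------------------------------------------------------------
# TSV I/O (documented dialect: one header line; first column cell_id or
# sample_id; one column per bin named chrom:start-end)
# ---------------------------------------------------------------------------

def _check_bin_columns(columns, genome: BinnedGenome, path) -> None:
    expected = genome.bin_names()
    if len(columns) != len(expected):
        raise ValueError(
            f"{path}: expected {len(expected)} bin columns, found {len(columns)}"
        )
    if list(columns) != expected:
        bad = next(
            (a, b) for a, b in zip(columns, expected) if a != b
        )
        raise ValueError(
            f"{path}: bin column mismatch, found {bad[0]!r} where {bad[1]!r} "
            "was expected"
        )


def write_cell_matrix(matrix: CellCnMatrix, path) -> None:
    df = pd.DataFrame(matrix.values, columns=matrix.genome.bin_names())
    df.insert(0, "cell_id", matrix.cell_ids)
    df.to_csv(path, sep="\t", index=False)


def read_cell_matrix(path, genome: BinnedGenome, passage_label: str = "") -> CellCnMatrix:
    """Read a cells x bins TSV in the documented dialect.

    Malformed headers and bin-count mismatches raise ``ValueError`` naming
    the expected and observed columns.
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns.size == 0 or df.columns[0] != "cell_id":
        raise ValueError(f"{path}: first column must be 'cell_id'")
    _check_bin_columns(df.columns[1:], genome, path)
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    return CellCnMatrix(
        genome=genome,
        cell_ids=df["cell_id"].astype(str).tolist(),
        values=values,
        passage_label=passage_label,
    )


def write_bulk_profile(profile: BulkCnProfile, path) -> None:
    df = pd.DataFrame([profile.values], columns=profile.genome.bin_names())
    df.insert(0, "sample_id", [profile.sample_label])
    df.to_csv(path, sep="\t", index=False)


def read_bulk_profile(path, genome: BinnedGenome) -> BulkCnProfile:
    df = pd.read_csv(path, sep="\t")
    if df.columns.size == 0 or df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be 'sample_id'")
    _check_bin_columns(df.columns[1:], genome, path)
    if len(df) != 1:
        raise ValueError(f"{path}: bulk profile must have exactly one data row")
    return BulkCnProfile(
        genome=genome,
        values=df.iloc[0, 1:].to_numpy(dtype=float),
        sample_label=str(df.iloc[0, 0]),
    )


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def average_profile(matrix: CellCnMatrix, cell_subset=None) -> np.ndarray:
    """Component-wise mean copy number over (a subset of) cells."""
    if cell_subset is None:
        return matrix.values.mean(axis=0)
    subset = list(cell_subset)
    if not subset:
        raise ValueError("cell subset must be non-empty")
    index = {c: i for i, c in enumerate(matrix.cell_ids)}
    try:
        rows = [index[c] for c in subset]
    except KeyError as e:
        raise ValueError(f"unknown cell id {e.args[0]!r}") from None
    return matrix.values[rows].mean(axis=0)


def estimate_chromosome_number(
    profile: np.ndarray, genome: BinnedGenome, length_weighted: bool = False
) -> float:
    """Estimate the total chromosome count from a binned CN profile.

    Sums, over chromosomes, the mean copy number of that chromosome's bins.
    A uniformly diploid profile over K chromosomes gives exactly 2K. By
    default bins count equally within a chromosome (remainder bins are not
    down-weighted); set ``length_weighted=True`` for a base-pair-weighted
    mean per chromosome.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1 or profile.size != genome.n_bins:
        raise ValueError(
            f"profile length {profile.size} != {genome.n_bins} genome bins"
        )
    total = 0.0
    lengths = genome.bin_lengths
    for sl in genome.chromosome_slices().values():
        if length_weighted:
            total += float(np.average(profile[sl], weights=lengths[sl]))
        else:
            total += float(profile[sl].mean())
    return total


def proportion_of(assignments, cluster_ids) -> float:
    """Percentage of cells in the named clusters, to one decimal.

    ``assignments`` is either a per-cell label array or a
    :class:`~cnclone.clustering.ClusterSet`.
    """
    labels = np.asarray(getattr(assignments, "assignments", assignments))
    if labels.size == 0:
        raise ValueError("no cells")
    wanted = [cluster_ids] if np.isscalar(cluster_ids) else list(cluster_ids)
    known = set(np.unique(labels).tolist())
    for cid in wanted:
        if cid not in known:
            raise ValueError(f"unknown cluster id {cid!r}")
    count = int(np.isin(labels, wanted).sum())
    pct = 100.0 * count / labels.size
    return float(np.floor(pct * 10 + 0.5) / 10)  # half-up to one decimal
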