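"""Binned genome coordinate system.

Copy-number profiles in this package are defined over a fixed tiling of the
genome into windows ("bins") of a constant width, typically 1 Mb for bulk
SNP-array profiles and 5 Mb for shallow single-cell whole-genome sequencing.
Every matrix and profile indexes into a :class:`BinnedGenome`, which is the
single source of truth for bin coordinates.

Coordinates are 0-based, half-open ``[start, end)``, matching BED.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BinnedGenome",
    "make_binned_genome",
    "read_bins_bed",
    "write_bins_bed",
    "read_genome_table",
    "hg19_chromosome_lengths",
]


@dataclass(frozen=True)
class BinnedGenome:
    """An ordered tiling of chromosomes into fixed-width bins.

    Parameters
    ----------
    chromosomes :
        Per-bin chromosome name, in genome order.
    starts, ends :
        Per-bin 0-based half-open coordinates.
    bin_width :
        Nominal bin width in base pairs. The last bin of a chromosome may be
        shorter (the remainder bin).
    chromosome_order :
        Chromosome names in the order they are tiled.
    """

    chromosomes: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    bin_width: int
    chromosome_order: tuple = field(default=())

    def __post_init__(self):
        chroms = np.asarray(self.chromosomes, dtype=object)
        starts = np.asarray(self.starts, dtype=np.int64)
        ends = np.asarray(self.ends, dtype=np.int64)
        if not (len(chroms) == len(starts) == len(ends)):
            raise ValueError("chromosomes, starts and ends must be equal length")
        if np.any(ends <= starts):
            raise ValueError("every bin must have positive length")
        object.__setattr__(self, "chromosomes", chroms)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        order = self.chromosome_order or tuple(pd.unique(chroms))
        object.__setattr__(self, "chromosome_order", tuple(order))
        # sortedness / non-overlap within each chromosome
        for name, sl in self.chromosome_slices().items():
            s, e = starts[sl], ends[sl]
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"bins overlap or are unsorted on {name}")

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    def __len__(self) -> int:
        return self.n_bins

    @property
    def bin_lengths(self) -> np.ndarray:
        """Per-bin length in base pairs."""
        return self.ends - self.starts

    def chromosome_slices(self) -> dict:
        """Map chromosome name -> slice of bin indices, in genome order."""
        out = {}
        chroms = self.chromosomes
        for name in self.chromosome_order:
            idx = np.flatnonzero(chroms == name)
            if idx.size == 0:
                continue
            if not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
                raise ValueError(f"bins of chromosome {name} are not contiguous")
            out[name] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    def bin_names(self) -> list:
        """Column names in the ``chrom:start-end`` dialect."""
        return [
            f"{c}:{s}-{e}"
            for c, s, e in zip(self.chromosomes, self.starts, self.ends)
        ]

    def bin_index_of(self, chromosome: str, position: int) -> int:
        """Index of the bin containing a genomic position.

        Raises ``ValueError`` if the position falls outside the tiling.
        """
        sl = self.chromosome_slices().get(chromosome)
        if sl is None:
            raise ValueError(f"unknown chromosome {chromosome!r}")
        s, e = self.starts[sl], self.ends[sl]
        j = np.searchsorted(s, position, side="right") - 1
        if j < 0 or position >= e[j]:
            raise ValueError(
                f"position {chromosome}:{position} outside the binned genome"
            )
        return sl.start + int(j)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BinnedGenome):
            return NotImplemented
        return (
            self.bin_width == other.bin_width
            and self.chromosome_order == other.chromosome_order
            and np.array_equal(self.chromosomes, other.chromosomes)
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
        )


def make_binned_genome(chromosome_lengths: dict, bin_width: int) -> BinnedGenome:
    """Tile each chromosome left to right into ``bin_width`` windows.

    The last bin of a chromosome is the remainder and may be shorter.

    Parameters
    ----------
    chromosome_lengths :
        Ordered mapping of chromosome name -> length in base pairs.
    bin_width :
        Window width in base pairs.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    chroms, starts, ends = [], [], []
    for name, length in chromosome_lengths.items():
        length = int(length)
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        edges = list(range(0, length, bin_width)) + [length]
        for s, e in zip(edges[:-1], edges[1:]):
            chroms.append(name)
            starts.append(s)
            ends.append(e)
    return BinnedGenome(
        chromosomes=np.array(chroms, dtype=object),
        starts=np.array(starts, dtype=np.int64),
        ends=np.array(ends, dtype=np.int64),
        bin_width=int(bin_width),
        chromosome_order=tuple(chromosome_lengths.keys()),
    )


def write_bins_bed(genome: BinnedGenome, path) -> None:
    """Write the bin definition as BED3+1 (chrom, start, end, bin_index)."""
    df = pd.DataFrame(
        {
            "chrom": genome.chromosomes,
            "start": genome.starts,
            "end": genome.ends,
            "bin_index": np.arange(genome.n_bins),
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bins_bed(path, bin_width: int | None = None) -> BinnedGenome:
    """Read a BED3+1 bin definition written by :func:`write_bins_bed`.

    ``bin_width`` defaults to the modal bin length in the file.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "bin_index"]
    )
    if df.empty:
        raise ValueError(f"empty bin definition file: {path}")
    df = df.sort_values("bin_index")
    lengths = df["end"] - df["start"]
    if bin_width is None:
        bin_width = int(lengths.mode().iloc[0])
    return BinnedGenome(
        chromosomes=df["chrom"].to_numpy(dtype=object),
        starts=df["start"].to_numpy(np.int64),
        ends=df["end"].to_numpy(np.int64),
        bin_width=bin_width,
    )


def read_genome_table(path) -> dict:
    """Read a two-column TSV (chromosome, length) into an ordered dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return {str(r.chrom): int(r.length) for r in df.itertuples()}


def hg19_chromosome_lengths() -> dict:
    """hg19 chromosome lengths (bp) for realistic-scale runs."""
    return {
        "chr1": 249250621, "chr2": 243199373, "chr3": 198022430,
        "chr4": 191154276, "chr5": 180915260, "chr6": 171115067,
        "chr7": 159138663, "chr8": 146364022, "chr9": 141213431,
        "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
        "chr13": 115169878, "chr14": 107349540, "chr15": 102531392,
        "chr16": 90354753, "chr17": 81195210, "chr18": 78077248,
        "chr19": 59128983, "chr20": 63025520, "chr21": 48129895,
        "chr22": 51304566, "chrX": 155270560, "chrY": 59373566,
    }
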