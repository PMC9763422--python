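"""Cross-cluster segment merging for the parsimony analysis.

Adjacent bins in which every cluster keeps a constant integer copy number
are merged into maximal segments, so the merged segments remain vertically
comparable across clusters. Segments whose state is identical across all
clusters are then dropped: they carry no heterogeneity and cannot influence
the tree. Each retained segment keeps its genomic length in base pairs,
which is what the megabase edge metric sums over.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import BinnedGenome

__all__ = ["SegmentTable", "merge_segments", "segment_states_from_bins"]


@dataclass
class SegmentTable:
    """Merged, filtered segments with per-cluster integer CN states."""

    chromosomes: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    lengths_bp: np.ndarray
    states: np.ndarray  # clusters x segments, integer CN
    labels: list  # cluster labels, row order of `states`
    passages: list | None = None  # optional early/late passage tag per row

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)
        self.lengths_bp = np.asarray(self.lengths_bp, dtype=np.int64)
        if self.states.ndim != 2 or self.states.shape[0] != len(self.labels):
            raise ValueError("states must be clusters x segments matching labels")
        if self.states.shape[1] != len(self.lengths_bp):
            raise ValueError("one length per segment required")

    @property
    def n_segments(self) -> int:
        return self.states.shape[1]

    @property
    def n_clusters(self) -> int:
        return self.states.shape[0]

    def states_of(self, label) -> np.ndarray:
        return self.states[self.labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": self.chromosomes,
                "start": self.starts,
                "end": self.ends,
                "length_bp": self.lengths_bp,
            }
        )
        for i, lab in enumerate(self.labels):
            df[lab] = self.states[i]
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _profile_states(profiles) -> tuple:
    labels, rows, passages = [], [], []
    for p in profiles:
        labels.append(p.label)
        rows.append(np.asarray(p.state_cn, dtype=np.int64))
        passages.append(p.passage_label)
    return labels, np.vstack(rows), passages


def merge_segments(profiles, genome: BinnedGenome, keep_invariant: bool = False) -> SegmentTable:
    """Merge bins into maximal cross-cluster-constant segments, then filter.

    A new segment starts at every chromosome boundary and wherever *any*
    cluster changes state between adjacent bins, so every cluster is
    constant within every segment and merging is maximal. Segments with the
    same state across all clusters are removed unless ``keep_invariant``.

    Parameters
    ----------
    profiles :
        ``ClusterProfile`` objects (their ``state_cn`` vectors are used), or
        any objects with ``label``/``state_cn`` attributes.
    genome :
        The shared bin coordinate system.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need at least two cluster profiles to merge")
    for p in profiles:
        if p.genome is not None and genome is not None and p.genome != genome:
            raise ValueError(f"profile {p.label} is on a different genome")
    labels, S, passages = _profile_states(profiles)  # clusters x bins
    if S.shape[1] != genome.n_bins:
        raise ValueError("profile length does not match the genome bin count")

    chroms, starts, ends, lengths, seg_states = [], [], [], [], []
    bin_len = genome.bin_lengths
    for name, sl in genome.chromosome_slices().items():
        block = S[:, sl]
        nb = block.shape[1]
        # breakpoints: first bin, plus any bin where some cluster changes
        change = np.any(block[:, 1:] != block[:, :-1], axis=0)
        cut = np.concatenate(([0], np.flatnonzero(change) + 1, [nb]))
        for a, b in zip(cut[:-1], cut[1:]):
            lo, hi = sl.start + a, sl.start + b
            chroms.append(name)
            starts.append(int(genome.starts[lo]))
            ends.append(int(genome.ends[hi - 1]))
            lengths.append(int(bin_len[lo:hi].sum()))
            seg_states.append(block[:, a])

    states = np.array(seg_states, dtype=np.int64).T  # clusters x segments
    chroms = np.array(chroms, dtype=object)
    starts = np.array(starts, dtype=np.int64)
    ends = np.array(ends, dtype=np.int64)
    lengths = np.array(lengths, dtype=np.int64)
    if not keep_invariant:
        varying = np.any(states != states[0], axis=0)
        chroms, starts, ends = chroms[varying], starts[varying], ends[varying]
        lengths, states = lengths[varying], states[:, varying]
    return SegmentTable(
        chromosomes=chroms,
        starts=starts,
        ends=ends,
        lengths_bp=lengths,
        states=states,
        labels=labels,
        passages=passages,
    )


def segment_states_from_bins(state_cn: np.ndarray, table: SegmentTable, genome: BinnedGenome) -> np.ndarray:
    """Re-express a per-bin state vector on a segment table.

    Requires the vector to be constant within every segment (raises
    otherwise): merging must not lose information.
    """
    state_cn = np.asarray(state_cn, dtype=np.int64)
    out = np.empty(table.n_segments, dtype=np.int64)
    for j, (c, s, e) in enumerate(zip(table.chromosomes, table.starts, table.ends)):
        lo = genome.bin_index_of(c, int(s))
        hi = genome.bin_index_of(c, int(e) - 1)
        vals = state_cn[lo : hi + 1]
        if np.ptp(vals) != 0:
            raise ValueError(
                f"state vector varies within segment {c}:{s}-{e}; "
                "re-merge segments jointly first"
            )
        out[j] = vals[0]
    return out
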