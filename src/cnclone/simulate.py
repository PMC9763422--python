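"""Synthetic clone mixtures with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
small set of clones related by a tree of whole- and partial-chromosome
copy-number events on a diploid baseline; cells drawn from the clones with
passage-specific proportions; "intermittent" sub-clonal noise as independent
per-(cell, bin) +/-1 flips; and expression whose per-gene mean scales with
local copy number (the gene-dosage model). Everything is reproducible from
(spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cnmatrix import CellCnMatrix
from .genome import BinnedGenome, make_binned_genome

__all__ = [
    "CloneSpec",
    "PopulationSpec",
    "DosageSpec",
    "default_demo_genome",
    "realize_clone_profiles",
    "sample_cells",
    "sample_expression",
    "calibrate_noise_sd",
    "load_population_spec",
    "load_dosage_spec",
]


def default_demo_genome(bin_width: int = 5_000_000) -> BinnedGenome:
    """Small 6-chromosome genome (100-250 Mb) used in examples and tests."""
    lengths = {
        "chr1": 250_000_000,
        "chr2": 200_000_000,
        "chr3": 180_000_000,
        "chr4": 150_000_000,
        "chr5": 120_000_000,
        "chr6": 100_000_000,
    }
    return make_binned_genome(lengths, bin_width)


@dataclass
class CloneSpec:
    """A clone as a set of CN events on top of its parent.

    ``events`` are (chromosome, start_bin, end_bin, delta) with bin indices
    local to the chromosome, half-open, and delta in signed copies. The
    clone graph must be a tree rooted at a diploid ancestor
    (``parent_id is None``).
    """

    clone_id: str
    parent_id: str | None = None
    events: list = field(default_factory=list)
    baseline: int = 2


@dataclass
class PopulationSpec:
    """A two-passage mixture of clones with per-cell bin noise."""

    clones: list
    proportions_early: dict
    proportions_late: dict
    n_cells_early: int
    n_cells_late: int
    noise_rate: float = 0.05
    seed: int = 0
    noise_model: str = "flip"  # or "poisson"
    reads_per_copy: float = 50.0  # poisson mode only

    def __post_init__(self):
        for name, props in (
            ("proportions_early", self.proportions_early),
            ("proportions_late", self.proportions_late),
        ):
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must be in [0, 1]")


@dataclass
class DosageSpec:
    """Per-gene expression model with a tunable dosage coefficient.

    log2 expression = baseline + dosage_coefficient * log2(CN / 2) + noise,
    with per-gene baselines drawn once and shared between samples so the
    fold change isolates the dosage term.
    """

    n_genes: int
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.0
    dosage_coefficient: float = 1.0
    gene_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("need at least one gene")
        if self.baseline_log2_sd < 0 or self.gene_noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")


def realize_clone_profiles(specs, genome: BinnedGenome) -> dict:
    """Apply each clone's events along the clone tree; returns id -> CN vector.

    Child CN = parent CN + events. An event that would drive any bin below
    zero copies is rejected.
    """
    specs = list(specs)
    by_id = {s.clone_id: s for s in specs}
    if len(by_id) != len(specs):
        raise ValueError("clone ids must be unique")
    slices = genome.chromosome_slices()
    profiles: dict = {}

    def realize(cid, seen):
        if cid in profiles:
            return profiles[cid]
        if cid in seen:
            raise ValueError(f"clone graph has a cycle through {cid!r}")
        spec = by_id[cid]
        if spec.parent_id is None:
            base = np.full(genome.n_bins, spec.baseline, dtype=np.int64)
        else:
            if spec.parent_id not in by_id:
                raise ValueError(f"unknown parent {spec.parent_id!r} of {cid!r}")
            base = realize(spec.parent_id, seen | {cid}).copy()
        for chrom, b0, b1, delta in spec.events:
            sl = slices.get(chrom)
            if sl is None:
                raise ValueError(f"clone {cid!r}: unknown chromosome {chrom!r}")
            nb = sl.stop - sl.start
            if not (0 <= b0 < b1 <= nb):
                raise ValueError(
                    f"clone {cid!r}: event bins [{b0}, {b1}) outside {chrom} "
                    f"({nb} bins)"
                )
            base[sl.start + b0 : sl.start + b1] += int(delta)
        if np.any(base < 0):
            raise ValueError(f"clone {cid!r}: events drive copy number below 0")
        profiles[cid] = base
        return base

    for s in specs:
        realize(s.clone_id, frozenset())
    return profiles


def _noisy_cells(profiles_matrix, rng, spec: PopulationSpec):
    values = profiles_matrix.astype(float)
    if spec.noise_model == "flip":
        if spec.noise_rate > 0:
            flip = rng.random(values.shape) < spec.noise_rate
            sign = rng.choice([-1.0, 1.0], size=values.shape)
            values = np.clip(values + flip * sign, 0, None)
    elif spec.noise_model == "poisson":
        lam = values * spec.reads_per_copy
        values = rng.poisson(lam) / spec.reads_per_copy
    else:
        raise ValueError(f"unknown noise model {spec.noise_model!r}")
    return values


def sample_cells(spec: PopulationSpec, genome: BinnedGenome):
    """Draw the early- and late-passage cell matrices plus truth labels.

    Returns ``(early, late, truth)`` where truth is a DataFrame with
    cell_id, passage and the generating clone_id per cell.
    """
    rng = np.random.default_rng(spec.seed)
    profiles = realize_clone_profiles(spec.clones, genome)
    out = []
    truth_rows = []
    for passage, props, n in (
        ("early", spec.proportions_early, spec.n_cells_early),
        ("late", spec.proportions_late, spec.n_cells_late),
    ):
        ids = sorted(props)
        p = np.array([props[c] for c in ids])
        draw = rng.choice(len(ids), size=n, p=p)
        base = np.vstack([profiles[ids[d]] for d in draw])
        values = _noisy_cells(base, rng, spec)
        cell_ids = [f"{passage}_cell{i:04d}" for i in range(n)]
        out.append(
            CellCnMatrix(
                genome=genome,
                cell_ids=cell_ids,
                values=values,
                passage_label=passage,
            )
        )
        truth_rows += [
            {"cell_id": cid, "passage": passage, "clone_id": ids[d]}
            for cid, d in zip(cell_ids, draw)
        ]
    return out[0], out[1], pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Dosage-coupled expression
# ---------------------------------------------------------------------------

_CN_FLOOR = 0.1  # guards log2 of fully lost regions


def sample_expression(
    spec: DosageSpec, cn_profile_a, cn_profile_b, genome: BinnedGenome
) -> pd.DataFrame:
    """Generate a gene table whose expression follows the dosage model.

    Genes are placed uniformly over the genome (start positions uniform in
    base pairs); per sample, log2 RPKM = baseline +
    coefficient * log2(CN at the gene / 2) + Normal(0, gene_noise_sd).
    """
    rng = np.random.default_rng(spec.seed)
    a = np.asarray(
        getattr(cn_profile_a, "values", cn_profile_a), dtype=float
    )
    b = np.asarray(
        getattr(cn_profile_b, "values", cn_profile_b), dtype=float
    )
    if a.size != genome.n_bins or b.size != genome.n_bins:
        raise ValueError("CN profiles must match the genome bin count")

    cum = np.concatenate(([0], np.cumsum(genome.bin_lengths)))
    total = cum[-1]
    pos = np.sort(rng.integers(0, total, size=spec.n_genes))
    bins = np.searchsorted(cum, pos, side="right") - 1
    starts = (pos - cum[bins] + genome.starts[bins]).astype(np.int64)
    lengths_kb = rng.uniform(1.0, 50.0, size=spec.n_genes)

    baseline = rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, spec.n_genes)
    dose_a = spec.dosage_coefficient * np.log2(np.maximum(a[bins], _CN_FLOOR) / 2.0)
    dose_b = spec.dosage_coefficient * np.log2(np.maximum(b[bins], _CN_FLOOR) / 2.0)
    noise_a = rng.normal(0.0, spec.gene_noise_sd, spec.n_genes)
    noise_b = rng.normal(0.0, spec.gene_noise_sd, spec.n_genes)

    chroms = genome.chromosomes[bins]
    chrom_end = genome.ends[bins]  # cap genes at their bin's chromosome tail
    ends = np.minimum(starts + (lengths_kb * 1000).astype(np.int64), chrom_end)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(spec.n_genes)],
            "chrom": chroms,
            "start": starts,
            "end": ends,
            "length_kb": lengths_kb,
            "rpkm_A": 2.0 ** (baseline + dose_a + noise_a),
            "rpkm_B": 2.0 ** (baseline + dose_b + noise_b),
        }
    )


def calibrate_noise_sd(
    cn_profile_a,
    cn_profile_b,
    genome: BinnedGenome,
    n_genes: int,
    dosage_coefficient: float,
    target_r: float,
    epsilon: float = 0.1,
) -> float:
    """Per-gene noise sd giving a chosen population-level bin correlation.

    With genes spread uniformly (g = n_genes / n_bins per bin on average)
    and the dosage model, the bin-mean fold change is
    c * x + Normal(0, 2 sigma^2 / g) where x is the log2 CN ratio track, so
    the population Pearson r is c sd(x) / sqrt(c^2 var(x) + 2 sigma^2 / g).
    Solving for sigma yields the closed form used here.
    """
    if not 0 < target_r < 1:
        raise ValueError("target_r must be in (0, 1)")
    if dosage_coefficient == 0:
        raise ValueError("target r is unreachable with a zero coefficient")
    a = np.asarray(getattr(cn_profile_a, "values", cn_profile_a), dtype=float)
    b = np.asarray(getattr(cn_profile_b, "values", cn_profile_b), dtype=float)
    x = np.log2((a + epsilon) / (b + epsilon))
    var_x = float(np.var(x))
    if var_x == 0:
        raise ValueError("CN tracks are identical; no dosage signal to scale")
    g = n_genes / genome.n_bins
    var_noise = dosage_coefficient**2 * var_x * (1.0 / target_r**2 - 1.0)
    return float(np.sqrt(g / 2.0 * var_noise))


# ---------------------------------------------------------------------------
# YAML specs
# ---------------------------------------------------------------------------

def load_population_spec(path) -> tuple:
    """Read a YAML population spec; returns (PopulationSpec, BinnedGenome)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    genome = make_binned_genome(
        {k: int(v) for k, v in doc["genome"]["chromosome_lengths"].items()},
        int(doc["genome"]["bin_width"]),
    )
    clones = [
        CloneSpec(
            clone_id=str(c["clone_id"]),
            parent_id=c.get("parent_id"),
            events=[tuple(e) for e in c.get("events", [])],
            baseline=int(c.get("baseline", 2)),
        )
        for c in doc["clones"]
    ]
    spec = PopulationSpec(
        clones=clones,
        proportions_early={str(k): float(v) for k, v in doc["proportions_early"].items()},
        proportions_late={str(k): float(v) for k, v in doc["proportions_late"].items()},
        n_cells_early=int(doc["n_cells_early"]),
        n_cells_late=int(doc["n_cells_late"]),
        noise_rate=float(doc.get("noise_rate", 0.05)),
        seed=int(doc.get("seed", 0)),
        noise_model=str(doc.get("noise_model", "flip")),
    )
    return spec, genome


def load_dosage_spec(path) -> DosageSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return DosageSpec(**doc)
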