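"""Synthetic polyploid loci, duplication scenarios, LTR pairs and reads.

Everything is generated under a Jukes-Cantor substitution process (the
distance models used downstream), from a single integer seed, so every
pipeline stage has deterministic, download-free inputs with known truth.

The default configuration emulates the study conditions of the
motivating sugarcane loci: a locus of ploidy 8 with 7 haplotypes
observed (one missing), haplotypes radiating ~0.5 Myr ago at the coding
rate, equal expression across all genomic copies, and transcriptome
reads drawn multinomially over the expressed haplotypes with a 0.1%
per-base error rate.  A duplication scenario adds a second region
sharing an interval of the locus, split off 2.3 Myr ago (the age of the
oldest dated transposon insertions, a floor for the duplication age),
and an optional outgroup diverged before the duplication.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from haplodose.catalog import RegionAlignment, VariantRecord, call_variants
from haplodose.clock import CODING_RATE, NONCODING_RATE
from haplodose.errors import ConfigError

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class DuplicationConfig:
    """A second region copy sharing an interval of the locus."""

    age: float = 2.3e6  # years since the duplication
    interval: tuple[int, int] | None = None  # 1-based closed; None = whole locus
    ploidy: int = 10
    observed: int = 9


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated polyploid locus."""

    seed: int
    ploidy: int = 8
    observed: int = 7
    length: int = 564
    radiation_age: float = 5.0e5  # years since haplotype radiation
    rate: float = CODING_RATE
    duplication: DuplicationConfig | None = None
    outgroup_age: float | None = None  # years; diverges before any duplication
    weights: tuple[float, ...] | None = None  # per-haplotype expression; sum 1
    depth: float = 500.0  # mean per-base read coverage
    read_length: int = 80
    error_rate: float = 1e-3
    deletion: tuple[int, int, int] | None = None  # (haplotype index, 1-based pos, len)

    def __post_init__(self) -> None:
        if not 0 <= self.observed <= self.ploidy:
            raise ConfigError("observed haplotypes exceed ploidy")
        if self.rate <= 0:
            raise ConfigError("substitution rate must be positive")
        if self.radiation_age * self.rate >= 0.2:
            raise ConfigError("radiation age too deep: distances would saturate")
        if self.weights is not None:
            if len(self.weights) != self.ploidy:
                raise ConfigError("need one expression weight per genomic copy")
            if abs(sum(self.weights) - 1) > 1e-9:
                raise ConfigError("expression weights must sum to 1")
            if any(w < 0 for w in self.weights):
                raise ConfigError("expression weights must be non-negative")

    def resolved_weights(self) -> tuple[float, ...]:
        if self.weights is not None:
            return self.weights
        return tuple(1 / self.ploidy for _ in range(self.ploidy))


@dataclass(frozen=True)
class TruthSet:
    """Everything the generator knows about one simulated locus."""

    config: SimConfig
    haplotypes: tuple[tuple[str, str], ...]  # all P copies, ungapped
    observed_ids: tuple[str, ...]
    alignment: RegionAlignment  # all P copies, gapped if a deletion was simulated
    variants: tuple[VariantRecord, ...]
    weights: tuple[float, ...]
    expected_proportions: dict[int, float]  # position -> true variant-read fraction
    region2: tuple[tuple[str, str], ...] = ()
    outgroup: tuple[str, str] | None = None

    @property
    def observed_haplotypes(self) -> tuple[tuple[str, str], ...]:
        keep = set(self.observed_ids)
        return tuple((h, s) for h, s in self.haplotypes if h in keep)


@dataclass(frozen=True)
class SimulatedReads:
    reads: tuple[tuple[str, str], ...]
    truth_haplotype: tuple[str, ...]  # source haplotype id per read
    truth_start: tuple[int, ...]  # 0-based start per read


# ---------------------------------------------------------------------------
# JC evolution
# ---------------------------------------------------------------------------


def jc_mismatch_probability(branch_length: float) -> float:
    """Expected per-site mismatch after a JC branch of length d."""
    return 0.75 * (1.0 - math.exp(-4.0 * branch_length / 3.0))


def evolve_sequence(
    seq: str, t: float, r: float, rng: np.random.Generator | int
) -> str:
    """Evolve a sequence for ``t`` years at rate ``r`` under JC.

    Each site substitutes with the JC probability at branch length
    ``t * r``; the target base is uniform over the three alternatives.
    Deterministic under a fixed generator state or integer seed.
    """
    if r <= 0:
        raise ConfigError("substitution rate must be positive")
    if t < 0:
        raise ConfigError("time must be non-negative")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    p = jc_mismatch_probability(t * r)
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < p
    if hit.any():
        idx = np.flatnonzero(hit)
        current = np.array([_INDEX[c] for c in seq], dtype=np.int64)[idx]
        shift = rng.integers(1, 4, size=idx.size)
        arr[idx] = _BASES[(current + shift) % 4]
    return arr.tobytes().decode()


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


# ---------------------------------------------------------------------------
# locus simulation
# ---------------------------------------------------------------------------


def simulate_locus(cfg: SimConfig) -> TruthSet:
    """Simulate a polyploid locus and its truth set.

    An ancestral sequence radiates into ``ploidy`` haplotypes (star
    tree, each branch ``radiation_age`` years); only the first
    ``observed`` are exposed as sequenced.  With a duplication, the
    locus ancestor splits ``duplication.age`` years ago and the second
    region's copies radiate from their own ancestor over the shared
    interval.  An optional outgroup diverges ``outgroup_age`` years ago,
    before the duplication.
    """
    rng = np.random.default_rng(cfg.seed)
    ancestral = random_sequence(cfg.length, rng)

    dup = cfg.duplication
    if dup is not None:
        if dup.age <= cfg.radiation_age:
            raise ConfigError("duplication must predate the haplotype radiation")
        stem = dup.age - cfg.radiation_age
        anc1 = evolve_sequence(ancestral, stem, cfg.rate, rng)
        anc2 = evolve_sequence(ancestral, stem, cfg.rate, rng)
    else:
        anc1, anc2 = ancestral, None

    haplotypes = tuple(
        (f"H{i + 1:02d}", evolve_sequence(anc1, cfg.radiation_age, cfg.rate, rng))
        for i in range(cfg.ploidy)
    )

    region2: tuple[tuple[str, str], ...] = ()
    if dup is not None:
        lo, hi = dup.interval or (1, cfg.length)
        segment = anc2[lo - 1 : hi]
        region2 = tuple(
            (
                f"R2_H{i + 1:02d}",
                evolve_sequence(segment, cfg.radiation_age, cfg.rate, rng),
            )
            for i in range(dup.ploidy)
        )

    outgroup = None
    if cfg.outgroup_age is not None:
        if dup is not None and cfg.outgroup_age <= dup.age:
            raise ConfigError("outgroup must diverge before the duplication")
        outgroup = (
            "OUTGROUP",
            evolve_sequence(ancestral, 2 * cfg.outgroup_age, cfg.rate, rng),
        )

    aligned = dict(haplotypes)
    if cfg.deletion is not None:
        hap_idx, pos, length = cfg.deletion
        hap_id = haplotypes[hap_idx][0]
        s = aligned[hap_id]
        aligned[hap_id] = s[: pos - 1] + "-" * length + s[pos - 1 + length :]

    alignment = RegionAlignment(
        region_id="sim",
        haplotypes=tuple(aligned.items()),
        reference_id=haplotypes[0][0],
        duplication=(dup.interval or (1, cfg.length)) if dup else None,
    )
    variants = tuple(call_variants(alignment))

    weights = cfg.resolved_weights()
    weight_of = {hap: w for (hap, _), w in zip(haplotypes, weights)}
    expected = {
        v.position: sum(weight_of.get(h, 0.0) for h in v.carriers)
        for v in variants
    }

    return TruthSet(
        config=cfg,
        haplotypes=haplotypes,
        observed_ids=tuple(h for h, _ in haplotypes[: cfg.observed]),
        alignment=alignment,
        variants=variants,
        weights=weights,
        expected_proportions=expected,
        region2=region2,
        outgroup=outgroup,
    )


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def simulate_reads(
    truth: TruthSet, cfg: SimConfig | None = None, seed: int | None = None
) -> SimulatedReads:
    """Draw transcriptome reads over the expressed haplotypes.

    The source haplotype of each read is multinomial in the expression
    weights; start positions are uniform; each base flips to a random
    other base with the per-base error rate.  The read count is
    ``depth * length / read_length`` (mean per-base coverage ``depth``).
    """
    cfg = cfg or truth.config
    if cfg.depth <= 0:
        raise ConfigError("depth must be positive")
    if cfg.read_length > cfg.length:
        raise ConfigError("read length exceeds sequence length")
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    n_reads = int(math.ceil(cfg.depth * cfg.length / cfg.read_length))
    weights = np.asarray(truth.weights)
    hap_ids = [h for h, _ in truth.haplotypes]
    hap_seqs = [s for _, s in truth.haplotypes]
    choice = rng.choice(len(hap_ids), size=n_reads, p=weights)
    starts = rng.integers(0, cfg.length - cfg.read_length + 1, size=n_reads)
    reads = []
    for i, (hap_i, start) in enumerate(zip(choice, starts)):
        fragment = hap_seqs[hap_i][start : start + cfg.read_length]
        if cfg.error_rate > 0:
            errs = np.flatnonzero(rng.random(len(fragment)) < cfg.error_rate)
            if errs.size:
                chars = list(fragment)
                shifts = rng.integers(1, 4, size=errs.size)
                for e, sh in zip(errs, shifts):
                    chars[e] = "ACGT"[(_INDEX[chars[e]] + sh) % 4]
                fragment = "".join(chars)
        reads.append((f"read{i:06d}", fragment))
    return SimulatedReads(
        reads=tuple(reads),
        truth_haplotype=tuple(hap_ids[i] for i in choice),
        truth_start=tuple(int(s) for s in starts),
    )


def simulate_ltr_pair(
    age: float, r: float = NONCODING_RATE, length: int = 2000, seed: int = 0
) -> tuple[str, str, float]:
    """An LTR pair: identical at insertion, each evolved ``age`` years.

    Returns the two repeat sequences plus the true age.
    """
    if age * r >= 0.1:
        raise ConfigError("age too deep: LTR divergence would saturate")
    rng = np.random.default_rng(seed)
    ancestral = random_sequence(length, rng)
    ltr5 = evolve_sequence(ancestral, age, r, rng)
    ltr3 = evolve_sequence(ancestral, age, r, rng)
    return ltr5, ltr3, age


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------


def write_fasta(path: str | Path, records: Sequence[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_fastq(path: str | Path, reads: Sequence[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def region01_preset(seed: int) -> SimConfig:
    """Ploidy-8 locus, 7 observed haplotypes, all copies expressed."""
    return SimConfig(seed=seed)


def region02_preset(seed: int) -> SimConfig:
    """Ploidy-10 duplication scenario with one silenced observed haplotype."""
    weights = tuple(0.0 if i == 8 else 1 / 9 for i in range(10))
    return SimConfig(
        seed=seed,
        ploidy=10,
        observed=9,
        radiation_age=2.0e6,  # paralog haplotypes are older than Region01's
        weights=weights,
        duplication=DuplicationConfig(),
        outgroup_age=7.0e6,
    )
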