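"""Pairwise distances and molecular-clock dating.

Distance models: raw p-distance, Jukes-Cantor one-parameter correction
(JC69), Kimura two-parameter (K2P, transitions vs transversions) for
noncoding DNA, and Nei-Gojobori (NG86) synonymous/nonsynonymous coding
distances with the JC correction.  Divergence times follow the strict
molecular clock ``T = d / (2 r)`` with per-site per-year substitution
rates (defaults: 6.5e-9 for coding grass DNA, 1.3e-8 for noncoding);
LTR retrotransposon insertions are dated from the divergence of an
element's two terminal repeats, which are identical at insertion time.

Columns containing a gap or ``N`` in either sequence are excluded
pairwise everywhere.  Distances outside the log domain of a correction
are flagged saturated rather than raised.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

from haplodose.catalog import _CODON_TABLE, _STOPS
from haplodose.errors import ConfigError, InputError

#: substitutions per site per year for grass coding sequence
CODING_RATE = 6.5e-9
#: substitutions per site per year for grass noncoding / intergenic DNA
NONCODING_RATE = 1.3e-8

_PURINES = {"A", "G"}
_SKIP = {"-", "N"}


@dataclass(frozen=True)
class SubstitutionCounts:
    """Mismatch breakdown of one aligned pair (pairwise-deleted sites)."""

    sites: int
    transitions: int
    transversions: int

    def __post_init__(self) -> None:
        if self.sites <= 0:
            raise InputError("no comparable sites between sequences")

    @property
    def P(self) -> float:
        return self.transitions / self.sites

    @property
    def Q(self) -> float:
        return self.transversions / self.sites

    @property
    def p(self) -> float:
        return self.P + self.Q


@dataclass(frozen=True)
class DistanceEstimate:
    """A model-corrected distance in substitutions per site."""

    model: str  # p | jc69 | k2p | ng86_dS | ng86_dN
    d: float
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid and self.d < 0:
            raise InputError(f"negative distance {self.d}")


@dataclass(frozen=True)
class CodonPairStats:
    """NG86 site and difference counts for one aligned CDS pair."""

    syn_sites: float
    nonsyn_sites: float
    syn_differences: float
    nonsyn_differences: float
    codons: int

    @property
    def pS(self) -> float:
        return self.syn_differences / self.syn_sites

    @property
    def pN(self) -> float:
        return self.nonsyn_differences / self.nonsyn_sites


@dataclass(frozen=True)
class RateModel:
    """A strict-clock substitution rate, substitutions/site/year."""

    r: float

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ConfigError(f"rate must be positive, got {self.r}")

    @classmethod
    def coding(cls) -> "RateModel":
        return cls(CODING_RATE)

    @classmethod
    def noncoding(cls) -> "RateModel":
        return cls(NONCODING_RATE)


# ---------------------------------------------------------------------------
# counting and nucleotide distances
# ---------------------------------------------------------------------------


def count_substitutions(seq_a: str, seq_b: str) -> SubstitutionCounts:
    """Transition/transversion counts over pairwise-complete columns."""
    if len(seq_a) != len(seq_b):
        raise InputError(
            f"aligned sequences differ in length ({len(seq_a)} vs {len(seq_b)})"
        )
    sites = ts = tv = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x in _SKIP or y in _SKIP:
            continue
        sites += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    if sites == 0:
        raise InputError("no comparable sites between sequences")
    return SubstitutionCounts(sites, ts, tv)


def p_distance(counts: SubstitutionCounts) -> DistanceEstimate:
    return DistanceEstimate("p", counts.p)


def jc69_distance(p: float) -> DistanceEstimate:
    """JC69 correction ``d = -(3/4) ln(1 - 4p/3)``; saturated at p >= 3/4."""
    if not 0 <= p <= 1:
        raise InputError(f"mismatch proportion {p} outside [0, 1]")
    if p >= 0.75:
        return DistanceEstimate("jc69", math.inf, valid=False)
    return DistanceEstimate("jc69", -0.75 * math.log1p(-4 * p / 3))


def k2p_distance(counts: SubstitutionCounts) -> DistanceEstimate:
    """K2P distance ``-(1/2)ln(1-2P-Q) - (1/4)ln(1-2Q)``."""
    P, Q = counts.P, counts.Q
    if 1 - 2 * P - Q <= 0 or 1 - 2 * Q <= 0:
        return DistanceEstimate("k2p", math.inf, valid=False)
    d = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
    return DistanceEstimate("k2p", d)


def pair_distance(seq_a: str, seq_b: str, model: str = "jc69") -> DistanceEstimate:
    """Model-corrected distance between two aligned sequences."""
    counts = count_substitutions(seq_a, seq_b)
    if model == "p":
        return p_distance(counts)
    if model == "jc69":
        return jc69_distance(counts.p)
    if model == "k2p":
        return k2p_distance(counts)
    raise ConfigError(f"unknown nucleotide distance model {model!r}")


# ---------------------------------------------------------------------------
# NG86 synonymous / nonsynonymous distances
# ---------------------------------------------------------------------------


def _translate(codon: str) -> str | None:
    """Amino acid, '*' for a stop, None if the codon is ambiguous."""
    if codon in _STOPS:
        return "*"
    return _CODON_TABLE.get(codon)


@lru_cache(maxsize=None)
def _syn_fraction(codon: str) -> float:
    """Synonymous site count of a codon (0..3).

    For each position, the fraction of the three single-base neighbours
    coding the same amino acid; changes into stop codons count as
    nonsynonymous.
    """
    aa = _translate(codon)
    total = 0.0
    for i in range(3):
        syn = 0
        for base in "ACGT":
            if base == codon[i]:
                continue
            neighbour = codon[:i] + base + codon[i + 1 :]
            if neighbour not in _STOPS and _translate(neighbour) == aa:
                syn += 1
        total += syn / 3
    return total


def _path_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(syn, nonsyn) differences between two codons.

    Multi-difference codons are averaged with equal weight over all
    orderings of the minimal mutational path; orderings passing through
    a stop codon are excluded (all orderings are used if every one hits
    a stop).
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_positions):
        current = codon_a
        syn = nonsyn = 0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in _STOPS:
                through_stop = True
            if _translate(nxt) == _translate(current):
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        paths.append((syn, nonsyn, through_stop))
    usable = [(s, n) for s, n, stop in paths if not stop] or [
        (s, n) for s, n, _ in paths
    ]
    syn = sum(s for s, _ in usable) / len(usable)
    nonsyn = sum(n for _, n in usable) / len(usable)
    return syn, nonsyn


def _check_cds(cds: str, label: str) -> None:
    if len(cds) % 3 != 0:
        raise InputError(f"{label}: CDS length {len(cds)} not a multiple of 3")
    for i in range(0, len(cds) - 3, 3):
        if cds[i : i + 3] in _STOPS:
            raise InputError(f"{label}: internal stop codon at position {i + 1}")


def ng86_distance(
    cds_a: str, cds_b: str
) -> tuple[CodonPairStats, DistanceEstimate, DistanceEstimate]:
    """NG86 synonymous/nonsynonymous distances with JC correction.

    Site counts are averaged over the two sequences; codons with a gap
    or ambiguous base in either sequence are skipped pairwise.  Returns
    the codon statistics plus ``dS`` and ``dN`` (saturated estimates are
    flagged invalid).
    """
    if len(cds_a) != len(cds_b):
        raise InputError("aligned CDS pair differs in length")
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    _check_cds(cds_a, "first CDS")
    _check_cds(cds_b, "second CDS")
    S = Sd = Nd = 0.0
    codons = 0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        if any(ch in _SKIP for ch in ca + cb):
            continue
        if _translate(ca) is None or _translate(cb) is None:
            continue
        codons += 1
        S += (_syn_fraction(ca) + _syn_fraction(cb)) / 2
        syn, nonsyn = _path_differences(ca, cb)
        Sd += syn
        Nd += nonsyn
    if codons == 0:
        raise InputError("no comparable codons between sequences")
    N = 3 * codons - S
    stats = CodonPairStats(S, N, Sd, Nd, codons)
    dS = jc69_distance(min(stats.pS, 1.0)) if S > 0 else jc69_distance(0.0)
    dN = jc69_distance(min(stats.pN, 1.0)) if N > 0 else jc69_distance(0.0)
    return (
        stats,
        DistanceEstimate("ng86_dS", dS.d, dS.valid),
        DistanceEstimate("ng86_dN", dN.d, dN.valid),
    )


# ---------------------------------------------------------------------------
# dating
# ---------------------------------------------------------------------------


def divergence_time(d: DistanceEstimate, rate: RateModel | float) -> float | None:
    """Strict-clock divergence time ``T = d / (2 r)`` in years.

    Returns None (undated) for a saturated distance.
    """
    r = rate.r if isinstance(rate, RateModel) else float(rate)
    if r <= 0:
        raise ConfigError(f"rate must be positive, got {r}")
    if not d.valid:
        return None
    return d.d / (2 * r)


def ltr_insertion_age(
    ltr5: str,
    ltr3: str,
    rate: RateModel | float = NONCODING_RATE,
    model: str = "k2p",
) -> float | None:
    """Insertion age of an LTR element from its two aligned terminal repeats.

    The repeats are identical on insertion and each accumulates
    substitutions independently, so their corrected distance ``d``
    converts to an age ``d / (2 r)``.
    """
    return divergence_time(pair_distance(ltr5, ltr3, model), rate)
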