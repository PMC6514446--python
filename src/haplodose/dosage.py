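"""Missing-haplotype allele dosage test.

In a polyploid with locus ploidy ``P`` known from cytology but only
``H < P`` haplotypes recovered by sequencing, each SNP's transcriptome
allele ratio can be compared with the genomic allele dosage it would
have under two hypotheses about the unobserved haplotype(s):

* ``missing_common`` — the missing haplotype carries the common allele,
  so the genomic variant dosage is the observed count ``x`` out of ``P``;
* ``missing_variant`` — the missing haplotype carries the variant
  allele, giving ``x + 1`` out of ``P``.

When a SNP is seen in the transcriptome but in none of the sequenced
haplotypes, only the missing haplotype can carry it and both hypotheses
coincide at ``(P - H) / P``.

Each hypothesis is tested with the exact two-sided binomial test of the
variant read count against the genomic proportion ``v/P`` (the exact
fraction, not a rounded display value).  The null is accepted at
``p >= alpha`` (default 0.05): the genomic dosage then explains the
transcriptome ratio.  Sites inside a duplicated segment shared with
another region are excluded from testing (their transcriptome counts mix
two loci) but are still reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from haplodose.errors import ConfigError, InputError

DEFAULT_ALPHA = 0.05
#: relative tolerance of the small-probability summation, guarding the
#: outcome-inclusion comparison against floating-point noise
REL_TOL = 1e-7


@dataclass(frozen=True)
class PloidyContext:
    """Ploidy of one region and the number of haplotypes recovered."""

    region_id: str
    ploidy: int
    observed_haplotypes: int

    def __post_init__(self) -> None:
        if self.ploidy <= 0:
            raise ConfigError(f"ploidy must be positive, got {self.ploidy}")
        if not 0 <= self.observed_haplotypes <= self.ploidy:
            raise ConfigError(
                f"observed haplotypes {self.observed_haplotypes} exceed ploidy {self.ploidy}"
            )

    @property
    def missing(self) -> int:
        return self.ploidy - self.observed_haplotypes


@dataclass(frozen=True)
class DosageHypothesis:
    """One genomic-dosage hypothesis: ``v`` variant copies out of ``P``."""

    scenario: str  # missing_common | missing_variant
    genomic_variant: int
    ploidy: int

    def __post_init__(self) -> None:
        if not 0 <= self.genomic_variant <= self.ploidy:
            raise InputError(
                f"genomic variant count {self.genomic_variant} outside [0, {self.ploidy}]"
            )

    @property
    def genomic_common(self) -> int:
        return self.ploidy - self.genomic_variant

    @property
    def proportion(self) -> Fraction:
        return Fraction(self.genomic_variant, self.ploidy)


@dataclass(frozen=True)
class HypothesisResult:
    hypothesis: DosageHypothesis
    p_value: float
    accept: bool


@dataclass(frozen=True)
class DosageTestResult:
    """Binomial test of one SNP's transcriptome ratio against its hypotheses."""

    variant_coverage: int
    coverage: int
    hypotheses: tuple[HypothesisResult, ...]
    untestable: bool = False

    @property
    def transcriptome_proportion(self) -> float | None:
        """k/n rounded half-up to two decimals, as reported in tables."""
        if self.coverage == 0:
            return None
        ratio = Decimal(str(self.variant_coverage / self.coverage))
        return float(ratio.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))

    @property
    def any_accepted(self) -> bool:
        return any(h.accept for h in self.hypotheses)


# ---------------------------------------------------------------------------
# exact binomial test
# ---------------------------------------------------------------------------


def exact_binomial_two_sided(
    k: int, n: int, p0: float | Fraction, rel_tol: float = REL_TOL
) -> float:
    """Exact two-sided binomial p-value, small-probability summation.

    Sums ``Binom(i; n, p0)`` over every outcome ``i`` whose point
    probability is at most ``(1 + rel_tol)`` times that of the observed
    ``k`` — the convention of the classical exact binomial test (as in
    R's ``binom.test``).  No normal approximation is used.  Degenerate
    nulls ``p0 = 0`` or ``1`` return 1 when ``k`` matches the only
    possible outcome and 0 otherwise.
    """
    if n <= 0:
        raise InputError(f"number of trials must be positive, got {n}")
    if not 0 <= k <= n:
        raise InputError(f"successes k={k} outside [0, {n}]")
    p0 = float(p0)
    if not 0 <= p0 <= 1:
        raise InputError(f"null proportion {p0} outside [0, 1]")
    if p0 == 0.0:
        return 1.0 if k == 0 else 0.0
    if p0 == 1.0:
        return 1.0 if k == n else 0.0
    pmf = binom.pmf(np.arange(n + 1), n, p0)
    cutoff = pmf[k] * (1 + rel_tol)
    return float(min(1.0, pmf[pmf <= cutoff].sum()))


def build_hypotheses(
    detected_in_genome: bool,
    observed_variant_count: int,
    ctx: PloidyContext,
) -> tuple[DosageHypothesis, DosageHypothesis]:
    """The two missing-haplotype dosage hypotheses for one SNP.

    For a SNP present among the sequenced haplotypes (``x`` carriers),
    the hypotheses are ``(x, P)`` and ``(x + 1, P)``.  For a SNP found
    only in the transcriptome both coincide: only the missing
    haplotype(s) can carry it, giving ``(P - H, P)`` twice.
    """
    x = observed_variant_count
    if detected_in_genome:
        if not 0 <= x <= ctx.observed_haplotypes:
            raise InputError(
                f"observed variant count {x} outside [0, {ctx.observed_haplotypes}]"
            )
        if x + ctx.missing > ctx.ploidy:
            raise InputError(
                f"variant count {x} plus {ctx.missing} missing exceeds ploidy {ctx.ploidy}"
            )
        return (
            DosageHypothesis("missing_common", x, ctx.ploidy),
            DosageHypothesis("missing_variant", x + 1, ctx.ploidy),
        )
    return (
        DosageHypothesis("missing_common", ctx.missing, ctx.ploidy),
        DosageHypothesis("missing_variant", ctx.missing, ctx.ploidy),
    )


def test_snp_dosage(
    variant_coverage: int,
    coverage: int,
    hypotheses: Sequence[DosageHypothesis],
    alpha: float = DEFAULT_ALPHA,
) -> DosageTestResult:
    """Test one SNP's read counts against each dosage hypothesis.

    Null proportions are the exact fractions ``v/P``.  Zero coverage
    yields a result flagged untestable rather than an error.
    """
    if coverage == 0:
        return DosageTestResult(variant_coverage, coverage, (), untestable=True)
    results = []
    for hyp in hypotheses:
        p = exact_binomial_two_sided(variant_coverage, coverage, hyp.proportion)
        results.append(HypothesisResult(hyp, p, p >= alpha))
    return DosageTestResult(variant_coverage, coverage, tuple(results))


# ---------------------------------------------------------------------------
# table-level driver
# ---------------------------------------------------------------------------

_HYP_COLUMNS = [
    ("GenomicVariant1", "GenomicTotal1"),
    ("GenomicVariant2", "GenomicTotal2"),
]
_SCENARIOS = ("missing_common", "missing_variant")


def _row_hypotheses(row: pd.Series, ctx: PloidyContext | None):
    """Hypotheses for one counts row: explicit overrides win over the rule."""
    v1 = row.get("GenomicVariant1")
    if v1 is not None and not pd.isna(v1):
        hyps = []
        for scenario, (vcol, tcol) in zip(_SCENARIOS, _HYP_COLUMNS):
            total = row.get(tcol)
            total = ctx.ploidy if (total is None or pd.isna(total)) else int(total)
            hyps.append(DosageHypothesis(scenario, int(row[vcol]), total))
        return tuple(hyps)
    if ctx is None:
        raise InputError(
            "rows without explicit GenomicVariant columns need a PloidyContext"
        )
    return build_hypotheses(
        bool(row["GenomicDetected"]), int(row["ObservedVariantCount"]), ctx
    )


@dataclass(frozen=True)
class DosageTableSummary:
    n_testable: int
    n_accepted: int
    n_excluded_duplication: int

    @property
    def fraction_accepted(self) -> float | None:
        if self.n_testable == 0:
            return None
        return self.n_accepted / self.n_testable


def run_dosage_table(
    counts: pd.DataFrame,
    ctx: PloidyContext | None = None,
    alpha: float = DEFAULT_ALPHA,
    exclude_duplication: bool = True,
) -> tuple[pd.DataFrame, DosageTableSummary]:
    """Run the dosage test over a whole counts table.

    ``counts`` needs columns ``Position``, ``Coverage``,
    ``VariantCoverage`` and either explicit per-hypothesis columns
    ``GenomicVariant1/GenomicTotal1/GenomicVariant2/GenomicTotal2`` or
    ``GenomicDetected`` + ``ObservedVariantCount`` with a
    :class:`PloidyContext`.  An optional boolean ``InDuplication``
    column marks sites inside a shared duplicated segment; with
    ``exclude_duplication`` those rows are reported untested.  Rows come
    back ordered by position with per-hypothesis p-values and accept
    flags, plus a summary of how many testable sites accept at least one
    hypothesis.
    """
    df = counts.copy().sort_values("Position", kind="stable").reset_index(drop=True)
    in_dup = (
        df["InDuplication"].fillna(False).astype(bool)
        if "InDuplication" in df
        else pd.Series(False, index=df.index)
    )
    out_rows = []
    n_testable = n_accepted = n_dup = 0
    for idx, row in df.iterrows():
        rendered = {
            col: row[col]
            for col in (
                "SNP",
                "Name",
                "Change",
                "PolymorphismType",
                "Position",
                "Coverage",
                "VariantCoverage",
                "GenomicDetected",
                "InDuplication",
            )
            if col in df.columns
        }
        k, n = int(row["VariantCoverage"]), int(row["Coverage"])
        rendered["TranscriptomeProportion"] = (
            float(
                Decimal(str(k / n)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
            )
            if n > 0
            else None
        )
        if exclude_duplication and in_dup[idx]:
            n_dup += 1
            rendered["Tested"] = False
            out_rows.append(rendered)
            continue
        result = test_snp_dosage(k, n, _row_hypotheses(row, ctx), alpha)
        rendered["Tested"] = not result.untestable
        for i, hyp_res in enumerate(result.hypotheses, start=1):
            rendered[f"GenomicVariant{i}"] = hyp_res.hypothesis.genomic_variant
            rendered[f"Genomic{i}"] = hyp_res.hypothesis.genomic_common
            rendered[f"GenomicProportion{i}"] = float(hyp_res.hypothesis.proportion)
            rendered[f"Pvalue{i}"] = hyp_res.p_value
            rendered[f"Accept{i}"] = hyp_res.accept
        if not result.untestable:
            n_testable += 1
            n_accepted += int(result.any_accepted)
        out_rows.append(rendered)
    table = pd.DataFrame(out_rows)
    return table, DosageTableSummary(n_testable, n_accepted, n_dup)
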