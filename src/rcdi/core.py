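"""Codon counting, synonymous frequencies and the RCDI statistic.

The Relative Codon Deoptimization Index of a gene against a reference
codon-usage table is

    RCDI = sum_i (CiFa_i / CiFh_i) * N_i / N

where, within each synonymous family, CiFa is the codon's relative frequency
in the test gene, CiFh its relative frequency in the reference, N_i the
codon's count in the gene and N the total number of counted codons. RCDI is
1 when the gene's within-family codon usage matches the reference exactly and
grows with deoptimization, up to the inverse of the smallest reference
synonymous frequency among families present in the gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .formats import CodingSequence, CodonUsageTable
from .genetic_code import CODONS, STOP, GeneticCode

_UNAMBIGUOUS = set("ACGT")


@dataclass(frozen=True)
class CodonCounts:
    """Codon occurrence counts for one gene (N_i and N)."""

    counts: dict[str, int]
    total: int
    excluded: int = 0  # codons skipped for ambiguity characters
    stops: int = 0  # stop codons seen (skipped unless include_stops)

    def __post_init__(self) -> None:
        if self.total != sum(self.counts.values()):
            raise ValueError("total must equal the sum of counts")


def count_codons(
    seq: CodingSequence, code: GeneticCode, include_stops: bool = False
) -> CodonCounts:
    """Count codons in frame 1. Ambiguous codons are excluded and tallied;
    stop codons are skipped unless *include_stops*."""
    counts: dict[str, int] = {}
    excluded = stops = 0
    for codon in seq.codons:
        if not set(codon) <= _UNAMBIGUOUS:
            excluded += 1
            continue
        if code.codon_to_aa[codon] == STOP:
            stops += 1
            if not include_stops:
                continue
        counts[codon] = counts.get(codon, 0) + 1
    return CodonCounts(
        counts=counts, total=sum(counts.values()), excluded=excluded, stops=stops
    )


@dataclass(frozen=True)
class SynonymousFrequencyTable:
    """Per-codon relative frequency within its synonymous family.

    Houses CiFh when built from a reference codon-usage table and CiFa when
    built from a gene's own codon counts. Families with no observations are
    undefined: their codons map to NaN, which is distinct from an observed
    frequency of zero.
    """

    freq: dict[str, float]
    code: GeneticCode = field(repr=False)

    def __post_init__(self) -> None:
        for aa, family in self.code.families.items():
            vals = [self.freq[c] for c in family]
            if any(math.isnan(v) for v in vals):
                if not all(math.isnan(v) for v in vals):
                    raise ValueError(f"family {aa}: mixed defined/undefined")
                continue
            if abs(sum(vals) - 1.0) > 1e-9:
                raise ValueError(
                    f"family {aa}: frequencies sum to {sum(vals)}, not 1"
                )

    def defined(self, codon: str) -> bool:
        return not math.isnan(self.freq[codon])

    def min_defined(self) -> float:
        return min(v for v in self.freq.values() if not math.isnan(v))


def synonymous_frequencies(
    source: CodonCounts | CodonUsageTable, code: GeneticCode
) -> SynonymousFrequencyTable:
    """Normalise codon values within each synonymous family.

    ``freq[c] = value[c] / sum over codons synonymous with c``. Families whose
    total is zero are marked undefined (NaN). An all-zero source is an error.
    """
    if isinstance(source, CodonCounts):
        values = {c: float(source.counts.get(c, 0)) for c in CODONS}
    else:
        values = {c: float(source.values[c]) for c in CODONS}
    if sum(values.values()) == 0:
        raise ValueError("all-zero codon values: frequencies undefined")
    freq: dict[str, float] = {}
    for family in code.families.values():
        total = sum(values[c] for c in family)
        for c in family:
            freq[c] = values[c] / total if total > 0 else math.nan
    return SynonymousFrequencyTable(freq=freq, code=code)


@dataclass(frozen=True)
class RcdiResult:
    """RCDI of one gene plus the per-codon breakdown and GC metrics."""

    gene_id: str
    rcdi: float
    contributions: dict[str, float]  # (CiFa/CiFh) * N_i per counted codon
    gc_percent: float
    gc3_percent: float
    n_codons: int
    excluded_codons: int = 0
    warnings: tuple[str, ...] = ()


def _gc_of_codons(counted: dict[str, int]) -> tuple[float, float]:
    n = sum(counted.values())
    if n == 0:
        return 0.0, 0.0
    gc = sum(k * sum(b in "GC" for b in c) for c, k in counted.items())
    gc3 = sum(k for c, k in counted.items() if c[2] in "GC")
    return 100.0 * gc / (3 * n), 100.0 * gc3 / n


def gc_metrics(seq: CodingSequence) -> tuple[float, float]:
    """Overall %G+C and third-position %G+C3 over unambiguous codons."""
    counted: dict[str, int] = {}
    for codon in seq.codons:
        if set(codon) <= _UNAMBIGUOUS:
            counted[codon] = counted.get(codon, 0) + 1
    return _gc_of_codons(counted)


def rcdi(
    seq: CodingSequence,
    reference: SynonymousFrequencyTable,
    code: GeneticCode,
    include_stops: bool = False,
    pseudo_freq: float | None = None,
) -> RcdiResult:
    """Compute the RCDI of *seq* against *reference*.

    CiFa is computed from the gene's own codon counts. A codon present in the
    gene but with zero or undefined reference frequency raises unless
    *pseudo_freq* supplies a small replacement frequency. GC metrics are
    computed over the same counted codons the index uses.
    """
    if reference.code.table_id != code.table_id:
        raise ValueError("reference table built under a different genetic code")
    counted = count_codons(seq, code, include_stops=include_stops)
    if counted.total == 0:
        raise ValueError(f"{seq.id}: no countable codons")
    cifa = synonymous_frequencies(counted, code)

    warnings: list[str] = []
    if counted.excluded:
        warnings.append(f"{counted.excluded} codon(s) excluded for ambiguity codes")
    internal_stops = sum(
        1
        for i, codon in enumerate(seq.codons[:-1])
        if set(codon) <= _UNAMBIGUOUS and code.codon_to_aa[codon] == STOP
    )
    if internal_stops:
        warnings.append(f"{internal_stops} internal stop codon(s)")

    contributions: dict[str, float] = {}
    total = 0.0
    for codon, n_i in counted.counts.items():
        cifh = reference.freq[codon]
        if math.isnan(cifh) or cifh == 0.0:
            if pseudo_freq is None:
                raise ValueError(
                    f"{seq.id}: codon absent from reference: {codon}"
                )
            cifh = pseudo_freq
        contributions[codon] = (cifa.freq[codon] / cifh) * n_i
        total += contributions[codon]

    gc, gc3 = _gc_of_codons(counted.counts)
    return RcdiResult(
        gene_id=seq.id,
        rcdi=total / counted.total,
        contributions=contributions,
        gc_percent=gc,
        gc3_percent=gc3,
        n_codons=counted.total,
        excluded_codons=counted.excluded,
        warnings=tuple(warnings),
    )
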