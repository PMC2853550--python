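"""Companion codon-usage indices: CAI, ENC and the expected-ENC curve.

These complement RCDI: CAI measures adaptation to a reference's *preferred*
codons (reference-dependent, like RCDI, but 1-extremal under a different
condition); ENC measures departure from equal synonymous-codon use without
any reference, from 20 (one codon per amino acid) to 61 (uniform use); the
expected-ENC curve gives the ENC a gene would have if its codon usage were
driven by third-position G+C alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .core import count_codons
from .formats import CodingSequence, CodonUsageTable
from .genetic_code import STOP, GeneticCode


@dataclass(frozen=True)
class RelativeAdaptivenessTable:
    """CAI weights: each codon's reference frequency over its family maximum."""

    w: dict[str, float]
    code: GeneticCode = field(repr=False)

    def __post_init__(self) -> None:
        for aa, family in self.code.families.items():
            if aa == STOP:
                continue
            if abs(max(self.w[c] for c in family) - 1.0) > 1e-9:
                raise ValueError(f"family {aa}: maximal codon must have w = 1")


def relative_adaptiveness(
    table: CodonUsageTable, code: GeneticCode, pseudo_count: bool = True
) -> RelativeAdaptivenessTable:
    """Build CAI weights from a reference codon-usage table.

    With *pseudo_count*, codons unused in the reference get
    w = 0.5 / (family maximum value) instead of zero, so CAI stays finite.
    """
    w: dict[str, float] = {}
    for aa, family in code.families.items():
        if aa == STOP:
            continue
        fmax = max(table.values[c] for c in family)
        if fmax == 0:
            raise ValueError(f"family {aa}: all reference values are zero")
        for c in family:
            v = table.values[c]
            if v == 0 and pseudo_count:
                v = 0.5
            w[c] = v / fmax
    return RelativeAdaptivenessTable(w=w, code=code)


def cai(
    seq: CodingSequence,
    weights: RelativeAdaptivenessTable,
    code: GeneticCode,
) -> float:
    """Codon Adaptation Index: geometric mean of relative adaptiveness.

    Stop codons and single-codon families (Met, Trp under the standard code)
    are excluded from the exponent, following the usual convention. A zero
    weight on a used codon is an error (enable pseudo-counting in the weight
    table instead).
    """
    counted = count_codons(seq, code, include_stops=False)
    log_sum = 0.0
    n = 0
    for codon, k in counted.counts.items():
        if len(code.family_of(codon)) == 1:
            continue
        wc = weights.w[codon]
        if wc <= 0:
            raise ValueError(
                f"{seq.id}: zero adaptiveness for codon {codon}; "
                "build weights with pseudo_count=True"
            )
        log_sum += k * math.log(wc)
        n += k
    if n == 0:
        raise ValueError(f"{seq.id}: CAI undefined (no degenerate-family codons)")
    return math.exp(log_sum / n)


def enc(seq: CodingSequence, code: GeneticCode) -> float:
    """Wright's Effective Number of Codons.

    Per family with its amino acid observed n >= 2 times, the codon
    homozygosity is F = (n * sum p^2 - 1) / (n - 1); F values are averaged
    within degeneracy classes and ENC = n1 + sum over classes of
    (class size) / (mean F), n1 being the number of single-codon families.
    A missing 3-fold class is imputed as the mean of the 2- and 4-fold
    averages; families with F <= 0 (tiny samples) are unusable. The result
    is clipped to the number of sense codons (61 for the standard code).
    """
    counted = count_codons(seq, code, include_stops=False)
    f_by_size: dict[int, list[float]] = {}
    for aa, family in code.families.items():
        if aa == STOP or len(family) == 1:
            continue
        n = sum(counted.counts.get(c, 0) for c in family)
        if n < 2:
            continue
        s = sum((counted.counts.get(c, 0) / n) ** 2 for c in family)
        f = (n * s - 1.0) / (n - 1.0)
        if f > 0:
            f_by_size.setdefault(len(family), []).append(f)

    class_counts: dict[int, int] = {}
    n_single = 0
    for aa, family in code.families.items():
        if aa == STOP:
            continue
        if len(family) == 1:
            n_single += 1
        else:
            class_counts[len(family)] = class_counts.get(len(family), 0) + 1

    f_mean: dict[int, float] = {
        size: sum(fs) / len(fs) for size, fs in f_by_size.items()
    }
    for size in class_counts:
        if size not in f_mean:
            if size == 3 and 2 in f_mean and 4 in f_mean:
                f_mean[3] = (f_mean[2] + f_mean[4]) / 2.0
            else:
                raise ValueError(
                    f"{seq.id}: ENC undefined (no usable {size}-fold family)"
                )
    value = n_single + sum(
        class_counts[size] / f_mean[size] for size in class_counts
    )
    return min(value, float(len(code.sense_codons)))


def expected_enc(gc3: float) -> float:
    """Wright's expected ENC from third-position G+C alone.

    ENC_exp(s) = 2 + s + 29 / (s^2 + (1-s)^2) with s the G+C3 fraction,
    strictly inside (0, 1). Symmetric about s = 0.5, where it peaks at 60.5.
    """
    if not 0.0 < gc3 < 1.0:
        raise ValueError("gc3 must lie strictly in (0, 1)")
    return 2.0 + gc3 + 29.0 / (gc3**2 + (1.0 - gc3) ** 2)
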