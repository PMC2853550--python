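import numpy as np
import pytest

from rcdi import (
    CodingSequence,
    CodonUsageTable,
    get_genetic_code,
    synonymous_frequencies,
)
from rcdi.genetic_code import CODONS, STOP


@pytest.fixture(scope="session")
def code1():
    return get_genetic_code(1)


@pytest.fixture(scope="session")
def sense_codons(code1):
    return list(code1.sense_codons)


@pytest.fixture(scope="session")
def uniform_table():
    """Reference with equal value for every codon (uniform family usage)."""
    return CodonUsageTable({c: 100.0 for c in CODONS})


@pytest.fixture(scope="session")
def human_like_table(code1):
    """Synthetic table whose Ser family gives TCG relative frequency 0.0567,
    the lowest synonymous frequency of the human reference usage."""
    values = {c: 100.0 for c in CODONS}
    ser = code1.families["S"]
    for c in ser:
        values[c] = (10000.0 - 567.0) / (len(ser) - 1)
    values["TCG"] = 567.0
    return CodonUsageTable(values)


@pytest.fixture(scope="session")
def human_like_ref(human_like_table, code1):
    return synonymous_frequencies(human_like_table, code1)


def random_gene(rng, sense, n_codons, gene_id="g"):
    return CodingSequence(gene_id, "".join(rng.choice(sense, size=n_codons)))


def random_reference(rng, code):
    """A full-support reference table with random positive codon values."""
    values = {c: float(v) for c, v in zip(CODONS, rng.integers(1, 200, size=64))}
    return synonymous_frequencies(CodonUsageTable(values), code)


def matched_pair(rng, code, n_families=6, max_count=5):
    """A (gene, reference) pair whose within-family frequencies agree exactly.

    Reference values are set to the gene's own integer codon counts, so
    CiFa = CiFh in every counted family and RCDI must equal 1.
    """
    aas = [a for a in code.families if a != STOP and len(code.families[a]) > 1]
    chosen = rng.choice(aas, size=min(n_families, len(aas)), replace=False)
    values = {c: 0.0 for c in CODONS}
    codon_list = []
    for aa in chosen:
        family = code.families[aa]
        counts = rng.integers(0, max_count + 1, size=len(family))
        if counts.sum() == 0:
            counts[rng.integers(len(family))] = 1
        for c, k in zip(family, counts):
            values[c] = float(k)
            codon_list.extend([c] * int(k))
    for aa, family in code.families.items():
        if aa not in set(chosen):
            for c in family:
                values[c] = 1.0
    order = rng.permutation(len(codon_list))
    seq = CodingSequence("matched", "".join(codon_list[i] for i in order))
    return seq, synonymous_frequencies(CodonUsageTable(values), code)


def naive_rcdi(seq, reference, code):
    """Brute-force per-codon loop over the RCDI sum, for oracle checks."""
    counted = [
        c
        for c in seq.codons
        if set(c) <= set("ACGT") and code.codon_to_aa[c] != STOP
    ]
    n = len(counted)
    fam_totals = {}
    counts = {}
    for c in counted:
        counts[c] = counts.get(c, 0) + 1
    for c in counted:
        aa = code.codon_to_aa[c]
        fam_totals[aa] = fam_totals.get(aa, 0) + 1
    total = 0.0
    for c in counted:  # one term per codon occurrence
        cifa = counts[c] / fam_totals[code.codon_to_aa[c]]
        total += cifa / reference.freq[c]
    return total / n
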