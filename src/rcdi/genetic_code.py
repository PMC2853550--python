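"""NCBI genetic codes as explicit 64-codon maps.

Thin wrapper over Biopython's codon tables that always exposes the full
64-codon map (stop codons included, marked ``*``) for one NCBI
translation-table id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable as _BioCodonTable

STOP = "*"
BASES = "TCAG"
CODONS: tuple[str, ...] = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES
)


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code: map from each of the 64 DNA codons to an amino acid.

    Stop codons map to ``"*"``. Synonymous families (sets of codons encoding
    the same amino acid) are precomputed because every index in this package
    normalises codon frequencies within families.
    """

    table_id: int
    codon_to_aa: dict[str, str]
    families: dict[str, tuple[str, ...]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(CODONS):
            raise ValueError("genetic code must map exactly the 64 DNA codons")
        if STOP not in self.codon_to_aa.values():
            raise ValueError("genetic code must contain at least one stop codon")
        fams: dict[str, list[str]] = {}
        for codon in CODONS:  # fixed TCAG order keeps families deterministic
            fams.setdefault(self.codon_to_aa[codon], []).append(codon)
        object.__setattr__(
            self, "families", {aa: tuple(cs) for aa, cs in fams.items()}
        )

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return self.families[STOP]

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODONS if self.codon_to_aa[c] != STOP)

    def family_of(self, codon: str) -> tuple[str, ...]:
        """All codons synonymous with *codon* (including itself)."""
        return self.families[self.codon_to_aa[codon]]

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]


@lru_cache(maxsize=None)
def get_genetic_code(table_id: int = 1) -> GeneticCode:
    """Return the NCBI translation table *table_id* as a :class:`GeneticCode`.

    Raises ``ValueError`` listing the supported ids if *table_id* is unknown.
    """
    try:
        table = _BioCodonTable.unambiguous_dna_by_id[table_id]
    except KeyError:
        supported = sorted(_BioCodonTable.unambiguous_dna_by_id)
        raise ValueError(
            f"unsupported genetic code id {table_id}; supported ids: {supported}"
        ) from None
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = STOP
    return GeneticCode(table_id=table_id, codon_to_aa=mapping)
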