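"""Model/results interface tying the pieces together.

``CodonDeoptimizationModel`` holds a query CDS set, a reference codon-usage
table and a genetic code; ``fit()`` computes per-gene RCDI (optionally CAI,
ENC and expected ENC) and, when requested, the eRCDI significance threshold
from matched random sequences. The returned results object carries the
per-gene table as a DataFrame, the null-distribution diagnostics and a
``summary()`` in the style of statistical modelling packages.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import formats
from .core import RcdiResult, SynonymousFrequencyTable, rcdi, synonymous_frequencies
from .ercdi import (
    ErcdiConfig,
    ErcdiResult,
    RandomCdsGenerator,
    composition_profile,
    expected_rcdi,
    markov_transition,
)
from .formats import CodingSequence, CodonUsageTable, RejectedSequence
from .genetic_code import GeneticCode, get_genetic_code
from .indices import cai, enc, expected_enc, relative_adaptiveness


def _trim_incomplete(seq_id: str, raw: str) -> tuple[str, str | None]:
    extra = len(raw) % 3
    if extra:
        return raw[:-extra], f"{seq_id}: trimmed {extra} trailing nucleotide(s)"
    return raw, None


class CodonDeoptimizationModel:
    """RCDI/eRCDI analysis of a set of coding sequences vs a reference."""

    def __init__(
        self,
        sequences: list[CodingSequence],
        reference: CodonUsageTable | SynonymousFrequencyTable,
        genetic_code: int | GeneticCode = 1,
        include_stops: bool = False,
        pseudo_freq: float | None = None,
    ) -> None:
        if not sequences:
            raise ValueError("no sequences")
        self.code = (
            genetic_code
            if isinstance(genetic_code, GeneticCode)
            else get_genetic_code(genetic_code)
        )
        self.sequences = list(sequences)
        if isinstance(reference, SynonymousFrequencyTable):
            self.reference = reference
            self.reference_table = None
        else:
            self.reference_table = reference
            self.reference = synonymous_frequencies(reference, self.code)
        self.include_stops = include_stops
        self.pseudo_freq = pseudo_freq
        self.rejected: list[RejectedSequence] = []
        self.log: list[str] = []

    @classmethod
    def from_files(
        cls,
        fasta_path: str,
        table_path: str,
        genetic_code: int = 1,
        dialect: str = "auto",
        trim_incomplete: bool = False,
        **kwargs,
    ) -> "CodonDeoptimizationModel":
        with open(fasta_path) as fh:
            text = fh.read()
        log: list[str] = []
        if trim_incomplete:
            accepted, rejected, log = _read_fasta_trimming(text)
        else:
            accepted, rejected = formats.read_fasta(text)
        with open(table_path) as fh:
            table = formats.parse_codon_usage_table(fh, dialect=dialect)
        if not accepted:
            raise ValueError("no valid coding sequences in input")
        model = cls(accepted, table, genetic_code=genetic_code, **kwargs)
        model.rejected = rejected
        model.log = log
        return model

    # -- simulation hangs off the model -------------------------------------
    def simulate_null(
        self, n: int, seed: int = 0, method: str = "poisson", length: int | None = None
    ) -> list[CodingSequence]:
        """Generate *n* random CDS matched to the query composition."""
        import numpy as np

        profile = composition_profile(self.sequences, self.code)
        transition = (
            markov_transition(self.sequences, self.code)
            if method == "markov"
            else None
        )
        gen = RandomCdsGenerator(
            profile, self.code, method=method, transition=transition
        )
        rng = np.random.default_rng(seed)
        return [
            gen.generate(rng, length=length, seq_id=f"random_{i + 1}")
            for i in range(n)
        ]

    def fit(
        self,
        ercdi: ErcdiConfig | bool | None = None,
        with_cai: bool = False,
        with_enc: bool = False,
    ) -> "CodonDeoptimizationResults":
        """Compute RCDI per gene and, optionally, the eRCDI threshold."""
        genes = [
            rcdi(
                s,
                self.reference,
                self.code,
                include_stops=self.include_stops,
                pseudo_freq=self.pseudo_freq,
            )
            for s in self.sequences
        ]
        indices: dict[str, dict[str, float]] = {}
        if with_cai or with_enc:
            weights = (
                relative_adaptiveness(self.reference_table, self.code)
                if (with_cai and self.reference_table is not None)
                else None
            )
            for seq, res in zip(self.sequences, genes):
                row: dict[str, float] = {}
                if with_cai:
                    if weights is None:
                        raise ValueError(
                            "CAI needs the raw reference codon-usage table"
                        )
                    row["cai"] = cai(seq, weights, self.code)
                if with_enc:
                    row["enc"] = enc(seq, self.code)
                    g3 = res.gc3_percent / 100.0
                    row["expected_enc"] = (
                        expected_enc(g3) if 0.0 < g3 < 1.0 else float("nan")
                    )
                indices[res.gene_id] = row
        ercdi_result: ErcdiResult | None = None
        if ercdi:
            config = ercdi if isinstance(ercdi, ErcdiConfig) else ErcdiConfig()
            ercdi_result = expected_rcdi(
                self.sequences,
                self.reference,
                self.code,
                config,
                pseudo_freq=self.pseudo_freq,
            )
        return CodonDeoptimizationResults(
            model=self, genes=genes, ercdi=ercdi_result, indices=indices
        )


@dataclass
class CodonDeoptimizationResults:
    """Fitted RCDI values, companion indices and the eRCDI null summary."""

    model: CodonDeoptimizationModel
    genes: list[RcdiResult]
    ercdi: ErcdiResult | None = None
    indices: dict[str, dict[str, float]] | None = None

    @property
    def frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            row = {
                "gene_id": g.gene_id,
                "n_codons": g.n_codons,
                "rcdi": g.rcdi,
                "gc_percent": g.gc_percent,
                "gc3_percent": g.gc3_percent,
            }
            if self.indices and g.gene_id in self.indices:
                row.update(self.indices[g.gene_id])
            if self.ercdi is not None:
                row["deoptimized"] = g.rcdi > self.ercdi.ercdi
            rows.append(row)
        return pd.DataFrame(rows)

    def to_report(self, fmt: str = "tsv", precision: int = 4) -> str:
        return formats.write_report(
            self.genes,
            ercdi=self.ercdi,
            fmt=fmt,
            precision=precision,
            indices=self.indices,
        )

    def summary(self) -> str:
        lines = [
            "Codon Deoptimization Analysis",
            "=" * 60,
            f"Genes: {len(self.genes)}   genetic code: "
            f"{self.model.code.table_id}",
            "",
            self.frame.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        if self.ercdi is not None:
            e = self.ercdi
            lines += [
                "",
                f"eRCDI null ({e.method}, n={e.n_random}, seed={e.seed}):",
                f"  random RCDI mean {e.random_rcdi_mean:.4f}  "
                f"SD {e.random_rcdi_sd:.4f}",
                f"  tolerance factor k {e.tolerance_factor:.4f} "
                f"(confidence {e.confidence}, coverage {e.coverage})",
                f"  eRCDI = {e.ercdi:.4f}",
                f"  KS normality: D={e.ks_statistic:.4f}, "
                f"p(Lilliefors)={e.ks_pvalue:.4f}",
            ]
        return "\n".join(lines)

    def plot_null(self, ax=None):
        """Histogram of the null RCDI distribution with the eRCDI line."""
        if self.ercdi is None:
            raise ValueError("fit with ercdi=... to obtain a null distribution")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.ercdi.random_rcdi_values, bins=30, color="0.7")
        ax.axvline(self.ercdi.ercdi, color="C3", label="eRCDI")
        for g in self.genes:
            ax.axvline(g.rcdi, color="C0", linestyle=":")
        ax.set_xlabel("RCDI")
        ax.set_ylabel("random sequences")
        ax.legend()
        return ax


def _read_fasta_trimming(
    text: str,
) -> tuple[list[CodingSequence], list[RejectedSequence], list[str]]:
    """FASTA reading with trailing 1-2 nt trimmed instead of rejected."""
    import io

    from Bio import SeqIO

    accepted: list[CodingSequence] = []
    rejected: list[RejectedSequence] = []
    log: list[str] = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = formats.normalize_nucleotides(str(rec.seq))
        seq, note = _trim_incomplete(rec.id, seq)
        if note:
            log.append(note)
        if not seq:
            rejected.append(RejectedSequence(rec.id, "empty sequence"))
            continue
        try:
            accepted.append(CodingSequence(rec.id, seq))
        except ValueError as exc:
            rejected.append(RejectedSequence(rec.id, str(exc)))
    return accepted, rejected, log
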