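"""Input/output: FASTA coding sequences, codon-usage tables, result reports.

Two table dialects are read: the codon-usage-database layout with several
``CODON per-thousand (count)`` groups per line, and a plain two-column
``CODON value`` layout. Codons may be spelled with U or T; tables are stored
T-spelled. Whether values are raw counts or frequencies per thousand is
inferred from their sum unless the caller overrides it.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, TextIO

from Bio import SeqIO

from .genetic_code import CODONS

if TYPE_CHECKING:  # pragma: no cover
    from .core import RcdiResult
    from .ercdi import ErcdiResult

# IUPAC nucleotide one-letter codes (ambiguity codes allowed in sequences;
# codons containing them are excluded from counting, not rejected).
IUPAC_NT = set("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class CodingSequence:
    """An in-frame coding sequence: id plus an upper-case DNA string."""

    id: str
    nucleotides: str

    def __post_init__(self) -> None:
        n = len(self.nucleotides)
        if n == 0 or n % 3 != 0:
            raise ValueError(
                f"{self.id}: length not multiple of 3 (length {n})"
            )
        bad = set(self.nucleotides) - IUPAC_NT
        if bad:
            raise ValueError(
                f"{self.id}: invalid characters {sorted(bad)}"
            )

    @property
    def codons(self) -> list[str]:
        s = self.nucleotides
        return [s[i : i + 3] for i in range(0, len(s), 3)]

    def __len__(self) -> int:
        return len(self.nucleotides)


@dataclass(frozen=True)
class RejectedSequence:
    id: str
    reason: str


def normalize_nucleotides(raw: str) -> str:
    """Upper-case and convert RNA to DNA (U -> T)."""
    return raw.upper().replace("U", "T")


def read_fasta(
    stream: TextIO | str,
) -> tuple[list[CodingSequence], list[RejectedSequence]]:
    """Parse FASTA into coding sequences.

    Returns ``(accepted, rejected)``: records violating the coding-sequence
    invariants (empty, frame-broken, bad alphabet) land in *rejected* with a
    reason instead of being dropped. Raises on an empty stream or on leading
    non-FASTA content (with the offending line number).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    text = stream.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.lstrip().startswith(">"):
                raise ValueError(
                    f"line {lineno}: not FASTA (expected '>' header, got {line[:30]!r})"
                )
            break
    else:
        raise ValueError("no sequences: input is empty")

    accepted: list[CodingSequence] = []
    rejected: list[RejectedSequence] = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = normalize_nucleotides(str(rec.seq))
        n = len(seq)
        if n == 0 or n % 3 != 0:
            rejected.append(
                RejectedSequence(rec.id, f"length not multiple of 3 (length {n})")
            )
            continue
        bad = set(seq) - IUPAC_NT
        if bad:
            rejected.append(
                RejectedSequence(rec.id, f"invalid characters {sorted(bad)}")
            )
            continue
        accepted.append(CodingSequence(rec.id, seq))
    if not accepted and not rejected:
        raise ValueError("no sequences: input contains no FASTA records")
    return accepted, rejected


def write_fasta(seqs: Iterable[CodingSequence], width: int = 60) -> str:
    out = []
    for s in seqs:
        out.append(f">{s.id}")
        out.extend(
            s.nucleotides[i : i + width] for i in range(0, len(s.nucleotides), width)
        )
    return "\n".join(out) + "\n"


@dataclass(frozen=True)
class CodonUsageTable:
    """Reference codon usage: one non-negative value per codon.

    ``scale`` records whether values are raw counts or frequencies per
    thousand; within-family normalisation makes the two interchangeable for
    every index computed here.
    """

    values: dict[str, float]
    scale: str = "counts"  # "counts" | "per_thousand"

    def __post_init__(self) -> None:
        if set(self.values) != set(CODONS):
            missing = sorted(set(CODONS) - set(self.values))
            extra = sorted(set(self.values) - set(CODONS))
            raise ValueError(
                f"codon usage table must cover all 64 codons "
                f"(missing {missing}, unexpected {extra})"
            )
        neg = [c for c, v in self.values.items() if v < 0]
        if neg:
            raise ValueError(f"negative value for codon(s) {neg}")
        if self.scale not in ("counts", "per_thousand"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "per_thousand":
            total = sum(self.values.values())
            if abs(total - 1000.0) > 0.5:
                raise ValueError(
                    f"per-thousand table sums to {total:.3f}, expected ~1000"
                )


_TOKEN_RE = re.compile(
    r"([ACGTU]{3})\s+(\d+(?:\.\d+)?|\.\d+)(?:\s*\(\s*(\d+(?:\.\d+)?)\s*\))?"
)


def _infer_scale(values: dict[str, float]) -> str:
    return "per_thousand" if abs(sum(values.values()) - 1000.0) <= 0.5 else "counts"


def parse_codon_usage_table(
    stream: TextIO | str,
    dialect: str = "auto",
    scale: str | None = None,
) -> CodonUsageTable:
    """Parse a reference codon-usage table.

    ``dialect`` is ``kazusa_style`` (several ``CODON per-thousand (count)``
    groups per line, as printed by the codon usage database), ``two_column``
    (one ``CODON value`` pair per line) or ``auto``. When the kazusa layout
    carries raw counts in parentheses those are kept (scale ``counts``);
    otherwise the per-thousand column is used. ``scale`` overrides inference.
    """
    text = stream if isinstance(stream, str) else stream.read()
    if dialect not in ("auto", "kazusa_style", "two_column"):
        raise ValueError(f"unknown dialect {dialect!r}")
    has_parens = "(" in text
    if dialect == "auto":
        dialect = "kazusa_style" if has_parens else "two_column"

    per_thousand: dict[str, float] = {}
    counts: dict[str, float] = {}
    for m in _TOKEN_RE.finditer(text):
        codon = m.group(1).upper().replace("U", "T")
        if codon in per_thousand:
            raise ValueError(f"duplicated codon {codon}")
        per_thousand[codon] = float(m.group(2))
        if m.group(3) is not None:
            counts[codon] = float(m.group(3))

    if not per_thousand:
        raise ValueError("no codon entries found")
    missing = sorted(set(CODONS) - set(per_thousand))
    if missing:
        raise ValueError(f"missing codon(s): {missing}")

    if dialect == "kazusa_style" and len(counts) == len(per_thousand):
        values, inferred = counts, "counts"
    else:
        values = per_thousand
        inferred = _infer_scale(values)
    return CodonUsageTable(values=values, scale=scale or inferred)


def format_codon_usage_table(table: CodonUsageTable) -> str:
    """Write a table back out in the two-column dialect."""
    return "\n".join(f"{c} {table.values[c]:g}" for c in CODONS) + "\n"


# ---------------------------------------------------------------------------
# Reports


def _sig(x: float, precision: int) -> float:
    # half-even rounding for display; internal values keep full precision
    return round(float(x), precision)


def results_to_dict(
    results: "Iterable[RcdiResult]",
    ercdi: "ErcdiResult | None" = None,
    indices: dict[str, dict[str, float]] | None = None,
) -> dict:
    """Assemble the four report blocks as plain Python objects.

    Blocks: per-gene parameters, global parameters, statistical tests and the
    expected RCDI. The last three are ``None`` when no eRCDI run was done.
    """
    genes = []
    for r in results:
        row = {
            "gene_id": r.gene_id,
            "n_codons": r.n_codons,
            "rcdi": r.rcdi,
            "gc_percent": r.gc_percent,
            "gc3_percent": r.gc3_percent,
            "excluded_codons": r.excluded_codons,
            "contributions": dict(r.contributions),
            "warnings": list(r.warnings),
        }
        if indices and r.gene_id in indices:
            row.update(indices[r.gene_id])
        genes.append(row)
    doc: dict = {"genes": genes}
    if ercdi is None:
        doc["global"] = None
        doc["statistical_tests"] = None
        doc["expected_rcdi"] = None
    else:
        doc["global"] = {
            "mean_gc_percent": 100.0 * ercdi.profile.gc_target,
            "mean_length_codons": ercdi.profile.mean_length_codons,
            "amino_acid_composition": dict(ercdi.profile.aa_freq),
            "n_random": ercdi.n_random,
        }
        doc["statistical_tests"] = {
            "ks_statistic": ercdi.ks_statistic,
            "ks_pvalue_lilliefors": ercdi.ks_pvalue,
            "ks_pvalue_plain": ercdi.ks_pvalue_plain,
            "chi2_gc": [
                {"gene_id": g, "statistic": s, "pvalue": p}
                for g, s, p in ercdi.chi2_gc
            ],
            "chi2_aa": [
                {"gene_id": g, "statistic": s, "pvalue": p}
                for g, s, p in ercdi.chi2_aa
            ],
        }
        doc["expected_rcdi"] = {
            "random_rcdi_mean": ercdi.random_rcdi_mean,
            "random_rcdi_sd": ercdi.random_rcdi_sd,
            "ercdi": ercdi.ercdi,
            "tolerance_factor": ercdi.tolerance_factor,
            "confidence": ercdi.confidence,
            "coverage": ercdi.coverage,
            "method": ercdi.method,
        }
    return doc


def write_report(
    results: "Iterable[RcdiResult]",
    ercdi: "ErcdiResult | None" = None,
    fmt: str = "tsv",
    precision: int = 4,
    indices: dict[str, dict[str, float]] | None = None,
) -> str:
    """Render the report as TSV (rounded display) or JSON (full precision).

    The JSON form round-trips bit-for-bit through ``json.loads``. The TSV gene
    block has columns gene_id, n_codons, rcdi, gc_percent, gc3_percent, any
    companion-index columns, then one column per codon holding the per-codon
    contribution (CiFa/CiFh)*Ni.
    """
    doc = results_to_dict(results, ercdi, indices)
    if fmt == "json":
        return json.dumps(doc, indent=1)
    if fmt != "tsv":
        raise ValueError(f"unknown report format {fmt!r}")

    p = precision
    lines: list[str] = ["# gene parameters"]
    extra_cols: list[str] = []
    for row in doc["genes"]:
        for key in ("cai", "enc", "expected_enc"):
            if key in row and key not in extra_cols:
                extra_cols.append(key)
    header = ["gene_id", "n_codons", "rcdi", "gc_percent", "gc3_percent"]
    header += extra_cols + list(CODONS)
    lines.append("\t".join(header))
    for row in doc["genes"]:
        cells = [
            row["gene_id"],
            str(row["n_codons"]),
            str(_sig(row["rcdi"], p)),
            str(_sig(row["gc_percent"], p)),
            str(_sig(row["gc3_percent"], p)),
        ]
        for key in extra_cols:
            v = row.get(key)
            cells.append("NA" if v is None else str(_sig(v, p)))
        contrib = row["contributions"]
        cells += [str(_sig(contrib.get(c, 0.0), p)) for c in CODONS]
        lines.append("\t".join(cells))

    if doc["global"] is None:
        lines.append("# expected RCDI: absent (no eRCDI run)")
        return "\n".join(lines) + "\n"

    g = doc["global"]
    lines += [
        "# global parameters",
        f"mean_gc_percent\t{_sig(g['mean_gc_percent'], p)}",
        f"mean_length_codons\t{g['mean_length_codons']}",
        f"n_random\t{g['n_random']}",
        "aa\tfrequency",
    ]
    lines += [
        f"{aa}\t{_sig(fq, p)}"
        for aa, fq in sorted(g["amino_acid_composition"].items())
    ]
    t = doc["statistical_tests"]
    lines += [
        "# statistical tests",
        f"ks_statistic\t{_sig(t['ks_statistic'], p)}",
        f"ks_pvalue_lilliefors\t{_sig(t['ks_pvalue_lilliefors'], p)}",
        f"ks_pvalue_plain\t{_sig(t['ks_pvalue_plain'], p)}",
        "test\tgene_id\tstatistic\tpvalue",
    ]
    for name in ("chi2_gc", "chi2_aa"):
        lines += [
            f"{name}\t{e['gene_id']}\t{_sig(e['statistic'], p)}\t{_sig(e['pvalue'], p)}"
            for e in t[name]
        ]
    e = doc["expected_rcdi"]
    lines += [
        "# expected RCDI",
        f"random_rcdi_mean\t{_sig(e['random_rcdi_mean'], p)}",
        f"random_rcdi_sd\t{_sig(e['random_rcdi_sd'], p)}",
        f"tolerance_factor\t{_sig(e['tolerance_factor'], p)}",
        f"ercdi\t{_sig(e['ercdi'], p)}",
    ]
    return "\n".join(lines) + "\n"
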