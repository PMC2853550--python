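# rcdi — Relative Codon Deoptimization Index and its expected value

Viral genes can be codon-*optimized* toward their host (fast replication) or
codon-*deoptimized* (attenuation, latency, vaccine design). The **Relative
Codon Deoptimization Index (RCDI)** quantifies this by comparing a gene's
synonymous codon usage with a reference genome's:

```
RCDI = Σ_i (CiFa_i / CiFh_i) · N_i / N
```

where, within each synonymous-codon family, `CiFa` is codon *i*'s relative
frequency in the test gene, `CiFh` its relative frequency in the reference,
`N_i` its count in the gene and `N` the total codon count. RCDI = 1 when the
gene's within-family usage matches the reference exactly; it grows with
deoptimization up to `1 / min CiFh` (for a human-like reference this maximum
is 17.64, reached by a gene made solely of TCG, the rarest serine codon at
frequency 0.0567).

A raw RCDI can be inflated by %G+C or amino-acid composition alone. The
**eRCDI** is a significance threshold: random coding sequences are generated
with the same amino-acid composition and overall %G+C as the queries
(i.i.d.-codon "poisson" or first-order amino-acid-chain "markov" generators),
each is scored with RCDI, and the eRCDI is the one-sided normal tolerance
limit `mean + k·SD` of that null distribution (k from the noncentral-*t*
quantile for a chosen confidence and coverage). Genes whose RCDI exceeds the
eRCDI are deoptimized beyond what composition alone explains. The package
also reports a Lilliefors-corrected KS normality test of the null and
per-sequence chi-square homogeneity tests, plus the companion indices CAI,
Wright's ENC and the expected-ENC curve from %G+C₃.

Audience: virologists and molecular evolution researchers analysing
host–virus codon adaptation, and protein-expression engineers choosing
deoptimization levels for gene design.

## Worked example

```python
import numpy as np
from rcdi import (CodingSequence, CodonUsageTable, CodonDeoptimizationModel,
                  ErcdiConfig)
from rcdi.genetic_code import CODONS

# human-like reference: serine's TCG at within-family frequency 0.0567
code_families_S = ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC")
values = {c: 100.0 for c in CODONS}
for c in code_families_S:
    values[c] = (10000 - 567) / 5
values["TCG"] = 567.0
reference = CodonUsageTable(values)

genes = [
    CodingSequence("worst", "TCG" * 150),                      # maximally deoptimized Ser usage
    CodingSequence("bland", "TCT" * 50 + "TCC" * 50 + "AGC" * 50),
]
model = CodonDeoptimizationModel(genes, reference, genetic_code=1)
res = model.fit(ercdi=ErcdiConfig(n_random=100, seed=3))
print(res.summary())
```

prints

```
Codon Deoptimization Analysis
============================================================
Genes: 2   genetic code: 1

gene_id  n_codons    rcdi  gc_percent  gc3_percent  deoptimized
  worst       150 17.6367     66.6667     100.0000         True
  bland       150  1.7668     55.5556      66.6667        False

eRCDI null (poisson, n=100, seed=3):
  random RCDI mean 2.2398  SD 0.2926
  tolerance factor k 2.6840 (confidence 0.95, coverage 0.99)
  eRCDI = 3.0251
  KS normality: D=0.0932, p(Lilliefors)=0.0344
```

`worst` hits the theoretical maximum 1/0.0567 = 17.64 and far exceeds the
eRCDI threshold 3.03, so its deoptimization cannot be explained by
composition; `bland` (RCDI 1.77) stays below the threshold — its usage is
within the range random sequences of the same %G+C and amino-acid makeup
reach. The same analysis is available from the shell:

```
rcdi ercdi --fasta genes.fa --codon-table usage.txt --n-random 500 --seed 3
```

(subcommands: `rcdi`, `ercdi`, `indices`, `random`).

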