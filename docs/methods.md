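# Methods

## The index

For a coding sequence read in frame from its first nucleotide, codons are
grouped into synonymous families under an NCBI genetic code. With `N_i` the
count of codon *i*, `N` the total counted codons, `CiFa_i` the codon's
relative frequency within its family in the test gene and `CiFh_i` the same
quantity in the reference codon-usage table,

    RCDI = Σ_i (CiFa_i / CiFh_i) · N_i / N .

`CiFa` is computed from the gene's own counts, per gene (not pooled across a
multi-gene input). Writing the family share `s_f = Σ_{i∈f} N_i / N`, the sum
decomposes as `Σ_f s_f Σ_{i∈f} CiFa_i² / CiFh_i`; since within each family
both frequency vectors sum to 1, Cauchy–Schwarz gives
`Σ CiFa²/CiFh ≥ (Σ CiFa)² / Σ CiFh = 1`, so RCDI ≥ 1 with equality iff
CiFa = CiFh in every counted family. The same inequality bounds RCDI above
by the inverse of the smallest reference frequency among codons present;
for a human-like reference the extreme is a pure-TCG gene,
RCDI = 1/0.0567 ≈ 17.64.

The per-codon report column is the product `(CiFa_i/CiFh_i)·N_i` (the
summand of the defining sum before division by N); summing it and dividing
by N reproduces the RCDI, a bookkeeping identity the tests assert.

Conventions (each an explicit, flagged choice):

- **Stop codons** are excluded from N and from family normalisation by
  default (`include_stops=True` restores them). Normalising synonymous
  frequencies over stops is biologically meaningless for a single-ORF gene.
- **Ambiguity codes** (N, R, Y, …) exclude the containing codon from
  counting; the excluded tally is reported. %G+C and %G+C₃ are computed over
  the *counted* codons only, so the GC columns and the index describe the
  same positions.
- **Frame-broken records** (length not a multiple of 3) are rejected with a
  reason, never silently truncated; `--trim-incomplete` opts into trimming
  trailing 1–2 nt with a logged note.
- A gene codon whose reference frequency is zero or undefined makes the
  index infinite/undefined and is an error naming the codon; `--pseudo-freq`
  substitutes a small user-chosen frequency instead.
- Internal stop codons are reported as a warning and the computation
  proceeds (they are simply not counted).
- Reports print at 4 decimal places (half-even); JSON keeps full precision
  and round-trips bit-for-bit.

## The eRCDI null

Composition alone moves the RCDI, so significance is judged against random
sequences matched to the query set's pooled amino-acid composition
(length-weighted, i.e. of the concatenated input; a per-gene-mean variant is
deliberately not the default) and pooled overall G+C fraction. The null is
summarised by the one-sided normal tolerance limit

    eRCDI = mean + k(n, confidence, coverage) · SD ,

with the sample SD on n−1 degrees of freedom and
`k = t⁻¹_{nct}(confidence; df=n−1, nc=z_coverage·√n) / √n` from the
noncentral-*t* quantile (Howe's approximation is a logged fallback only).
Defaults: n_random = 500 random sequences, confidence 0.95, coverage 0.99,
random-sequence length = rounded mean query length. With the defaults the
limit exceeds the 0.99 quantile of the null in 95% of repeated draws, a
calibration the test suite verifies by simulation. k → z_coverage as
n → ∞ at rate O(1/√n) (the gap is ≈ 3·10⁻³ at n = 10⁶ and ≈ 10⁻³ at 10⁷).

**Generation mechanism.** The generators act at the codon level — an
interpretation, since only the generators' names (Poisson/Markov) are fixed
by the method's lineage:

- *poisson*: each codon independent; the amino acid is drawn from the target
  composition, then a synonymous codon with probability ∝ `w^{g(c)}`, where
  `g(c)` counts G/C at the family's degenerate positions (positions at which
  the family's codons differ).
- *markov*: amino acids follow a first-order chain whose transition matrix
  is estimated from pooled bigram counts of the query amino-acid sequences
  (rows without observations fall back to the pooled composition); codons as
  above.

The single weight `w > 0` is shared by all families and solved by bisection
on log w (tolerance 1e-10 on the expected GC) so that the closed-form
expected G+C fraction equals the target; the expectation is monotone in w.
Targets outside the achievable interval `[min, max]` implied by the
composition raise an error reporting that interval; targets exactly on a
boundary degenerate to the minimal- or maximal-GC codon of each family. No
stop codons are ever emitted. All randomness flows through one seeded
numpy generator, so identical configuration gives bit-identical results.

**Statistical tests.** Normality of the null RCDI values is tested with a
one-sample KS statistic against a normal with the sample's own mean and SD;
because the parameters are estimated from the same data, the reported
p-value uses the Lilliefors correction (the uncorrected plain-KS p is also
reported for comparison with implementations that skip the correction).
Homogeneity of the query set is tested per sequence against the pooled set
(not pairwise): a df = 1 chi-square of G+C vs A+T position counts against
the pooled G+C fraction, and a chi-square of amino-acid counts against the
pooled composition with expected-count-< 1 categories pooled. Expectations
are formed as single ratios of integer totals, so identical inputs give a
statistic of exactly 0 and p = 1.

## Companion indices

- **CAI**: geometric mean over counted codons of `w_c` = reference frequency
  over family maximum, excluding stops and single-codon families from the
  exponent; reference-unused codons get `w = 0.5/family maximum` when
  pseudo-counting is on (default). CAI = 1 requires all-maximal codons,
  whereas RCDI = 1 requires *matched* usage — the two extremes differ, which
  a test demonstrates on constructed genes.
- **ENC** (Wright): per family with its amino acid observed n ≥ 2 times,
  homozygosity `F = (nΣp̂² − 1)/(n − 1)`; F averaged within degeneracy
  classes; `ENC = n₁ + Σ_classes (class size)/F̄`. A missing 3-fold class is
  imputed as the mean of the 2- and 4-fold averages; F ≤ 0 families (tiny
  samples) are unusable; the value is clipped at the number of sense codons
  (61). With no usable family in a required class the ENC is undefined (an
  error, not a guess).
- **Expected ENC**: `2 + s + 29/(s² + (1−s)²)` with `s` the G+C₃ fraction
  strictly inside (0,1); peaks at 60.5 at s = 0.5. Note the curve is not
  symmetric: the linear term makes `f(s) − f(1−s) = 2s − 1`.

## Synthetic data and what the tests show

No external data ship with the package. Fixtures are built
programmatically: a "human-like" reference (uniform families except serine,
where TCG takes the 0.0567 share that produces the documented 17.64
maximum), uniform and 3:1-biased tables, random genes drawn uniformly from
sense codons, and matched gene/reference pairs whose integer codon counts
realise the reference frequencies exactly. These exercise the algebra and
calibration of the method; they do not emulate real genomes' correlated
codon usage, dinucleotide constraints or gene-length distributions, so
passing tests certify the estimator and its null machinery, not any
biological claim about a particular virus–host pair. Reproducing published
large-scale survey correlations (thousands of downloaded viral sequences)
is out of scope.

Problem sizes used in the checks — 100–1000 random gene/reference pairs,
1000 generated sequences of ~300 codons plus single 10⁵-codon draws for
composition fidelity, 500 simulated samples for tolerance-limit coverage,
200 replicates for KS calibration — were chosen as the smallest sizes at
which the binomial/Monte-Carlo error bands are meaningfully narrower than
the tolerances being checked.

## Known limitations

- The Poisson/Markov naming follows the expected-value lineage of the
  method, but whether the original server's generators act on nucleotides
  or codons is not recoverable; the codon-level definition here is exact and
  testable but may differ from the historical server's output.
- The Markov chain's stationary distribution is the empirical bigram
  stationary, which can differ slightly from the pooled composition for
  short inputs.
- Lilliefors p-values come from the standard table interpolation and are
  accurate to roughly the table's resolution, not machine precision.
- eRCDI assumes the null RCDI distribution is near-normal (hence the KS
  check); for very short random sequences the distribution is visibly
  skewed and the tolerance limit is conservative on the high side.
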