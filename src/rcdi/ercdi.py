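"""Expected RCDI: a significance threshold from matched random sequences.

A gene's RCDI can be inflated by %G+C or amino-acid composition alone, with
no codon-preference signal. To separate the two, random coding sequences are
generated with the same amino-acid composition and overall %G+C as the query
set, the RCDI of each is computed against the same reference, and the eRCDI
is the one-sided normal tolerance limit mean + k*SD of that null
distribution: with the stated confidence the limit exceeds the stated
coverage fraction of random-sequence RCDI values. A query RCDI above the
eRCDI therefore indicates deoptimization beyond compositional bias.

Random sequences are built at the codon level. Amino acids are drawn either
i.i.d. from the pooled query composition ("poisson") or from a first-order
chain estimated from the query amino-acid sequences ("markov"). Within each
synonymous family the codon is drawn with probability proportional to
w**g(c), where g(c) counts G/C at the family's degenerate positions and the
single weight w > 0 is solved so the expected overall G+C fraction equals
the target. No stop codons are emitted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .core import (
    SynonymousFrequencyTable,
    count_codons,
    rcdi,
)
from .formats import CodingSequence
from .genetic_code import STOP, GeneticCode

logger = logging.getLogger(__name__)

_UNAMBIGUOUS = set("ACGT")


# ---------------------------------------------------------------------------
# Composition profile

@dataclass(frozen=True)
class CompositionProfile:
    """Amino-acid composition, GC target and mean length of a query set."""

    aa_freq: dict[str, float]
    gc_target: float
    mean_length_codons: int

    def __post_init__(self) -> None:
        total = sum(self.aa_freq.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"amino-acid frequencies sum to {total}, not 1")
        if not 0.0 < self.gc_target < 1.0:
            raise ValueError("gc_target must lie strictly in (0, 1)")
        if self.mean_length_codons < 1:
            raise ValueError("mean length must be >= 1 codon")


def composition_profile(
    seqs: list[CodingSequence], code: GeneticCode
) -> CompositionProfile:
    """Pool amino-acid composition and G+C over all counted codons.

    Pooling weights genes by length (the composition of the concatenated
    input), and the mean length is the rounded mean codon count per gene.
    """
    if not seqs:
        raise ValueError("composition profile needs at least one sequence")
    aa_counts: dict[str, int] = {}
    gc = positions = 0
    lengths: list[int] = []
    for seq in seqs:
        counted = count_codons(seq, code, include_stops=False)
        lengths.append(counted.total)
        for codon, k in counted.counts.items():
            aa = code.codon_to_aa[codon]
            aa_counts[aa] = aa_counts.get(aa, 0) + k
            gc += k * sum(b in "GC" for b in codon)
            positions += 3 * k
    total = sum(aa_counts.values())
    if total == 0:
        raise ValueError("no countable codons in input")
    return CompositionProfile(
        aa_freq={aa: c / total for aa, c in sorted(aa_counts.items())},
        gc_target=gc / positions,
        mean_length_codons=max(1, round(sum(lengths) / len(lengths))),
    )


# ---------------------------------------------------------------------------
# GC-weighted codon sampler

@dataclass(frozen=True)
class _Family:
    aa: str
    codons: tuple[str, ...]
    g: tuple[int, ...]  # G/C count at degenerate positions, per codon
    fixed_gc: int  # G/C count at positions shared by the whole family


def _family_structures(code: GeneticCode, aas: list[str]) -> list[_Family]:
    fams = []
    for aa in aas:
        if aa == STOP:
            raise ValueError("stop symbol cannot appear in an aa profile")
        codons = code.families.get(aa)
        if codons is None:
            raise ValueError(f"amino acid {aa!r} absent from genetic code")
        degenerate = [j for j in range(3) if len({c[j] for c in codons}) > 1]
        fixed = [j for j in range(3) if j not in degenerate]
        fams.append(
            _Family(
                aa=aa,
                codons=codons,
                g=tuple(sum(c[j] in "GC" for j in degenerate) for c in codons),
                fixed_gc=sum(codons[0][j] in "GC" for j in fixed),
            )
        )
    return fams


def _expected_gc(w: float, fams: list[_Family], p: np.ndarray) -> float:
    e = 0.0
    for pa, fam in zip(p, fams):
        wg = np.array([w**g for g in fam.g], dtype=float)
        e += pa * (fam.fixed_gc + float(np.dot(fam.g, wg) / wg.sum()))
    return e / 3.0


def achievable_gc_interval(
    profile: CompositionProfile, code: GeneticCode
) -> tuple[float, float]:
    """The [min, max] overall G+C fraction reachable by synonymous choice."""
    aas = [a for a, f in profile.aa_freq.items() if f > 0]
    fams = _family_structures(code, aas)
    p = np.array([profile.aa_freq[a] for a in aas])
    lo = sum(pa * (f.fixed_gc + min(f.g)) for pa, f in zip(p, fams)) / 3.0
    hi = sum(pa * (f.fixed_gc + max(f.g)) for pa, f in zip(p, fams)) / 3.0
    return lo, hi


def gc_weight_solve(
    profile: CompositionProfile, code: GeneticCode, tol: float = 1e-10
) -> float:
    """Solve for the G/C weight w with E[GC fraction](w) = gc_target.

    The expectation is computed in closed form from the profile and the
    per-family codon structure; E is strictly increasing in w, so a bisection
    on log w converges to *tol* on the expected GC. Returns ``0.0`` or
    ``math.inf`` when the target sits exactly on the achievable boundary
    (degenerate sampler: minimal- or maximal-GC codons only); raises when the
    target is outside the achievable interval, reporting that interval.
    """
    aas = [a for a, f in profile.aa_freq.items() if f > 0]
    fams = _family_structures(code, aas)
    p = np.array([profile.aa_freq[a] for a in aas])
    lo, hi = achievable_gc_interval(profile, code)
    target = profile.gc_target
    if target < lo - 1e-9 or target > hi + 1e-9:
        raise ValueError(
            f"gc_target {target:.4f} unreachable; achievable interval "
            f"[{lo:.4f}, {hi:.4f}] for this amino-acid composition"
        )
    if hi - lo <= 1e-12:  # no synonymous GC freedom at all
        return 1.0
    if target <= lo + 1e-12:
        return 0.0
    if target >= hi - 1e-12:
        return math.inf

    t_lo, t_hi = -50.0, 50.0
    while _expected_gc(math.exp(t_lo), fams, p) > target:
        t_lo -= 50.0
    while _expected_gc(math.exp(t_hi), fams, p) < target:
        t_hi += 50.0
    for _ in range(200):
        t = 0.5 * (t_lo + t_hi)
        e = _expected_gc(math.exp(t), fams, p)
        if abs(e - target) <= tol:
            break
        if e < target:
            t_lo = t
        else:
            t_hi = t
    return math.exp(t)


def markov_transition(
    seqs: list[CodingSequence], code: GeneticCode
) -> tuple[list[str], np.ndarray]:
    """First-order amino-acid transition matrix from the query sequences.

    Bigram counts are pooled over all sequences (pairs spanning a skipped
    stop/ambiguous codon are not counted); rows with no observations fall
    back to the pooled stationary composition.
    """
    profile = composition_profile(seqs, code)
    aas = sorted(a for a, f in profile.aa_freq.items() if f > 0)
    idx = {a: i for i, a in enumerate(aas)}
    k = len(aas)
    counts = np.zeros((k, k))
    for seq in seqs:
        prev: int | None = None
        for codon in seq.codons:
            if not set(codon) <= _UNAMBIGUOUS or code.codon_to_aa[codon] == STOP:
                prev = None
                continue
            cur = idx[code.codon_to_aa[codon]]
            if prev is not None:
                counts[prev, cur] += 1
            prev = cur
    pi = np.array([profile.aa_freq[a] for a in aas])
    trans = np.empty_like(counts)
    for i in range(k):
        row_total = counts[i].sum()
        trans[i] = counts[i] / row_total if row_total > 0 else pi
    return aas, trans


class RandomCdsGenerator:
    """Generate random coding sequences matched to a composition profile.

    ``method="poisson"`` draws amino acids i.i.d.; ``method="markov"`` walks
    a first-order amino-acid chain (supply ``transition`` from
    :func:`markov_transition`, else the chain degenerates to i.i.d.). Codons
    within a family follow the w**g weighting with w solved once at
    construction.
    """

    def __init__(
        self,
        profile: CompositionProfile,
        code: GeneticCode,
        method: str = "poisson",
        transition: tuple[list[str], np.ndarray] | None = None,
    ) -> None:
        if method not in ("poisson", "markov"):
            raise ValueError(f"unknown generation method {method!r}")
        self.profile = profile
        self.code = code
        self.method = method
        self.aas = [a for a, f in profile.aa_freq.items() if f > 0]
        self.p = np.array([profile.aa_freq[a] for a in self.aas])
        self.p = self.p / self.p.sum()
        fams = _family_structures(code, self.aas)
        self.w = gc_weight_solve(profile, code)
        self._codons: list[np.ndarray] = []
        self._codon_p: list[np.ndarray] = []
        for fam in fams:
            g = np.array(fam.g, dtype=float)
            if self.w == 0.0:
                probs = (g == g.min()).astype(float)
            elif math.isinf(self.w):
                probs = (g == g.max()).astype(float)
            else:
                logw = math.log(self.w)
                probs = np.exp(g * logw - g.max() * logw)
            self._codons.append(np.array(fam.codons))
            self._codon_p.append(probs / probs.sum())
        if method == "markov":
            if transition is None:
                self._trans = np.tile(self.p, (len(self.aas), 1))
            else:
                t_aas, t_mat = transition
                if t_aas != self.aas:
                    raise ValueError(
                        "transition matrix states do not match profile amino acids"
                    )
                self._trans = np.asarray(t_mat, dtype=float)

    def generate(
        self,
        rng: np.random.Generator,
        length: int | None = None,
        seq_id: str = "random",
    ) -> CodingSequence:
        L = length or self.profile.mean_length_codons
        k = len(self.aas)
        if self.method == "poisson":
            aa_idx = rng.choice(k, size=L, p=self.p)
        else:
            cum = np.cumsum(self._trans, axis=1)
            aa_idx = np.empty(L, dtype=int)
            aa_idx[0] = rng.choice(k, p=self.p)
            u = rng.random(L)
            for i in range(1, L):
                aa_idx[i] = np.searchsorted(cum[aa_idx[i - 1]], u[i])
        codons = np.empty(L, dtype=object)
        for j in range(k):
            pos = np.nonzero(aa_idx == j)[0]
            if pos.size:
                codons[pos] = rng.choice(
                    self._codons[j], size=pos.size, p=self._codon_p[j]
                )
        return CodingSequence(seq_id, "".join(codons))


def generate_random_cds(
    profile: CompositionProfile,
    code: GeneticCode,
    rng: np.random.Generator,
    method: str = "poisson",
    length: int | None = None,
    transition: tuple[list[str], np.ndarray] | None = None,
    seq_id: str = "random",
) -> CodingSequence:
    gen = RandomCdsGenerator(profile, code, method=method, transition=transition)
    return gen.generate(rng, length=length, seq_id=seq_id)


# ---------------------------------------------------------------------------
# Tolerance limit and statistical tests

def tolerance_factor(n: int, confidence: float, coverage: float) -> float:
    """One-sided normal tolerance factor k.

    mean + k*SD of a normal sample of size *n* exceeds the *coverage*
    quantile of the population with probability *confidence*. Exact value via
    the noncentral-t quantile, k = t^{-1}(confidence; df=n-1,
    nc=z_coverage*sqrt(n)) / sqrt(n); Howe's approximation is used (and
    logged) only if the noncentral quantile fails to evaluate.
    """
    if n < 2:
        raise ValueError("tolerance factor needs n >= 2")
    if not (0.0 < confidence < 1.0 and 0.0 < coverage < 1.0):
        raise ValueError("confidence and coverage must lie in (0, 1)")
    z_p = stats.norm.ppf(coverage)
    k = stats.nct.ppf(confidence, n - 1, z_p * math.sqrt(n)) / math.sqrt(n)
    if not math.isfinite(k):
        z_c = stats.norm.ppf(confidence)
        a = 1.0 - z_c**2 / (2.0 * (n - 1))
        b = z_p**2 - z_c**2 / n
        k = (z_p + math.sqrt(max(z_p**2 - a * b, 0.0))) / a
        logger.warning(
            "noncentral-t quantile unavailable (n=%d); using Howe approximation", n
        )
    return float(k)


@dataclass(frozen=True)
class KsNormalityResult:
    statistic: float
    pvalue: float  # Lilliefors-corrected (parameters estimated from data)
    pvalue_plain: float  # uncorrected one-sample KS p, for parity
    method: str = "lilliefors"


def ks_normality(values) -> KsNormalityResult:
    """Kolmogorov-Smirnov test of normality with estimated parameters.

    The null parameters are the sample mean and SD, so the reported p-value
    uses the Lilliefors correction; the uncorrected (badly conservative)
    plain-KS p is also reported.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise ValueError(
            "KS normality test needs >= 8 values; increase n_random"
        )
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate sample: zero standard deviation")
    stat, p_lillie = lilliefors(x, dist="norm", pvalmethod="table")
    _, p_plain = stats.kstest(x, "norm", args=(x.mean(), sd))
    return KsNormalityResult(
        statistic=float(stat), pvalue=float(p_lillie), pvalue_plain=float(p_plain)
    )


def _chi2(observed: list[float], expected: list[float]) -> tuple[float, float]:
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = max(len(obs) - 1, 1)
    return stat, float(stats.chi2.sf(stat, df))


def chi2_homogeneity(
    seqs: list[CodingSequence], code: GeneticCode
) -> tuple[list[tuple[str, float, float]], list[tuple[str, float, float]]]:
    """Chi-square goodness-of-fit of each sequence against the pooled set.

    Returns ``(gc_tests, aa_tests)``, each a per-sequence list of
    ``(gene_id, statistic, pvalue)``. The GC test compares a sequence's
    G+C vs A+T position counts with those expected under the pooled G+C
    fraction (df = 1); the amino-acid test compares its amino-acid counts
    with expectations under the pooled composition, pooling categories with
    expected count < 1.
    """
    if len(seqs) < 2:
        raise ValueError("homogeneity test needs at least 2 sequences")
    per_seq = []
    pooled_aa: dict[str, int] = {}
    pooled_gc = pooled_pos = 0
    for seq in seqs:
        counted = count_codons(seq, code, include_stops=False)
        aa_counts: dict[str, int] = {}
        gc = 0
        for codon, k in counted.counts.items():
            aa = code.codon_to_aa[codon]
            aa_counts[aa] = aa_counts.get(aa, 0) + k
            gc += k * sum(b in "GC" for b in codon)
        per_seq.append((seq.id, aa_counts, counted.total, gc))
        for aa, k in aa_counts.items():
            pooled_aa[aa] = pooled_aa.get(aa, 0) + k
        pooled_gc += gc
        pooled_pos += 3 * counted.total
    pooled_total = sum(pooled_aa.values())
    aas = sorted(pooled_aa)

    gc_tests: list[tuple[str, float, float]] = []
    aa_tests: list[tuple[str, float, float]] = []
    for gene_id, aa_counts, n_i, gc_i in per_seq:
        pos_i = 3 * n_i
        # integer-ratio expectations keep identical inputs at exactly 0
        e_gc = pooled_gc * pos_i / pooled_pos
        gc_tests.append(
            (gene_id, *_chi2([gc_i, pos_i - gc_i], [e_gc, pos_i - e_gc]))
        )
        obs = [float(aa_counts.get(a, 0)) for a in aas]
        exp = [pooled_aa[a] * n_i / pooled_total for a in aas]
        keep_o, keep_e, pool_o, pool_e = [], [], 0.0, 0.0
        for o, e in zip(obs, exp):
            if e >= 1.0:
                keep_o.append(o)
                keep_e.append(e)
            else:
                pool_o += o
                pool_e += e
        if pool_e > 0:
            keep_o.append(pool_o)
            keep_e.append(pool_e)
        if len(keep_o) < 2:
            aa_tests.append((gene_id, 0.0, 1.0))
        else:
            aa_tests.append((gene_id, *_chi2(keep_o, keep_e)))
    return gc_tests, aa_tests


# ---------------------------------------------------------------------------
# eRCDI driver

@dataclass(frozen=True)
class ErcdiConfig:
    """Parameters of the eRCDI null: sample size, generator, tolerance levels."""

    n_random: int = 500
    method: str = "poisson"  # "poisson" | "markov"
    confidence: float = 0.95
    coverage: float = 0.99
    seed: int = 0
    length_codons: int | None = None  # None -> mean length of the inputs

    def __post_init__(self) -> None:
        if self.n_random < 2:
            raise ValueError("n_random must be >= 2")
        if self.method not in ("poisson", "markov"):
            raise ValueError(f"unknown generation method {self.method!r}")
        for name in ("confidence", "coverage"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")

    @classmethod
    def from_file(cls, path: str) -> "ErcdiConfig":
        """Load a config from JSON or ``key=value`` lines.

        Recognised keys: n_random, method, confidence, coverage, seed,
        length_codons (``mean_of_inputs`` or an integer)."""
        import json

        with open(path) as fh:
            text = fh.read()
        try:
            raw = json.loads(text)
        except json.JSONDecodeError:
            raw = {}
            for line in text.splitlines():
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"bad config line: {line!r}")
                key, value = (p.strip() for p in line.split("=", 1))
                raw[key] = value
        kwargs: dict = {}
        casts = {
            "n_random": int,
            "method": str,
            "confidence": float,
            "coverage": float,
            "seed": int,
            "length_codons": lambda v: None if v in (None, "mean_of_inputs") else int(v),
        }
        for key, value in raw.items():
            if key not in casts:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = casts[key](value)
        return cls(**kwargs)


@dataclass(frozen=True)
class ErcdiResult:
    """Null RCDI distribution summary and the eRCDI tolerance limit."""

    random_rcdi_mean: float
    random_rcdi_sd: float
    ercdi: float
    tolerance_factor: float
    ks_statistic: float
    ks_pvalue: float
    ks_pvalue_plain: float
    chi2_gc: list[tuple[str, float, float]]
    chi2_aa: list[tuple[str, float, float]]
    n_random: int
    profile: CompositionProfile
    confidence: float
    coverage: float
    method: str
    seed: int
    random_rcdi_values: tuple[float, ...] = field(repr=False, default=())
    warnings: tuple[str, ...] = ()


def expected_rcdi(
    seqs: list[CodingSequence],
    reference: SynonymousFrequencyTable,
    code: GeneticCode,
    config: ErcdiConfig = ErcdiConfig(),
    pseudo_freq: float | None = None,
) -> ErcdiResult:
    """Compute the eRCDI of a query set.

    Builds the pooled composition profile, generates ``config.n_random``
    matched random sequences, scores each with RCDI against *reference*, and
    returns mean + k*SD with k from :func:`tolerance_factor`, plus the KS
    normality test on the null values and per-sequence chi-square
    homogeneity tests on the inputs. Fully reproducible for a fixed seed.
    """
    profile = composition_profile(seqs, code)
    transition = (
        markov_transition(seqs, code) if config.method == "markov" else None
    )
    gen = RandomCdsGenerator(
        profile, code, method=config.method, transition=transition
    )
    rng = np.random.default_rng(config.seed)
    length = config.length_codons or profile.mean_length_codons
    values = np.array(
        [
            rcdi(
                gen.generate(rng, length=length, seq_id=f"random_{i}"),
                reference,
                code,
                pseudo_freq=pseudo_freq,
            ).rcdi
            for i in range(config.n_random)
        ]
    )
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    k = tolerance_factor(config.n_random, config.confidence, config.coverage)

    warnings: list[str] = []
    try:
        ks = ks_normality(values)
        ks_stat, ks_p, ks_plain = ks.statistic, ks.pvalue, ks.pvalue_plain
    except ValueError as exc:
        warnings.append(f"KS normality test skipped: {exc}")
        ks_stat = ks_p = ks_plain = math.nan
    if len(seqs) >= 2:
        chi2_gc, chi2_aa = chi2_homogeneity(seqs, code)
    else:
        chi2_gc, chi2_aa = [], []
        warnings.append("homogeneity test skipped: single input sequence")

    return ErcdiResult(
        random_rcdi_mean=mean,
        random_rcdi_sd=sd,
        ercdi=mean + k * sd,
        tolerance_factor=k,
        ks_statistic=ks_stat,
        ks_pvalue=ks_p,
        ks_pvalue_plain=ks_plain,
        chi2_gc=chi2_gc,
        chi2_aa=chi2_aa,
        n_random=config.n_random,
        profile=profile,
        confidence=config.confidence,
        coverage=config.coverage,
        method=config.method,
        seed=config.seed,
        random_rcdi_values=tuple(float(v) for v in values),
        warnings=tuple(warnings),
    )
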