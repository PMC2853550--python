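import math

import numpy as np
import pytest
from scipy import stats

from rcdi import (
    CodingSequence,
    CompositionProfile,
    ErcdiConfig,
    RandomCdsGenerator,
    achievable_gc_interval,
    chi2_homogeneity,
    composition_profile,
    expected_rcdi,
    gc_weight_solve,
    ks_normality,
    markov_transition,
    tolerance_factor,
)

from conftest import random_gene


class TestCompositionProfile:
    def test_single_aa_gene(self, code1):
        p = composition_profile([CodingSequence("g", "ATG" * 10)], code1)
        assert p.aa_freq == {"M": 1.0}
        assert p.mean_length_codons == 10
        assert p.gc_target == pytest.approx(1 / 3)

    def test_mean_length_is_arithmetic_mean(self, code1):
        seqs = [
            CodingSequence("a", "ATG" * 9),
            CodingSequence("b", "ATG" * 15),
        ]
        assert composition_profile(seqs, code1).mean_length_codons == 12

    def test_gc_pooled_across_genes(self, code1):
        seqs = [
            CodingSequence("a", "GGG" * 10),
            CodingSequence("b", "AAA" * 10),
        ]
        assert composition_profile(seqs, code1).gc_target == pytest.approx(0.5)

    def test_empty_input_errors(self, code1):
        with pytest.raises(ValueError):
            composition_profile([], code1)


class TestGcWeightSolve:
    def test_identity_when_target_is_unweighted_expectation(self, code1):
        # Phe (TTT/TTC): at w=1 the expected GC fraction is (0 + 1/2)/3
        profile = CompositionProfile({"F": 1.0}, (0 + 0.5) / 3, 50)
        assert gc_weight_solve(profile, code1) == pytest.approx(1.0, abs=1e-4)

    def test_monotone_in_target(self, code1):
        profile = {"K": 0.5, "F": 0.5}
        ws = [
            gc_weight_solve(CompositionProfile(profile, t, 50), code1)
            for t in (0.10, 0.15, 0.20, 0.25)
        ]
        assert all(a < b for a, b in zip(ws, ws[1:]))

    def test_two_fold_family_closed_form(self, code1):
        # Lys (AAA/AAG): E[GC](w) = w / (3 (1 + w)); target 0.2 -> w = 1.5
        profile = CompositionProfile({"K": 1.0}, 0.2, 50)
        assert gc_weight_solve(profile, code1) == pytest.approx(1.5, abs=1e-6)

    def test_unreachable_target_reports_interval(self, code1):
        with pytest.raises(ValueError, match="achievable interval"):
            gc_weight_solve(CompositionProfile({"K": 1.0}, 0.9, 50), code1)

    def test_achievable_interval_lys(self, code1):
        lo, hi = achievable_gc_interval(CompositionProfile({"K": 1.0}, 0.2, 50), code1)
        assert (lo, hi) == (0.0, pytest.approx(1 / 3))


class TestGenerator:
    def test_no_degeneracy_forces_sequence(self, code1):
        profile = CompositionProfile({"M": 1.0}, 1 / 3, 7)
        gen = RandomCdsGenerator(profile, code1)
        seq = gen.generate(np.random.default_rng(0))
        assert seq.nucleotides == "ATG" * 7

    def test_boundary_target_takes_extreme_codons(self, code1):
        profile = CompositionProfile({"F": 1.0}, 1 / 3, 30)  # max achievable
        gen = RandomCdsGenerator(profile, code1)
        seq = gen.generate(np.random.default_rng(0))
        assert seq.nucleotides == "TTC" * 30

    def test_no_stop_codons_and_aa_composition_converges(self, code1, sense_codons):
        rng = np.random.default_rng(5)
        seqs = [random_gene(rng, sense_codons, 400, f"g{i}") for i in range(3)]
        profile = composition_profile(seqs, code1)
        gen = RandomCdsGenerator(profile, code1)
        out = gen.generate(np.random.default_rng(1), length=20000)
        codons = out.codons
        assert all(code1.codon_to_aa[c] != "*" for c in codons)
        obs = {}
        for c in codons:
            aa = code1.codon_to_aa[c]
            obs[aa] = obs.get(aa, 0) + 1
        tv = 0.5 * sum(
            abs(obs.get(aa, 0) / len(codons) - f)
            for aa, f in profile.aa_freq.items()
        )
        assert tv < 0.05

    def test_mean_gc_matches_target(self, code1, sense_codons):
        rng = np.random.default_rng(8)
        seqs = [random_gene(rng, sense_codons, 300, f"g{i}") for i in range(2)]
        profile = composition_profile(seqs, code1)
        gen = RandomCdsGenerator(profile, code1)
        g = np.random.default_rng(2)
        fracs = []
        for _ in range(300):
            s = gen.generate(g, length=300).nucleotides
            fracs.append((s.count("G") + s.count("C")) / len(s))
        fracs = np.array(fracs)
        se = fracs.std(ddof=1) / math.sqrt(fracs.size)
        assert abs(fracs.mean() - profile.gc_target) < 3 * se

    def test_markov_transition_rows_are_distributions(self, code1, sense_codons):
        rng = np.random.default_rng(3)
        seqs = [random_gene(rng, sense_codons, 200, f"g{i}") for i in range(2)]
        aas, trans = markov_transition(seqs, code1)
        assert trans.shape == (len(aas), len(aas))
        np.testing.assert_allclose(trans.sum(axis=1), 1.0, atol=1e-12)

    def test_markov_generation_matches_composition(self, code1, sense_codons):
        rng = np.random.default_rng(9)
        seqs = [random_gene(rng, sense_codons, 500, f"g{i}") for i in range(2)]
        profile = composition_profile(seqs, code1)
        gen = RandomCdsGenerator(
            profile, code1, method="markov",
            transition=markov_transition(seqs, code1),
        )
        out = gen.generate(np.random.default_rng(4), length=20000)
        obs = {}
        for c in out.codons:
            aa = code1.codon_to_aa[c]
            obs[aa] = obs.get(aa, 0) + 1
        tv = 0.5 * sum(
            abs(obs.get(aa, 0) / 20000 - f) for aa, f in profile.aa_freq.items()
        )
        assert tv < 0.05


class TestToleranceFactor:
    def test_approaches_coverage_quantile_from_above(self):
        z99 = stats.norm.ppf(0.99)
        ks = [tolerance_factor(n, 0.95, 0.99) for n in (50, 500, 5000, 10**6)]
        assert all(a > b for a, b in zip(ks, ks[1:]))
        assert all(k > z99 for k in ks)
        assert ks[-1] == pytest.approx(z99, abs=5e-3)

    def test_symmetric_case_is_zero(self):
        for n in (2, 10, 50):
            assert tolerance_factor(n, 0.5, 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_monte_carlo_coverage_calibration(self):
        k = tolerance_factor(50, 0.95, 0.99)
        rng = np.random.default_rng(12)
        x = rng.normal(size=(3000, 50))
        limits = x.mean(axis=1) + k * x.std(axis=1, ddof=1)
        frac = (limits > stats.norm.ppf(0.99)).mean()
        assert abs(frac - 0.95) < 0.02

    @pytest.mark.parametrize("conf,cov", [(0.0, 0.99), (0.95, 1.0), (-1, 0.5)])
    def test_invalid_probabilities(self, conf, cov):
        with pytest.raises(ValueError):
            tolerance_factor(50, conf, cov)

    def test_needs_two_observations(self):
        with pytest.raises(ValueError):
            tolerance_factor(1, 0.95, 0.99)


class TestKsNormality:
    def test_too_few_values(self):
        with pytest.raises(ValueError, match="8"):
            ks_normality([1.0] * 7)

    def test_constant_vector_degenerate(self):
        with pytest.raises(ValueError, match="zero standard deviation"):
            ks_normality([2.0] * 50)

    def test_power_against_exponential(self):
        rng = np.random.default_rng(7)
        rejections = sum(
            ks_normality(rng.exponential(size=500)).pvalue < 0.05
            for _ in range(30)
        )
        assert rejections >= 29

    def test_plain_ks_p_is_more_conservative(self):
        rng = np.random.default_rng(1)
        res = ks_normality(rng.normal(size=500))
        assert res.pvalue_plain >= res.pvalue - 1e-12
        assert res.method == "lilliefors"


class TestChi2Homogeneity:
    def test_identical_sequences_exact_zero(self, code1):
        seqs = [CodingSequence(f"g{i}", "ATGTCGAAACTT" * 10) for i in range(4)]
        gc_tests, aa_tests = chi2_homogeneity(seqs, code1)
        for _, stat, p in gc_tests + aa_tests:
            assert stat == 0.0
            assert p == 1.0

    def test_single_sequence_errors(self, code1):
        with pytest.raises(ValueError, match="2 sequences"):
            chi2_homogeneity([CodingSequence("g", "ATGTCG")], code1)

    def test_gc_outlier_detected(self, code1):
        seqs = [CodingSequence(f"a{i}", "AAATTTAAA" * 30) for i in range(3)]
        seqs.append(CodingSequence("rich", "GGGCCCGGG" * 30))
        gc_tests, _ = chi2_homogeneity(seqs, code1)
        by_id = {g: p for g, _, p in gc_tests}
        assert by_id["rich"] < 0.01

    def test_type_one_error_calibration(self, code1, sense_codons):
        rng = np.random.default_rng(21)
        seqs = [random_gene(rng, sense_codons, 400, f"g{i}") for i in range(2)]
        profile = composition_profile(seqs, code1)
        gen = RandomCdsGenerator(profile, code1)
        g = np.random.default_rng(22)
        pvals = []
        for _ in range(100):
            batch = [gen.generate(g, length=300, seq_id=f"s{j}") for j in range(3)]
            gc_tests, _ = chi2_homogeneity(batch, code1)
            pvals.extend(p for _, _, p in gc_tests)
        rate = np.mean(np.asarray(pvals) < 0.05)
        assert 0.01 < rate < 0.10


@pytest.fixture(scope="module")
def query(code1, sense_codons):
    rng = np.random.default_rng(30)
    return [random_gene(rng, sense_codons, 250, f"g{i}") for i in range(3)]


class TestExpectedRcdi:
    def test_seeded_determinism_bitwise(self, query, human_like_ref, code1):
        cfg = ErcdiConfig(n_random=60, seed=123)
        a = expected_rcdi(query, human_like_ref, code1, cfg)
        b = expected_rcdi(query, human_like_ref, code1, cfg)
        assert a == b
        assert a.random_rcdi_values == b.random_rcdi_values

    def test_limit_assembly_matches_independent_noncentral_t(
        self, query, human_like_ref, code1
    ):
        cfg = ErcdiConfig(n_random=200, seed=5)
        res = expected_rcdi(query, human_like_ref, code1, cfg)
        vals = np.array(res.random_rcdi_values)
        n = vals.size
        k = stats.nct.ppf(0.95, n - 1, stats.norm.ppf(0.99) * math.sqrt(n)) / math.sqrt(n)
        assert res.ercdi == pytest.approx(
            vals.mean() + k * vals.std(ddof=1), abs=1e-12
        )
        assert res.ercdi > res.random_rcdi_mean

    def test_median_tolerance_is_the_mean(self, query, human_like_ref, code1):
        cfg = ErcdiConfig(n_random=60, seed=9, confidence=0.5, coverage=0.5)
        res = expected_rcdi(query, human_like_ref, code1, cfg)
        assert res.ercdi == pytest.approx(res.random_rcdi_mean, abs=1e-12)

    def test_strictly_increasing_in_confidence_and_coverage(
        self, query, human_like_ref, code1
    ):
        base = dict(n_random=60, seed=9)
        e = lambda conf, cov: expected_rcdi(
            query, human_like_ref, code1,
            ErcdiConfig(confidence=conf, coverage=cov, **base),
        ).ercdi
        assert e(0.95, 0.90) < e(0.95, 0.99)
        assert e(0.90, 0.99) < e(0.99, 0.99)

    def test_config_from_file_both_dialects(self, tmp_path):
        kv = tmp_path / "cfg.txt"
        kv.write_text(
            "n_random = 40\nmethod = markov\nconfidence = 0.9\n"
            "coverage = 0.95\nseed = 5\nlength_codons = mean_of_inputs\n"
        )
        js = tmp_path / "cfg.json"
        js.write_text(
            '{"n_random": 40, "method": "markov", "confidence": 0.9,'
            ' "coverage": 0.95, "seed": 5, "length_codons": null}'
        )
        assert ErcdiConfig.from_file(str(kv)) == ErcdiConfig.from_file(str(js))
        assert ErcdiConfig.from_file(str(kv)).n_random == 40
        bad = tmp_path / "bad.txt"
        bad.write_text("n_random = 40\nbogus = 1\n")
        with pytest.raises(ValueError, match="unknown config key"):
            ErcdiConfig.from_file(str(bad))

    def test_stub_normal_sample_recovers_tolerance_limit(self):
        rng = np.random.default_rng(77)
        vals = rng.normal(2.0, 0.1, size=500)
        k = tolerance_factor(500, 0.95, 0.99)
        limit = vals.mean() + k * vals.std(ddof=1)
        assert limit == pytest.approx(2.0 + k * 0.1, abs=0.02)
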