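import numpy as np
import pytest

from conftest import exact_counts
from ffsig.oracle import Scenario, ScenarioKind
from ffsig.panel import SnpLocus, Subtype, build_panel
from ffsig.signature import (
    AlleleCountTable,
    FFEstimate,
    allele_frequencies,
    compute_signature,
    estimate_background,
    estimate_ff_type1,
    estimate_ff_type3,
    estimate_ff_type4,
    estimate_ff_y,
)
from ffsig.simulate import SimConfig, simulate_case, simulate_counts
from ffsig.oracle import contributors_for_scenario, mother_only_contributors


class TestAlleleFrequencies:
    def test_simple(self):
        assert allele_frequencies({"A": 90, "G": 10}) == {"A": 0.9, "G": 0.1}

    def test_single_allele(self):
        assert allele_frequencies({"A": 100}) == {"A": 1.0}

    def test_four_alleles(self):
        freqs = allele_frequencies({"A": 475, "G": 25, "C": 0, "T": 0})
        assert freqs["A"] == pytest.approx(0.95)
        assert freqs["G"] == pytest.approx(0.05)
        assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_zero_depth_raises(self):
        with pytest.raises(ZeroDivisionError):
            allele_frequencies({"A": 0, "G": 0})

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            allele_frequencies({"A": -1, "G": 2})


class TestCountTable:
    def test_validation(self):
        with pytest.raises(ValueError):
            AlleleCountTable({"s": [1, 2, 3]})
        with pytest.raises(ValueError):
            AlleleCountTable({"s": [1, 2, 3, -4]})

    def test_depth_and_freqs(self):
        t = AlleleCountTable({"s": [95, 0, 5, 0]})
        assert t.depth("s") == 100
        assert t.frequencies("s")[0] == pytest.approx(0.95)


class TestType1:
    def test_single_snp_freq_005_gives_ff_010(self):
        panel = build_panel([SnpLocus("s", "X", 1, ("A", "A"), ("G", "G"))])
        counts = AlleleCountTable({"s": [95, 0, 5, 0]})
        est = estimate_ff_type1(counts, panel)
        assert est.value == pytest.approx(0.10)
        assert est.n_snps == 1

    def test_zero_paternal_frequency_gives_zero(self):
        panel = build_panel([SnpLocus("s", "X", 1, ("A", "A"), ("G", "G"))])
        counts = AlleleCountTable({"s": [100, 0, 0, 0]})
        assert estimate_ff_type1(counts, panel).value == 0.0

    def test_trisomy_oracle_value(self, mini_panel):
        # maternal MI trisomy at f=0.10: FF1 = 2*0.05/1.05
        scenario = Scenario(ScenarioKind.TRI_MAT_MEI1, 0.10)
        counts = exact_counts(mini_panel, scenario)
        est = estimate_ff_type1(counts, mini_panel)
        assert est.value == pytest.approx(0.095238, abs=1e-6)

    def test_no_usable_snps_flagged(self, mini_panel):
        counts = AlleleCountTable(
            {l.snp_id: [0, 0, 0, 0] for l in mini_panel}
        )
        est = estimate_ff_type1(counts, mini_panel)
        assert not est.available
        assert est.n_snps == 0


class TestType3:
    def test_transmitted_and_silent_subtypes(self, mini_panel):
        scenario = Scenario(ScenarioKind.NORMAL, 0.10)  # P1 transmitted
        counts = exact_counts(mini_panel, scenario)
        p1 = estimate_ff_type3(counts, mini_panel, Subtype.T3_P1)
        p2 = estimate_ff_type3(counts, mini_panel, Subtype.T3_P2)
        assert p1.value == pytest.approx(0.10, abs=1e-9)
        assert p2.value == pytest.approx(0.0, abs=1e-9)

    def test_paternal_heterodisomy_both_subtypes_half_t1(self, mini_panel):
        scenario = Scenario(ScenarioKind.UPD_PAT_HETERO, 0.10)
        counts = exact_counts(mini_panel, scenario)
        t1 = estimate_ff_type1(counts, mini_panel)
        p1 = estimate_ff_type3(counts, mini_panel, Subtype.T3_P1)
        p2 = estimate_ff_type3(counts, mini_panel, Subtype.T3_P2)
        assert t1.value == pytest.approx(0.20, abs=1e-9)
        assert p1.value == pytest.approx(0.10, abs=1e-9)
        assert p2.value == pytest.approx(0.10, abs=1e-9)

    def test_wrong_subtype_rejected(self, mini_panel):
        counts = exact_counts(mini_panel, Scenario(ScenarioKind.NORMAL, 0.1))
        with pytest.raises(ValueError):
            estimate_ff_type3(counts, mini_panel, Subtype.T4_ALPHA)


class TestType4:
    def test_normal_m1_transmitted(self, mini_panel):
        counts = exact_counts(mini_panel, Scenario(ScenarioKind.NORMAL, 0.10))
        alpha = estimate_ff_type4(counts, mini_panel, Subtype.T4_ALPHA)
        beta = estimate_ff_type4(counts, mini_panel, Subtype.T4_BETA)
        assert alpha.value == pytest.approx(0.10, abs=1e-9)
        assert beta.value == pytest.approx(0.0, abs=1e-9)

    def test_normal_m2_transmitted_negates_beta(self, mini_panel):
        counts = exact_counts(
            mini_panel,
            Scenario(ScenarioKind.NORMAL, 0.10, transmitted_maternal="M2"),
        )
        alpha = estimate_ff_type4(counts, mini_panel, Subtype.T4_ALPHA)
        beta = estimate_ff_type4(counts, mini_panel, Subtype.T4_BETA)
        assert alpha.value == pytest.approx(0.0, abs=1e-9)
        assert beta.value == pytest.approx(-0.10, abs=1e-9)

    def test_trisomy_symmetric_half_values(self, mini_panel):
        counts = exact_counts(
            mini_panel, Scenario(ScenarioKind.TRI_MAT_MEI1, 0.10)
        )
        alpha = estimate_ff_type4(counts, mini_panel, Subtype.T4_ALPHA)
        beta = estimate_ff_type4(counts, mini_panel, Subtype.T4_BETA)
        assert alpha.value == pytest.approx(0.047619, abs=1e-6)
        assert beta.value == pytest.approx(-0.047619, abs=1e-6)


class TestBackground:
    def test_error_free_is_zero(self, mini_panel):
        counts = exact_counts(mini_panel, Scenario(ScenarioKind.NORMAL, 0.1))
        assert estimate_background(counts, mini_panel).value == 0.0

    def test_constant_second_allele(self):
        panel = build_panel(
            [
                SnpLocus(f"s{i}", "X", i + 1, ("A", "A"), ("A", "A"))
                for i in range(3)
            ]
        )
        counts = AlleleCountTable(
            {f"s{i}": [999, 1, 0, 0] for i in range(3)}
        )
        assert estimate_background(counts, panel).value == pytest.approx(
            0.001
        )

    def test_error_model_background_matches_independent_mc(self):
        # 60 T2 SNPs, e=0.003, depth 640.  Each error allele has expected
        # frequency e/3, but the background statistic is the SECOND-HIGHEST
        # frequency, i.e. the max of the three error alleles, which is
        # biased above e/3 at finite depth; oracle it by direct Monte Carlo
        # of the substitution model, independent of the simulator.
        e, depth, n = 0.003, 640, 60
        rng = np.random.default_rng(123)
        draws = rng.multinomial(
            depth, [1 - e, e / 3, e / 3, e / 3], size=20000
        )
        second = np.sort(draws, axis=1)[:, -2] / depth
        mc_mean = second.mean()
        mc_se = second.std() / np.sqrt(n)  # matches the 60-SNP average

        panel = build_panel(
            [
                SnpLocus(f"s{i}", "X", i + 1, ("A", "A"), ("A", "A"))
                for i in range(n)
            ]
        )
        config = SimConfig(
            composition={"T2": n}, error_rate=e, mean_depth=depth
        )
        counts = simulate_counts(
            panel, mother_only_contributors(), config, seed=7
        )
        est = estimate_background(counts, panel)
        assert est.value == pytest.approx(mc_mean, abs=4 * mc_se)
        # e/3 remains the right scale (within a factor ~2 at this depth)
        assert 0.0005 < est.value < 0.004


class TestYLocus:
    def test_no_y_loci_raises(self):
        panel = build_panel([SnpLocus("s", "X", 1, ("A", "A"), ("G", "G"))])
        counts = AlleleCountTable({"s": [95, 0, 5, 0]})
        with pytest.raises(ValueError, match="Y loci"):
            estimate_ff_y(counts, panel)

    def test_zero_y_reads_calls_female(self, mini_panel):
        counts = exact_counts(mini_panel, Scenario(ScenarioKind.NORMAL, 0.1))
        est, sex = estimate_ff_y(counts, mini_panel)
        assert sex == "female"
        assert est is None

    def test_male_fetus_ff(self, default_config):
        scenario = Scenario(ScenarioKind.MALE_FETUS_X, 0.10)
        bundle = simulate_case(scenario, default_config, seed=3)
        est, sex = estimate_ff_y(bundle.plasma, bundle.panel)
        assert sex == "male"
        # FF_Y = f / (1 - f/2) ~ 0.105 with only 4 Y loci of noise
        assert est.value == pytest.approx(0.105, abs=0.03)

    def test_xxy_flag_from_signature(self, default_config):
        scenario = Scenario(ScenarioKind.XXY, 0.10)
        bundle = simulate_case(scenario, default_config, seed=4)
        sig = compute_signature(bundle.plasma, bundle.panel)
        assert sig.sex_call == "male"
        assert sig.xxy_flag

    def test_normal_male_not_xxy(self, default_config):
        bundle = simulate_case(
            Scenario(ScenarioKind.MALE_FETUS_X, 0.10), default_config, seed=5
        )
        sig = compute_signature(bundle.plasma, bundle.panel)
        assert sig.sex_call == "male"
        assert not sig.xxy_flag


class TestSignature:
    def test_oracle_normal_pattern(self, mini_panel):
        counts = exact_counts(mini_panel, Scenario(ScenarioKind.NORMAL, 0.10))
        sig = compute_signature(counts, mini_panel)
        assert sig.ff_t1.value == pytest.approx(0.10, abs=1e-9)
        assert sig.ff_t3[Subtype.T3_P1].value == pytest.approx(0.1, abs=1e-9)
        assert sig.ff_t3[Subtype.T3_P2].value == pytest.approx(0, abs=1e-9)
        assert sig.ff_t4[Subtype.T4_ALPHA].value == pytest.approx(
            0.1, abs=1e-9
        )
        assert sig.ff_t4[Subtype.T4_BETA].value == pytest.approx(0, abs=1e-9)
        assert sig.background.value == pytest.approx(0, abs=1e-9)

    def test_maternal_heterodisomy_all_zero(self, mini_panel):
        counts = exact_counts(
            mini_panel, Scenario(ScenarioKind.UPD_MAT_HETERO, 0.10)
        )
        sig = compute_signature(counts, mini_panel)
        for est in (
            sig.ff_t1,
            *sig.ff_t3.values(),
            *sig.ff_t4.values(),
        ):
            assert est.value == pytest.approx(0.0, abs=1e-9)

    def test_twin_2_to_1_ratio(self, mini_panel):
        scenario = Scenario(
            ScenarioKind.TWINS_DIZYGOTIC, 0.10, twin_split=2 / 3
        )
        counts = exact_counts(mini_panel, scenario)
        sig = compute_signature(counts, mini_panel)
        t3_1 = sig.ff_t3[Subtype.T3_P1].value
        t3_2 = sig.ff_t3[Subtype.T3_P2].value
        assert t3_1 / t3_2 == pytest.approx(2.0, abs=1e-6)
        t4a = sig.ff_t4[Subtype.T4_ALPHA].value
        t4b = sig.ff_t4[Subtype.T4_BETA].value
        assert abs(t4a) / abs(t4b) == pytest.approx(2.0, abs=1e-6)

    def test_scale_invariance(self, normal_bundle):
        sig1 = compute_signature(normal_bundle.plasma, normal_bundle.panel)
        doubled = normal_bundle.plasma.scaled(2.0)
        sig2 = compute_signature(doubled, normal_bundle.panel)
        assert sig2.ff_t1.value == pytest.approx(sig1.ff_t1.value)
        for st in sig1.ff_t4:
            assert sig2.ff_t4[st].value == pytest.approx(
                sig1.ff_t4[st].value
            )
        assert sig2.background.value == pytest.approx(sig1.background.value)

    def test_m_relabel_negates_type4(self, mini_panel):
        counts = exact_counts(mini_panel, Scenario(ScenarioKind.NORMAL, 0.10))
        relabeled = build_panel(
            [
                SnpLocus(
                    l.snp_id,
                    l.chrom,
                    l.pos,
                    (l.maternal_hap[1], l.maternal_hap[0]),
                    l.paternal_hap,
                    l.is_y_locus,
                )
                if not l.is_y_locus
                else l
                for l in mini_panel
            ]
        )
        sig = compute_signature(counts, mini_panel)
        sig_swapped = compute_signature(counts, relabeled)
        # alpha <-> beta swap with sign flip
        assert sig_swapped.ff_t4[Subtype.T4_BETA].value == pytest.approx(
            -sig.ff_t4[Subtype.T4_ALPHA].value, abs=1e-12
        )
        assert sig_swapped.ff_t4[Subtype.T4_ALPHA].value == pytest.approx(
            -sig.ff_t4[Subtype.T4_BETA].value, abs=1e-12
        )

    def test_inconsistent_snp_excluded(self):
        panel = build_panel(
            [
                SnpLocus("s1", "X", 1, ("A", "A"), ("G", "G")),
                SnpLocus("s2", "X", 2, ("A", "A"), ("G", "G")),
            ]
        )
        # s2 shows 30% T, impossible given parental genotypes A/G
        counts = AlleleCountTable(
            {"s1": [95, 0, 5, 0], "s2": [65, 0, 5, 30]}
        )
        sig = compute_signature(counts, panel)
        assert sig.ff_t1.n_snps == 1
        assert sig.excluded.get("inconsistent") == 1

    def test_dispersion_is_mean_absolute_deviation(self):
        est = FFEstimate.from_values([0.1, 0.2, 0.3])
        assert est.value == pytest.approx(0.2)
        assert est.dispersion == pytest.approx(np.mean([0.1, 0.0, 0.1]))
        assert est.sd == pytest.approx(np.std([0.1, 0.2, 0.3], ddof=1))
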