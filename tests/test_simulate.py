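"""The generative model: cohorts, measurement error, variant panels, IO."""

import math

import numpy as np
import pandas as pd
import pytest

from cfbgwas import (
    Cohort,
    MeasurementErrorConfig,
    PanelComposition,
    SimulationParams,
    ValidationError,
    apply_measurement_error,
    simulate_cohort,
    simulate_panel,
)
from oracles import baseline_cfb_correlation


@pytest.mark.parametrize(
    "kwargs",
    [
        {"maf": 0.0},
        {"maf": 0.6},
        {"n_subjects": 1},
        {"sd_eps0": 0.0},
        {"sd_eps1": -1.0},
        {"treatment_prob": 1.0},
        {"age_range": (65.0, 18.0)},
    ],
)
def test_params_validation(kwargs):
    with pytest.raises(ValidationError):
        SimulationParams(**kwargs)


def test_defaults_reproduce_reference_setting():
    p = SimulationParams()
    assert (p.n_subjects, p.maf) == (1000, 0.2)
    assert (p.intercept_baseline, p.beta_T, p.beta_X) == (4.6, -0.25, -0.01)
    assert p.treatment_prob == 0.5 and p.age_range == (18.0, 65.0)


def test_same_seed_gives_bit_identical_cohorts():
    p = SimulationParams(beta_G0=0.1, beta_y0=-0.2, seed=7)
    a, b = simulate_cohort(p), simulate_cohort(p)
    for field in ("y0", "y1", "treatment", "age", "genotype"):
        np.testing.assert_array_equal(getattr(a, field), getattr(b, field))
    c = simulate_cohort(SimulationParams(beta_G0=0.1, beta_y0=-0.2, seed=8))
    assert not np.array_equal(a.y0, c.y0)


def test_log_baseline_mean_matches_intercept():
    # with all genetic effects off, mean(ln y0) estimates the intercept 4.6
    n = 10_000
    cohort = simulate_cohort(SimulationParams(n_subjects=n, seed=1))
    assert abs(cohort.log_y0.mean() - 4.6) < 3.0 / math.sqrt(n)


def test_degenerate_noise_pins_log_baseline():
    p = SimulationParams(n_subjects=100, sd_eps0=1e-12, seed=2)
    cohort = simulate_cohort(p)
    np.testing.assert_allclose(cohort.log_y0, 4.6, atol=1e-9)


def test_baseline_cfb_correlation_matches_closed_form():
    p = SimulationParams(n_subjects=100_000, beta_y0=-0.2, seed=3)
    cohort = simulate_cohort(p)
    emp = np.corrcoef(cohort.log_y0, cohort.log_fold_cfb)[0, 1]
    # Fisher-z se at n=1e5 is ~0.0032; allow ~4 se
    assert abs(emp - baseline_cfb_correlation(p)) < 0.013


def test_marginal_moments_at_large_n():
    p = SimulationParams(n_subjects=100_000, beta_G0=0.1, seed=4)
    cohort = simulate_cohort(p)
    g = cohort.genotype
    se_mean_g = math.sqrt(2 * p.maf * (1 - p.maf) / p.n_subjects)
    assert abs(g.mean() - 2 * p.maf) < 3 * se_mean_g
    # residual sd of ln y0 given G
    resid = cohort.log_y0 - 4.6 - 0.1 * g
    assert abs(resid.var(ddof=1) - 1.0) < 0.02
    assert abs(cohort.treatment.mean() - 0.5) < 3 * 0.5 / math.sqrt(p.n_subjects)
    assert cohort.age.min() >= 18.0 and cohort.age.max() <= 65.0


def test_parameter_recovery_by_generating_regression():
    """Regressing CFB on [1, T, X, ln y0, G, GT] on a large cohort recovers
    the generating coefficients within 3 standard errors."""
    import statsmodels.api as sm

    p = SimulationParams(
        n_subjects=100_000, beta_G0=0.1, beta_y0=-0.2, beta_G=0.15, beta_GT=0.1, seed=5
    )
    cohort = simulate_cohort(p)
    X = np.column_stack(
        [
            np.ones(len(cohort)),
            cohort.treatment,
            cohort.age,
            cohort.log_y0,
            cohort.genotype,
            cohort.genotype * cohort.treatment,
        ]
    )
    fit = sm.OLS(cohort.log_fold_cfb, X).fit()
    truth = [None, p.beta_T, p.beta_X, p.beta_y0, p.beta_G, p.beta_GT]
    for j, b in enumerate(truth):
        if b is not None:
            assert abs(fit.params[j] - b) < 3 * fit.bse[j], f"coefficient {j}"


class TestMeasurementError:
    def test_presets(self):
        assert MeasurementErrorConfig.preset("white") == MeasurementErrorConfig(0.0, 0.0)
        assert MeasurementErrorConfig.preset("same") == MeasurementErrorConfig(0.25, 0.25)
        assert MeasurementErrorConfig.preset("opposite") == MeasurementErrorConfig(-0.25, 0.25)
        assert not MeasurementErrorConfig.preset("none").enabled
        with pytest.raises(ValidationError):
            MeasurementErrorConfig.preset("bogus")
        with pytest.raises(ValidationError):
            MeasurementErrorConfig(sigma=-0.1)

    def test_zero_error_is_identity(self, small_cohort):
        config = MeasurementErrorConfig(mu0=0.0, mu1=0.0, sigma=0.0)
        out = apply_measurement_error(small_cohort, config, rng=0)
        np.testing.assert_array_equal(out.y0, small_cohort.y0)
        np.testing.assert_array_equal(out.y1, small_cohort.y1)

    def test_input_cohort_unmodified(self, small_cohort):
        before = small_cohort.y0.copy()
        apply_measurement_error(small_cohort, MeasurementErrorConfig.preset("same"), rng=0)
        np.testing.assert_array_equal(small_cohort.y0, before)

    def test_same_direction_bias_inflates_mean_by_25_percent(self):
        cohort = simulate_cohort(SimulationParams(n_subjects=100_000, seed=6))
        out = apply_measurement_error(cohort, MeasurementErrorConfig.preset("same"), rng=7)
        ratio = out.y0 / cohort.y0
        assert abs(ratio.mean() - 1.25) < 3 * 0.25 / math.sqrt(len(cohort))

    def test_floor_truncation_by_hand(self):
        # y0 = 0.5 with r0 = -0.9 exactly: (1 - 0.9) * 0.5 = 0.05 -> floored to 1
        cohort = Cohort(
            y0=np.array([0.5, 2.0]),
            y1=np.array([3.0, 3.0]),
            treatment=np.array([0.0, 1.0]),
            age=np.array([30.0, 40.0]),
            genotype=np.array([0.0, 1.0]),
        )
        config = MeasurementErrorConfig(mu0=-0.9, mu1=0.0, sigma=0.0)
        out = apply_measurement_error(cohort, config, rng=0)
        np.testing.assert_allclose(out.y0, [1.0, 1.0])  # 0.1*2.0=0.2 also floored
        np.testing.assert_allclose(out.y1, [3.0, 3.0])

    def test_relative_errors_within_049_band_95_percent(self):
        # sigma = 1/4 puts ~95% of relative errors within +-0.49 of their mean
        cohort = simulate_cohort(SimulationParams(n_subjects=200_000, seed=8))
        out = apply_measurement_error(cohort, MeasurementErrorConfig.preset("white"), rng=9)
        r = out.y0 / cohort.y0 - 1.0
        frac = np.mean(np.abs(r) < 0.49)
        assert 0.94 < frac < 0.96


class TestPanel:
    def test_all_null_composition(self):
        panel = simulate_panel(50, 100, PanelComposition(), seed=0)
        t = panel.variant_truth
        assert (t[["beta_G0", "beta_G", "beta_GT"]].to_numpy() == 0).all()
        assert panel.genotypes.shape == (50, 100)

    def test_class_bookkeeping(self):
        comp = PanelComposition(frac_baseline=0.1, frac_null=0.9, beta_G0=0.1)
        panel = simulate_panel(100, 1000, comp, seed=1)
        n_base = int((panel.variant_truth["beta_G0"] != 0).sum())
        assert n_base == 100
        # flagged-null variants must have no direct CFB effects
        null_rows = panel.variant_truth["category"] == "null"
        assert (panel.variant_truth.loc[null_rows, ["beta_G", "beta_GT"]] == 0).all().all()

    def test_empirical_allele_frequency(self):
        panel = simulate_panel(2000, 200, PanelComposition(), seed=2, maf=0.2)
        freqs = panel.genotypes.mean(axis=0) / 2.0
        se = math.sqrt(0.2 * 0.8 / (2 * 2000))
        assert np.all(np.abs(freqs - 0.2) < 5 * se)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValidationError):
            PanelComposition(frac_baseline=0.5, frac_null=0.9)

    def test_single_causal_vs_additive_shapes(self):
        comp_s = PanelComposition(frac_cfb=0.5, frac_null=0.5)
        comp_a = PanelComposition(frac_cfb=0.5, frac_null=0.5, rule="additive")
        ps = simulate_panel(30, 10, comp_s, seed=3)
        pa = simulate_panel(30, 10, comp_a, seed=3)
        assert ps.y0.shape == (30, 10) and pa.y0.shape == (30,)
        # shared covariates are drawn from the same child stream
        np.testing.assert_array_equal(ps.treatment, pa.treatment)

    def test_determinism(self):
        comp = PanelComposition(frac_baseline=0.2, frac_null=0.8)
        a = simulate_panel(40, 20, comp, seed=11)
        b = simulate_panel(40, 20, comp, seed=11)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        np.testing.assert_array_equal(a.y1, b.y1)


class TestIO:
    def test_cohort_tsv_round_trip(self, tmp_path):
        p = SimulationParams(n_subjects=50, beta_G0=0.1, seed=12)
        cohort = simulate_cohort(p)
        path = tmp_path / "cohort.tsv"
        cohort.to_tsv(path)
        back = Cohort.from_tsv(path)
        np.testing.assert_allclose(back.y0, cohort.y0)
        np.testing.assert_array_equal(back.genotype, cohort.genotype)
        assert back.truth == p

    def test_cohort_accepts_g_column(self):
        df = pd.DataFrame(
            {"subject_id": [1, 2], "y0": [1.0, 2.0], "y1": [2.0, 3.0],
             "treatment": [0, 1], "age": [30, 40], "g_rs123": [0, 2]}
        )
        cohort = Cohort.from_frame(df)
        np.testing.assert_array_equal(cohort.genotype, [0, 2])

    def test_panel_tsv(self, tmp_path):
        panel = simulate_panel(20, 5, PanelComposition(rule="additive"), seed=4)
        path = tmp_path / "panel.tsv"
        panel.to_tsv(path)
        df = pd.read_csv(path, sep="\t")
        assert [c for c in df.columns if c.startswith("g_")] == [f"g_v{j}" for j in range(1, 6)]
        assert len(df) == 20

    def test_vcf_dosage_import(self, tmp_path):
        pytest.importorskip("cyvcf2")
        from cfbgwas import simulate as sim

        vcf = tmp_path / "tiny.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/1\t0/0\n"
        )
        geno = sim.genotypes_from_vcf(vcf)
        assert list(geno.index) == ["S1", "S2", "S3"]
        np.testing.assert_array_equal(geno["rs1"], [0, 1, 2])
        np.testing.assert_array_equal(geno["rs2"], [1, 1, 0])


def test_cohort_invariants_enforced():
    with pytest.raises(ValidationError):
        Cohort(
            y0=np.array([1.0, -2.0]), y1=np.array([1.0, 1.0]),
            treatment=np.zeros(2), age=np.zeros(2), genotype=np.zeros(2),
        )
    with pytest.raises(ValidationError):
        Cohort(
            y0=np.ones(2), y1=np.ones(2), treatment=np.zeros(2),
            age=np.zeros(2), genotype=np.array([0.0, 3.0]),
        )
    with pytest.raises(ValidationError):
        Cohort(
            y0=np.ones(3), y1=np.ones(2), treatment=np.zeros(2),
            age=np.zeros(2), genotype=np.zeros(2),
        )
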