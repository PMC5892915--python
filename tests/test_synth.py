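"""Generator contracts: determinism, the one-factor panel structure,
class-dependent crypt profiles, treatment kinetics, organoid/expression/
microbiome samplers."""

import numpy as np
import pandas as pd
import pytest

from colitiskit import histo, synth
from colitiskit.synth import CohortConfig


def test_panel_dimensions(default_config):
    assert len(default_config.analyte_names) == 54
    assert default_config.analyte_units.count("pg/ml") == 37
    assert default_config.analyte_units.count("RFU") == 17


def test_all_control_cohort_stays_at_baseline():
    cfg = CohortConfig(n_focal=0, n_continuous=0, seed=7)
    cohort = synth.generate_cohort(cfg)
    assert all(a.true_class == "control" for a in cohort)
    assert all(a.inflammation_score == 0 for a in cohort)
    for a in cohort:
        cleaned = histo.clean_measurements(a.crypt_profile)
        assert cleaned.mean_distal_height() == pytest.approx(cfg.baseline_crypt_um, rel=0.05)


def test_same_seed_gives_identical_cohorts(default_config):
    a = synth.generate_cohort(default_config)
    b = synth.generate_cohort(default_config)
    for x, y in zip(a, b):
        assert x.id == y.id and x.true_class == y.true_class
        assert x.inflammation_score == y.inflammation_score
        np.testing.assert_array_equal(x.panel_row, y.panel_row)
        pd.testing.assert_frame_equal(x.crypt_profile.data, y.crypt_profile.data)


def test_panel_leading_eigenvector_matches_loadings(default_config, cohort, panel):
    """Sample covariance's first eigenvector aligns with the configured
    loading direction, as the analytic one-factor covariance predicts."""
    X = panel.to_numpy(float)
    cov = np.cov(X, rowvar=False)
    w, v = np.linalg.eigh(cov)
    lead = v[:, -1]
    loadings = np.asarray(default_config.inflammation_loading)
    # oracle: eigendecomposition of diag(noise^2) + loadings loadings' var(score)
    scores = np.array([a.inflammation_score for a in cohort])
    analytic = np.diag(np.asarray(default_config.noise_sd) ** 2) + np.outer(
        loadings, loadings
    ) * scores.var(ddof=1)
    _, va = np.linalg.eigh(analytic)
    r_loadings = abs(lead @ loadings) / np.linalg.norm(loadings)
    r_analytic = abs(lead @ va[:, -1])
    assert r_loadings > 0.9
    assert r_analytic > 0.9


@pytest.mark.parametrize("seed", range(5))
def test_continuous_distal_heights_inside_hyperplastic_range(default_config, seed):
    rng = np.random.default_rng(seed)
    prof = synth.sample_crypt_profile("continuous", default_config, rng)
    cleaned = histo.clean_measurements(prof)
    lo, hi = default_config.hyperplasia_range_um
    d = cleaned.distal["height_um"].to_numpy()
    assert np.all((d >= lo) & (d <= hi))


def test_control_profile_below_classification_threshold(default_config, rng):
    prof = synth.sample_crypt_profile("control", default_config, rng)
    cleaned = histo.clean_measurements(prof)
    assert cleaned.data["height_um"].max() < 300.0
    assert histo.classify_extent(cleaned) == "control"


def test_focal_profile_elevates_a_contiguous_distal_window(default_config, rng):
    prof = synth.sample_crypt_profile("focal", default_config, rng, score=0.5)
    cleaned = histo.clean_measurements(prof)
    d = cleaned.distal
    high = (d["height_um"] > 300).to_numpy()
    assert 0 < high.sum() < len(high)
    # elevated measurements form one contiguous run
    runs = np.flatnonzero(np.diff(high.astype(int)) != 0)
    assert len(runs) <= 2
    # infiltrate co-locates with hyperplasia
    assert d.loc[high, "infiltrate_score"].min() >= 2


def test_focal_distal_variance_exceeds_control():
    cfg = CohortConfig(off_axis_fraction=0.0)
    wins = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        focal = synth.sample_crypt_profile("focal", cfg, rng)
        control = synth.sample_crypt_profile("control", cfg, rng)
        v_f = focal.distal["height_um"].var(ddof=1)
        v_c = control.distal["height_um"].var(ddof=1)
        wins += v_f > v_c
    assert wins == 100


def test_concentrations_nonnegative_and_fractions_valid(cohort):
    for a in cohort:
        assert np.all(a.panel_row[:37] >= 0)  # pg/ml analytes truncate at 0
        fracs = np.array(list(a.infiltrate_fractions.values()))
        assert np.all((fracs >= 0) & (fracs <= 1)) and fracs.sum() <= 1


class TestTreatment:
    def test_duration_zero_is_identity(self, cohort, default_config):
        model = synth.default_treatment(default_config)
        out = synth.apply_treatment(cohort, model, 0.0, default_config)
        assert out is cohort

    def test_immediate_drop_reaches_baseline(self, default_config):
        cfg = CohortConfig(n_control=0, n_focal=0, n_continuous=3, seed=1)
        cohort = synth.generate_cohort(cfg)
        model = synth.default_treatment(cfg)
        out = synth.apply_treatment(cohort, model, 48.0, cfg)
        j = cfg.analyte_names.index("M-CSF")  # immediate_drop, halftime 1 h
        base = cfg.analyte_baselines[j]
        for a in out:
            assert a.panel_row[j] == pytest.approx(base, rel=0.01)

    def test_graded_decline_follows_closed_form(self, default_config):
        cfg = CohortConfig(n_control=0, n_focal=0, n_continuous=1, seed=2)
        cohort = synth.generate_cohort(cfg)
        model = synth.default_treatment(cfg)
        j = cfg.analyte_names.index("MIP-1a")
        x0, base = cohort[0].panel_row[j], cfg.analyte_baselines[j]
        for t in (6.0, 24.0):
            out = synth.apply_treatment(cohort, model, t, cfg)
            expected = base + (x0 - base) * 2 ** (-t / model.halftime_h["MIP-1a"])
            assert out[0].panel_row[j] == pytest.approx(expected, rel=1e-12)

    def test_transient_increase_peaks_then_subsides(self, default_config):
        cfg = CohortConfig(n_control=0, n_focal=0, n_continuous=1, seed=3)
        cohort = synth.generate_cohort(cfg)
        model = synth.default_treatment(cfg)
        j = cfg.analyte_names.index("IL-6")
        x0 = cohort[0].panel_row[j]
        peak = synth.apply_treatment(cohort, model, model.halftime_h["IL-6"], cfg)
        late = synth.apply_treatment(cohort, model, 48.0, cfg)
        assert peak[0].panel_row[j] > x0
        assert late[0].panel_row[j] <= x0

    def test_declining_analytes_monotone_in_duration(self):
        cfg = CohortConfig(n_control=0, n_focal=0, n_continuous=2,
                           noise_sd=tuple(0.0 for _ in synth.DEFAULT_ANALYTES),
                           crypt_noise_sd_um=1e-9, off_axis_fraction=0.0, seed=4)
        cohort = synth.generate_cohort(cfg)
        model = synth.default_treatment(cfg)
        decl = [j for j, a in enumerate(cfg.analyte_names)
                if model.kinetic_class[a] in ("immediate_drop", "graded_decline")]
        prev = None
        for t in (0.0, 1.0, 4.0, 8.0, 24.0, 48.0):
            vals = np.array([a.panel_row[decl] for a in
                             synth.apply_treatment(cohort, model, t, cfg)])
            if prev is not None:
                assert np.all(vals <= prev + 1e-9)
            prev = vals

    def test_crypt_height_and_infiltrate_recover(self, default_config):
        cfg = CohortConfig(n_control=0, n_focal=0, n_continuous=2, seed=5)
        cohort = synth.generate_cohort(cfg)
        model = synth.default_treatment(cfg)
        early = synth.apply_treatment(cohort, model, 8.0, cfg)
        late = synth.apply_treatment(cohort, model, 72.0, cfg)
        for a0, a8, a72 in zip(cohort, early, late):
            assert a8.crypt_profile.mean_distal_height() < a0.crypt_profile.mean_distal_height()
            # innate fractions untouched before the lag, reduced after
            for ct in synth.INNATE_CELL_TYPES:
                assert a8.infiltrate_fractions[ct] == a0.infiltrate_fractions[ct]
                assert a72.infiltrate_fractions[ct] < a0.infiltrate_fractions[ct]

    def test_unknown_analyte_rejected(self, cohort, default_config):
        model = synth.default_treatment(default_config)
        bad = synth.TreatmentModel(
            name="bad",
            kinetic_class={**model.kinetic_class, "nonexistent": "immediate_drop"},
            halftime_h={**model.halftime_h, "nonexistent": 1.0},
            epithelial_recovery_halftime_h=24.0, infiltrate_lag_h=24.0,
            control_baseline=model.control_baseline, baseline_crypt_um=180.0,
        )
        with pytest.raises(ValueError, match="nonexistent"):
            synth.apply_treatment(cohort, bad, 1.0, default_config)


class TestOrganoids:
    def test_zero_noise_returns_exact_condition_means(self):
        cfg = CohortConfig(noise_sd=tuple(0.0 for _ in synth.DEFAULT_ANALYTES))
        rng = np.random.default_rng(0)
        for cond in synth.ORGANOID_CONDITIONS:
            row = synth.sample_organoid_panel(cond, cfg, rng)
            np.testing.assert_allclose(row, synth.organoid_condition_means(cond, cfg))

    def test_stem_exceeds_goblet_for_inflammation_loaded_analytes(self, default_config):
        stem = synth.organoid_condition_means("stem", default_config)
        goblet = synth.organoid_condition_means("goblet", default_config)
        j = default_config.analyte_names.index("MCP-1")
        assert stem[j] > goblet[j]
        loadings = np.asarray(default_config.inflammation_loading)
        mask = np.array([a not in default_config.goblet_elevated
                         for a in default_config.analyte_names]) & (loadings > 0)
        assert np.all(stem[mask] >= goblet[mask])

    def test_goblet_elevated_analyte_reverses_pattern(self, default_config):
        stem = synth.organoid_condition_means("stem", default_config)
        goblet = synth.organoid_condition_means("goblet", default_config)
        j = default_config.analyte_names.index("MIP-1a")
        assert goblet[j] > stem[j]


class TestExpression:
    def test_pure_mixture_zero_noise_reproduces_signature(self, rng):
        sig = synth.default_signatures()
        pure = pd.DataFrame(0.0, index=["s1"], columns=list(synth.EPITHELIAL_TYPES))
        pure["tac"] = 1.0
        expr = synth.sample_expression_matrix(pure, sig, rng, noise_sd=0.0)
        np.testing.assert_allclose(expr["s1"].to_numpy(), sig["tac"].to_numpy())

    def test_tac_genes_up_goblet_markers_down_in_inflamed(self, rng):
        sig = synth.default_signatures()
        mix, labels = synth.default_mixtures(rng=rng)
        expr = synth.sample_expression_matrix(mix, sig, rng)
        inflamed = expr.loc[:, (labels == "inflamed").to_numpy()].mean(axis=1)
        control = expr.loc[:, (labels == "noninflamed").to_numpy()].mean(axis=1)
        diff = inflamed - control
        assert diff.loc[list(synth.TAC_CHEMOKINES)].min() > 0
        assert diff.loc["Mki67"] > 0
        assert diff.loc["Muc2"] < 0

    def test_rejects_proportions_not_summing_to_one(self, rng):
        sig = synth.default_signatures()
        bad = pd.DataFrame([[0.5] * 6], index=["s1"], columns=list(synth.EPITHELIAL_TYPES))
        with pytest.raises(ValueError, match="sum to 1"):
            synth.sample_expression_matrix(bad, sig, rng)


class TestCountsTable:
    def test_rows_sum_to_depth(self, rng):
        groups = pd.Series(["control"] * 3 + ["inflamed"] * 3,
                           index=[f"s{i}" for i in range(6)])
        counts = synth.sample_counts_table(groups, synth.default_taxon_profiles(), 5000, rng)
        assert (counts.sum(axis=1) == 5000).all()

    def test_identical_profiles_converge_at_depth(self, rng):
        from colitiskit import microbiome
        prof = synth.default_taxon_profiles().iloc[[0]]
        groups = pd.Series(["control", "control"], index=["a", "b"])
        counts = synth.sample_counts_table(groups, prof, depth=10**6, rng=rng,
                                           concentration=1e9)
        D = microbiome.bray_curtis(microbiome.relative_abundance(counts))
        assert D.values[0, 1] < 0.01

    def test_disjoint_supports_give_dissimilarity_one(self, rng):
        from colitiskit import microbiome
        prof = pd.DataFrame(
            [[0.5, 0.5, 0.0, 0.0], [0.0, 0.0, 0.5, 0.5]],
            index=["g1", "g2"], columns=["t1", "t2", "t3", "t4"],
        )
        groups = pd.Series(["g1", "g2"], index=["a", "b"])
        counts = synth.sample_counts_table(groups, prof, depth=100, rng=rng)
        D = microbiome.bray_curtis(microbiome.relative_abundance(counts))
        assert D.values[0, 1] == pytest.approx(1.0)


@pytest.mark.parametrize(
    "kwargs,match",
    [
        (dict(colon_length_um=-1), "colon length"),
        (dict(analyte_names=()), "analyte list|one entry per analyte"),
        (dict(hyperplasia_range_um=(600.0, 300.0)), "low < high"),
        (dict(n_control=-1), "class sizes"),
        (dict(noise_sd=tuple([-1.0] * 54)), "noise_sd"),
    ],
)
def test_config_validation(kwargs, match):
    with pytest.raises(ValueError, match=match):
        CohortConfig(**kwargs)
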