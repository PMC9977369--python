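import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from psdgold.model import Particle, PSDRecord, StudyDataset
from psdgold.radial import profile_matrix, radial_profile
from psdgold.nulls import NullSpec, simulate_profiles
from psdgold.stats import (
    count_area_r2,
    density_per_um2,
    kruskal_wallis_h,
    mann_whitney_u,
    ranked_rm_anova_dunnett,
    receptor_ratio,
    summarize,
    summary_table,
)

from conftest import make_record, square_region


class TestSummarize:
    def test_symmetric_sample(self):
        s = summarize([1.0, 2.0, 3.0], "g")
        assert (s.mean, s.sd, s.median, s.skewness) == (2.0, 1.0, 2.0, 0.0)

    @pytest.mark.parametrize("mean,sd,cv", [
        (22.70, 13.73, 0.60), (24.02, 13.38, 0.56),
        (37.02, 21.58, 0.58), (30.29, 15.58, 0.51),
    ])
    def test_cv_matches_reference_rows(self, mean, sd, cv):
        # grain-count groups print CV consistent with SD/mean at 2 decimals
        assert round(sd / mean, 2) == cv

    def test_lognormal_moments_within_3se(self):
        mu, sigma, n = 1.0, 0.5, 10_000
        rng = np.random.default_rng(0)
        x = rng.lognormal(mu, sigma, n)
        s = summarize(x, "ln")
        m_true = np.exp(mu + sigma**2 / 2)
        v_true = (np.exp(sigma**2) - 1) * np.exp(2 * mu + sigma**2)
        assert abs(s.mean - m_true) < 3 * np.sqrt(v_true / n)
        # SE of the sample SD for a lognormal (via fourth moment)
        m4 = sps.moment(x, moment=4)
        se_var = np.sqrt((m4 - v_true**2) / n)
        assert abs(s.variance - v_true) < 3 * se_var

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            summarize([1.0], "g")

    def test_summary_table_columns(self):
        df = summary_table({"a": [1, 2, 3], "b": [4, 5, 6, 7]})
        assert list(df.columns) == ["group", "n_psd", "mean", "sd", "median",
                                    "iqr", "min", "max", "skewness",
                                    "variance", "cv"]
        assert list(df.n_psd) == [3, 4]


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(1.0, 1e4), min_size=2, max_size=40))
def test_summary_internal_identities(values):
    s = summarize(values, "g")
    assert s.cv * s.mean == pytest.approx(s.sd, rel=1e-12)
    assert s.variance == pytest.approx(s.sd**2, rel=1e-12)
    assert s.iqr >= 0
    assert s.min <= s.median <= s.max


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        r = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert r.p_value == pytest.approx(1.0)

    def test_small_sample_exact_enumeration(self):
        r = mann_whitney_u([1, 2], [3, 4])
        assert r.statistic == 0
        assert r.p_value == pytest.approx(2 / 6)

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        assert mann_whitney_u(a, b).p_value == pytest.approx(
            mann_whitney_u(b, a).p_value)

    def test_asymptotic_close_to_exact_at_8v8(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 8), rng.normal(0.8, 1, 8)
        exact = mann_whitney_u(a, b).p_value  # enumeration path
        asym = sps.mannwhitneyu(a, b, alternative="two-sided",
                                method="asymptotic").pvalue
        assert abs(exact - asym) < 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestKruskalWallis:
    def test_identical_groups(self):
        r = kruskal_wallis_h({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert r.omnibus.statistic == pytest.approx(0.0, abs=1e-9)
        assert r.omnibus.p_value == pytest.approx(1.0, abs=1e-6)

    def test_hand_computed_h(self):
        # ranks 1..6, group rank sums 3, 7, 11 (no ties):
        # H = 12/(6*7) * (3^2/2 + 7^2/2 + 11^2/2) - 3*7 = 32/7
        r = kruskal_wallis_h({"a": [1, 2], "b": [3, 4], "c": [5, 6]})
        assert r.omnibus.statistic == pytest.approx(32 / 7)

    def test_posthoc_bonferroni(self):
        r = kruskal_wallis_h({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        assert len(r.posthoc) == 3
        for t in r.posthoc:
            assert t.p_adjusted == pytest.approx(min(1.0, t.p_value * 3))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis_h({"a": [1], "b": []})

    def test_chi2_p_close_to_permutation_oracle(self):
        rng = np.random.default_rng(11)
        groups = [rng.normal(0, 1, 10), rng.normal(0.3, 1, 10),
                  rng.normal(0.9, 1, 10)]
        r = kruskal_wallis_h({f"g{i}": g for i, g in enumerate(groups)})
        pooled = np.concatenate(groups)
        h_obs = sps.kruskal(*groups).statistic
        hits = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            h = sps.kruskal(perm[:10], perm[10:20], perm[20:]).statistic
            hits += h >= h_obs - 1e-12
        p_perm = hits / n_perm
        assert abs(r.omnibus.p_value - p_perm) < 0.02


class TestRankedRmComparison:
    def _measured_and_sims(self, true_model, sim_model, n_psd=60, seed=0):
        from psdgold.synth import generate_study
        from psdgold.validation import _single_cell_config, _simulated_stack

        ds, _ = generate_study(_single_cell_config(
            n_psd, density=500.0, placement=true_model, seed=seed))
        recs = [r for r in ds.records if r.particles]
        profiles = [radial_profile(r) for r in recs]
        measured = profile_matrix([], profiles=profiles)
        rng = np.random.default_rng(seed + 1)
        sims = {sim_model: _simulated_stack(recs, profiles, sim_model,
                                            100, 1 / 3, rng)}
        return measured, sims

    def test_condition_identical_to_measured_not_significant(self):
        rng = np.random.default_rng(2)
        measured_vals = rng.uniform(0, 1, (10, 5))
        import pandas as pd

        measured = pd.DataFrame(measured_vals)
        sims = {"same": np.repeat(measured_vals[:, None, :], 50, axis=1)}
        res = ranked_rm_anova_dunnett(measured, sims)
        assert res.comparisons[0].p_value == pytest.approx(1.0)

    def test_wrong_null_rejected(self):
        measured, sims = self._measured_and_sims("center_gaussian", "equal")
        res = ranked_rm_anova_dunnett(measured, sims)
        assert res.comparisons[0].p_value <= 0.05

    def test_true_null_retained(self):
        measured, sims = self._measured_and_sims("equal", "equal")
        res = ranked_rm_anova_dunnett(measured, sims)
        assert res.comparisons[0].p_value > 0.05

    def test_needs_two_psds(self):
        import pandas as pd

        with pytest.raises(ValueError):
            ranked_rm_anova_dunnett(pd.DataFrame([[1.0, 2.0]]),
                                    {"m": np.ones((1, 5, 2))})


def _record_with_count(side, k, psd_id):
    pts = [(0.0, 0.0)] * k
    return make_record(square_region(side), pts, psd_id=psd_id)


class TestCountArea:
    def test_exact_linear_relation(self):
        recs = [_record_with_count(side, int(round(400 * (side / 1000) ** 2)),
                                   f"p{side}")
                for side in (100, 150, 200, 250, 300)]
        fit = count_area_r2(recs)
        assert fit.r2 == pytest.approx(1.0, abs=1e-6)
        assert fit.slope == pytest.approx(400, rel=0.05)

    def test_independent_counts_give_near_zero_r2(self):
        rng = np.random.default_rng(17)
        recs = [_record_with_count(float(rng.uniform(100, 300)),
                                   int(rng.poisson(20)), f"p{i}")
                for i in range(500)]
        fit = count_area_r2(recs)
        assert fit.r2 < 0.05

    def test_needs_three_records(self):
        with pytest.raises(ValueError):
            count_area_r2([_record_with_count(100, 5, "a"),
                           _record_with_count(200, 10, "b")])


class TestDensityAndRatio:
    def test_density_value(self):
        # 10 grains on a 0.025 um^2 square -> 400 grains/um^2
        side = np.sqrt(0.025) * 1000
        rec = _record_with_count(side, 10, "d")
        assert density_per_um2(rec) == pytest.approx(400.0)

    def test_density_scaling_law(self):
        rec = _record_with_count(200.0, 8, "d")
        big = make_record(square_region(400.0), [(0.0, 0.0)] * 8, psd_id="big")
        assert density_per_um2(big) == pytest.approx(density_per_um2(rec) / 4)

    def test_group_mean_density_is_mean_of_ratios(self):
        # documents the per-PSD convention: mean of count/area differs from
        # pooled count / pooled area for heterogeneous areas
        recs = [_record_with_count(100.0, 10, "s"),
                _record_with_count(300.0, 10, "l")]
        dens = [density_per_um2(r) for r in recs]
        pooled = 20 / (0.01 + 0.09)
        assert not np.isclose(np.mean(dens), pooled)

    def test_equal_counts_give_unit_ratio(self, two_receptor_dataset):
        row = receptor_ratio(two_receptor_dataset, "L4", "spine")
        assert row.grand_mean == pytest.approx(1.0)
        assert row.sd == pytest.approx(0.0)

    def test_hand_computed_two_animal_ratio(self):
        # animal ratios 0.8 and 0.6 -> grand mean 0.7, SD ~0.1414
        records = []
        for animal, (n_a, n_g) in [("A01", (8, 10)), ("A02", (6, 10))]:
            for receptor, n in (("AMPA", n_a), ("GluN1", n_g)):
                records.append(PSDRecord(
                    psd_id=f"{animal}{receptor}", animal_id=animal,
                    layer="L4", target="shaft", region=square_region(200.0),
                    particles=tuple(Particle(x=0, y=0, gold_size=5,
                                             receptor=receptor)
                                    for _ in range(n)),
                ))
        ds = StudyDataset(records=records)
        row = receptor_ratio(ds, "L4", "shaft")
        assert row.grand_mean == pytest.approx(0.7)
        assert row.sd == pytest.approx(np.std([0.8, 0.6], ddof=1))

    def test_missing_receptor_rejected(self, two_receptor_dataset):
        from psdgold.model import select

        only_ampa = select(two_receptor_dataset, receptor="AMPA")
        with pytest.raises(ValueError):
            receptor_ratio(only_ampa, "L4", "spine")
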