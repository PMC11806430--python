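"""Reflectivity extraction, REML mixed models, and modality comparison."""

import warnings

import numpy as np
import pandas as pd
import pytest

import gaconcord as g
from gaconcord.oct import ReflectanceProfile
from gaconcord.stats import locus_reflectivity, reflectivity_histogram


def make_profile(values, res=10.0, start=-100.0):
    values = np.asarray(values, dtype=float)
    pos = start + np.arange(len(values)) * res
    return ReflectanceProfile(
        positions_um=pos, mean_raw=values, truncated=np.zeros(len(values), bool)
    )


class TestLocusReflectivity:
    def test_constant_profile_is_fixed_point(self):
        prof = make_profile(np.full(50, 112.5))
        assert locus_reflectivity(prof, 0.0) == 112.5
        assert locus_reflectivity(prof, 150.0) == 112.5

    def test_zero_footprint_takes_nearest_column(self):
        prof = make_profile(np.arange(50, dtype=float))
        assert locus_reflectivity(prof, -100.0 + 7 * 10.0 + 2.0, footprint_um=0.0) == 7.0

    def test_step_profile_centred_locus_averages_to_midpoint(self):
        vals = np.where(np.arange(50) < 10, 100.0, 200.0)
        prof = make_profile(vals, res=10.0, start=-100.0)
        # step is between columns at -10 and 0; a locus at the midpoint -5 with
        # a 50 um footprint covers three columns of each level
        assert locus_reflectivity(prof, -5.0, footprint_um=50.0) == 150.0

    def test_position_outside_domain_raises(self):
        prof = make_profile(np.full(10, 50.0))
        with pytest.raises(ValueError):
            locus_reflectivity(prof, 10_000.0)


class TestFitGroupedRepeated:
    def test_balanced_single_visit_equals_arithmetic_means(self):
        # balanced design: GLS coincides with per-group arithmetic means for
        # any exchangeable covariance (Zyskind), so the degenerate
        # repeated-measures model must reproduce them exactly
        df = g.simulate_locus_observations(
            eye_sd=10.0, n_eyes=8, n_visits=1, n_loci_per_class=3, seed=3
        )
        fit = g.fit_grouped_repeated(df, covariance="AR1")
        arith = df.groupby("locus_class")["reflectivity"].mean()
        for cls, est in fit.group_means.items():
            assert est.estimate == pytest.approx(arith[cls], abs=1e-6)

    def test_matches_statsmodels_random_intercept(self):
        # independent oracle: with one visit per series the model reduces to
        # a random-intercept LMM, which statsmodels MixedLM fits by REML
        import statsmodels.formula.api as smf

        df = g.simulate_locus_observations(
            n_eyes=10, n_visits=1, n_loci_per_class=4, seed=9
        )
        fit = g.fit_grouped_repeated(df, covariance="AR1")
        sm_fit = smf.mixedlm(
            "reflectivity ~ 0 + C(locus_class)", df, groups=df["eye_id"]
        ).fit(reml=True)
        for i, cls in enumerate(sorted(df["locus_class"].unique())):
            sm_est = sm_fit.params[f"C(locus_class)[{cls}]"]
            sm_se = sm_fit.bse[f"C(locus_class)[{cls}]"]
            assert fit.group_means[cls].estimate == pytest.approx(sm_est, abs=1e-4)
            assert fit.group_means[cls].se == pytest.approx(sm_se, rel=0.02)

    def test_recovers_generating_means(self):
        truth = {"absolute": 128.0, "relative": 113.0, "nonscotomatous": 104.0}
        df = g.simulate_locus_observations(seed=17)
        fit = g.fit_grouped_repeated(df, covariance="AR1")
        for cls, mu in truth.items():
            est = fit.group_means[cls]
            assert abs(est.estimate - mu) < 4 * est.se

    def test_auto_selects_by_lowest_aic(self):
        df = g.simulate_locus_observations(n_eyes=8, n_visits=3, seed=21)
        fit = g.fit_grouped_repeated(df, covariance="auto")
        assert fit.covariance_structure in ("AR1", "ARH1", "CSH")
        assert set(fit.candidate_criteria) == {"AR1", "ARH1", "CSH"}
        assert fit.fit_criterion == min(fit.candidate_criteria.values())

    def test_significant_global_test_triggers_pairwise(self):
        df = g.simulate_locus_observations(n_eyes=8, n_visits=2, seed=2)
        fit = g.fit_grouped_repeated(df, covariance="AR1")
        assert fit.global_p < 0.05
        assert len(fit.pairwise_differences) == 3
        for d in fit.pairwise_differences:
            assert d.ci_low <= d.estimate <= d.ci_high

    def test_null_data_usually_skips_pairwise(self):
        df = g.simulate_locus_observations(
            class_means=(110.0, 110.0, 110.0), n_eyes=8, n_visits=2, seed=5
        )
        fit = g.fit_grouped_repeated(df, covariance="AR1")
        if fit.global_p >= 0.05:
            assert fit.pairwise_differences == ()

    def test_single_group_rejected(self):
        df = g.simulate_locus_observations(n_eyes=4, n_visits=1, seed=0)
        with pytest.raises(ValueError):
            g.fit_grouped_repeated(df[df["locus_class"] == "absolute"])

    def test_cis_contain_point_estimates(self):
        df = g.simulate_locus_observations(n_eyes=6, n_visits=2, seed=8)
        fit = g.fit_grouped_repeated(df, covariance="CSH")
        for est in fit.group_means.values():
            assert est.ci_low <= est.estimate <= est.ci_high


class TestCompareModalities:
    @staticmethod
    def paired_frame(diff, n_eyes=6, n_visits=3, sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for e in range(n_eyes):
            for v in range(n_visits):
                for axis in ("horizontal", "vertical"):
                    faf = rng.uniform(0.5, 0.8)
                    rows.append(
                        {
                            "eye_id": f"eye{e}",
                            "visit": v,
                            "axis": axis,
                            "dsc_faf": faf,
                            "dsc_oct": faf + diff + rng.normal(0, sd),
                        }
                    )
        return pd.DataFrame(rows)

    def test_identical_modalities_give_zero_difference(self):
        fit = g.compare_modalities(self.paired_frame(diff=0.0))
        d = fit.pairwise_differences[0]
        assert d.estimate == pytest.approx(0.0, abs=1e-9)
        assert d.ci_low <= 0.0 <= d.ci_high

    def test_positive_difference_detected(self):
        fit = g.compare_modalities(self.paired_frame(diff=0.03, sd=0.01, seed=1))
        d = fit.pairwise_differences[0]
        assert d.estimate > 0
        assert d.p_value < 0.05

    def test_single_eye_degrades_with_warning(self):
        df = self.paired_frame(diff=0.02, sd=0.01, n_eyes=1, n_visits=8, seed=2)
        with pytest.warns(UserWarning, match="single-eye"):
            fit = g.compare_modalities(df)
        assert fit.pairwise_differences[0].estimate == pytest.approx(0.02, abs=0.02)

    def test_no_pairs_rejected(self):
        with pytest.raises(ValueError):
            g.compare_modalities(self.paired_frame(0.0).iloc[:0])


class TestReflectivityHistogram:
    def test_single_class_single_unit_bin_has_density_one(self):
        df = pd.DataFrame({"locus_class": ["absolute"] * 5, "reflectivity": [0.5] * 5})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = reflectivity_histogram(df, bins=np.array([0.0, 1.0]))
        edges, dens = out["absolute"]
        assert dens.tolist() == [1.0]

    def test_separated_point_masses_do_not_overlap(self):
        df = pd.DataFrame(
            {
                "locus_class": ["absolute"] * 5 + ["nonscotomatous"] * 5,
                "reflectivity": [200.0] * 5 + [50.0] * 5,
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = reflectivity_histogram(df, bins=np.linspace(0, 255, 18))
        a = out["absolute"][1] > 0
        b = out["nonscotomatous"][1] > 0
        assert not np.any(a & b)

    def test_empty_class_warns_and_is_omitted(self):
        df = pd.DataFrame({"locus_class": ["absolute"] * 5, "reflectivity": [100.0] * 5})
        with pytest.warns(UserWarning, match="relative"):
            out = reflectivity_histogram(df)
        assert "relative" not in out

    def test_csv_written(self, tmp_path):
        df = g.simulate_locus_observations(n_eyes=2, n_visits=1, seed=0)
        path = tmp_path / "hist.csv"
        reflectivity_histogram(df, csv_path=path)
        table = pd.read_csv(path)
        assert {"bin_left", "bin_right", "absolute"} <= set(table.columns)
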