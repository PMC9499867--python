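import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy import stats

from preclad import preprocess, schema, synthetic
from preclad.synthetic import CohortConfig, TrajectorySpec


def _noiseless_config(seed=0):
    cc = CohortConfig(seed=seed)
    cc.trajectories = {
        name: replace(spec, cv=0.0, age_coef=0.0, sex_coef=0.0)
        for name, spec in cc.trajectories.items()}
    return cc


class TestGenerateCohort:
    def test_seeded_determinism_byte_identical(self, tmp_path):
        cc = CohortConfig(n=120, seed=42)
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        synthetic.generate_cohort(cc).to_csv(a, index=False)
        synthetic.generate_cohort(cc).to_csv(b, index=False)
        assert a.read_bytes() == b.read_bytes()

    def test_different_seeds_differ(self):
        a = synthetic.generate_cohort(CohortConfig(n=100, seed=1))
        b = synthetic.generate_cohort(CohortConfig(n=100, seed=2))
        assert not np.allclose(a[schema.CSF_AB4240], b[schema.CSF_AB4240])

    def test_abeta_positive_fraction_calibrated(self):
        for seed in range(5):
            df = synthetic.generate_cohort(CohortConfig(seed=seed))
            frac = (df[schema.CSF_AB4240] < 0.071).mean()
            assert 0.29 <= frac <= 0.39

    def test_noiseless_values_on_the_sigmoid_curve(self):
        cc = _noiseless_config()
        df = synthetic.generate_cohort(cc, include_latent=True)
        spec = cc.trajectories["plasma_ptau231"]
        expected = 10 ** spec.log10_curve(df["latent_cl"])
        assert np.allclose(df["plasma_ptau231"], expected, rtol=1e-12)

    def test_noiseless_monotone_in_latent_burden(self):
        cc = _noiseless_config()
        df = synthetic.generate_cohort(cc, include_latent=True).sort_values("latent_cl")
        for col in schema.PLASMA_COLUMNS:
            diffs = np.diff(df[col].to_numpy())
            direction = schema.biomarker_info(col).direction
            assert np.all(direction * diffs >= -1e-12), col

    def test_concentrations_positive_and_ratios_in_range(self, default_cohort):
        df, _ = default_cohort
        assert schema.validate_schema(df.drop(columns=["latent_cl"])) == []

    def test_log_concentrations_normalish_within_reference(self):
        # multiplicative lognormal noise: log10 values in the amyloid-normal
        # stratum should pass Shapiro-Wilk most of the time
        rejected = 0
        for seed in range(10):
            df = synthetic.generate_cohort(CohortConfig(n=300, seed=seed))
            ref = df[schema.CSF_AB4240] > 0.1
            vals = np.log10(df.loc[ref, "plasma_nfl"])[:200]
            if stats.shapiro(vals).pvalue < 0.01:
                rejected += 1
        assert rejected <= 1

    def test_at_counts_near_study_cell_counts(self):
        # target cell counts 249/104/31/13 of 397; allow binomial 99% slack
        counts = {"A-T-": [], "A+T-": [], "A+T+": [], "A-T+": []}
        for seed in range(5):
            df = synthetic.generate_cohort(CohortConfig(seed=seed))
            labels = pd.Series(preprocess.classify_at(
                df[schema.CSF_AB4240], df[schema.CSF_MPTAU181]))
            for k in counts:
                counts[k].append((labels == k).sum())
        for target, key in ((249, "A-T-"), (104, "A+T-"), (31, "A+T+"), (13, "A-T+")):
            p = target / 397
            sd = np.sqrt(397 * p * (1 - p))
            assert abs(np.mean(counts[key]) - target) < 2.58 * sd, key

    def test_pet_availability_fraction(self, default_cohort):
        df, cc = default_cohort
        n_pet = df[schema.CENTILOIDS].notna().sum()
        assert n_pet == int(round(cc.pet_fraction * cc.n))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_cohort(CohortConfig(n=5))
        with pytest.raises(ValueError):
            synthetic.generate_cohort(CohortConfig(prop_abeta_pos=1.5))
        bad = CohortConfig()
        bad.trajectories["plasma_nfl"] = TrajectorySpec(
            "plasma_nfl", 12.0, 70.0, 15.0, 0.5, 0.35)  # decreasing but marked up
        with pytest.raises(ValueError):
            synthetic.generate_cohort(bad)


class TestFollowup:
    def test_seeded_determinism(self, default_cohort):
        df, cc = default_cohort
        a = synthetic.generate_followup(df, cc)
        b = synthetic.generate_followup(df, cc)
        pd.testing.assert_frame_equal(a, b)

    def test_subsample_sizes(self, default_cohort, followup):
        df, cc = default_cohort
        n_cog = followup[schema.subtest_col("fcsrt", 1)].notna().sum()
        n_pet = followup[schema.CL_V2].notna().sum()
        assert n_cog == int(round(cc.followup_cog_fraction * cc.n))
        assert n_pet == int(round(cc.followup_pet_fraction * cc.n))

    def test_intervals_near_three_years(self, followup):
        d1 = pd.to_datetime(followup[schema.COG_DATE_V1])
        d2 = pd.to_datetime(followup[schema.COG_DATE_V2])
        years = (d2 - d1).dt.days / 365.25
        assert 2.8 < years.mean() < 3.8

    def test_null_interaction_no_slope_difference_by_group(self):
        # with coupling off, mean cognitive slope is equal across amyloid strata
        cc = CohortConfig(n=3000, seed=3, interaction_strength=0.0,
                          followup_cog_fraction=0.999)
        df = synthetic.generate_cohort(cc, include_latent=True)
        fu = synthetic.generate_followup(df, cc)
        d1 = pd.to_datetime(fu[schema.COG_DATE_V1])
        d2 = pd.to_datetime(fu[schema.COG_DATE_V2])
        years = ((d2 - d1).dt.days / 365.25).to_numpy()
        slope = (fu["fcsrt_v2"] - fu["fcsrt_v1"]).to_numpy() / years
        pos = (df[schema.CSF_AB4240] < 0.071).to_numpy()
        ok = np.isfinite(slope)
        diff = slope[ok & pos].mean() - slope[ok & ~pos].mean()
        se = np.sqrt(slope[ok & pos].var() / (ok & pos).sum()
                     + slope[ok & ~pos].var() / (ok & ~pos).sum())
        assert abs(diff) < 3.5 * se

    def test_mismatched_ids_rejected(self, default_cohort):
        df, cc = default_cohort
        broken = df.copy()
        broken[schema.ID] = "same"
        with pytest.raises(ValueError, match="ids"):
            synthetic.generate_followup(broken, cc)

    def test_missing_latent_rejected(self, default_cohort):
        df, cc = default_cohort
        with pytest.raises(ValueError, match="latent"):
            synthetic.generate_followup(df.drop(columns=["latent_cl"]), cc)


class TestGroundTruth:
    def test_flat_trajectory_never_crosses(self):
        cc = CohortConfig()
        cc.trajectories["plasma_nfl"] = replace(
            cc.trajectories["plasma_nfl"], fold_change=1.0)
        assert synthetic.ground_truth_crossing(cc, 2.0, "plasma_nfl") is None

    def test_steep_sigmoid_crossing_near_midpoint(self):
        cc = CohortConfig()
        cc.trajectories["plasma_ptau231"] = replace(
            cc.trajectories["plasma_ptau231"], midpoint=25.0, width=1.0,
            fold_change=4.0)
        crossing = synthetic.ground_truth_crossing(cc, 2.0, "plasma_ptau231")
        assert crossing == pytest.approx(25.0, abs=2.0)

    def test_zero_threshold_at_reference_mean_intersection(self):
        cc = CohortConfig()
        crossing = synthetic.ground_truth_crossing(cc, 0.0, "plasma_ptau231")
        spec = cc.trajectories["plasma_ptau231"]
        mean_ref, _ = synthetic.reference_stats(cc, "plasma_ptau231")
        assert spec.log10_curve(crossing) == pytest.approx(mean_ref, abs=1e-6)

    def test_default_crossing_order_staggered(self):
        cc = CohortConfig()
        c231 = synthetic.ground_truth_crossing(cc, 2.0, "plasma_ptau231")
        c217 = synthetic.ground_truth_crossing(cc, 2.0, "plasma_ptau217")
        cgfap = synthetic.ground_truth_crossing(cc, 2.0, "plasma_gfap")
        assert c231 < c217 < cgfap
        for late in ("plasma_ptau181", "plasma_nfl", "plasma_ab4240"):
            assert synthetic.ground_truth_crossing(cc, 2.0, late) is None


class TestConfigFile:
    def test_yaml_config_with_trajectory_override(self, tmp_path):
        p = tmp_path / "cohort.yaml"
        p.write_text(
            "n: 150\nseed: 9\nprop_abeta_pos: 0.3\n"
            "trajectories:\n  plasma_ptau231:\n    midpoint: 18.0\n")
        cc = CohortConfig.from_yaml(p)
        assert cc.n == 150 and cc.prop_abeta_pos == 0.3
        assert cc.trajectories["plasma_ptau231"].midpoint == 18.0
        # untouched markers keep defaults
        assert cc.trajectories["plasma_nfl"].midpoint == 70.0
        df = synthetic.generate_cohort(cc)
        assert len(df) == 150

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "cohort.yaml"
        p.write_text("n_participants: 10\n")
        with pytest.raises(ValueError, match="n_participants"):
            CohortConfig.from_yaml(p)
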