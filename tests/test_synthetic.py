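import math

import numpy as np
import pandas as pd
import pytest

from lesionnet.connectome import LesionMask
from lesionnet.errors import ConfigurationError
from lesionnet.synthetic import (
    DEFAULT_EFFECT_PROFILE,
    NORMATIVE_METRICS,
    SimConfig,
    simulate_cohort,
    simulate_lesions,
    simulate_metric_table,
    simulate_parcellation,
    simulate_study,
    simulate_tractogram,
)


class TestConfigValidation:
    def test_negative_counts(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_hc=-1).validate()

    def test_empty_cohort(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_hc=0, n_aoms=0, n_loms=0).validate()

    def test_bad_sigma_multipliers(self):
        with pytest.raises(ConfigurationError):
            SimConfig(center_sigma_multipliers=(1.0,) * 6).validate()
        with pytest.raises(ConfigurationError):
            SimConfig(center_sigma_multipliers=(1, 1, 1, 1, 1, 1, -2)).validate()

    def test_loms_onset_below_45_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(loms_onset_range=(40.0, 60.0)).validate()

    def test_unknown_metric_in_profile(self):
        cfg = SimConfig(metric_effect_profile={"not_a_metric": (0.0, 0.0)})
        with pytest.raises(ConfigurationError):
            cfg.validate()

    def test_probability_out_of_range(self):
        with pytest.raises(ConfigurationError):
            SimConfig(education_p={"HC": 1.4}).validate()


class TestCohort:
    def test_group_age_windows(self):
        cfg = SimConfig(n_hc=50, n_aoms=50, n_loms=80, seed=3)
        cohort = simulate_cohort(cfg)
        loms = cohort[cohort["group"] == "LOMS"]
        aoms = cohort[cohort["group"] == "AOMS"]
        hc = cohort[cohort["group"] == "HC"]
        assert (loms["age_at_onset"] >= 45).all()
        assert ((aoms["age_at_onset"] > 18) & (aoms["age_at_onset"] < 45)).all()
        assert (cohort.loc[cohort["group"] != "HC", "disease_duration"] <= 6).all()
        assert hc["age_at_mri"].between(18, 77).all()

    def test_duration_consistency(self):
        cohort = simulate_cohort(SimConfig(n_hc=10, n_aoms=40, n_loms=40, seed=5))
        pat = cohort[cohort["group"] != "HC"]
        np.testing.assert_allclose(
            pat["disease_duration"], pat["age_at_mri"] - pat["age_at_onset"], atol=1e-9
        )

    def test_same_seed_byte_identical(self):
        cfg = SimConfig(n_hc=40, n_aoms=30, n_loms=20, seed=9)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_impaired_fraction_matches_configured_rate(self):
        # intercept-only model at the observed impairment rate
        rate = 0.39
        cfg = SimConfig(
            n_hc=0,
            n_aoms=10000,
            n_loms=0,
            impairment_model={"intercept": math.log(rate / (1 - rate))},
            seed=21,
        )
        cohort = simulate_cohort(cfg)
        frac = cohort["sdmt_impaired"].astype(bool).mean()
        se = math.sqrt(rate * (1 - rate) / 10000)
        assert abs(frac - rate) < 2 * se

    def test_impairment_consistent_with_z(self, small_study):
        cohort, _ = small_study
        pat = cohort[cohort["group"] != "HC"]
        assert ((pat["sdmt_z"] < -1.5) == pat["sdmt_impaired"].astype(bool)).all()


class TestMetricTable:
    def test_null_profile_groups_identical_in_expectation(self):
        profile = {m: (0.0, 0.0) for m in NORMATIVE_METRICS}
        cfg = SimConfig(
            n_hc=800, n_aoms=800, n_loms=800, metric_effect_profile=profile, seed=2
        )
        cohort = simulate_cohort(cfg)
        mt = simulate_metric_table(cohort, cfg)
        df = cohort[["subject_id", "group", "age_at_mri"]].merge(mt, on="subject_id")
        # compare group means at matched ages (ages differ by design, so
        # detrend by the known age slope before comparing)
        for metric in ("density", "modularity"):
            from lesionnet.synthetic import _BASE_PARAMS

            par = _BASE_PARAMS[metric]
            resid = df[metric] - par.age_beta * (df["age_at_mri"] - 45.0)
            means = resid.groupby(df["group"]).mean()
            assert means.max() - means.min() < 5 * par.sigma / math.sqrt(800)

    def test_heteroscedastic_centers(self):
        cfg = SimConfig(
            n_hc=4000, n_aoms=0, n_loms=0, n_centers=2,
            center_sigma_multipliers=(1.0, 2.0), seed=13,
        )
        cohort = simulate_cohort(cfg)
        mt = simulate_metric_table(cohort, cfg)
        df = cohort.merge(mt, on="subject_id")
        sds = {}
        for c in ("C1", "C2"):
            sub = df[df["center_id"] == c]
            x = np.column_stack(
                [
                    np.ones(len(sub)),
                    (sub["sex"] == "M").astype(float),
                    sub["age_at_mri"] - 45,
                    (sub["sex"] == "M").astype(float) * (sub["age_at_mri"] - 45),
                ]
            )
            beta, *_ = np.linalg.lstsq(x, sub["density"], rcond=None)
            sds[c] = (sub["density"] - x @ beta).std()
        assert sds["C2"] / sds["C1"] == pytest.approx(2.0, rel=0.15)

    def test_unknown_metric_rejected(self):
        cfg = SimConfig(metric_effect_profile={"bogus": (1.0, 1.0)})
        with pytest.raises(ConfigurationError):
            simulate_cohort(cfg)

    def test_ranges(self, small_study):
        _, mt = small_study
        assert (mt["lv_ml"] >= 0).all()
        for col in ("inter_disc_pct", "intra_disc_pct"):
            assert mt[col].between(0, 100).all()
        for col in ("density", "commissural_ratio", "clustering"):
            assert mt[col].between(0, 1).all()


class TestParcellation:
    def test_four_nodes_two_per_hemisphere(self):
        parc = simulate_parcellation(4, (20, 20, 20), seed=1)
        counts = parc.node_table["hemisphere"].value_counts()
        assert counts["L"] == 2 and counts["R"] == 2
        # disjoint regions: every labeled voxel holds exactly one label
        assert set(np.unique(parc.labels)) == {0, 1, 2, 3, 4}

    def test_253_nodes(self):
        parc = simulate_parcellation(253, (40, 40, 40), seed=1)
        assert len(parc.node_table) == 253
        assert parc.node_table["hemisphere"].value_counts()["MID"] == 1

    def test_partition_property(self):
        parc = simulate_parcellation(10, (16, 16, 16), seed=2)
        labeled = parc.labels[parc.labels > 0]
        assert set(np.unique(labeled)) <= set(parc.node_table["node_id"])

    def test_capacity_error(self):
        with pytest.raises(ConfigurationError):
            simulate_parcellation(1000, (4, 4, 4), seed=0)

    def test_too_few_nodes(self):
        with pytest.raises(ConfigurationError):
            simulate_parcellation(1, (10, 10, 10), seed=0)


class TestTractogram:
    def test_zero_commissural_fraction(self):
        parc = simulate_parcellation(8, (16, 16, 16), seed=4)
        tract = simulate_tractogram(parc, 200, commissural_fraction=0.0, seed=5)
        hemi = dict(zip(parc.node_table["node_id"], parc.node_table["hemisphere"]))
        vs = parc.voxel_size
        for s in tract.streamlines:
            ends = [parc.labels[tuple(np.floor(p / vs).astype(int))] for p in (s[0], s[-1])]
            assert {hemi[e] for e in ends} in ({"L"}, {"R"})

    def test_commissural_fraction_sampled(self):
        parc = simulate_parcellation(8, (16, 16, 16), seed=4)
        tract = simulate_tractogram(parc, 1000, commissural_fraction=0.2, seed=6)
        hemi = dict(zip(parc.node_table["node_id"], parc.node_table["hemisphere"]))
        vs = parc.voxel_size
        crossing = 0
        for s in tract.streamlines:
            ends = [parc.labels[tuple(np.floor(p / vs).astype(int))] for p in (s[0], s[-1])]
            if {hemi[e] for e in ends} == {"L", "R"}:
                crossing += 1
        se = math.sqrt(0.2 * 0.8 / 1000)
        assert abs(crossing / 1000 - 0.2) < 3 * se

    def test_determinism(self):
        parc = simulate_parcellation(6, (12, 12, 12), seed=1)
        t1 = simulate_tractogram(parc, 50, 0.3, seed=7)
        t2 = simulate_tractogram(parc, 50, 0.3, seed=7)
        assert all(np.array_equal(a, b) for a, b in zip(t1.streamlines, t2.streamlines))
        np.testing.assert_array_equal(t1.fa, t2.fa)

    def test_fa_in_unit_interval(self):
        parc = simulate_parcellation(6, (12, 12, 12), seed=1)
        tract = simulate_tractogram(parc, 100, 0.5, seed=8)
        assert ((tract.fa > 0) & (tract.fa <= 1)).all()

    def test_bad_fraction(self):
        parc = simulate_parcellation(6, (12, 12, 12), seed=1)
        with pytest.raises(ConfigurationError):
            simulate_tractogram(parc, 10, 1.5, seed=0)


class TestLesions:
    def test_zero_target_empty(self):
        mask = simulate_lesions((16, 16, 16), 1.0, 0.0, seed=1)
        assert mask.lv_ml == 0.0
        assert not mask.mask.any()

    def test_unit_arithmetic(self):
        # 2000 voxels at 1 mm^3 = 2.0 mL
        m = np.zeros((20, 20, 20), dtype=bool)
        m.flat[:2000] = True
        assert LesionMask(mask=m, voxel_size=1.0).lv_ml == pytest.approx(2.0)

    def test_volume_near_target(self):
        target = 0.5
        n_foci = 5
        mask = simulate_lesions((30, 30, 30), 1.0, target, n_foci=n_foci, seed=3)
        assert abs(mask.lv_ml - target) <= 1.5 * target / n_foci

    def test_determinism(self):
        a = simulate_lesions((16, 16, 16), 1.0, 0.3, seed=9)
        b = simulate_lesions((16, 16, 16), 1.0, 0.3, seed=9)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_target_exceeding_grid(self):
        with pytest.raises(ConfigurationError):
            simulate_lesions((5, 5, 5), 1.0, 10.0, seed=0)


def test_simulate_study_deterministic(small_config):
    c1, m1 = simulate_study(small_config)
    c2, m2 = simulate_study(small_config)
    pd.testing.assert_frame_equal(c1, c2)
    pd.testing.assert_frame_equal(m1, m2)
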