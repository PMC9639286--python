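"""Generator contracts: atlas structure, cohort composition, image and
cognition models, and seeded determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from taucog.config import DOMAINS, GROUPS, ConfigError, SimulationConfig
from taucog.grids import SizingError
from taucog.synthetic import (
    generate_atlas,
    generate_cognition,
    generate_cohort,
    generate_subjects,
    generate_tau_volumes,
)


class TestAtlas:
    def test_all_region_classes_present(self, atlas20):
        atlas, maps = atlas20
        names = {info.name for info in atlas.label_dict.values()}
        assert {"background", "cerebellum", "subcortex", "hippocampus"} <= names
        present = set(np.unique(atlas.labels))
        assert all(lab in present for lab in atlas.label_dict)
        gm = atlas.cortical_gm_mask()
        for s in range(1, 7):
            assert (atlas.braak_mask({s}) & gm).any(), f"Braak stage {s} missing"
        for d in DOMAINS:
            m = maps[d].mask
            assert m.dtype == bool and (m & gm).any()

    def test_domain_maps_mutually_distinguishable(self, atlas20):
        _, maps = atlas20
        for a in range(4):
            for b in range(a + 1, 4):
                ma, mb = maps[DOMAINS[a]].mask, maps[DOMAINS[b]].mask
                jacc = (ma & mb).sum() / (ma | mb).sum()
                assert jacc < 1.0

    def test_seeded_determinism(self):
        a1, m1 = generate_atlas((10, 10, 10), seed=3)
        a2, m2 = generate_atlas((10, 10, 10), seed=3)
        assert np.array_equal(a1.labels, a2.labels)
        for d in DOMAINS:
            assert np.array_equal(m1[d].mask, m2[d].mask)

    def test_too_small_grid_raises(self):
        with pytest.raises(SizingError):
            generate_atlas((2, 2, 2), seed=0)
        with pytest.raises(SizingError):
            generate_atlas((20, 20, 7), seed=0)


class TestSubjects:
    def test_group_counts_and_exclusion_rule(self):
        cfg = SimulationConfig.adni_like()
        subs = generate_subjects(cfg)
        assert len(subs) == 261
        assert (subs["amyloid_status"] == "NEG").sum() == 121
        neg = subs[subs["amyloid_status"] == "NEG"]
        assert (neg["clinical_status"] == "CN").all()

    def test_dementia_only_cohort(self):
        cfg = SimulationConfig.adni_like(
            counts={"CN_NEG": 0, "CN_POS": 0, "MCI_POS": 0, "DEM_POS": 10}
        )
        subs = generate_subjects(cfg)
        assert len(subs) == 10
        assert (subs["clinical_status"] == "DEM").all()

    def test_burdens_positive_and_group_ordered(self):
        subs = generate_subjects(SimulationConfig.adni_like())
        bcols = [f"burden_{d}" for d in DOMAINS]
        assert (subs[bcols] >= 0).all().all()
        means = subs.groupby("group")[bcols].mean().mean(axis=1)
        assert (
            means["CN_NEG"] < means["CN_POS"] < means["MCI_POS"] < means["DEM_POS"]
        )

    def test_cross_domain_burden_correlation_positive(self):
        subs = generate_subjects(SimulationConfig.adni_like())
        mci = subs[subs["group"] == "MCI_POS"]
        corr = np.log(mci[[f"burden_{d}" for d in DOMAINS]]).corr().to_numpy()
        off = corr[~np.eye(4, dtype=bool)]
        assert (off > 0.2).all()

    def test_seeded_determinism(self):
        cfg = SimulationConfig.adni_like(seed=5)
        pd.testing.assert_frame_equal(generate_subjects(cfg), generate_subjects(cfg))

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig.adni_like(grid_dims=(4, 20, 20))
        with pytest.raises(ConfigError):
            SimulationConfig.adni_like(
                counts={"CN_NEG": -1, "CN_POS": 0, "MCI_POS": 0, "DEM_POS": 0}
            )


class TestTauVolumes:
    def _one_subject(self, burden):
        row = {
            "subject_id": "S0", "group": "CN_NEG", "clinical_status": "CN",
            "amyloid_status": "NEG", "age": 70.0, "sex": 0, "education": 16.0,
            "apoe4": 0,
        }
        row.update({f"burden_{d}": b for d, b in zip(DOMAINS, burden)})
        return pd.DataFrame([row])

    def test_zero_burden_matches_negative_distribution(self, atlas20, rng):
        atlas, maps = atlas20
        cfg = SimulationConfig.adni_like()
        vols = generate_tau_volumes(self._one_subject([0, 0, 0, 0]), atlas, maps, cfg)
        brain = atlas.brain_mask()
        vals = vols[0].values[brain]
        sample = rng.choice(vals, size=2000, replace=False)
        ref = rng.normal(cfg.suvr_neg_mean, cfg.suvr_neg_sd, size=2000)
        assert stats.ks_2samp(sample, ref).pvalue > 0.01

    def test_dementia_global_suvr_matches_target(self, atlas20):
        atlas, maps = atlas20
        cfg = SimulationConfig.adni_like(
            counts={"CN_NEG": 0, "CN_POS": 0, "MCI_POS": 0, "DEM_POS": 25}
        )
        subs = generate_subjects(cfg)
        vols = generate_tau_volumes(subs, atlas, maps, cfg)
        gm = atlas.cortical_gm_mask() & ~atlas.off_target_mask()
        mean = np.mean([v.values[gm].mean() for v in vols])
        assert abs(mean - 1.46) < 0.1

    def test_doubling_burden_raises_domain_mean(self, atlas20):
        atlas, maps = atlas20
        cfg = SimulationConfig.adni_like()
        subs = pd.concat(
            [self._one_subject([1, 0.5, 0.5, 0.5]), self._one_subject([2, 0.5, 0.5, 0.5])],
            ignore_index=True,
        )
        from taucog._rng import stage_rng

        # identical noise stream per subject: regenerate separately
        v1 = generate_tau_volumes(subs.iloc[[0]], atlas, maps, cfg, rng=stage_rng(0, "x"))[0]
        v2 = generate_tau_volumes(subs.iloc[[1]], atlas, maps, cfg, rng=stage_rng(0, "x"))[0]
        mem = maps["MEM"].mask
        assert v2.values[mem].mean() > v1.values[mem].mean()

    def test_all_values_positive(self, small_cohort):
        for v in small_cohort.volumes[:10]:
            brain = small_cohort.atlas.brain_mask()
            assert (v.values[brain] > 0).all()

    def test_group_mean_global_suvr_increases_with_severity(self, small_cohort):
        atlas = small_cohort.atlas
        gm = atlas.cortical_gm_mask() & ~atlas.off_target_mask()
        means = {}
        subs = small_cohort.subjects
        by_id = {v.subject_id: v for v in small_cohort.volumes}
        for g in GROUPS:
            ids = subs[subs["group"] == g]["subject_id"]
            means[g] = np.mean([by_id[i].values[gm].mean() for i in ids])
        assert means["CN_NEG"] < means["CN_POS"] < means["MCI_POS"] < means["DEM_POS"]


class TestCognition:
    def test_noiseless_observations_reproduce_true_slope(self):
        cfg = SimulationConfig.adni_like(
            counts={"CN_NEG": 5, "CN_POS": 0, "MCI_POS": 0, "DEM_POS": 5},
            score_residual_sd={d: 0.0 for d in DOMAINS},
            dropout_last_visit=0.0,
        )
        subs = generate_subjects(cfg)
        cog, truth = generate_cognition(subs, cfg)
        for (sid, d), g in cog.groupby(["subject_id", "domain"]):
            slope = np.polyfit(g["time"], g["score"], 1)[0]
            true = truth[(truth.subject_id == sid) & (truth.domain == d)]["true_slope"].iloc[0]
            assert abs(slope - true) < 1e-10

    def test_dementia_memory_decline_matches_target(self):
        cfg = SimulationConfig.adni_like()
        subs = generate_subjects(cfg)
        _, truth = generate_cognition(subs, cfg)
        dem = subs[subs["group"] == "DEM_POS"]["subject_id"]
        mem = truth[(truth["domain"] == "MEM") & truth["subject_id"].isin(dem)]
        assert abs(mem["true_slope"].mean() - (-0.179)) < 0.04

    def test_group_change_rate_means_within_2se_of_targets(self):
        cfg = SimulationConfig.adni_like()
        subs = generate_subjects(cfg)
        _, truth = generate_cognition(subs, cfg)
        tr = truth.merge(subs[["subject_id", "group"]], on="subject_id")
        gm = tr.groupby(["domain", "group"])["true_slope"].mean()
        for d in DOMAINS:
            for g in GROUPS:
                target = cfg.slope_mean[d][g]
                se2 = 2 * cfg.slope_sd[d][g] / np.sqrt(cfg.counts[g])
                assert abs(gm[(d, g)] - target) <= se2, (d, g)

    def test_zero_coupling_decouples_burden_and_slope(self):
        cfg = SimulationConfig.adni_like(
            counts={"CN_NEG": 0, "CN_POS": 0, "MCI_POS": 200, "DEM_POS": 0},
            coupling={d: 0.0 for d in DOMAINS},
        )
        subs = generate_subjects(cfg)
        _, truth = generate_cognition(subs, cfg)
        m = truth[truth["domain"] == "MEM"].merge(subs, on="subject_id")
        r, p = stats.pearsonr(m["burden_MEM"], m["true_slope"])
        assert p > 0.05

    def test_visit_schedule_invariants(self, small_cohort):
        cog = small_cohort.cognition
        per = cog.groupby(["subject_id", "domain"])["time"]
        assert (per.nunique() >= 2).all()
        assert (per.min() == 0.0).all()

    def test_seeded_determinism_end_to_end(self, small_config):
        c1 = generate_cohort(small_config)
        c2 = generate_cohort(small_config)
        pd.testing.assert_frame_equal(c1.cognition, c2.cognition)
        assert np.array_equal(c1.volumes[0].values, c2.volumes[0].values)
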