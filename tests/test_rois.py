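"""ROI construction, voxel-wise mixture fitting, TPP transform, extraction."""

import numpy as np
import pytest

from taucog.grids import DomainMap, GridMismatchError, LabelInfo, RegionAtlas, TauVolume
from taucog.rois import (
    CoverageError,
    GmmConfig,
    RoiConstructionError,
    SampleSizeError,
    VoxelMixtureModel,
    build_domain_roi,
    build_global_roi,
    build_temporal_roi,
    fit_voxel_gmm,
    tpp_transform,
    extract_roi_signal,
)

GM1 = 11  # cortical GM, Braak 1
GM2 = 12  # cortical GM, Braak 2
HIP = 3


def tiny_atlas(labels: np.ndarray) -> RegionAtlas:
    return RegionAtlas(
        labels,
        {
            0: LabelInfo("background"),
            HIP: LabelInfo("hippocampus", off_target=True),
            GM1: LabelInfo("gm_braak1", cortical_gm=True, braak_stage=1),
            GM2: LabelInfo("gm_braak2", cortical_gm=True, braak_stage=2),
            13: LabelInfo("gm_braak3", cortical_gm=True, braak_stage=3),
        },
    )


class TestRoiConstruction:
    def test_map_inside_gm_equals_map_support(self):
        labels = np.full((4, 4, 4), GM1, dtype=int)
        atlas = tiny_atlas(labels)
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        roi = build_domain_roi(DomainMap("MEM", mask), atlas)
        assert np.array_equal(roi.mask(), mask)

    def test_hippocampal_voxels_excluded(self):
        labels = np.full((4, 4, 4), GM1, dtype=int)
        labels[0, :, :] = HIP
        atlas = tiny_atlas(labels)
        mask = np.ones((4, 4, 4), dtype=bool)
        roi = build_domain_roi(DomainMap("LAN", mask), atlas)
        assert not roi.mask()[0].any()
        assert roi.mask()[1:].all()

    def test_map_disjoint_from_gm_raises(self):
        labels = np.full((4, 4, 4), GM1, dtype=int)
        labels[0, :, :] = HIP
        atlas = tiny_atlas(labels)
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0, :, :] = True  # only off-target voxels
        with pytest.raises(RoiConstructionError):
            build_domain_roi(DomainMap("EF", mask), atlas)

    def test_grid_mismatch_raises(self):
        atlas = tiny_atlas(np.full((4, 4, 4), GM1, dtype=int))
        with pytest.raises(GridMismatchError):
            build_domain_roi(DomainMap("VS", np.ones((5, 4, 4), dtype=bool)), atlas)

    def test_global_roi_hand_count(self):
        labels = np.full((4, 4, 4), 0, dtype=int)
        labels[:2] = GM1
        labels[2] = GM2
        labels[3] = HIP
        atlas = tiny_atlas(labels)
        roi = build_global_roi(atlas)
        assert len(roi) == 3 * 16  # brute-force: 3 of 4 x-slabs are GM
        assert not roi.mask()[3].any()

    def test_temporal_roi_stage_membership(self):
        labels = np.full((4, 4, 4), GM2, dtype=int)
        labels[0] = GM1
        labels[1] = 13  # Braak 3
        atlas = tiny_atlas(labels)
        roi = build_temporal_roi(atlas)
        m = roi.mask()
        assert m[0].all() and m[1].all()
        assert not m[2:].any()  # stage 2 excluded

    def test_temporal_only_stage2_raises(self):
        atlas = tiny_atlas(np.full((4, 4, 4), GM2, dtype=int))
        with pytest.raises(RoiConstructionError):
            build_temporal_roi(atlas)

    def test_off_target_excluded_from_every_roi(self, atlas20):
        atlas, maps = atlas20
        off = atlas.off_target_mask()
        from taucog.rois import build_all_rois

        for roi in build_all_rois(atlas, maps).values():
            assert not (roi.mask() & off).any()


def _volumes_from_matrix(data: np.ndarray) -> list:
    """(n_subjects, n_voxels) -> TauVolumes on an (n_voxels,1,1) grid."""
    n, m = data.shape
    return [TauVolume(f"S{i}", data[i].reshape(m, 1, 1)) for i in range(n)]


class TestVoxelGmm:
    def test_recovers_known_mixture(self, rng):
        n = 1000
        comp = rng.random(n) < 0.4
        x = np.where(comp, rng.normal(1.5, 0.10, n), rng.normal(1.0, 0.05, n))
        vols = _volumes_from_matrix(x[:, None])
        fit = fit_voxel_gmm(vols, np.array([0]))
        assert fit.informative[0]
        assert abs(fit.mu1[0] - 1.0) <= 0.02
        assert abs(fit.mu2[0] - 1.5) <= 0.02
        assert abs(fit.w2[0] - 0.4) <= 0.05
        assert abs(fit.w1[0] + fit.w2[0] - 1.0) < 1e-9

    def test_agrees_with_sklearn_on_one_voxel(self, rng):
        sklearn = pytest.importorskip("sklearn.mixture")
        n = 800
        comp = rng.random(n) < 0.5
        x = np.where(comp, rng.normal(2.0, 0.15, n), rng.normal(1.1, 0.08, n))
        fit = fit_voxel_gmm(_volumes_from_matrix(x[:, None]), np.array([0]))
        gm = sklearn.GaussianMixture(2, tol=1e-8, max_iter=500, random_state=0).fit(
            x[:, None]
        )
        ref = np.sort(gm.means_.ravel())
        assert abs(fit.mu1[0] - ref[0]) < 0.02
        assert abs(fit.mu2[0] - ref[1]) < 0.02

    def test_parameter_recovery_over_many_voxels(self, rng):
        # separation >= 3 sigma at n=500 subjects: median |d mu2| < 0.02
        n_sub, n_vox = 500, 100
        mu2_true = rng.uniform(1.4, 1.8, n_vox)
        data = np.empty((n_sub, n_vox))
        for j in range(n_vox):
            comp = rng.random(n_sub) < 0.4
            data[:, j] = np.where(
                comp, rng.normal(mu2_true[j], 0.1, n_sub), rng.normal(1.0, 0.05, n_sub)
            )
        fit = fit_voxel_gmm(_volumes_from_matrix(data), np.arange(n_vox))
        err = np.abs(fit.mu2 - mu2_true)[fit.informative]
        assert np.median(err) < 0.02

    def test_identical_values_flagged_non_informative(self):
        data = np.full((100, 1), 1.2)
        fit = fit_voxel_gmm(_volumes_from_matrix(data), np.array([0]))
        assert not fit.informative[0]

    def test_loglik_nondecreasing(self, rng):
        n = 300
        comp = rng.random(n) < 0.5
        x = np.where(comp, rng.normal(1.6, 0.1, n), rng.normal(1.0, 0.07, n))
        fit = fit_voxel_gmm(
            _volumes_from_matrix(x[:, None]), np.array([0]), keep_history=True
        )
        hist = fit.loglik_history[:, 0]
        hist = hist[np.isfinite(hist)]
        assert (np.diff(hist) >= -1e-9).all()

    def test_too_few_subjects_raises(self, rng):
        vols = _volumes_from_matrix(rng.normal(1, 0.1, (10, 3)))
        with pytest.raises(SampleSizeError):
            fit_voxel_gmm(vols, np.arange(3))


def symmetric_model() -> VoxelMixtureModel:
    one = np.array([0.5])
    return VoxelMixtureModel(
        voxel_indices=np.array([0]),
        shape=(1, 1, 1),
        w1=one, w2=one,
        mu1=np.array([1.0]), mu2=np.array([1.6]),
        sd1=np.array([0.1]), sd2=np.array([0.1]),
        informative=np.array([True]),
        converged=np.array([True]),
    )


class TestTppTransform:
    @pytest.mark.parametrize(
        "x,expected,tol",
        [
            (1.3, 0.5, 1e-12),
            (1.0, 1.522998e-08, 1e-13),  # density ratio exp(-18)/(1+exp(-18))
            (1.6, 1 - 1.522998e-08, 1e-13),
        ],
    )
    def test_symmetric_model_values(self, x, expected, tol):
        vol = TauVolume("s", np.array([[[x]]]))
        out = tpp_transform(vol, symmetric_model())
        assert abs(out.values[0, 0, 0] - expected) < tol

    def test_monotone_in_suvr(self):
        model = symmetric_model()
        xs = np.linspace(0.5, 2.5, 101)
        tpps = [
            tpp_transform(TauVolume("s", np.array([[[x]]])), model).values[0, 0, 0]
            for x in xs
        ]
        assert (np.diff(tpps) >= 0).all()
        assert all(0.0 <= t <= 1.0 for t in tpps)

    def test_non_informative_voxel_is_missing(self):
        model = symmetric_model()
        model.informative = np.array([False])
        out = tpp_transform(TauVolume("s", np.array([[[1.3]]])), model)
        assert np.isnan(out.values[0, 0, 0])

    def test_grid_mismatch_raises(self):
        with pytest.raises(GridMismatchError):
            tpp_transform(TauVolume("s", np.ones((2, 1, 1))), symmetric_model())


class TestExtractSignal:
    def _roi(self, shape, idx):
        from taucog.rois import RoiDefinition

        return RoiDefinition("MEM", np.asarray(idx), shape)

    def test_constant_volume_mean(self):
        vol = TauVolume("s", np.full((3, 3, 3), 1.2))
        roi = self._roi((3, 3, 3), [0, 5, 13])
        assert extract_roi_signal(vol, roi, "SUVR") == pytest.approx(1.2)

    def test_hand_computed_mean(self):
        vals = np.zeros((2, 2, 2))
        vals.reshape(-1)[[1, 3, 6]] = [0.2, 0.4, 0.9]
        vol = TauVolume("s", vals)
        roi = self._roi((2, 2, 2), [1, 3, 6])
        assert extract_roi_signal(vol, roi, "SUVR") == pytest.approx(0.5)

    def test_tpp_all_ones(self):
        vol = TauVolume("s", np.ones((2, 2, 2)))
        roi = self._roi((2, 2, 2), [0, 1, 2])
        assert extract_roi_signal(vol, roi, "TPP") == pytest.approx(1.0)

    def test_tpp_coverage_error(self):
        vals = np.full((2, 2, 2), np.nan)
        vals.reshape(-1)[0] = 0.5
        vol = TauVolume("s", vals)
        roi = self._roi((2, 2, 2), [0, 1, 2, 3])
        with pytest.raises(CoverageError):
            extract_roi_signal(vol, roi, "TPP")

    def test_tpp_drops_missing_voxels(self):
        vals = np.full((2, 2, 2), np.nan)
        vals.reshape(-1)[[0, 1, 2]] = [0.2, 0.4, 0.6]
        vol = TauVolume("s", vals)
        roi = self._roi((2, 2, 2), [0, 1, 2, 3])
        assert extract_roi_signal(vol, roi, "TPP") == pytest.approx(0.4)


class TestSignalConsistency:
    def test_suvr_and_tpp_signals_rank_correlated(self, small_cohort):
        """Domain signal in raw-SUVR and mixture-transformed modes must agree
        in rank on a burden-coupled cohort (the SUVR sensitivity analysis)."""
        from scipy import stats

        from taucog.rois import build_all_rois, extract_signal_table

        coh = small_cohort
        rois = build_all_rois(coh.atlas, coh.domain_maps)
        union = np.unique(np.concatenate([r.voxel_indices for r in rois.values()]))
        fit = fit_voxel_gmm(coh.volumes, union)
        suvr = extract_signal_table(coh.volumes, rois, mode="SUVR")
        tpp = extract_signal_table(coh.volumes, rois, mode="TPP", models=fit)
        for roi in ("MEM", "GLOBAL"):
            a = suvr[suvr.roi == roi].set_index("subject_id")["value"]
            b = tpp[tpp.roi == roi].set_index("subject_id")["value"]
            rho = stats.spearmanr(a, b.loc[a.index])[0]
            assert rho > 0.8
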