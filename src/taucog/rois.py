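"""Tau-PET regions of interest and the tau-positivity-probability transform.

Six ROIs are used: the four cognitive-domain masks intersected with
cortical gray matter (minus flortaucipir off-target regions: hippocampus,
subcortex, cerebellum), a global neocortical ROI, and a temporal-lobe ROI
built from Braak-stage 1/3/4 regions.

To suppress residual off-target signal, per-voxel SUVR samples across the
cohort are modelled as a two-component Gaussian mixture (tau-negative vs
tau-positive subpopulations); a subject's tau-positivity probability (TPP)
at a voxel is the posterior probability of the higher-mean component. ROI
signal is the arithmetic mean over the ROI's voxels, of SUVR directly or of
TPP at voxels where the mixture is informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import DomainMap, RegionAtlas, TauVolume, check_same_grid


class RoiConstructionError(ValueError):
    """ROI would be empty after masking."""


class SampleSizeError(ValueError):
    """Too few subjects to fit the voxel-wise mixture."""


class CoverageError(ValueError):
    """Too few informative voxels inside an ROI for a TPP mean."""


@dataclass(frozen=True)
class RoiDefinition:
    """A named set of voxels, stored as flat indices into the grid."""

    name: str
    voxel_indices: np.ndarray  # flat indices (C order)
    shape: tuple

    def __len__(self) -> int:
        return int(self.voxel_indices.size)

    def mask(self) -> np.ndarray:
        m = np.zeros(int(np.prod(self.shape)), dtype=bool)
        m[self.voxel_indices] = True
        return m.reshape(self.shape)


def _finalize(name: str, mask: np.ndarray, atlas: RegionAtlas) -> RoiDefinition:
    mask = mask & ~atlas.off_target_mask()
    idx = np.flatnonzero(mask.reshape(-1))
    if idx.size == 0:
        raise RoiConstructionError(f"ROI {name!r} is empty after off-target masking")
    return RoiDefinition(name, idx, tuple(atlas.shape))


def build_domain_roi(domain_map: DomainMap, atlas: RegionAtlas) -> RoiDefinition:
    """Domain mask ∩ cortical gray matter, minus off-target regions."""
    check_same_grid(domain_map, atlas)
    return _finalize(domain_map.domain, domain_map.mask & atlas.cortical_gm_mask(), atlas)


def build_global_roi(atlas: RegionAtlas) -> RoiDefinition:
    """All cortical gray matter minus off-target regions."""
    return _finalize("GLOBAL", atlas.cortical_gm_mask(), atlas)


def build_temporal_roi(atlas: RegionAtlas) -> RoiDefinition:
    """Braak-stage 1, 3 and 4 regions minus off-target regions.

    (Stage-1 voxels that carry an off-target label, e.g. hippocampus, are
    excluded: off-target exclusion takes precedence.)
    """
    return _finalize("TEMPORAL", atlas.braak_mask({1, 3, 4}), atlas)


def build_all_rois(atlas: RegionAtlas, domain_maps: dict) -> dict:
    rois = {d: build_domain_roi(m, atlas) for d, m in domain_maps.items()}
    rois["GLOBAL"] = build_global_roi(atlas)
    rois["TEMPORAL"] = build_temporal_roi(atlas)
    return rois


# ---------------------------------------------------------------------------
# voxel-wise two-component Gaussian mixture


@dataclass
class GmmConfig:
    min_subjects: int = 50
    tol: float = 1e-8
    max_iter: int = 500
    sd_floor: float = 1e-3
    separation_threshold: float = 0.05  # SUVR units between component means
    weight_floor: float = 0.01


@dataclass
class VoxelMixtureModel:
    """Fitted per-voxel mixtures over a set of retained voxels."""

    voxel_indices: np.ndarray  # flat indices into the grid
    shape: tuple
    w1: np.ndarray
    w2: np.ndarray
    mu1: np.ndarray
    mu2: np.ndarray
    sd1: np.ndarray
    sd2: np.ndarray
    informative: np.ndarray  # bool per voxel
    converged: np.ndarray
    loglik_history: np.ndarray | None = field(default=None, repr=False)


def _normal_pdf(x, mu, sd):
    z = (x - mu) / sd
    return np.exp(-0.5 * z * z) / (np.sqrt(2.0 * np.pi) * sd)


def fit_voxel_gmm(
    volumes: list[TauVolume],
    roi_union: np.ndarray,
    config: GmmConfig | None = None,
    keep_history: bool = False,
) -> VoxelMixtureModel:
    """Fit a 1-D two-component Gaussian mixture per voxel, across subjects.

    EM is vectorised over voxels: every voxel in `roi_union` (flat indices
    or boolean mask) gets its own mixture fitted on the across-subject SUVR
    sample. Components are sorted by mean; a voxel is flagged
    non-informative when the fit did not converge, the means are closer
    than the separation threshold, or a component weight is negligible.
    """
    cfg = config or GmmConfig()
    if len(volumes) < cfg.min_subjects:
        raise SampleSizeError(
            f"{len(volumes)} subjects < required minimum {cfg.min_subjects}"
        )
    check_same_grid(*volumes)
    shape = tuple(volumes[0].shape)
    if roi_union.dtype == bool:
        vox = np.flatnonzero(roi_union.reshape(-1))
    else:
        vox = np.asarray(roi_union, dtype=int).reshape(-1)

    data = np.stack([v.values.reshape(-1)[vox] for v in volumes])  # (n_sub, n_vox)
    n, m = data.shape

    sample_sd = data.std(axis=0, ddof=1)
    q25, q75 = np.percentile(data, [25, 75], axis=0)
    degenerate = (sample_sd < cfg.sd_floor) | (q75 - q25 <= 0)

    mu1 = q25.copy()
    mu2 = q75.copy()
    sd1 = np.maximum(sample_sd / 2.0, cfg.sd_floor)
    sd2 = sd1.copy()
    w1 = np.full(m, 0.5)
    w2 = np.full(m, 0.5)

    active = ~degenerate
    converged = np.zeros(m, dtype=bool)
    last_ll = np.full(m, -np.inf)
    history = [] if keep_history else None

    for _ in range(cfg.max_iter):
        if not active.any():
            break
        a = active
        p1 = w1[a] * _normal_pdf(data[:, a], mu1[a], sd1[a])
        p2 = w2[a] * _normal_pdf(data[:, a], mu2[a], sd2[a])
        tot = p1 + p2
        tot = np.maximum(tot, 1e-300)
        r2 = p2 / tot
        r1 = 1.0 - r2

        ll = np.log(tot).sum(axis=0)
        improved = ll - last_ll[a]
        newly_conv = improved < cfg.tol
        if history is not None:
            full_ll = last_ll.copy()
            full_ll[a] = ll
            history.append(full_ll)
        last_ll[a] = ll

        n1 = r1.sum(axis=0)
        n2 = r2.sum(axis=0)
        n1 = np.maximum(n1, 1e-12)
        n2 = np.maximum(n2, 1e-12)
        m1 = (r1 * data[:, a]).sum(axis=0) / n1
        m2 = (r2 * data[:, a]).sum(axis=0) / n2
        v1 = (r1 * (data[:, a] - m1) ** 2).sum(axis=0) / n1
        v2 = (r2 * (data[:, a] - m2) ** 2).sum(axis=0) / n2
        mu1[a], mu2[a] = m1, m2
        sd1[a] = np.maximum(np.sqrt(v1), cfg.sd_floor)
        sd2[a] = np.maximum(np.sqrt(v2), cfg.sd_floor)
        w1[a] = n1 / n
        w2[a] = n2 / n

        conv_idx = np.flatnonzero(a)[newly_conv]
        converged[conv_idx] = True
        active[conv_idx] = False

    # sort components by mean
    swap = mu1 > mu2
    for lo, hi in ((mu1, mu2), (sd1, sd2), (w1, w2)):
        lo[swap], hi[swap] = hi[swap], lo[swap].copy()

    informative = (
        converged
        & ~degenerate
        & ((mu2 - mu1) >= cfg.separation_threshold)
        & (np.minimum(w1, w2) >= cfg.weight_floor)
    )
    return VoxelMixtureModel(
        voxel_indices=vox,
        shape=shape,
        w1=w1,
        w2=w2,
        mu1=mu1,
        mu2=mu2,
        sd1=sd1,
        sd2=sd2,
        informative=informative,
        converged=converged,
        loglik_history=np.array(history) if history is not None else None,
    )


def tpp_transform(volume: TauVolume, models: VoxelMixtureModel) -> TauVolume:
    """Posterior probability of the tau-positive (higher-mean) component.

    Non-informative voxels — and voxels outside the modelled set — are NaN
    (missing). Output values lie in [0, 1].
    """
    if tuple(volume.shape) != tuple(models.shape):
        from .grids import GridMismatchError

        raise GridMismatchError("volume grid does not match fitted mixture grid")
    out = np.full(volume.shape, np.nan)
    inf = models.informative
    vox = models.voxel_indices[inf]
    x = volume.values.reshape(-1)[vox]
    p1 = models.w1[inf] * _normal_pdf(x, models.mu1[inf], models.sd1[inf])
    p2 = models.w2[inf] * _normal_pdf(x, models.mu2[inf], models.sd2[inf])
    tpp = p2 / np.maximum(p1 + p2, 1e-300)
    flat = out.reshape(-1)
    flat[vox] = np.clip(tpp, 0.0, 1.0)
    return TauVolume(volume.subject_id, out, volume.affine.copy())


def extract_roi_signal(
    volume: TauVolume,
    roi: RoiDefinition,
    mode: str = "SUVR",
    min_coverage: float = 0.5,
) -> float:
    """Mean signal across the ROI's voxels.

    SUVR mode averages all ROI voxels; TPP mode drops missing voxels and
    requires at least `min_coverage` of the ROI to be informative.
    """
    if tuple(volume.shape) != tuple(roi.shape):
        from .grids import GridMismatchError

        raise GridMismatchError("volume grid does not match ROI grid")
    vals = volume.values.reshape(-1)[roi.voxel_indices]
    if mode.upper() == "SUVR":
        return float(vals.mean())
    if mode.upper() == "TPP":
        ok = ~np.isnan(vals)
        if ok.mean() < min_coverage:
            raise CoverageError(
                f"ROI {roi.name!r}: only {ok.mean():.0%} informative voxels "
                f"(< {min_coverage:.0%})"
            )
        return float(vals[ok].mean())
    raise ValueError(f"unknown mode {mode!r}")


def extract_signal_table(
    volumes: list[TauVolume],
    rois: dict,
    mode: str = "TPP",
    models: VoxelMixtureModel | None = None,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Per-subject per-ROI signals as a long table.

    In TPP mode, volumes are transformed through the fitted mixtures first.
    """
    mode = mode.upper()
    rows = []
    for vol in volumes:
        target = tpp_transform(vol, models) if mode == "TPP" else vol
        for name, roi in rois.items():
            val = extract_roi_signal(target, roi, mode=mode, min_coverage=min_coverage)
            rows.append(
                {"subject_id": vol.subject_id, "roi": name, "mode": mode, "value": val}
            )
    return pd.DataFrame(rows)
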