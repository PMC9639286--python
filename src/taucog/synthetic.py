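"""Synthetic cohort generator.

Emulates the data the tau-PET analysis consumes: a region atlas with
cortical gray matter, off-target (hippocampus / subcortex / cerebellum) and
Braak-stage labels; four binary cognitive-domain activation masks standing
in for meta-analytic task-fMRI maps; per-subject SUVR volumes whose signal
inside a domain's regions scales with that subject's latent tau burden for
the domain; and longitudinal domain composites whose annual slope couples
to the same latent burden. Everything is driven by one seed through named
substreams, so outputs are bit-reproducible.

Amyloid-negative subjects are controls by construction (the cohorts exclude
amyloid-negative cognitive impairment), and tau burden rises with clinical
severity, so downstream group contrasts have the expected ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .config import DOMAINS, GROUPS, SimulationConfig
from .grids import (
    DomainMap,
    LabelInfo,
    RegionAtlas,
    SizingError,
    TauVolume,
    check_same_grid,
)

# atlas labels
LAB_BACKGROUND = 0
LAB_CEREBELLUM = 1
LAB_SUBCORTEX = 2
LAB_HIPPOCAMPUS = 3
LAB_GM_BRAAK = {s: 10 + s for s in range(1, 7)}  # cortical GM, Braak stage s

_LABEL_DICT = {
    LAB_BACKGROUND: LabelInfo("background"),
    LAB_CEREBELLUM: LabelInfo("cerebellum", off_target=True),
    LAB_SUBCORTEX: LabelInfo("subcortex", off_target=True),
    LAB_HIPPOCAMPUS: LabelInfo("hippocampus", off_target=True),
    **{
        lab: LabelInfo(f"cortical_gm_braak{s}", cortical_gm=True, braak_stage=s)
        for s, lab in LAB_GM_BRAAK.items()
    },
}

GROUP_TO_STATUS = {
    "CN_NEG": ("CN", "NEG"),
    "CN_POS": ("CN", "POS"),
    "MCI_POS": ("MCI", "POS"),
    "DEM_POS": ("DEM", "POS"),
}

# domain-map inclusion probabilities: each cortical voxel has one "home"
# domain; Braak-1/3/4 (temporal) voxels are enriched so temporal tau runs
# above the global mean, as in real flortaucipir data.
_P_HOME_TEMPORAL = 0.90
_P_HOME_OTHER = 0.80
_P_CROSS_TEMPORAL = 0.07
_P_CROSS_OTHER = 0.05
_P_HIPPOCAMPUS_OVERLAP = 0.30  # activation maps do overlap off-target anatomy


def generate_atlas(grid_dims, seed: int):
    """Build the region atlas and four binary domain maps on one grid.

    The anatomy is schematic: a one-voxel background shell, a basal
    cerebellar slab, a central subcortical core with an adjacent
    hippocampal block, and a cortical remainder split into six Braak-stage
    shells ordered by distance from the hippocampus. Domain maps are seeded
    random voxel sets over cortical GM (spatial contiguity is irrelevant to
    ROI means) with deliberate hippocampal overlap to exercise off-target
    exclusion downstream.

    Returns (RegionAtlas, {domain: DomainMap}).
    """
    nx, ny, nz = (int(v) for v in grid_dims)
    if min(nx, ny, nz) < 8:
        raise SizingError(f"grid {grid_dims} too small: every dimension must be >= 8")

    labels = np.full((nx, ny, nz), LAB_BACKGROUND, dtype=np.int16)
    interior = np.zeros_like(labels, dtype=bool)
    interior[1:-1, 1:-1, 1:-1] = True

    # cerebellum: bottom slab of the interior
    zc = 1 + max(1, (nz - 2) // 5)
    ii, jj, kk = np.indices(labels.shape)
    cereb = interior & (kk < zc)
    labels[cereb] = LAB_CEREBELLUM

    # subcortex: central box of the cerebrum
    cerebrum = interior & ~cereb
    x0, x1 = nx // 2 - max(1, nx // 6), nx // 2 + max(1, nx // 6)
    y0, y1 = ny // 2 - max(1, ny // 6), ny // 2 + max(1, ny // 6)
    zmid0 = zc + (nz - 1 - zc) // 3
    zmid1 = zmid0 + max(2, (nz - 1 - zc) // 3)
    sub = cerebrum & (ii >= x0) & (ii < x1) & (jj >= y0) & (jj < y1) & (kk >= zmid0) & (kk < zmid1)
    labels[sub] = LAB_SUBCORTEX

    # hippocampus: small block just below the subcortical core
    hip = (
        cerebrum
        & (ii >= x0)
        & (ii < min(x1, x0 + 2))
        & (jj >= y0)
        & (jj < min(y1, y0 + 2))
        & (kk >= max(zc, zmid0 - 2))
        & (kk < zmid0)
    )
    labels[hip] = LAB_HIPPOCAMPUS

    gm = cerebrum & (labels == LAB_BACKGROUND)
    if not (cereb.any() and sub.any() and hip.any() and gm.sum() >= 12):
        raise SizingError("grid too small to place all region classes")

    # Braak stages 1..6: cortical voxels ranked by distance to hippocampus
    gm_idx = np.argwhere(gm)
    hip_center = np.argwhere(hip).mean(axis=0)
    dist = np.linalg.norm(gm_idx - hip_center, axis=1)
    order = np.argsort(dist, kind="stable")
    chunks = np.array_split(order, 6)
    for stage, chunk in enumerate(chunks, start=1):
        sel = gm_idx[chunk]
        labels[sel[:, 0], sel[:, 1], sel[:, 2]] = LAB_GM_BRAAK[stage]

    atlas = RegionAtlas(labels, dict(_LABEL_DICT))

    # domain maps
    rng = stage_rng(seed, "domain_maps")
    gm_mask = atlas.cortical_gm_mask()
    temporal = atlas.braak_mask({1, 3, 4}) & gm_mask
    n_gm = int(gm_mask.sum())
    home = rng.integers(0, 4, size=n_gm)
    u = rng.random((n_gm, 4))
    is_temp = temporal[gm_mask]
    maps = {}
    for d_idx, domain in enumerate(DOMAINS):
        p_home = np.where(is_temp, _P_HOME_TEMPORAL, _P_HOME_OTHER)
        p_cross = np.where(is_temp, _P_CROSS_TEMPORAL, _P_CROSS_OTHER)
        p = np.where(home == d_idx, p_home, p_cross)
        mask = np.zeros(labels.shape, dtype=bool)
        mask[gm_mask] = u[:, d_idx] < p
        # partial overlap with hippocampal off-target anatomy
        hip_u = rng.random(int(hip.sum()))
        mask[hip] = hip_u < _P_HIPPOCAMPUS_OVERLAP
        maps[domain] = DomainMap(domain, mask, atlas.affine.copy())

    for d in DOMAINS:
        if not (maps[d].mask & gm_mask).any():
            raise SizingError(f"domain map {d} empty within cortical GM")
    for a in range(4):
        for b in range(a + 1, 4):
            ma, mb = maps[DOMAINS[a]].mask, maps[DOMAINS[b]].mask
            if (ma & mb).sum() == (ma | mb).sum():
                raise SizingError("degenerate identical domain maps; enlarge the grid")
    return atlas, maps


def generate_subjects(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the baseline subject table with latent per-domain tau burdens.

    Burdens are lognormal with a group-specific mean (rising CN -> dementia)
    and a shared cross-domain correlation on the log scale.
    """
    config.validate()
    if rng is None:
        rng = stage_rng(config.seed, "subjects")
    rho = config.burden_rho
    corr = np.full((4, 4), rho) + np.eye(4) * (1.0 - rho)
    chol = np.linalg.cholesky(corr)

    rows = []
    idx = 0
    for group in GROUPS:
        n = int(config.counts.get(group, 0))
        status, amyloid = GROUP_TO_STATUS[group]
        mu = config.burden_log_mu(group)
        for _ in range(n):
            age = float(
                np.clip(
                    rng.normal(config.age_mean[group], config.age_sd[group]),
                    *config.age_range,
                )
            )
            sex = int(rng.random() < config.female_frac[group])
            edu = float(
                np.clip(rng.normal(config.education_mean[group], config.education_sd[group]), 6, 24)
            )
            apoe4 = int(rng.random() < config.apoe4_frac[group])
            z = chol @ rng.standard_normal(4)
            burden = np.minimum(np.exp(mu + config.burden_log_sigma * z), config.burden_cap)
            rows.append(
                {
                    "subject_id": f"{config.subject_prefix}{idx:04d}",
                    "group": group,
                    "clinical_status": status,
                    "amyloid_status": amyloid,
                    "age": age,
                    "sex": sex,
                    "education": edu,
                    "apoe4": apoe4,
                    **{f"burden_{d}": float(b) for d, b in zip(DOMAINS, burden)},
                }
            )
            idx += 1
    return pd.DataFrame(rows)


def generate_tau_volumes(
    subjects: pd.DataFrame,
    atlas: RegionAtlas,
    domain_maps: dict,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[TauVolume]:
    """Simulate one SUVR volume per subject.

    In-brain voxels are i.i.d. Normal(mu_neg, sd_neg) noise around the
    tau-negative level, plus, inside each domain map, an elevation
    proportional to the subject's latent burden for that domain. Values are
    clipped at a small positive floor (SUVR is a strictly positive ratio).
    """
    check_same_grid(atlas, *domain_maps.values())
    if rng is None:
        rng = stage_rng(config.seed, "tau_volumes")
    brain = atlas.brain_mask()
    h = float(config.elevation_heterogeneity)
    gain = rng.uniform(1.0 - h, 1.0 + h, size=atlas.shape)
    elev = np.zeros(atlas.shape)
    volumes = []
    for _, row in subjects.iterrows():
        elev[:] = 0.0
        for d in DOMAINS:
            elev[domain_maps[d].mask] += config.elevation_per_burden * row[f"burden_{d}"]
        elev *= gain
        vals = np.zeros(atlas.shape)
        noise = rng.normal(config.suvr_neg_mean, config.suvr_neg_sd, size=atlas.shape)
        vals[brain] = noise[brain] + elev[brain]
        np.clip(vals, 0.0, None, out=vals)
        vals[brain] = np.maximum(vals[brain], config.suvr_floor)
        volumes.append(TauVolume(str(row["subject_id"]), vals, atlas.affine.copy()))
    return volumes


def generate_cognition(
    subjects: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
):
    """Simulate longitudinal domain composites.

    Per subject and domain the true annual slope is the group mean plus a
    coupling term on the latent burden (centred at the sample group mean,
    so group-level slope means sit on their configured targets even though
    the lognormal burden is heavy-tailed) plus Gaussian noise whose SD is
    chosen so the total group slope SD matches the configured target. Observations are baseline + slope*time + residual
    noise on the configured visit schedule, with per-subject dropout of the
    last visit.

    Returns (cognition, truth): long observation table and the per-subject
    per-domain true slopes/baselines (retained for parameter-recovery tests).
    """
    config.validate()
    if rng is None:
        rng = stage_rng(config.seed, "cognition")
    times = np.asarray(config.visit_times, dtype=float)
    group_burden_mean = subjects.groupby("group")[[f"burden_{d}" for d in DOMAINS]].mean()
    obs_rows, truth_rows = [], []
    for _, row in subjects.iterrows():
        group = row["group"]
        keep_last = rng.random() >= config.dropout_last_visit
        t_sub = times if (keep_last or len(times) <= 2) else times[:-1]
        for d in DOMAINS:
            centred = row[f"burden_{d}"] - group_burden_mean.loc[group, f"burden_{d}"]
            slope = (
                config.slope_mean[d][group]
                + config.coupling[d] * centred
                + rng.normal(0.0, config.residual_slope_sd(d, group))
            )
            baseline = rng.normal(config.baseline_mean[d][group], config.baseline_sd[d])
            noise = rng.normal(0.0, config.score_residual_sd[d], size=t_sub.size)
            scores = baseline + slope * t_sub + noise
            truth_rows.append(
                {
                    "subject_id": row["subject_id"],
                    "domain": d,
                    "true_slope": slope,
                    "true_baseline": baseline,
                }
            )
            for t, s in zip(t_sub, scores):
                obs_rows.append(
                    {
                        "subject_id": row["subject_id"],
                        "domain": d,
                        "time": float(t),
                        "score": float(s),
                    }
                )
    return pd.DataFrame(obs_rows), pd.DataFrame(truth_rows)


@dataclass
class SyntheticCohort:
    """Everything one simulated study provides to the analysis."""

    config: SimulationConfig
    subjects: pd.DataFrame
    atlas: RegionAtlas
    domain_maps: dict
    volumes: list
    cognition: pd.DataFrame
    truth: pd.DataFrame


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Run all generators off the config's root seed."""
    config.validate()
    atlas, maps = generate_atlas(config.grid_dims, config.seed)
    subjects = generate_subjects(config)
    volumes = generate_tau_volumes(subjects, atlas, maps, config)
    cognition, truth = generate_cognition(subjects, config)
    return SyntheticCohort(config, subjects, atlas, maps, volumes, cognition, truth)
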