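"""End-to-end pipeline: simulate -> ROIs/TPP -> signals -> change rates ->
bootstrapped ROI comparison -> personalized composites -> power table.

Every stage reads and writes plain artifacts (CSV/JSON/NIfTI) in the output
directory, so stages can be re-run individually and the whole run is
reproducible byte-for-byte from the config seed. Randomness flows from the
single root seed through named substreams per stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._rng import stage_rng
from .config import DOMAINS, SimulationConfig
from .endpoints import (
    build_composites,
    ensemble_covariates,
    fit_prediction_ensemble,
    paired_composite_comparison,
    predict_decline,
)
from .grids import load_atlas, load_domain_map, load_volume, save_atlas, save_domain_map, save_volume
from .prediction import assemble_analysis_table, compare_r2_distributions, run_bootstrap
from .rois import GmmConfig, build_all_rois, extract_signal_table, fit_voxel_gmm
from .synthetic import generate_atlas, generate_cognition, generate_subjects, generate_tau_volumes
from .trajectories import fit_change_rates

log = logging.getLogger(__name__)

ROI_SETS = {d: (d, "GLOBAL", "TEMPORAL") for d in DOMAINS}


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    simulate: SimulationConfig | None = None
    #: used instead of simulation when data already exist on disk
    data_dir: str | None = None
    sample: str = "abeta_pos"  # or "pooled"
    tau_mode: str = "TPP"  # or "SUVR"
    use_education: bool = True
    use_apoe4: bool = True
    bootstrap: int = 1000
    seed: int = 0
    alpha: float = 0.05
    target_power: float = 0.80
    attenuations: tuple = (0.20, 0.30, 0.40)
    gmm_min_subjects: int = 50

    def validate(self) -> "PipelineConfig":
        if self.simulate is None and self.data_dir is None:
            raise PipelineConfigError("config needs either a simulate block or a data_dir")
        if self.data_dir is not None and not Path(self.data_dir).exists():
            raise PipelineConfigError(f"data_dir {self.data_dir} does not exist")
        if self.bootstrap < 1:
            raise PipelineConfigError("bootstrap must be >= 1")
        if self.sample not in ("abeta_pos", "pooled"):
            raise PipelineConfigError(f"unknown sample {self.sample!r}")
        if self.tau_mode.upper() not in ("TPP", "SUVR"):
            raise PipelineConfigError(f"unknown tau mode {self.tau_mode!r}")
        return self

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        sim = raw.pop("simulate", None)
        cfg = cls(**{**raw, "simulate": SimulationConfig.from_dict(sim) if sim else None})
        if "attenuations" in raw:
            cfg.attenuations = tuple(raw["attenuations"])
        return cfg.validate()

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(d, indent=2, default=list))


def _outdir(outdir) -> Path:
    p = Path(outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: PipelineConfig, outdir) -> None:
    out = _outdir(outdir)
    sim = config.simulate
    if sim is None:
        raise PipelineConfigError("no simulate block in config")
    sim = dataclasses.replace(sim, seed=config.seed)
    atlas, maps = generate_atlas(sim.grid_dims, sim.seed)
    subjects = generate_subjects(sim)
    volumes = generate_tau_volumes(subjects, atlas, maps, sim)
    cognition, truth = generate_cognition(subjects, sim)

    save_atlas(atlas, out / "atlas.nii", out / "atlas_labels.json")
    for d, m in maps.items():
        save_domain_map(m, out / f"map_{d}.nii")
    voldir = out / "volumes"
    voldir.mkdir(exist_ok=True)
    for v in volumes:
        save_volume(v, voldir / f"{v.subject_id}.nii")
    subjects.to_csv(out / "subjects.csv", index=False)
    cognition.to_csv(out / "cognition.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)


def _load_data(out: Path):
    atlas = load_atlas(out / "atlas.nii", out / "atlas_labels.json")
    maps = {d: load_domain_map(out / f"map_{d}.nii", d) for d in DOMAINS}
    subjects = pd.read_csv(out / "subjects.csv")
    volumes = [
        load_volume(out / "volumes" / f"{sid}.nii", str(sid))
        for sid in subjects["subject_id"]
    ]
    return atlas, maps, subjects, volumes


def stage_signals(config: PipelineConfig, outdir) -> None:
    """Build ROIs, fit the voxel-wise mixtures, extract SUVR and TPP signals."""
    out = _outdir(outdir)
    atlas, maps, subjects, volumes = _load_data(out)
    rois = build_all_rois(atlas, maps)
    union = np.unique(np.concatenate([r.voxel_indices for r in rois.values()]))
    gmm = fit_voxel_gmm(
        volumes, union, GmmConfig(min_subjects=config.gmm_min_subjects)
    )
    suvr = extract_signal_table(volumes, rois, mode="SUVR")
    tpp = extract_signal_table(volumes, rois, mode="TPP", models=gmm)
    pd.concat([suvr, tpp], ignore_index=True).to_csv(out / "roi_signals.csv", index=False)
    frac = float(gmm.informative.mean())
    (out / "gmm_summary.json").write_text(
        json.dumps(
            {
                "n_voxels": int(gmm.voxel_indices.size),
                "informative_fraction": frac,
                "n_subjects": len(volumes),
            },
            indent=2,
        )
    )


def stage_slopes(config: PipelineConfig, outdir) -> None:
    out = _outdir(outdir)
    cognition = pd.read_csv(out / "cognition.csv")
    res = fit_change_rates(cognition)
    res.change_rates.to_csv(out / "change_rates.csv", index=False)
    res.excluded.to_csv(out / "excluded_subjects.csv", index=False)
    (out / "model_summary.json").write_text(json.dumps(res.summaries, indent=2))


def _analysis_tables(config: PipelineConfig, out: Path, include_baseline=True,
                     use_education=None, use_apoe4=None, sample=None):
    subjects = pd.read_csv(out / "subjects.csv")
    change_rates = pd.read_csv(out / "change_rates.csv")
    signals = pd.read_csv(out / "roi_signals.csv")
    use_edu = config.use_education if use_education is None else use_education
    use_apo = config.use_apoe4 if use_apoe4 is None else use_apoe4
    tables = {}
    for d in DOMAINS:
        tables[d] = assemble_analysis_table(
            subjects,
            change_rates,
            signals,
            domain=d,
            sample=sample or config.sample,
            mode=config.tau_mode,
            use_education=use_edu,
            use_apoe4=use_apo,
            include_baseline=include_baseline,
        )
    return tables


def stage_compare(config: PipelineConfig, outdir) -> None:
    """Bootstrapped domain vs global vs temporal ROI comparison per domain."""
    out = _outdir(outdir)
    tables = _analysis_tables(config, out)
    r2_frames, cmp_rows = [], []
    for d in DOMAINS:
        rng = stage_rng(config.seed, f"bootstrap_{d}")
        res = run_bootstrap(tables[d], ROI_SETS[d], B=config.bootstrap, rng=rng)
        r2 = res.r2.copy()
        r2.insert(0, "domain", d)
        r2_frames.append(r2)
        wide = res.r2.pivot(index="iteration", columns="roi", values="partial_r2")
        for other in ("GLOBAL", "TEMPORAL"):
            c = compare_r2_distributions(
                wide[d].to_numpy(), wide[other].to_numpy(), d, other
            )
            cmp_rows.append(
                {
                    "domain": d,
                    "roi_a": c.roi_a,
                    "roi_b": c.roi_b,
                    "t": c.t,
                    "p": c.p,
                    "cohens_d": c.cohens_d,
                    "ci_a_lo": c.ci_a[0],
                    "ci_a_hi": c.ci_a[1],
                    "ci_b_lo": c.ci_b[0],
                    "ci_b_hi": c.ci_b[1],
                    "ci_overlap": c.ci_overlap,
                }
            )
    pd.concat(r2_frames, ignore_index=True).to_csv(out / "bootstrap_r2.csv", index=False)
    pd.DataFrame(cmp_rows).to_csv(out / "comparisons.csv", index=False)


def stage_personalize(config: PipelineConfig, outdir) -> None:
    """Train the ensemble on the AD-spectrum sample, build composites."""
    out = _outdir(outdir)
    # ensemble covariate set: no baseline score, no education
    tables = _analysis_tables(
        config, out, include_baseline=False, use_education=False, sample="abeta_pos"
    )
    rng = stage_rng(config.seed, "ensemble")
    ensemble = fit_prediction_ensemble(
        tables, B=config.bootstrap, rng=rng, use_apoe4=config.use_apoe4
    )

    # one wide row per subject carrying every predictor, plus actual changes
    base = tables["MEM"][["subject_id"] + list(ensemble_covariates(config.use_apoe4))]
    for d in DOMAINS:
        base = base.merge(tables[d][["subject_id", f"tau_{d}"]], on="subject_id")
    preds = predict_decline(ensemble, base)

    change_rates = pd.read_csv(out / "change_rates.csv")
    all_wide = change_rates.pivot(index="subject_id", columns="domain", values="annual_change")
    wide = all_wide.loc[base["subject_id"]].reset_index()
    # z-scores are referenced to the whole cohort (controls included), so a
    # declining AD-spectrum sample has composites with a nonzero mean
    std = all_wide.reset_index()
    ensemble.standardization = {
        d: (float(std[d].mean()), float(std[d].std(ddof=1))) for d in DOMAINS
    }
    composites = build_composites(wide, preds, standardization=std)
    cmp = paired_composite_comparison(
        composites["personalized"].to_numpy(), composites["unweighted"].to_numpy()
    )
    ensemble.save(out / "ensemble.json")
    composites.to_csv(out / "composites.csv", index=False)
    (out / "composite_comparison.json").write_text(
        json.dumps({"t": cmp.t, "p": cmp.p, "d_paired": cmp.d_paired, "n": cmp.n}, indent=2)
    )


def stage_power(config: PipelineConfig, outdir) -> None:
    from .power import power_table

    out = _outdir(outdir)
    composites = pd.read_csv(out / "composites.csv")
    change_rates = pd.read_csv(out / "change_rates.csv")
    mem = change_rates[change_rates["domain"] == "MEM"].set_index("subject_id")
    mem = mem.loc[composites["subject_id"], "annual_change"].to_numpy()
    endpoints = {
        "MEM": mem,
        "UNWEIGHTED": composites["unweighted"].to_numpy(),
        "PERSONALIZED": composites["personalized"].to_numpy(),
    }
    table = power_table(
        endpoints,
        attenuations=config.attenuations,
        alpha=config.alpha,
        power=config.target_power,
    )
    table.to_csv(out / "power_table.csv", index=False)


STAGES = (
    ("simulate", stage_simulate),
    ("signals", stage_signals),
    ("slopes", stage_slopes),
    ("compare", stage_compare),
    ("personalize", stage_personalize),
    ("power", stage_power),
)


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run every stage in order and write a run report."""
    config.validate()
    out = _outdir(outdir)
    report = {
        "seed": config.seed,
        "taucog_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "stages": [],
        "warnings": [],
    }
    for name, fn in STAGES:
        if name == "simulate" and config.simulate is None:
            report["stages"].append({"name": name, "skipped": "external data_dir"})
            continue
        try:
            fn(config, out)
        except Exception as exc:  # keep partial outputs, name the stage
            report["stages"].append({"name": name, "error": str(exc)})
            (out / "run_report.json").write_text(json.dumps(report, indent=2))
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        report["stages"].append({"name": name, "ok": True})
    for fname in ("subjects.csv", "change_rates.csv", "bootstrap_r2.csv", "composites.csv"):
        fpath = out / fname
        if fpath.exists():
            report.setdefault("row_counts", {})[fname] = sum(1 for _ in fpath.open()) - 1
    (out / "run_report.json").write_text(json.dumps(report, indent=2))
    return out
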