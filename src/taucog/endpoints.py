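"""Tau-PET-informed personalized cognitive composites.

A 1000-model bootstrap ensemble is trained on the discovery AD-spectrum
sample: per domain, annual cognitive change regressed on the matched
domain tau signal plus age, sex, clinical status, and (optionally) APOE4 —
note no baseline score and no education in this covariate set. The
ensemble transfers unchanged to any cohort with identically defined
predictors: a subject's predicted decline per domain is the mean of the B
linear predictions.

Predicted declines are square-ranked (1 = slowest predicted decline up to
16 = fastest) and the personalized composite is the weighted mean of the
subject's z-scored *actual* change rates with those weights; the
conventional comparator is the plain mean of the same z-scores. The two
composites are compared by paired t-test (d_paired = t / sqrt(n)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .prediction import DegenerateDataError

DOMAINS = ("MEM", "LAN", "EF", "VS")
SQUARED_RANKS = (1.0, 4.0, 9.0, 16.0)


@dataclass
class ModelEnsemble:
    """Per-domain bootstrap coefficient matrices over one predictor layout."""

    coef: dict  # domain -> (B, k) array
    layout: dict  # domain -> list of predictor names (const first)
    covariate_set: str = "age+sex+status+apoe4"
    standardization: dict = field(default_factory=dict)  # domain -> (mean, sd)

    @property
    def n_models(self) -> int:
        return next(iter(self.coef.values())).shape[0]

    def save(self, path: str | Path) -> None:
        payload = {
            "covariate_set": self.covariate_set,
            "layout": self.layout,
            "coef": {d: c.tolist() for d, c in self.coef.items()},
            "standardization": {d: list(v) for d, v in self.standardization.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ModelEnsemble":
        raw = json.loads(Path(path).read_text())
        return cls(
            coef={d: np.asarray(c, dtype=float) for d, c in raw["coef"].items()},
            layout=raw["layout"],
            covariate_set=raw["covariate_set"],
            standardization={d: tuple(v) for d, v in raw["standardization"].items()},
        )


def ensemble_covariates(use_apoe4: bool = True) -> tuple:
    cols = ["age", "sex", "status_MCI", "status_DEM"]
    if use_apoe4:
        cols.append("apoe4")
    return tuple(cols)


def fit_prediction_ensemble(
    tables: dict,
    B: int = 1000,
    rng: np.random.Generator | None = None,
    use_apoe4: bool = True,
    identity_first: bool = False,
) -> ModelEnsemble:
    """Train the bootstrap ensemble on discovery-sample analysis tables.

    `tables[domain]` must carry columns `outcome`, `tau_<domain>`, and the
    ensemble covariates, with one common subject order across domains (the
    subject resample is shared across domains within an iteration).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(0)
    covs = ensemble_covariates(use_apoe4)
    ids = None
    designs, ys, layout = {}, {}, {}
    for d in DOMAINS:
        t = tables[d]
        if ids is None:
            ids = t["subject_id"].to_numpy()
        elif not np.array_equal(t["subject_id"].to_numpy(), ids):
            raise ValueError("tables must share one subject order across domains")
        cols = [f"tau_{d}"] + list(covs)
        missing = [c for c in cols if c not in t.columns]
        if missing:
            raise KeyError(f"missing predictor column(s) {missing} for domain {d}")
        designs[d] = np.column_stack(
            [np.ones(len(t))] + [t[c].to_numpy(float) for c in cols]
        )
        ys[d] = t["outcome"].to_numpy(float)
        layout[d] = ["const"] + cols

    n = len(ids)
    coef = {d: np.empty((B, designs[d].shape[1])) for d in DOMAINS}
    redraws, max_redraws = 0, max(1, int(np.ceil(0.1 * B)))
    b = 0
    while b < B:
        if identity_first and b == 0:
            idx = np.arange(n)
        else:
            idx = rng.integers(0, n, size=n)
        ok = all(
            np.linalg.matrix_rank(designs[d][idx]) == designs[d].shape[1]
            for d in DOMAINS
        )
        if not ok:
            redraws += 1
            if redraws > max_redraws:
                raise DegenerateDataError("too many singular resamples")
            continue
        for d in DOMAINS:
            beta, _, _, _ = np.linalg.lstsq(designs[d][idx], ys[d][idx], rcond=None)
            coef[d][b] = beta
        b += 1

    tag = "age+sex+status+apoe4" if use_apoe4 else "age+sex+status"
    return ModelEnsemble(coef=coef, layout=layout, covariate_set=tag)


def predict_decline(ensemble: ModelEnsemble, rows: pd.DataFrame) -> pd.DataFrame:
    """Mean predicted annual change per domain for each subject row.

    Rows must contain every predictor named in the ensemble layout; a
    missing field raises a KeyError naming it.
    """
    out = {"subject_id": rows["subject_id"].to_numpy()}
    for d in DOMAINS:
        cols = ensemble.layout[d][1:]  # skip const
        for c in cols:
            if c not in rows.columns:
                raise KeyError(f"missing predictor {c!r} for domain {d}")
        X = np.column_stack(
            [np.ones(len(rows))] + [rows[c].to_numpy(float) for c in cols]
        )
        out[f"pred_{d}"] = X @ ensemble.coef[d].mean(axis=0)
    return pd.DataFrame(out)


def square_rank_weights(predicted: np.ndarray) -> np.ndarray:
    """Squared-rank weights: fastest predicted decline (most negative) -> 16.

    Ties (differences below 1e-12) are broken by canonical domain order
    MEM < LAN < EF < VS, the earlier domain taking the larger weight.
    """
    v = np.asarray(predicted, dtype=float)
    if v.shape != (4,) or not np.all(np.isfinite(v)):
        raise ValueError("predicted change must be 4 finite values")
    # cluster near-equal values so the tie-break is deterministic
    order = np.argsort(v, kind="stable")
    cluster = np.empty(4, dtype=int)
    cid = 0
    cluster[order[0]] = 0
    for i in range(1, 4):
        if v[order[i]] - v[order[i - 1]] > 1e-12:
            cid += 1
        cluster[order[i]] = cid
    # ascending value => faster decline first; earlier domain index wins ties
    ranking = sorted(range(4), key=lambda i: (cluster[i], i))
    weights = np.empty(4)
    for pos, dom in enumerate(ranking):
        weights[dom] = SQUARED_RANKS[3 - pos]
    return weights


@dataclass
class PairedComparison:
    t: float
    p: float
    d_paired: float
    n: int


def build_composites(
    changes: pd.DataFrame,
    predictions: pd.DataFrame,
    standardization: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Personalized (squared-rank-weighted) and unweighted composites.

    `changes` is wide: subject_id plus actual annual change per domain
    (columns MEM/LAN/EF/VS). Each domain is z-scored against the
    standardization sample (defaults to `changes` itself; the pipeline
    passes the whole cohort, controls included, so that an AD-spectrum
    sample keeps a nonzero mean decline after standardization). The personalized
    composite is the weighted mean sum(w*z)/sum(w) with sum(w)=30; the
    unweighted composite is the plain mean of the four z-scores.
    """
    std = standardization if standardization is not None else changes
    mean_sd = {}
    for d in DOMAINS:
        mu = float(std[d].mean())
        sd = float(std[d].std(ddof=1))
        if sd == 0.0:
            raise ValueError(f"zero SD in standardization sample for {d}")
        mean_sd[d] = (mu, sd)

    merged = changes.merge(predictions, on="subject_id", validate="one_to_one")
    rows = []
    for _, r in merged.iterrows():
        z = np.array([(r[d] - mean_sd[d][0]) / mean_sd[d][1] for d in DOMAINS])
        pred = np.array([r[f"pred_{d}"] for d in DOMAINS])
        w = square_rank_weights(pred)
        rows.append(
            {
                "subject_id": r["subject_id"],
                **{f"z_{d}": z[i] for i, d in enumerate(DOMAINS)},
                **{f"w_{d}": w[i] for i, d in enumerate(DOMAINS)},
                "personalized": float((w * z).sum() / w.sum()),
                "unweighted": float(z.mean()),
            }
        )
    return pd.DataFrame(rows)


def paired_composite_comparison(
    personalized: np.ndarray, unweighted: np.ndarray
) -> PairedComparison:
    """Paired t-test of personalized vs unweighted composite decline.

    Negative differences mean the personalized composite declines faster.
    d_paired = mean(diff)/SD(diff) = t/sqrt(n).
    """
    a = np.asarray(personalized, dtype=float)
    b = np.asarray(unweighted, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0.0:
        if np.all(diff == 0.0):
            return PairedComparison(0.0, 1.0, 0.0, a.size)
        raise ValueError("zero-variance nonzero-mean differences: t degenerate")
    t, p = stats.ttest_rel(a, b)
    return PairedComparison(float(t), float(p), float(diff.mean() / sd), int(a.size))
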