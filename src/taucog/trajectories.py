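"""Subject-specific annual cognitive change rates.

Per cognitive domain, a linear mixed model is fitted on the whole cohort:

    score_ij = (b0 + u0_i) + (b1 + u1_i) * time_ij + e_ij

with correlated subject-level random intercept and slope, estimated by
REML (statsmodels MixedLM). A subject's annual change rate is the fixed
slope plus the predicted (BLUP) random-slope deviation. Subjects with
fewer than two distinct visits in a domain are excluded and reported.

Numerical edge cases: a singular random-effects covariance triggers a
refit with independent (diagonal) random effects; when the data are
exactly linear per subject (zero residual variance) the BLUPs coincide
with per-subject OLS slopes, which are then returned directly since the
likelihood is degenerate there.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLMParams

log = logging.getLogger(__name__)

DOMAINS = ("MEM", "LAN", "EF", "VS")


@dataclass
class ChangeRateResult:
    """Per-subject annual change rates plus per-domain model summaries."""

    change_rates: pd.DataFrame  # subject_id, domain, annual_change, baseline_score
    summaries: dict = field(default_factory=dict)
    excluded: pd.DataFrame | None = None


def per_subject_ols_slopes(obs: pd.DataFrame) -> pd.Series:
    """Independent per-subject least-squares slopes (no pooling)."""

    def _slope(g):
        t = g["time"].to_numpy(dtype=float)
        y = g["score"].to_numpy(dtype=float)
        return np.polyfit(t, y, 1)[0]

    return obs.groupby("subject_id", sort=True).apply(_slope, include_groups=False)


def _baselines(obs: pd.DataFrame) -> pd.Series:
    first = obs.sort_values(["subject_id", "time"]).groupby("subject_id", sort=True).first()
    return first["score"]


def _fit_domain(obs: pd.DataFrame):
    """Fit one domain's mixed model; returns (slopes Series, summary dict)."""
    obs = obs.sort_values(["subject_id", "time"]).reset_index(drop=True)
    summary: dict = {"n_subjects": obs["subject_id"].nunique(), "n_obs": len(obs)}

    # exactly-linear data per subject: the residual variance is 0 and the
    # mixed model is degenerate; its BLUP limit is the per-subject OLS slope
    ols = per_subject_ols_slopes(obs)
    # residuals around each subject's own line
    resid = []
    for sid, g in obs.groupby("subject_id", sort=True):
        coef = np.polyfit(g["time"], g["score"], 1)
        resid.append(g["score"].to_numpy() - np.polyval(coef, g["time"].to_numpy()))
    max_resid = max(float(np.abs(r).max()) if r.size else 0.0 for r in resid)
    scale = max(float(obs["score"].abs().max()), 1.0)
    if max_resid <= 1e-10 * scale:
        summary.update(model="noiseless-ols-limit", fixed_slope=float(ols.mean()))
        return ols, summary

    model = sm.MixedLM.from_formula(
        "score ~ time", groups="subject_id", re_formula="~time", data=obs
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True)
    cov_re = np.asarray(result.cov_re)
    eig = np.linalg.eigvalsh(cov_re)
    singular = (not result.converged) or eig.min() < 1e-10 * max(eig.max(), 1e-12)
    summary["model"] = "lmm-random-intercept-slope"
    if singular:
        log.warning("singular random-effects covariance; refitting with "
                    "independent random intercept and slope")
        free = MixedLMParams.from_components(
            fe_params=np.ones(2), cov_re=np.eye(2)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = model.fit(reml=True, free=free)
        summary["model"] = "lmm-independent-random-effects"
        summary["singular_fallback"] = True

    fe = result.fe_params
    re = result.random_effects
    slopes = pd.Series(
        {sid: float(fe["time"] + eff.get("time", 0.0)) for sid, eff in re.items()}
    ).sort_index()
    summary.update(
        fixed_intercept=float(fe["Intercept"]),
        fixed_slope=float(fe["time"]),
        fixed_slope_se=float(result.bse_fe["time"]),
        resid_var=float(result.scale),
        cov_re=np.asarray(result.cov_re).tolist(),
        converged=bool(result.converged),
    )
    return slopes, summary


def fit_change_rates(cognition: pd.DataFrame, domains=DOMAINS) -> ChangeRateResult:
    """Estimate annual change rates for every subject and domain.

    `cognition` is long format: subject_id, domain, time, score.
    """
    rows, summaries, excluded_rows = [], {}, []
    for d in domains:
        obs = cognition[cognition["domain"] == d]
        if obs.empty:
            continue
        nvisits = obs.groupby("subject_id")["time"].nunique()
        bad = nvisits[nvisits < 2].index
        for sid in bad:
            excluded_rows.append(
                {"subject_id": sid, "domain": d, "reason": "fewer than 2 visits"}
            )
        obs = obs[~obs["subject_id"].isin(bad)]
        if obs.empty:
            continue
        slopes, summary = _fit_domain(obs)
        base = _baselines(obs)
        for sid in slopes.index:
            rows.append(
                {
                    "subject_id": sid,
                    "domain": d,
                    "annual_change": float(slopes[sid]),
                    "baseline_score": float(base[sid]),
                }
            )
        summaries[d] = summary
    return ChangeRateResult(
        change_rates=pd.DataFrame(rows),
        summaries=summaries,
        excluded=pd.DataFrame(excluded_rows, columns=["subject_id", "domain", "reason"]),
    )
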