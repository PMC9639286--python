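"""Bootstrapped comparison of tau-PET ROIs as predictors of cognitive decline.

For each cognitive domain, the annual change rate is regressed on one tau
ROI signal (the matched domain ROI, the global ROI, or the temporal-lobe
ROI) plus covariates, in B bootstrap resamples. Within an iteration the
same subject resample is used for every ROI, so the per-iteration partial
R² values are paired and can be compared with paired t-tests; percentile
95% CIs of the R² distributions support a non-parametric comparison.

Partial R² is computed relative to the reduced model without the tau term:
(RSS_reduced − RSS_full) / RSS_reduced — the share of covariate-unexplained
variance in cognitive change captured by the tau signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

FULL_COVARIATES = ("age", "sex", "education", "status_MCI", "status_DEM", "apoe4", "baseline")


class DegenerateDataError(ValueError):
    """Too many singular bootstrap designs."""


def covariate_columns(use_education: bool = True, use_apoe4: bool = True,
                      include_baseline: bool = True) -> tuple:
    cols = ["age", "sex"]
    if use_education:
        cols.append("education")
    cols += ["status_MCI", "status_DEM"]
    if use_apoe4:
        cols.append("apoe4")
    if include_baseline:
        cols.append("baseline")
    return tuple(cols)


def assemble_analysis_table(
    subjects: pd.DataFrame,
    change_rates: pd.DataFrame,
    roi_signals: pd.DataFrame,
    domain: str,
    sample: str = "abeta_pos",
    mode: str = "TPP",
    use_education: bool = True,
    use_apoe4: bool = True,
    include_baseline: bool = True,
) -> pd.DataFrame:
    """One row per subject: outcome, all ROI signals, expanded covariates.

    `sample` is "abeta_pos" (AD-spectrum, the main analysis sample) or
    "pooled" (amyloid-negative controls plus AD-spectrum). Clinical status
    is dummy-coded with CN as reference. Rows with missing required fields
    are dropped.
    """
    if sample not in ("abeta_pos", "pooled"):
        raise ValueError(f"unknown sample {sample!r}")
    subj = subjects.copy()
    if sample == "abeta_pos":
        subj = subj[subj["amyloid_status"] == "POS"]
    if subj.empty:
        raise ValueError("empty sample after amyloid filtering")

    cr = change_rates[change_rates["domain"] == domain][
        ["subject_id", "annual_change", "baseline_score"]
    ].rename(columns={"annual_change": "outcome", "baseline_score": "baseline"})

    sig = roi_signals[roi_signals["mode"] == mode.upper()]
    wide = sig.pivot_table(index="subject_id", columns="roi", values="value")
    wide = wide.rename(columns=lambda r: f"tau_{r}").reset_index()

    table = subj.merge(cr, on="subject_id").merge(wide, on="subject_id")
    table["status_MCI"] = (table["clinical_status"] == "MCI").astype(float)
    table["status_DEM"] = (table["clinical_status"] == "DEM").astype(float)

    covs = covariate_columns(use_education, use_apoe4, include_baseline)
    keep = ["subject_id", "outcome"] + [c for c in table.columns if c.startswith("tau_")]
    keep += list(covs)
    table = table[keep].dropna().reset_index(drop=True)
    if table.empty:
        raise ValueError("empty analysis table after dropping incomplete rows")
    table.attrs["covariates"] = covs
    table.attrs["domain"] = domain
    table.attrs["sample"] = sample
    return table


# ---------------------------------------------------------------------------


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def partial_r2(y: np.ndarray, X_full: np.ndarray, X_reduced: np.ndarray) -> float:
    """(RSS_reduced − RSS_full) / RSS_reduced, in [0, 1]."""
    rss_full = _rss(y, X_full)
    rss_red = _rss(y, X_reduced)
    if rss_red == 0.0:
        raise ZeroDivisionError("reduced-model RSS is zero; partial R² undefined")
    return float(np.clip((rss_red - rss_full) / rss_red, 0.0, 1.0))


@dataclass
class BootstrapResult:
    """Paired bootstrap output for one domain across several ROIs."""

    r2: pd.DataFrame  # columns: iteration, roi, partial_r2
    coefs: dict  # roi -> (B, k) array; column 1 is the tau coefficient
    coef_names: dict  # roi -> list of predictor names
    indices: np.ndarray  # (B, n) resample indices
    n_redraws: int = 0


def _design(table: pd.DataFrame, roi: str, covs) -> tuple[np.ndarray, list]:
    cols = [f"tau_{roi}"] + list(covs)
    X = np.column_stack([np.ones(len(table))] + [table[c].to_numpy(float) for c in cols])
    return X, ["const"] + cols


def run_bootstrap(
    table: pd.DataFrame,
    rois,
    B: int = 1000,
    rng: np.random.Generator | None = None,
    identity_first: bool = False,
) -> BootstrapResult:
    """B paired bootstrap OLS fits per ROI on one domain's analysis table.

    The subject resample (with replacement, original size) is shared across
    ROIs within an iteration. Resamples whose design matrix is singular for
    any ROI (e.g. a dummy column constant) are redrawn; more than 10%
    redraws aborts. `identity_first=True` forces iteration 0 to the
    identity resample (full-sample OLS), used for exactness checks.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    n = len(table)
    if n < 20:
        raise ValueError(f"need >= 20 rows, got {n}")
    rng = rng if rng is not None else np.random.default_rng(0)
    covs = table.attrs.get("covariates", covariate_columns())
    y_all = table["outcome"].to_numpy(float)

    designs = {}
    names = {}
    for roi in rois:
        designs[roi], names[roi] = _design(table, roi, covs)
    X_red = np.column_stack(
        [np.ones(n)] + [table[c].to_numpy(float) for c in covs]
    )
    k_red = X_red.shape[1]

    r2_rows = []
    coefs = {roi: np.empty((B, designs[roi].shape[1])) for roi in rois}
    indices = np.empty((B, n), dtype=np.intp)
    redraws = 0
    max_redraws = max(1, int(np.ceil(0.1 * B)))

    b = 0
    while b < B:
        if identity_first and b == 0:
            idx = np.arange(n)
        else:
            idx = rng.integers(0, n, size=n)
        ok = np.linalg.matrix_rank(X_red[idx]) == k_red
        if ok:
            for roi in rois:
                Xb = designs[roi][idx]
                if np.linalg.matrix_rank(Xb) < Xb.shape[1]:
                    ok = False
                    break
        if not ok:
            redraws += 1
            if redraws > max_redraws:
                raise DegenerateDataError(
                    f"more than {max_redraws} singular resamples out of {B}"
                )
            continue
        yb = y_all[idx]
        Xr = X_red[idx]
        rss_red = _rss(yb, Xr)
        for roi in rois:
            Xb = designs[roi][idx]
            beta, _, _, _ = np.linalg.lstsq(Xb, yb, rcond=None)
            resid = yb - Xb @ beta
            rss_full = float(resid @ resid)
            if rss_red == 0.0:
                raise ZeroDivisionError("reduced-model RSS is zero in a resample")
            pr2 = float(np.clip((rss_red - rss_full) / rss_red, 0.0, 1.0))
            coefs[roi][b] = beta
            r2_rows.append({"iteration": b, "roi": roi, "partial_r2": pr2})
        indices[b] = idx
        b += 1

    return BootstrapResult(
        r2=pd.DataFrame(r2_rows),
        coefs=coefs,
        coef_names=names,
        indices=indices,
        n_redraws=redraws,
    )


# ---------------------------------------------------------------------------


@dataclass
class ComparisonResult:
    """Paired comparison of two bootstrapped partial-R² distributions."""

    roi_a: str
    roi_b: str
    t: float
    p: float
    cohens_d: float
    ci_a: tuple
    ci_b: tuple
    ci_overlap: bool


def compare_r2_distributions(
    r2_a: np.ndarray, r2_b: np.ndarray, roi_a: str = "a", roi_b: str = "b"
) -> ComparisonResult:
    """Paired t-test and Cohen's d on per-iteration differences, with
    percentile 95% CIs of each distribution."""
    a = np.asarray(r2_a, dtype=float)
    b = np.asarray(r2_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("distributions must be paired and of length >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0.0:
        if np.all(diff == 0.0):
            t, p, d = 0.0, 1.0, 0.0
        else:
            raise ValueError("zero-variance nonzero difference vector: t undefined")
    else:
        t, p = stats.ttest_rel(a, b)
        d = float(diff.mean() / sd)
    ci_a = tuple(np.percentile(a, [2.5, 97.5]))
    ci_b = tuple(np.percentile(b, [2.5, 97.5]))
    overlap = (ci_a[0] <= ci_b[1]) and (ci_b[0] <= ci_a[1])
    return ComparisonResult(roi_a, roi_b, float(t), float(p), d, ci_a, ci_b, overlap)
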