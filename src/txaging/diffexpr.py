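"""Per-gene age association via linear, negative-binomial, and hurdle models.

Each gene is tested for a continuous age trend with age and sex as the
only covariates, under two model families:

* a **linear** model on log2(CPM), ordinary least squares, Wald t test;
* a **count** family on rounded CPB: a standard NB regression (log link,
  gene-wise ML dispersion) for genes with no zero CPB value, and a
  two-part **hurdle** model (logistic zero/nonzero part + zero-truncated
  NB on the positive counts) for genes with at least one zero.  The zeros
  in this design are treated as structural — true absence — so a hurdle
  rather than a zero-inflated mixture is appropriate.

The **consensus** set is the intersection: genes significant in both
families with concordant coefficient sign.  Requiring agreement between a
Gaussian model on the log scale and a count model on the natural scale is
a conservative filter against family-specific artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.discrete.truncated_model import TruncatedLFNegativeBinomialP
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .normalize import CountMatrix, NormalizedMatrix, to_cpm, to_cpb, filter_min_samples, nb_exclusion_filter

__all__ = [
    "RegressionFit",
    "fit_linear",
    "fit_nb",
    "fit_hurdle",
    "fit_count_family",
    "consensus",
    "run_diffexpr",
]


@dataclass
class RegressionFit:
    """Age-association result for one feature under one model family."""

    feature_id: str
    model: str  # linear | nb | zanb
    beta_age: float = np.nan
    se_age: float = np.nan
    p_wald: float = np.nan
    beta_sex: float = np.nan
    converged: bool = False
    exclusion_reason: str | None = None
    # hurdle only: zero-component coefficients (logit scale)
    zero_beta_age: float = np.nan
    zero_p: float = np.nan
    zero_separation: bool = False

    def as_row(self) -> dict:
        return {
            "feature_id": self.feature_id,
            "model": self.model,
            "beta_age": self.beta_age,
            "se_age": self.se_age,
            "p_wald": self.p_wald,
            "beta_sex": self.beta_sex,
            "converged": self.converged,
            "exclusion_reason": self.exclusion_reason or "",
            "zero_beta_age": self.zero_beta_age,
            "zero_p": self.zero_p,
        }


def _design(ages, sexes) -> np.ndarray:
    ages = np.asarray(ages, dtype=float)
    if sexes is None:
        return np.column_stack([np.ones_like(ages), ages])
    sexes = np.asarray(sexes, dtype=float)
    return np.column_stack([np.ones_like(ages), ages, sexes])


def fits_to_frame(fits: list[RegressionFit]) -> pd.DataFrame:
    return pd.DataFrame.from_records([f.as_row() for f in fits]).set_index("feature_id")


# ---------------------------------------------------------------------------
# linear family


def fit_linear(
    y, ages, sexes, feature_id: str = "", drop_nonfinite: bool = True
) -> RegressionFit:
    """OLS of log2(CPM) on intercept + age + sex.

    Samples at the zero-count sentinel (``-inf``) are excluded from the
    fit by default rather than floored, so an arbitrary floor cannot
    dominate the slope.  Inference: two-sided Wald t with n - p degrees of
    freedom.  ``sexes=None`` fits an age-only design.
    """
    y = np.asarray(y, dtype=float)
    X = _design(ages, sexes)
    if drop_nonfinite:
        keep = np.isfinite(y)
        y, X = y[keep], X[keep]
    fit = RegressionFit(feature_id=feature_id, model="linear")
    if len(y) < X.shape[1] + 1:
        fit.exclusion_reason = "too few finite observations"
        return fit
    if np.linalg.matrix_rank(X) < X.shape[1]:
        fit.exclusion_reason = "rank-deficient design"
        return fit
    res = sm.OLS(y, X).fit()
    fit.beta_age = float(res.params[1])
    fit.se_age = float(res.bse[1])
    if X.shape[1] > 2:
        fit.beta_sex = float(res.params[2])
    fit.p_wald = float(res.pvalues[1]) if res.bse[1] > 0 else 1.0
    if np.ptp(y) == 0:  # constant response: slope exactly 0, no evidence
        fit.beta_age, fit.p_wald = 0.0, 1.0
    fit.converged = True
    return fit


# ---------------------------------------------------------------------------
# count family


def _nb_start_params(y, X) -> np.ndarray:
    """Poisson fit for the mean part + method-of-moments dispersion start."""
    try:
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        beta0 = np.asarray(pois.params)
        mu = pois.fittedvalues
    except Exception:
        beta0 = np.zeros(X.shape[1])
        beta0[0] = np.log(max(np.mean(y), 1e-8))
        mu = np.full_like(np.asarray(y, dtype=float), max(np.mean(y), 1e-8))
    y = np.asarray(y, dtype=float)
    alpha = np.sum((y - mu) ** 2 - mu) / np.sum(mu**2)
    alpha = float(np.clip(alpha, 1e-8, 1e4))
    return np.append(beta0, alpha)


def fit_nb(y, ages, sexes, feature_id: str = "", maxiter: int = 200) -> RegressionFit:
    """NB regression (log link) for genes whose CPB is positive everywhere.

    Dispersion is estimated per gene by maximum likelihood, started at a
    method-of-moments value.  Inference: two-sided Wald z for the age
    coefficient.
    """
    y = np.asarray(y)
    if (y == 0).any():
        raise ValueError("fit_nb requires all-positive counts; route zeros to fit_hurdle")
    X = _design(ages, sexes)
    fit = RegressionFit(feature_id=feature_id, model="nb")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        fit.exclusion_reason = "rank-deficient design"
        return fit
    start = _nb_start_params(y, X)
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("newton", "bfgs"):
            try:
                res = sm.NegativeBinomial(y, X).fit(
                    start_params=start, method=method, maxiter=maxiter, disp=0
                )
                if res.mle_retvals.get("converged", False):
                    break
            except Exception:
                res = None
    if res is None:
        fit.exclusion_reason = "nb fit failed"
        return fit
    converged = bool(res.mle_retvals.get("converged", True))
    fit.beta_age = float(res.params[1])
    fit.se_age = float(res.bse[1])
    fit.beta_sex = float(res.params[2])
    fit.p_wald = float(res.pvalues[1])
    if np.ptp(np.asarray(y, dtype=float)) == 0:
        fit.beta_age, fit.p_wald = 0.0, 1.0
    fit.converged = converged and np.isfinite(fit.p_wald) and fit.se_age > 0
    if not fit.converged:
        fit.exclusion_reason = "nb fit did not converge"
    return fit


def fit_hurdle(
    y, ages, sexes, feature_id: str = "", min_positive: int = 5, maxiter: int = 200
) -> RegressionFit:
    """Two-part (hurdle) model for genes with at least one zero CPB.

    Part 1: logistic regression of the zero/nonzero indicator on
    intercept + age + sex; perfect separation falls back to an
    L1-penalized fit and is flagged.  Part 2: zero-truncated NB on the
    positive counts with the same covariates.  The fit's headline
    ``beta_age``/``p_wald`` come from the truncated-count part, which
    models expression level among expressing samples — the same target as
    the linear model; the zero part's coefficients are reported alongside.
    """
    y = np.asarray(y)
    fit = RegressionFit(feature_id=feature_id, model="zanb")
    if not (y == 0).any():
        raise ValueError("fit_hurdle requires at least one zero; route to fit_nb")
    pos = y > 0
    if pos.sum() < min_positive:
        fit.exclusion_reason = f"fewer than {min_positive} positive observations"
        return fit
    X = _design(ages, sexes)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        fit.exclusion_reason = "rank-deficient design"
        return fit

    # zero/nonzero part (models the probability of expression)
    z = pos.astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            logit = sm.Logit(z, X).fit(disp=0, maxiter=maxiter)
            if not np.all(np.isfinite(logit.bse)) or np.abs(logit.params).max() > 1e3:
                raise PerfectSeparationError
            fit.zero_beta_age = float(logit.params[1])
            fit.zero_p = float(logit.pvalues[1])
        except Exception:  # includes perfect separation and singular designs
            try:
                pen = sm.Logit(z, X).fit_regularized(alpha=1.0, disp=0)
                fit.zero_beta_age = float(pen.params[1])
            except Exception:
                pass
            fit.zero_separation = True

    # positive-count part: zero-truncated NB
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = TruncatedLFNegativeBinomialP(y[pos], X[pos], truncation=0).fit(
                disp=0, maxiter=maxiter, method="bfgs"
            )
        except Exception as exc:
            fit.exclusion_reason = f"truncated NB fit failed: {type(exc).__name__}"
            return fit
    fit.beta_age = float(res.params[1])
    fit.se_age = float(res.bse[1])
    fit.beta_sex = float(res.params[2])
    fit.p_wald = float(res.pvalues[1])
    fit.converged = bool(np.isfinite(fit.p_wald)) and fit.se_age > 0
    if not fit.converged:
        fit.exclusion_reason = "truncated NB fit did not converge"
    return fit


def fit_count_family(
    cpb: NormalizedMatrix, ages, sexes, feature_ids=None
) -> list[RegressionFit]:
    """Route each feature to NB or hurdle purely by presence of a zero CPB."""
    if cpb.unit != "CPB_rounded":
        raise ValueError("count family expects rounded CPB input")
    vals = cpb.values
    ids = feature_ids if feature_ids is not None else vals.index
    fits = []
    for fid in ids:
        y = vals.loc[fid].to_numpy()
        if (y == 0).any():
            fits.append(fit_hurdle(y, ages, sexes, feature_id=fid))
        else:
            fits.append(fit_nb(y, ages, sexes, feature_id=fid))
    return fits


# ---------------------------------------------------------------------------
# consensus


def consensus(
    linear_fits: pd.DataFrame | list[RegressionFit],
    count_fits: pd.DataFrame | list[RegressionFit],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Intersect the two families' significant sets with sign agreement.

    A feature is in consensus iff it converged in both families, both
    p-values are < ``alpha``, and the age coefficients agree in sign.
    Returns a frame indexed by feature with per-family significance flags,
    the consensus flag, and the up/down direction (defined only within the
    consensus).  Features present in one family only are retained with
    ``in_consensus=False`` and a note.
    """
    lin = fits_to_frame(linear_fits) if isinstance(linear_fits, list) else linear_fits
    cnt = fits_to_frame(count_fits) if isinstance(count_fits, list) else count_fits
    out = lin[["beta_age", "p_wald", "converged"]].join(
        cnt[["model", "beta_age", "p_wald", "converged"]],
        how="outer",
        lsuffix="_linear",
        rsuffix="_count",
    )
    sig_lin = (out["converged_linear"] == True) & (out["p_wald_linear"] < alpha)  # noqa: E712
    sig_cnt = (out["converged_count"] == True) & (out["p_wald_count"] < alpha)  # noqa: E712
    same_sign = np.sign(out["beta_age_linear"]) == np.sign(out["beta_age_count"])
    cons = sig_lin & sig_cnt & same_sign
    out["significant_linear"] = sig_lin
    out["significant_nb_family"] = sig_cnt
    out["in_consensus"] = cons
    direction = pd.Series("", index=out.index, dtype=object)
    direction[cons & (out["beta_age_linear"] > 0)] = "up"
    direction[cons & (out["beta_age_linear"] < 0)] = "down"
    out["direction"] = direction
    out["note"] = np.where(
        out["converged_linear"].isna() | out["converged_count"].isna(),
        "present in one family only",
        "",
    )
    return out


def top_k(fits: pd.DataFrame, k: int = 20, ascending_p: bool = True) -> pd.DataFrame:
    """Top features ranked by ascending p, then |beta| descending, then id."""
    df = fits.copy()
    df["_absbeta"] = df["beta_age"].abs()
    df = df.sort_index()  # lexicographic id as the final tie-break
    df = df.sort_values(
        by=["p_wald", "_absbeta"], ascending=[True, False], kind="mergesort"
    )
    return df.drop(columns="_absbeta").head(k)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class DiffexprResult:
    """End-to-end per-gene results and bookkeeping of every exclusion."""

    linear: pd.DataFrame
    count: pd.DataFrame
    consensus: pd.DataFrame
    exclusions: pd.DataFrame
    n_unexpressed_removed: int


def run_diffexpr(
    cm: CountMatrix,
    samples: pd.DataFrame,
    alpha: float = 0.01,
    log2cpm_threshold: float = -3.0,
    cpb_threshold: float = 125.0,
    min_samples: int = 10,
    max_zero_samples: int = 50,
    median_floor: float = 630.0,
) -> DiffexprResult:
    """Full cascade: drop unexpressed, normalize, filter, fit both families.

    The linear branch fits log2(CPM) for genes passing the log2CPM filter;
    the count branch fits rounded CPB for genes passing the CPB filter and
    the excess-zero / low-median exclusions.  All exclusions are recorded
    with their reason.
    """
    from .normalize import drop_unexpressed

    cm, n_removed = drop_unexpressed(cm)
    ages = samples["age"].reindex(cm.sample_ids).to_numpy()
    sexes = samples["sex"].reindex(cm.sample_ids).to_numpy()

    log2cpm = to_cpm(cm, log2=True, pseudo=0.0)
    cpb = to_cpb(cm)

    lin_mask = filter_min_samples(log2cpm, log2cpm_threshold, min_samples)
    cpb_mask = filter_min_samples(cpb, cpb_threshold, min_samples)
    nb_keep, nb_reasons = nb_exclusion_filter(cpb, max_zero_samples, median_floor)

    exclusions = []
    for fid in cm.feature_ids[~lin_mask]:
        exclusions.append((fid, "linear", f"fewer than {min_samples} log2CPM >= {log2cpm_threshold}"))
    for fid in cm.feature_ids[~cpb_mask]:
        exclusions.append((fid, "count", f"fewer than {min_samples} CPB >= {cpb_threshold}"))
    for fid, reason in nb_reasons.items():
        exclusions.append((fid, "count", reason))

    lin_fits = [
        fit_linear(log2cpm.values.loc[fid].to_numpy(), ages, sexes, feature_id=fid)
        for fid in cm.feature_ids[lin_mask]
    ]
    count_ids = cm.feature_ids[cpb_mask & nb_keep]
    cnt_fits = fit_count_family(cpb, ages, sexes, feature_ids=count_ids)
    for f in cnt_fits:
        if not f.converged and f.exclusion_reason:
            exclusions.append((f.feature_id, "count", f.exclusion_reason))

    lin_df = fits_to_frame(lin_fits) if lin_fits else pd.DataFrame()
    cnt_df = fits_to_frame(cnt_fits) if cnt_fits else pd.DataFrame()
    cons = consensus(lin_df, cnt_df, alpha=alpha) if len(lin_df) and len(cnt_df) else pd.DataFrame()
    excl_df = pd.DataFrame(exclusions, columns=["feature_id", "branch", "reason"])
    return DiffexprResult(
        linear=lin_df,
        count=cnt_df,
        consensus=cons,
        exclusions=excl_df,
        n_unexpressed_removed=n_removed,
    )
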