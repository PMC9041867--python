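"""Shared metrics and the statistical comparison harness: out-of-sample
cv-r2, logistic enrichment tests with profile-likelihood intervals, rank
correlation against reference effect tables, and the locus-score and
conservation regressions."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import brentq

from .normalize import rank_inverse_normal

__all__ = [
    "cv_r2", "CVR2Result", "summarize_cv_r2", "logistic_enrichment",
    "LogisticTaskResult", "spearman_compare", "locus_tissue_regression",
    "impact_conservation_regression", "variant_key",
]


def cv_r2(y, f) -> float:
    """Out-of-sample coefficient of determination
    ``1 - sum((y_i - f_i)^2) / sum((y_i - ybar_test)^2)``.

    Computed against the *test-set* mean, so a model with no predictive
    ability scores <= 0 and values lie in (-inf, 1].
    """
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    if y.shape != f.shape or y.ndim != 1:
        raise ValueError("y and f must be equal-length vectors")
    if len(y) < 2:
        raise ValueError("need at least two test observations")
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        raise ValueError("constant y: cv-r2 denominator is zero")
    return float(1.0 - np.sum((y - f) ** 2) / sst)


@dataclass
class CVR2Result:
    """Repeated-split (or per-fold) cv-r2 values with a normal-theory CI."""

    values: list
    mean: float
    ci_low: float
    ci_high: float

    @property
    def captured(self) -> bool:
        """True when the whole 95% CI lies above zero."""
        return self.ci_low > 0


def summarize_cv_r2(values, min_repeats: int = 3) -> CVR2Result:
    """Mean and 95% CI (mean +/- 1.96 * SE, normality assumption) over
    repeated-split cv-r2 values."""
    values = [float(v) for v in values]
    if len(values) < min_repeats:
        raise ValueError(f"need at least {min_repeats} repeats")
    mean = float(np.mean(values))
    se = float(np.std(values, ddof=1) / np.sqrt(len(values)))
    return CVR2Result(values=values, mean=mean,
                      ci_low=mean - 1.96 * se, ci_high=mean + 1.96 * se)


@dataclass
class LogisticTaskResult:
    task: str
    score_name: str
    coefficient: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    n_excluded: int = 0
    covariates: tuple = ()
    separable: bool = False


def _profile_ci_bound(model, result, j, direction, alpha=0.05):
    """One profile-likelihood bound for coefficient ``j``: the value where
    the profile deviance crosses the chi-square(1) critical value."""
    crit = stats.chi2.ppf(1 - alpha, 1) / 2.0
    llf_full = result.llf
    exog = model.exog
    endog = model.endog
    x_j = exog[:, j]
    rest = np.delete(exog, j, axis=1)

    def profile_drop(beta_j):
        if rest.shape[1] > 0:
            sub = sm.GLM(endog, rest, family=sm.families.Binomial(),
                         offset=beta_j * x_j)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sub.fit(maxiter=200)
            llf = fit.llf
        else:
            mu = 1 / (1 + np.exp(-beta_j * x_j))
            mu = np.clip(mu, 1e-12, 1 - 1e-12)
            llf = np.sum(endog * np.log(mu) + (1 - endog) * np.log(1 - mu))
        return (llf_full - llf) - crit

    bhat = result.params[j]
    se = result.bse[j]
    step = direction * 1.96 * se
    lo, hi = bhat, bhat + step
    for _ in range(40):
        if profile_drop(hi) > 0:
            break
        hi += step
    else:
        raise RuntimeError("profile bound bracket not found")
    a, b = sorted((lo, hi))
    return brentq(lambda t: profile_drop(t), a, b, xtol=1e-6 * max(1.0, abs(bhat)))


def logistic_enrichment(scores, labels, covariates=None,
                        rank_normalize: bool = False, task: str = "",
                        score_name: str = "score",
                        covariate_names=()) -> LogisticTaskResult:
    """Maximum-likelihood logistic fit of ``label ~ score (+ covariates)``.

    Optionally rank-inverse-normal transforms the score first (so the
    coefficient is invariant to monotone transforms of the raw score).
    Reports the score coefficient with a profile-likelihood 95% CI (falling
    back to Wald with a warning if profiling fails) and the two-tailed Wald
    p-value.  Rows with missing score or covariate values are excluded and
    counted.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    else:
        cov = np.zeros((len(scores), 0))
    keep = np.isfinite(scores) & np.isfinite(labels)
    if cov.shape[1]:
        keep &= np.all(np.isfinite(cov), axis=1)
    n_excluded = int(np.sum(~keep))
    scores, labels, cov = scores[keep], labels[keep], cov[keep]
    classes = np.unique(labels)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("labels must contain both classes 0 and 1")
    if rank_normalize:
        scores = rank_inverse_normal(scores)
    X = np.column_stack([np.ones_like(scores), scores, cov])
    # drop covariate columns collinear with earlier columns
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    keep_cols = diag > 1e-8 * diag.max()
    if not keep_cols.all():
        warnings.warn("dropping collinear covariate column(s) from logistic design")
        X = X[:, keep_cols]
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    model = sm.GLM(labels, X, family=sm.families.Binomial())
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        result = model.fit(maxiter=200)
    separated = any(issubclass(w.category, PerfectSeparationWarning)
                    for w in caught)
    coef = float(result.params[1])
    se = float(result.bse[1])
    p = float(result.pvalues[1])
    separable = separated or not np.isfinite(se) \
        or se > 1e6 * max(1.0, abs(coef))
    if separable:
        return LogisticTaskResult(task=task, score_name=score_name,
                                  coefficient=coef, ci_low=-np.inf,
                                  ci_high=np.inf, p_value=p,
                                  n_used=len(labels), n_excluded=n_excluded,
                                  covariates=tuple(covariate_names),
                                  separable=True)
    try:
        lo = _profile_ci_bound(model, result, 1, direction=-1)
        hi = _profile_ci_bound(model, result, 1, direction=+1)
    except Exception:
        warnings.warn("profile-likelihood CI failed; falling back to Wald")
        lo, hi = coef - 1.96 * se, coef + 1.96 * se
    return LogisticTaskResult(task=task, score_name=score_name,
                              coefficient=coef, ci_low=float(lo),
                              ci_high=float(hi), p_value=p,
                              n_used=len(labels), n_excluded=n_excluded,
                              covariates=tuple(covariate_names))


def variant_key(chrom, pos, ref, alt, build="b37") -> str:
    """Canonical chromosome_position_ref_alt_build variant identifier."""
    return f"{chrom}_{pos}_{ref}_{alt}_{build}"


def spearman_compare(estimates: pd.Series, reference: pd.Series,
                     min_overlap: int = 10):
    """Spearman rank correlation between variant-effect estimates and a
    reference coefficient table, inner-joined on the variant key."""
    joined = pd.concat([estimates.rename("est"), reference.rename("ref")],
                       axis=1, join="inner").dropna()
    if len(joined) == 0:
        raise ValueError(
            "no intersecting variant keys; example estimate keys: "
            f"{list(estimates.index[:3])}, reference keys: "
            f"{list(reference.index[:3])}")
    if len(joined) < min_overlap:
        raise ValueError(f"only {len(joined)} intersecting variants "
                         f"(need >= {min_overlap})")
    rho, p = stats.spearmanr(joined["est"], joined["ref"])
    return float(rho), float(p)


@dataclass
class RegressionResult:
    slope: float
    p_value: float
    n: int
    adjusted_p: float = None
    dropped: int = 0


def _rank_ols(x, y):
    X = sm.add_constant(np.asarray(x, dtype=float))
    fit = sm.OLS(np.asarray(y, dtype=float), X).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


def locus_tissue_regression(locus_scores: dict, local_h2: pd.Series,
                            min_loci: int = 10) -> pd.DataFrame:
    """Per tissue: OLS of rank-normalized local SNP-heritability on the
    rank-normalized locus score (mean impact over scored positions within
    each locus), with Bonferroni adjustment over tissues.

    ``locus_scores`` maps tissue -> Series indexed by locus id; loci without
    a score or an h2 value are dropped and counted.
    """
    rows = []
    for tissue, scores in locus_scores.items():
        joined = pd.concat([scores.rename("score"),
                            local_h2.rename("h2")], axis=1, join="inner").dropna()
        dropped = len(local_h2) - len(joined)
        if len(joined) < min_loci:
            raise ValueError(
                f"{tissue}: only {len(joined)} loci with both score and h2")
        slope, p = _rank_ols(rank_inverse_normal(joined["score"].values),
                             rank_inverse_normal(joined["h2"].values))
        rows.append((tissue, slope, p, len(joined), dropped))
    df = pd.DataFrame(rows, columns=["tissue", "slope", "p_value", "n_loci",
                                     "n_dropped"]).set_index("tissue")
    df["adjusted_p"] = np.minimum(df["p_value"] * len(df), 1.0)
    return df


def impact_conservation_regression(impact, conservation,
                                   min_positions: int = 100):
    """OLS of per-position conservation scores on impact scores; returns the
    raw-scale and rank-normalized-scale fits.

    ``impact`` and ``conservation`` are Series indexed by genomic position;
    positions present in both are used.
    """
    joined = pd.concat([pd.Series(impact).rename("impact"),
                        pd.Series(conservation).rename("cons")],
                       axis=1, join="inner").dropna()
    if len(joined) == 0:
        raise ValueError("no jointly scored positions")
    if len(joined) < min_positions:
        raise ValueError(f"only {len(joined)} jointly scored positions")
    if np.allclose(joined["impact"].values, joined["impact"].values[0]):
        raise ValueError("constant impact: zero-variance regressor")
    slope, p = _rank_ols(joined["impact"].values, joined["cons"].values)
    slope_rn, p_rn = _rank_ols(rank_inverse_normal(joined["impact"].values),
                               rank_inverse_normal(joined["cons"].values))
    return (RegressionResult(slope=slope, p_value=p, n=len(joined)),
            RegressionResult(slope=slope_rn, p_value=p_rn, n=len(joined)))
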