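"""Chi-square based goodness-of-fit indices and utility thresholds.

Conventions, fixed to reproduce printed large-sample identities:

* the chi-square multiplier is ``n`` (not ``n - 1``);
* RMSEA uses the ``df * n`` denominator;
* SRMR averages squared standardized residuals over all 66 unique
  elements of an 11-variable matrix, diagonal included;
* the model-utility screen is strict: RMSEA < .05, CFI > .95, TLI > .95.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cfa import FitResult, SampleMoments, duplication_matrix, satorra_bentler_scaling

__all__ = [
    "BaselineResult",
    "FitIndices",
    "baseline_chi2",
    "compute_indices",
    "rmsea_ci",
    "srmr",
    "apply_thresholds",
    "fit_indices_for",
]

RMSEA_THRESHOLD = 0.05
CFI_THRESHOLD = 0.95
TLI_THRESHOLD = 0.95


@dataclass
class BaselineResult:
    """Independence-model (zero covariances, free variances) chi-square."""

    chi2_naive: float
    df: int
    chi2_scaled: float | None = None

    def chi2(self, scaled: bool) -> float:
        if scaled and self.chi2_scaled is not None:
            return self.chi2_scaled
        return self.chi2_naive


def baseline_chi2(moments: SampleMoments) -> BaselineResult:
    """Fit of the independence model, which has the closed form
    chi2_b = -n ln|R| (R the sample correlation matrix), df = p(p-1)/2.

    When the moments carry a fourth-moment matrix, the mean-scaled
    baseline statistic is computed as well so that robust incremental
    indices use a consistently scaled baseline.
    """
    s = moments.covariance
    p = s.shape[0]
    d = np.sqrt(np.diag(s))
    r = s / np.outer(d, d)
    sign, logdet_r = np.linalg.slogdet(r)
    if sign <= 0:
        raise ValueError("sample correlation matrix is not positive definite")
    chi2_b = float(-moments.n * logdet_r)
    df_b = p * (p - 1) // 2
    result = BaselineResult(chi2_naive=chi2_b, df=df_b)

    if moments.fourth_moment is not None and df_b > 0:
        sigma0_inv = np.diag(1.0 / np.diag(s))
        dup = duplication_matrix(p)
        weight = 0.5 * dup.T @ np.kron(sigma0_inv, sigma0_inv) @ dup
        # independence model: one free variance per indicator
        i_idx, j_idx = np.tril_indices(p)
        delta = np.zeros((len(i_idx), p))
        for col in range(p):
            delta[(i_idx == col) & (j_idx == col), col] = 1.0
        c = satorra_bentler_scaling(delta, weight, moments.fourth_moment, df_b)
        if np.isfinite(c) and c > 0:
            result.chi2_scaled = chi2_b / c
    return result


@dataclass
class FitIndices:
    """Fit indices for one model; ``cfi``/``tli`` are truncated to [0, 1]
    for reporting with the raw values retained."""

    chi2: float
    df: int
    n: int
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci90: tuple[float, float]
    srmr: float
    cfi_raw: float
    tli_raw: float
    scaled: bool = True

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "df": self.df,
            "cfi": self.cfi,
            "tli": self.tli,
            "srmr": self.srmr,
            "rmsea": self.rmsea,
            "rmsea_ci90_lower": self.rmsea_ci90[0],
            "rmsea_ci90_upper": self.rmsea_ci90[1],
            "scaled": self.scaled,
        }


def srmr(sample_cov: np.ndarray, implied_cov: np.ndarray) -> float:
    """Root of the mean squared standardized (correlation-metric) residual
    over the unique elements, diagonal included."""
    ds = np.sqrt(np.diag(sample_cov))
    di = np.sqrt(np.diag(implied_cov))
    r_s = sample_cov / np.outer(ds, ds)
    r_i = implied_cov / np.outer(di, di)
    resid = r_s - r_i
    i, j = np.tril_indices(sample_cov.shape[0])
    return float(np.sqrt(np.mean(resid[i, j] ** 2)))


def rmsea_ci(chi2: float, df: int, n: int, level: float = 0.90) -> tuple[float, float]:
    """90% interval for RMSEA by inverting the noncentral chi-square in the
    noncentrality parameter; bounds are clipped at zero."""
    if df <= 0:
        raise ValueError("df must be positive")
    lo_q = 1.0 - (1.0 - level) / 2.0  # .95
    hi_q = (1.0 - level) / 2.0  # .05

    def bound(prob: float) -> float:
        # find lambda with P(ncx2(df, lambda) <= chi2) = prob
        if stats.chi2.cdf(chi2, df) < prob:
            return 0.0
        hi = max(chi2 * 2.0, df + 10.0)
        while stats.ncx2.cdf(chi2, df, hi) > prob:
            hi *= 2.0
            if hi > 1e9:
                break
        from scipy.optimize import brentq

        return brentq(lambda lam: stats.ncx2.cdf(chi2, df, lam) - prob, 0.0, hi, xtol=1e-10)

    lam_lo = bound(lo_q)
    lam_hi = bound(hi_q)
    return (
        float(np.sqrt(max(lam_lo, 0.0) / (df * n))),
        float(np.sqrt(max(lam_hi, 0.0) / (df * n))),
    )


def compute_indices(
    chi2: float,
    df: int,
    baseline: BaselineResult,
    n: int,
    sample_cov: np.ndarray,
    implied_cov: np.ndarray,
    scaled: bool = True,
) -> FitIndices:
    """Assemble CFI, TLI, RMSEA (+90% CI) and SRMR from a fitted model's
    chi-square and the independence baseline."""
    if df <= 0:
        raise ValueError("fit indices undefined for df = 0 (saturated model)")
    chi2_b = baseline.chi2(scaled)
    df_b = baseline.df

    excess = max(chi2 - df, 0.0)
    excess_b = max(chi2_b - df_b, 0.0)
    denom = max(excess_b, excess)
    cfi_raw = 1.0 - (excess / denom if denom > 0 else 0.0)

    base_ratio = chi2_b / df_b
    tli_raw = (
        (base_ratio - chi2 / df) / (base_ratio - 1.0) if base_ratio != 1.0 else 1.0
    )

    return FitIndices(
        chi2=float(chi2),
        df=df,
        n=n,
        cfi=float(np.clip(cfi_raw, 0.0, 1.0)),
        tli=float(np.clip(tli_raw, 0.0, 1.0)),
        rmsea=float(np.sqrt(excess / (df * n))),
        rmsea_ci90=rmsea_ci(chi2, df, n),
        srmr=srmr(sample_cov, implied_cov),
        cfi_raw=float(cfi_raw),
        tli_raw=float(tli_raw),
        scaled=scaled,
    )


def fit_indices_for(fit: FitResult, baseline: BaselineResult | None = None, scaled: bool = True) -> FitIndices:
    """Indices for a completed fit; computes the baseline from the fit's
    own sample moments unless one is supplied."""
    if fit.moments is None:
        raise ValueError("fit carries no sample moments")
    if baseline is None:
        baseline = baseline_chi2(fit.moments)
    use_scaled = scaled and fit.chi2_scaled is not None
    chi2 = fit.chi2_scaled if use_scaled else fit.chi2_naive
    return compute_indices(
        chi2=chi2,
        df=fit.df,
        baseline=baseline,
        n=fit.n,
        sample_cov=fit.moments.covariance,
        implied_cov=fit.implied,
        scaled=use_scaled,
    )


def apply_thresholds(indices: FitIndices, admissible: bool | None = None) -> dict:
    """Model-utility screen: RMSEA < .05, CFI > .95, TLI > .95, all strict,
    combined with solution admissibility when supplied."""
    verdict = {
        "rmsea_ok": indices.rmsea < RMSEA_THRESHOLD,
        "cfi_ok": indices.cfi > CFI_THRESHOLD,
        "tli_ok": indices.tli > TLI_THRESHOLD,
    }
    passes = all(verdict.values())
    if admissible is not None:
        verdict["admissible"] = admissible
        passes = passes and admissible
    verdict["passes"] = passes
    return verdict
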