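"""Factor scores and their correlates.

Scores are computed with the regression (Thomson) estimator
``F = Z Sigma^-1 Lambda Phi`` from standardized indicator data, with
Bartlett (GLS) scores available for sensitivity analysis. The general
psychopathology score is conventionally rescaled to an IQ-like metric
(mean 100, SD 15); every correlation reported here is invariant to that
affine rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cfa import FitResult

__all__ = [
    "FactorScores",
    "regression_scores",
    "standardize_scores",
    "cross_derivation_correlations",
    "covariate_correlations",
]


@dataclass
class FactorScores:
    """Per-subject factor score matrix plus provenance metadata."""

    scores: pd.DataFrame
    derivation: str = "total_sample"  # or "subgroup"
    method: str = "regression"
    standardization: dict = field(default_factory=dict)  # factor -> (offset, scale)

    def __getitem__(self, factor: str) -> pd.Series:
        return self.scores[factor]


def _scoring_weights(fit: FitResult, method: str) -> np.ndarray:
    lam = fit.params.loadings
    phi = fit.params.factor_correlations
    if method == "regression":
        sigma = fit.implied
        return np.linalg.solve(sigma, lam @ phi)
    if method == "bartlett":
        theta_inv = np.diag(1.0 / fit.params.residual_variances)
        m = lam.T @ theta_inv @ lam
        return theta_inv @ lam @ np.linalg.inv(m)
    raise ValueError(f"unknown scoring method {method!r}")


def regression_scores(
    fit: FitResult,
    data: pd.DataFrame,
    means: np.ndarray | None = None,
    sds: np.ndarray | None = None,
    method: str = "regression",
    derivation: str = "total_sample",
) -> FactorScores:
    """Score ``data`` with a fitted model's weights.

    ``means``/``sds`` define the standardization applied before scoring;
    they default to the scaling recorded in the fit's sample moments, so
    that scoring subgroup members with a total-sample fit applies the
    total sample's weights and scale without refitting.
    """
    if means is None or sds is None:
        if fit.moments is None or fit.moments.means is None:
            raise ValueError("no standardization available; pass means and sds")
        means = fit.moments.means
        sds = fit.moments.sds
    x = data[list(fit.spec.indicators)].to_numpy(dtype=float)
    z = (x - np.asarray(means)) / np.asarray(sds)
    weights = _scoring_weights(fit, method)
    scores = z @ weights
    return FactorScores(
        scores=pd.DataFrame(scores, columns=list(fit.spec.factor_labels), index=data.index),
        derivation=derivation,
        method=method,
    )


def standardize_scores(
    scores: FactorScores,
    factors: tuple[str, ...] | None = None,
    mean: float = 100.0,
    sd: float = 15.0,
) -> FactorScores:
    """Affinely rescale the named score columns (default: all) to the
    requested mean and SD on the derivation sample. Rank order, and every
    correlation involving the scores, is unchanged."""
    out = scores.scores.copy()
    record = dict(scores.standardization)
    for f in factors if factors is not None else out.columns:
        col = out[f].to_numpy()
        s = col.std(ddof=0)
        if s == 0:
            raise ValueError(f"constant scores for factor {f!r}")
        m = col.mean()
        out[f] = (col - m) / s * sd + mean
        record[f] = {"mean": mean, "sd": sd}
    return FactorScores(
        scores=out,
        derivation=scores.derivation,
        method=scores.method,
        standardization=record,
    )


def _corr_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def cross_derivation_correlations(
    subgroup_scores: FactorScores,
    total_scores: FactorScores,
) -> pd.DataFrame:
    """Pearson correlations between subgroup-derived and total-sample-derived
    scores for the same subjects (rows: subgroup factor; columns: pairs of
    ``r`` and ``p`` per total-sample factor)."""
    a, b = subgroup_scores.scores, total_scores.scores
    if len(a) != len(b):
        raise ValueError("score sets must cover the same subjects")
    rows = {}
    for fa in a.columns:
        row = {}
        for fb in b.columns:
            r, p = _corr_with_p(a[fa].to_numpy(), b[fb].to_numpy())
            row[f"{fb}_r"] = r
            row[f"{fb}_p"] = p
        rows[fa] = row
    return pd.DataFrame(rows).T


def covariate_correlations(scores: FactorScores, covariates: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations of each factor score with each covariate,
    with two-sided p-values and conventional significance stars."""
    if len(scores.scores) != len(covariates):
        raise ValueError("scores and covariates must be row-aligned")
    rows = {}
    for f in scores.scores.columns:
        row = {}
        for c in covariates.columns:
            r, p = _corr_with_p(scores.scores[f].to_numpy(), covariates[c].to_numpy())
            row[f"{c}_r"] = r
            row[f"{c}_p"] = p
            row[f"{c}_sig"] = "**" if p < 0.01 else ("*" if p < 0.05 else "")
        rows[f] = row
    return pd.DataFrame(rows).T
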