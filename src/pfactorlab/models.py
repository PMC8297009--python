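"""Structural model templates and generating parameters.

Four confirmatory factor models of psychopathology over 11 disorder
indicators are supported:

``A_correlated``
    Three correlated specific factors — Externalising (5 substance/conduct
    indicators), Internalising (3 mood/anxiety indicators) and Thought
    Disorder (OCD, mania, schizophrenia) — with all three inter-factor
    correlations free.
``B_bifactor``
    A general factor *p* loading every indicator, orthogonal to three
    specific factors (Ext, Int, Tht) that are themselves mutually
    correlated.
``C_revised_bifactor``
    As B but with the thought-disorder specific factor removed: OCD, mania
    and schizophrenia load on *p* only, and only Ext~Int is free.
``D_single``
    A single general factor.

Identification is by unit factor variance throughout, so parameters live on
the fully standardized metric and generating parameter sets taken from
published standardized solutions can be used directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "INDICATORS",
    "EXT_INDICATORS",
    "INT_INDICATORS",
    "THT_INDICATORS",
    "MODEL_IDS",
    "ModelSpec",
    "ParameterSet",
    "build_model",
    "model_df",
    "implied_covariance",
    "generating_parameters",
    "covariate_targets",
]

#: Canonical indicator order used everywhere in the package.
INDICATORS: tuple[str, ...] = (
    "alc", "cann", "hd", "tob", "cd",
    "dep", "gad", "fears",
    "ocd", "mania", "schiz",
)

EXT_INDICATORS: tuple[str, ...] = ("alc", "cann", "hd", "tob", "cd")
INT_INDICATORS: tuple[str, ...] = ("dep", "gad", "fears")
THT_INDICATORS: tuple[str, ...] = ("ocd", "mania", "schiz")

MODEL_IDS: tuple[str, ...] = (
    "A_correlated", "B_bifactor", "C_revised_bifactor", "D_single",
)

_N_IND = len(INDICATORS)
_N_MOMENTS = _N_IND * (_N_IND + 1) // 2  # 66 unique covariance elements


@dataclass(frozen=True)
class ModelSpec:
    """Declarative template for one structural model.

    Attributes
    ----------
    model_id : str
        One of :data:`MODEL_IDS`.
    indicators : tuple of str
        Ordered indicator labels (always :data:`INDICATORS`).
    factor_labels : tuple of str
        Ordered factor names.
    loading_pattern : ndarray of bool, shape (11, k)
        True where a loading is freely estimated.
    free_factor_correlations : frozenset of frozenset
        Unordered factor pairs with a free correlation.
    fixed_orthogonal : frozenset of frozenset
        Factor pairs whose covariance is fixed to zero.
    """

    model_id: str
    indicators: tuple[str, ...]
    factor_labels: tuple[str, ...]
    loading_pattern: np.ndarray
    free_factor_correlations: frozenset[frozenset[str]]
    fixed_orthogonal: frozenset[frozenset[str]]

    def __post_init__(self) -> None:
        pattern = np.asarray(self.loading_pattern, dtype=bool)
        object.__setattr__(self, "loading_pattern", pattern)
        if pattern.shape != (len(self.indicators), len(self.factor_labels)):
            raise ValueError("loading_pattern shape does not match labels")
        if not pattern.any(axis=1).all():
            raise ValueError("every indicator needs at least one free loading")

    @property
    def n_factors(self) -> int:
        return len(self.factor_labels)

    @property
    def n_free_loadings(self) -> int:
        return int(self.loading_pattern.sum())

    @property
    def n_free_correlations(self) -> int:
        return len(self.free_factor_correlations)

    @property
    def n_free_parameters(self) -> int:
        """Free loadings + free factor correlations + residual variances."""
        return self.n_free_loadings + self.n_free_correlations + len(self.indicators)

    def correlation_pairs(self) -> list[tuple[int, int]]:
        """Free correlation (row, col) index pairs, row < col, sorted."""
        idx = {f: i for i, f in enumerate(self.factor_labels)}
        pairs = sorted(
            tuple(sorted(idx[f] for f in pair))
            for pair in self.free_factor_correlations
        )
        return [(int(a), int(b)) for a, b in pairs]

    def to_dict(self) -> dict:
        """Serializable template (YAML/JSON friendly)."""
        return {
            "model_id": self.model_id,
            "indicators": list(self.indicators),
            "factors": {
                f: [ind for ind, on in zip(self.indicators, self.loading_pattern[:, j]) if on]
                for j, f in enumerate(self.factor_labels)
            },
            "free_factor_correlations": sorted(sorted(p) for p in self.free_factor_correlations),
            "fixed_orthogonal": sorted(sorted(p) for p in self.fixed_orthogonal),
        }


@dataclass
class ParameterSet:
    """Numeric parameters for a :class:`ModelSpec` on the standardized metric.

    ``loadings`` must be zero wherever the spec's pattern is False;
    ``factor_correlations`` has a unit diagonal; ``residual_variances`` is
    the length-11 diagonal of the unique-variance matrix.
    """

    loadings: np.ndarray
    factor_correlations: np.ndarray
    residual_variances: np.ndarray
    factor_labels: tuple[str, ...] = ()
    indicators: tuple[str, ...] = INDICATORS

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.factor_correlations = np.asarray(self.factor_correlations, dtype=float)
        self.residual_variances = np.asarray(self.residual_variances, dtype=float)
        k = self.loadings.shape[1]
        if self.factor_correlations.shape != (k, k):
            raise ValueError("factor correlation matrix has wrong shape")
        if not np.allclose(np.diag(self.factor_correlations), 1.0):
            raise ValueError("factor correlations must have unit diagonal")
        if not np.allclose(self.factor_correlations, self.factor_correlations.T):
            raise ValueError("factor correlations must be symmetric")

    def conforms_to(self, spec: ModelSpec) -> bool:
        """True if loadings are zero outside the spec's free pattern."""
        if self.loadings.shape != spec.loading_pattern.shape:
            return False
        return bool(np.all(self.loadings[~spec.loading_pattern] == 0.0))

    @property
    def communalities(self) -> np.ndarray:
        lam, phi = self.loadings, self.factor_correlations
        return np.einsum("if,fg,ig->i", lam, phi, lam)


def build_model(model_id: str) -> ModelSpec:
    """Return the fixed template for one of the four structural models."""
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")

    def pattern(blocks: Mapping[str, tuple[str, ...]]) -> tuple[tuple[str, ...], np.ndarray]:
        factors = tuple(blocks)
        mat = np.zeros((_N_IND, len(factors)), dtype=bool)
        for j, f in enumerate(factors):
            for ind in blocks[f]:
                mat[INDICATORS.index(ind), j] = True
        return factors, mat

    if model_id == "A_correlated":
        factors, mat = pattern({"Ext": EXT_INDICATORS, "Int": INT_INDICATORS, "Tht": THT_INDICATORS})
        free = frozenset({frozenset({"Ext", "Int"}), frozenset({"Ext", "Tht"}), frozenset({"Int", "Tht"})})
        orth: frozenset = frozenset()
    elif model_id == "B_bifactor":
        factors, mat = pattern({
            "p": INDICATORS, "Ext": EXT_INDICATORS,
            "Int": INT_INDICATORS, "Tht": THT_INDICATORS,
        })
        free = frozenset({frozenset({"Ext", "Int"}), frozenset({"Ext", "Tht"}), frozenset({"Int", "Tht"})})
        orth = frozenset({frozenset({"p", "Ext"}), frozenset({"p", "Int"}), frozenset({"p", "Tht"})})
    elif model_id == "C_revised_bifactor":
        factors, mat = pattern({"p": INDICATORS, "Ext": EXT_INDICATORS, "Int": INT_INDICATORS})
        free = frozenset({frozenset({"Ext", "Int"})})
        orth = frozenset({frozenset({"p", "Ext"}), frozenset({"p", "Int"})})
    else:  # D_single
        factors, mat = pattern({"p": INDICATORS})
        free = frozenset()
        orth = frozenset()

    return ModelSpec(
        model_id=model_id,
        indicators=INDICATORS,
        factor_labels=factors,
        loading_pattern=mat,
        free_factor_correlations=free,
        fixed_orthogonal=orth,
    )


def model_df(spec: ModelSpec) -> int:
    """Degrees of freedom for a covariance-structure-only analysis.

    66 unique moments of an 11-variable covariance matrix minus free
    loadings, free factor correlations and the 11 residual variances.
    """
    return _N_MOMENTS - spec.n_free_parameters


def implied_covariance(spec: ModelSpec, params: ParameterSet) -> np.ndarray:
    """Model-implied covariance matrix Sigma = Lambda Phi Lambda' + Theta."""
    lam = params.loadings
    if lam.shape != spec.loading_pattern.shape:
        raise ValueError("loading matrix does not match model pattern shape")
    if not params.conforms_to(spec):
        raise ValueError("nonzero loading outside the model's free pattern")
    sigma = lam @ params.factor_correlations @ lam.T + np.diag(params.residual_variances)
    return (sigma + sigma.T) / 2.0


# ---------------------------------------------------------------------------
# Packaged generating parameters
# ---------------------------------------------------------------------------

def _read_data(name: str) -> pd.DataFrame:
    with resources.files("pfactorlab.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def generating_parameters(source: str = "caspi", model: str = "revised_bifactor") -> ParameterSet:
    """Published standardized generating parameters.

    Parameters
    ----------
    source : {"caspi", "simdata"}
        ``"caspi"`` is the original empirical standardized solution
        (Ext~Int = -.471); ``"simdata"`` is the solution refitted to the
        simulated population (Ext~Int = -.387).
    model : {"revised_bifactor", "correlated"}
        Which structural model the parameter set belongs to.

    Residual variances are completed as 1 minus each indicator's
    communality, so the implied matrix is a correlation matrix.
    """
    if model == "revised_bifactor":
        spec = build_model("C_revised_bifactor")
        table = _read_data("bifactor_loadings.csv")
    elif model == "correlated":
        spec = build_model("A_correlated")
        table = _read_data("correlated_loadings.csv")
    else:
        raise ValueError(f"unknown generating model {model!r}")
    table = table[table["source"] == source]
    if table.empty:
        raise ValueError(f"unknown source {source!r}")

    lam = np.zeros((_N_IND, spec.n_factors))
    for _, row in table.iterrows():
        j = spec.factor_labels.index(row["factor"])
        vals = row[list(INDICATORS)].to_numpy(dtype=float)
        lam[:, j] = np.where(np.isnan(vals), 0.0, vals)

    corr_tab = _read_data("factor_correlations.csv")
    corr_tab = corr_tab[(corr_tab["source"] == source) & (corr_tab["model"] == model)]
    phi = np.eye(spec.n_factors)
    for _, row in corr_tab.iterrows():
        a = spec.factor_labels.index(row["factor_a"])
        b = spec.factor_labels.index(row["factor_b"])
        phi[a, b] = phi[b, a] = float(row["value"])

    communality = np.einsum("if,fg,ig->i", lam, phi, lam)
    params = ParameterSet(
        loadings=lam,
        factor_correlations=phi,
        residual_variances=1.0 - communality,
        factor_labels=spec.factor_labels,
    )
    if not params.conforms_to(spec):
        raise ValueError("packaged parameters violate the model pattern")
    return params


def covariate_targets(source: str = "caspi") -> pd.DataFrame:
    """Target factor-covariate correlations (factor rows x VC/PR/WM/PS).

    Rows are indexed by factor (p, Ext, Int); columns are the four IQ
    subscale composites.
    """
    table = _read_data("covariate_targets.csv")
    table = table[table["source"] == source]
    if table.empty:
        raise ValueError(f"unknown source {source!r}")
    out = table.set_index("factor")[["VC", "PR", "WM", "PS"]].astype(float)
    if (out.abs() >= 1).any().any():
        raise ValueError("covariate targets must be valid correlations")
    return out
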