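"""Tertile-based overlapping subgroups.

Subjects are cut into thirds of the full sample three ways: per disorder
symptom variable, on the externalising and internalising factor scores,
and on the general *p* score. Thirds are coded 1 = upper, 2 = middle,
3 = lower. A subgroup is defined by a class (ext, int, tht) and a triple
of thirds:

* ext variant ``a(ext)-b(ext)-c``: at least one of the five externalising
  disorders in symptom third ``a``, Ext factor score in third ``b`` and
  *p* score in third ``c``;
* int variant analogously over the three internalising disorders and the
  Int score;
* tht variant ``a(tht)-X-c``: at least one thought disorder (OCD, mania,
  schizophrenia) in symptom third ``a`` and *p* in third ``c`` — there is
  no thought-disorder factor in the scoring model, hence the ``X``.

That yields 27 + 27 + 9 = 63 overlapping subgroups: the "at least one
disorder" rule means a subject with one disorder in the upper third and
another in the lower third belongs to variants with both ``a`` values.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import EXT_INDICATORS, INT_INDICATORS, THT_INDICATORS, INDICATORS

__all__ = [
    "SubgroupDefinition",
    "tertile_labels",
    "enumerate_subgroups",
    "format_label",
    "parse_label",
]

_CLASS_DISORDERS = {
    "ext": EXT_INDICATORS,
    "int": INT_INDICATORS,
    "tht": THT_INDICATORS,
}
_CLASS_FACTOR = {"ext": "Ext", "int": "Int"}


@dataclass
class SubgroupDefinition:
    """One subgroup: membership rule plus the resolved subject index set."""

    subgroup_class: str  # "ext", "int" or "tht"
    symptom_third: int
    factor_third: int | None  # None for the tht class
    p_third: int
    member_ids: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        if self.subgroup_class not in _CLASS_DISORDERS:
            raise ValueError(f"unknown subgroup class {self.subgroup_class!r}")
        if not self.label:
            self.label = format_label(self)

    @property
    def n(self) -> int:
        return len(self.member_ids)


def tertile_labels(values: np.ndarray) -> np.ndarray:
    """Thirds of the full sample: 1 = upper, 2 = middle, 3 = lower.

    Cut points are the empirical 1/3 and 2/3 quantiles; a value tied with
    a cut point goes to the higher (lower-numbered) category.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values to form thirds")
    q13, q23 = np.quantile(x, [1.0 / 3.0, 2.0 / 3.0])
    if q13 == q23:
        warnings.warn("degenerate tertile cut: values collapse into one category")
    out = np.full(x.shape, 3, dtype=int)
    out[x >= q13] = 2
    out[x >= q23] = 1
    return out


def format_label(definition: SubgroupDefinition) -> str:
    c = definition.subgroup_class
    if c == "tht":
        return f"{definition.symptom_third}(tht)-X-{definition.p_third}"
    return f"{definition.symptom_third}({c})-{definition.factor_third}({c})-{definition.p_third}"


_LABEL_RE = re.compile(
    r"^(?P<a>[123])\((?P<cls>ext|int|tht)\)-(?:(?P<b>[123])\((?P=cls)\)|X)-(?P<c>[123])$"
)


def parse_label(label: str) -> tuple[str, int, int | None, int]:
    """Inverse of :func:`format_label`: (class, symptom third, factor third, p third)."""
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"malformed subgroup label {label!r}")
    cls = m.group("cls")
    b = m.group("b")
    if (cls == "tht") != (b is None):
        raise ValueError(f"malformed subgroup label {label!r}")
    return cls, int(m.group("a")), None if b is None else int(b), int(m.group("c"))


def enumerate_subgroups(
    symptoms: pd.DataFrame,
    factor_scores: pd.DataFrame,
) -> list[SubgroupDefinition]:
    """Resolve all 63 subgroup definitions against a population.

    ``symptoms`` holds the 11 disorder columns; ``factor_scores`` must
    provide total-sample ``Ext``, ``Int`` and ``p`` columns. Thirds are
    always computed on the full sample, never within a subgroup.
    """
    for col in ("Ext", "Int", "p"):
        if col not in factor_scores.columns:
            raise ValueError(f"factor_scores is missing column {col!r}")
    sym_thirds = {
        d: tertile_labels(symptoms[d].to_numpy()) for d in INDICATORS
    }
    score_thirds = {
        f: tertile_labels(factor_scores[f].to_numpy()) for f in ("Ext", "Int", "p")
    }
    index = symptoms.index.to_numpy()

    defs: list[SubgroupDefinition] = []
    for cls in ("ext", "int", "tht"):
        disorders = _CLASS_DISORDERS[cls]
        sym_stack = np.stack([sym_thirds[d] for d in disorders])
        for a in (1, 2, 3):
            any_in_a = (sym_stack == a).any(axis=0)
            if cls == "tht":
                for c in (1, 2, 3):
                    mask = any_in_a & (score_thirds["p"] == c)
                    defs.append(
                        SubgroupDefinition(
                            subgroup_class=cls,
                            symptom_third=a,
                            factor_third=None,
                            p_third=c,
                            member_ids=index[mask],
                        )
                    )
            else:
                fac = score_thirds[_CLASS_FACTOR[cls]]
                for b in (1, 2, 3):
                    in_b = fac == b
                    for c in (1, 2, 3):
                        mask = any_in_a & in_b & (score_thirds["p"] == c)
                        defs.append(
                            SubgroupDefinition(
                                subgroup_class=cls,
                                symptom_third=a,
                                factor_third=b,
                                p_third=c,
                                member_ids=index[mask],
                            )
                        )
    assert len(defs) == 63
    return defs


def subgroup_manifest(definitions: list[SubgroupDefinition]) -> pd.DataFrame:
    """Summary table: label, class, thirds and realized size per subgroup."""
    return pd.DataFrame(
        {
            "label": [d.label for d in definitions],
            "class": [d.subgroup_class for d in definitions],
            "symptom_third": [d.symptom_third for d in definitions],
            "factor_third": [d.factor_third for d in definitions],
            "p_third": [d.p_third for d in definitions],
            "n": [d.n for d in definitions],
        }
    )
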