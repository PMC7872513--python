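"""Biological-aging indicators and composite indices.

An *aging indicator* is the residual of regressing predicted biological age on
chronological age (so it is exactly orthogonal to age); a positive value means
the subject is biologically older than expected for their age.  The telomere
layer is special-cased: the measured T/S ratio is multiplied by -1 and
standardized, but not age-regressed, so that on every indicator a larger
value means "older".

Two composite indices combine the five indicators on the subjects with all
five layers available: the sum of z-scored indicators, and the first
principal component of their correlation matrix (sign-oriented so the loading
sum is positive).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import InputError, LAYERS

__all__ = [
    "AgingIndicatorSet",
    "CompositeIndex",
    "residualize_on_age",
    "telomere_indicator",
    "composite_sum",
    "composite_pc1",
]


def residualize_on_age(predicted_age, chronological_age) -> np.ndarray:
    """OLS residuals of predicted biological age on chronological age.

    The residuals have mean zero and are exactly orthogonal to chronological
    age (normal equations), which is what makes downstream association models
    independent of age by construction.
    """
    yhat = np.asarray(predicted_age, dtype=float)
    age = np.asarray(chronological_age, dtype=float)
    if yhat.shape != age.shape:
        raise InputError("predicted and chronological age must have equal length")
    if len(age) < 3:
        raise InputError("age residualization needs at least 3 subjects")
    if age.std() == 0:
        raise InputError("chronological age is constant; slope undefined")
    ac = age - age.mean()
    slope = (ac @ (yhat - yhat.mean())) / (ac @ ac)
    intercept = yhat.mean() - slope * age.mean()
    return yhat - (intercept + slope * age)


def telomere_indicator(ts_ratio) -> np.ndarray:
    """Standardized negated telomere length (shorter telomere = older).

    Value = -T/S, then z-scored (SD with n-1 denominator); *not* age-regressed.
    """
    ts = np.asarray(ts_ratio, dtype=float)
    sd = ts.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise InputError("telomere values have zero variance")
    return -(ts - ts.mean()) / sd


@dataclass
class AgingIndicatorSet:
    """Per-subject aging values for the five layers.

    ``indicators`` is subjects x layers with NaN where a subject was not
    measured on a layer; ``age_regressed`` flags which columns are residuals
    of a clock (all but telomere).
    """

    indicators: pd.DataFrame
    age_regressed: dict[str, bool] = field(
        default_factory=lambda: {layer: layer != "telomere" for layer in LAYERS}
    )

    @property
    def overlap_ids(self) -> pd.Index:
        present = [l for l in self.indicators.columns]
        return self.indicators.index[self.indicators[present].notna().all(axis=1)]

    def missing_layers(self, required=LAYERS) -> list[str]:
        return [l for l in required if l not in self.indicators.columns]


@dataclass
class CompositeIndex:
    variant: str  # "sum" | "pc1"
    values: pd.Series
    scaling_means: pd.Series
    scaling_sds: pd.Series
    loadings: pd.Series | None = None
    leading_eigenvalue: float | None = None

    def to_json(self, path: str | Path) -> None:
        d = {
            "variant": self.variant,
            "scaling_means": self.scaling_means.to_dict(),
            "scaling_sds": self.scaling_sds.to_dict(),
        }
        if self.loadings is not None:
            d["loadings"] = self.loadings.to_dict()
            d["leading_eigenvalue"] = self.leading_eigenvalue
        Path(path).write_text(json.dumps(d, indent=1))


def _scaled_overlap(indicators: AgingIndicatorSet, required=LAYERS):
    missing = indicators.missing_layers(required)
    if missing:
        raise InputError(f"composite requires layers {list(required)}; missing: {missing}")
    overlap = indicators.overlap_ids
    if len(overlap) < 2:
        raise InputError(
            f"composite needs at least 2 overlap subjects, got {len(overlap)}"
        )
    block = indicators.indicators.loc[overlap, list(required)]
    means = block.mean()
    sds = block.std(ddof=1)
    if (sds == 0).any():
        raise InputError(
            f"zero-variance indicator(s) on the overlap: {sds.index[sds == 0].tolist()}"
        )
    return (block - means) / sds, means, sds


def composite_sum(indicators: AgingIndicatorSet, required=LAYERS) -> CompositeIndex:
    """Sum of the five z-scored indicators on the overlap subjects."""
    z, means, sds = _scaled_overlap(indicators, required)
    return CompositeIndex(
        variant="sum",
        values=z.sum(axis=1).rename("composite_sum"),
        scaling_means=means,
        scaling_sds=sds,
    )


def composite_pc1(indicators: AgingIndicatorSet, required=LAYERS) -> CompositeIndex:
    """First principal component of the five indicators' correlation matrix.

    Loadings are the unit-norm leading eigenvector, sign-oriented so their sum
    is positive; scores are the z-scored indicator matrix times the loadings.
    """
    z, means, sds = _scaled_overlap(indicators, required)
    C = np.cov(z.to_numpy(), rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(C)
    if len(eigvals) > 1 and np.isclose(eigvals[-1], eigvals[-2], rtol=0, atol=1e-12):
        warnings.warn(
            "tied leading eigenvalues; PC1 chosen by eigensolver order",
            stacklevel=2,
        )
    w = eigvecs[:, -1]
    total = w.sum()
    if total < 0 or (total == 0 and w[np.nonzero(w)[0][0]] < 0):
        w = -w
    loadings = pd.Series(w, index=z.columns, name="pc1_loading")
    scores = pd.Series(z.to_numpy() @ w, index=z.index, name="composite_pc1")
    return CompositeIndex(
        variant="pc1",
        values=scores,
        scaling_means=means,
        scaling_sds=sds,
        loadings=loadings,
        leading_eigenvalue=float(eigvals[-1]),
    )
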