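"""Per-layer preprocessing: missingness handling, technical residualization,
quantile-normal transformation.

The per-platform missingness rules mirror the conventions of targeted NMR
metabolomics (absolute missing-count filters, median imputation) and
multiplexed immunoassay proteomics (fractional missingness filter, imputation
at the detection limits).  All panels are then residualized on technical
covariates (batch, lab) and each marker is mapped to normal quantiles.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .cohort import OmicsLayer
from .config import InputError, PreprocessConfig

__all__ = [
    "PreprocessReport",
    "filter_and_impute_metabolomics",
    "filter_and_impute_proteins",
    "residualize_technical",
    "quantile_normal_transform",
    "preprocess_layer",
]


@dataclass
class PreprocessReport:
    layer: str
    n_subjects_removed: int = 0
    subjects_removed: list[str] = field(default_factory=list)
    n_markers_removed: int = 0
    markers_removed: list[str] = field(default_factory=list)
    n_imputed: int = 0
    impute_method: str | None = None
    covariates_residualized: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def filter_and_impute_metabolomics(
    layer: OmicsLayer,
    max_missing_per_subject: int = 25,
    max_missing_per_marker: int = 250,
) -> tuple[OmicsLayer, PreprocessReport]:
    """Metabolite-panel missingness handling.

    Subjects with more missing markers than ``max_missing_per_subject`` are
    removed first; then markers with more missing values than
    ``max_missing_per_marker`` (markers left with no observed value at all are
    removed regardless); remaining missings are replaced by the per-marker
    median of observed values.
    """
    if max_missing_per_subject < 0 or max_missing_per_marker < 0:
        raise InputError("missingness thresholds must be >= 0")
    out = layer.copy()
    report = PreprocessReport(layer=layer.name, impute_method="marker_median")

    subj_missing = out.mask.sum(axis=1)
    drop_subj = subj_missing.index[subj_missing > max_missing_per_subject]
    report.subjects_removed = drop_subj.tolist()
    report.n_subjects_removed = len(drop_subj)
    keep = subj_missing.index[subj_missing <= max_missing_per_subject]
    out.values = out.values.loc[keep]
    out.mask = out.mask.loc[keep]
    out.batch = out.batch.loc[keep]
    if out.lab is not None:
        out.lab = out.lab.loc[keep]
    if out.upper_mask is not None:
        out.upper_mask = out.upper_mask.loc[keep]

    marker_missing = out.mask.sum(axis=0)
    all_missing = marker_missing.index[marker_missing >= len(out.values)]
    drop_mark = marker_missing.index[marker_missing > max_missing_per_marker]
    drop_mark = drop_mark.union(all_missing, sort=False)
    if len(all_missing) and not all_missing.isin(
        marker_missing.index[marker_missing > max_missing_per_marker]
    ).all():
        report.warnings.append(
            f"markers entirely missing after subject filtering removed: "
            f"{all_missing.tolist()}"
        )
    report.markers_removed = drop_mark.tolist()
    report.n_markers_removed = len(drop_mark)
    keep_m = out.values.columns[~out.values.columns.isin(drop_mark)]
    out.values = out.values[keep_m]
    out.mask = out.mask[keep_m]
    if out.upper_mask is not None:
        out.upper_mask = out.upper_mask[keep_m]

    report.n_imputed = int(out.mask.to_numpy().sum())
    medians = out.values.median(axis=0, skipna=True)
    out.values = out.values.fillna(medians)
    out.mask = out.values.isna()
    out.upper_mask = None
    out.lower_limits = out.upper_limits = None
    return out, report


def filter_and_impute_proteins(
    layer: OmicsLayer, max_missing_fraction: float = 0.30
) -> tuple[OmicsLayer, PreprocessReport]:
    """Protein-panel missingness handling.

    Analytes missing in more than ``max_missing_fraction`` of subjects are
    removed; remaining censored entries are imputed at the detection limit
    (lower limit for below-range, upper limit for above-range entries).
    """
    if not 0 <= max_missing_fraction <= 1:
        raise InputError("max_missing_fraction must be in [0, 1]")
    out = layer.copy()
    report = PreprocessReport(layer=layer.name, impute_method="detection_limit")

    frac = out.mask.mean(axis=0)
    drop = frac.index[frac > max_missing_fraction]
    report.markers_removed = drop.tolist()
    report.n_markers_removed = len(drop)
    keep = frac.index[frac <= max_missing_fraction]
    out.values = out.values[keep]
    out.mask = out.mask[keep]
    upper = out.upper_mask[keep] if out.upper_mask is not None else None

    report.n_imputed = int(out.mask.to_numpy().sum())
    for marker in keep:
        col_mask = out.mask[marker]
        if not col_mask.any():
            continue
        up = upper[marker] if upper is not None else pd.Series(False, index=col_mask.index)
        low = col_mask & ~up
        if low.any():
            if out.lower_limits is None or marker not in out.lower_limits.index or pd.isna(
                out.lower_limits[marker]
            ):
                raise InputError(
                    f"marker {marker!r} has below-limit entries but no lower "
                    "detection limit configured"
                )
            out.values.loc[low, marker] = out.lower_limits[marker]
        if (col_mask & up).any():
            if out.upper_limits is None or marker not in out.upper_limits.index or pd.isna(
                out.upper_limits[marker]
            ):
                raise InputError(
                    f"marker {marker!r} has above-limit entries but no upper "
                    "detection limit configured"
                )
            out.values.loc[col_mask & up, marker] = out.upper_limits[marker]
    out.mask = out.values.isna()
    out.upper_mask = None
    return out, report


def residualize_technical(
    layer: OmicsLayer, covariates: tuple[str, ...] = ("batch", "lab")
) -> OmicsLayer:
    """Replace each marker by its residual from OLS on the technical factors.

    Factors are entered as indicator codes with an intercept; after the
    operation every (batch, lab) level has marker mean 0 up to numerical
    tolerance.  A level with a single subject simply gets residual 0 (with a
    warning); a layer with a single level reduces to mean-centering.
    """
    if layer.mask.to_numpy().any():
        raise InputError(
            f"layer {layer.name!r} still has missing entries; run the "
            "missingness step first"
        )
    out = layer.copy()
    factors = {}
    if "batch" in covariates:
        factors["batch"] = out.batch
    if "lab" in covariates and out.lab is not None:
        factors["lab"] = out.lab
    design = [np.ones((len(out.values), 1))]
    for name, fac in factors.items():
        counts = fac.value_counts()
        singletons = counts.index[counts == 1]
        if len(singletons):
            warnings.warn(
                f"{layer.name}: {name} level(s) {singletons.tolist()} have a "
                "single subject; their residuals are 0",
                stacklevel=2,
            )
        dummies = pd.get_dummies(fac, drop_first=True, dtype=float)
        if dummies.shape[1]:
            design.append(dummies.to_numpy())
    X = np.hstack(design)
    Y = out.values.to_numpy()
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    out.values = pd.DataFrame(
        Y - X @ coef, index=out.values.index, columns=out.values.columns
    )
    return out


def quantile_normal_transform(matrix: pd.DataFrame | np.ndarray):
    """Map each marker to normal quantiles: Phi^-1((rank - 0.5) / n).

    Ties get average ranks; a constant marker maps to all zeros (warning).
    The transform is monotone in the input within each marker and gives every
    non-constant marker the same symmetric, zero-mean marginal.
    """
    arr = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    if arr.ndim == 1:
        arr = arr[:, None]
        squeeze = True
    else:
        squeeze = False
    n = arr.shape[0]
    if n < 2:
        raise InputError("quantile-normal transform needs >= 2 subjects")
    if np.isnan(arr).any():
        raise InputError("quantile-normal transform requires complete data")
    out = np.empty_like(arr, dtype=float)
    constant = arr.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant marker(s) set to all zeros",
            stacklevel=2,
        )
    ranks = rankdata(arr, axis=0, method="average")
    out = norm.ppf((ranks - 0.5) / n)
    out[:, constant] = 0.0
    if squeeze:
        out = out[:, 0]
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def preprocess_layer(
    layer: OmicsLayer, config: PreprocessConfig | None = None
) -> tuple[OmicsLayer, PreprocessReport]:
    """Apply the per-layer pipeline: missingness -> residualize -> normalize.

    The telomere layer is a direct single-marker measurement and bypasses all
    steps.  Epigenetic/transcriptomic panels are assumed complete (their
    upstream platform QC is out of scope) and only go through residualization
    and normalization.
    """
    cfg = config or PreprocessConfig()
    if layer.name == "telomere":
        return layer.copy(), PreprocessReport(layer="telomere")
    if layer.name == "metabolomic":
        out, report = filter_and_impute_metabolomics(
            layer,
            cfg.metabolomic_max_missing_per_subject,
            cfg.metabolomic_max_missing_per_marker,
        )
    elif layer.name == "proteomic":
        out, report = filter_and_impute_proteins(layer, cfg.protein_max_missing_fraction)
    else:
        out, report = layer.copy(), PreprocessReport(layer=layer.name)
        if out.mask.to_numpy().any():
            raise InputError(
                f"layer {layer.name!r} has missing entries but no missingness "
                "rule is defined for it"
            )
    out = residualize_technical(out)
    report.covariates_residualized = ["batch"] + (["lab"] if out.lab is not None else [])
    out.values = quantile_normal_transform(out.values)
    return out, report
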