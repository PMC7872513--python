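"""Tab-separated on-disk formats for cohorts, layers and result tables.

All tables are TSV with a header row, "NA" for missing entries, and an
optional leading ``#`` comment line carrying the root seed and config hash of
the run that produced them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import OmicsLayer
from .config import InputError

NA = "NA"
FLOAT_FMT = "%.10g"


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    header_comment: str | None = None,
    index: bool = True,
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", na_rep=NA, float_format=FLOAT_FMT, index=index)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", na_values=[NA], index_col=index_col
    )


def write_cohort(cohort: pd.DataFrame, path: str | Path, header_comment=None) -> None:
    write_table(cohort, path, header_comment=header_comment)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = read_table(path, index_col="subject_id")
    if df.index.duplicated().any():
        raise InputError(f"duplicate subject ids in {path}")
    return df


def write_layer(layer: OmicsLayer, path: str | Path, header_comment=None) -> None:
    """Layer TSV: subject_id, batch[, lab], then one column per marker
    (missing entries as NA); detection limits in a JSON sidecar."""
    meta = pd.DataFrame({"batch": layer.batch})
    if layer.lab is not None:
        meta["lab"] = layer.lab
    df = pd.concat([meta, layer.values], axis=1)
    write_table(df, path, header_comment=header_comment)
    sidecar = {}
    if layer.lower_limits is not None:
        sidecar["lower_limits"] = layer.lower_limits.to_dict()
    if layer.upper_limits is not None:
        sidecar["upper_limits"] = layer.upper_limits.to_dict()
    if layer.upper_mask is not None and layer.upper_mask.to_numpy().any():
        rows, cols = np.where(layer.upper_mask.to_numpy())
        sidecar["upper_censored"] = [
            [layer.upper_mask.index[i], layer.upper_mask.columns[j]]
            for i, j in zip(rows, cols)
        ]
    if sidecar:
        Path(str(path) + ".limits.json").write_text(json.dumps(sidecar, indent=1))


def read_layer(path: str | Path, name: str) -> OmicsLayer:
    df = read_table(path, index_col="subject_id")
    if df.index.duplicated().any():
        raise InputError(f"duplicate subject ids in {path}")
    batch = df.pop("batch").astype(str)
    lab = df.pop("lab").astype(str) if "lab" in df.columns else None
    lower = upper = upper_mask = None
    sidecar_path = Path(str(path) + ".limits.json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        if "lower_limits" in sidecar:
            lower = pd.Series(sidecar["lower_limits"], name="lower_limit")
        if "upper_limits" in sidecar:
            upper = pd.Series(sidecar["upper_limits"], name="upper_limit")
        if "upper_censored" in sidecar:
            upper_mask = pd.DataFrame(False, index=df.index, columns=df.columns)
            for subj, marker in sidecar["upper_censored"]:
                upper_mask.loc[subj, marker] = True
    return OmicsLayer(
        name=name,
        values=df.astype(float),
        batch=batch,
        lab=lab,
        upper_mask=upper_mask,
        lower_limits=lower,
        upper_limits=upper,
    )


def write_json(obj, path: str | Path) -> None:
    def conv(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(obj, indent=1, default=conv))
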