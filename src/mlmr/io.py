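"""File formats: CSV/TSV feature + label tables, Mulan-style ARFF, provenance.

Canonical on-disk label encoding is {-1, 0, +1}: -1 absent, +1 present,
an all-zero row meaning the instance is unlabeled.  Files using the 0/1
multi-label dialect must be read with ``zero_one_labels=True`` so that
"negative" is never silently conflated with "unlabeled".  Matrices are
written with a header row and an instance-id first column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

__all__ = [
    "DatasetBundle",
    "read_dataset",
    "write_dataset",
    "read_arff_mulan",
    "write_provenance",
]


@dataclass
class DatasetBundle:
    features: np.ndarray
    labels: np.ndarray
    label_names: list[str]
    instance_ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.features.shape[0] != self.labels.shape[0]:
            raise InvalidInputError(
                f"feature rows ({self.features.shape[0]}) != label rows ({self.labels.shape[0]})"
            )
        if len(set(self.label_names)) != len(self.label_names):
            raise InvalidInputError("label names must be unique")


def _read_table(path: str | Path, sep: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise InvalidInputError(f"{path}: malformed table ({exc})") from exc
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            bad = int(np.flatnonzero(coerced.isna())[0])
            raise InvalidInputError(
                f"{path}: non-numeric value {df[col].iloc[bad]!r} "
                f"in column {col!r}, data line {bad + 2}"
            )
        df[col] = coerced
    return df


def read_dataset(
    features_path: str | Path,
    labels_path: str | Path,
    fmt: str = "csv",
    zero_one_labels: bool = False,
) -> DatasetBundle:
    """Read a feature table and label table pair.

    Labels must be in {-1, 0, +1} unless ``zero_one_labels`` is set, in
    which case the 0/1 dialect is mapped to -1/+1 (and no row can be
    marked unlabeled).
    """
    if fmt not in ("csv", "tsv"):
        raise InvalidInputError(f"unknown format {fmt!r}; use csv, tsv or read_arff_mulan")
    sep = "," if fmt == "csv" else "\t"
    fdf = _read_table(features_path, sep)
    ldf = _read_table(labels_path, sep)
    if fdf.shape[0] != ldf.shape[0]:
        raise InvalidInputError(
            f"row count mismatch: {features_path} has {fdf.shape[0]}, "
            f"{labels_path} has {ldf.shape[0]}"
        )
    labels = ldf.to_numpy()
    if zero_one_labels:
        if not np.isin(labels, (0, 1)).all():
            raise InvalidInputError(f"{labels_path}: 0/1 dialect declared but values outside {{0,1}}")
        labels = np.where(labels == 1, 1, -1)
    elif not np.isin(labels, (-1, 0, 1)).all():
        raise InvalidInputError(
            f"{labels_path}: label values outside {{-1, 0, +1}}; "
            "pass zero_one_labels=True for the 0/1 dialect"
        )
    return DatasetBundle(
        features=fdf.to_numpy(dtype=float),
        labels=labels.astype(np.int8),
        label_names=[str(c) for c in ldf.columns],
        instance_ids=[str(i) for i in fdf.index],
        meta={"features_path": str(features_path), "labels_path": str(labels_path)},
    )


def write_dataset(
    features_path: str | Path,
    labels_path: str | Path,
    X: np.ndarray,
    Y: np.ndarray,
    label_names: list[str] | None = None,
    instance_ids: list[str] | None = None,
    fmt: str = "csv",
) -> None:
    sep = "," if fmt == "csv" else "\t"
    n, d = X.shape
    L = Y.shape[1]
    ids = instance_ids or [f"i{r}" for r in range(n)]
    lnames = label_names or [f"label{j + 1}" for j in range(L)]
    pd.DataFrame(X, index=pd.Index(ids, name="id"),
                 columns=[f"f{j + 1}" for j in range(d)]).to_csv(features_path, sep=sep)
    pd.DataFrame(Y, index=pd.Index(ids, name="id"), columns=lnames).to_csv(labels_path, sep=sep)


def read_arff_mulan(arff_path: str | Path, xml_path: str | Path) -> DatasetBundle:
    """Read a Mulan-dialect multi-label ARFF file with its XML label list.

    The XML companion names the label attributes; every other numeric
    attribute is a feature.  Nominal {0,1} label attributes are mapped to
    -1/+1.  Only dense ARFF is supported.
    """
    import xml.etree.ElementTree as ET

    from scipy.io import arff as scipy_arff

    root = ET.parse(xml_path).getroot()
    label_names = [el.attrib["name"] for el in root.iter() if el.tag.endswith("label")]
    if not label_names:
        raise InvalidInputError(f"{xml_path}: no <label> elements found")
    data, meta = scipy_arff.loadarff(str(arff_path))
    cols = list(meta.names())
    missing = [ln for ln in label_names if ln not in cols]
    if missing:
        raise InvalidInputError(f"{arff_path}: label attributes missing from ARFF: {missing}")
    feat_cols = [c for c in cols if c not in label_names]

    def _num(col):
        v = data[col]
        if v.dtype.kind == "S":  # nominal attributes arrive as bytes
            return np.array([float(x.decode()) for x in v])
        return v.astype(float)

    X = np.column_stack([_num(c) for c in feat_cols]) if feat_cols else np.empty((len(data), 0))
    Yraw = np.column_stack([_num(c) for c in label_names])
    if not np.isin(Yraw, (0, 1)).all():
        raise InvalidInputError(f"{arff_path}: label attributes must be 0/1")
    Y = np.where(Yraw == 1, 1, -1).astype(np.int8)
    return DatasetBundle(
        features=X,
        labels=Y,
        label_names=label_names,
        instance_ids=[f"i{r}" for r in range(X.shape[0])],
        meta={"arff_path": str(arff_path), "xml_path": str(xml_path)},
    )


def write_provenance(path: str | Path, payload: dict) -> None:
    """JSON provenance record (config, seeds, package version)."""
    from . import __version__

    record = {"mlmr_version": __version__, **payload}
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
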