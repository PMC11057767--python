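"""CSV loading and preprocessing for real-data ridge workflows.

The model in this package carries no intercept, so by default the
response is centered and each predictor column is centered and scaled to
unit length (correlation form).  The applied centering and scaling
constants are retained so coefficients can be mapped back to the raw
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from ._errors import InvalidDataError
from .canonical import RegressionData

__all__ = ["Preprocessing", "Dataset", "load_csv", "from_arrays"]

SCALE_MODES = ("none", "unit_length", "z_score")


@dataclass(frozen=True)
class Preprocessing:
    """Record of the (single) preprocessing pass applied to a dataset."""

    center_y: bool
    scale_X: str
    y_mean: float
    x_means: np.ndarray
    x_scales: np.ndarray


@dataclass(frozen=True)
class Dataset:
    """A named regression dataset after preprocessing."""

    name: str
    data: RegressionData
    column_names: List[str]
    response_name: str
    preprocessing: Preprocessing


def _preprocess(
    X: np.ndarray, y: np.ndarray, center_y: bool, scale_X: str, columns: List[str]
) -> tuple[np.ndarray, np.ndarray, Preprocessing]:
    if scale_X not in SCALE_MODES:
        raise InvalidDataError(f"unknown scale_X mode {scale_X!r}; known: {SCALE_MODES}")
    y_mean = float(y.mean()) if center_y else 0.0
    y_out = y - y_mean
    x_means = X.mean(axis=0) if scale_X != "none" else np.zeros(X.shape[1])
    Xc = X - x_means
    if scale_X == "unit_length":
        scales = np.sqrt(np.sum(Xc**2, axis=0))
    elif scale_X == "z_score":
        scales = Xc.std(axis=0, ddof=1)
    else:
        scales = np.ones(X.shape[1])
    zero = np.nonzero(scales <= 0)[0]
    if zero.size:
        raise InvalidDataError(
            f"constant predictor column(s) {[columns[i] for i in zero]}: cannot scale"
        )
    return Xc / scales, y_out, Preprocessing(
        center_y=center_y, scale_X=scale_X, y_mean=y_mean, x_means=x_means, x_scales=scales
    )


def from_arrays(
    X: np.ndarray,
    y: np.ndarray,
    columns: Optional[List[str]] = None,
    name: str = "data",
    response_name: str = "y",
    center_y: bool = True,
    scale_X: str = "unit_length",
) -> Dataset:
    """Build a preprocessed Dataset directly from arrays."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if columns is None:
        columns = [f"x{i + 1}" for i in range(X.shape[1])]
    Xp, yp, prep = _preprocess(X, y, center_y, scale_X, columns)
    return Dataset(
        name=name,
        data=RegressionData(X=Xp, y=yp),
        column_names=list(columns),
        response_name=response_name,
        preprocessing=prep,
    )


def load_csv(
    path: str | Path,
    response_column: str,
    center_y: bool = True,
    scale_X: str = "unit_length",
) -> Dataset:
    """Load a numeric CSV (header row required) into a Dataset.

    Every column other than ``response_column`` is treated as a
    predictor.  Missing or non-numeric cells raise an error naming the
    offending row and column.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if response_column not in frame.columns:
        raise InvalidDataError(
            f"response column {response_column!r} not in {list(frame.columns)}"
        )
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        row = int(bad.any(axis=1).idxmax())
        col = bad.columns[bad.loc[row].to_numpy().argmax()]
        raise InvalidDataError(
            f"missing or non-numeric value at row {row}, column {col!r} of {path.name}"
        )
    predictors = [c for c in numeric.columns if c != response_column]
    if not predictors:
        raise InvalidDataError("no predictor columns in file")
    return from_arrays(
        numeric[predictors].to_numpy(float),
        numeric[response_column].to_numpy(float),
        columns=predictors,
        name=path.stem,
        response_name=response_column,
        center_y=center_y,
        scale_X=scale_X,
    )
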