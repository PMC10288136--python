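"""Radial-basis-function surrogates over the design space.

Each response (MST, the 14 local votes, the overall vote) gets its own
exact RBF interpolant fitted in the range-normalised unit box, with the
supply-angle levels coded on [0, 1].  Polyharmonic kernels (thin-plate
spline, cubic, quintic, each with the matching polynomial tail) are
shape-parameter free and reproduce the tail's polynomials exactly; a
Gaussian kernel with an explicit shape parameter is also available.
The quintic kernel (degree-2 tail) is the study default — it scored the
lowest holdout error in kernel selection — but needs 22+ training rows
in five dimensions; smaller designs should use cubic or thin-plate.
Holdout validation scores each response by R-squared and RMS error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RBFInterpolator

from .cabin import DesignPoint
from .doe import DesignMatrix, split_holdout
from .errors import ConfigurationError, NumericalError

_KERNEL_DEGREE = {
    "thin_plate_spline": 1,
    "gaussian": 0,
    "cubic": 1,
    "quintic": 2,
    "linear": 0,
}


@dataclass(frozen=True)
class RbfSurrogate:
    """Fitted RBF approximation of one response over the design box."""

    interpolator: RBFInterpolator
    columns: tuple[str, ...]
    ranges: dict[str, tuple[float, float]]
    categorical: dict[str, tuple[float, ...]]
    kernel: str
    shape: float | None
    response: str
    x_train: np.ndarray
    y_train: np.ndarray

    def _normalize(self, rows: pd.DataFrame) -> np.ndarray:
        cols = []
        for name in self.columns:
            x = rows[name].to_numpy(dtype=float)
            if name in self.categorical:
                levels = np.sort(np.asarray(self.categorical[name], dtype=float))
                idx = np.searchsorted(levels, x)
                cols.append(idx / max(len(levels) - 1, 1))
            else:
                lo, hi = self.ranges[name]
                cols.append((x - lo) / (hi - lo))
        return np.column_stack(cols)

    def predict_rows(self, rows: pd.DataFrame) -> np.ndarray:
        x = self._normalize(rows)
        if np.any(x < -1e-9) or np.any(x > 1 + 1e-9):
            warnings.warn(
                f"extrapolating the {self.response} surrogate outside the design box",
                stacklevel=2,
            )
        return self.interpolator(x)

    def predict(self, point: DesignPoint | dict[str, float]) -> float:
        """Evaluate at one operating condition."""
        d = point.as_dict() if isinstance(point, DesignPoint) else dict(point)
        missing = [c for c in self.columns if c not in d]
        if missing:
            raise ConfigurationError(f"design point missing factors: {missing}")
        return float(self.predict_rows(pd.DataFrame([d]))[0])


def fit_rbf(
    design: DesignMatrix,
    y: np.ndarray,
    kernel: str = "thin_plate_spline",
    shape: float | None = None,
    response: str = "y",
) -> RbfSurrogate:
    """Fit an exact-interpolation RBF to one response.

    Requires at least d+2 rows and no duplicated rows (a singular
    interpolation system otherwise).
    """
    x = design.normalized()
    y = np.asarray(y, dtype=float)
    n, d = x.shape
    if y.shape != (n,):
        raise ConfigurationError(f"response must have one value per row, got {y.shape}")
    if kernel not in _KERNEL_DEGREE:
        raise ConfigurationError(f"unknown kernel {kernel!r}")
    # the polynomial tail must be determined: comb(d+deg, deg) monomials
    degree = _KERNEL_DEGREE[kernel]
    min_rows = max(d + 2, math.comb(d + degree, degree) + 1)
    if n < min_rows:
        raise ConfigurationError(
            f"need at least {min_rows} rows for kernel {kernel!r} "
            f"(degree-{degree} tail) in {d} dimensions"
        )
    uniq = np.unique(np.round(x, 12), axis=0)
    if len(uniq) < n:
        raise ConfigurationError("duplicate design rows; remove them before fitting")
    kwargs: dict = {"kernel": kernel, "degree": _KERNEL_DEGREE[kernel]}
    if kernel == "gaussian":
        kwargs["epsilon"] = shape if shape is not None else 1.0
    try:
        interp = RBFInterpolator(x, y, **kwargs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise NumericalError(
            "singular RBF system; try a different kernel or shape parameter"
        ) from exc
    return RbfSurrogate(
        interpolator=interp,
        columns=tuple(design.frame.columns),
        ranges=dict(design.ranges),
        categorical=dict(design.categorical),
        kernel=kernel,
        shape=shape,
        response=response,
        x_train=x,
        y_train=y,
    )


@dataclass(frozen=True)
class ValidationReport:
    """Holdout scores, one row per response (R-squared and RMS error)."""

    scores: pd.DataFrame          # columns: response, r2, rms
    holdout_rows: np.ndarray
    kernel: str

    def score(self, response: str, metric: str) -> float:
        row = self.scores.loc[self.scores["response"] == response]
        if row.empty:
            raise KeyError(response)
        return float(row[metric].iloc[0])


def cross_validate(
    design: DesignMatrix,
    responses: pd.DataFrame,
    fraction: float = 0.10,
    seed: int = 0,
    kernel: str = "thin_plate_spline",
    shape: float | None = None,
) -> ValidationReport:
    """Single seeded holdout validation of every response surrogate.

    Fits on the training rows only and scores on the holdout:
    R2 = 1 - sum((y-yhat)^2)/sum((y-ybar)^2) and RMS = sqrt(mean
    (y-yhat)^2).  A zero-variance holdout response has undefined R2,
    reported as NaN.
    """
    if len(responses) != design.n:
        raise ConfigurationError("responses must align with the design rows")
    train, test = split_holdout(design, fraction, seed)
    sub = DesignMatrix(
        frame=design.frame.iloc[train].reset_index(drop=True),
        ranges=design.ranges,
        categorical=design.categorical,
        seed=design.seed,
    )
    test_rows = design.frame.iloc[test]
    records = []
    for name in responses.columns:
        y = responses[name].to_numpy(dtype=float)
        model = fit_rbf(sub, y[train], kernel=kernel, shape=shape, response=name)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            yhat = model.predict_rows(test_rows)
        resid = y[test] - yhat
        rms = float(np.sqrt(np.mean(resid**2)))
        ss_tot = float(np.sum((y[test] - y[test].mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
        records.append({"response": name, "r2": r2, "rms": rms})
    return ValidationReport(
        scores=pd.DataFrame(records), holdout_rows=test, kernel=kernel
    )
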