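"""One-factor sweeps and rank-correlation tables for the comfort chain.

Spearman correlation is computed as Pearson correlation on mid-ranks
(tie-corrected).  Significance uses the t approximation for n > 8 and
an exact two-sided permutation enumeration for n <= 8, where the
approximation is poor.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.stats import t as t_dist

from .cabin import ANGLE_LEVELS, BOUNDS, DesignPoint
from .errors import ConfigurationError, RangeError
from .segments import SEGMENTS
from .sensation import ComfortResult

#: reference fixed settings of the one-factor studies
DEFAULT_FIXED = DesignPoint(
    t_supply=15.0, q_supply=600.0, angle=45.0, solar=1100.0, altitude=1.0
)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation and two-sided p-value.

    Returns (nan, nan) when either argument has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("x and y must be equal-length 1-D sequences")
    n = len(x)
    if n < 3:
        raise ConfigurationError("need at least 3 observations")
    rx, ry = rankdata(x), rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan"), float("nan")
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    rho = float(np.clip(rho, -1.0, 1.0))

    if n <= 8:  # exact permutation distribution
        perms = np.array(list(permutations(range(n))))
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        rhos = (rx_c @ ry_c[perms].T) / (n * sx * sy)
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    elif abs(rho) >= 1.0:
        p = 0.0
    else:
        t_stat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * t_dist.sf(abs(t_stat), df=n - 2))
    return rho, p


@dataclass(frozen=True)
class SweepTable:
    """Chain evaluations along a grid of one design factor."""

    factor: str
    grid: np.ndarray
    fixed: DesignPoint
    results: tuple[ComfortResult, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, r in zip(self.grid, self.results):
            row = {self.factor: float(g), "otsv": r.otsv, "mst": r.mst}
            row.update({s.value: float(v) for s, v in zip(SEGMENTS, r.ltsv)})
            rows.append(row)
        return pd.DataFrame(rows)


def sweep(
    factor: str,
    grid: Sequence[float],
    fixed: DesignPoint,
    chain: Callable[[DesignPoint], ComfortResult],
) -> SweepTable:
    """Evaluate the full chain along ``grid`` of ``factor``, others fixed."""
    grid = np.asarray(grid, dtype=float)
    if len(grid) == 0:
        raise ConfigurationError("empty grid")
    if np.any(np.diff(grid) <= 0) and len(grid) > 1:
        raise ConfigurationError("grid must be strictly increasing")
    if factor in BOUNDS:
        lo, hi = BOUNDS[factor]
        if grid.min() < lo or grid.max() > hi:
            raise RangeError(f"{factor} grid outside [{lo}, {hi}]")
    elif factor == "angle":
        bad = set(grid) - set(ANGLE_LEVELS)
        if bad:
            raise RangeError(f"angle grid outside levels {ANGLE_LEVELS}: {bad}")
    else:
        raise ConfigurationError(f"unknown factor {factor!r}")
    results = []
    for g in grid:
        point = DesignPoint(**{**fixed.as_dict(), factor: float(g)})
        results.append(chain(point.validate()))
    return SweepTable(factor=factor, grid=grid, fixed=fixed, results=tuple(results))


def solar_correlation_study(
    angle: float,
    factor: str,
    chain: Callable[[DesignPoint], ComfortResult],
    n_grid: int = 9,
    fixed: DesignPoint = DEFAULT_FIXED,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of each vote against one solar factor.

    Sweeps ``factor`` (solar radiation or solar altitude) over an evenly
    spaced grid at the reference fixed settings for the given supply
    angle, then correlates every local vote and the overall vote with
    the factor.  Non-significant entries (p >= alpha) are flagged,
    mirroring the starred convention of sensitivity tables.
    """
    if factor not in ("solar", "altitude"):
        raise ConfigurationError("factor must be 'solar' or 'altitude'")
    if n_grid < 5:
        raise ConfigurationError("need at least 5 grid points")
    lo, hi = BOUNDS[factor]
    grid = np.linspace(lo, hi, n_grid)
    base = DesignPoint(**{**fixed.as_dict(), "angle": float(angle)})
    table = sweep(factor, grid, base, chain)
    frame = table.to_frame()
    records = []
    names = ["otsv"] + [s.value for s in SEGMENTS]
    for name in names:
        rho, p = spearman(grid, frame[name].to_numpy())
        records.append(
            {
                "angle": float(angle),
                "part": name,
                "rho": rho,
                "p": p,
                "significant": bool(p < alpha) if np.isfinite(p) else False,
            }
        )
    return pd.DataFrame(records)
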