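"""Space-filling design of experiments: maximin-optimised Latin hypercubes.

Continuous factors are stratified one point per equal-width bin (sampled
at bin midpoints); a categorical factor is assigned in balanced blocks.
A seeded random Latin hypercube is then improved under the maximin
criterion (largest minimum pairwise distance in range-normalised space,
categorical levels coded on [0, 1]) by a column-entry swap search, which
preserves the one-point-per-bin projection property by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError


@dataclass(frozen=True)
class DesignMatrix:
    """A design sample with its range/level metadata and seed."""

    frame: pd.DataFrame
    ranges: dict[str, tuple[float, float]]
    categorical: dict[str, tuple[float, ...]] = field(default_factory=dict)
    seed: int = 0

    @property
    def n(self) -> int:
        return len(self.frame)

    def normalized(self) -> np.ndarray:
        """Rows mapped to the unit box (categorical levels evenly spaced)."""
        cols = []
        for name in self.frame.columns:
            x = self.frame[name].to_numpy(dtype=float)
            if name in self.categorical:
                levels = np.asarray(self.categorical[name], dtype=float)
                idx = np.searchsorted(np.sort(levels), x)
                denom = max(len(levels) - 1, 1)
                cols.append(idx / denom)
            else:
                lo, hi = self.ranges[name]
                cols.append((x - lo) / (hi - lo))
        return np.column_stack(cols)


def _min_pairwise_distance(x: np.ndarray) -> float:
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    return float(np.sqrt(d2.min()))


def maximin_criterion(design: DesignMatrix) -> float:
    """Minimum pairwise distance of the range-normalised design."""
    return _min_pairwise_distance(design.normalized())


def _random_lhd(
    n: int,
    ranges: dict[str, tuple[float, float]],
    categorical: dict[str, tuple[float, ...]],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Seeded start design; returns the frame and its normalised matrix."""
    data: dict[str, np.ndarray] = {}
    norm_cols: list[np.ndarray] = []
    for name, (lo, hi) in ranges.items():
        perm = rng.permutation(n)
        unit = (perm + 0.5) / n
        data[name] = lo + unit * (hi - lo)
        norm_cols.append(unit)
    for name, levels in categorical.items():
        reps = -(-n // len(levels))  # ceil
        block = np.tile(np.asarray(levels, dtype=float), reps)[:n]
        perm = rng.permutation(n)
        data[name] = block[perm]
        idx = np.searchsorted(np.sort(np.asarray(levels, dtype=float)), data[name])
        norm_cols.append(idx / max(len(levels) - 1, 1))
    return pd.DataFrame(data), np.column_stack(norm_cols)


def opt_lhd(
    n: int,
    ranges: dict[str, tuple[float, float]],
    categorical: dict[str, tuple[float, ...]] | None = None,
    seed: int = 0,
    budget: int = 10_000,
) -> DesignMatrix:
    """Maximin-optimised Latin hypercube design.

    Parameters
    ----------
    n : number of design points (>= 2, and >= the largest level count).
    ranges : per-factor (low, high) bounds for the continuous factors.
    categorical : per-factor level sets, balanced to within one count.
    seed : seeds both the start design and the swap search.
    budget : number of candidate swaps examined.
    """
    categorical = categorical or {}
    if n < 2:
        raise ConfigurationError("need at least 2 design points")
    for name, (lo, hi) in ranges.items():
        if not hi > lo:
            raise ConfigurationError(f"degenerate range for {name}: [{lo}, {hi}]")
    for name, levels in categorical.items():
        if n < len(levels):
            raise ConfigurationError(
                f"n={n} smaller than the {len(levels)} levels of {name}"
            )
    rng = np.random.default_rng(seed)
    frame, x = _random_lhd(n, ranges, categorical, rng)
    columns = list(frame.columns)

    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    best = d2.min()
    for _ in range(budget):
        c = int(rng.integers(len(columns)))
        i, j = rng.choice(n, size=2, replace=False)
        x[[i, j], c] = x[[j, i], c]
        for r in (i, j):
            row = np.sum((x - x[r]) ** 2, axis=1)
            row[r] = np.inf
            d2[r, :] = row
            d2[:, r] = row
        cand = d2.min()
        if cand > best:
            best = cand
            name = columns[c]
            frame.loc[[i, j], name] = frame.loc[[j, i], name].to_numpy()
        else:  # revert
            x[[i, j], c] = x[[j, i], c]
            for r in (i, j):
                row = np.sum((x - x[r]) ** 2, axis=1)
                row[r] = np.inf
                d2[r, :] = row
                d2[:, r] = row
    return DesignMatrix(
        frame=frame.reset_index(drop=True),
        ranges=dict(ranges),
        categorical={k: tuple(v) for k, v in categorical.items()},
        seed=seed,
    )


def split_holdout(
    design: DesignMatrix, fraction: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded train/holdout row split (disjoint, exhaustive).

    Returns (train_rows, test_rows) as index arrays; the holdout size is
    round(n * fraction).
    """
    if not 0.0 < fraction < 1.0:
        raise ConfigurationError("fraction must be in (0, 1)")
    n = design.n
    k = int(round(n * fraction))
    if k == 0 or k == n:
        raise ConfigurationError(f"holdout of size {k} out of {n} is degenerate")
    rng = np.random.default_rng(seed)
    test = np.sort(rng.choice(n, size=k, replace=False))
    train = np.setdiff1d(np.arange(n), test)
    return train, test
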