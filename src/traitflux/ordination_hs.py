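"""Principal-axes ordination of mixed quantitative/categorical tables.

Quantitative columns are standardized to weighted mean 0 and variance 1.
A categorical variable with L levels is expanded to indicator columns; the
indicator for a level with weighted frequency f is centred and scaled as
(d − f) / sqrt(f·(L−1)), which gives every variable — quantitative or
categorical — total inertia 1 under the row weights, so the total inertia
of the decomposition equals the number of variables.  All-quantitative
input reduces exactly to weighted-correlation PCA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MixedTable", "OrdinationResult", "ScaledTable", "scale_mixed_table", "hill_smith"]

#: Eigenvalues below this fraction of the leading one are reported as 0.
_EIG_TOL = 1e-10


class ZeroVarianceError(ValueError):
    """A quantitative column is constant or a categorical has one level."""


@dataclass
class MixedTable:
    """Observations × variables table with per-column kind tags.

    ``kinds`` maps column name to ``"quantitative"`` or ``"categorical"``.
    ``row_weights`` default to uniform; they are normalized to sum 1.
    """

    data: pd.DataFrame
    kinds: dict[str, str]
    row_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        unknown = set(self.data.columns) - set(self.kinds)
        if unknown:
            raise ValueError(f"columns without kind tag: {sorted(unknown)}")
        n = len(self.data)
        if self.row_weights is None:
            self.row_weights = np.full(n, 1.0 / n)
        else:
            w = np.asarray(self.row_weights, dtype=float)
            if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
                raise ValueError("row weights must be non-negative and sum > 0")
            self.row_weights = w / w.sum()

    @property
    def n_variables(self) -> int:
        return self.data.shape[1]


@dataclass
class ScaledTable:
    """The expanded, centred and scaled numeric matrix of a MixedTable."""

    matrix: np.ndarray  # n_rows × n_scaled_columns
    columns: list[tuple[str, str | None]]  # (variable, level or None)
    row_weights: np.ndarray
    dropped: list[str] = field(default_factory=list)  # zero-variance columns zeroed

    def variable_of(self, j: int) -> str:
        return self.columns[j][0]


def scale_mixed_table(
    table: MixedTable, allow_zero_variance: bool = False
) -> ScaledTable:
    """Expand and scale a mixed table under its row weights.

    With ``allow_zero_variance`` a constant quantitative column (or a
    single-level categorical) is mapped to zeros instead of raising; this is
    needed for trait tables of within-species deviations where a variable
    may carry no variation at all.
    """
    w = table.row_weights
    cols: list[np.ndarray] = []
    names: list[tuple[str, str | None]] = []
    dropped: list[str] = []
    for name in table.data.columns:
        kind = table.kinds[name]
        if kind == "quantitative":
            x = table.data[name].to_numpy(dtype=float)
            if np.any(~np.isfinite(x)):
                raise ValueError(f"non-finite values in quantitative column {name!r}")
            m = float(np.sum(w * x))
            var = float(np.sum(w * (x - m) ** 2))
            if var <= 0:
                if not allow_zero_variance:
                    raise ZeroVarianceError(
                        f"quantitative column {name!r} has zero weighted variance"
                    )
                cols.append(np.zeros_like(x))
                dropped.append(name)
            else:
                cols.append((x - m) / math.sqrt(var))
            names.append((name, None))
        elif kind == "categorical":
            raw = table.data[name].astype(str).to_numpy()
            levels = sorted(set(raw))
            if len(levels) < 2:
                if not allow_zero_variance:
                    raise ZeroVarianceError(
                        f"categorical column {name!r} has a single level"
                    )
                cols.append(np.zeros(len(raw)))
                names.append((name, levels[0] if levels else None))
                dropped.append(name)
                continue
            L = len(levels)
            for lev in levels:
                d = (raw == lev).astype(float)
                f = float(np.sum(w * d))
                cols.append((d - f) / math.sqrt(f * (L - 1)))
                names.append((name, lev))
        else:
            raise ValueError(f"unknown column kind {kind!r} for {name!r}")
    matrix = np.column_stack(cols) if cols else np.zeros((len(table.data), 0))
    return ScaledTable(matrix=matrix, columns=names, row_weights=w, dropped=dropped)


@dataclass
class OrdinationResult:
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    row_scores: np.ndarray  # n_rows × n_axes
    column_coefficients: np.ndarray  # n_scaled_columns × n_axes (eigenvectors)
    columns: list[tuple[str, str | None]]
    total_inertia: float

    def variable_loadings(self, axis: int) -> pd.Series:
        """Squared coefficients aggregated per variable on one axis."""
        agg: dict[str, float] = {}
        for j, (var, _lev) in enumerate(self.columns):
            agg[var] = agg.get(var, 0.0) + float(self.column_coefficients[j, axis] ** 2)
        return pd.Series(agg)


def hill_smith(table: MixedTable, n_axes: int = 2) -> OrdinationResult:
    """Weighted principal decomposition of a mixed-variable table.

    Returns eigenvalues (descending, small ones clipped to 0), percentage of
    total inertia per axis, weighted row scores and column coefficients.
    Axis signs are fixed by making the largest-magnitude coefficient on each
    axis positive.
    """
    if len(table.data) < 2 or table.n_variables < 2:
        raise ValueError("need at least 2 rows and 2 variables")
    scaled = scale_mixed_table(table)
    Z, w = scaled.matrix, scaled.row_weights
    C = Z.T @ (Z * w[:, None])  # weighted cross-product (P × P)
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    eigval = np.where(eigval < _EIG_TOL * max(eigval[0], 0.0), 0.0, eigval)
    eigval = np.clip(eigval, 0.0, None)
    k = min(n_axes, len(eigval))
    vectors = eigvec[:, :k].copy()
    for a in range(k):
        j = int(np.argmax(np.abs(vectors[:, a])))
        if vectors[j, a] < 0:
            vectors[:, a] = -vectors[:, a]
    total = float(np.trace(C))
    return OrdinationResult(
        eigenvalues=eigval,
        pct_variance=100.0 * eigval / total if total > 0 else eigval * 0.0,
        row_scores=Z @ vectors,
        column_coefficients=vectors,
        columns=scaled.columns,
        total_inertia=total,
    )
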