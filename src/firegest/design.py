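"""Covariate term specification and design-matrix construction.

Terms are declared with :class:`TermSpec` (linear, categorical, natural
cubic spline, or periodic Fourier) and expanded into numeric columns with
:func:`build_design`.  Fitted transforms (spline knots, category levels)
are retained so the same basis can be re-evaluated on new values, e.g. on
an exposure grid when drawing an exposure-response curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TermSpec",
    "NaturalSpline",
    "fourier_basis",
    "DesignMatrix",
    "build_design",
]


@dataclass(frozen=True)
class TermSpec:
    """Declarative description of one model term.

    Parameters
    ----------
    name : str
        Column in the input data frame.
    kind : str
        ``"linear"``, ``"categorical"``, ``"ns"`` (natural cubic spline)
        or ``"cyclic"`` (periodic Fourier basis; the periodic alternative
        for calendar-month terms).
    df : int, optional
        Basis dimension for ``"ns"``/``"cyclic"`` terms.
    increment : float
        Unit increment at which odds ratios for a linear term are
        reported (e.g. 1 ug/m3 PM2.5, 1 % burned area, 10 g/m3/month
        dry-matter emission).
    period : float
        Period of a cyclic term (months by default).
    """

    name: str
    kind: str = "linear"
    df: Optional[int] = None
    increment: float = 1.0
    period: float = 12.0

    def __post_init__(self):
        if self.kind not in ("linear", "categorical", "ns", "cyclic"):
            raise ValueError(f"unknown term kind {self.kind!r}")
        if self.kind in ("ns", "cyclic"):
            if self.df is None or self.df < 2:
                raise ValueError(
                    f"term {self.name!r}: spline/cyclic terms need df >= 2; "
                    "use a linear term for a single degree of freedom"
                )
        if self.kind == "cyclic" and self.df % 2 != 0:
            raise ValueError("cyclic terms need an even df (sin/cos pairs)")


class NaturalSpline:
    """Natural cubic spline basis (truncated-power parameterisation).

    ``df`` basis columns, no intercept.  Boundary knots sit at the
    observed min/max, internal knots at equally spaced quantiles, so a
    df-column basis uses df - 1 internal knots.  The function is linear
    beyond the boundary knots (zero second derivative), which makes
    extrapolation — e.g. evaluating an exposure basis at 0 — well
    behaved.
    """

    def __init__(self, df: int, knots: Optional[Sequence[float]] = None):
        if df < 2:
            raise ValueError("natural spline needs df >= 2; use a linear term")
        self.df = int(df)
        self.knots_ = None if knots is None else np.asarray(knots, dtype=float)

    def fit(self, x) -> "NaturalSpline":
        x = np.asarray(x, dtype=float)
        lo, hi = np.min(x), np.max(x)
        if not hi > lo:
            raise ValueError("cannot place spline knots on a constant variable")
        probs = np.arange(1, self.df) / self.df
        internal = np.quantile(x, probs)
        knots = np.unique(np.concatenate([[lo], internal, [hi]]))
        if knots.size < 3:
            raise ValueError(
                "too few distinct values to place natural-spline knots"
            )
        self.knots_ = knots
        return self

    def transform(self, x) -> np.ndarray:
        if self.knots_ is None:
            raise RuntimeError("spline not fitted")
        x = np.asarray(x, dtype=float)
        k = self.knots_
        K = k.size

        def d(j):
            num = np.maximum(x - k[j], 0.0) ** 3 - np.maximum(x - k[-1], 0.0) ** 3
            return num / (k[-1] - k[j])

        dlast = d(K - 2)
        cols = [x] + [d(j) - dlast for j in range(K - 2)]
        return np.column_stack(cols)

    def fit_transform(self, x) -> np.ndarray:
        return self.fit(x).transform(x)


def fourier_basis(x, df: int, period: float = 12.0) -> np.ndarray:
    """Sin/cos harmonic basis for periodic covariates (df/2 harmonics)."""
    x = np.asarray(x, dtype=float)
    cols = []
    for h in range(1, df // 2 + 1):
        w = 2.0 * np.pi * h * x / period
        cols.append(np.sin(w))
        cols.append(np.cos(w))
    return np.column_stack(cols)


@dataclass
class DesignMatrix:
    """Expanded numeric design with bookkeeping for OR reporting."""

    X: np.ndarray
    names: list
    terms: list
    term_columns: dict  # term name -> list of column indices
    increments: dict  # linear term name -> unit increment
    transforms: dict = field(default_factory=dict)  # fitted splines / levels

    @property
    def ncols(self) -> int:
        return self.X.shape[1]


def _categorical_columns(values: pd.Series, levels=None):
    if levels is None:
        if isinstance(values.dtype, pd.CategoricalDtype):
            levels = list(values.cat.categories)
        else:
            levels = sorted(pd.unique(values.dropna()))
    if len(levels) < 2:
        raise ValueError("categorical term needs at least two levels")
    cols, names = [], []
    for lev in levels[1:]:  # lowest level is the reference
        cols.append((values == lev).to_numpy(dtype=float))
        names.append(lev)
    return cols, names, levels


def build_design(
    data: pd.DataFrame, terms: Sequence[TermSpec], transforms: Optional[dict] = None
) -> DesignMatrix:
    """Expand ``terms`` against ``data`` into a numeric design matrix.

    ``transforms`` (from a previous build) pins spline knots and
    categorical level sets so that two builds share the same basis.
    """
    transforms = dict(transforms or {})
    blocks, names, term_columns, increments = [], [], {}, {}
    col = 0
    for t in terms:
        if t.name not in data.columns:
            raise KeyError(f"term variable {t.name!r} not in data")
        x = data[t.name]
        if t.kind == "linear":
            arr = np.asarray(x, dtype=float)[:, None]
            cnames = [t.name]
            increments[t.name] = t.increment
        elif t.kind == "categorical":
            levels = transforms.get(t.name)
            cols, levnames, levels = _categorical_columns(x, levels)
            transforms[t.name] = levels
            arr = np.column_stack(cols)
            cnames = [f"{t.name}[{lev}]" for lev in levnames]
        elif t.kind == "ns":
            spl = transforms.get(t.name)
            if spl is None:
                spl = NaturalSpline(t.df).fit(np.asarray(x, dtype=float))
                transforms[t.name] = spl
            arr = spl.transform(np.asarray(x, dtype=float))
            cnames = [f"{t.name}_ns{i + 1}" for i in range(arr.shape[1])]
        else:  # cyclic
            arr = fourier_basis(x, t.df, t.period)
            cnames = [f"{t.name}_cyc{i + 1}" for i in range(arr.shape[1])]
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite values in expanded term {t.name!r}")
        blocks.append(arr)
        names.extend(cnames)
        term_columns[t.name] = list(range(col, col + arr.shape[1]))
        col += arr.shape[1]
    X = np.hstack(blocks) if blocks else np.empty((len(data), 0))
    return DesignMatrix(
        X=X,
        names=names,
        terms=list(terms),
        term_columns=term_columns,
        increments=increments,
        transforms=transforms,
    )
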