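"""Conditional logistic regression for 1:m matched sets.

The model conditions on one case per matched set, eliminating the
set-specific intercept: the contribution of set *s* with case covariates
``x_case`` is ``x_case @ beta - log(sum_j exp(x_j @ beta))`` over all
events *j* in the set.  Estimation is Newton-Raphson on the exact
conditional log-likelihood with step-halving; the covariance is the
inverse observed information at the optimum.

This module also provides the likelihood-ratio test, exposure-by-group
interaction fits with a heterogeneity test, and nonlinear (spline or
categorical-bin) exposure-response fits, all built on the same model
object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .design import DesignMatrix, NaturalSpline, TermSpec, build_design

__all__ = [
    "ConditionalLogit",
    "ConditionalLogitResults",
    "lrt",
    "fit_subgroup_interaction",
    "fit_nonlinear_exposure",
    "fit_categorical_exposure",
    "SubgroupFit",
    "ExposureResponseCurve",
]

_IDENT_TOL = 1e-12


class ConvergenceError(RuntimeError):
    pass


class ConditionalLogit:
    """Conditional logit model for matched case-control sets.

    Parameters
    ----------
    endog : array-like of {0, 1}
        Case indicator, exactly one 1 per set.
    exog : 2-d array
        Covariate matrix (no intercept; set-constant columns are not
        identifiable and are flagged).
    groups : array-like
        Matched-set identifier per row.
    names : sequence of str, optional
        Column names for reporting.
    """

    def __init__(self, endog, exog, groups, names=None, design: Optional[DesignMatrix] = None):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        groups = np.asarray(groups)
        if X.shape[0] != y.size or groups.size != y.size:
            raise ValueError("endog, exog and groups must align")
        order = np.argsort(groups, kind="stable")
        self._order = order
        self.y = y[order]
        self.X = X[order]
        self.groups = groups[order]
        self.names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
        self.design = design

        # set boundaries
        g = self.groups
        starts = np.flatnonzero(np.r_[True, g[1:] != g[:-1]])
        self._starts = starts
        self._set_sizes = np.diff(np.r_[starts, g.size])
        cases_per_set = np.add.reduceat(self.y, starts)
        if not np.allclose(cases_per_set, 1.0):
            raise ValueError("each matched set must contain exactly one case")
        if np.any(self._set_sizes < 2):
            raise ValueError("each matched set needs at least one control")
        self.n_sets = starts.size
        self.n_events = g.size
        self._set_index = np.repeat(np.arange(self.n_sets), self._set_sizes)

        # a column constant within every set carries no conditional information
        mins = np.minimum.reduceat(self.X, starts, axis=0)
        maxs = np.maximum.reduceat(self.X, starts, axis=0)
        span = np.max(maxs - mins, axis=0)
        self.nonidentifiable = [self.names[j] for j in np.flatnonzero(span <= _IDENT_TOL)]
        self._free = np.flatnonzero(span > _IDENT_TOL)

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        terms: Sequence[TermSpec],
        outcome: str = "is_case",
        set_id: str = "set_id",
        transforms: Optional[dict] = None,
    ) -> "ConditionalLogit":
        dm = build_design(data, terms, transforms=transforms)
        return cls(
            data[outcome].to_numpy(),
            dm.X,
            data[set_id].to_numpy(),
            names=dm.names,
            design=dm,
        )

    # ------------------------------------------------------------------
    def _eta(self, beta_free):
        return self.X[:, self._free] @ beta_free

    def loglike(self, beta_free) -> float:
        eta = self._eta(beta_free)
        lse = np.array(
            [logsumexp(eta[s : s + n]) for s, n in zip(self._starts, self._set_sizes)]
        )
        return float(eta[self.y == 1].sum() - lse.sum())

    def _ll_score_hess(self, beta_free):
        Xf = self.X[:, self._free]
        eta = Xf @ beta_free
        # softmax within sets, stabilised by the per-set max
        m = np.maximum.reduceat(eta, self._starts)
        e = np.exp(eta - m[self._set_index])
        denom = np.add.reduceat(e, self._starts)
        p = e / denom[self._set_index]
        ll = float(eta[self.y == 1].sum() - (np.log(denom) + m).sum())
        mu = np.empty((self.n_sets, Xf.shape[1]))
        pX = p[:, None] * Xf
        np.add.reduceat(pX, self._starts, axis=0, out=mu)
        score = Xf[self.y == 1].sum(axis=0) - mu.sum(axis=0)
        info = Xf.T @ pX - mu.T @ mu  # observed information (positive semidefinite)
        return ll, score, info

    def fit(
        self,
        start_params=None,
        maxiter: int = 50,
        tol: float = 1e-10,
        max_halvings: int = 10,
    ) -> "ConditionalLogitResults":
        k = self._free.size
        if k == 0:
            raise ValueError("no identifiable covariates (all set-constant)")
        beta = np.zeros(k) if start_params is None else np.asarray(start_params, float).copy()
        ll, score, info = self._ll_score_hess(beta)
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError as err:
                raise ConvergenceError(
                    f"singular information matrix at iteration {it}; "
                    f"non-identifiable columns: {self.nonidentifiable}"
                ) from err
            new_beta = beta + step
            new_ll, new_score, new_info = self._ll_score_hess(new_beta)
            halvings = 0
            while not np.isfinite(new_ll) or new_ll < ll:
                halvings += 1
                if halvings > max_halvings:
                    break
                step *= 0.5
                new_beta = beta + step
                new_ll, new_score, new_info = self._ll_score_hess(new_beta)
            if not np.isfinite(new_ll) or new_ll < ll:
                break  # no ascent possible; treat current point as optimum
            rel = abs(new_ll - ll) / (abs(ll) + 1.0)
            beta, ll, score, info = new_beta, new_ll, new_score, new_info
            if rel < tol:
                converged = True
                break
        if not converged:
            # step-halving can stall on float noise at the optimum; a
            # negligible gradient is the operative criterion then
            if np.linalg.norm(score) <= 1e-4 * (1 + abs(ll)):
                converged = True
            else:
                raise ConvergenceError(
                    f"Newton-Raphson did not converge in {it} iterations "
                    f"(|score| = {np.linalg.norm(score):.3g}, ll = {ll:.6g})"
                )
        cov_free = np.linalg.inv(info)
        return ConditionalLogitResults(self, beta, cov_free, ll, converged, it)


class ConditionalLogitResults:
    """Estimates, uncertainties, and diagnostics from a conditional-logit fit.

    ``params``/``bse`` are indexed by column name; columns flagged as
    non-identifiable (constant within every set) carry NaN.
    """

    def __init__(self, model, beta_free, cov_free, llf, converged, niter):
        self.model = model
        self.llf = float(llf)
        self.converged = bool(converged)
        self.niter = int(niter)
        self.n_sets = model.n_sets
        self.n_events = model.n_events
        self.df_model = beta_free.size

        k = len(model.names)
        full = np.full(k, np.nan)
        full[model._free] = beta_free
        self.params = pd.Series(full, index=model.names, name="coef")
        cov = np.full((k, k), np.nan)
        cov[np.ix_(model._free, model._free)] = cov_free
        self.cov_params = pd.DataFrame(cov, index=model.names, columns=model.names)
        self._beta_free = beta_free
        self._cov_free = cov_free

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.cov_params.to_numpy())),
            index=self.params.index,
            name="se",
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        """OR and Wald CI per term at its stated unit increment.

        Spline/categorical columns are reported per basis column
        (increment 1); linear terms use their ``TermSpec.increment``.
        """
        inc = pd.Series(1.0, index=self.params.index)
        if self.model.design is not None:
            for name, unit in self.model.design.increments.items():
                if name in inc.index:
                    inc[name] = unit
        ci = self.conf_int(alpha)
        out = pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "increment": inc,
                "or": np.exp(self.params * inc),
                "or_lower": np.exp(ci["lower"] * inc),
                "or_upper": np.exp(ci["upper"] * inc),
            }
        )
        return out

    def summary(self) -> str:
        ors = self.odds_ratios()
        lines = [
            "Conditional logistic regression (matched sets)",
            f"  sets: {self.n_sets}   events: {self.n_events}   "
            f"params: {self.df_model}",
            f"  log-likelihood: {self.llf:.4f}   converged: {self.converged} "
            f"({self.niter} iterations)",
        ]
        if self.model.nonidentifiable:
            lines.append(
                "  non-identifiable (set-constant) columns: "
                + ", ".join(self.model.nonidentifiable)
            )
        lines.append("")
        lines.append(
            f"{'term':<24}{'coef':>10}{'se':>10}{'OR':>9}{'2.5%':>9}{'97.5%':>9}"
        )
        for name, row in ors.iterrows():
            lines.append(
                f"{name:<24}{row['coef']:>10.4f}{row['se']:>10.4f}"
                f"{row['or']:>9.4f}{row['or_lower']:>9.4f}{row['or_upper']:>9.4f}"
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """One row per coefficient, for CSV serialisation."""
        out = self.odds_ratios().reset_index(names="term")
        return out


# ----------------------------------------------------------------------
def lrt(
    nested: ConditionalLogitResults,
    full: ConditionalLogitResults,
    check_names: bool = True,
):
    """Likelihood-ratio chi-square test of nested conditional-logit fits.

    Returns ``(statistic, df, p)``.  Requires the nested model's columns
    to be a subset of the full model's and both fits to use the same
    sets.  ``check_names=False`` skips the column-name containment check
    for models nested structurally rather than by name — e.g. a linear
    exposure term, which lies in the span of its natural-spline basis.
    """
    if nested.n_sets != full.n_sets or nested.n_events != full.n_events:
        raise ValueError("models were fitted to different matched sets")
    if check_names:
        nested_cols = set(nested.params.index)
        full_cols = set(full.params.index)
        if not nested_cols <= full_cols:
            raise ValueError("models are not nested (column sets differ)")
    df = full.df_model - nested.df_model
    if df < 0:
        raise ValueError("full model has fewer free parameters than nested model")
    statistic = 2.0 * (full.llf - nested.llf)
    statistic = max(statistic, 0.0)
    p = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    return statistic, df, p


# ----------------------------------------------------------------------
@dataclass
class SubgroupFit:
    """Group-specific exposure effects plus a heterogeneity LRT."""

    group_var: str
    table: pd.DataFrame  # index: group level; or, ci, coef, se
    p_heterogeneity: float
    lrt_statistic: float
    lrt_df: int
    full: ConditionalLogitResults
    reduced: ConditionalLogitResults


def fit_subgroup_interaction(
    data: pd.DataFrame,
    terms: Sequence[TermSpec],
    exposure: str,
    group_var: str,
    outcome: str = "is_case",
    set_id: str = "set_id",
    levels=None,
) -> SubgroupFit:
    """Fit exposure-by-group interactions and test effect heterogeneity.

    The grouping variable may be constant within each set (mother-level
    characteristics, whose main effects cancel in the matched design) or
    vary at event level (maternal age band recomputed at each event).
    Group-specific ORs are reported per unit increment of ``exposure``;
    the heterogeneity p-value is the LRT against the common-effect model.
    """
    if levels is None:
        levels = sorted(pd.unique(data[group_var].dropna()))
    if len(levels) < 2:
        raise ValueError("heterogeneity test needs at least two groups with data")
    for lev in levels:
        if not (data[group_var] == lev).any():
            raise ValueError(f"group {lev!r} has no events")
    work = data.copy()
    inter_names = []
    for lev in levels[1:]:
        cname = f"{exposure}:x:{lev}"
        work[cname] = work[exposure].to_numpy(dtype=float) * (
            work[group_var] == lev
        ).to_numpy(dtype=float)
        inter_names.append((lev, cname))
    base_terms = list(terms)
    exp_term = next(t for t in base_terms if t.name == exposure)
    full_terms = base_terms + [
        TermSpec(cname, "linear", increment=exp_term.increment)
        for _, cname in inter_names
    ]
    reduced = ConditionalLogit.from_dataframe(work, base_terms, outcome, set_id).fit()
    full = ConditionalLogit.from_dataframe(work, full_terms, outcome, set_id).fit()
    statistic, df, p = lrt(reduced, full)

    # group effects: beta_exposure (+ interaction contrast for non-reference)
    rows = []
    cov = full.cov_params
    b = full.params
    z = stats.norm.ppf(0.975)
    unit = exp_term.increment
    for lev in levels:
        if lev == levels[0]:
            coef = b[exposure]
            var = cov.loc[exposure, exposure]
        else:
            cname = dict(inter_names)[lev]
            coef = b[exposure] + b[cname]
            var = (
                cov.loc[exposure, exposure]
                + cov.loc[cname, cname]
                + 2 * cov.loc[exposure, cname]
            )
        se = float(np.sqrt(var))
        rows.append(
            {
                "group": lev,
                "coef": float(coef),
                "se": se,
                "or": float(np.exp(coef * unit)),
                "or_lower": float(np.exp((coef - z * se) * unit)),
                "or_upper": float(np.exp((coef + z * se) * unit)),
            }
        )
    table = pd.DataFrame(rows).set_index("group")
    return SubgroupFit(group_var, table, p, statistic, df, full, reduced)


# ----------------------------------------------------------------------
@dataclass
class ExposureResponseCurve:
    """Log-OR exposure-response relative to zero exposure."""

    grid: np.ndarray
    log_or: np.ndarray
    log_or_lower: np.ndarray
    log_or_upper: np.ndarray
    p_nonlinearity: float
    fit: ConditionalLogitResults

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "exposure": self.grid,
                "log_or": self.log_or,
                "log_or_lower": self.log_or_lower,
                "log_or_upper": self.log_or_upper,
            }
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.grid, np.exp(self.log_or), "-", label="OR")
        ax.plot(self.grid, np.exp(self.log_or_lower), "--", color="grey")
        ax.plot(self.grid, np.exp(self.log_or_upper), "--", color="grey")
        ax.axhline(1.0, color="k", lw=0.5)
        ax.set_xlabel("exposure")
        ax.set_ylabel("odds ratio vs 0")
        return ax


def fit_nonlinear_exposure(
    data: pd.DataFrame,
    terms: Sequence[TermSpec],
    exposure: str,
    spline_df: int = 3,
    outcome: str = "is_case",
    set_id: str = "set_id",
    grid: Optional[np.ndarray] = None,
    n_grid: int = 50,
) -> ExposureResponseCurve:
    """Replace the linear exposure term with a natural-spline term.

    Returns the log-OR curve relative to exposure 0 with pointwise Wald
    CIs, evaluated on ``grid`` (default: 50 points from 0 to the 99th
    exposure percentile), plus a linearity LRT: the linear function lies
    in the natural-spline span, so the fully adjusted linear model is
    nested in the spline model with ``spline_df - 1`` extra df.
    """
    x = data[exposure].to_numpy(dtype=float)
    spline = NaturalSpline(spline_df).fit(x)
    if spline_df > spline.knots_.size - 1:
        raise ValueError("spline df exceeds the identifiable dimension")
    basis = spline.transform(x)
    work = data.copy()
    bnames = [f"{exposure}_ns{i + 1}" for i in range(basis.shape[1])]
    for i, nm in enumerate(bnames):
        work[nm] = basis[:, i]
    other = [t for t in terms if t.name != exposure]
    linear_terms = list(terms)
    spline_terms = other + [TermSpec(nm, "linear") for nm in bnames]

    linear_fit = ConditionalLogit.from_dataframe(work, linear_terms, outcome, set_id).fit()
    spline_fit = ConditionalLogit.from_dataframe(work, spline_terms, outcome, set_id).fit()
    _, _, p_nonlin = lrt(linear_fit, spline_fit, check_names=False)

    if grid is None:
        hi = np.percentile(x, 99)
        grid = np.linspace(0.0, hi, n_grid)
    grid = np.asarray(grid, dtype=float)
    B = spline.transform(grid) - spline.transform(np.zeros_like(grid))
    beta = spline_fit.params[bnames].to_numpy()
    cov = spline_fit.cov_params.loc[bnames, bnames].to_numpy()
    log_or = B @ beta
    var = np.einsum("ij,jk,ik->i", B, cov, B)
    se = np.sqrt(np.maximum(var, 0.0))
    z = stats.norm.ppf(0.975)
    return ExposureResponseCurve(
        grid, log_or, log_or - z * se, log_or + z * se, p_nonlin, spline_fit
    )


def fit_categorical_exposure(
    data: pd.DataFrame,
    terms: Sequence[TermSpec],
    exposure: str,
    bins: Sequence[float],
    outcome: str = "is_case",
    set_id: str = "set_id",
) -> pd.DataFrame:
    """Categorical-bins exposure variant: OR per bin vs the lowest bin."""
    work = data.copy()
    x = work[exposure].to_numpy(dtype=float)
    cats = pd.cut(x, bins=bins, include_lowest=True)
    work["_exposure_bin"] = cats.astype(str)
    levels = [str(c) for c in cats.categories]
    other = [t for t in terms if t.name != exposure]
    cat_terms = other + [TermSpec("_exposure_bin", "categorical")]
    model = ConditionalLogit.from_dataframe(
        work, cat_terms, outcome, set_id, transforms={"_exposure_bin": levels}
    )
    res = model.fit()
    rows = [{"bin": levels[0], "or": 1.0, "or_lower": np.nan, "or_upper": np.nan}]
    ors = res.odds_ratios()
    for lev in levels[1:]:
        nm = f"_exposure_bin[{lev}]"
        rows.append(
            {
                "bin": lev,
                "or": ors.loc[nm, "or"],
                "or_lower": ors.loc[nm, "or_lower"],
                "or_upper": ors.loc[nm, "or_upper"],
            }
        )
    return pd.DataFrame(rows)
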