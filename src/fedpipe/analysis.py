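"""Severity modelling: multilevel logistic regression on the expanded table.

The scientific question is the association between disease-modifying
therapy (DMT) exposure and a binary COVID-19 severity outcome
(hospitalization, ICU admission, ventilation, death), adjusting for age
band, sex, MS phenotype and dichotomized disability, with a random
intercept per contributing data source:

    logit P(y_ij = 1) = x_ij' beta + b_j,      b_j ~ Normal(0, sigma^2)

The model is specified by :class:`ModelSpec`, built and fitted through
:class:`SeverityModel`, and reported by :class:`SeverityModelResults`
(adjusted odds ratios ``exp(beta)`` with Wald 95% CIs).

The marginal likelihood integrates the random intercept by Gauss-Hermite
quadrature (default 25 nodes) on data collapsed to unique
(source, covariate-pattern) cells, which makes the fit deterministic,
row-order invariant, and fast even for large expanded tables.  With a
single source the model degenerates and the fit falls back to ordinary
logistic regression with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools import numdiff

from .integration import EMPTY_LABEL, ExpandedTable

__all__ = [
    "ModelSpec",
    "Design",
    "SeverityModel",
    "SeverityModelResults",
    "build_design",
    "fit_severity_model",
    "report",
    "FitError",
]

DEFAULT_REFERENCES = {
    "age_years": "18-50",
    "sex": "female",
    "ms_type": "relapsing_remitting",
    "edss_value": "0-6",
    "type_dmt": "untreated",
}


class FitError(RuntimeError):
    """The likelihood optimization failed irrecoverably."""


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one severity model.

    Parameters
    ----------
    outcome : str
        One binary severity indicator (a yes/no scheme variable).
    fixed_effects : tuple of str
        Categorized adjustment variables; each must be a scheme variable.
    group : str
        The grouping factor of the random intercept (the data source).
    reference_levels : mapping
        Per-variable reference category (carries no coefficient).
    contrast : str
        ``"reference"`` — every non-reference DMT level gets its own
        coefficient against the reference (default); or ``"one_vs_rest"``
        — a single indicator for ``contrast_target`` against all other
        levels pooled (the "compared to all other DMTs" parameterization).
    contrast_target : str, optional
        The DMT level contrasted under ``one_vs_rest``.
    """

    outcome: str = "covid19_admission_hospital"
    fixed_effects: tuple[str, ...] = (
        "age_years",
        "sex",
        "ms_type",
        "edss_value",
        "type_dmt",
    )
    group: str = "source"
    reference_levels: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_REFERENCES)
    )
    contrast: str = "reference"
    contrast_target: str | None = None

    def __post_init__(self) -> None:
        if self.contrast not in ("reference", "one_vs_rest"):
            raise ValueError(f"unknown contrast {self.contrast!r}")
        if self.contrast == "one_vs_rest" and not self.contrast_target:
            raise ValueError("one_vs_rest contrast needs a contrast_target")


@dataclass
class Design:
    """Model-ready matrices: one-hot X (with intercept), binary y, group labels."""

    X: pd.DataFrame
    y: np.ndarray
    groups: np.ndarray
    n_excluded: int

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_groups(self) -> int:
        return len(np.unique(self.groups))


def build_design(table: ExpandedTable, spec: ModelSpec) -> Design:
    """One-hot encode the expanded table against the reference levels.

    Rows with an EMPTY label in the outcome or any modelled variable are
    excluded (complete-case) and counted in ``n_excluded``.
    """
    scheme = table.scheme
    for var in spec.fixed_effects + (spec.outcome,):
        if var not in scheme.variables:
            raise ValueError(f"{var!r} is not a scheme variable")
    df = table.to_dataframe(include_source=True)
    modelled = list(spec.fixed_effects) + [spec.outcome]
    keep = ~(df[modelled] == EMPTY_LABEL).any(axis=1)
    n_excluded = int((~keep).sum())
    df = df.loc[keep]
    y = (df[spec.outcome] == "yes").to_numpy(dtype=float)
    cols: dict[str, np.ndarray] = {"const": np.ones(len(df))}
    for var in spec.fixed_effects:
        if var == "type_dmt" and spec.contrast == "one_vs_rest":
            target = spec.contrast_target
            if target not in scheme.labels(var):
                raise ValueError(f"contrast_target {target!r} is not a DMT level")
            cols[f"{var}[{target} vs rest]"] = (df[var] == target).to_numpy(dtype=float)
            continue
        ref = spec.reference_levels.get(var)
        labels = scheme.labels(var)
        if ref not in labels:
            raise ValueError(f"reference level {ref!r} is not a category of {var!r}")
        for label in labels:
            if label == ref:
                continue
            cols[f"{var}[{label}]"] = (df[var] == label).to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=df.index)
    return Design(X=X, y=y, groups=df["source"].to_numpy(), n_excluded=n_excluded)


def _collapse(design: Design) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Collapse to unique (group, covariate pattern) cells.

    Returns (Xc, successes, trials, group_start_indices); rows are sorted
    by (group, pattern), so the collapsed representation — and hence the
    fit — is invariant to the input row order.
    """
    df = design.X.copy()
    df["_group"] = design.groups
    df["_y"] = design.y
    keys = ["_group"] + [c for c in design.X.columns]
    agg = df.groupby(keys, sort=True)["_y"].agg(["sum", "count"]).reset_index()
    Xc = agg[list(design.X.columns)].to_numpy(dtype=float)
    s = agg["sum"].to_numpy(dtype=float)
    m = agg["count"].to_numpy(dtype=float)
    groups = agg["_group"].to_numpy()
    # reduceat boundaries: first index of each group block
    change = np.flatnonzero(np.r_[True, groups[1:] != groups[:-1]])
    return Xc, s, m, change


def _nll_factory(Xc, s, m, starts, n_ghq: int):
    nodes, weights = np.polynomial.hermite.hermgauss(n_ghq)
    log_w = np.log(weights) - 0.5 * np.log(np.pi)

    def nll(params: np.ndarray) -> float:
        beta = params[:-1]
        sigma = np.exp(params[-1])
        eta = Xc @ beta
        lp = eta[:, None] + np.sqrt(2.0) * sigma * nodes[None, :]
        # log p and log(1-p) without overflow
        log_p = -np.logaddexp(0.0, -lp)
        log_q = -np.logaddexp(0.0, lp)
        row_ll = s[:, None] * log_p + (m - s)[:, None] * log_q
        group_ll = np.add.reduceat(row_ll, starts, axis=0)
        return -float(np.sum(special.logsumexp(group_ll + log_w[None, :], axis=1)))

    return nll


@dataclass
class SeverityModelResults:
    """Fitted multilevel severity model.

    Attributes
    ----------
    params : pandas.Series
        Log-odds estimates (including the intercept).
    bse : pandas.Series
        Wald standard errors.
    re_var : float or None
        Variance of the source random intercept (None under the
        single-source fallback).
    converged : bool
        Optimizer success and a finite, invertible observed information.
        When False, odds-ratio reporting is withheld.
    """

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    re_var: float | None
    converged: bool
    n_used: int
    n_excluded: int
    n_groups: int
    llf: float
    fallback: bool = False

    @property
    def re_sd(self) -> float | None:
        return None if self.re_var is None else float(np.sqrt(self.re_var))

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        """Adjusted odds ratios with Wald CIs, one row per non-reference term."""
        if not self.converged:
            raise FitError("model did not converge; odds ratios withheld")
        ci = self.conf_int(alpha)
        terms = [t for t in self.params.index if t != "const"]
        return pd.DataFrame(
            {
                "aOR": np.exp(self.params[terms]),
                "ci_low": np.exp(ci.loc[terms, "lower"]),
                "ci_high": np.exp(ci.loc[terms, "upper"]),
            }
        )

    def summary(self) -> str:
        lines = [
            f"Severity model: {self.spec.outcome}",
            f"  n = {self.n_used} (excluded {self.n_excluded} incomplete), "
            f"groups = {self.n_groups}",
            f"  log-likelihood = {self.llf:.2f}",
        ]
        if self.fallback:
            lines.append("  single-source fallback: ordinary logistic regression")
        if self.re_var is not None:
            lines.append(f"  random-intercept variance = {self.re_var:.4f}")
        lines.append(f"  converged = {self.converged}")
        if self.converged:
            ors = self.odds_ratios()
            lines.append(f"  {'term':<42}{'aOR (95% CI)':>22}")
            for term, row in ors.iterrows():
                lines.append(
                    f"  {term:<42}{row.aOR:>8.2f} ({row.ci_low:.2f}-{row.ci_high:.2f})"
                )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Flat results table (one row per non-reference coefficient)."""
        ors = self.odds_ratios()
        out = ors.reset_index(names="term")
        out.insert(0, "outcome", self.spec.outcome)
        out["estimate"] = self.params[out["term"]].to_numpy()
        out["se"] = self.bse[out["term"]].to_numpy()
        out["n"] = self.n_used
        out["groups"] = self.n_groups
        return out


class SeverityModel:
    """Multilevel logistic severity model on an :class:`ExpandedTable`.

    Examples
    --------
    >>> model = SeverityModel(expanded, ModelSpec(outcome="covid19_admission_hospital"))
    >>> result = model.fit()
    >>> print(result.summary())
    """

    def __init__(self, table: ExpandedTable, spec: ModelSpec | None = None) -> None:
        self.spec = spec or ModelSpec()
        self.design = build_design(table, self.spec)

    @classmethod
    def from_expanded(cls, table: ExpandedTable, **spec_kwargs) -> "SeverityModel":
        return cls(table, ModelSpec(**spec_kwargs))

    def fit(self, n_ghq: int = 25, maxiter: int = 500) -> SeverityModelResults:
        """Maximum-likelihood fit (Gauss-Hermite marginal likelihood, BFGS).

        Deterministic given the input and the quadrature/optimizer settings.
        """
        design = self.design
        if design.n == 0:
            raise FitError("no usable rows after complete-case exclusion")
        if design.n_groups < 2:
            return self._fit_single_level()
        Xc, s, m, starts = _collapse(design)
        nll = _nll_factory(Xc, s, m, starts, n_ghq)

        # start from the pooled (no random effect) logistic fit
        import statsmodels.api as sm

        glm = sm.GLM(np.c_[s, m - s], Xc, family=sm.families.Binomial())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            start_beta = glm.fit().params
        x0 = np.r_[start_beta, np.log(0.5)]
        opt = optimize.minimize(
            nll, x0, method="BFGS", options={"maxiter": maxiter, "gtol": 1e-6}
        )
        hess = numdiff.approx_hess(opt.x, nll)
        names = list(design.X.columns)
        k = len(names)
        converged = bool(opt.success) or float(np.max(np.abs(opt.jac))) < 1e-3
        try:
            cov = np.linalg.inv(hess)
            bse_all = np.sqrt(np.diag(cov))
            if not np.all(np.isfinite(bse_all[:k])):
                converged = False
                bse_all = np.full(k + 1, np.nan)
        except np.linalg.LinAlgError:
            converged = False
            bse_all = np.full(k + 1, np.nan)
        sigma = float(np.exp(opt.x[-1]))
        return SeverityModelResults(
            spec=self.spec,
            params=pd.Series(opt.x[:k], index=names),
            bse=pd.Series(bse_all[:k], index=names),
            re_var=sigma**2,
            converged=converged,
            n_used=design.n,
            n_excluded=design.n_excluded,
            n_groups=design.n_groups,
            llf=-float(opt.fun),
        )

    def _fit_single_level(self) -> SeverityModelResults:
        import statsmodels.api as sm

        warnings.warn(
            "fewer than 2 groups: falling back to ordinary logistic regression",
            UserWarning,
            stacklevel=3,
        )
        design = self.design
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(design.y, design.X).fit(disp=False)
        return SeverityModelResults(
            spec=self.spec,
            params=pd.Series(res.params, index=design.X.columns),
            bse=pd.Series(res.bse, index=design.X.columns),
            re_var=None,
            converged=bool(res.mle_retvals.get("converged", True)),
            n_used=design.n,
            n_excluded=design.n_excluded,
            n_groups=design.n_groups,
            llf=float(res.llf),
            fallback=True,
        )


def fit_severity_model(
    table: ExpandedTable, spec: ModelSpec | None = None, **fit_kwargs
) -> SeverityModelResults:
    """Convenience wrapper: build and fit in one call."""
    return SeverityModel(table, spec).fit(**fit_kwargs)


def report(results: Sequence[SeverityModelResults]) -> pd.DataFrame:
    """Tabular report over several fitted outcomes.

    One row per non-reference coefficient, with ``aOR (95% CI)`` formatted
    to 2 decimals in the ``formatted`` column; non-converged fits are
    represented by a single row noting the withheld estimates.
    """
    columns = ["outcome", "term", "aOR", "ci_low", "ci_high", "estimate", "se",
               "n", "groups", "formatted"]
    frames = []
    for res in results:
        if not res.converged:
            frames.append(pd.DataFrame([{
                "outcome": res.spec.outcome, "term": "(not converged)",
                "aOR": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "estimate": np.nan, "se": np.nan, "n": res.n_used,
                "groups": res.n_groups, "formatted": "withheld",
            }]))
            continue
        frame = res.to_frame()
        frame["formatted"] = [
            f"{r.aOR:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f})" for r in frame.itertuples()
        ]
        frames.append(frame[columns])
    if not frames:
        return pd.DataFrame(columns=columns)
    return pd.concat(frames, ignore_index=True)[columns]
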