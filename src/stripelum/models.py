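"""Gaussian-GLM fitting, AICc model selection and post hoc contrasts.

Candidate models are ordinary Gaussian linear models (OLS) over categorical
design factors with treatment (dummy) coding.  Model comparison uses the
small-sample-corrected Akaike information criterion,

    AICc = -2 logL + 2k + 2k(k + 1) / (n - k - 1),

with the Gaussian log-likelihood evaluated at the ML variance RSS/n and the
parameter count k including the residual variance, so an intercept-only model
has k = 2.  A model is *supported* when its AICc is within two units of the
best model AND more than two units below the null model; among supported
models the one with fewest parameters is preferred.

Post hoc pairwise contrasts use estimated marginal means: model-based group
means averaged over the levels of the other factors with equal weights,
tested against the pooled residual variance with Tukey-adjusted p-values.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "ModelFit",
    "SelectionTable",
    "ContrastResult",
    "CorrelationResult",
    "fit_gaussian_glm",
    "aicc",
    "build_selection_table",
    "emm_pairwise",
    "pearson_test",
]

logger = logging.getLogger(__name__)

AICC_TIE_TOL = 1e-8


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: a response and categorical predictors.

    ``interactions`` lists pairs of predictors whose two-way interaction is
    included; each member must also appear in ``predictors``.  An empty
    predictor list is the null (intercept-only) model.
    """

    response: str
    predictors: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()
    label: str | None = None

    def __post_init__(self):
        for a, b in self.interactions:
            if a not in self.predictors or b not in self.predictors:
                raise ValueError(
                    f"interaction {a}:{b} references an undeclared predictor"
                )

    @property
    def name(self) -> str:
        if self.label:
            return self.label
        terms = list(self.predictors) + [f"{a} x {b}" for a, b in self.interactions]
        return " + ".join(terms) if terms else "1 (null model)"


@dataclass
class ModelFit:
    """A fitted Gaussian linear model and its information-criterion inputs.

    ``k`` counts the estimated parameters: every fixed-effect coefficient
    (intercept included) plus one for the residual variance.  This is the
    degrees-of-freedom convention information-criterion packages use, so the
    null model has k = 2.
    """

    spec: ModelSpec
    n: int
    k: int
    params: pd.Series
    rss: float
    loglik: float
    cov_unbiased: np.ndarray  # sigma2_hat * (X'X)^-1 with sigma2 = RSS/(n-p)
    levels: dict[str, list[str]]
    row_index: pd.Index

    @property
    def n_coefficients(self) -> int:
        return len(self.params)

    @property
    def residual_df(self) -> int:
        return self.n - self.n_coefficients

    @property
    def aicc(self) -> float:
        return aicc(self)


def _design_matrix(
    table: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Treatment-coded design matrix; reference is the alphabetically first level."""
    cols = {"Intercept": np.ones(len(table))}
    levels: dict[str, list[str]] = {}
    dummies: dict[str, dict[str, np.ndarray]] = {}
    for p in spec.predictors:
        if p not in table.columns:
            raise ValueError(f"predictor {p!r} is not a column of the table")
        vals = table[p].astype(str)
        levs = sorted(vals.unique())
        if any(vals.value_counts().reindex(levs).fillna(0) < 1):
            raise ValueError(f"unobserved level in predictor {p!r}")
        levels[p] = levs
        dummies[p] = {lev: (vals == lev).to_numpy(float) for lev in levs}
        for lev in levs[1:]:
            cols[f"{p}[{lev}]"] = dummies[p][lev]
    for a, b in spec.interactions:
        for la in levels[a][1:]:
            for lb in levels[b][1:]:
                cols[f"{a}[{la}]:{b}[{lb}]"] = dummies[a][la] * dummies[b][lb]
    return pd.DataFrame(cols, index=table.index), levels


def fit_gaussian_glm(table: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit a Gaussian linear model by ordinary least squares.

    Rows with a missing response are dropped (with a logged count).  The
    log-likelihood uses the ML variance RSS/n; ``k`` counts coefficients plus
    the residual variance.  A rank-deficient design raises a ``ValueError``
    naming the aliased columns.
    """
    if spec.response not in table.columns:
        raise ValueError(f"response {spec.response!r} is not a column of the table")
    y_all = pd.to_numeric(table[spec.response], errors="coerce")
    keep = y_all.notna()
    if (~keep).any():
        logger.info(
            "dropping %d rows with missing %s", int((~keep).sum()), spec.response
        )
    data = table.loc[keep]
    X, levels = _design_matrix(data, spec)

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, _, piv = _pivoted_qr(X.to_numpy())
        aliased = [X.columns[j] for j in piv[rank:]]
        raise ValueError(f"rank-deficient design; aliased term(s): {aliased}")

    res = sm.OLS(y_all.loc[keep].to_numpy(float), X.to_numpy()).fit()
    n = len(data)
    p = X.shape[1]
    rss = float(res.ssr)
    loglik = -n / 2.0 * (math.log(2 * math.pi * rss / n) + 1.0)
    return ModelFit(
        spec=spec,
        n=n,
        k=p + 1,
        params=pd.Series(res.params, index=X.columns),
        rss=rss,
        loglik=loglik,
        cov_unbiased=np.asarray(res.cov_params()),
        levels=levels,
        row_index=data.index,
    )


def _pivoted_qr(a: np.ndarray):
    from scipy.linalg import qr

    return qr(a, mode="economic", pivoting=True)


def aicc(fit: ModelFit) -> float:
    """Small-sample-corrected Akaike information criterion of a fit."""
    n, k = fit.n, fit.k
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n = {n} <= k + 1 = {k + 1}")
    return -2.0 * fit.loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class SelectionTable:
    """A ranked candidate-model comparison.

    ``table`` has one row per model, sorted by AICc ascending, with columns
    ``model``, ``k``, ``aicc``, ``delta_aicc``, ``supported``, ``preferred``,
    ``is_null``, ``tied``.  ``verdict`` summarises the support rule's outcome.
    """

    table: pd.DataFrame
    fits: dict[str, ModelFit] = field(default_factory=dict)
    verdict: str = ""

    def __repr__(self):
        return f"SelectionTable(verdict={self.verdict!r})\n{self.table}"


def build_selection_table(
    table: pd.DataFrame, specs: list[ModelSpec]
) -> SelectionTable:
    """Fit a candidate set on identical rows and rank by AICc.

    All models are fitted on the complete cases over the union of their
    variables, so likelihoods are comparable; fits ending up on differing
    rows raise.  Support and preference flags follow the two-unit rule
    described in the module docstring.  Delta-AICc ties (< 1e-8) are flagged,
    never silently ordered.
    """
    if len(specs) < 2:
        raise ValueError("need at least two candidate models")
    used = {specs[0].response}
    for s in specs:
        used.update(s.predictors)
    sub = table.dropna(subset=[c for c in used if c in table.columns])

    fits = {}
    rows = []
    index = None
    for s in specs:
        f = fit_gaussian_glm(sub, s)
        if index is None:
            index = f.row_index
        elif not index.equals(f.row_index):
            raise ValueError(
                f"model {s.name!r} was fitted on different rows; "
                "likelihoods are not comparable"
            )
        fits[s.name] = f
        rows.append(
            {"model": s.name, "k": f.k, "aicc": aicc(f), "is_null": not s.predictors}
        )
    df = pd.DataFrame(rows).sort_values(["aicc", "k"], kind="stable")
    df["delta_aicc"] = df["aicc"] - df["aicc"].iloc[0]
    df["tied"] = False
    d = df["delta_aicc"].to_numpy()
    for i in range(1, len(df)):
        if abs(d[i] - d[i - 1]) < AICC_TIE_TOL:
            df.iloc[i, df.columns.get_loc("tied")] = True
            df.iloc[i - 1, df.columns.get_loc("tied")] = True

    null_aicc = None
    if df["is_null"].any():
        null_aicc = float(df.loc[df["is_null"], "aicc"].iloc[0])
    supported = (df["delta_aicc"] <= 2.0) & ~df["is_null"]
    if null_aicc is not None:
        supported &= df["aicc"] < null_aicc - 2.0
    df["supported"] = supported
    df["preferred"] = False
    if supported.any():
        best = df.loc[supported].sort_values(["k", "aicc"], kind="stable").index[0]
        df.loc[best, "preferred"] = True
        verdict = f"preferred model: {df.loc[best, 'model']}"
    else:
        verdict = "no supported predictors"
    df = df.reset_index(drop=True)
    df = df[
        ["model", "delta_aicc", "k", "aicc", "supported", "preferred", "is_null", "tied"]
    ]
    return SelectionTable(table=df, fits=fits, verdict=verdict)


@dataclass(frozen=True)
class ContrastResult:
    """One pairwise difference of estimated marginal means."""

    pair: str
    estimate: float
    se: float
    t: float
    df: int
    p_adjusted: float
    adjustment: str


def _grid_row(fit: ModelFit, assignment: dict[str, str]) -> np.ndarray:
    """Design row for one cell of the reference grid."""
    cols = fit.params.index
    row = np.zeros(len(cols))
    active = {}
    for p, levs in fit.levels.items():
        lev = assignment[p]
        for l2 in levs[1:]:
            active[f"{p}[{l2}]"] = 1.0 if lev == l2 else 0.0
    for j, c in enumerate(cols):
        if c == "Intercept":
            row[j] = 1.0
        elif ":" in c:
            a, b = c.split(":")
            row[j] = active.get(a, 0.0) * active.get(b, 0.0)
        else:
            row[j] = active.get(c, 0.0)
    return row


def emm_pairwise(
    fit: ModelFit, factor: str, *, adjustment: str = "tukey"
) -> list[ContrastResult]:
    """Pairwise contrasts of estimated marginal means for one factor.

    Marginal means average the model predictions over the levels of the other
    categorical predictors with equal weights.  Differences are tested with
    the pooled (unbiased) residual variance on n - p denominator degrees of
    freedom.  ``adjustment`` is ``tukey`` (default, via the studentized range
    distribution), ``bonferroni`` or ``none``.  If the model contains an
    interaction involving ``factor``, marginal means are still equal-weight
    averages and a warning is issued, since they then mask level-dependent
    effects.
    """
    if factor not in fit.levels:
        raise ValueError(f"{factor!r} is not a predictor of this model")
    levels = fit.levels[factor]
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    if any(factor in pair for pair in fit.spec.interactions):
        warnings.warn(
            f"model contains an interaction involving {factor!r}; marginal "
            "means average over the other factor's levels with equal weights",
            UserWarning,
            stacklevel=2,
        )
    others = [p for p in fit.levels if p != factor]
    other_grids = list(
        itertools.product(*(fit.levels[p] for p in others))
    ) or [()]

    emm_rows = {}
    for lev in levels:
        rows = []
        for combo in other_grids:
            assignment = {factor: lev, **dict(zip(others, combo))}
            rows.append(_grid_row(fit, assignment))
        emm_rows[lev] = np.mean(rows, axis=0)

    beta = fit.params.to_numpy()
    df = fit.residual_df
    n_levels = len(levels)
    m = n_levels * (n_levels - 1) // 2
    out = []
    for l1, l2 in itertools.combinations(levels, 2):
        c = emm_rows[l1] - emm_rows[l2]
        est = float(c @ beta)
        se = float(np.sqrt(c @ fit.cov_unbiased @ c))
        t = est / se
        if adjustment == "tukey":
            p = float(st.studentized_range.sf(abs(t) * np.sqrt(2.0), n_levels, df))
        elif adjustment == "bonferroni":
            p = min(1.0, 2.0 * float(st.t.sf(abs(t), df)) * m)
        elif adjustment == "none":
            p = 2.0 * float(st.t.sf(abs(t), df))
        else:
            raise ValueError(f"unknown adjustment {adjustment!r}")
        out.append(
            ContrastResult(
                pair=f"{l1} - {l2}",
                estimate=est,
                se=se,
                t=t,
                df=df,
                p_adjusted=p,
                adjustment=adjustment,
            )
        )
    return out


@dataclass(frozen=True)
class CorrelationResult:
    """A Pearson correlation with its test, reported as r(df) and p."""

    r: float
    df: int
    p: float
    t: float


def pearson_test(x, y) -> CorrelationResult:
    """Two-sided Pearson correlation test between two numeric vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has undefined correlation")
    res = st.pearsonr(x, y)
    n = len(x)
    r = float(res.statistic)
    t = r * math.sqrt((n - 2) / max(1e-300, 1.0 - r * r))
    return CorrelationResult(r=r, df=n - 2, p=float(res.pvalue), t=t)
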