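"""Mixed-model estimation of condition marginal means and Stroop components.

Each measure (IT, RT, MD, PE rate) is modelled with a linear mixed model:
stimulus type enters as five dummy variables against the colour-neutral
reference, participants contribute a random intercept and, where the data
support them, independent random slopes for the five dummies. The random
structure is chosen by a parsimony procedure: start from the full structure
and iteratively drop the smallest-variance slope while the fit is singular or
non-convergent, or while a likelihood-ratio test (alpha = 0.20) does not
support keeping it; the intercept is always retained.

Estimation is profiled REML (:mod:`stroop_trace.reml`), exact for this
diagonal-variance-component family; ``backend="statsmodels"`` fits the same
model with statsmodels MixedLM and serves as an independent cross-check in
the test suite. Marginal means are intercept/offset sums with delta-method
standard errors from the fixed-effect covariance. Confidence intervals use
the normal approximation (recorded as df_method="normal" on every estimate):
neither backend provides Satterthwaite degrees of freedom, and at this
design's sample sizes the difference is a few percent of the interval width.

Components are differences of marginal means (see ``conditions``); their
telescoping additivity identities hold exactly for every fitted model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.regression.mixed_linear_model import MixedLM

from .conditions import (
    COMPONENT_CONTRASTS,
    CONDITIONS,
    REFERENCE_CONDITION,
    component_values,
    composition_residuals,
)
from .errors import DataError, FitError
from .reml import reml_fit

#: Non-reference conditions, in fixed order: one dummy (and candidate random
#: slope) each.
DUMMY_CONDITIONS: tuple[str, ...] = tuple(
    c for c in CONDITIONS if c != REFERENCE_CONDITION
)

LRT_ALPHA = 0.20
_SINGULAR_TOL = 1e-6  # slope variance below tol * residual variance is singular

#: Measure name -> column holding the trial/cell value.
MEASURE_COLUMNS = {
    "it": "it_ms",
    "rt": "rt_ms",
    "md": "md_above",
    "pe": "pe_rate",
}


@dataclass(frozen=True)
class RandomStructure:
    """By-participant random terms: the intercept plus these condition slopes."""

    slopes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        bad = [s for s in self.slopes if s not in DUMMY_CONDITIONS]
        if bad:
            raise DataError(f"random slopes must be non-reference conditions, got {bad}")

    def describe(self) -> str:
        return "intercept" + ("" if not self.slopes else " + " + " + ".join(self.slopes))


FULL_STRUCTURE = RandomStructure(slopes=DUMMY_CONDITIONS)
INTERCEPT_ONLY = RandomStructure()


@dataclass
class FittedModel:
    """One fitted mixed model for one measure."""

    measure: str
    structure: RandomStructure
    coef: pd.Series  # intercept (neutral mean) + 5 condition offsets
    cov_fe: np.ndarray  # covariance of the fixed effects
    slope_variances: dict[str, float]
    intercept_variance: float
    residual_variance: float
    llf: float
    converged: bool
    singular: bool
    n_obs: int
    n_participants: int
    df_method: str = "normal"


def _prepare(data: pd.DataFrame, measure: str) -> pd.DataFrame:
    col = MEASURE_COLUMNS.get(measure, measure)
    for required in ("participant_id", "condition", col):
        if required not in data.columns:
            raise DataError(f"data lacks required column {required!r}")
    df = data[["participant_id", "condition", col]].rename(columns={col: "value"})
    df = df.dropna(subset=["value"]).reset_index(drop=True)
    unknown = set(df["condition"]) - set(CONDITIONS)
    if unknown:
        raise DataError(f"unknown conditions in data: {sorted(unknown)}")
    return df


def _robust_fit(model: MixedLM):
    # lbfgs is fastest but can degenerate when a variance sits on the zero
    # boundary; powell/nm are slower and markedly more robust there.
    last_exc: Exception | None = None
    for method in ("lbfgs", "powell", "nm"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=True, method=method, maxiter=500)
            if (
                np.isfinite(res.llf)
                and np.all(np.isfinite(res.fe_params))
                and np.all(np.isfinite(np.asarray(res.bse_fe)))
            ):
                return res
        except (np.linalg.LinAlgError, ValueError, OverflowError) as exc:  # pragma: no cover
            last_exc = exc
    raise FitError(f"mixed-model estimation failed: {last_exc}")


def _fit_statsmodels(df: pd.DataFrame, structure: RandomStructure):
    """statsmodels MixedLM fit with independent variance components."""
    df = df.copy()
    for c in DUMMY_CONDITIONS:
        df[f"d_{c}"] = (df["condition"] == c).astype(float)
    formula = "value ~ " + " + ".join(f"d_{c}" for c in DUMMY_CONDITIONS)
    vc_formula = {c: f"0 + d_{c}" for c in structure.slopes} or None
    model = MixedLM.from_formula(
        formula, data=df, groups="participant_id", re_formula="1", vc_formula=vc_formula
    )
    res = _robust_fit(model)
    slope_vars = {}
    if structure.slopes:
        vc_order = list(model.exog_vc.names)
        slope_vars = {c: float(v) for c, v in zip(vc_order, np.atleast_1d(res.vcomp))}
    p = 1 + len(DUMMY_CONDITIONS)
    return (
        np.asarray(res.fe_params, dtype=float),
        np.asarray(res.cov_params())[:p, :p],
        slope_vars,
        float(np.asarray(res.cov_re)[0, 0]),
        float(res.scale),
        float(res.llf),
        bool(res.converged),
    )


def fit_lmm(
    data: pd.DataFrame,
    measure: str,
    structure: RandomStructure,
    backend: str = "profiled",
) -> FittedModel:
    """REML fit of the dummy-coded mixed model with the given random structure.

    The default backend is this package's profiled REML solver (see
    :mod:`stroop_trace.reml`); ``backend="statsmodels"`` fits the identical
    model with statsmodels MixedLM (used as an independent cross-check).
    """
    df = _prepare(data, measure)
    names = ["intercept"] + list(DUMMY_CONDITIONS)
    if backend == "profiled":
        n = len(df)
        dummies = {
            c: (df["condition"] == c).to_numpy(dtype=float) for c in DUMMY_CONDITIONS
        }
        X = np.column_stack([np.ones(n)] + [dummies[c] for c in DUMMY_CONDITIONS])
        Z = np.column_stack([np.ones(n)] + [dummies[c] for c in structure.slopes])
        res = reml_fit(df["value"].to_numpy(dtype=float), X, df["participant_id"].to_numpy(), Z)
        vc = res.variance_components
        beta, cov_fe = res.beta, res.cov_beta
        slope_vars = {c: float(v) for c, v in zip(structure.slopes, vc[1:])}
        intercept_var, resid_var = float(vc[0]), res.sigma2
        llf, converged = res.llf, res.converged
    elif backend == "statsmodels":
        beta, cov_fe, slope_vars, intercept_var, resid_var, llf, converged = (
            _fit_statsmodels(df, structure)
        )
    else:
        raise DataError(f"unknown backend {backend!r}")
    singular = any(v < _SINGULAR_TOL * resid_var for v in slope_vars.values())
    return FittedModel(
        measure=measure,
        structure=structure,
        coef=pd.Series(beta, index=names),
        cov_fe=np.asarray(cov_fe),
        slope_variances=slope_vars,
        intercept_variance=intercept_var,
        residual_variance=resid_var,
        llf=float(llf),
        converged=bool(converged),
        singular=bool(singular),
        n_obs=len(df),
        n_participants=int(df["participant_id"].nunique()),
    )


def select_random_structure(data: pd.DataFrame, measure: str) -> RandomStructure:
    """Parsimonious random structure: prune unsupported slopes from the full set.

    With at most one observation per participant x condition cell (e.g. the
    partial-error rates) only the intercept is estimable and it is returned
    directly.
    """
    df = _prepare(data, measure)
    if df["participant_id"].nunique() < 2:
        raise DataError("random-structure selection requires at least 2 participants")
    cell_counts = df.groupby(["participant_id", "condition"]).size()
    if cell_counts.max() <= 1:
        return INTERCEPT_ONLY

    structure = FULL_STRUCTURE
    current = fit_lmm(df, "value", structure)
    while structure.slopes:
        drop = min(structure.slopes, key=lambda c: (current.slope_variances[c], c))
        reduced_structure = RandomStructure(
            slopes=tuple(s for s in structure.slopes if s != drop)
        )
        if not current.converged or current.singular:
            structure = reduced_structure
            current = fit_lmm(df, "value", structure)
            continue
        reduced = fit_lmm(df, "value", reduced_structure)
        lrt = max(0.0, 2.0 * (current.llf - reduced.llf))
        p = st.chi2.sf(lrt, df=1)
        if p >= LRT_ALPHA:
            structure, current = reduced_structure, reduced
        else:
            break
    return structure


@dataclass
class MarginalMeans:
    """Model-implied per-condition means with delta-method standard errors."""

    measure: str
    table: pd.DataFrame  # condition, mean, se, df
    contrast_matrix: np.ndarray = field(repr=False, default=None)
    cov_fe: np.ndarray = field(repr=False, default=None)
    df_method: str = "normal"

    def mean(self, condition: str) -> float:
        return float(self.table.set_index("condition").loc[condition, "mean"])

    def means(self) -> dict[str, float]:
        return dict(zip(self.table["condition"], self.table["mean"]))


def marginal_means(model: FittedModel) -> MarginalMeans:
    """Condition means: neutral = intercept, others = intercept + offset."""
    p = len(model.coef)
    rows = []
    lmat = np.zeros((len(CONDITIONS), p))
    for i, c in enumerate(CONDITIONS):
        lvec = np.zeros(p)
        lvec[0] = 1.0
        if c != REFERENCE_CONDITION:
            lvec[model.coef.index.get_loc(c)] = 1.0
        lmat[i] = lvec
        est = float(lvec @ model.coef.to_numpy())
        se = float(np.sqrt(lvec @ model.cov_fe @ lvec))
        rows.append({"condition": c, "mean": est, "se": se, "df": np.inf})
    return MarginalMeans(
        measure=model.measure,
        table=pd.DataFrame(rows),
        contrast_matrix=lmat,
        cov_fe=model.cov_fe,
        df_method=model.df_method,
    )


@dataclass
class ComponentEstimate:
    """One named Stroop component: a contrast of two marginal means."""

    name: str
    minuend: str
    subtrahend: str
    estimate: float
    se: float
    df: float
    ci_level: float
    ci_low: float
    ci_high: float


def component_contrasts(
    mm: MarginalMeans, ci_level: float = 0.99
) -> list[ComponentEstimate]:
    """All eight components with two-sided CIs at ``ci_level``."""
    if not 0.0 < ci_level < 1.0:
        raise DataError("ci_level must be in (0, 1)")
    idx = {c: i for i, c in enumerate(CONDITIONS)}
    z = st.norm.ppf(0.5 + ci_level / 2.0)
    out = []
    for name, (a, b) in COMPONENT_CONTRASTS.items():
        lvec = mm.contrast_matrix[idx[a]] - mm.contrast_matrix[idx[b]]
        est = mm.mean(a) - mm.mean(b)
        se = float(np.sqrt(lvec @ mm.cov_fe @ lvec))
        out.append(
            ComponentEstimate(
                name=name,
                minuend=a,
                subtrahend=b,
                estimate=est,
                se=se,
                df=np.inf,
                ci_level=ci_level,
                ci_low=est - z * se,
                ci_high=est + z * se,
            )
        )
    return out


def components_frame(components: Sequence[ComponentEstimate]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "component": [c.name for c in components],
            "minuend": [c.minuend for c in components],
            "subtrahend": [c.subtrahend for c in components],
            "estimate": [c.estimate for c in components],
            "se": [c.se for c in components],
            "df": [c.df for c in components],
            "ci_level": [c.ci_level for c in components],
            "ci_low": [c.ci_low for c in components],
            "ci_high": [c.ci_high for c in components],
        }
    )
    resid = composition_residuals({c.name: c.estimate for c in components})
    df["additivity_residual"] = [resid.get(name, 0.0) for name in df["component"]]
    return df


@dataclass
class ComponentAnalysis:
    model: FittedModel
    marginal: MarginalMeans
    components: list[ComponentEstimate]


def estimate_components(
    data: pd.DataFrame,
    measure: str,
    ci_level: float = 0.99,
    structure: RandomStructure | None = None,
) -> ComponentAnalysis:
    """Fit (selecting the random structure unless one is given), then contrast."""
    df = _prepare(data, measure)
    if structure is None:
        structure = select_random_structure(df, "value")
    model = fit_lmm(df, "value", structure)
    model = FittedModel(**{**model.__dict__, "measure": measure})
    mm = marginal_means(model)
    return ComponentAnalysis(
        model=model, marginal=mm, components=component_contrasts(mm, ci_level)
    )


def sanity_check_additivity(components: Sequence[ComponentEstimate]) -> dict[str, float]:
    """Residuals of the telescoping identities for a fitted component set."""
    return composition_residuals({c.name: c.estimate for c in components})


__all__ = [
    "RandomStructure",
    "FULL_STRUCTURE",
    "INTERCEPT_ONLY",
    "FittedModel",
    "fit_lmm",
    "select_random_structure",
    "MarginalMeans",
    "marginal_means",
    "ComponentEstimate",
    "component_contrasts",
    "components_frame",
    "ComponentAnalysis",
    "estimate_components",
    "component_values",
]
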