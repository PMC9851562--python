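"""Component estimation across the 101 normalized time steps.

For each step t a mixed model with the usual dummy coding is fitted to the
deviation (d_t) or x-coordinate (x_t) profile values; the requested component
contrast is formed with a 95% CI. The per-step random structure is a
simplified selection: a by-participant intercept, plus the single slope for
the contrasted condition when a likelihood-ratio test (alpha = 0.20) supports
it. A step whose fit fails is flagged and treated as a CI containing zero.

Intervals of sustained significance are maximal runs of steps whose CI
excludes zero, reported when at least ``min_run`` steps long (10 by default:
10% of total movement duration; 5 is conventional for plotting). Step s
corresponds to approximately (s-1)% of the total response duration, including
the pre-initiation dwell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .conditions import COMPONENT_CONTRASTS, REFERENCE_CONDITION
from .errors import DataError
from .inference import (
    INTERCEPT_ONLY,
    LRT_ALPHA,
    RandomStructure,
    component_contrasts,
    fit_lmm,
    marginal_means,
)

N_STEPS = 101
DEFAULT_MIN_RUN = 10


def significant_intervals(
    ci_low: np.ndarray, ci_high: np.ndarray, min_run: int = DEFAULT_MIN_RUN
) -> list[tuple[int, int]]:
    """Maximal runs of 1-based steps whose CI excludes zero, length >= min_run.

    NaN bounds (failed fits) count as containing zero.
    """
    lo = np.asarray(ci_low, dtype=float)
    hi = np.asarray(ci_high, dtype=float)
    if lo.shape != hi.shape:
        raise DataError("ci_low and ci_high must have equal length")
    with np.errstate(invalid="ignore"):
        sig = (lo > 0.0) | (hi < 0.0)
    sig = np.where(np.isnan(lo) | np.isnan(hi), False, sig)
    intervals: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(sig):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_run:
                intervals.append((start + 1, i))
            start = None
    if start is not None and len(sig) - start >= min_run:
        intervals.append((start + 1, len(sig)))
    return intervals


def peak(estimates: np.ndarray, measure: str) -> tuple[int, float]:
    """(step, estimate) of the maximal effect in the expected direction.

    Deviation components peak at maximal magnitude; x-coordinate components
    at their most negative value (the incorrect-response side). Ties break
    toward the earliest step; NaN steps are ignored.
    """
    est = np.asarray(estimates, dtype=float)
    if np.all(np.isnan(est)):
        raise DataError("no converged steps to locate a peak")
    if measure == "deviation":
        score = np.abs(est)
        score = np.where(np.isnan(score), -np.inf, score)
        idx = int(np.argmax(score))
    elif measure == "x_coordinate":
        score = np.where(np.isnan(est), np.inf, est)
        idx = int(np.argmin(score))
    else:
        raise DataError(f"unknown timecourse measure {measure!r}")
    return idx + 1, float(est[idx])


@dataclass
class TimecourseResult:
    """Stepwise component estimates with peak and sustained-run summaries."""

    measure: str
    component: str
    ci_level: float
    min_run: int
    table: pd.DataFrame  # step, estimate, se, df, ci_low, ci_high, converged, significant
    peak_step: int
    peak_estimate: float
    intervals: list[tuple[int, int]]


def _slope_condition(component: str) -> str:
    a, b = COMPONENT_CONTRASTS[component]
    return a if a != REFERENCE_CONDITION else b


def fit_timecourse(
    profiles: pd.DataFrame,
    measure: str,
    component: str,
    ci_level: float = 0.95,
    min_run: int = DEFAULT_MIN_RUN,
    slope: str = "auto",
) -> TimecourseResult:
    """Fit one mixed model per time step and contrast the component.

    ``profiles`` is the long table from :func:`stroop_trace.measures.profiles_table`
    (columns participant_id, condition, step, deviation, x_coordinate).
    ``slope`` is "auto" (LRT-supported single slope), "never", or "always".
    """
    if component not in COMPONENT_CONTRASTS:
        raise DataError(f"unknown component {component!r}")
    if measure not in ("deviation", "x_coordinate"):
        raise DataError(f"unknown timecourse measure {measure!r}")
    if slope not in ("auto", "never", "always"):
        raise DataError("slope must be 'auto', 'never' or 'always'")
    slope_cond = _slope_condition(component)
    slope_structure = RandomStructure(slopes=(slope_cond,))
    z = st.norm.ppf(0.5 + ci_level / 2.0)

    rows = []
    for step, sub in profiles.groupby("step", sort=True):
        data = sub[["participant_id", "condition", measure]].rename(
            columns={measure: "value"}
        )
        values = data["value"].to_numpy()
        if np.var(values) < 1e-18:
            # anchored steps (1 and 101) are constant across trials by design
            rows.append(
                {"step": int(step), "estimate": 0.0, "se": 0.0, "df": np.inf,
                 "ci_low": 0.0, "ci_high": 0.0, "converged": True}
            )
            continue
        try:
            model = fit_lmm(data, "value", INTERCEPT_ONLY)
            if slope != "never":
                try:
                    with_slope = fit_lmm(data, "value", slope_structure)
                    if slope == "always":
                        model = with_slope
                    elif with_slope.converged and not with_slope.singular:
                        lrt = max(0.0, 2.0 * (with_slope.llf - model.llf))
                        if st.chi2.sf(lrt, df=1) < LRT_ALPHA:
                            model = with_slope
                except Exception:
                    pass  # keep the intercept-only fit
            ok = model.converged
            est = se = np.nan
            if ok:
                comp = next(
                    c
                    for c in component_contrasts(marginal_means(model), ci_level)
                    if c.name == component
                )
                est, se = comp.estimate, comp.se
        except Exception:
            ok = False
            est = se = np.nan
        rows.append(
            {
                "step": int(step),
                "estimate": est if ok else np.nan,
                "se": se if ok else np.nan,
                "df": np.inf,
                "ci_low": est - z * se if ok else np.nan,
                "ci_high": est + z * se if ok else np.nan,
                "converged": bool(ok),
            }
        )
    table = pd.DataFrame(rows).sort_values("step").reset_index(drop=True)
    intervals = significant_intervals(
        table["ci_low"].to_numpy(), table["ci_high"].to_numpy(), min_run
    )
    sig = np.zeros(len(table), dtype=bool)
    for a, b in intervals:
        sig[(table["step"] >= a) & (table["step"] <= b)] = True
    table["significant"] = sig
    peak_step, peak_est = peak(table["estimate"].to_numpy(), measure)
    return TimecourseResult(
        measure=measure,
        component=component,
        ci_level=ci_level,
        min_run=min_run,
        table=table,
        peak_step=peak_step,
        peak_estimate=peak_est,
        intervals=intervals,
    )
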