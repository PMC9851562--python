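"""Mixed-model estimation: recovery, selection, marginal means, contrasts."""

import numpy as np
import pandas as pd
import pytest

from stroop_trace.conditions import CONDITIONS, REFERENCE_CONDITION
from stroop_trace.errors import DataError
from stroop_trace.inference import (
    FULL_STRUCTURE,
    INTERCEPT_ONLY,
    FittedModel,
    RandomStructure,
    component_contrasts,
    components_frame,
    estimate_components,
    fit_lmm,
    marginal_means,
    select_random_structure,
)
from stroop_trace.preprocess import filter_trials
from stroop_trace.simulate import simulate_dataset

from conftest import small_config

OFFSETS = {
    "standard_incongruent": 119.0,
    "nonresponse_set": 41.0,
    "associated_incongruent": 5.0,
    "neutral": 0.0,
    "associated_congruent": -25.0,
    "standard_congruent": -41.0,
}


def make_data(
    n_participants=12,
    n_trials=8,
    base=1070.0,
    offsets=OFFSETS,
    participant_sd=40.0,
    slope_sd=None,
    resid_sd=100.0,
    seed=0,
):
    """Balanced Gaussian data with known fixed effects and random structure."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        b = rng.normal(0, participant_sd)
        for c in CONDITIONS:
            slope = 0.0
            if slope_sd and c in slope_sd:
                slope = rng.normal(0, slope_sd[c])
            mu = base + offsets[c] + b + slope
            for i in range(n_trials):
                rows.append((f"P{p:02d}", c, mu + rng.normal(0, resid_sd)))
    return pd.DataFrame(rows, columns=["participant_id", "condition", "value"])


def test_noiseless_balanced_data_recovers_means_exactly():
    df = make_data(participant_sd=0.0, resid_sd=0.0, n_participants=4, n_trials=2)
    model = fit_lmm(df, "value", INTERCEPT_ONLY)
    mm = marginal_means(model)
    for c in CONDITIONS:
        assert mm.mean(c) == pytest.approx(1070.0 + OFFSETS[c], abs=1e-6)


def test_single_participant_degenerates_to_least_squares():
    df = make_data(n_participants=1, participant_sd=0.0, seed=3)
    model = fit_lmm(df, "value", INTERCEPT_ONLY)
    X = np.column_stack(
        [np.ones(len(df))]
        + [(df["condition"] == c).to_numpy(float) for c in CONDITIONS if c != REFERENCE_CONDITION]
    )
    beta, *_ = np.linalg.lstsq(X, df["value"].to_numpy(), rcond=None)
    np.testing.assert_allclose(model.coef.to_numpy(), beta, atol=1e-6)


def test_profiled_backend_agrees_with_statsmodels():
    """Dual-route check: this package's REML solver vs statsmodels MixedLM."""
    df = make_data(
        n_participants=15,
        slope_sd={"standard_incongruent": 60.0},
        seed=5,
    )
    for structure in (
        INTERCEPT_ONLY,
        RandomStructure(slopes=("standard_incongruent",)),
    ):
        a = fit_lmm(df, "value", structure)
        b = fit_lmm(df, "value", structure, backend="statsmodels")
        np.testing.assert_allclose(a.coef.to_numpy(), b.coef.to_numpy(), atol=1e-3)
        np.testing.assert_allclose(
            np.sqrt(np.diag(a.cov_fe)), np.sqrt(np.diag(b.cov_fe)), rtol=1e-3
        )
        assert a.llf == pytest.approx(b.llf, abs=1e-3)
        assert a.residual_variance == pytest.approx(b.residual_variance, rel=1e-3)
        assert a.intercept_variance == pytest.approx(
            b.intercept_variance, rel=0.05, abs=5.0
        )
    # the 5-slope surface is nearly flat near its optimum; require the profiled
    # solver to reach at least statsmodels' REML criterion value
    a = fit_lmm(df, "value", FULL_STRUCTURE)
    b = fit_lmm(df, "value", FULL_STRUCTURE, backend="statsmodels")
    assert a.llf >= b.llf - 1e-3
    np.testing.assert_allclose(a.coef.to_numpy(), b.coef.to_numpy(), atol=0.5)


def test_rt_recovery_on_simulated_study(layout):
    cfg = small_config(seed=41, n_participants=20, n_trials_per_condition=16)
    kept, _ = filter_trials(simulate_dataset(cfg, layout))
    data = pd.DataFrame(
        {
            "participant_id": [t.participant_id for t in kept],
            "condition": [t.condition for t in kept],
            "rt_ms": [t.rt_ms for t in kept],
        }
    )
    analysis = estimate_components(data, "rt", ci_level=0.99)
    mm = analysis.marginal
    neutral = mm.table.set_index("condition").loc["neutral"]
    assert abs(neutral["mean"] - 1070.0) < 3 * neutral["se"]
    comps = {c.name: c for c in analysis.components}
    truth = 160.0
    assert abs(comps["total_stroop"].estimate - truth) < 4 * comps["total_stroop"].se


def test_selection_prefers_intercept_only_without_slope_variance():
    """With no true slope variance most replicates prune every slope.

    A boundary LRT at alpha=0.20 keeps a spurious slope in a minority of
    datasets, so the check is a majority over seeded replicates.
    """
    picks = []
    for seed in range(6):
        df = make_data(seed=seed, n_participants=10, n_trials=6)
        picks.append(select_random_structure(df, "value"))
    assert sum(s == INTERCEPT_ONLY for s in picks) >= 3
    assert all(len(s.slopes) <= 2 for s in picks)


def test_selection_retains_a_large_slope():
    picks = []
    for seed in range(4):
        df = make_data(
            seed=100 + seed,
            n_participants=24,
            n_trials=12,
            slope_sd={"standard_incongruent": 150.0},
            resid_sd=60.0,
        )
        picks.append(select_random_structure(df, "value"))
    assert sum("standard_incongruent" in s.slopes for s in picks) >= 3


def test_selection_intercept_only_for_one_value_per_cell():
    df = make_data(n_trials=1, seed=9)
    assert select_random_structure(df, "value") == INTERCEPT_ONLY


def test_selection_requires_two_participants():
    df = make_data(n_participants=1)
    with pytest.raises(DataError, match="participants"):
        select_random_structure(df, "value")


def _manual_model(coef_map, se=1.0):
    names = ["intercept"] + [c for c in CONDITIONS if c != REFERENCE_CONDITION]
    coef = pd.Series([coef_map.get(n, 0.0) for n in names], index=names)
    return FittedModel(
        measure="rt",
        structure=INTERCEPT_ONLY,
        coef=coef,
        cov_fe=np.eye(len(names)) * se**2,
        slope_variances={},
        intercept_variance=0.0,
        residual_variance=se**2,
        llf=0.0,
        converged=True,
        singular=False,
        n_obs=100,
        n_participants=10,
    )


def test_marginal_means_intercept_plus_offset():
    model = _manual_model({"intercept": 1070.0, "standard_incongruent": 119.0})
    mm = marginal_means(model)
    assert mm.mean("neutral") == pytest.approx(1070.0)
    assert mm.mean("standard_incongruent") == pytest.approx(1189.0)
    zero = marginal_means(_manual_model({"intercept": 500.0}))
    assert all(zero.mean(c) == pytest.approx(500.0) for c in CONDITIONS)


def test_component_contrasts_reported_means_arithmetic():
    """Published marginal means give total=160, interference=119, facilitation=41."""
    model = _manual_model(
        {
            "intercept": 1070.0,
            "standard_incongruent": 119.0,
            "nonresponse_set": 41.0,
            "associated_incongruent": 5.0,
            "associated_congruent": -25.0,
            "standard_congruent": -41.0,
        }
    )
    comps = {c.name: c for c in component_contrasts(marginal_means(model), 0.99)}
    assert comps["total_stroop"].estimate == pytest.approx(1189.0 - 1029.0)
    assert comps["interference"].estimate == pytest.approx(119.0)
    assert comps["facilitation"].estimate == pytest.approx(41.0)
    assert comps["total_stroop"].ci_low < 160.0 < comps["total_stroop"].ci_high


def test_additivity_residuals_vanish_for_fitted_components(layout):
    df = make_data(seed=13)
    analysis = estimate_components(df, "value", structure=INTERCEPT_ONLY)
    frame = components_frame(analysis.components)
    assert frame["additivity_residual"].abs().max() < 1e-9


def test_reference_recoding_leaves_components_unchanged():
    """Relabelling which condition is 'reference' must not move any contrast."""
    import statsmodels.formula.api as smf

    df = make_data(seed=17, n_participants=10, n_trials=6)
    analysis = estimate_components(df, "value", structure=INTERCEPT_ONLY)
    comps = {c.name: c.estimate for c in analysis.components}
    alt = smf.mixedlm(
        "value ~ C(condition, Treatment('standard_congruent'))",
        df,
        groups="participant_id",
    ).fit(reml=True)
    prefix = "C(condition, Treatment('standard_congruent'))[T."
    means = {
        c: alt.fe_params["Intercept"]
        + (0.0 if c == "standard_congruent" else alt.fe_params[f"{prefix}{c}]"])
        for c in CONDITIONS
    }
    for name, (a, b) in [
        ("total_stroop", ("standard_incongruent", "standard_congruent")),
        ("interference", ("standard_incongruent", "neutral")),
        ("facilitation", ("neutral", "standard_congruent")),
    ]:
        assert comps[name] == pytest.approx(means[a] - means[b], abs=1e-4)


def test_marginal_mean_se_matches_parametric_bootstrap():
    """Delta-method SEs agree with a parametric bootstrap within 15%."""
    rng = np.random.default_rng(23)
    df = make_data(n_participants=10, n_trials=6, seed=19)
    model = fit_lmm(df, "value", INTERCEPT_ONLY)
    mm = marginal_means(model)
    n_p, n_t = 10, 6
    boot = []
    for _ in range(400):
        rows = []
        for p in range(n_p):
            b = rng.normal(0, np.sqrt(model.intercept_variance))
            for c in CONDITIONS:
                mu = mm.mean(c) + b
                vals = mu + rng.normal(0, np.sqrt(model.residual_variance), n_t)
                rows.extend((f"P{p:02d}", c, v) for v in vals)
        bdf = pd.DataFrame(rows, columns=["participant_id", "condition", "value"])
        bmodel = fit_lmm(bdf, "value", INTERCEPT_ONLY)
        boot.append([marginal_means(bmodel).mean(c) for c in CONDITIONS])
    boot_se = np.std(np.asarray(boot), axis=0, ddof=1)
    fitted_se = mm.table.set_index("condition").loc[list(CONDITIONS), "se"].to_numpy()
    np.testing.assert_allclose(fitted_se, boot_se, rtol=0.15)
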