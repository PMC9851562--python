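"""Published reference estimates used for calibration and worked examples.

These are the marginal means and component estimates reported for the
original mouse-tracking Stroop study that this pipeline reimplements
(n = 83 participants, 32 trials per condition). The generator's defaults are
calibrated to the marginal means; the component table provides the printed
worked-example inputs whose additivity the contrast algebra must reproduce.

Units: IT/RT in ms, MD in normalized task units, PE in percent.
"""

from __future__ import annotations

from . import conditions as cond

#: Reported marginal means per measure and condition.
REPORTED_MARGINAL_MEANS: dict[str, dict[str, float]] = {
    "it": dict(zip(cond.CONDITIONS, [169.0, 169.0, 168.0, 168.0, 170.0, 167.0])),
    "rt": dict(zip(cond.CONDITIONS, [1189.0, 1111.0, 1075.0, 1070.0, 1045.0, 1029.0])),
    "md": dict(zip(cond.CONDITIONS, [0.676, 0.517, 0.526, 0.480, 0.459, 0.427])),
    "pe": dict(zip(cond.CONDITIONS, [36.7, 26.1, 28.6, 24.9, 24.0, 22.3])),
}

#: Reported component estimates (contrasts of mixed-model marginal means).
#: Only components the study printed are listed.
REPORTED_COMPONENTS: dict[str, dict[str, float]] = {
    "rt": {
        "total_stroop": 159.8,
        "interference": 119.2,
        "facilitation": 40.6,
        "response_conflict": 77.9,
        "semantic_conflict": 4.5,
        "semantic_relevance": 36.8,
        "response_facilitation": 15.6,
        "semantic_facilitation": 25.0,
    },
    "md": {
        "total_stroop": 0.249,
        "interference": 0.196,
        "facilitation": 0.053,
        "response_conflict": 0.159,
        "semantic_conflict": 0.046,
        "semantic_relevance": -0.009,
        "response_facilitation": 0.032,
    },
    "pe": {
        "total_stroop": 14.41,
        "interference": 11.85,
        "facilitation": 2.55,
        "response_conflict": 10.61,
        "semantic_conflict": 3.7,
        "semantic_relevance": -2.46,
        "response_facilitation": 1.73,
    },
}

#: Reported exclusion percentages of total trials.
REPORTED_EXCLUSIONS = {"omission": 0.34, "error": 0.58, "rt_outlier": 1.0}


def reported_composite_sums(measure: str) -> dict[str, float]:
    """Sum the printed subcomponents into each composite they compose.

    Returns composite name -> sum of its printed parts, for composites whose
    parts are all available for ``measure``.
    """
    comps = REPORTED_COMPONENTS[measure]
    sums = {}
    for composite, parts in cond.COMPOSITION.items():
        if all(p in comps for p in parts):
            sums[composite] = float(sum(comps[p] for p in parts))
    return sums
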