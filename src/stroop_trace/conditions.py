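"""Stimulus-type conditions and the contrast algebra of Stroop components.

The design has a single six-level Stimulus-type factor. The colour-neutral
condition is the reference level throughout: interference-type components
compare a conflict condition against it, facilitation-type components compare
it against a congruent condition. Every named component is a difference of
two condition means (minuend − subtrahend), so composite effects telescope
exactly:

    interference + facilitation                          = total_stroop
    response_conflict + semantic_relevance
                      + semantic_conflict                = interference
    response_facilitation + semantic_facilitation        = facilitation
"""

from __future__ import annotations

from typing import Mapping

from .errors import ConfigError

STANDARD_INCONGRUENT = "standard_incongruent"
NONRESPONSE_SET = "nonresponse_set"
ASSOCIATED_INCONGRUENT = "associated_incongruent"
NEUTRAL = "neutral"
ASSOCIATED_CONGRUENT = "associated_congruent"
STANDARD_CONGRUENT = "standard_congruent"

#: The six stimulus-type conditions, ordered from most conflicting to most
#: facilitating (the order used in report tables).
CONDITIONS: tuple[str, ...] = (
    STANDARD_INCONGRUENT,
    NONRESPONSE_SET,
    ASSOCIATED_INCONGRUENT,
    NEUTRAL,
    ASSOCIATED_CONGRUENT,
    STANDARD_CONGRUENT,
)

#: Reference level for dummy coding in every mixed model.
REFERENCE_CONDITION = NEUTRAL

#: Component name -> (minuend condition, subtrahend condition).
COMPONENT_CONTRASTS: dict[str, tuple[str, str]] = {
    "total_stroop": (STANDARD_INCONGRUENT, STANDARD_CONGRUENT),
    "interference": (STANDARD_INCONGRUENT, NEUTRAL),
    "facilitation": (NEUTRAL, STANDARD_CONGRUENT),
    "response_conflict": (STANDARD_INCONGRUENT, NONRESPONSE_SET),
    "semantic_conflict": (ASSOCIATED_INCONGRUENT, NEUTRAL),
    "semantic_relevance": (NONRESPONSE_SET, ASSOCIATED_INCONGRUENT),
    "response_facilitation": (ASSOCIATED_CONGRUENT, STANDARD_CONGRUENT),
    "semantic_facilitation": (NEUTRAL, ASSOCIATED_CONGRUENT),
}

COMPONENT_NAMES: tuple[str, ...] = tuple(COMPONENT_CONTRASTS)

#: Telescoping identities: composite component -> its additive parts.
COMPOSITION: dict[str, tuple[str, ...]] = {
    "total_stroop": ("interference", "facilitation"),
    "interference": ("response_conflict", "semantic_relevance", "semantic_conflict"),
    "facilitation": ("response_facilitation", "semantic_facilitation"),
}


def validate_condition(label: str) -> str:
    if label not in CONDITIONS:
        raise ConfigError(f"unknown condition label {label!r}")
    return label


def component_values(means: Mapping[str, float]) -> dict[str, float]:
    """Compute all eight components from a map of condition means.

    Works for ground-truth offsets, raw means, or model marginal means alike;
    the additivity identities hold exactly by construction.
    """
    missing = [c for c in CONDITIONS if c not in means]
    if missing:
        raise ConfigError(f"means missing conditions: {missing}")
    return {
        name: float(means[a]) - float(means[b])
        for name, (a, b) in COMPONENT_CONTRASTS.items()
    }


def composition_residuals(components: Mapping[str, float]) -> dict[str, float]:
    """Residual of each telescoping identity (composite − sum of parts).

    Exactly zero (to floating point) whenever every component comes from one
    set of condition means.
    """
    return {
        name: float(components[name]) - sum(float(components[p]) for p in parts)
        for name, parts in COMPOSITION.items()
    }
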