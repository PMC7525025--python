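"""Activity state vocabulary and the ambulatory/stationary dichotomy.

The fine-grained vocabulary follows common wrist-worn HAR corpora: four
gait-involving states and four non-locomotive states.  ``jogging`` doubles
as "running" (single state).  ``non_wear`` marks intervals with no sensor
data and never receives samples.
"""

from __future__ import annotations

AMBULATORY_STATES: tuple[str, ...] = ("walking", "climbing_stairs", "cycling", "jogging")
STATIONARY_STATES: tuple[str, ...] = ("sitting", "standing", "lying_down", "hand_work")
NON_WEAR = "non_wear"
ALL_STATES: tuple[str, ...] = AMBULATORY_STATES + STATIONARY_STATES + (NON_WEAR,)

#: integer per-sample codes used throughout
UNCLASSIFIED = -1
STATIONARY = 0
AMBULATORY = 1

BINARY_OF: dict[str, int] = {
    **{s: AMBULATORY for s in AMBULATORY_STATES},
    **{s: STATIONARY for s in STATIONARY_STATES},
}

BINARY_NAME = {AMBULATORY: "ambulatory", STATIONARY: "stationary"}

#: stable integer code per fine state (non_wear gets -1: it has no samples)
FINE_CODE: dict[str, int] = {s: i for i, s in enumerate(AMBULATORY_STATES + STATIONARY_STATES)}
FINE_NAME: dict[int, str] = {i: s for s, i in FINE_CODE.items()}


def binary_of_code(fine_code: int) -> int:
    """Map a fine-state integer code to the ambulatory/stationary code."""
    if fine_code < 0:
        return UNCLASSIFIED
    return BINARY_OF[FINE_NAME[fine_code]]
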