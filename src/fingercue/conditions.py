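"""Force-condition labels and sign conventions shared across the package.

Six force combinations are presented in each experiment.  ``T``/``I`` refer to
thumb and index finger; ``UP``/``DN`` to the direction of the tangential
(vertical shear) force on that digit.  Positive tangential force is upward.
"""

# Canonical presentation order (also the column-block order in reports).
CONDITIONS: tuple[str, ...] = (
    "TUP_IUP",
    "TDN_IDN",
    "TUP_IDN",
    "TDN_IUP",
    "NULL",
    "FN_ONLY",
)

#: The opposite-direction combinations that elicit the matching illusion.
OPPOSITE_CONDITIONS: tuple[str, ...] = ("TUP_IDN", "TDN_IUP")

#: Same-direction combinations (no systematic bias expected).
SAME_DIRECTION_CONDITIONS: tuple[str, ...] = ("TUP_IUP", "TDN_IDN")

#: Expected sign of (thumb, index) tangential force per condition; 0 = no
#: tangential force is applied to that digit.
TANGENTIAL_SIGNS: dict[str, tuple[int, int]] = {
    "TUP_IUP": (+1, +1),
    "TDN_IDN": (-1, -1),
    "TUP_IDN": (+1, -1),
    "TDN_IUP": (-1, +1),
    "NULL": (0, 0),
    "FN_ONLY": (0, 0),
}

EXPERIMENTS: tuple[int, ...] = (1, 2, 3)


def validate_condition(condition: str) -> str:
    if condition not in CONDITIONS:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        )
    return condition


def validate_experiment(experiment: int) -> int:
    if experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment!r}; expected 1, 2 or 3")
    return int(experiment)
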