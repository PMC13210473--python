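"""Recovery arithmetic for leaf gas-exchange and water-status group means.

Group means of a physiological metric (net photosynthetic rate Pn in
umol CO2 m-2 s-1, stomatal conductance Gs in mol m-2 s-1, leaf water
potential in MPa) across the CK / DT / DTR conditions are reduced to two
percentages relative to the control: percent-of-control (reported to one
decimal) and percent reduction (reported to the nearest integer).
"""

from __future__ import annotations

from .matrix import InputError


def _check(means: dict[str, float], control: str) -> None:
    if control not in means:
        raise InputError(f"control condition {control!r} absent from means")
    if means[control] <= 0:
        raise InputError("control mean must be positive")


def percent_of_control(means: dict[str, float], condition: str, control: str = "CK") -> float:
    """100 * mean(condition) / mean(control), rounded to 1 decimal."""
    _check(means, control)
    if condition not in means:
        raise InputError(f"condition {condition!r} absent from means")
    return round(100.0 * means[condition] / means[control], 1)


def percent_reduction(means: dict[str, float], condition: str, control: str = "CK") -> int:
    """100 * (mean(control) - mean(condition)) / mean(control), nearest integer."""
    _check(means, control)
    if condition not in means:
        raise InputError(f"condition {condition!r} absent from means")
    return round(100.0 * (means[control] - means[condition]) / means[control])
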