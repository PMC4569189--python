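"""MRI acquisition-parameter helpers.

The T1-weighted sequence used for direct pallidal targeting prepares
magnetization in 90 - tau1 - 180 - tau2 - acquisition cycles.  The two
relaxation intervals split the total preparation duration TI as

    tau1 = quot * TI        tau2 = TI - tau1

with quot in [0, 1]; symmetric timing corresponds to quot = 0.5.
"""

from __future__ import annotations

__all__ = ["InvalidParameterError", "mdeft_timing"]


class InvalidParameterError(ValueError):
    """Acquisition parameter outside its valid range."""


def mdeft_timing(quot: float, TI: float) -> tuple[float, float]:
    """Split the preparation duration ``TI`` (ms) into (tau1, tau2).

    ``tau1 + tau2 == TI`` exactly.  Raises
    :class:`InvalidParameterError` unless ``0 <= quot <= 1`` and
    ``TI > 0``.
    """
    if not 0.0 <= quot <= 1.0:
        raise InvalidParameterError(f"quot must be within [0, 1], got {quot}")
    if TI <= 0:
        raise InvalidParameterError(f"TI must be positive, got {TI}")
    tau1 = quot * TI
    return tau1, TI - tau1
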