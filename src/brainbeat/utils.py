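"""Small shared helpers."""

from __future__ import annotations

from .errors import InvalidParameterError

__all__ = ["cycle_fraction_to_time"]


def cycle_fraction_to_time(fraction: float, heart_rate_bpm: float) -> float:
    """Convert a cycle fraction to milliseconds at a given heart rate.

    E.g. 20% of the cycle at 60 bpm is 200 ms.
    """
    if heart_rate_bpm <= 0:
        raise InvalidParameterError("heart_rate_bpm must be > 0")
    return fraction * (60000.0 / heart_rate_bpm)
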