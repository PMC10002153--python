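"""Third-molar maturity index and the minor/adult decision.

I3M = (a + b) / c, the summed open-apex width over the tooth height.  The
ratio is dimensionless, so the pixel scale of a radiograph crop cancels.
The forensic cut-off is 0.08: below it the apices are essentially closed
and the subject is classified as an adult (>= 18 years); at or above it,
as a minor.  Exact equality is classified as *minor* — the conservative
direction in a safeguarding context — and both the threshold and this
boundary rule are explicit parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidMeasurementError
from .tda import Measurement

DEFAULT_THRESHOLD = 0.08

MINOR = "minor"
ADULT = "adult"


@dataclass
class I3MResult:
    """An I3M score with the decision it implies."""

    i3m: float
    threshold: float
    decision: str
    measurement: Measurement | None = None


def compute_i3m(measurement: Measurement) -> float:
    """(a + b) / c for one measurement."""
    if measurement.c_px <= 0:
        raise InvalidMeasurementError("tooth height c must be positive")
    return (measurement.a_px + measurement.b_px) / measurement.c_px


def classify_age(i3m: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """'adult' iff i3m < threshold, else 'minor' (equality counts as minor)."""
    if i3m < 0:
        raise InvalidMeasurementError("I3M cannot be negative")
    if threshold <= 0:
        raise InvalidMeasurementError("threshold must be positive")
    return ADULT if i3m < threshold else MINOR


def score_measurement(
    measurement: Measurement, threshold: float = DEFAULT_THRESHOLD
) -> I3MResult:
    """Convenience wrapper: score + decision for one measurement."""
    i3m = compute_i3m(measurement)
    return I3MResult(
        i3m=i3m,
        threshold=threshold,
        decision=classify_age(i3m, threshold),
        measurement=measurement,
    )
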