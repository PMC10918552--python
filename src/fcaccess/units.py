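"""Distance-unit handling.

All layer coordinates are assumed to be in meters (projected CRS with
linear units); thresholds carry explicit units and are converted here.
1 mile = 1609.344 m exactly (international mile); the common "1 mile =
1.6 km" shorthand is display rounding, not a conversion factor.
"""

from .errors import ConfigurationError

METERS_PER_MILE = 1609.344
METERS_PER_KM = 1000.0

DISTANCE_UNITS = ("miles", "km", "meters")
TIME_UNITS = ("minutes",)


def to_meters(value: float, units: str) -> float:
    """Convert a distance threshold to meters."""
    if units == "miles":
        return value * METERS_PER_MILE
    if units == "km":
        return value * METERS_PER_KM
    if units == "meters":
        return float(value)
    raise ConfigurationError(
        f"unknown distance unit {units!r}; expected one of {DISTANCE_UNITS}"
    )
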