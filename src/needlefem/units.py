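"""Unit helpers.

Everything inside the package is SI (m, Pa, N/m, J/m^2).  Configuration
files speak the bench units of the application (mm, kPa); conversion
happens once, at load time.
"""

from __future__ import annotations

import math

MM = 1e-3  # m per mm
KPA = 1e3  # Pa per kPa


def mm(value: float) -> float:
    """Convert millimetres to metres."""
    return value * MM


def to_mm(value: float) -> float:
    """Convert metres to millimetres."""
    return value / MM


def kpa(value: float) -> float:
    """Convert kilopascals to pascals."""
    return value * KPA


def to_kpa(value: float) -> float:
    """Convert pascals to kilopascals."""
    return value / KPA


def deg(value: float) -> float:
    """Convert degrees to radians."""
    return math.radians(value)


def to_deg(value: float) -> float:
    """Convert radians to degrees."""
    return math.degrees(value)
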