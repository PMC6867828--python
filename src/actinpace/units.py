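"""Unit handling.

All concentrations are stored internally in molar.  I/O layers accept
nM/uM columns or ``"18 nM"``-style strings and convert on entry, which
removes mixed-unit bookkeeping as a source of error.
"""

from __future__ import annotations

import re

#: molar multipliers for recognised concentration unit strings
CONCENTRATION_UNITS = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,  # micro sign
    "μM": 1e-6,  # greek mu
    "nM": 1e-9,
    "pM": 1e-12,
}

#: filament length contributed by one incorporated actin subunit (nm)
RISE_PER_SUBUNIT_NM = 2.7

_QUANTITY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([A-Za-zµμ]+)\s*$")


def to_molar(value: float, unit: str) -> float:
    """Convert ``value`` expressed in ``unit`` (e.g. ``"nM"``) to molar."""
    try:
        return float(value) * CONCENTRATION_UNITS[unit]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r}") from None


def parse_concentration(text) -> float:
    """Parse ``"18 nM"`` / ``"1.2 uM"`` / plain numbers (molar) to molar."""
    if isinstance(text, (int, float)):
        return float(text)
    m = _QUANTITY_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse concentration {text!r}")
    return to_molar(float(m.group(1)), m.group(2))


def subunits_per_s_to_um_per_s(v: float) -> float:
    """Convert an elongation velocity from subunits/s to um/s (2.7 nm rise)."""
    return v * RISE_PER_SUBUNIT_NM * 1e-3


def um_per_s_to_subunits_per_s(v: float) -> float:
    """Convert an elongation velocity from um/s to subunits/s."""
    return v / (RISE_PER_SUBUNIT_NM * 1e-3)
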