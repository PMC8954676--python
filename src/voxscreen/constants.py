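"""Physical constant tables shared across modules."""

from __future__ import annotations

#: Bondi van der Waals radii in Angstrom. Elements missing from Bondi's
#: compilation fall back to ``VDW_DEFAULT`` (the carbon radius), which keeps
#: clash thresholds conservative for exotic atoms.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "SI": 2.10,
    "B": 1.92,
}

VDW_DEFAULT = 1.70


def vdw_radius(element: str) -> float:
    """Bondi radius of an element symbol (case-insensitive), with fallback."""
    return VDW_RADII.get(element.upper(), VDW_DEFAULT)
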