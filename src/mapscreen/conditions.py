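"""Extraction-condition vocabulary for the polymer screen.

The screen covers eleven membrane-active polymer (MAP) conditions drawn from
three chemistry classes — styrene–maleic acid (SMA), chloro-styrene–maleic
acid (ChloroSMA, "CS") and acrylic acid/styrene (AASTY) copolymers — plus two
detergent controls (RIPA and NP40) commonly used in membrane proteomics.
"""

from __future__ import annotations

# 11 polymers + 2 detergent controls, in the screen's canonical order.
DEFAULT_CONDITIONS: tuple[str, ...] = (
    "SMA200",
    "SMA300",
    "CS20",
    "CS40",
    "CS60",
    "CS80",
    "AASTY645",
    "AASTY650",
    "AASTY1145",
    "AASTY1150",
    "AASTY80",
    "RIPA",
    "NP40",
)

# Chemistry class per condition; "detergent" marks the micellar controls.
CONDITION_CLASSES: dict[str, str] = {
    "SMA200": "SMA",
    "SMA300": "SMA",
    "CS20": "ChloroSMA",
    "CS40": "ChloroSMA",
    "CS60": "ChloroSMA",
    "CS80": "ChloroSMA",
    "AASTY645": "AASTY",
    "AASTY650": "AASTY",
    "AASTY1145": "AASTY",
    "AASTY1150": "AASTY",
    "AASTY80": "AASTY",
    "RIPA": "detergent",
    "NP40": "detergent",
}

DETERGENT_CLASS = "detergent"


def polymer_conditions(class_map: dict[str, str] | None = None) -> list[str]:
    """Conditions whose class is any polymer chemistry (i.e. not a detergent)."""
    cmap = CONDITION_CLASSES if class_map is None else class_map
    return [c for c, k in cmap.items() if k != DETERGENT_CLASS]
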