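"""Fixed six-category label table for cranial CSF-compartment maps.

The whole package shares one ordered code table; label maps are stored as
unsigned 8-bit NIfTI volumes with these codes.
"""

from __future__ import annotations

BACKGROUND = 0
PARENCHYMA = 1
VENTRICLES = 2
SYLVIAN_BASAL = 3
HIGH_CONVEXITY_SAS = 4
OTHER_SAS = 5

#: Ordered category codes; index == code.
CATEGORIES: tuple[int, ...] = (
    BACKGROUND,
    PARENCHYMA,
    VENTRICLES,
    SYLVIAN_BASAL,
    HIGH_CONVEXITY_SAS,
    OTHER_SAS,
)

CATEGORY_NAMES: dict[int, str] = {
    BACKGROUND: "background",
    PARENCHYMA: "parenchyma",
    VENTRICLES: "ventricles",
    SYLVIAN_BASAL: "sylvian_basal",
    HIGH_CONVEXITY_SAS: "high_convexity_sas",
    OTHER_SAS: "other_sas",
}

#: CSF compartment codes (everything that contributes to intracranial CSF).
CSF_CATEGORIES: tuple[int, ...] = (
    VENTRICLES,
    SYLVIAN_BASAL,
    HIGH_CONVEXITY_SAS,
    OTHER_SAS,
)

#: Subarachnoid-space codes (CSF outside the ventricular system).
SAS_CATEGORIES: tuple[int, ...] = (SYLVIAN_BASAL, HIGH_CONVEXITY_SAS, OTHER_SAS)
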