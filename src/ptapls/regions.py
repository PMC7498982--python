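"""The five-region coarse brain parcellation used throughout the package.

The parcellation splits the brain into five bilateral regions chosen to
separate superficial hemispheric white matter from deep midline structures:

====  =======================================================  ==========
code  anatomy                                                  depth class
====  =======================================================  ==========
FT    fronto-temporal white matter                             superficial
PO    parieto-occipital white matter                           superficial
CC    corpus callosum, cingular and subcingular white matter   deep
BS    brainstem (pons, midbrain, upper medulla)                deep
BT    basal ganglia (caudate, putamen, pallidum) and thalamus  superficial*
====  =======================================================  ==========

*BT is grey matter and is grouped with the hemispheric regions in the
deep-vs-superficial contrast pattern (CC/BS vs FT/PO/BT).
"""

from __future__ import annotations

#: Canonical region order used for every 5-vector in the package.
REGIONS: tuple[str, ...] = ("FT", "PO", "CC", "BS", "BT")

#: Integer labels used in label volumes; 0 is background.
REGION_LABELS: dict[str, int] = {"FT": 1, "PO": 2, "CC": 3, "BS": 4, "BT": 5}

LABEL_TO_REGION: dict[int, str] = {v: k for k, v in REGION_LABELS.items()}

#: Regions that are primarily white matter and receive the FA threshold.
WM_REGIONS: tuple[str, ...] = ("FT", "PO", "CC", "BS")

#: Deep midline regions, sign-split against the rest in the second pattern.
DEEP_REGIONS: tuple[str, ...] = ("CC", "BS")

BACKGROUND_LABEL: int = 0
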