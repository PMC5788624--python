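"""Marker-panel registry.

Single source of truth for the six-miRNA panel measured by qRT-PCR and the
subset of markers the subtype classifier actually consumes. miR-182 is
quantified and reported in the statistics but excluded from classification:
its expression does not separate clear cell from papillary RCC.
"""

from __future__ import annotations

MIR_221 = "miR-221"
MIR_222 = "miR-222"
MIR_126 = "miR-126"
MIR_182 = "miR-182"
MIR_200B = "miR-200b"
MIR_200C = "miR-200c"

#: Full qRT-PCR panel, in reporting order.
PANEL: tuple[str, ...] = (MIR_221, MIR_222, MIR_126, MIR_182, MIR_200B, MIR_200C)

#: Markers used by the two-step classifier (miR-182 excluded).
CLASSIFIER_MARKERS: tuple[str, ...] = (MIR_221, MIR_222, MIR_126, MIR_200B, MIR_200C)

#: Tumor subtype labels.
CCRCC = "ccRCC"
PRCC = "pRCC"
CHRCC = "chRCC"
ONCOCYTOMA = "oncocytoma"

SUBTYPES: tuple[str, ...] = (CCRCC, PRCC, CHRCC, ONCOCYTOMA)

#: Step-1 groups: proximal-nephron-derived vs distal-nephron-derived tumors.
PROXIMAL = "proximal"  # ccRCC + pRCC
DISTAL = "distal"      # chRCC + oncocytoma
GREY = "grey"
INDETERMINATE = "indeterminate"

STEP1_GROUP_OF = {CCRCC: PROXIMAL, PRCC: PROXIMAL, CHRCC: DISTAL, ONCOCYTOMA: DISTAL}
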