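"""The Luminex Cytokine 35-Plex Human Panel and the clinical variable set.

Column names are plain ASCII identifiers (``IL-1 beta`` becomes ``IL1B``)
so they can double as graph-node labels and CSV headers.
"""

from __future__ import annotations

#: The 35 analytes of the Luminex Cytokine 35-Plex Human Panel, fixed order.
LUMINEX_35: tuple[str, ...] = (
    "EGF",
    "EOTAXIN",
    "FGF_BASIC",
    "G_CSF",
    "GM_CSF",
    "HGF",
    "IFN_ALPHA",
    "IFN_GAMMA",
    "IL1B",
    "IL1A",
    "IL1RA",
    "IL2",
    "IL2R",
    "IL3",
    "IL4",
    "IL5",
    "IL6",
    "IL7",
    "IL8",
    "IL9",
    "IL10",
    "IL12",
    "IL13",
    "IL15",
    "IL17A",
    "IL17F",
    "IL22",
    "CXCL10",
    "CCL2",
    "CXCL9",
    "CCL3",
    "CCL4",
    "CCL5",
    "TNF_ALPHA",
    "VEGF",
)

#: Continuous clinical variables (static demographics plus dynamic vitals/labs).
CLINICAL_CONTINUOUS: tuple[str, ...] = ("age", "wbc", "resp_rate", "co2")

#: Binary clinical flags; passed to the network untouched (no binning).
CLINICAL_BINARY: tuple[str, ...] = ("sex", "comorbidity", "antihistamines")

CLINICAL_ALL: tuple[str, ...] = CLINICAL_CONTINUOUS + CLINICAL_BINARY

#: Name of the dichotomized functional-recovery outcome node.
OUTCOME: str = "recovery"

#: Modeling timepoints for the analyte panel.
TIMEPOINTS: tuple[str, str] = ("pre_antivenom", "post_antivenom")


def panel_names() -> list[str]:
    """Return the 35 analyte labels of the Luminex 35-plex panel, fixed order."""
    return list(LUMINEX_35)
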