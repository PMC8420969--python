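"""Default antibody panel: cell subsets, signalling readouts, stimuli, and the
knowledge-based penalization mask.

The panel describes 34 manually-gated immune cell subsets covering the major
innate and adaptive compartments of cord blood, 11 intracellular signalling
readouts (10 phospho-epitopes plus total IkB), and three stimulation
conditions (LPS, IFNa, and an IL-2/IL-4/IL-6 cocktail) alongside the
unstimulated control.

Gating convention: every event is a singlet live leukocyte; all subsets
except granulocytes additionally fall inside the mononuclear gate.
Frequencies are therefore expressed as percent of mononuclear cells for all
subsets except granulocytes, which are expressed as percent of leukocytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

UNSTIM = "unstim"
STIMULI = ("LPS", "IFNa", "IL")
CONDITIONS = (UNSTIM,) + STIMULI

PROTEINS = (
    "pSTAT1",
    "pSTAT3",
    "pSTAT5",
    "pSTAT6",
    "pCREB",
    "pMAPKAPK2",
    "pERK12",
    "pS6",
    "pP38",
    "pNFkB",
    "IkB",
)

#: 34 disjoint gated subsets.  Granulocytes sit outside the mononuclear gate.
SUBSETS = (
    "granulocytes",
    "cMC",
    "intMC",
    "ncMC",
    "mDC",
    "pDC",
    "dnDC",
    "basophils",
    "HSPC",
    "NK_CD56dimCD16pos",
    "NK_CD56brightCD16neg",
    "NK_CD56dimCD16neg",
    "ILC",
    "B_naive",
    "B_memory",
    "B_transitional",
    "plasmablasts",
    "CD4_naive",
    "CD4_TCM",
    "CD4_TEM",
    "CD4_TEMRA",
    "CD8_naive",
    "CD8_TCM",
    "CD8_TEM",
    "CD8_TEMRA",
    "Treg",
    "CD4_CD161pos",
    "CD8_CD161pos",
    "NKT_like",
    "gd_T",
    "dn_T",
    "CD4_HLADRpos",
    "CD8_HLADRpos",
    "Tfh_like",
)

#: Myeloid / antigen-presenting subsets with canonical TLR4 (LPS) machinery.
MYELOID_SUBSETS = (
    "granulocytes",
    "cMC",
    "intMC",
    "ncMC",
    "mDC",
    "pDC",
    "dnDC",
    "basophils",
)

#: T-lymphocyte subsets (includes unconventional/innate-like T cells).
T_CELL_SUBSETS = (
    "CD4_naive",
    "CD4_TCM",
    "CD4_TEM",
    "CD4_TEMRA",
    "CD8_naive",
    "CD8_TCM",
    "CD8_TEM",
    "CD8_TEMRA",
    "Treg",
    "CD4_CD161pos",
    "CD8_CD161pos",
    "NKT_like",
    "gd_T",
    "dn_T",
    "CD4_HLADRpos",
    "CD8_HLADRpos",
    "Tfh_like",
)

CD4_T_SUBSETS = (
    "CD4_naive",
    "CD4_TCM",
    "CD4_TEM",
    "CD4_TEMRA",
    "Treg",
    "CD4_CD161pos",
    "CD4_HLADRpos",
    "Tfh_like",
)

#: Cytotoxic lymphocyte subsets (type-I-interferon responsive).
CYTOTOXIC_SUBSETS = (
    "CD8_TCM",
    "CD8_TEM",
    "CD8_TEMRA",
    "NKT_like",
    "NK_CD56dimCD16pos",
    "NK_CD56brightCD16neg",
)


@dataclass(frozen=True)
class Panel:
    """Immutable description of the assay panel.

    Parameters
    ----------
    subsets : tuple of str
        Gated cell-subset labels (disjoint; one label per event).
    proteins : tuple of str
        Intracellular signalling readouts.
    stimuli : tuple of str
        Stimulation conditions (the unstimulated control is implicit).
    non_mononuclear : tuple of str
        Subsets gated outside the mononuclear gate (frequency denominator
        is then total leukocytes).
    """

    subsets: tuple = SUBSETS
    proteins: tuple = PROTEINS
    stimuli: tuple = STIMULI
    non_mononuclear: tuple = ("granulocytes",)

    def is_mononuclear(self, subset: str) -> bool:
        return subset not in self.non_mononuclear

    def validate_subset(self, subset: str) -> None:
        if subset not in self.subsets:
            from .errors import ConfigMismatchError

            raise ConfigMismatchError(f"unknown subset {subset!r}")

    def validate_protein(self, protein: str) -> None:
        if protein not in self.proteins:
            from .errors import ConfigMismatchError

            raise ConfigMismatchError(f"unknown protein {protein!r}")


DEFAULT_PANEL = Panel()

# ---------------------------------------------------------------------------
# Knowledge-based penalization mask
# ---------------------------------------------------------------------------

#: Proteins downstream of TLR4 engagement (MAP-kinase / NFkB axis).
_LPS_PROTEINS = ("pMAPKAPK2", "pP38", "pERK12", "pNFkB", "pS6", "pCREB", "IkB")
#: JAK/STAT readouts downstream of the type-I interferon receptor.
_IFNA_PROTEINS = ("pSTAT1", "pSTAT3", "pSTAT5", "pSTAT6")
#: Readouts downstream of common-gamma-chain / gp130 cytokines (IL-2/4/6).
_IL_PROTEINS = ("pSTAT3", "pSTAT5", "pSTAT6", "pS6")


def default_penalization_mask(panel: Panel = DEFAULT_PANEL) -> dict:
    """Return the default mechanistic penalization mask.

    Maps ``(subset, protein, stimulus)`` to a boolean *allowed* flag.
    Response features are admissible only for mechanistically plausible
    receptor/pathway combinations: MAP-kinase/NFkB readouts after LPS in
    myeloid (TLR4-bearing) subsets, STAT readouts after IFNa in all subsets,
    and STAT3/5/6 plus pS6 after the interleukin cocktail in all subsets.
    The mask is a function of the panel alone — never of any sample value.
    """
    mask = {}
    for subset in panel.subsets:
        for protein in panel.proteins:
            mask[(subset, protein, "LPS")] = (
                subset in MYELOID_SUBSETS and protein in _LPS_PROTEINS
            )
            mask[(subset, protein, "IFNa")] = protein in _IFNA_PROTEINS
            mask[(subset, protein, "IL")] = protein in _IL_PROTEINS
    return mask
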