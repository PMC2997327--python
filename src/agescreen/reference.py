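"""Published reference tables used for bookkeeping checks and worked examples.

Two small plain-text constants from the original cross-model screen:

* the top-ranked genes shared by both experimental groups, with their
  per-group up/down occurrence counts (the combined score is *recomputed*
  from the per-direction counts, never read from here); and
* the five-category chronological-lifespan classification of the 93
  deletion strains assayed in the yeast screen.

These are inputs to worked examples and consistency checks; no analysis
result is copied from them.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "top_shared_occurrences",
    "screen_category_lists",
    "STUDY_GROUP_SIZES",
    "STUDY_CONTROL_ARRAYS",
    "STUDY_PROBE_UNIVERSE",
    "STUDY_BACKGROUND_RATES",
]

# Comparisons per experimental group and baseline arrays in the study design
STUDY_GROUP_SIZES = {"EG1": 17, "EG2": 18}
# Control/baseline arrays per cell model (HUVEC, PFF, RPTEC, PrSC, CD8, MSC)
STUDY_CONTROL_ARRAYS = {
    "HUVEC": 6,
    "PFF": 8,
    "RPTEC": 4,
    "PrSC": 10,
    "CD8": 15,
    "MSC": 4,
}
# Probe sets on the whole-genome array (the enrichment universe)
STUDY_PROBE_UNIVERSE = 54_675
# Estimated per-comparison DE probabilities reported for the two groups
STUDY_BACKGROUND_RATES = {"EG1": 0.11, "EG2": 0.12}

# Per-direction occurrence counts of the top genes common to both groups:
# (gene, EG1 up, EG1 down, EG2 up, EG2 down)
_TOP_SHARED = [
    ("KIAA0101", 7, 7, 6, 7),
    ("APOBEC3G", 0, 10, 8, 8),
    ("MEST", 4, 5, 8, 8),
    ("RRM2", 7, 5, 4, 9),
    ("SYDE2", 7, 5, 5, 8),
    ("TXNIP", 2, 9, 7, 7),
    ("BHLHB2", 5, 6, 10, 3),
    ("BICD1", 10, 3, 7, 4),
    ("CYP51A1", 10, 1, 10, 3),
    ("HMGCS1", 9, 3, 9, 3),
    ("SKP2", 5, 9, 3, 7),
    ("SLC1A4", 6, 1, 11, 6),
    ("TCF8", 6, 6, 6, 6),
    ("C20orf129", 11, 1, 7, 4),
    ("CD302", 7, 4, 6, 6),
    ("IFI44L", 3, 7, 8, 5),
    ("PDGFD", 5, 4, 6, 8),
    ("RUNX1", 2, 9, 9, 3),
    ("TCEA3", 2, 8, 4, 9),
    ("TSPAN2", 4, 6, 7, 6),
]


def top_shared_occurrences() -> pd.DataFrame:
    """Per-direction occurrence counts of the top shared genes.

    Columns: gene, eg1_up, eg1_down, eg2_up, eg2_down.  Combined scores are
    deliberately absent — compute them as the sum of the four counts.
    """
    return pd.DataFrame(
        _TOP_SHARED, columns=["gene", "eg1_up", "eg1_down", "eg2_up", "eg2_down"]
    )


# Five-band chronological-lifespan classification of the screened deletion
# strains (gene names of the deleted ORFs).
_SCREEN_CATEGORIES = {
    "strongly_reduced": (
        "KGD1", "SOD2", "RPL31A", "NCR1", "LYS9", "SHM1", "GCN5", "HAP3",
        "PIM1", "PRY1", "ATG18", "CYC1", "RPL13B", "MSW1", "RAD27", "YDC1",
        "TIF3",
    ),
    "slightly_reduced": (
        "CLB1", "CLB2", "APM1", "SYM1", "IDP2", "GSY2", "ALT2", "SIZ1",
        "TIF1", "TIF2", "NPL3", "PTC5", "RNR3", "ERG24", "MRT4", "MSH6",
        "NUP170", "HAT1", "INP53", "SSO1", "TWF1", "SGT2", "LHS1", "RPL37A",
        "ARF1", "DHP5", "CHL1", "TRX1", "UBC8", "CHD1", "SPE2", "HRT3",
        "MRE11", "MSH2", "DBP1", "SSN3", "SSF1",
    ),
    "not_affected": (
        "HTA2", "AIP1", "HXK1", "SER1", "YPK2", "UBC11", "ENO1", "RPL22B",
        "RPL43B", "PEX13", "REV3", "SYG1", "MSH5", "ERP6", "TPK1", "PER1",
        "URA2", "SLH1", "CHK1", "ALD5", "CAF40",
    ),
    "slightly_increased": (
        "MAD2", "PCH2", "YTA7", "PHO89", "UGA1", "DIE2", "CAF17", "HMT1",
        "ALG5", "SSA3", "LSB6",
    ),
    "strongly_increased": (
        "CYS4", "DNF1", "ALD4", "PDX3", "RNH201", "UBC12", "PRS3",
    ),
}


def screen_category_lists() -> dict[str, tuple[str, ...]]:
    """Gene lists of the published lifespan screen, keyed by category."""
    return {k: tuple(v) for k, v in _SCREEN_CATEGORIES.items()}
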