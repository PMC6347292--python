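"""Published benchmark measurements for the tebipenem pivoxil–β-CD system.

These transcribed literature tables serve as desk-scale inputs for end-to-end
checks of the analysis chain: observed first-order rate constants per storage
condition (for the Arrhenius regression), reported activation parameters,
bidirectional Caco-2 Papp values, and the broth-dilution MIC table for 20
bacterial strains under free drug vs inclusion complex.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

#: (temperature K, kobs s^-1) ladders per (formulation, condition).
#: Conditions: "RH76" = humid (RH ~76%), "RH0" = dry air.
ARRHENIUS_LADDERS: Dict[Tuple[str, str], Tuple[Tuple[float, float], ...]] = {
    ("TP", "RH76"): ((303.0, 3.94e-6), (313.0, 4.80e-6), (323.0, 5.38e-6), (333.0, 6.12e-6)),
    ("TP-bCD", "RH76"): ((303.0, 3.69e-6), (313.0, 4.22e-6), (323.0, 4.67e-6), (333.0, 5.22e-6)),
    ("TP", "RH0"): ((333.0, 7.64e-6), (343.0, 8.39e-6), (353.0, 9.42e-6), (363.0, 1.09e-5)),
    ("TP-bCD", "RH0"): ((333.0, 6.80e-6), (343.0, 7.32e-6), (353.0, 7.98e-6), (363.0, 8.85e-6)),
}

#: Reported activation parameters per (formulation, condition):
#: Ea (kJ/mol), dH (kJ/mol), dS "as printed" (J/K/mol).
REPORTED_ACTIVATION: Dict[Tuple[str, str], Dict[str, float]] = {
    ("TP", "RH76"): {"ea_kJ": 12.07, "dH_kJ": 9.59, "dS": -244.91},
    ("TP-bCD", "RH76"): {"ea_kJ": 9.59, "dH_kJ": 7.11, "dS": -244.92},
    ("TP", "RH0"): {"ea_kJ": 11.84, "dH_kJ": 9.36, "dS": -244.91},
    ("TP-bCD", "RH0"): {"ea_kJ": 8.79, "dH_kJ": 6.31, "dS": -244.92},
}

#: Reported Papp (cm/s) and efflux ratio per compound.
PAPP_TABLE: Dict[str, Dict[str, float]] = {
    "TP": {"papp_ab": 40.22e-6, "papp_ba": 75.14e-6, "efflux_ratio": 1.87},
    "TP-bCD": {"papp_ab": 5.28e-6, "papp_ba": 8.96e-6, "efflux_ratio": 1.70},
}

#: Wide-format MIC table (mg/L): organism, strain label, Gram group,
#: MIC of free drug, MIC of the inclusion complex, and whether the source
#: flagged the strain as having a reduced MIC under the complex.
MIC_TABLE: List[dict] = [
    {"organism": "Salmonella typhimurium", "strain": "clinical", "gram": "negative",
     "mic_free": 125, "mic_complex": 125, "flagged_reduced": False},
    {"organism": "Salmonella typhimurium", "strain": "ATCC 14028", "gram": "negative",
     "mic_free": 125, "mic_complex": 125, "flagged_reduced": False},
    {"organism": "Listeria monocytogenes", "strain": "clinical", "gram": "positive",
     "mic_free": 125, "mic_complex": 125, "flagged_reduced": False},
    {"organism": "Listeria monocytogenes", "strain": "ATCC 7644", "gram": "positive",
     "mic_free": 125, "mic_complex": 125, "flagged_reduced": False},
    {"organism": "Staphylococcus aureus", "strain": "clinical", "gram": "positive",
     "mic_free": 31, "mic_complex": 15, "flagged_reduced": True},
    {"organism": "Staphylococcus aureus", "strain": "ATCC 25923", "gram": "positive",
     "mic_free": 15, "mic_complex": 4, "flagged_reduced": True},
    {"organism": "Klebsiella pneumoniae", "strain": "clinical", "gram": "negative",
     "mic_free": 125, "mic_complex": 125, "flagged_reduced": False},
    {"organism": "Klebsiella pneumoniae", "strain": "ATCC 31488", "gram": "negative",
     "mic_free": 31, "mic_complex": 31, "flagged_reduced": False},
    {"organism": "Pseudomonas aeruginosa", "strain": "clinical", "gram": "negative",
     "mic_free": 250, "mic_complex": 125, "flagged_reduced": True},
    {"organism": "Pseudomonas aeruginosa", "strain": "ATCC 27853", "gram": "negative",
     "mic_free": 250, "mic_complex": 125, "flagged_reduced": True},
    {"organism": "Proteus mirabilis", "strain": "clinical", "gram": "negative",
     "mic_free": 125, "mic_complex": 62, "flagged_reduced": True},
    {"organism": "Proteus mirabilis", "strain": "ATCC 12453", "gram": "negative",
     "mic_free": 31, "mic_complex": 15, "flagged_reduced": True},
    {"organism": "Enterobacter aerogenes", "strain": "clinical", "gram": "negative",
     "mic_free": 250, "mic_complex": 250, "flagged_reduced": False},
    {"organism": "Enterobacter aerogenes", "strain": "ATCC 13048", "gram": "negative",
     "mic_free": 62, "mic_complex": 62, "flagged_reduced": False},
    {"organism": "Enterobacter hormaechei", "strain": "clinical", "gram": "negative",
     "mic_free": 125, "mic_complex": 125, "flagged_reduced": False},
    {"organism": "Enterobacter hormaechei", "strain": "ATCC 700323", "gram": "negative",
     "mic_free": 125, "mic_complex": 125, "flagged_reduced": False},
    {"organism": "Enterococcus faecalis", "strain": "clinical", "gram": "positive",
     "mic_free": 250, "mic_complex": 125, "flagged_reduced": True},
    {"organism": "Enterococcus faecalis", "strain": "ATCC 29212", "gram": "positive",
     "mic_free": 250, "mic_complex": 125, "flagged_reduced": True},
    {"organism": "Alcaligenes faecalis", "strain": "clinical", "gram": "negative",
     "mic_free": 125, "mic_complex": 125, "flagged_reduced": False},
    {"organism": "Alcaligenes faecalis", "strain": "ATCC 29212", "gram": "negative",
     "mic_free": 125, "mic_complex": 125, "flagged_reduced": False},
]

#: Reported f1/f2 comparisons of complex vs free drug per dissolution medium.
REPORTED_F1_F2: Dict[str, Tuple[float, float]] = {
    "pH 1.2": (25.43, 45.09),
    "pH 7.2": (90.62, 21.39),
}
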