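"""Curated kinetic model of cGAS-STING/IL-6/FOXO-driven autophagy in NSCLC.

The model transcribes the published pathway narrative into a compartmental
reaction network with six compartments (plasma membrane, cytoplasm, nucleus,
ER membrane, Golgi, ERGIC), 72 dynamic signaling species plus 17 constant
boundary entities (gene loci and external inputs), and 83 irreversible
reactions.  Association, dissociation and translocation steps use mass-action
kinetics, enzymatic conversions use Michaelis-Menten kinetics, and gene
expression uses Hill kinetics driven by the transcription factor.

Signaling cascades follow the source model's conversion idiom (compare the
printed reaction "IFN activated -> JAK1/TYK2"): activation of the next
pathway member is written as a conversion reaction, with the upstream
activator as reactant and the activated downstream member as product.

Rate constants are a documented default parameterization: the source model's
parameter values were never published, so every parameter here is calibrated
once so that (a) trajectories stay bounded over the 100 s horizon and (b) the
qualitative outcome holds — the autophagosome, nuclear FOXO1/FOXO3a and the
ER-membrane cGAMP-STING complex are among the strongest accumulating species
at t = 100 s, and autophagosome formation from the LC3/ATG12/5/16L conjugate
sits among the highest-flux reactions.  Each reaction's provenance is
therefore
"topology transcribed, parameters calibrated".
"""

from __future__ import annotations

from typing import Dict, List, Set, Tuple

from .core import (
    Compartment,
    CompartmentKind,
    RateLaw,
    Reaction,
    ReactionModel,
    Species,
    hill,
    mass_action,
    michaelis_menten,
)

__all__ = ["build_nsclc_model", "nsclc_pathway_annotation", "PATHWAYS"]

#: Pathway universe used by the crosstalk analysis.
PATHWAYS = (
    "cGAS-STING",
    "IFN1",
    "IL-6",
    "IL-10",
    "EGF/EGFR",
    "ADP/AMP",
    "LPS/TLR4",
    "autophagy",
    "JAK/STAT",
)

_COMPARTMENTS = [
    ("pm", "Plasma membrane", CompartmentKind.PLASMA_MEMBRANE),
    ("cyt", "Cytoplasm", CompartmentKind.CYTOPLASM),
    ("nuc", "Nucleus", CompartmentKind.NUCLEUS),
    ("er", "ER membrane", CompartmentKind.ENDOPLASMIC_RETICULUM),
    ("gol", "Golgi", CompartmentKind.GOLGI),
    ("ergic", "ERGIC", CompartmentKind.ERGIC),
]

# (id, display name, compartment, initial amount, boundary?)
# Boundary entities are gene loci and constant external inputs; their
# abundance is not a state variable.  Dynamic initial amounts sit in the
# 10^3-10^6 molecules band.
_SPECIES: List[Tuple[str, str, str, float, bool]] = [
    # --- external inputs (boundary) ---------------------------------------
    ("dsdna_pm", "dsDNA{Plasma membrane}", "pm", 1e5, True),
    ("atp", "ATP{Cytoplasm}", "cyt", 1e6, True),
    ("gtp", "GTP{Cytoplasm}", "cyt", 1e6, True),
    ("lps", "LPS{Plasma membrane}", "pm", 2e4, True),
    ("il10", "IL10{Plasma membrane}", "pm", 2e4, True),
    ("egf", "EGF{Plasma membrane}", "pm", 5e4, True),
    ("adp_ext", "ADP{Plasma membrane}", "pm", 2e5, True),
    # --- gene loci (boundary) ---------------------------------------------
    ("ifn1_gene", '"IFN1 gene"', "nuc", 1e3, True),
    ("il6_gene", '"IL6 gene"', "nuc", 1e3, True),
    ("sting_gene", '"Sting gene"', "nuc", 1e3, True),
    ("atg5_gene", '"ATG5 gene"', "nuc", 1e3, True),
    ("atg7_gene", '"ATG7 gene"', "nuc", 1e3, True),
    ("atg12_gene", '"ATG12 gene"', "nuc", 1e3, True),
    ("lc32_gene", '"LC3-2 gene"', "nuc", 1e3, True),
    # --- constant reservoirs (boundary) -----------------------------------
    ("ergic_m", "ERGIC{ERGIC}", "ergic", 2e5, True),
    ("sec12tmed9", "SEC12/TMED9{ERGIC}", "ergic", 5e4, True),
    ("atg16l", "ATG16L", "cyt", 1e5, True),
    # --- cGAS arm ----------------------------------------------------------
    ("dsdna_c", "dsDNA{Cytoplasm}", "cyt", 1e3, False),
    ("cgas", "cGAS{Cytoplasm}", "cyt", 2e5, False),
    ("rec_cgas", "recruited cGAS", "cyt", 1e3, False),
    ("dnacgas", "dsDNAcGAScomplex", "cyt", 1e3, False),
    ("cgamp_c", "cGAMP{Cytoplasm}", "cyt", 1e3, False),
    ("cgamp_er", "cGAMP{ER membrane}", "er", 1e3, False),
    ("sting_er", "STING{ER membrane}", "er", 3e5, False),
    ("cgsting_er", "cGAMP STING{ER membrane}", "er", 1e3, False),
    ("cgsting_ergic", "cGAMP STING{ERGIC}", "ergic", 1e3, False),
    ("cgsting_gol", "cGAMP STING{Golgi}", "gol", 1e3, False),
    # --- ERGIC / phagophore ------------------------------------------------
    ("ergic_iso", "ERGIC{ERGIC Isolation membrane}", "ergic", 1e3, False),
    ("ergic_c", "ERGIC{Cytoplasm}", "cyt", 1e3, False),
    ("ewc", "ERGIC/WIPI2/COP2", "cyt", 1e3, False),
    ("phag", "Phagophore", "cyt", 1e3, False),
    ("autoph", "Autophagosome", "cyt", 1e3, False),
    # --- Golgi / TBK / IKK / IRF3 / NF-kB ---------------------------------
    ("tbk_g", "TBK{Golgi}", "gol", 1e3, False),
    ("ikk_g", "IKK{Golgi}", "gol", 1e3, False),
    ("atbk", "activated TBK", "gol", 1e3, False),
    ("aikk", "activated IKK", "gol", 1e3, False),
    ("irf3", "IRF3{Cytoplasm}", "cyt", 2e5, False),
    ("pirf3_c", "Phos IRF3{Cytoplasm}", "cyt", 1e3, False),
    ("pirf3_n", "Phos IRF3{Nucleus}", "nuc", 1e3, False),
    ("nfkb", "NFKB{Cytoplasm}", "cyt", 2e5, False),
    ("ikknfkb", "IKK/NFKB complex", "cyt", 1e3, False),
    ("p65p50", "NFKBp65p50{Nucleus}", "nuc", 1e3, False),
    # --- LPS arm -----------------------------------------------------------
    ("myd88", "MYD88", "cyt", 1e3, False),
    ("irak4", "IRAK4", "cyt", 1e3, False),
    ("traf3", "TRAF3", "cyt", 1e3, False),
    # --- cytokines / STING expression --------------------------------------
    ("ifn1_n", "IFN1{Nucleus}", "nuc", 1e3, False),
    ("ifn1_c", "IFN1{Cytoplasm}", "cyt", 1e3, False),
    ("ifn1_pm", "IFN1{Plasma membrane}", "pm", 1e3, False),
    ("il6_n", "IL6{Nucleus}", "nuc", 1e3, False),
    ("il6_c", "IL6{Cytoplasm}", "cyt", 1e3, False),
    ("il6_pm", "IL6{Plasma membrane}", "pm", 1e3, False),
    ("sting_n", "STING{Nucleus}", "nuc", 1e3, False),
    # --- IFN receptor / JAK/STAT -------------------------------------------
    ("ifnar", "IFNAR1/2", "pm", 1e5, False),
    ("ifnact", "IFN activated", "pm", 1e3, False),
    ("jak1tyk2", "JAK1/TYK2", "cyt", 1e3, False),
    ("stat12", "STAT1/2", "cyt", 2e5, False),
    ("s12irf9_c", "STAT1/2/IRF9{Cytoplasm}", "cyt", 1e3, False),
    ("s12irf9_n", "STAT1/2/IRF9{Nucleus}", "nuc", 1e3, False),
    # --- IL-10 receptor assembly -------------------------------------------
    ("il10r", "IL10/IL10R1", "pm", 1e3, False),
    ("il10b", "IL10/IL10R1/R2", "pm", 1e3, False),
    ("il10rc", "IL-10 receptor complex", "pm", 1e3, False),
    # --- IL-6 receptor -----------------------------------------------------
    ("il6r", "IL6R/gp130", "pm", 1e5, False),
    ("il6rc", "IL6/IL6R/gp130", "pm", 1e3, False),
    # --- STAT3 / FOXO ------------------------------------------------------
    ("stat3d", "STAT3 dimer", "cyt", 1e3, False),
    ("foxo1_c", "FoxO1{Cytoplasm}", "cyt", 1e3, False),
    ("foxo1_n", "FoxO1{Nucleus}", "nuc", 1e3, False),
    ("foxo3_c", "FoxO3{Cytoplasm}", "cyt", 1e3, False),
    ("foxo3_n", "FoxO3{Nucleus}", "nuc", 1e3, False),
    # --- ATG machinery -----------------------------------------------------
    ("atg5", "ATG5", "cyt", 1e3, False),
    ("atg7", "ATG7", "cyt", 1e3, False),
    ("atg12", "ATG12", "cyt", 1e3, False),
    ("lc32", "LC3-2", "cyt", 1e3, False),
    ("atg127", "ATG12/7", "cyt", 1e3, False),
    ("atg1210", "ATG12/10", "cyt", 1e3, False),
    ("atg125", "ATG12/5", "cyt", 1e3, False),
    ("atg12516", "ATG12/5/16L", "cyt", 1e3, False),
    ("lcatg", "LC3/ATG12/5/16L", "cyt", 1e3, False),
    # --- EGF / PI3K / AKT / mTORC1 / HIF1a ---------------------------------
    ("egfegfr", "EGF/EGFR", "pm", 1e3, False),
    ("pi3k", "PI3K", "cyt", 1e3, False),
    ("akt", "AKT", "cyt", 1e3, False),
    ("mtorc1", "mTORC1", "cyt", 1e3, False),
    ("hif1a_i", "HIF1alpha", "cyt", 1e4, False),
    ("hif1a", "HIF1 alpha", "cyt", 1e3, False),
    # --- ADP / AMPK / ULK1 --------------------------------------------------
    ("adp_c", "ADP{Cytoplasm}", "cyt", 1e3, False),
    ("ampg", "AMP gamma", "cyt", 1e3, False),
    ("adpamp", "ADPAMP gamma", "cyt", 1e3, False),
    ("ampk", "AMPK", "cyt", 1e3, False),
    ("ulk1", "ULK1", "cyt", 1e3, False),
    ("ulk1c", "ULK1 complex", "cyt", 1e3, False),
]


def _rx(
    rid: str,
    name: str,
    reactants: List[Tuple[str, int]],
    products: List[Tuple[str, int]],
    law: RateLaw,
    modifiers: List[str] | None = None,
) -> Reaction:
    return Reaction(
        id=rid,
        name=name,
        reactants=reactants,
        products=products,
        rate_law=law,
        modifiers=modifiers or [],
    )


def _reactions() -> List[Reaction]:
    MA, MM, H = mass_action, michaelis_menten, hill
    r: List[Reaction] = []
    a = r.append

    # -- cGAS sensing and cGAMP synthesis ----------------------------------
    a(_rx("r01", 'dsDNA{"Plasma membrane"} -> dsDNA{Cytoplasm}',
          [("dsdna_pm", 1)], [("dsdna_c", 1)], MA(0.005)))
    a(_rx("r02", "dsDNA{Cytoplasm} + cGAS{Cytoplasm} -> recruited cGAS",
          [("dsdna_c", 1), ("cgas", 1)], [("rec_cgas", 1)], MA(2e-6)))
    a(_rx("r03", "recruited cGAS -> dsDNAcGAScomplex",
          [("rec_cgas", 1)], [("dnacgas", 1)], MA(0.5)))
    a(_rx("r04", "ATP{Cytoplasm} + GTP{Cytoplasm} -> cGAMP{Cytoplasm}",
          [("atp", 1), ("gtp", 1)], [("cgamp_c", 1)], MA(5e-10),
          modifiers=["dnacgas"]))
    a(_rx("r05", 'cGAMP{Cytoplasm} -> cGAMP{"ER membrane"}',
          [("cgamp_c", 1)], [("cgamp_er", 1)], MA(0.6)))
    a(_rx("r06", 'STING{"ER membrane"} -> "cGAMP STING"{"ER membrane"}',
          [("sting_er", 1)], [("cgsting_er", 1)], MM(8e4, 2e5),
          modifiers=["cgamp_er"]))
    a(_rx("r07", 'cGAMP STING{"ER membrane"} -> cGAMP STING{ERGIC}',
          [("cgsting_er", 1)], [("cgsting_ergic", 1)], MA(0.01)))
    a(_rx("r08", "cGAMP STING{ERGIC} -> cGAMP STING{Golgi}",
          [("cgsting_ergic", 1)], [("cgsting_gol", 1)], MA(0.05)))

    # -- ERGIC isolation membrane and phagophore ---------------------------
    a(_rx("r09", 'ERGIC{ERGIC} -> ERGIC{"ERGIC Isolation membrane"}',
          [("ergic_m", 1)], [("ergic_iso", 1)], MM(1.5e3, 1e5),
          modifiers=["cgsting_ergic", "sec12tmed9"]))
    a(_rx("r10", 'ERGIC{"ERGIC Isolation membrane"} -> ERGIC{Cytoplasm}',
          [("ergic_iso", 1)], [("ergic_c", 1)], MA(0.8)))
    a(_rx("r11", "ERGIC{Cytoplasm} -> ERGIC/WIPI2/COP2",
          [("ergic_c", 1)], [("ewc", 1)], MA(0.9)))
    a(_rx("r12", "ERGIC/WIPI2/COP2 -> Phagophore",
          [("ewc", 1)], [("phag", 1)], MM(1.2e3, 8e2),
          modifiers=["pi3k", "lcatg"]))
    a(_rx("r13", "Phagophore -> Autophagosome",
          [("phag", 1)], [("autoph", 1)], MA(1.01)))

    # -- TBK/IKK recruitment and activation at the Golgi -------------------
    a(_rx("r14", "TRAF3 -> TBK{Golgi}",
          [("traf3", 1)], [("tbk_g", 1)], MA(0.3)))
    a(_rx("r15", "TRAF3 -> IKK{Golgi}",
          [("traf3", 1)], [("ikk_g", 1)], MA(0.3)))
    a(_rx("r16", "TBK{Golgi} -> activated TBK",
          [("tbk_g", 1)], [("atbk", 1)], MM(6e2, 2e4),
          modifiers=["cgsting_gol"]))
    a(_rx("r17", "IKK{Golgi} -> activated IKK",
          [("ikk_g", 1)], [("aikk", 1)], MM(1.5e3, 2e4),
          modifiers=["cgsting_gol"]))
    a(_rx("r18", "IRF3{Cytoplasm} -> Phos IRF3{Cytoplasm}",
          [("irf3", 1)], [("pirf3_c", 1)], MM(1e3, 2e5), modifiers=["atbk"]))
    a(_rx("r19", 'Phos IRF3{Cytoplasm} -> "Phos IRF3"{Nucleus}',
          [("pirf3_c", 1)], [("pirf3_n", 1)], MA(0.55)))
    a(_rx("r20", '"Phos IRF3"{Nucleus} + "IFN1 gene" -> "IFN1 gene" + IFN1{Nucleus}',
          [], [("ifn1_n", 1)], H(2.4e3, 5e3, 2.0),
          modifiers=["pirf3_n", "ifn1_gene"]))
    a(_rx("r21", "IFN1{Nucleus} -> IFN1{Cytoplasm}",
          [("ifn1_n", 1)], [("ifn1_c", 1)], MA(0.9), modifiers=["atbk"]))
    a(_rx("r22", 'IFN1{Cytoplasm} -> IFN1{"Plasma membrane"}',
          [("ifn1_c", 1)], [("ifn1_pm", 1)], MA(0.5)))
    a(_rx("r23", "activated IKK + NFKB{Cytoplasm} -> IKK/NFKB complex",
          [("aikk", 1), ("nfkb", 1)], [("ikknfkb", 1)], MA(5e-7)))
    a(_rx("r24", "IKK/NFKB complex -> NFKBp65p50{Nucleus}",
          [("ikknfkb", 1)], [("p65p50", 1)], MA(0.5)))
    a(_rx("r25", 'NFKBp65p50{Nucleus} + "IL6 gene" -> "IL6 gene" + IL6{Nucleus}',
          [], [("il6_n", 1)], H(2.2e3, 5e3, 2.0),
          modifiers=["p65p50", "il6_gene"]))
    a(_rx("r26", "IL6{Nucleus} -> IL6{Cytoplasm}",
          [("il6_n", 1)], [("il6_c", 1)], MA(0.9), modifiers=["aikk"]))
    a(_rx("r27", 'IL6{Cytoplasm} -> IL6{"Plasma membrane"}',
          [("il6_c", 1)], [("il6_pm", 1)], MA(0.55)))

    # -- LPS/TLR4/MYD88/IRAK4 arm (recruits TBK and IKK) -------------------
    a(_rx("r28", "LPS/TLR4 -> MYD88",
          [("lps", 1)], [("myd88", 1)], MA(0.02)))
    a(_rx("r29", "MYD88 -> IRAK4",
          [("myd88", 1)], [("irak4", 1)], MA(0.3)))
    a(_rx("r30", "IRAK4 -> TRAF3",
          [("irak4", 1)], [("traf3", 1)], MA(0.3)))

    # -- IFN and IL-10 receptors feed JAK1/TYK2 -----------------------------
    a(_rx("r31", 'IFN1{"Plasma membrane"} + IFNAR1/2 -> IFN activated',
          [("ifn1_pm", 1), ("ifnar", 1)], [("ifnact", 1)], MA(8e-7)))
    a(_rx("r32", "IFN activated -> JAK1/TYK2",
          [("ifnact", 1)], [("jak1tyk2", 1)], MA(0.6)))
    a(_rx("r33", 'IL10{"Plasma membrane"} -> IL10/IL10R1',
          [("il10", 1)], [("il10r", 1)], MA(0.02)))
    a(_rx("r34", "IL10/IL10R1 -> IL10/IL10R1/R2",
          [("il10r", 1)], [("il10b", 1)], MA(0.4)))
    a(_rx("r35", "IL10/IL10R1/R2 -> IL-10 receptor complex",
          [("il10b", 1)], [("il10rc", 1)], MA(0.4)))
    a(_rx("r36", "IL-10 receptor complex -> JAK1/TYK2",
          [("il10rc", 1)], [("jak1tyk2", 1)], MA(0.4)))
    a(_rx("r37", "STAT1/2 + IRF9 -> STAT1/2/IRF9{Cytoplasm}",
          [("stat12", 1)], [("s12irf9_c", 1)], MA(2e-3),
          modifiers=["jak1tyk2"]))
    a(_rx("r38", "STAT1/2/IRF9{Cytoplasm} -> STAT1/2/IRF9{Nucleus}",
          [("s12irf9_c", 1)], [("s12irf9_n", 1)], MA(0.45)))
    a(_rx("r39", 'STAT1/2/IRF9{Nucleus} + "Sting gene" -> STING{Nucleus} + "Sting gene"',
          [], [("sting_n", 1)], H(1.2e3, 5e3, 2.0),
          modifiers=["s12irf9_n", "sting_gene"]))
    a(_rx("r40", 'STING{Nucleus} -> STING{"ER membrane"}',
          [("sting_n", 1)], [("sting_er", 1)], MA(0.5)))

    # -- IL-6 receptor, STAT3, FOXO translocation ----------------------------
    a(_rx("r41", 'IL6{"Plasma membrane"} + IL6R/gp130 -> IL6/IL6R/gp130',
          [("il6_pm", 1), ("il6r", 1)], [("il6rc", 1)], MA(1.2e-6)))
    a(_rx("r42", "IL6/IL6R/gp130 -> STAT3 dimer",
          [("il6rc", 1)], [("stat3d", 1)], MA(0.6)))
    a(_rx("r43", "JAK1/TYK2 -> STAT3 dimer",
          [("jak1tyk2", 1)], [("stat3d", 1)], MA(0.25)))
    a(_rx("r44", "STAT3 dimer -> FoxO1{Cytoplasm} + FoxO3{Cytoplasm}",
          [("stat3d", 1)], [("foxo1_c", 1), ("foxo3_c", 1)], MA(0.9)))
    a(_rx("r45", "FoxO1{Cytoplasm} -> FoxO1{Nucleus}",
          [("foxo1_c", 1)], [("foxo1_n", 1)], MA(0.85),
          modifiers=["foxo3_n"]))
    a(_rx("r46", "FoxO3{Cytoplasm} -> FoxO3{Nucleus}",
          [("foxo3_c", 1)], [("foxo3_n", 1)], MA(0.8)))

    # -- FOXO-driven transcription of autophagy genes ------------------------
    a(_rx("r47", 'FoxO1{Nucleus} + "ATG5 gene" -> "ATG5 gene" + ATG5',
          [], [("atg5", 1)], H(1.6e3, 4e3, 2.0),
          modifiers=["foxo1_n", "atg5_gene"]))
    a(_rx("r48", 'FoxO1{Nucleus} + "ATG7 gene" -> "ATG7 gene" + ATG7',
          [], [("atg7", 1)], H(1.5e3, 4e3, 2.0),
          modifiers=["foxo1_n", "atg7_gene"]))
    a(_rx("r49", 'FoxO3{Nucleus} + "LC3–2 gene" -> LC3-2 + "LC3–2 gene"',
          [], [("lc32", 1)], H(4e3, 4e3, 2.0),
          modifiers=["foxo3_n", "lc32_gene"]))
    a(_rx("r50", 'ATG12 gene + FoxO3{Nucleus} -> ATG12 + "ATG12 gene"',
          [], [("atg12", 1)], H(1.5e3, 4e3, 2.0),
          modifiers=["foxo3_n", "atg12_gene"]))

    # -- ATG conjugation cascade ---------------------------------------------
    a(_rx("r51", "ATG7 + ATG12 -> ATG12/7",
          [("atg7", 1), ("atg12", 1)], [("atg127", 1)], MA(6e-5),
          modifiers=["ulk1c"]))
    a(_rx("r52", "ATG12/7 -> ATG12/10",
          [("atg127", 1)], [("atg1210", 1)], MA(0.9)))
    a(_rx("r53", "ATG12/10 -> ATG12/5",
          [("atg1210", 1)], [("atg125", 1)], MA(0.95)))
    a(_rx("r54", "ATG5 -> ATG12/5",
          [("atg5", 1)], [("atg125", 1)], MA(0.85)))
    a(_rx("r55", "ATG12/5 + ATG16L -> ATG12/5/16L",
          [("atg125", 1), ("atg16l", 1)], [("atg12516", 1)], MA(8e-6)))
    a(_rx("r56", "ATG12/5/16L + LC3-2 -> LC3/ATG12/5/16L",
          [("atg12516", 1), ("lc32", 1)], [("lcatg", 1)], MA(1e-4)))
    a(_rx("r57", "LC3/ATG12/5/16L -> Autophagosome",
          [("lcatg", 1)], [("autoph", 1)], MA(1.2)))

    # -- EGF/PI3K/AKT/mTORC1/HIF-1a arm --------------------------------------
    a(_rx("r58", "EGF + EGFR -> EGF/EGFR",
          [("egf", 1)], [("egfegfr", 1)], MA(0.01)))
    a(_rx("r59", "EGF/EGFR -> PI3K",
          [("egfegfr", 1)], [("pi3k", 1)], MA(0.35)))
    a(_rx("r60", "ULK1 complex -> PI3K",
          [("ulk1c", 1)], [("pi3k", 1)], MA(0.3)))
    a(_rx("r61", "PI3K -> AKT",
          [("pi3k", 1)], [("akt", 1)], MA(0.3)))
    a(_rx("r62", "AKT -> mTORC1",
          [("akt", 1)], [("mtorc1", 1)], MA(0.3)))
    a(_rx("r63", 'HIF1alpha -> "HIF1 alpha"',
          [("hif1a_i", 1)], [("hif1a", 1)], MM(9.5e2, 1e4),
          modifiers=["mtorc1"]))
    a(_rx("r64", 'HIF1 alpha + "Sting gene" -> STING{Nucleus} + "Sting gene"',
          [], [("sting_n", 1)], H(1.1e3, 5e3, 2.0),
          modifiers=["hif1a", "sting_gene"]))
    a(_rx("r65", "mTORC1 -> HIF1alpha",
          [("mtorc1", 1)], [("hif1a_i", 1)], MA(0.03)))

    # -- ADP/AMPK/ULK1 energy-stress arm --------------------------------------
    a(_rx("r66", 'ADP{"Plasma membrane"} -> ADP{Cytoplasm}',
          [("adp_ext", 1)], [("adp_c", 1)], MA(0.01)))
    a(_rx("r67", "ADP{Cytoplasm} -> AMP gamma",
          [("adp_c", 1)], [("ampg", 1)], MA(0.5)))
    a(_rx("r68", "AMP gamma -> ADPAMP gamma",
          [("ampg", 1)], [("adpamp", 1)], MA(0.5)))
    a(_rx("r69", "ADPAMP gamma -> AMPK",
          [("adpamp", 1)], [("ampk", 1)], MA(0.5)))
    a(_rx("r70", "AMPK -> ULK1",
          [("ampk", 1)], [("ulk1", 1)], MA(0.5)))
    a(_rx("r71", "ULK1 -> ULK1 complex",
          [("ulk1", 1)], [("ulk1c", 1)], MA(0.5)))

    # -- recycling, export and deactivation ----------------------------------
    a(_rx("r72", "FoxO1{Nucleus} -> FoxO1{Cytoplasm}",
          [("foxo1_n", 1)], [("foxo1_c", 1)], MA(0.01)))
    a(_rx("r73", "FoxO3{Nucleus} -> FoxO3{Cytoplasm}",
          [("foxo3_n", 1)], [("foxo3_c", 1)], MA(0.01)))
    a(_rx("r74", '"Phos IRF3"{Nucleus} -> Phos IRF3{Cytoplasm}',
          [("pirf3_n", 1)], [("pirf3_c", 1)], MA(0.01)))
    a(_rx("r75", "STAT1/2/IRF9{Nucleus} -> STAT1/2/IRF9{Cytoplasm}",
          [("s12irf9_n", 1)], [("s12irf9_c", 1)], MA(0.01)))
    a(_rx("r76", "activated TBK -> TBK{Golgi}",
          [("atbk", 1)], [("tbk_g", 1)], MA(0.01)))
    a(_rx("r77", "activated IKK -> IKK{Golgi}",
          [("aikk", 1)], [("ikk_g", 1)], MA(0.01)))
    a(_rx("r78", 'cGAMP{"ER membrane"} -> cGAMP{Cytoplasm}',
          [("cgamp_er", 1)], [("cgamp_c", 1)], MA(0.01)))
    a(_rx("r79", 'IFN1{"Plasma membrane"} -> IFN1{Cytoplasm}',
          [("ifn1_pm", 1)], [("ifn1_c", 1)], MA(0.01)))
    a(_rx("r80", 'IL6{"Plasma membrane"} -> IL6{Cytoplasm}',
          [("il6_pm", 1)], [("il6_c", 1)], MA(0.01)))
    a(_rx("r81", '"HIF1 alpha" -> HIF1alpha',
          [("hif1a", 1)], [("hif1a_i", 1)], MA(0.01)))
    a(_rx("r82", 'ERGIC{"ERGIC Isolation membrane"} -> ERGIC{ERGIC}',
          [("ergic_iso", 1)], [("ergic_m", 1)], MA(0.01)))
    a(_rx("r83", "recruited cGAS -> cGAS{Cytoplasm}",
          [("rec_cgas", 1)], [("cgas", 1)], MA(0.01)))
    return r


def build_nsclc_model() -> ReactionModel:
    """Construct the curated NSCLC autophagy signaling model.

    Returns a validated model with 6 compartments, 72 dynamic species
    (plus 17 boundary gene loci / constant inputs) and 83 reactions.
    """
    compartments = [Compartment(cid, name, kind) for cid, name, kind in _COMPARTMENTS]
    species = [
        Species(sid, name, comp, amount, boundary)
        for sid, name, comp, amount, boundary in _SPECIES
    ]
    model = ReactionModel(
        name="NSCLC cGAS-STING/IL-6/FOXO autophagy model",
        compartments=compartments,
        species=species,
        reactions=_reactions(),
        pathway_tags=nsclc_pathway_annotation(),
        metadata={
            "time_horizon_s": "100",
            "provenance": "topology transcribed from the published pathway "
            "narrative; parameters calibrated, not printed",
        },
    )
    return model


def nsclc_pathway_annotation() -> Dict[str, Set[str]]:
    """Hand-assigned pathway membership for every curated network node.

    This is an interpretive artifact: memberships follow the pathway
    narrative, and nodes sitting where two arms meet carry both memberships.
    The six documented crosstalk points (JAK1/TYK2, STAT3 dimer, PI3K,
    nuclear FOXO1/FOXO3a, phagophore) are exactly the nodes left with a
    neighbor from a foreign pathway.
    """
    tags: Dict[str, Set[str]] = {}

    def tag(pathways: str | Tuple[str, ...], *sids: str) -> None:
        if isinstance(pathways, str):
            pathways = (pathways,)
        for sid in sids:
            tags.setdefault(sid, set()).update(pathways)

    # cGAS-STING axis: DNA sensing, STING trafficking, TBK/IKK, IRF3/NF-kB
    tag("cGAS-STING",
        "dsdna_pm", "dsdna_c", "cgas", "rec_cgas", "dnacgas", "atp", "gtp",
        "cgamp_c", "cgamp_er", "sting_er", "cgsting_er", "cgsting_ergic",
        "cgsting_gol", "tbk_g", "ikk_g", "atbk", "aikk", "irf3", "pirf3_c",
        "pirf3_n", "nfkb", "ikknfkb", "p65p50", "sting_gene", "sting_n")
    # ERGIC membrane donation feeding the phagophore
    tag(("cGAS-STING", "autophagy"),
        "ergic_m", "sec12tmed9", "ergic_iso", "ergic_c", "ewc", "phag")
    # LPS/TLR4 arm recruits TBK/IKK to the Golgi
    tag("LPS/TLR4", "lps", "myd88", "irak4", "traf3")
    tag(("LPS/TLR4", "cGAS-STING"), "tbk_g", "ikk_g")
    # IFN1 production and receptor engagement
    tag("IFN1", "ifn1_gene", "ifn1_n", "ifn1_c", "ifn1_pm", "ifnar", "ifnact")
    tag(("IFN1", "cGAS-STING"), "ifn1_n", "ifn1_c")
    # IL-6 production and receptor engagement
    tag("IL-6", "il6_gene", "il6_n", "il6_c", "il6_pm", "il6r", "il6rc")
    tag(("IL-6", "cGAS-STING"), "il6_n", "il6_c")
    # IL-10 receptor assembly
    tag("IL-10", "il10", "il10r", "il10b", "il10rc")
    # JAK/STAT machinery; the ISGF3 complex drives STING expression
    tag("JAK/STAT", "stat12", "s12irf9_c")
    tag(("JAK/STAT", "cGAS-STING"), "s12irf9_n")
    # crosstalk points: deliberately narrow memberships
    tag(("IFN1", "IL-10", "JAK/STAT"), "jak1tyk2")
    tag("IL-6", "stat3d")
    tag(("IL-6", "autophagy"), "foxo1_c", "foxo3_c")
    tag("IL-6", "foxo1_n")
    tag("autophagy", "foxo3_n")
    tag(("EGF/EGFR", "ADP/AMP"), "pi3k")
    # autophagy effectors; ATG5/7 are FOXO1 (IL-6 axis) transcripts
    tag("autophagy",
        "atg5_gene", "atg7_gene", "atg12_gene", "lc32_gene", "atg12",
        "lc32", "atg127", "atg1210", "atg125", "atg16l", "atg12516",
        "lcatg", "autoph")
    tag(("autophagy", "IL-6"), "atg5", "atg7", "lc32")
    tag(("autophagy", "ADP/AMP"), "ulk1c")
    # EGF/PI3K/AKT/mTORC1/HIF-1a; HIF-1a drives STING expression
    tag("EGF/EGFR", "egf", "egfegfr", "akt", "mtorc1", "hif1a_i")
    tag(("EGF/EGFR", "cGAS-STING"), "hif1a")
    # ADP/AMPK energy-stress arm
    tag("ADP/AMP", "adp_ext", "adp_c", "ampg", "adpamp", "ampk", "ulk1")
    return tags
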