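"""Rank a differential for one IHC panel against a tiny in-memory knowledge base.

A lung nodule in a patient with a breast-cancer history and a thyroid
nodule: the differential is primary lung adenocarcinoma vs metastatic
breast carcinoma vs metastatic papillary thyroid carcinoma. The first-round
panel (CK7, CK20, TTF-1, GCDFP-15, galectin-3, napsin A) comes back
CK7+/TTF-1+/galectin-3+/napsin A+ and CK20-/GCDFP-15-.
"""

from ihcbayes import (
    AntibodyRecord,
    AntibodyRegistry,
    CasePanel,
    DiseaseEntity,
    KnowledgeBase,
    PositivityEntry,
    RankerConfig,
    rank_diagnoses,
)

registry = AntibodyRegistry([
    AntibodyRecord("CK7"), AntibodyRecord("CK20"),
    AntibodyRecord("TTF-1", synonyms=("NKX2-1",)),
    AntibodyRecord("GCDFP-15"), AntibodyRecord("Galectin-3"),
    AntibodyRecord("Napsin A"),
])

profiles = {
    "lung-adeno": {"CK7": 0.95, "CK20": 0.1, "TTF-1": 0.75, "GCDFP-15": 0.0,
                   "Galectin-3": 0.5, "Napsin A": 0.75},
    "breast-idc": {"CK7": 0.95, "CK20": 0.1, "TTF-1": 0.0, "GCDFP-15": 0.75,
                   "Galectin-3": 0.1, "Napsin A": 0.0},
    "thyroid-papillary": {"CK7": 0.95, "CK20": 0.0, "TTF-1": 0.95,
                          "GCDFP-15": 0.0, "Galectin-3": 0.95, "Napsin A": 0.1},
}

kb = KnowledgeBase(antibodies=registry)
for disease_id, prof in profiles.items():
    kb.diseases[disease_id] = DiseaseEntity(disease_id, disease_id,
                                            category="primary carcinoma")
    for ab, v in prof.items():
        kb.profiles[(disease_id, ab)] = PositivityEntry(v)

panel = CasePanel.from_mapping(
    {"CK7": "+", "CK20": "-", "ttf-1": "+", "GCDFP-15": "-",
     "galectin 3": "+", "Napsin A": "+"},
    registry,
)

for s in rank_diagnoses(kb, panel, RankerConfig(top_k=10)):
    print(f"{s.rank}. {s.disease_id:20s} posterior={s.posterior:6.3f} "
          f"concordance={s.concordance:5.1f}%")

print()
print("The posterior is each disease's share of the evidence (sums to 1);")
print("the concordance is its absolute per-marker fit as a percentage.")
print("Lung and thyroid both fit the panel; breast is effectively excluded")
print("by TTF-1+/napsin A+ with GCDFP-15-.")
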