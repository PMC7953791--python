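"""Shared fixtures: a tiny hand-written knowledge base and a brute-force
ranking oracle that forms every likelihood product directly, without logs."""

from __future__ import annotations

import numpy as np
import pytest

from ihcbayes import (
    AntibodyRecord,
    AntibodyRegistry,
    CasePanel,
    DiseaseEntity,
    KnowledgeBase,
    PositivityEntry,
    RankerConfig,
)


def make_kb(
    profiles: dict[str, dict[str, float]],
    *,
    registry: AntibodyRegistry | None = None,
    categories: dict[str, str] | None = None,
    equivalence: dict[str, str] | None = None,
) -> KnowledgeBase:
    """Build a KnowledgeBase from a plain disease -> {antibody: value} dict."""
    if registry is None:
        names = sorted({ab for prof in profiles.values() for ab in prof})
        registry = AntibodyRegistry([AntibodyRecord(n) for n in names])
    kb = KnowledgeBase(antibodies=registry)
    categories = categories or {}
    equivalence = equivalence or {}
    for disease_id, prof in profiles.items():
        kb.diseases[disease_id] = DiseaseEntity(
            disease_id=disease_id,
            display_name=disease_id,
            category=categories.get(disease_id, "primary carcinoma"),
            equivalence_group=equivalence.get(disease_id),
        )
        for ab, value in prof.items():
            kb.profiles[(disease_id, ab)] = PositivityEntry(value)
    return kb


def brute_force_rank(kb, panel: CasePanel, config: RankerConfig):
    """Independent oracle: direct products, no log space, no library ranker.

    Returns a list of (disease_id, likelihood, posterior, concordance,
    n_profiled) sorted by the same ordering contract as rank_diagnoses.
    """
    rows = []
    for disease_id in kb.diseases:
        profile = kb.profile_of(disease_id)
        product = 1.0
        n_profiled = 0
        n_factors = 0
        for ab, outcome in panel.results.items():
            p = profile.get(ab)
            if p is None:
                if config.missing_policy == "skip":
                    continue
                p = config.impute_value
            else:
                n_profiled += 1
            p = min(max(p, config.floor), 1.0 - config.floor)
            product *= p if outcome else 1.0 - p
            n_factors += 1
        if n_factors == 0:
            continue
        concordance = 100.0 * product ** (1.0 / n_factors)
        rows.append([disease_id, product, n_profiled, concordance])
    if isinstance(config.prior, str):
        weights = {d: prod for d, prod, _, _ in rows}
    else:
        weights = {d: prod * config.prior[d] for d, prod, _, _ in rows}
    total = sum(weights.values())
    scored = [
        (d, prod, weights[d] / total, conc, n_prof)
        for d, prod, n_prof, conc in rows
    ]
    keyfun = (
        (lambda r: (-r[2], -r[4], r[0]))
        if config.score_mode == "posterior"
        else (lambda r: (-r[3], -r[4], r[0]))
    )
    return sorted(scored, key=keyfun)[: config.top_k]


def random_small_kb(rng: np.random.Generator) -> tuple[KnowledgeBase, CasePanel]:
    """A random KB with <=6 diseases x <=6 markers plus a random panel."""
    n_d = int(rng.integers(1, 7))
    n_a = int(rng.integers(1, 7))
    markers = [f"M{i}" for i in range(n_a)]
    profiles = {}
    for d in range(n_d):
        chosen = [m for m in markers if rng.random() < 0.7]
        profiles[f"D{d}"] = {m: float(rng.choice([0, 0.1, 0.3, 0.5, 0.75, 0.95]))
                             for m in chosen}
    panel_markers = [m for m in markers if rng.random() < 0.8] or [markers[0]]
    panel = CasePanel({m: bool(rng.integers(2)) for m in panel_markers})
    return make_kb(profiles), panel


@pytest.fixture
def registry() -> AntibodyRegistry:
    return AntibodyRegistry([
        AntibodyRecord("TTF-1", synonyms=("NKX2-1",)),
        AntibodyRecord("CK7", synonyms=("Cytokeratin 7",)),
        AntibodyRecord("CK20"),
        AntibodyRecord("Napsin A"),
        AntibodyRecord("CDX2"),
        AntibodyRecord("EGFR", synonyms=("HER1",), prognostic_only=True),
        AntibodyRecord("p53", synonyms=("TP53",), prognostic_only=True),
    ])


@pytest.fixture
def toy_kb() -> KnowledgeBase:
    """Three diseases, three markers; likelihoods for panel A+,B-,C+ are
    D1: 0.9*0.2*0.1 = 0.018, D2: 0.5^3 = 0.125, D3: 0.9*0.9*0.9 = 0.729."""
    return make_kb({
        "D1": {"A": 0.9, "B": 0.8, "C": 0.1},
        "D2": {"A": 0.5, "B": 0.5, "C": 0.5},
        "D3": {"A": 0.9, "B": 0.1, "C": 0.9},
    })


@pytest.fixture
def toy_panel() -> CasePanel:
    return CasePanel({"A": True, "B": False, "C": True})
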