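"""Synthetic knowledge bases and labelled case sets.

The real curated database (thousands of neoplasms x hundreds of antibodies)
and the patient panels it was validated on are not redistributable, so this
module generates stand-ins with the same statistical structure: positivity
values restricted to the six-value curation vocabulary, a few markers per
disease that are highly specific (95% in the disease, <=10% elsewhere),
panels of 1-13 markers averaging 6.8 per case, and binary results sampled
from the profile with a configurable *atypicality rate* — the probability
that a result contradicts the curated profile, emulating the dominant
error source in real IHC archives.

Everything is deterministic under the spec's seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ArgumentError
from .evaluation import ValidationCase
from .kb import (
    CATEGORIES,
    AntibodyRecord,
    AntibodyRegistry,
    DiseaseEntity,
    KnowledgeBase,
    PositivityEntry,
    write_knowledge_base,
)

__all__ = [
    "VOCABULARY",
    "SyntheticSpec",
    "generate_knowledge_base",
    "generate_cases",
    "generate_fixture_bundle",
    "clone_disease",
    "spec_from_manifest",
]

#: The discrete positivity vocabulary profiles are drawn from.
VOCABULARY: tuple[float, ...] = (0.0, 0.10, 0.30, 0.50, 0.75, 0.95)

_ORGANS = (
    "lung", "liver", "kidney", "stomach", "large intestine and rectum",
    "breast", "soft tissue", "lymph node", "pancreas", "skin",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters; defaults mirror realistic archive statistics.

    ``panel_size_mean`` / ``panel_size_range`` follow the 6.8-marker average
    and 1-13 range of diagnostic panels in practice; ``atypicality_rate`` is
    the per-result probability of contradicting the profile.
    """

    n_diseases: int = 30
    n_antibodies: int = 80
    markers_per_disease: tuple[int, int] = (10, 18)
    specific_markers_per_disease: int = 2
    panel_size_mean: float = 6.8
    panel_size_range: tuple[int, int] = (1, 13)
    atypicality_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_diseases < 1 or self.n_antibodies < 1:
            raise ArgumentError("n_diseases and n_antibodies must be >= 1")
        if self.specific_markers_per_disease * self.n_diseases > self.n_antibodies:
            raise ArgumentError(
                "infeasible: more disease-specific markers "
                f"({self.specific_markers_per_disease} x {self.n_diseases}) "
                f"than antibodies ({self.n_antibodies})"
            )
        lo, hi = self.panel_size_range
        if not 1 <= lo <= hi <= self.n_antibodies:
            raise ArgumentError(
                f"panel_size_range {self.panel_size_range} must lie in [1, n_antibodies]"
            )
        if not 0.0 <= self.atypicality_rate <= 1.0:
            raise ArgumentError("atypicality_rate must be in [0, 1]")
        mlo, mhi = self.markers_per_disease
        if not self.specific_markers_per_disease <= mlo <= mhi <= self.n_antibodies:
            raise ArgumentError(
                f"markers_per_disease {self.markers_per_disease} infeasible"
            )


def _antibody_name(i: int) -> str:
    return f"AB{i + 1:03d}"


def _disease_id(i: int) -> str:
    return f"D{i + 1:03d}"


def generate_knowledge_base(spec: SyntheticSpec) -> KnowledgeBase:
    """Generate a profile table over the curation vocabulary.

    Each disease owns ``specific_markers_per_disease`` markers profiled at
    0.95 for it; every specific marker is profiled in every disease (as
    lineage markers are in real curation) at 0.10 or 0 outside its owner.
    The ``markers_per_disease`` range governs how many additional markers
    from the shared (non-specific) pool each disease profiles, drawn
    uniformly from the vocabulary.
    """
    rng = np.random.default_rng(spec.seed)
    antibodies = [
        AntibodyRecord(canonical_name=_antibody_name(i))
        for i in range(spec.n_antibodies)
    ]
    registry = AntibodyRegistry(antibodies)
    kb = KnowledgeBase(antibodies=registry)

    k = spec.specific_markers_per_disease
    # block-partition the first n_diseases*k antibodies as owned specifics
    owner_of: dict[str, int] = {}
    specific: dict[int, list[str]] = {}
    for d in range(spec.n_diseases):
        names = [_antibody_name(d * k + j) for j in range(k)]
        specific[d] = names
        for name in names:
            owner_of[name] = d

    all_names = [_antibody_name(i) for i in range(spec.n_antibodies)]
    # shared pool = antibodies that are nobody's specific marker
    shared = [n for n in all_names if n not in owner_of]
    mlo, mhi = spec.markers_per_disease
    for d in range(spec.n_diseases):
        disease_id = _disease_id(d)
        kb.diseases[disease_id] = DiseaseEntity(
            disease_id=disease_id,
            display_name=f"Synthetic neoplasm {d + 1}",
            organ=_ORGANS[d % len(_ORGANS)],
            category=CATEGORIES[d % len(CATEGORIES)],
        )
        # specific markers are universally profiled, as lineage markers are
        # in real curation: "always" (0.95) for the owner, "never" elsewhere
        for name, owner in owner_of.items():
            value = 0.95 if owner == d else 0.0
            kb.profiles[(disease_id, name)] = PositivityEntry(value)
        n_extra = min(int(rng.integers(mlo, mhi + 1)) - k, len(shared))
        if n_extra > 0:
            chosen = rng.choice(len(shared), size=n_extra, replace=False)
            for idx in sorted(int(c) for c in chosen):
                value = float(rng.choice(VOCABULARY))
                kb.profiles[(disease_id, shared[idx])] = PositivityEntry(value)
    # profile any antibody the draws left uncovered so QC sees no dead columns
    covered = {ab for (_, ab) in kb.profiles}
    for name in all_names:
        if name not in covered:
            d = int(rng.integers(spec.n_diseases))
            value = 0.10 if name in owner_of else float(rng.choice(VOCABULARY))
            kb.profiles[(_disease_id(d), name)] = PositivityEntry(value)
    return kb


def _panel_size(rng: np.random.Generator, spec: SyntheticSpec) -> int:
    """1 + Binomial(12, p) matched to the mean, clipped to the spec range."""
    p = (spec.panel_size_mean - 1.0) / 12.0
    size = 1 + int(rng.binomial(12, min(max(p, 0.0), 1.0)))
    lo, hi = spec.panel_size_range
    return min(max(size, lo), hi)


def generate_cases(
    kb: KnowledgeBase,
    n_cases: int,
    spec: SyntheticSpec,
) -> list[ValidationCase]:
    """Sample labelled cases from a knowledge base.

    Per case: a uniform true disease; a panel emulating how a pathologist
    works up a suspected entity — its specific (lineage) markers first
    (when size permits), then the graded shared markers it is profiled
    for, then other diseases' lineage markers, finally unprofiled
    antibodies (scored at chance); each result is Bernoulli(profile
    positivity, unclipped) and then flipped with probability
    ``atypicality_rate``.
    """
    if n_cases < 1:
        raise ArgumentError("n_cases must be >= 1")
    if spec.panel_size_range[0] > len(kb.antibodies.canonical_names()):
        raise ArgumentError("panel size range infeasible for this knowledge base")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, n_cases]))
    disease_ids = sorted(kb.diseases)
    all_names = kb.antibodies.canonical_names()
    # a marker is a lineage (specific) marker if it hits the top vocabulary
    # value in exactly one disease and stays at/below 0.10 everywhere else
    high_in: dict[str, list[str]] = {}
    for (d, ab), entry in kb.profiles.items():
        if entry.value >= VOCABULARY[-1]:
            high_in.setdefault(ab, []).append(d)
    lineage = {
        ab
        for ab, owners in high_in.items()
        if len(owners) >= 1
        and all(
            e.value <= 0.10
            for (d, a), e in kb.profiles.items()
            if a == ab and d not in owners
        )
    }
    cases: list[ValidationCase] = []
    for c in range(n_cases):
        disease_id = disease_ids[int(rng.integers(len(disease_ids)))]
        profile = kb.profile_of(disease_id)
        size = _panel_size(rng, spec)
        own_specific = sorted(
            ab for ab, v in profile.items() if v >= VOCABULARY[-1] and ab in lineage
        )
        shared = sorted(ab for ab in profile
                        if ab not in own_specific and ab not in lineage)
        other_lineage = sorted(ab for ab in profile
                               if ab in lineage and ab not in own_specific)
        unprofiled = sorted(ab for ab in all_names if ab not in profile)
        panel_markers: list[str] = own_specific[:size]
        rest = size - len(panel_markers)
        for pool in (shared, other_lineage, unprofiled):
            if rest <= 0 or not pool:
                continue
            take = min(rest, len(pool))
            picks = rng.choice(len(pool), size=take, replace=False)
            panel_markers += [pool[int(i)] for i in sorted(picks)]
            rest -= take
        results: dict[str, bool] = {}
        for ab in panel_markers:
            p = profile.get(ab, 0.5)
            res = bool(rng.random() < p)
            if rng.random() < spec.atypicality_rate:
                res = not res
            results[ab] = res
        entity = kb.diseases[disease_id]
        cases.append(ValidationCase(
            case_id=f"case-{c + 1:05d}",
            panel=results,
            true_disease_id=disease_id,
            category=entity.category,
            organ=entity.organ,
        ))
    return cases


def clone_disease(
    kb: KnowledgeBase,
    disease_id: str,
    new_id: str,
    *,
    equivalence_group: str | None = None,
) -> None:
    """Duplicate one disease's profile under a new id (overlap experiments)."""
    source = kb.diseases[disease_id]
    if equivalence_group is not None:
        kb.diseases[disease_id] = dataclasses.replace(
            source, equivalence_group=equivalence_group
        )
    kb.diseases[new_id] = DiseaseEntity(
        disease_id=new_id,
        display_name=source.display_name,
        organ=source.organ,
        category=source.category,
        equivalence_group=equivalence_group,
    )
    for ab, value in kb.profile_of(disease_id).items():
        kb.profiles[(new_id, ab)] = PositivityEntry(value)


_PROGNOSTIC = (
    AntibodyRecord("EGFR", synonyms=("HER1", "ERBB1"), prognostic_only=True),
    AntibodyRecord("p53", synonyms=("TP53",), prognostic_only=True),
)


def generate_fixture_bundle(destination: str | Path, spec: SyntheticSpec) -> Path:
    """Write a matched kb/registry/case bundle plus a JSON manifest.

    The registry gains a few synonym entries and the prognostic-only
    markers EGFR and p53, which are mixed into some case panels so the
    filtering step has something to strip. Returns the manifest path.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    kb = generate_knowledge_base(spec)
    cases = generate_cases(kb, n_cases=max(50, 2 * spec.n_diseases), spec=spec)

    # registry: generated antibodies (a few with synonyms) + prognostic markers
    records: list[AntibodyRecord] = []
    for i, rec in enumerate(kb.antibodies.records):
        syns = (f"anti {rec.canonical_name}",) if i % 7 == 0 else ()
        records.append(AntibodyRecord(rec.canonical_name, synonyms=syns))
    records.extend(_PROGNOSTIC)
    registry = AntibodyRegistry(records)
    kb.antibodies = registry

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 9151]))
    for case in cases:
        if rng.random() < 0.15:
            marker = _PROGNOSTIC[int(rng.integers(len(_PROGNOSTIC)))].canonical_name
            case.panel[marker] = bool(rng.integers(2))  # type: ignore[index]

    kb_path = dest / "kb.tsv"
    registry_path = dest / "registry.tsv"
    cases_path = dest / "cases.tsv"
    write_knowledge_base(kb, kb_path, rendering="numeric")

    reg_lines = ["canonical_name\tsynonyms\tprognostic_only"]
    for rec in records:
        reg_lines.append(
            f"{rec.canonical_name}\t{';'.join(rec.synonyms)}"
            f"\t{'true' if rec.prognostic_only else 'false'}"
        )
    registry_path.write_text("\n".join(reg_lines) + "\n", encoding="utf-8", newline="\n")

    marker_order = [r.canonical_name for r in records]
    case_lines = ["\t".join(["case_id", "true_disease_id", "category", "organ"] + marker_order)]
    for case in cases:
        cells = [case.case_id, case.true_disease_id, case.category, case.organ]
        for ab in marker_order:
            res = case.panel.get(ab)
            cells.append("" if res is None else ("+" if res else "-"))
        case_lines.append("\t".join(cells))
    cases_path.write_text("\n".join(case_lines) + "\n", encoding="utf-8", newline="\n")

    manifest = {
        "spec": dataclasses.asdict(spec),
        "files": {
            "knowledge_base": kb_path.name,
            "registry": registry_path.name,
            "cases": cases_path.name,
        },
    }
    manifest_path = dest / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n",
        encoding="utf-8", newline="\n",
    )
    return manifest_path


def spec_from_manifest(manifest_path: str | Path) -> SyntheticSpec:
    """Rebuild the generation spec recorded in a bundle manifest."""
    data = json.loads(Path(manifest_path).read_text(encoding="utf-8"))
    fields = dict(data["spec"])
    for key in ("markers_per_disease", "panel_size_range"):
        fields[key] = tuple(fields[key])
    return SyntheticSpec(**fields)
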