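"""Disease x antibody positivity knowledge base.

The knowledge base is a sparse table of positivity probabilities
``P(marker positive | disease)`` curated from reference literature, plus a
registry of antibody names with synonyms and a registry of disease entities
(organ, category, optional site-equivalence group).

Qualitative curation terms are encoded on a fixed six-value scale
(``always`` = 95% ... ``never`` = 0%); conflicting sources are merged by
arithmetic mean; values are rendered either numerically or as the five
display grades (``++`` down to ``--``) used in marker-profile tables.
"""

from __future__ import annotations

import difflib
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    ArgumentError,
    LoadError,
    RangeError,
    RegistryIntegrityError,
    UnknownAntibodyError,
    VocabularyError,
)

__all__ = [
    "TERM_ENCODING",
    "CATEGORIES",
    "GRADE_DISPLAY",
    "AntibodyRecord",
    "AntibodyRegistry",
    "DiseaseEntity",
    "PositivityEntry",
    "KnowledgeBase",
    "Finding",
    "encode_positivity_term",
    "decode_grade",
    "display_grade",
    "merge_source_values",
    "normalize_antibody_name",
    "resolve_antibody",
    "load_registry",
    "load_knowledge_base",
    "write_knowledge_base",
    "validate_knowledge_base",
]

#: Qualitative curation vocabulary -> positivity fraction.
TERM_ENCODING: dict[str, float] = {
    "always": 0.95,
    "often": 0.75,
    "in about a half of cases": 0.50,
    "half": 0.50,
    "seldom": 0.30,
    "rarely": 0.10,
    "occasionally": 0.10,
    "rarely/occasionally": 0.10,
    "never": 0.0,
}

#: Closed vocabulary of disease categories used in validation reports.
CATEGORIES: tuple[str, ...] = (
    "primary carcinoma",
    "metastatic carcinoma",
    "benign (normal) lesion",
    "benign mesenchymal tumour",
    "malignant mesenchymal tumour",
)

# Grade bins on the percent scale: [75,100], [50,75), [30,50), [10,30), [0,10).
_GRADE_BINS: tuple[tuple[float, str], ...] = (
    (75.0, "++"),
    (50.0, "+"),
    (30.0, "+/-"),
    (10.0, "-/+"),
    (0.0, "--"),
)

#: ASCII grade label -> typographic display form.
GRADE_DISPLAY: dict[str, str] = {
    "++": "++",
    "+": "+",
    "+/-": "+/−",
    "-/+": "−/+",
    "--": "–",
}

# Grade -> representative vocabulary value, used when decoding grade-rendered
# tables back to numbers (lossy by construction).
_GRADE_DECODE: dict[str, float] = {
    "++": 0.95,
    "+": 0.50,
    "+/-": 0.30,
    "-/+": 0.10,
    "--": 0.0,
}
_GRADE_DECODE.update({GRADE_DISPLAY[k]: v for k, v in _GRADE_DECODE.copy().items()})


def encode_positivity_term(term: str) -> float:
    """Encode a curation cell as a positivity fraction in [0, 1].

    Accepts the qualitative vocabulary (case-insensitive; ``rarely`` and
    ``occasionally`` are synonymous) or a numeric percentage such as
    ``"49%"`` or ``"49"``.
    """
    if not isinstance(term, str):
        raise VocabularyError(f"positivity term must be text, got {type(term).__name__}")
    raw = term.strip()
    key = re.sub(r"\s*/\s*", "/", raw.lower())
    key = re.sub(r"\s+", " ", key)
    if key in TERM_ENCODING:
        return TERM_ENCODING[key]
    numeric = key[:-1].strip() if key.endswith("%") else key
    try:
        pct = float(numeric)
    except ValueError:
        raise VocabularyError(
            f"unknown positivity term {raw!r}; expected one of "
            f"{sorted(set(TERM_ENCODING))} or a numeric percentage"
        ) from None
    if not 0.0 <= pct <= 100.0:
        raise RangeError(f"percentage {pct} outside [0, 100]")
    return pct / 100.0


def display_grade(value: float, *, unicode: bool = False) -> str:
    """Map a positivity fraction to its display grade.

    Percent bins are half-open with the top bin closed: [75,100] -> ``++``,
    [50,75) -> ``+``, [30,50) -> ``+/-``, [10,30) -> ``-/+``, [0,10) -> ``--``.
    ASCII labels are returned by default; ``unicode=True`` yields the
    typographic forms used in pretty output.
    """
    if not 0.0 <= value <= 1.0:
        raise RangeError(f"positivity {value} outside [0, 1]")
    pct = value * 100.0
    for lower, label in _GRADE_BINS:
        if pct >= lower:
            return GRADE_DISPLAY[label] if unicode else label
    return GRADE_DISPLAY["--"] if unicode else "--"  # pragma: no cover


def decode_grade(label: str) -> float:
    """Invert :func:`display_grade` onto a representative vocabulary value."""
    key = label.strip()
    if key not in _GRADE_DECODE:
        raise VocabularyError(f"unknown grade label {label!r}")
    return _GRADE_DECODE[key]


@dataclass(frozen=True)
class PositivityEntry:
    """One positivity value plus the source values it was averaged from."""

    value: float
    source_values: tuple[float, ...] = ()

    def __post_init__(self):
        if not 0.0 <= self.value <= 1.0:
            raise RangeError(f"positivity {self.value} outside [0, 1]")
        object.__setattr__(self, "source_values", tuple(self.source_values))


def merge_source_values(values: Sequence[float]) -> PositivityEntry:
    """Merge per-source positivity values by arithmetic mean.

    Conflicting sources are averaged without weighting; the inputs are kept
    in ``source_values`` for provenance.
    """
    if len(values) == 0:
        raise ArgumentError("cannot merge an empty list of source values")
    for v in values:
        if not 0.0 <= v <= 1.0:
            raise RangeError(f"source value {v} outside [0, 1]")
    return PositivityEntry(value=math.fsum(values) / len(values), source_values=tuple(values))


_SEPARATORS = re.compile(r"[-/\s]+")


def normalize_antibody_name(name: str) -> str:
    """Normalization key: lowercase, trimmed, separator-insensitive.

    Hyphen, slash, whitespace and the empty string are treated as equivalent
    separators, so ``TTF-1``, ``TTF 1`` and ``TTF1`` share one key.
    """
    return _SEPARATORS.sub("", name.strip().lower())


@dataclass(frozen=True)
class AntibodyRecord:
    canonical_name: str
    synonyms: tuple[str, ...] = ()
    prognostic_only: bool = False

    def __post_init__(self):
        if not self.canonical_name.strip():
            raise ArgumentError("canonical_name must be non-empty")
        object.__setattr__(self, "synonyms", tuple(self.synonyms))


class AntibodyRegistry:
    """Canonical-name resolution over a set of :class:`AntibodyRecord`.

    Construction is permissive: integrity defects (duplicate canonicals,
    synonym collisions, a canonical listed as another record's synonym) are
    collected and reported by :meth:`integrity_findings`; resolving a name
    whose key is ambiguous raises :class:`RegistryIntegrityError`.
    """

    def __init__(self, records: Iterable[AntibodyRecord]):
        self.records: tuple[AntibodyRecord, ...] = tuple(records)
        self._canonical: dict[str, str] = {}
        self._synonym: dict[str, str] = {}
        self._ambiguous: dict[str, set[str]] = {}
        self._findings: list[Finding] = []
        for rec in self.records:
            key = normalize_antibody_name(rec.canonical_name)
            if key in self._canonical and self._canonical[key] != rec.canonical_name:
                self._mark_ambiguous(key, self._canonical[key], rec.canonical_name,
                                     "duplicate-canonical")
            self._canonical.setdefault(key, rec.canonical_name)
        for rec in self.records:
            for syn in rec.synonyms:
                key = normalize_antibody_name(syn)
                if key in self._canonical and self._canonical[key] != rec.canonical_name:
                    self._mark_ambiguous(key, self._canonical[key], rec.canonical_name,
                                         "synonym-shadows-canonical")
                    continue
                if key in self._synonym and self._synonym[key] != rec.canonical_name:
                    self._mark_ambiguous(key, self._synonym[key], rec.canonical_name,
                                         "synonym-collision")
                    continue
                self._synonym.setdefault(key, rec.canonical_name)

    def _mark_ambiguous(self, key: str, first: str, second: str, kind: str) -> None:
        self._ambiguous.setdefault(key, set()).update({first, second})
        self._findings.append(Finding(
            kind=kind, subject=key,
            message=f"name key {key!r} maps to both {first!r} and {second!r}",
        ))

    def integrity_findings(self) -> list["Finding"]:
        return list(self._findings)

    def canonical_names(self) -> list[str]:
        return [rec.canonical_name for rec in self.records]

    def record(self, canonical_name: str) -> AntibodyRecord:
        for rec in self.records:
            if rec.canonical_name == canonical_name:
                return rec
        raise UnknownAntibodyError(canonical_name)

    def is_prognostic_only(self, name: str) -> bool:
        return self.record(self.resolve(name)).prognostic_only

    def resolve(self, name: str) -> str:
        """Resolve any alias to its canonical name (canonical names win)."""
        key = normalize_antibody_name(name)
        if key in self._ambiguous:
            raise RegistryIntegrityError(
                f"name {name!r} is ambiguous in the registry: "
                f"maps to {sorted(self._ambiguous[key])}"
            )
        if key in self._canonical:
            return self._canonical[key]
        if key in self._synonym:
            return self._synonym[key]
        pool = {**self._synonym, **self._canonical}
        near = difflib.get_close_matches(key, pool.keys(), n=3, cutoff=0.6)
        raise UnknownAntibodyError(name, candidates=[pool[k] for k in near])


def resolve_antibody(name: str, registry: AntibodyRegistry | Iterable[AntibodyRecord]) -> str:
    """Functional wrapper around :meth:`AntibodyRegistry.resolve`."""
    if not isinstance(registry, AntibodyRegistry):
        registry = AntibodyRegistry(registry)
    return registry.resolve(name)


@dataclass(frozen=True)
class DiseaseEntity:
    disease_id: str
    display_name: str
    organ: str = ""
    category: str = CATEGORIES[0]
    equivalence_group: str | None = None

    def __post_init__(self):
        if not self.disease_id.strip():
            raise ArgumentError("disease_id must be non-empty")
        if self.category not in CATEGORIES:
            raise ArgumentError(
                f"category {self.category!r} not in {list(CATEGORIES)}"
            )


@dataclass
class KnowledgeBase:
    """Sparse disease x antibody positivity store."""

    diseases: dict[str, DiseaseEntity] = field(default_factory=dict)
    antibodies: AntibodyRegistry = field(default_factory=lambda: AntibodyRegistry([]))
    profiles: dict[tuple[str, str], PositivityEntry] = field(default_factory=dict)

    def profile_of(self, disease_id: str) -> dict[str, float]:
        """Positivity map ``canonical antibody -> fraction`` for one disease."""
        if disease_id not in self.diseases:
            from .errors import UnknownDiseaseError

            raise UnknownDiseaseError(f"unknown disease {disease_id!r}")
        return {
            ab: entry.value
            for (d, ab), entry in self.profiles.items()
            if d == disease_id
        }

    def equivalence_members(self, disease_id: str) -> set[str]:
        """All disease ids sharing ``disease_id``'s equivalence group (incl. itself)."""
        ent = self.diseases.get(disease_id)
        if ent is None:
            from .errors import UnknownDiseaseError

            raise UnknownDiseaseError(f"unknown disease {disease_id!r}")
        if not ent.equivalence_group:
            return {disease_id}
        return {
            d.disease_id
            for d in self.diseases.values()
            if d.equivalence_group == ent.equivalence_group
        }


_META_COLUMNS = ["disease_id", "display_name", "organ", "category", "equivalence_group"]


def load_registry(source: str | Path) -> AntibodyRegistry:
    """Load an antibody registry from TSV or JSON.

    TSV columns: ``canonical_name``, ``synonyms`` (semicolon-separated),
    ``prognostic_only`` (true/false). JSON: list of objects with the same
    field names.
    """
    path = Path(source)
    if not path.exists():
        raise LoadError(f"registry file not found: {path}")
    records: list[AntibodyRecord] = []
    if path.suffix.lower() == ".json":
        try:
            data = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise LoadError(f"registry JSON malformed: {exc}") from exc
        for i, obj in enumerate(data):
            try:
                records.append(AntibodyRecord(
                    canonical_name=obj["canonical_name"],
                    synonyms=tuple(obj.get("synonyms", [])),
                    prognostic_only=bool(obj.get("prognostic_only", False)),
                ))
            except (KeyError, ArgumentError) as exc:
                raise LoadError(f"bad registry record: {exc}", row=i + 1) from exc
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        required = {"canonical_name"}
        if not required.issubset(df.columns):
            raise LoadError(
                f"registry header missing columns {sorted(required - set(df.columns))}"
            )
        for i, row in df.iterrows():
            syns = tuple(s.strip() for s in row.get("synonyms", "").split(";") if s.strip())
            flag = str(row.get("prognostic_only", "false")).strip().lower()
            if flag not in {"true", "false", ""}:
                raise LoadError(f"bad prognostic_only value {flag!r}",
                                row=int(i) + 2, column="prognostic_only")
            try:
                records.append(AntibodyRecord(
                    canonical_name=row["canonical_name"].strip(),
                    synonyms=syns,
                    prognostic_only=flag == "true",
                ))
            except ArgumentError as exc:
                raise LoadError(str(exc), row=int(i) + 2, column="canonical_name") from exc
    registry = AntibodyRegistry(records)
    bad = registry.integrity_findings()
    if bad:
        raise RegistryIntegrityError(
            "; ".join(f.message for f in bad)
        )
    return registry


def load_knowledge_base(
    profile_source: str | Path,
    registry_source: str | Path | AntibodyRegistry,
    *,
    rendering: str = "numeric",
) -> KnowledgeBase:
    """Load a wide-TSV profile table plus a registry into a :class:`KnowledgeBase`.

    Header: ``disease_id, display_name, organ, category, equivalence_group``
    followed by one column per antibody (resolved through the registry).
    Cells are numeric percentages, vocabulary terms, or blank (= missing).
    ``rendering="grade"`` parses grade labels instead (lossy decode).
    """
    if rendering not in {"numeric", "grade"}:
        raise ArgumentError(f"rendering must be 'numeric' or 'grade', got {rendering!r}")
    registry = (
        registry_source
        if isinstance(registry_source, AntibodyRegistry)
        else load_registry(registry_source)
    )
    path = Path(profile_source)
    if not path.exists():
        raise LoadError(f"profile file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[: len(_META_COLUMNS)]) != _META_COLUMNS:
        raise LoadError(
            f"profile header must start with {_META_COLUMNS}, "
            f"got {list(df.columns[:len(_META_COLUMNS)])}"
        )
    antibody_cols: dict[str, str] = {}
    for col in df.columns[len(_META_COLUMNS):]:
        try:
            antibody_cols[col] = registry.resolve(col)
        except UnknownAntibodyError as exc:
            raise LoadError(f"unresolvable antibody column: {exc}", column=col) from exc

    kb = KnowledgeBase(antibodies=registry)
    for i, row in df.iterrows():
        rownum = int(i) + 2  # 1-based, counting the header line
        disease_id = row["disease_id"].strip()
        if disease_id in kb.diseases:
            raise LoadError(f"duplicate disease_id {disease_id!r}", row=rownum,
                            column="disease_id")
        try:
            entity = DiseaseEntity(
                disease_id=disease_id,
                display_name=row["display_name"].strip() or disease_id,
                organ=row["organ"].strip(),
                category=row["category"].strip(),
                equivalence_group=row["equivalence_group"].strip() or None,
            )
        except ArgumentError as exc:
            raise LoadError(str(exc), row=rownum) from exc
        kb.diseases[disease_id] = entity
        for col, canonical in antibody_cols.items():
            cell = row[col].strip()
            if not cell:
                continue
            try:
                value = (
                    encode_positivity_term(cell)
                    if rendering == "numeric"
                    else decode_grade(cell)
                )
            except (VocabularyError, RangeError) as exc:
                raise LoadError(f"bad cell {cell!r}: {exc}", row=rownum, column=col) from exc
            kb.profiles[(disease_id, canonical)] = PositivityEntry(value)
    return kb


def write_knowledge_base(
    kb: KnowledgeBase,
    destination: str | Path,
    *,
    rendering: str = "numeric",
) -> None:
    """Write the wide-TSV profile table; numeric rendering round-trips to 1e-9."""
    if rendering not in {"numeric", "grade"}:
        raise ArgumentError(f"rendering must be 'numeric' or 'grade', got {rendering!r}")
    path = Path(destination)
    antibody_order = [
        ab for ab in kb.antibodies.canonical_names()
        if any(key[1] == ab for key in kb.profiles)
    ]
    lines = ["\t".join(_META_COLUMNS + antibody_order)]
    for disease_id in kb.diseases:
        ent = kb.diseases[disease_id]
        cells = [ent.disease_id, ent.display_name, ent.organ, ent.category,
                 ent.equivalence_group or ""]
        for ab in antibody_order:
            entry = kb.profiles.get((disease_id, ab))
            if entry is None:
                cells.append("")
            elif rendering == "numeric":
                cells.append(format(entry.value * 100.0, ".10g"))
            else:
                cells.append(display_grade(entry.value))
        lines.append("\t".join(cells))
    try:
        path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    except OSError as exc:
        raise LoadError(f"cannot write {path}: {exc}") from exc


@dataclass(frozen=True)
class Finding:
    """One QC finding; ``kind`` is machine-readable, ``message`` is for humans."""

    kind: str
    subject: str
    message: str


def validate_knowledge_base(kb: KnowledgeBase) -> list[Finding]:
    """QC a knowledge base; returns findings, never raises on content issues.

    Checks: out-of-range values, orphan profile keys, diseases with no
    profiled antibody, antibodies profiled nowhere, registry collisions,
    and stored values inconsistent with their source-value mean.
    """
    findings: list[Finding] = list(kb.antibodies.integrity_findings())
    canonical = set(kb.antibodies.canonical_names())
    profiled_diseases: set[str] = set()
    profiled_antibodies: set[str] = set()
    for (disease_id, ab), entry in kb.profiles.items():
        profiled_diseases.add(disease_id)
        profiled_antibodies.add(ab)
        if disease_id not in kb.diseases:
            findings.append(Finding("orphan-profile-key", f"{disease_id}/{ab}",
                                    f"profile references unknown disease {disease_id!r}"))
        if ab not in canonical:
            findings.append(Finding("orphan-profile-key", f"{disease_id}/{ab}",
                                    f"profile references unknown antibody {ab!r}"))
        if not 0.0 <= entry.value <= 1.0:  # defensive: constructor should forbid
            findings.append(Finding("out-of-range", f"{disease_id}/{ab}",
                                    f"value {entry.value} outside [0, 1]"))
        if entry.source_values:
            mean = math.fsum(entry.source_values) / len(entry.source_values)
            if abs(mean - entry.value) > 1e-12:
                findings.append(Finding("mean-mismatch", f"{disease_id}/{ab}",
                                        f"value {entry.value} != mean of sources {mean}"))
    for disease_id in kb.diseases:
        if disease_id not in profiled_diseases:
            findings.append(Finding("empty-profile", disease_id,
                                    f"disease {disease_id!r} has no profiled antibody"))
    for ab in canonical:
        if ab not in profiled_antibodies and not kb.antibodies.record(ab).prognostic_only:
            # prognostic-only markers are expected to carry no origin profile
            findings.append(Finding("unused-antibody", ab,
                                    f"antibody {ab!r} is profiled in no disease"))
    return findings
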