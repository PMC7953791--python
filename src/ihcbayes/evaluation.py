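"""Validation harness: case filtering, top-k hit rates, chi-square comparison.

A labelled case is a *hit* when its ground-truth diagnosis (or any disease
sharing its site-equivalence group, e.g. the same stromal tumour recorded
for stomach and small intestine) appears in the top-k differential.
Cases are pre-filtered the way a pathology archive would be curated:
prognostic-only markers (EGFR, p53, ...) are stripped, and cases with
inconclusive results, no diagnostic marker, or fewer than three retained
antibodies are excluded with machine-readable reasons.

Hit rates between two datasets are compared with an uncorrected Pearson
chi-square test on the 2x2 accurate/error table.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import chi2_contingency

from .errors import (
    ArgumentError,
    DegenerateTableError,
    LoadError,
    UnknownDiseaseError,
)
from .kb import AntibodyRegistry, KnowledgeBase
from .ranker import CasePanel, DiagnosisScore, RankerConfig, parse_result_token, rank_diagnoses

__all__ = [
    "ValidationCase",
    "CategoryCounts",
    "HitRateReport",
    "ChiSquareResult",
    "load_cases",
    "filter_cases",
    "is_hit",
    "evaluate_dataset",
    "pearson_chi_square",
    "compare_error_rates",
    "split_dataset",
]

log = logging.getLogger(__name__)

#: Machine-readable exclusion reasons.
REASON_INCONCLUSIVE = "inconclusive-result"
REASON_TOO_FEW = "fewer-than-3-antibodies"
REASON_NO_DIAGNOSTIC = "no-diagnostic-markers"

_MIN_PANEL = 3

_CASE_META = ["case_id", "true_disease_id", "category", "organ"]


@dataclass
class ValidationCase:
    """A labelled case: a raw panel plus its ground-truth diagnosis.

    ``panel`` maps canonical antibody name to True/False, or None for an
    inconclusive result (excluded by :func:`filter_cases`).
    """

    case_id: str
    panel: Mapping[str, bool | None]
    true_disease_id: str
    category: str = ""
    organ: str = ""


def load_cases(source: str | Path, registry: AntibodyRegistry) -> list[ValidationCase]:
    """Load labelled cases from CSV/TSV in wide or long dialect.

    Wide: columns ``case_id, true_disease_id, category, organ`` then one
    column per antibody with +/- cells (blank = untested). Long: the same
    meta columns plus ``antibody`` and ``result``, one marker per row.
    Unparseable result tokens are kept as None so filtering can exclude
    the case with a recorded reason; structural problems raise LoadError.
    """
    path = Path(source)
    if not path.exists():
        raise LoadError(f"case file not found: {path}")
    delim = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        if not set(_CASE_META) <= set(header):
            raise LoadError(f"case file header must include {_CASE_META}, got {header}")
        rows = list(reader)
    long_form = {"antibody", "result"} <= set(header)
    cases: dict[str, ValidationCase] = {}
    if long_form:
        for i, row in enumerate(rows):
            cid = row["case_id"].strip()
            canonical = registry.resolve(row["antibody"].strip())
            case = cases.setdefault(cid, ValidationCase(
                case_id=cid, panel={},
                true_disease_id=row["true_disease_id"].strip(),
                category=row["category"].strip(), organ=row["organ"].strip(),
            ))
            if canonical in case.panel:
                raise LoadError(f"duplicate marker {canonical!r} for case {cid!r}",
                                row=i + 2, column="antibody")
            case.panel[canonical] = parse_result_token(row["result"])
    else:
        marker_cols = [c for c in header if c not in _CASE_META]
        resolved = {c: registry.resolve(c) for c in marker_cols}
        for i, row in enumerate(rows):
            cid = row["case_id"].strip()
            if cid in cases:
                raise LoadError(f"duplicate case_id {cid!r}", row=i + 2, column="case_id")
            panel: dict[str, bool | None] = {}
            for col in marker_cols:
                cell = (row[col] or "").strip()
                if not cell:
                    continue
                panel[resolved[col]] = parse_result_token(cell)
            cases[cid] = ValidationCase(
                case_id=cid, panel=panel,
                true_disease_id=row["true_disease_id"].strip(),
                category=row["category"].strip(), organ=row["organ"].strip(),
            )
    return list(cases.values())


def filter_cases(
    cases: Sequence[ValidationCase],
    registry: AntibodyRegistry,
) -> tuple[list[ValidationCase], list[tuple[str, str]]]:
    """Apply the validation-protocol case filters.

    Per case: strip prognostic-only markers; exclude on any inconclusive
    result, on zero remaining diagnostic markers, or on fewer than three
    remaining antibodies. Returns (retained cases with stripped panels,
    list of (case_id, reason)).
    """
    retained: list[ValidationCase] = []
    excluded: list[tuple[str, str]] = []
    for case in cases:
        if any(v is None for v in case.panel.values()):
            excluded.append((case.case_id, REASON_INCONCLUSIVE))
            continue
        stripped = {
            ab: bool(res)
            for ab, res in case.panel.items()
            if not registry.is_prognostic_only(ab)
        }
        if not stripped:
            excluded.append((case.case_id, REASON_NO_DIAGNOSTIC))
            continue
        if len(stripped) < _MIN_PANEL:
            excluded.append((case.case_id, REASON_TOO_FEW))
            continue
        retained.append(ValidationCase(
            case_id=case.case_id, panel=stripped,
            true_disease_id=case.true_disease_id,
            category=case.category, organ=case.organ,
        ))
    return retained, excluded


def is_hit(
    true_disease_id: str,
    ranked: Sequence[DiagnosisScore],
    kb: KnowledgeBase,
    k: int,
) -> bool:
    """True iff the truth (or a site-equivalent disease) is in the top k."""
    if k < 1:
        raise ArgumentError(f"k must be >= 1, got {k}")
    accepted = kb.equivalence_members(true_disease_id)
    return any(s.disease_id in accepted for s in ranked[:k])


@dataclass(frozen=True)
class CategoryCounts:
    n_cases: int
    n_accurate: int

    def __post_init__(self):
        if self.n_accurate > self.n_cases or min(self.n_cases, self.n_accurate) < 0:
            raise ArgumentError(
                f"inconsistent counts: {self.n_accurate} accurate of {self.n_cases}"
            )

    @property
    def n_error(self) -> int:
        return self.n_cases - self.n_accurate

    @property
    def hit_rate_pct(self) -> float:
        return 100.0 * self.n_accurate / self.n_cases if self.n_cases else float("nan")

    @property
    def error_rate_pct(self) -> float:
        return 100.0 * self.n_error / self.n_cases if self.n_cases else float("nan")


@dataclass
class HitRateReport:
    """Accurate/error tallies, overall and per category, for one dataset."""

    per_category: dict[str, CategoryCounts]
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def total(self) -> CategoryCounts:
        return CategoryCounts(
            n_cases=sum(c.n_cases for c in self.per_category.values()),
            n_accurate=sum(c.n_accurate for c in self.per_category.values()),
        )

    @classmethod
    def from_counts(
        cls,
        n_accurate: int,
        n_error: int,
        *,
        category: str = "all",
    ) -> "HitRateReport":
        """Build a single-row report from printed accurate/error counts."""
        return cls(per_category={
            category: CategoryCounts(n_cases=n_accurate + n_error, n_accurate=n_accurate)
        })

    def to_table(self) -> str:
        """Render the report as TSV (rates to 1 decimal place)."""
        lines = ["category\tn_cases\tn_accurate\tn_error\thit_rate_pct\terror_rate_pct"]
        for name in sorted(self.per_category):
            c = self.per_category[name]
            lines.append(
                f"{name}\t{c.n_cases}\t{c.n_accurate}\t{c.n_error}"
                f"\t{c.hit_rate_pct:.1f}\t{c.error_rate_pct:.1f}"
            )
        t = self.total
        lines.append(
            f"total\t{t.n_cases}\t{t.n_accurate}\t{t.n_error}"
            f"\t{t.hit_rate_pct:.1f}\t{t.error_rate_pct:.1f}"
        )
        if self.excluded:
            lines.append(f"# excluded\t{len(self.excluded)}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        payload = {
            "per_category": {
                name: {
                    "n_cases": c.n_cases,
                    "n_accurate": c.n_accurate,
                    "n_error": c.n_error,
                    "hit_rate_pct": round(c.hit_rate_pct, 1),
                    "error_rate_pct": round(c.error_rate_pct, 1),
                }
                for name, c in sorted(self.per_category.items())
            },
            "total": {
                "n_cases": self.total.n_cases,
                "n_accurate": self.total.n_accurate,
                "n_error": self.total.n_error,
                "hit_rate_pct": round(self.total.hit_rate_pct, 1),
            },
            "excluded": [list(e) for e in self.excluded],
        }
        return json.dumps(payload, indent=2)


def evaluate_dataset(
    cases: Sequence[ValidationCase],
    kb: KnowledgeBase,
    config: RankerConfig | None = None,
    *,
    excluded: Iterable[tuple[str, str]] = (),
) -> HitRateReport:
    """Rank every (pre-filtered) case and tally top-k hits per category."""
    if len(cases) == 0:
        raise ArgumentError("no cases to evaluate")
    config = config or RankerConfig()
    tallies: dict[str, list[int]] = {}
    for case in cases:
        panel = CasePanel(case.panel)
        ranked = rank_diagnoses(kb, panel, config)
        hit = is_hit(case.true_disease_id, ranked, kb, config.top_k)
        bucket = tallies.setdefault(case.category or "uncategorized", [0, 0])
        bucket[0] += 1
        bucket[1] += int(hit)
    return HitRateReport(
        per_category={
            name: CategoryCounts(n_cases=n, n_accurate=acc)
            for name, (n, acc) in tallies.items()
        },
        excluded=list(excluded),
    )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    degrees_of_freedom: int
    p_value: float


def pearson_chi_square(table: Sequence[Sequence[float]]) -> ChiSquareResult:
    """Uncorrected Pearson chi-square on a 2x2 contingency table."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ArgumentError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ArgumentError("counts must be nonnegative")
    if (arr.sum(axis=0) <= 0).any() or (arr.sum(axis=1) <= 0).any():
        raise DegenerateTableError("every row and column margin must be positive")
    stat, p, dof, _ = chi2_contingency(arr, correction=False)
    return ChiSquareResult(statistic=float(stat), degrees_of_freedom=int(dof),
                           p_value=float(p))


def compare_error_rates(
    report_a: HitRateReport, report_b: HitRateReport
) -> ChiSquareResult:
    """Chi-square on the 2x2 accurate/error table of two reports' totals."""
    a, b = report_a.total, report_b.total
    if a.n_cases == 0 or b.n_cases == 0:
        raise DegenerateTableError("both reports need positive totals")
    return pearson_chi_square([[a.n_accurate, a.n_error], [b.n_accurate, b.n_error]])


def split_dataset(
    cases: Sequence[ValidationCase],
    ratio: tuple[float, float] = (0.6, 0.4),
    seed: int = 0,
) -> tuple[list[ValidationCase], list[ValidationCase]]:
    """Seeded random split (e.g. 6:4 training/validation); a true partition."""
    if len(cases) == 0:
        raise ArgumentError("cannot split an empty case list")
    if min(ratio) < 0 or abs(sum(ratio) - 1.0) > 1e-9:
        raise ArgumentError(f"ratio must be nonnegative and sum to 1, got {ratio}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))
    n_a = int(round(len(cases) * ratio[0]))
    part_a = [cases[i] for i in order[:n_a]]
    part_b = [cases[i] for i in order[n_a:]]
    return part_a, part_b
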