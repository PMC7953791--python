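"""Naive-Bayes ranking of diseases against a binary IHC panel.

For a panel of binary marker results ``B`` and a candidate disease ``A``
with curated per-marker positivities ``P(b_i = + | A)``, the likelihood of
the panel is the product of per-marker factors

    L(A) = prod_i  p_i'            if b_i positive
           prod_i (1 - p_i')       if b_i negative

with each positivity clipped to ``[floor, 1 - floor]`` so that a single
atypical result (e.g. a positive stain against a "never" entry) demotes a
disease rather than excluding it outright. Posteriors follow Bayes' rule
``P(A|B) = P(B|A) P(A) / sum_j P(B|A_j) P(A_j)`` computed in log space;
the default prior is uniform (disease incidence treated as negligible for
the computation), so posteriors are normalized likelihoods.

Two scores are reported per disease: the *posterior* (relative, sums to 1
across the differential) and the *concordance* (absolute per-disease fit:
the geometric mean of the factors on the percent scale).
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    ArgumentError,
    EmptyDifferentialError,
    LoadError,
    NoOverlapError,
    RangeError,
)
from .kb import AntibodyRegistry, KnowledgeBase

__all__ = [
    "MISSING",
    "CasePanel",
    "RankerConfig",
    "DiagnosisScore",
    "parse_result_token",
    "marker_factor",
    "case_likelihood",
    "normalize_posteriors",
    "concordance_score",
    "rank_diagnoses",
]

log = logging.getLogger(__name__)

#: Sentinel for an untested (disease, marker) pair.
MISSING = None

_POSITIVE_TOKENS = {"+", "pos", "positive", "1", "true"}
_NEGATIVE_TOKENS = {"-", "neg", "negative", "0", "false"}


def parse_result_token(token: str) -> bool | None:
    """Parse a binary IHC result token; returns None for inconclusive text."""
    t = str(token).strip().lower()
    if t in _POSITIVE_TOKENS:
        return True
    if t in _NEGATIVE_TOKENS:
        return False
    return None


@dataclass(frozen=True)
class CasePanel:
    """One case's binary IHC results keyed by canonical antibody name."""

    results: Mapping[str, bool]

    def __post_init__(self):
        if len(self.results) == 0:
            raise ArgumentError("a panel must contain at least one marker")
        for ab, res in self.results.items():
            if not isinstance(res, (bool, np.bool_)):
                raise ArgumentError(
                    f"result for {ab!r} must be binary, got {res!r}"
                )
        object.__setattr__(self, "results", dict(self.results))

    @classmethod
    def from_mapping(
        cls, results: Mapping[str, object], registry: AntibodyRegistry
    ) -> "CasePanel":
        """Build a panel from raw name -> token pairs, canonicalizing names."""
        parsed: dict[str, bool] = {}
        for name, token in results.items():
            canonical = registry.resolve(name)
            if canonical in parsed:
                raise ArgumentError(f"duplicate marker {canonical!r} in panel")
            value = token if isinstance(token, bool) else parse_result_token(str(token))
            if value is None:
                raise ArgumentError(
                    f"inconclusive result {token!r} for marker {name!r}"
                )
            parsed[canonical] = value
        return cls(parsed)

    @classmethod
    def from_file(cls, source: str | Path, registry: AntibodyRegistry) -> "CasePanel":
        """Read a panel from CSV/TSV (columns ``antibody``, ``result``) or JSON."""
        path = Path(source)
        if not path.exists():
            raise LoadError(f"panel file not found: {path}")
        if path.suffix.lower() == ".json":
            data = json.loads(path.read_text(encoding="utf-8"))
            if not isinstance(data, dict):
                raise LoadError("panel JSON must be an object of antibody -> result")
            return cls.from_mapping(data, registry)
        delim = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh, delimiter=delim)
            if reader.fieldnames is None or not {"antibody", "result"} <= set(
                reader.fieldnames
            ):
                raise LoadError("panel file must have 'antibody' and 'result' columns")
            pairs = {row["antibody"]: row["result"] for row in reader}
        if not pairs:
            raise LoadError("panel file contains no markers")
        return cls.from_mapping(pairs, registry)


@dataclass(frozen=True)
class RankerConfig:
    """Tunable inference parameters.

    floor
        Clip bound epsilon applied to every positivity before use, keeping
        factors inside (0, 1) and log-likelihoods finite.
    missing_policy
        ``"impute"`` scores untested pairs at ``impute_value`` (default 0.5,
        uninformative) so sparsely profiled diseases stay comparable;
        ``"skip"`` drops them, which biases comparisons when profile
        coverage differs between diseases.
    prior
        ``"uniform"`` or an explicit ``disease_id -> probability`` map.
    score_mode
        Which score orders the differential: ``"posterior"`` or
        ``"concordance"``.
    """

    floor: float = 0.01
    missing_policy: str = "impute"
    impute_value: float = 0.5
    prior: str | Mapping[str, float] = "uniform"
    top_k: int = 10
    score_mode: str = "posterior"

    def __post_init__(self):
        if not 0.0 < self.floor < 0.5:
            raise RangeError(f"floor must be in (0, 0.5), got {self.floor}")
        if self.missing_policy not in {"impute", "skip"}:
            raise ArgumentError(
                f"missing_policy must be 'impute' or 'skip', got {self.missing_policy!r}"
            )
        if not 0.0 <= self.impute_value <= 1.0:
            raise RangeError(f"impute_value {self.impute_value} outside [0, 1]")
        if self.top_k < 1:
            raise ArgumentError(f"top_k must be >= 1, got {self.top_k}")
        if self.score_mode not in {"posterior", "concordance"}:
            raise ArgumentError(
                f"score_mode must be 'posterior' or 'concordance', got {self.score_mode!r}"
            )
        if not isinstance(self.prior, str):
            total = math.fsum(self.prior.values())
            if abs(total - 1.0) > 1e-9:
                raise ArgumentError(f"explicit priors must sum to 1, got {total}")
            if any(p < 0 for p in self.prior.values()):
                raise RangeError("priors must be nonnegative")
            object.__setattr__(self, "prior", dict(self.prior))
        elif self.prior != "uniform":
            raise ArgumentError(f"prior must be 'uniform' or a map, got {self.prior!r}")


@dataclass
class DiagnosisScore:
    """One disease's scored fit to a query panel."""

    disease_id: str
    log_likelihood: float
    factors: dict[str, float]
    n_profiled: int
    concordance: float
    posterior: float = float("nan")
    rank: int = 0


def marker_factor(
    positivity: float | None, outcome: bool, config: RankerConfig
) -> float | None:
    """Per-marker likelihood factor; ``None`` when the marker is skipped."""
    if positivity is MISSING:
        if config.missing_policy == "skip":
            return None
        positivity = config.impute_value
    if not 0.0 <= positivity <= 1.0:
        raise RangeError(f"positivity {positivity} outside [0, 1]")
    p = min(max(positivity, config.floor), 1.0 - config.floor)
    return p if outcome else 1.0 - p


def case_likelihood(
    profile: Mapping[str, float],
    panel: CasePanel,
    config: RankerConfig,
) -> tuple[float, dict[str, float], int]:
    """Log-likelihood of a panel under one disease profile.

    Returns ``(log_likelihood, factors, n_profiled)`` where ``factors``
    records every contributing marker and ``n_profiled`` counts markers
    backed by an actual profile entry (imputed markers are excluded from
    the count but included in the product).
    """
    factors: dict[str, float] = {}
    n_profiled = 0
    for ab in sorted(panel.results):
        outcome = panel.results[ab]
        positivity = profile.get(ab, MISSING)
        f = marker_factor(positivity, outcome, config)
        if f is None:
            continue
        factors[ab] = f
        if positivity is not MISSING:
            n_profiled += 1
    if not factors:
        raise NoOverlapError(
            "no panel marker overlaps the disease profile under policy 'skip'"
        )
    ll = math.fsum(math.log(f) for f in factors.values())
    return ll, factors, n_profiled


def normalize_posteriors(
    likelihoods: Mapping[str, float],
    prior: str | Mapping[str, float] = "uniform",
) -> dict[str, float]:
    """Posterior over diseases from log-likelihoods, computed stably.

    ``posterior_i = prior_i * exp(ll_i) / sum_j prior_j * exp(ll_j)``; the
    maximum log term is subtracted before exponentiation, so a uniform
    prior cancels exactly.
    """
    if len(likelihoods) == 0:
        raise ArgumentError("no likelihoods to normalize")
    ids = sorted(likelihoods)
    ll = np.array([likelihoods[d] for d in ids], dtype=float)
    if isinstance(prior, str):
        if prior != "uniform":
            raise ArgumentError(f"prior must be 'uniform' or a map, got {prior!r}")
        log_prior = np.zeros(len(ids))
    else:
        missing = [d for d in ids if d not in prior]
        if missing:
            raise ArgumentError(f"explicit prior missing diseases: {missing}")
        with np.errstate(divide="ignore"):
            log_prior = np.log(np.array([prior[d] for d in ids], dtype=float))
    joint = ll + log_prior
    joint -= joint.max()
    weights = np.exp(joint)
    post = weights / weights.sum()
    return dict(zip(ids, post.tolist()))


def concordance_score(factors: Mapping[str, float]) -> float:
    """Geometric mean of the likelihood factors on the percent scale."""
    if len(factors) == 0:
        raise ArgumentError("no factors to score")
    logs = [math.log(f) for f in factors.values()]
    return 100.0 * math.exp(math.fsum(logs) / len(logs))


def rank_diagnoses(
    kb: KnowledgeBase,
    panel: CasePanel,
    config: RankerConfig | None = None,
) -> list[DiagnosisScore]:
    """Score every disease against a panel and return the top-k differential.

    Diseases with no contributing marker (possible only under
    ``missing_policy="skip"``) are omitted with a logged notice. Ordering:
    descending score (posterior or concordance per ``score_mode``), then
    descending ``n_profiled``, then ascending ``disease_id``.
    """
    config = config or RankerConfig()
    scores: dict[str, DiagnosisScore] = {}
    for disease_id in kb.diseases:
        profile = kb.profile_of(disease_id)
        try:
            ll, factors, n_profiled = case_likelihood(profile, panel, config)
        except NoOverlapError:
            log.info("disease %s skipped: no overlapping marker", disease_id)
            continue
        scores[disease_id] = DiagnosisScore(
            disease_id=disease_id,
            log_likelihood=ll,
            factors=factors,
            n_profiled=n_profiled,
            concordance=concordance_score(factors),
        )
    if not scores:
        raise EmptyDifferentialError("no disease could be scored for this panel")
    posteriors = normalize_posteriors(
        {d: s.log_likelihood for d, s in scores.items()}, config.prior
    )
    for d, s in scores.items():
        s.posterior = posteriors[d]

    def sort_key(s: DiagnosisScore):
        primary = s.posterior if config.score_mode == "posterior" else s.concordance
        return (-primary, -s.n_profiled, s.disease_id)

    ordered = sorted(scores.values(), key=sort_key)[: config.top_k]
    for i, s in enumerate(ordered, start=1):
        s.rank = i
    return ordered
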