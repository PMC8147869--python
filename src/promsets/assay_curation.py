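"""Assay-level curation cascade and inconsistency detection.

Assays are screened by an ordered rule cascade (source, target mapping,
organism, antitarget, hit rate, reported inconsistencies / cytotoxic
readouts, assay format); the report records per-rule attrition. A separate
detector finds assays contributing conflicting compound-target outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from promsets.activity_data import ASSAY_FORMATS, ActivityRecord, AssayRecord
from promsets.errors import ContractError

#: Cascade rule names, in application order.
RULE_ORDER = (
    "source",
    "target_mapping",
    "human_target",
    "antitarget",
    "hit_rate",
    "reported_flags",
    "assay_format",
)


@dataclass
class CurationConfig:
    """Parameters of the assay-selection cascade."""

    max_hit_rate: float = 0.02
    antitarget_ids: frozenset[str] = frozenset()
    allowed_sources: frozenset[str] = frozenset({"native"})
    require_target_mapping: bool = True
    require_human: bool = True
    assay_formats: frozenset[str] = frozenset(ASSAY_FORMATS)

    def __post_init__(self) -> None:
        if not (0.0 < self.max_hit_rate <= 1.0):
            raise ValueError("max_hit_rate must be in (0, 1]")
        if not set(self.assay_formats) <= ASSAY_FORMATS:
            raise ValueError(f"unknown assay formats: {set(self.assay_formats) - ASSAY_FORMATS}")


@dataclass
class CurationReport:
    """Per-rule attrition along the cascade."""

    attrition: list[tuple[str, int, int]] = field(default_factory=list)  # (rule, removed, remaining)
    retained: list[str] = field(default_factory=list)

    def removed_by(self, rule: str) -> int:
        for name, removed, _ in self.attrition:
            if name == rule:
                return removed
        raise KeyError(rule)

    def as_rows(self) -> list[dict]:
        return [
            {"rule": name, "removed": removed, "remaining": remaining}
            for name, removed, remaining in self.attrition
        ]


def compute_hit_rate(assay: AssayRecord) -> float:
    """Fraction of tested substances reported active."""
    if assay.n_tested == 0:
        raise ContractError(f"assay {assay.assay_id}: hit rate undefined for n_tested=0")
    return assay.n_active / assay.n_tested


def _rule_predicates(config: CurationConfig):
    # Each predicate returns True when the assay PASSES the rule.
    return [
        ("source", lambda a: a.source in config.allowed_sources),
        (
            "target_mapping",
            lambda a: not (config.require_target_mapping and "unmapped_target" in a.flags),
        ),
        ("human_target", lambda a: not (config.require_human and "nonhuman" in a.flags)),
        (
            "antitarget",
            lambda a: a.target_id not in config.antitarget_ids and "antitarget" not in a.flags,
        ),
        ("hit_rate", lambda a: compute_hit_rate(a) <= config.max_hit_rate),
        (
            "reported_flags",
            lambda a: "inconsistent" not in a.flags and "cytotoxic_readout" not in a.flags,
        ),
        ("assay_format", lambda a: a.assay_format in config.assay_formats),
    ]


def filter_assays(
    assays: Sequence[AssayRecord],
    config: CurationConfig,
) -> tuple[list[str], CurationReport]:
    """Apply the selection cascade; return retained assay ids and the report.

    An assay is removed by the first rule it fails, so per-rule attrition
    counts partition the removals. The retained set and report are
    independent of input order (attrition depends only on membership).
    """
    ids = [a.assay_id for a in assays]
    if len(set(ids)) != len(ids):
        raise ContractError("assay ids must be unique")
    remaining = sorted(assays, key=lambda a: a.assay_id)
    report = CurationReport()
    for rule, passes in _rule_predicates(config):
        kept = [a for a in remaining if passes(a)]
        report.attrition.append((rule, len(remaining) - len(kept), len(kept)))
        remaining = kept
    report.retained = [a.assay_id for a in remaining]
    return report.retained, report


def detect_inconsistent_assays(
    records: Iterable[ActivityRecord],
    retained: Iterable[str],
) -> set[str]:
    """Assays contributing to a compound-target pair with conflicting calls.

    A pair is conflicting when, across the retained assays, it carries both
    an active and an inactive outcome; every assay reporting that pair is
    returned.
    """
    retained = set(retained)
    outcomes: dict[tuple[str, str], set[str]] = {}
    contributors: dict[tuple[str, str], set[str]] = {}
    for r in records:
        if r.assay_id not in retained:
            continue
        key = (r.compound_id, r.target_id)
        outcomes.setdefault(key, set()).add(r.outcome)
        contributors.setdefault(key, set()).add(r.assay_id)
    flagged: set[str] = set()
    for key, seen in outcomes.items():
        if len(seen) > 1:
            flagged |= contributors[key]
    return flagged


def drop_conflicting_pairs(
    records: Sequence[ActivityRecord],
    retained: Iterable[str],
) -> list[ActivityRecord]:
    """Pair-granularity alternative: drop only the conflicting
    compound-target pairs instead of whole assays."""
    retained = set(retained)
    outcomes: dict[tuple[str, str], set[str]] = {}
    for r in records:
        if r.assay_id in retained:
            outcomes.setdefault((r.compound_id, r.target_id), set()).add(r.outcome)
    bad = {k for k, seen in outcomes.items() if len(seen) > 1}
    return [
        r
        for r in records
        if r.assay_id in retained and (r.compound_id, r.target_id) not in bad
    ]
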