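"""Activity matrix, promiscuity degrees, and MT/ST group assembly.

The central algorithm: distill curated activity records into a ternary
compound × target matrix, compute each compound's promiscuity degree (PD,
number of active targets) and test frequency, select MT compounds at a PD
threshold, and pair each MT compound with per-target ST compounds that are
active against one group target and experimentally confirmed inactive
against all the others — guaranteeing complete test data for every group.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from promsets.activity_data import (
    ActivityRecord,
    CompoundGroup,
    PromiscuityDataset,
)
from promsets.errors import ConsistencyError, ContractError

ACTIVE = "active"
INACTIVE = "inactive"
UNTESTED = "untested"


@dataclass
class ActivityMatrix:
    """Ternary compound × target outcome structure.

    ``outcome`` stores only tested pairs; an absent entry means untested.
    """

    compounds: list[str] = field(default_factory=list)
    targets: list[str] = field(default_factory=list)
    outcome: dict[tuple[str, str], str] = field(default_factory=dict)

    def get(self, compound_id: str, target_id: str) -> str:
        return self.outcome.get((compound_id, target_id), UNTESTED)

    def active_targets(self, compound_id: str) -> list[str]:
        return [t for t in self.targets if self.outcome.get((compound_id, t)) == ACTIVE]

    def tested_targets(self, compound_id: str) -> list[str]:
        return [t for t in self.targets if (compound_id, t) in self.outcome]


def build_activity_matrix(records: Iterable[ActivityRecord]) -> ActivityMatrix:
    """Collapse assay-level records to compound-target calls.

    A pair is active if any record is active, inactive if all its records
    are inactive. Conflicting pairs raise :class:`ConsistencyError` — they
    signal that upstream inconsistency handling was skipped.
    """
    compounds: list[str] = []
    targets: list[str] = []
    seen_c: set[str] = set()
    seen_t: set[str] = set()
    outcome: dict[tuple[str, str], str] = {}
    for r in records:
        if r.compound_id not in seen_c:
            seen_c.add(r.compound_id)
            compounds.append(r.compound_id)
        if r.target_id not in seen_t:
            seen_t.add(r.target_id)
            targets.append(r.target_id)
        key = (r.compound_id, r.target_id)
        prev = outcome.get(key)
        if prev is not None and prev != r.outcome:
            raise ConsistencyError(
                f"conflicting outcomes for pair {key}: upstream curation skipped?"
            )
        outcome[key] = r.outcome
    return ActivityMatrix(compounds=compounds, targets=targets, outcome=outcome)


def promiscuity_degree(matrix: ActivityMatrix, compound_id: str) -> int:
    """Number of targets the compound is active against."""
    if compound_id not in set(matrix.compounds):
        raise KeyError(f"unknown compound {compound_id!r}")
    return len(matrix.active_targets(compound_id))


def test_frequency(matrix: ActivityMatrix, compound_id: str) -> int:
    """Number of targets with a recorded (active or inactive) outcome."""
    if compound_id not in set(matrix.compounds):
        raise KeyError(f"unknown compound {compound_id!r}")
    return len(matrix.tested_targets(compound_id))


def select_mt(matrix: ActivityMatrix, pd_min: int) -> list[str]:
    """Compounds with PD ≥ pd_min, ordered by PD descending then id."""
    if pd_min < 2:
        raise ContractError("pd_min must be >= 2")
    pds = {c: len(matrix.active_targets(c)) for c in matrix.compounds}
    hits = [c for c, pd in pds.items() if pd >= pd_min]
    return sorted(hits, key=lambda c: (-pds[c], c))


def assemble_groups(
    matrix: ActivityMatrix,
    pd_min: int,
    *,
    name: str = "dataset",
    assay_set: str = "mixed",
) -> PromiscuityDataset:
    """Pair MT compounds with per-target ST compounds under the
    completeness guarantee.

    For each MT compound (PD ≥ pd_min, processed in ``select_mt`` order) and
    each of its active targets in matrix target order, an unused candidate
    with PD = 1, active against that target and confirmed inactive against
    every other group target, is selected; each ST compound is selected at
    most once across the whole dataset. Targets without a qualifying
    candidate get no ST member; MT compounds ending up with zero ST members
    are omitted. Ties among candidates break by highest test frequency,
    then lowest compound id.
    """
    if pd_min < 2:
        raise ContractError("pd_min must be >= 2")
    pd = {c: len(matrix.active_targets(c)) for c in matrix.compounds}
    tf = {c: len(matrix.tested_targets(c)) for c in matrix.compounds}
    mt_ids = select_mt(matrix, pd_min)

    # ST candidates per target: PD == 1 compounds active against it.
    st_by_target: dict[str, list[str]] = {t: [] for t in matrix.targets}
    for c in matrix.compounds:
        if pd[c] == 1:
            st_by_target[matrix.active_targets(c)[0]].append(c)
    for t in st_by_target:
        st_by_target[t].sort(key=lambda c: (-tf[c], c))

    used: set[str] = set()
    groups: list[CompoundGroup] = []
    for mt in mt_ids:
        target_set = tuple(matrix.active_targets(mt))
        st_members: dict[str, str] = {}
        for t in target_set:
            others = [x for x in target_set if x != t]
            for cand in st_by_target[t]:
                if cand in used:
                    continue
                if all(matrix.get(cand, o) == INACTIVE for o in others):
                    st_members[t] = cand
                    used.add(cand)
                    break
        if not st_members:
            continue
        members = [mt, *st_members.values()]
        groups.append(
            CompoundGroup(
                group_id=len(groups),
                mt_compound=mt,
                target_set=target_set,
                st_members=st_members,
                n_tested_per_member={c: tf[c] for c in members},
            )
        )
    return PromiscuityDataset(
        name=name,
        assay_set=assay_set,
        pd_threshold=pd_min,
        groups=groups,
    )


@dataclass
class CompletenessViolation:
    group_id: int
    compound_id: str
    target_id: str | None
    rule: str


def verify_completeness(
    dataset: PromiscuityDataset,
    matrix: ActivityMatrix,
) -> list[CompletenessViolation]:
    """Itemized check of the dataset against the matrix.

    Verifies, per group: every member tested on every group target; MT
    member PD ≥ dataset threshold; each ST member PD exactly 1 and active on
    its own target; and global ST uniqueness. Returns an empty list when the
    dataset is sound.
    """
    known_c = set(matrix.compounds)
    violations: list[CompletenessViolation] = []
    seen_st: dict[str, int] = {}
    for g in dataset.groups:
        for cid in g.members():
            if cid not in known_c:
                violations.append(CompletenessViolation(g.group_id, cid, None, "unknown_compound"))
                continue
            for t in g.target_set:
                if matrix.get(cid, t) == UNTESTED:
                    violations.append(
                        CompletenessViolation(g.group_id, cid, t, "untested_on_group_target")
                    )
        if g.mt_compound in known_c:
            if len(matrix.active_targets(g.mt_compound)) < dataset.pd_threshold:
                violations.append(
                    CompletenessViolation(g.group_id, g.mt_compound, None, "mt_pd_below_threshold")
                )
        for t, cid in g.st_members.items():
            if cid not in known_c:
                continue
            if len(matrix.active_targets(cid)) != 1:
                violations.append(CompletenessViolation(g.group_id, cid, None, "st_pd_not_one"))
            elif matrix.get(cid, t) != ACTIVE:
                violations.append(
                    CompletenessViolation(g.group_id, cid, t, "st_inactive_on_own_target")
                )
            if cid in seen_st:
                violations.append(CompletenessViolation(g.group_id, cid, None, "st_reused"))
            else:
                seen_st[cid] = g.group_id
    return violations


def read_matrix_tsv(path: str | Path) -> ActivityMatrix:
    """Long-format matrix interchange: compound_id, target_id, outcome."""
    compounds: list[str] = []
    targets: list[str] = []
    seen_c: set[str] = set()
    seen_t: set[str] = set()
    outcome: dict[tuple[str, str], str] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            c, t, o = row["compound_id"], row["target_id"], row["outcome"]
            if o == UNTESTED:
                continue
            if o not in (ACTIVE, INACTIVE):
                raise ConsistencyError(f"unknown outcome {o!r} for ({c}, {t})")
            if (c, t) in outcome and outcome[(c, t)] != o:
                raise ConsistencyError(f"conflicting outcomes for pair ({c}, {t})")
            if c not in seen_c:
                seen_c.add(c)
                compounds.append(c)
            if t not in seen_t:
                seen_t.add(t)
                targets.append(t)
            outcome[(c, t)] = o
    return ActivityMatrix(compounds=compounds, targets=targets, outcome=outcome)


def write_matrix_tsv(matrix: ActivityMatrix, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["compound_id", "target_id", "outcome"])
        for c in matrix.compounds:
            for t in matrix.targets:
                o = matrix.outcome.get((c, t))
                if o is not None:
                    w.writerow([c, t, o])


def matrix_records(matrix: ActivityMatrix) -> list[tuple[str, str, str]]:
    """All tested (compound, target, outcome) triples in matrix order."""
    return [
        (c, t, matrix.outcome[(c, t)])
        for c in matrix.compounds
        for t in matrix.targets
        if (c, t) in matrix.outcome
    ]


def profiles(matrix: ActivityMatrix) -> dict[str, tuple[int, int]]:
    """(PD, test frequency) per compound."""
    return {
        c: (len(matrix.active_targets(c)), len(matrix.tested_targets(c)))
        for c in matrix.compounds
    }


def test_frequency_contrast(dataset: PromiscuityDataset) -> tuple[float, float]:
    """(median ST test frequency, median MT test frequency) of the dataset."""
    import statistics

    st = [
        g.n_tested_per_member[cid]
        for g in dataset.groups
        for cid in g.st_members.values()
    ]
    mt = [g.n_tested_per_member[g.mt_compound] for g in dataset.groups]
    if not st or not mt:
        raise ContractError("dataset has no groups")
    return statistics.median(st), statistics.median(mt)
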