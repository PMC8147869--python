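"""Core data model for screening records and MT/ST group datasets.

Defines the record types used throughout the pipeline and the reader/writer
for the tab-delimited dataset dialect (seven named columns, UTF-8, header
row). Also provides small long-format TSV helpers for assay, compound and
activity-record tables used by the CLI and the synthetic generator.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from promsets.errors import ConsistencyError, FormatError

ASSAY_FORMATS = frozenset({"biochemical", "cell_based"})
ASSAY_SOURCES = frozenset({"native", "external"})
ASSAY_FLAGS = frozenset(
    {"inconsistent", "cytotoxic_readout", "antitarget", "nonhuman", "unmapped_target"}
)
OUTCOMES = frozenset({"active", "inactive"})
LIABILITY_FLAGS = frozenset(
    {"pains", "chemical_liability", "aggregator", "fluc_inhibitor", "cytotoxic"}
)
REMOVAL_MARKS = ("random_removal_set", "nn_removal_set")

#: Column order of the deposited dataset dialect.
DATASET_COLUMNS = (
    "NostereoAromaticSMILES",
    "is_MT",
    "group",
    "cid",
    "target_ids",
    "n_tested",
    "random_removal_set",
    "nn_removal_set",
)

_TARGET_SEPARATORS = (";", ",", "|")


@dataclass(frozen=True)
class AssayRecord:
    """One screening assay with its target and outcome counts."""

    assay_id: str
    target_id: str
    assay_format: str
    source: str
    n_tested: int
    n_active: int
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.assay_format not in ASSAY_FORMATS:
            raise ValueError(f"unknown assay_format: {self.assay_format!r}")
        if self.source not in ASSAY_SOURCES:
            raise ValueError(f"unknown source: {self.source!r}")
        if not set(self.flags) <= ASSAY_FLAGS:
            raise ValueError(f"unknown assay flags: {set(self.flags) - ASSAY_FLAGS}")
        if self.n_tested < 0 or self.n_active < 0 or self.n_active > self.n_tested:
            raise ValueError(
                f"invalid counts for {self.assay_id}: "
                f"n_active={self.n_active}, n_tested={self.n_tested}"
            )


@dataclass(frozen=True)
class ActivityRecord:
    """One binary compound-target outcome from one assay.

    No potency value is stored; the outcome is a qualitative call.
    """

    compound_id: str
    target_id: str
    assay_id: str
    outcome: str

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be active/inactive, got {self.outcome!r}")


@dataclass(frozen=True)
class CompoundRecord:
    """A compound structure with optional liability annotations."""

    compound_id: str
    smiles: str
    liability_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not set(self.liability_flags) <= LIABILITY_FLAGS:
            raise ValueError(
                f"unknown liability flags: {set(self.liability_flags) - LIABILITY_FLAGS}"
            )


@dataclass
class CompoundGroup:
    """One MT compound, its active-target set, and per-target ST companions.

    ``st_members`` is partial: a target without a qualifying ST compound has
    no entry. ``n_tested_per_member`` carries each member's test frequency.
    """

    group_id: int
    mt_compound: str
    target_set: tuple[str, ...]
    st_members: dict[str, str] = field(default_factory=dict)
    n_tested_per_member: dict[str, int] = field(default_factory=dict)

    def members(self) -> list[str]:
        """All compound ids of the group, MT first, ST in target order."""
        out = [self.mt_compound]
        for tid in self.target_set:
            if tid in self.st_members:
                out.append(self.st_members[tid])
        return out

    def validate(self) -> None:
        if len(self.st_members) < 1:
            raise ConsistencyError(f"group {self.group_id}: no ST members")
        if not set(self.st_members) <= set(self.target_set):
            raise ConsistencyError(
                f"group {self.group_id}: ST targets outside the group target set"
            )
        if self.mt_compound in self.st_members.values():
            raise ConsistencyError(
                f"group {self.group_id}: MT compound reused as ST member"
            )


@dataclass
class PromiscuityDataset:
    """A named collection of MT/ST compound groups.

    ``removal_marks`` maps a compound id to the reduced-set halves its group
    was removed into (subset of :data:`REMOVAL_MARKS`). ``smiles`` maps every
    member compound id to its canonical structure.
    """

    name: str
    assay_set: str
    pd_threshold: int
    groups: list[CompoundGroup] = field(default_factory=list)
    removal_marks: dict[str, set[str]] = field(default_factory=dict)
    smiles: dict[str, str] = field(default_factory=dict)

    def compound_ids(self) -> list[str]:
        return [cid for g in self.groups for cid in g.members()]

    def validate(self) -> None:
        if self.assay_set not in {"mixed", "biochemical"}:
            raise ConsistencyError(f"unknown assay_set {self.assay_set!r}")
        if self.pd_threshold < 2:
            raise ConsistencyError("pd_threshold must be >= 2")
        gids = [g.group_id for g in self.groups]
        if len(set(gids)) != len(gids):
            raise ConsistencyError("duplicate group ids")
        seen: set[str] = set()
        for g in self.groups:
            g.validate()
            for cid in g.members():
                if cid in seen:
                    raise ConsistencyError(f"compound {cid} appears in more than one group")
                seen.add(cid)
        for cid, marks in self.removal_marks.items():
            if not set(marks) <= set(REMOVAL_MARKS):
                raise ConsistencyError(f"unknown removal mark for {cid}: {marks}")


@dataclass
class DatasetSummary:
    """Composition counts of a :class:`PromiscuityDataset`."""

    n_mt: int
    n_st: int
    n_groups: int
    n_targets: int
    st_per_mt_histogram: dict[int, int]

    def as_dict(self) -> dict:
        return {
            "n_mt": self.n_mt,
            "n_st": self.n_st,
            "n_groups": self.n_groups,
            "n_targets": self.n_targets,
            "st_per_mt_histogram": {str(k): v for k, v in sorted(self.st_per_mt_histogram.items())},
        }


def _parse_bool(value: str, column: str) -> bool:
    v = value.strip().lower()
    if v in {"true", "1"}:
        return True
    if v in {"false", "0"}:
        return False
    raise FormatError(f"column {column!r}: cannot parse boolean {value!r}")


def _detect_separator(value: str) -> str:
    for sep in _TARGET_SEPARATORS:
        if sep in value:
            return sep
    return ";"


def read_dataset_tsv(
    path: str | Path,
    *,
    name: str | None = None,
    assay_set: str = "mixed",
    pd_threshold: int | None = None,
) -> PromiscuityDataset:
    """Read a dataset file in the deposited tab-delimited dialect.

    One row per compound. The MT row of a group carries the full group
    target list in ``target_ids``; each ST row carries either its own single
    target or (legacy form) the full list, in which case ST targets are
    assigned positionally and the group must be complete.

    Raises :class:`FormatError` for a missing mandatory column and
    :class:`ConsistencyError` for duplicate cids or incoherent group rows.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, no header") from None
        col = {c: i for i, c in enumerate(header)}
        for required in DATASET_COLUMNS:
            if required not in col:
                raise FormatError(f"{path}: missing mandatory column {required!r}")
        rows = [r for r in reader if r and any(cell.strip() for cell in r)]

    sep = ";"
    if rows:
        sep = _detect_separator(rows[0][col["target_ids"]])

    by_group: dict[str, list[dict]] = {}
    order: list[str] = []
    seen_cids: set[str] = set()
    for r in rows:
        cid = r[col["cid"]].strip()
        if cid in seen_cids:
            raise ConsistencyError(f"{path}: duplicate cid {cid!r}")
        seen_cids.add(cid)
        gkey = r[col["group"]].strip()
        if gkey not in by_group:
            by_group[gkey] = []
            order.append(gkey)
        by_group[gkey].append(
            {
                "cid": cid,
                "smiles": r[col["NostereoAromaticSMILES"]].strip(),
                "is_mt": _parse_bool(r[col["is_MT"]], "is_MT"),
                "targets": tuple(
                    t.strip() for t in r[col["target_ids"]].split(sep) if t.strip()
                ),
                "n_tested": int(r[col["n_tested"]]),
                "random": _parse_bool(r[col["random_removal_set"]], "random_removal_set"),
                "nn": _parse_bool(r[col["nn_removal_set"]], "nn_removal_set"),
            }
        )

    groups: list[CompoundGroup] = []
    marks: dict[str, set[str]] = {}
    smiles: dict[str, str] = {}
    for gkey in order:
        members = by_group[gkey]
        mt_rows = [m for m in members if m["is_mt"]]
        if len(mt_rows) != 1:
            raise ConsistencyError(
                f"{path}: group {gkey!r} has {len(mt_rows)} MT rows (expected 1)"
            )
        mt = mt_rows[0]
        target_set = mt["targets"]
        st_rows = [m for m in members if not m["is_mt"]]
        st_members: dict[str, str] = {}
        positional = [m for m in st_rows if m["targets"] == target_set and len(target_set) > 1]
        if positional and len(positional) == len(st_rows):
            # legacy form: every ST row repeats the group target list
            if len(st_rows) != len(target_set):
                raise ConsistencyError(
                    f"{path}: group {gkey!r} repeats the group target list on ST rows "
                    "but is incomplete; per-target assignment is ambiguous"
                )
            for tid, m in zip(target_set, st_rows):
                st_members[tid] = m["cid"]
        else:
            for m in st_rows:
                if len(m["targets"]) != 1 or m["targets"][0] not in target_set:
                    raise ConsistencyError(
                        f"{path}: group {gkey!r}: ST row {m['cid']!r} target list "
                        f"{m['targets']} disagrees with group targets {target_set}"
                    )
                tid = m["targets"][0]
                if tid in st_members:
                    raise ConsistencyError(
                        f"{path}: group {gkey!r}: two ST rows for target {tid!r}"
                    )
                st_members[tid] = m["cid"]
        try:
            gid = int(gkey)
        except ValueError:
            gid = len(groups)
        group = CompoundGroup(
            group_id=gid,
            mt_compound=mt["cid"],
            target_set=target_set,
            st_members=st_members,
            n_tested_per_member={m["cid"]: m["n_tested"] for m in members},
        )
        groups.append(group)
        for m in members:
            smiles[m["cid"]] = m["smiles"]
            mset = set()
            if m["random"]:
                mset.add("random_removal_set")
            if m["nn"]:
                mset.add("nn_removal_set")
            if mset:
                marks[m["cid"]] = mset

    if pd_threshold is None:
        sizes = [len(g.target_set) for g in groups]
        pd_threshold = max(2, min(sizes)) if sizes else 2
    dataset = PromiscuityDataset(
        name=name if name is not None else path.stem,
        assay_set=assay_set,
        pd_threshold=pd_threshold,
        groups=groups,
        removal_marks=marks,
        smiles=smiles,
    )
    dataset.validate()
    return dataset


def write_dataset_tsv(dataset: PromiscuityDataset, path: str | Path) -> None:
    """Write a dataset in the deposited dialect.

    Row order is deterministic: groups by ascending group id (re-numbered
    0..n-1), MT row first, ST rows in target-position order. Booleans are
    emitted as ``True``/``False`` and target lists joined with ``;``.
    """
    dataset.validate()
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(DATASET_COLUMNS)
        for new_gid, group in enumerate(sorted(dataset.groups, key=lambda g: g.group_id)):
            marks = dataset.removal_marks

            def _row(cid: str, is_mt: bool, targets: str) -> list[str]:
                return [
                    dataset.smiles.get(cid, ""),
                    str(is_mt),
                    str(new_gid),
                    cid,
                    targets,
                    str(group.n_tested_per_member.get(cid, 0)),
                    str("random_removal_set" in marks.get(cid, ())),
                    str("nn_removal_set" in marks.get(cid, ())),
                ]

            writer.writerow(_row(group.mt_compound, True, ";".join(group.target_set)))
            for tid in group.target_set:
                if tid in group.st_members:
                    writer.writerow(_row(group.st_members[tid], False, tid))


def dataset_summary(dataset: PromiscuityDataset) -> DatasetSummary:
    """Composition counts: MT/ST totals, target count, ST-per-MT histogram."""
    dataset.validate()
    hist = Counter(len(g.st_members) for g in dataset.groups)
    targets = {t for g in dataset.groups for t in g.target_set}
    return DatasetSummary(
        n_mt=len(dataset.groups),
        n_st=sum(len(g.st_members) for g in dataset.groups),
        n_groups=len(dataset.groups),
        n_targets=len(targets),
        st_per_mt_histogram=dict(hist),
    )


# ---------------------------------------------------------------------------
# Long-format world tables (assays / compounds / activity records)
# ---------------------------------------------------------------------------


def write_assay_table(assays: Iterable[AssayRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["assay_id", "target_id", "assay_format", "source", "n_tested", "n_active", "flags"])
        for a in assays:
            w.writerow(
                [a.assay_id, a.target_id, a.assay_format, a.source,
                 a.n_tested, a.n_active, ";".join(sorted(a.flags))]
            )


def read_assay_table(path: str | Path) -> list[AssayRecord]:
    out = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            flags = frozenset(f for f in row["flags"].split(";") if f)
            out.append(
                AssayRecord(
                    assay_id=row["assay_id"],
                    target_id=row["target_id"],
                    assay_format=row["assay_format"],
                    source=row["source"],
                    n_tested=int(row["n_tested"]),
                    n_active=int(row["n_active"]),
                    flags=flags,
                )
            )
    return out


def write_compound_table(compounds: Iterable[CompoundRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["compound_id", "smiles", "liability_flags"])
        for c in compounds:
            w.writerow([c.compound_id, c.smiles, ";".join(sorted(c.liability_flags))])


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    out = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            flags = frozenset(f for f in row["liability_flags"].split(";") if f)
            out.append(CompoundRecord(row["compound_id"], row["smiles"], flags))
    return out


def write_record_table(records: Iterable[ActivityRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["compound_id", "target_id", "assay_id", "outcome"])
        for r in records:
            w.writerow([r.compound_id, r.target_id, r.assay_id, r.outcome])


def read_record_table(path: str | Path) -> list[ActivityRecord]:
    out = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                ActivityRecord(row["compound_id"], row["target_id"], row["assay_id"], row["outcome"])
            )
    return out


def annotate_removal(
    dataset: PromiscuityDataset,
    removed_group_ids: Iterable[int],
    mark: str,
) -> PromiscuityDataset:
    """Return a copy of ``dataset`` with ``mark`` set on every compound of
    the removed groups, so reduced sets can be extracted from one file."""
    if mark not in REMOVAL_MARKS:
        raise ValueError(f"unknown removal mark {mark!r}")
    removed = set(removed_group_ids)
    marks = {cid: set(v) for cid, v in dataset.removal_marks.items()}
    for g in dataset.groups:
        if g.group_id in removed:
            for cid in g.members():
                marks.setdefault(cid, set()).add(mark)
    return PromiscuityDataset(
        name=dataset.name,
        assay_set=dataset.assay_set,
        pd_threshold=dataset.pd_threshold,
        groups=[
            CompoundGroup(
                g.group_id, g.mt_compound, g.target_set,
                dict(g.st_members), dict(g.n_tested_per_member),
            )
            for g in dataset.groups
        ],
        removal_marks=marks,
        smiles=dict(dataset.smiles),
    )


def subset_groups(dataset: PromiscuityDataset, keep: Iterable[int], name: str | None = None) -> PromiscuityDataset:
    """A new dataset retaining only the groups whose ids are in ``keep``."""
    keep = set(keep)
    groups = [
        CompoundGroup(
            g.group_id, g.mt_compound, g.target_set,
            dict(g.st_members), dict(g.n_tested_per_member),
        )
        for g in dataset.groups
        if g.group_id in keep
    ]
    cids = {cid for g in groups for cid in g.members()}
    return PromiscuityDataset(
        name=name if name is not None else dataset.name,
        assay_set=dataset.assay_set,
        pd_threshold=dataset.pd_threshold,
        groups=groups,
        removal_marks={c: set(v) for c, v in dataset.removal_marks.items() if c in cids},
        smiles={c: s for c, s in dataset.smiles.items() if c in cids},
    )


def summary_from_marks(dataset: PromiscuityDataset, mark: str) -> Mapping[str, int]:
    """Count compounds carrying / not carrying a removal mark (diagnostics)."""
    marked = sum(1 for c in dataset.compound_ids() if mark in dataset.removal_marks.get(c, ()))
    return {"marked": marked, "unmarked": len(dataset.compound_ids()) - marked}
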