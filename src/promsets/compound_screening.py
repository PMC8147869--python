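"""Compound-level interference filtering.

Rule sets combine substructure patterns (SMARTS) and compound-id deny
lists; a compound is flagged by a rule set when it matches at least one
pattern or its id is denied. Flagged compounds' activity records are
removed before matrix construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from rdkit import Chem

from promsets.activity_data import ActivityRecord, CompoundRecord
from promsets.errors import ConfigurationError

RULE_SET_NAMES = ("pains", "chemical_liability", "aggregator", "fluc_inhibitor")

#: Small default substructure collection for interference-prone motifs.
#: Production runs supply full published collections via rule-set files.
DEFAULT_PAINS_SMARTS = (
    ("quinone_A", "O=C1C=CC(=O)C=C1"),
    ("catechol_A", "c1cc(O)c(O)cc1"),
    ("azo_A", "N=Nc1ccccc1"),
    ("rhodanine", "S=C1NC(=O)CS1"),
    ("ene_rhod_A", "C=C1SC(=S)NC1=O"),
    ("mannich_A", "NCc1ccccc1O"),
)


@dataclass
class LiabilityRuleSet:
    """One named liability filter: SMARTS patterns and/or a deny list."""

    name: str
    patterns: Sequence[str] = ()
    deny_list: frozenset[str] = frozenset()
    _queries: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.name not in RULE_SET_NAMES:
            raise ConfigurationError(f"unknown rule set name {self.name!r}")
        self._queries = []
        for p in self.patterns:
            q = Chem.MolFromSmarts(p)
            if q is None:
                raise ConfigurationError(f"rule set {self.name!r}: invalid SMARTS {p!r}")
            self._queries.append(q)

    def matches(self, compound: CompoundRecord) -> bool:
        if compound.compound_id in self.deny_list:
            return True
        if not self._queries:
            return False
        mol = Chem.MolFromSmiles(compound.smiles)
        if mol is None:
            raise ConfigurationError(
                f"compound {compound.compound_id}: invalid SMILES {compound.smiles!r}"
            )
        return any(mol.HasSubstructMatch(q) for q in self._queries)


def load_smarts_file(name: str, path: str | Path) -> LiabilityRuleSet:
    """Rule set from a file of one SMARTS per line (optional tab-separated
    label after the pattern; ``#`` lines ignored)."""
    patterns = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        patterns.append(line.split("\t")[0].strip())
    return LiabilityRuleSet(name=name, patterns=patterns)


def load_deny_list_file(name: str, path: str | Path) -> LiabilityRuleSet:
    """Rule set from a file of one compound id per line."""
    ids = frozenset(
        line.strip()
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.startswith("#")
    )
    return LiabilityRuleSet(name=name, deny_list=ids)


def default_pains_rule_set() -> LiabilityRuleSet:
    return LiabilityRuleSet(name="pains", patterns=[s for _, s in DEFAULT_PAINS_SMARTS])


def flag_compounds(
    compounds: Iterable[CompoundRecord],
    rule_sets: Sequence[LiabilityRuleSet],
) -> dict[str, set[str]]:
    """Flags accumulated over all rule sets, keyed by compound id.

    Compounds matching no rule set are absent from the result.
    """
    flags: dict[str, set[str]] = {}
    for c in compounds:
        hit = {rs.name for rs in rule_sets if rs.matches(c)}
        if hit:
            flags[c.compound_id] = hit
    return flags


def remove_flagged(
    records: Sequence[ActivityRecord],
    flags: Mapping[str, set[str]],
) -> list[ActivityRecord]:
    """Drop records of compounds carrying any flag; order preserved."""
    flagged = {cid for cid, f in flags.items() if f}
    return [r for r in records if r.compound_id not in flagged]
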