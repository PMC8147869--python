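"""Synthetic screening worlds with planted ground truth.

Generates complete worlds — assays, real enumerable structures, binary
activity records — where every downstream quantity (per-compound
promiscuity degree, ternary outcome table, scaffold family, liability
flags, per-rule curation violations) is known by construction. Structures
are scaffold + substituent enumerations, so within-family fingerprint
similarity exceeds between-family similarity and the similarity-driven
stages are exercised realistically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
from rdkit import Chem

from promsets.activity_data import (
    ActivityRecord,
    AssayRecord,
    CompoundRecord,
    write_assay_table,
    write_compound_table,
    write_record_table,
)
from promsets.compound_screening import LiabilityRuleSet
from promsets.errors import ConfigurationError

# Scaffold cores with one prefix ({a}) and one branch ({b}) substitution
# site. All combinations with the substituent lists below parse.
SCAFFOLD_TEMPLATES = (
    "{a}c1ccc({b})cc1",
    "{a}c1ccc({b})cn1",
    "{a}c1cnc({b})cn1",
    "{a}c1ccc({b})o1",
    "{a}c1ccc({b})s1",
    "{a}c1ccc({b})[nH]1",
    "{a}c1ccc2ccc({b})cc2c1",
    "{a}c1ccc2ncc({b})cc2c1",
    "{a}C1CCC({b})CC1",
    "{a}C1CCC({b})CN1",
    "{a}c1nnc({b})o1",
    "{a}c1ccc2[nH]cc({b})c2c1",
    "{a}c1nc({b})cs1",
    "{a}c1nc({b})co1",
    "{a}c1cnn({b})c1",
    "{a}c1cc({b})n[nH]1",
    "{a}c1cc({b})no1",
    "{a}c1ccc({b})nn1",
    "{a}c1nc({b})ncn1",
    "{a}c1ccc2scc({b})c2c1",
    "{a}c1ccc2occ({b})c2c1",
    "{a}c1cnc2ccc({b})cc2c1",
    "{a}C1CCN({b})CC1",
    "{a}C1CCC({b})OC1",
    "{a}C1CCC({b})C1",
    "{a}c1ccc(-c2ccc({b})cc2)cc1",
    "{a}c1ccc(Oc2ccc({b})cc2)cc1",
    "{a}c1ccc(C{b})cc1",
    "{a}C1CC({b})C1",
    "{a}c1ccc(N{b})cc1",
    "{a}c1ccc2c(c1)oc({b})n2",
    "{a}c1ccc2c(c1)sc({b})n2",
    "{a}c1ccc2c(c1)[nH]c({b})n2",
    "{a}c1cc2cccnc2c({b})c1",
    "{a}C1CN({b})CCN1C",
    "{a}c1cc({b})cc(C)c1",
)

# Substituents attach via their last atom in prefix position and their
# first atom in branch position; both lists are fully combinable.
PREFIX_SUBSTITUENTS = (
    "C", "CC", "CCC", "CCCC", "CO", "CCO", "CN", "CCN",
    "COC", "CC(C)C", "FC(F)(F)", "ClC", "N#C", "BrC", "CCS", "OC",
)
BRANCH_SUBSTITUENTS = (
    "C", "CC", "CCC", "CCCC", "CO", "CCO", "CN", "CCN",
    "COC", "C(C)C", "C(F)(F)F", "CCl", "C#N", "CBr", "CCS", "O",
)


@dataclass
class WorldConfig:
    """Knobs of the synthetic screening world."""

    n_targets: int = 8
    n_assays_per_target: int = 2
    n_compounds: int = 120
    frac_mt: float = 0.2
    pd_distribution: dict[int, float] | None = None
    test_coverage: float = 0.8
    st_test_coverage: float | None = None  # Fig-2-style contrast knob
    base_hit_rate: float = 0.005
    frac_cell_based: float = 0.0
    n_scaffold_families: int = 6
    n_mt_families: int | None = None  # class-disjoint families when set
    analogs_per_family: int = 32
    cluster_analogs: bool = False  # keep analog enumeration order (tight clusters)
    frac_liability: float = 0.0
    frac_antitarget_assays: float = 0.0
    frac_high_hit_rate_assays: float = 0.0
    n_inconsistent_pairs: int = 0
    seed: int = 0

    def resolved_pd_distribution(self) -> dict[int, float]:
        if self.pd_distribution is not None:
            dist = dict(self.pd_distribution)
        else:
            mt_pd = min(5, self.n_targets)
            dist = {1: 1.0 - self.frac_mt, mt_pd: self.frac_mt}
        total = sum(dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"pd_distribution sums to {total}, expected 1")
        if any(k < 1 or k > self.n_targets for k in dist):
            raise ConfigurationError(
                f"pd_distribution support must be within 1..{self.n_targets}"
            )
        if any(p < 0 for p in dist.values()):
            raise ConfigurationError("pd_distribution probabilities must be >= 0")
        return dist

    def validate(self) -> None:
        for name in ("frac_mt", "test_coverage", "base_hit_rate", "frac_cell_based",
                     "frac_liability", "frac_antitarget_assays", "frac_high_hit_rate_assays"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.n_scaffold_families < 1:
            raise ConfigurationError("n_scaffold_families must be >= 1")
        if self.n_scaffold_families > len(SCAFFOLD_TEMPLATES):
            raise ConfigurationError(
                f"at most {len(SCAFFOLD_TEMPLATES)} scaffold families are available"
            )
        if self.n_compounds > self.n_scaffold_families * self.analogs_per_family:
            raise ConfigurationError(
                "requested compounds exceed enumerable analogs "
                f"({self.n_scaffold_families} x {self.analogs_per_family})"
            )
        self.resolved_pd_distribution()


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed the way the pipeline reports it."""

    pd: dict[str, int] = field(default_factory=dict)
    outcomes: dict[tuple[str, str], str] = field(default_factory=dict)
    family: dict[str, int] = field(default_factory=dict)
    liability_cids: frozenset[str] = frozenset()
    high_hit_rate_assays: frozenset[str] = frozenset()
    antitarget_assays: frozenset[str] = frozenset()
    inconsistent_assays: frozenset[str] = frozenset()
    inconsistent_pairs: tuple[tuple[str, str], ...] = ()

    def violation_counts(self) -> dict[str, int]:
        return {
            "hit_rate": len(self.high_hit_rate_assays),
            "antitarget": len(self.antitarget_assays),
            "inconsistent_assays": len(self.inconsistent_assays),
            "liability_compounds": len(self.liability_cids),
        }


@dataclass
class World:
    assays: list[AssayRecord]
    compounds: list[CompoundRecord]
    records: list[ActivityRecord]
    truth: GroundTruth

    def __iter__(self):
        return iter((self.assays, self.compounds, self.records, self.truth))


def _enumerate_family(family_idx: int, exclude: set[str]) -> list[str]:
    """Canonical analog SMILES of one scaffold family, enumeration order,
    deduplicated globally against ``exclude``."""
    template = SCAFFOLD_TEMPLATES[family_idx]
    out: list[str] = []
    seen: set[str] = set()
    for a in PREFIX_SUBSTITUENTS:
        for b in BRANCH_SUBSTITUENTS:
            smi = Chem.MolToSmiles(Chem.MolFromSmiles(template.format(a=a, b=b)))
            if smi not in seen and smi not in exclude:
                seen.add(smi)
                out.append(smi)
    return out


@lru_cache(maxsize=1)
def _base_pools() -> tuple[tuple[str, ...], ...]:
    """Analog pools of every scaffold family, globally deduplicated in
    family order. Cached: the enumeration is seed-independent."""
    pools: list[tuple[str, ...]] = []
    used: set[str] = set()
    for f in range(len(SCAFFOLD_TEMPLATES)):
        pool = _enumerate_family(f, used)
        used.update(pool)
        pools.append(tuple(pool))
    return tuple(pools)


def _family_pool(family_idx: int, _exclude: set[str] | None = None) -> list[str]:
    return list(_base_pools()[family_idx])


def generate_structures(config: WorldConfig) -> dict[str, str]:
    """Deterministic compound-id → canonical SMILES assignment.

    Compound i belongs to family i // analogs_per_family and receives that
    family's next analog in a seed-shuffled enumeration order.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pools: list[list[str]] = []
    used: set[str] = set()
    for f in range(config.n_scaffold_families):
        pool = _family_pool(f, used)
        if len(pool) < config.analogs_per_family:
            raise ConfigurationError(
                f"family {f} offers only {len(pool)} distinct analogs"
            )
        if not config.cluster_analogs:
            order = rng.permutation(len(pool))
            pool = [pool[i] for i in order]
        used.update(pool)
        pools.append(pool)
    out: dict[str, str] = {}
    for i in range(config.n_compounds):
        fam = i // config.analogs_per_family
        out[_cid(i)] = pools[fam][i % config.analogs_per_family]
    return out


def _cid(i: int) -> str:
    return f"C{i:05d}"


def generate_world(config: WorldConfig) -> World:
    """Build a full synthetic world; see module docstring.

    Planted curation violations live in dedicated extra assays (and, for
    conflicts, previously untested compound-target pairs), so removing them
    restores a matrix identical to the planted outcome table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    targets = [f"T{i:03d}" for i in range(config.n_targets)]

    # planted promiscuity degrees
    dist = config.resolved_pd_distribution()
    pd_values = sorted(dist)
    probs = np.array([dist[k] for k in pd_values], dtype=float)
    probs = probs / probs.sum()
    planted_pd = rng.choice(pd_values, size=config.n_compounds, p=probs)

    cids = [_cid(i) for i in range(config.n_compounds)]
    mt_idx = [i for i in range(config.n_compounds) if planted_pd[i] >= 2]
    st_idx = [i for i in range(config.n_compounds) if planted_pd[i] < 2]

    # structures: either sequential family blocks, or class-disjoint families
    family: dict[str, int] = {}
    if config.n_mt_families is None:
        smiles = generate_structures(config)
        for i, cid in enumerate(cids):
            family[cid] = i // config.analogs_per_family
    else:
        k = config.n_mt_families
        n_fam = config.n_scaffold_families
        if not (1 <= k < n_fam):
            raise ConfigurationError("n_mt_families must be in [1, n_scaffold_families)")
        if len(mt_idx) > k * config.analogs_per_family:
            raise ConfigurationError("too many MT compounds for the MT families")
        if len(st_idx) > (n_fam - k) * config.analogs_per_family:
            raise ConfigurationError("too many ST compounds for the ST families")
        pools = []
        used: set[str] = set()
        for f in range(n_fam):
            pool = _family_pool(f, used)
            if len(pool) < config.analogs_per_family:
                raise ConfigurationError(
                    f"family {f} offers only {len(pool)} distinct analogs"
                )
            if not config.cluster_analogs:
                order = rng.permutation(len(pool))
                pool = [pool[i] for i in order]
            used.update(pool)
            pools.append(pool)
        smiles = {}
        for j, i in enumerate(mt_idx):  # round-robin over MT families
            fam = j % k
            smiles[cids[i]] = pools[fam][j // k]
            family[cids[i]] = fam
        for j, i in enumerate(st_idx):  # round-robin over ST families
            fam = k + j % (n_fam - k)
            smiles[cids[i]] = pools[fam][j // (n_fam - k)]
            family[cids[i]] = fam

    # clean assays
    assays: list[AssayRecord] = []
    assay_ids_by_target: dict[str, list[str]] = {t: [] for t in targets}
    for t in targets:
        for j in range(config.n_assays_per_target):
            aid = f"A_{t}_{j}"
            n_tested = int(rng.integers(2000, 20000))
            fmt = "cell_based" if rng.random() < config.frac_cell_based else "biochemical"
            assays.append(
                AssayRecord(
                    assay_id=aid,
                    target_id=t,
                    assay_format=fmt,
                    source="native",
                    n_tested=n_tested,
                    n_active=int(config.base_hit_rate * n_tested),
                )
            )
            assay_ids_by_target[t].append(aid)

    # activity records and planted outcome table
    records: list[ActivityRecord] = []
    outcomes: dict[tuple[str, str], str] = {}
    for i, cid in enumerate(cids):
        k = int(planted_pd[i])
        active = set(rng.choice(len(targets), size=k, replace=False).tolist())
        coverage = config.test_coverage
        if k == 1 and config.st_test_coverage is not None:
            coverage = config.st_test_coverage
        for ti, t in enumerate(targets):
            if ti in active:
                outcome = "active"
            elif rng.random() < coverage:
                outcome = "inactive"
            else:
                continue
            aid = assay_ids_by_target[t][int(rng.integers(len(assay_ids_by_target[t])))]
            records.append(ActivityRecord(cid, t, aid, outcome))
            outcomes[(cid, t)] = outcome

    n_clean = len(assays)

    # planted high-hit-rate assays (counts only; their tested substances are
    # outside the compound set, so no records are emitted)
    n_high = round(config.frac_high_hit_rate_assays * n_clean)
    high_ids = []
    for i in range(n_high):
        t = targets[int(rng.integers(len(targets)))]
        aid = f"AH{i:03d}"
        n_tested = int(rng.integers(2000, 20000))
        assays.append(
            AssayRecord(aid, t, "biochemical", "native", n_tested, int(0.05 * n_tested))
        )
        high_ids.append(aid)

    # planted antitarget assays
    n_anti = round(config.frac_antitarget_assays * n_clean)
    anti_ids = []
    for i in range(n_anti):
        aid = f"AA{i:03d}"
        n_tested = int(rng.integers(2000, 20000))
        assays.append(
            AssayRecord(
                aid, f"ANTI{i:03d}", "biochemical", "native",
                n_tested, int(config.base_hit_rate * n_tested),
                flags=frozenset({"antitarget"}),
            )
        )
        anti_ids.append(aid)

    # planted inconsistent pairs in dedicated assay pairs, on previously
    # untested compound-target pairs
    untested = [
        (cid, t) for cid in cids for t in targets if (cid, t) not in outcomes
    ]
    if config.n_inconsistent_pairs > len(untested):
        raise ConfigurationError(
            "not enough untested pairs to plant the requested conflicts"
        )
    incons_assays: list[str] = []
    incons_pairs: list[tuple[str, str]] = []
    if config.n_inconsistent_pairs:
        chosen = rng.choice(len(untested), size=config.n_inconsistent_pairs, replace=False)
        for j, idx in enumerate(sorted(int(x) for x in chosen)):
            cid, t = untested[idx]
            a1, a2 = f"XI{j:03d}A", f"XI{j:03d}B"
            for aid in (a1, a2):
                n_tested = int(rng.integers(2000, 20000))
                assays.append(
                    AssayRecord(aid, t, "biochemical", "native",
                                n_tested, int(config.base_hit_rate * n_tested))
                )
            records.append(ActivityRecord(cid, t, a1, "inactive"))
            records.append(ActivityRecord(cid, t, a2, "active"))
            incons_assays += [a1, a2]
            incons_pairs.append((cid, t))

    # planted liability compounds (deny-list based)
    n_liab = round(config.frac_liability * config.n_compounds)
    liab = frozenset(
        cids[int(i)] for i in rng.choice(config.n_compounds, size=n_liab, replace=False)
    )

    compounds = [
        CompoundRecord(cid, smiles[cid]) for cid in cids
    ]
    truth = GroundTruth(
        pd={cid: int(planted_pd[i]) for i, cid in enumerate(cids)},
        outcomes=outcomes,
        family=family,
        liability_cids=liab,
        high_hit_rate_assays=frozenset(high_ids),
        antitarget_assays=frozenset(anti_ids),
        inconsistent_assays=frozenset(incons_assays),
        inconsistent_pairs=tuple(incons_pairs),
    )
    return World(assays=assays, compounds=compounds, records=records, truth=truth)


def liability_rule_sets(truth: GroundTruth) -> list[LiabilityRuleSet]:
    """Deny-list rule set matching the planted liability compounds."""
    return [LiabilityRuleSet(name="chemical_liability", deny_list=truth.liability_cids)]


# ---------------------------------------------------------------------------
# Preset configurations and the fixture suite
# ---------------------------------------------------------------------------


def tiny_config(seed: int = 0) -> WorldConfig:
    return WorldConfig(
        n_targets=6, n_compounds=40, n_scaffold_families=4, analogs_per_family=10,
        pd_distribution={1: 0.8, 5: 0.2}, test_coverage=0.9, seed=seed,
    )


def conflict_config(seed: int = 0, n_pairs: int = 3) -> WorldConfig:
    return WorldConfig(
        n_targets=6, n_compounds=40, n_scaffold_families=4, analogs_per_family=10,
        pd_distribution={1: 0.8, 5: 0.2}, test_coverage=0.7,
        n_inconsistent_pairs=n_pairs, seed=seed,
    )


def liability_config(seed: int = 0, frac: float = 0.2) -> WorldConfig:
    return WorldConfig(
        n_targets=6, n_compounds=50, n_scaffold_families=5, analogs_per_family=10,
        pd_distribution={1: 0.8, 5: 0.2}, test_coverage=0.9,
        frac_liability=frac, seed=seed,
    )


def analog_cluster_config(seed: int = 0, n_compounds: int = 160) -> WorldConfig:
    """Dense analog families: groups form similarity clusters, exercising
    NN removal."""
    return WorldConfig(
        n_targets=6, n_compounds=n_compounds, n_scaffold_families=8,
        analogs_per_family=28, n_mt_families=2,
        pd_distribution={1: 0.8, 5: 0.2}, test_coverage=0.95, seed=seed,
    )


def separable_config(seed: int = 0, n_compounds: int = 1300) -> WorldConfig:
    """Structurally separated MT/ST classes (disjoint scaffold families).

    Tight analog clusters (``cluster_analogs``) make nearest-neighbor
    relationships carry much of the class signal, so NN removal degrades
    predictions more than random removal.
    """
    return WorldConfig(
        n_targets=10, n_assays_per_target=2, n_compounds=n_compounds,
        n_scaffold_families=32, analogs_per_family=100, n_mt_families=16,
        cluster_analogs=True,
        pd_distribution={1: 0.87, 5: 0.13}, test_coverage=0.95, seed=seed,
    )


def write_world(world: World, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_assay_table(world.assays, out / "assays.tsv")
    write_compound_table(world.compounds, out / "compounds.tsv")
    write_record_table(world.records, out / "records.tsv")
    truth = {
        "pd": world.truth.pd,
        "outcomes": {f"{c}\t{t}": o for (c, t), o in world.truth.outcomes.items()},
        "family": world.truth.family,
        "liability_cids": sorted(world.truth.liability_cids),
        "high_hit_rate_assays": sorted(world.truth.high_hit_rate_assays),
        "antitarget_assays": sorted(world.truth.antitarget_assays),
        "inconsistent_assays": sorted(world.truth.inconsistent_assays),
        "inconsistent_pairs": [list(p) for p in world.truth.inconsistent_pairs],
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1), encoding="utf-8")


def make_fixture_suite(out_dir: str | Path) -> None:
    """Write the named small worlds used by tests and documentation."""
    presets = {
        "tiny_world": tiny_config(0),
        "conflict_world": conflict_config(0),
        "liability_world": liability_config(0),
        "analog_cluster_world": analog_cluster_config(0),
        "separable_world": separable_config(0, n_compounds=600),
    }
    for name, cfg in presets.items():
        world = generate_world(cfg)
        write_world(world, Path(out_dir) / name)
        (Path(out_dir) / name / "config.json").write_text(
            json.dumps({k: v for k, v in asdict(cfg).items()}, indent=1, default=str),
            encoding="utf-8",
        )
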