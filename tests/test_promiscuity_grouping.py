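import random

import pytest

from promsets.activity_data import ActivityRecord
from promsets.errors import ConsistencyError, ContractError
from promsets.promiscuity_grouping import \
    test_frequency as compute_test_frequency, \
    test_frequency_contrast as compute_tf_contrast
from promsets.promiscuity_grouping import (
    ActivityMatrix,
    assemble_groups,
    build_activity_matrix,
    promiscuity_degree,
    read_matrix_tsv,
    select_mt,
    verify_completeness,
    write_matrix_tsv,
)
from promsets.synthetic_data import WorldConfig, generate_world, tiny_config


def matrix_from(outcomes):
    """Build a matrix from {(cid, tid): outcome}."""
    compounds, targets = [], []
    for c, t in outcomes:
        if c not in compounds:
            compounds.append(c)
        if t not in targets:
            targets.append(t)
    return ActivityMatrix(compounds=compounds, targets=targets, outcome=dict(outcomes))


def random_matrix(rng, n_compounds=12, n_targets=6):
    outcome = {}
    compounds = [f"c{i}" for i in range(n_compounds)]
    targets = [f"t{i}" for i in range(n_targets)]
    for c in compounds:
        for t in targets:
            r = rng.random()
            if r < 0.3:
                outcome[(c, t)] = "active"
            elif r < 0.7:
                outcome[(c, t)] = "inactive"
    return ActivityMatrix(compounds=compounds, targets=targets, outcome=outcome)


class TestBuildMatrix:
    def test_single_active(self):
        m = build_activity_matrix([ActivityRecord("c", "T", "A", "active")])
        assert m.get("c", "T") == "active"

    def test_two_inactive_records_collapse(self):
        m = build_activity_matrix(
            [
                ActivityRecord("c", "T", "A", "inactive"),
                ActivityRecord("c", "T", "B", "inactive"),
            ]
        )
        assert m.get("c", "T") == "inactive"

    def test_absent_pair_untested(self):
        m = build_activity_matrix([ActivityRecord("c", "T", "A", "active")])
        assert m.get("c", "U") == "untested"

    def test_conflict_raises(self):
        with pytest.raises(ConsistencyError, match="conflicting"):
            build_activity_matrix(
                [
                    ActivityRecord("c", "T", "A", "active"),
                    ActivityRecord("c", "T", "B", "inactive"),
                ]
            )

    def test_matrix_equals_planted_truth(self, tiny_world, tiny_matrix):
        assert tiny_matrix.outcome == tiny_world.truth.outcomes

    def test_matrix_tsv_round_trip(self, tiny_matrix, tmp_path):
        path = tmp_path / "m.tsv"
        write_matrix_tsv(tiny_matrix, path)
        m2 = read_matrix_tsv(path)
        assert m2.outcome == tiny_matrix.outcome
        assert m2.compounds == tiny_matrix.compounds


class TestProfiles:
    def test_pd_counts_actives(self):
        m = matrix_from(
            {("c", f"T{i}"): "active" for i in range(3)} | {("c", "T4"): "inactive"}
        )
        assert promiscuity_degree(m, "c") == 3

    def test_pd_zero_for_all_inactive(self):
        m = matrix_from({("c", "T0"): "inactive"})
        assert promiscuity_degree(m, "c") == 0

    def test_compute_test_frequency(self):
        m = matrix_from(
            {("c", f"T{i}"): "active" for i in range(2)}
            | {("c", f"T{i}"): "inactive" for i in range(2, 7)}
            | {("d", "T9"): "inactive"}
        )
        assert compute_test_frequency(m, "c") == 7

    def test_fully_untested_row(self):
        m = ActivityMatrix(compounds=["c"], targets=["T0"], outcome={})
        assert compute_test_frequency(m, "c") == 0

    def test_unknown_compound(self):
        m = matrix_from({("c", "T"): "active"})
        with pytest.raises(KeyError):
            promiscuity_degree(m, "zzz")
        with pytest.raises(KeyError):
            compute_test_frequency(m, "zzz")

    def test_pd_against_brute_force_oracle(self):
        rng = random.Random(11)
        for _ in range(30):
            m = random_matrix(rng)
            for c in m.compounds:
                brute_pd = sum(
                    1 for t in m.targets if m.outcome.get((c, t)) == "active"
                )
                brute_tf = sum(1 for t in m.targets if (c, t) in m.outcome)
                assert promiscuity_degree(m, c) == brute_pd
                assert compute_test_frequency(m, c) == brute_tf
                assert brute_pd <= brute_tf


class TestSelectMT:
    def _matrix(self):
        # PDs: c0->1, c1->2, c2->5, c3->7
        out = {}
        for i, pd in enumerate([1, 2, 5, 7]):
            for j in range(pd):
                out[(f"c{i}", f"t{j}")] = "active"
        return matrix_from(out)

    def test_threshold_five(self):
        assert select_mt(self._matrix(), 5) == ["c3", "c2"]

    def test_threshold_three(self):
        assert select_mt(self._matrix(), 3) == ["c3", "c2"]
        m = self._matrix()
        m.outcome[("c1", "t2")] = "active"
        assert select_mt(m, 3) == ["c3", "c2", "c1"]

    def test_monotone_in_threshold(self):
        rng = random.Random(5)
        for _ in range(20):
            m = random_matrix(rng)
            assert set(select_mt(m, 5)) <= set(select_mt(m, 3))

    def test_pd_min_contract(self):
        with pytest.raises(ContractError):
            select_mt(self._matrix(), 1)


def five_target_world():
    """1 MT active on T0..T4 plus 5 disjoint fully-tested ST candidates."""
    out = {}
    for j in range(5):
        out[("mt", f"t{j}")] = "active"
    for i in range(5):
        for j in range(5):
            out[(f"s{i}", f"t{j}")] = "active" if i == j else "inactive"
    return matrix_from(out)


class TestAssembleGroups:
    def test_forced_full_group(self):
        ds = assemble_groups(five_target_world(), 5)
        assert len(ds.groups) == 1
        g = ds.groups[0]
        assert g.mt_compound == "mt"
        assert g.st_members == {f"t{j}": f"s{j}" for j in range(5)}

    def test_untested_candidate_excluded(self):
        m = five_target_world()
        del m.outcome[("s0", "t3")]  # s0 now untested on a group target
        ds = assemble_groups(m, 5)
        assert "t0" not in ds.groups[0].st_members

    def test_competition_first_mt_wins(self):
        # two MT compounds share targets; single qualifying ST
        out = {}
        for mt in ("m1", "m2"):
            for j in range(5):
                out[(mt, f"t{j}")] = "active"
        for j in range(5):
            out[("s", f"t{j}")] = "active" if j == 0 else "inactive"
        m = matrix_from(out)
        ds = assemble_groups(m, 5)
        # processing order: equal PD -> lower id first
        assert len(ds.groups) == 1
        assert ds.groups[0].mt_compound == "m1"
        assert ds.groups[0].st_members == {"t0": "s"}

    def test_tie_break_prefers_higher_compute_test_frequency(self):
        out = {}
        for j in range(5):
            out[("mt", f"t{j}")] = "active"
        # both candidates qualify for t0; 'b' has higher test frequency
        for cand in ("a", "b"):
            for j in range(5):
                out[(cand, f"t{j}")] = "active" if j == 0 else "inactive"
        out[("b", "t5")] = "inactive"
        m = matrix_from(out)
        ds = assemble_groups(m, 5)
        assert ds.groups[0].st_members["t0"] == "b"

    def test_mt_without_any_st_omitted(self):
        out = {("mt", f"t{j}"): "active" for j in range(5)}
        ds = assemble_groups(matrix_from(out), 5)
        assert ds.groups == []

    def test_pd_min_contract(self):
        with pytest.raises(ContractError):
            assemble_groups(five_target_world(), 1)

    def test_no_qualifying_candidate_skipped(self):
        """Exhaustive check: every target left without an ST member truly had
        no unused qualifying candidate at that group's processing time."""
        rng = random.Random(23)
        for _ in range(20):
            m = random_matrix(rng, n_compounds=30, n_targets=6)
            ds = assemble_groups(m, 3)
            pd = {c: promiscuity_degree(m, c) for c in m.compounds}
            used = {cid for g in ds.groups for cid in g.st_members.values()}
            grouped_mts = {g.mt_compound: g for g in ds.groups}
            for mt in select_mt(m, 3):
                g = grouped_mts.get(mt)
                tset = [t for t in m.targets if m.outcome.get((mt, t)) == "active"]
                missing = [t for t in tset if g is None or t not in g.st_members]
                for t in missing:
                    qualifying = [
                        c
                        for c in m.compounds
                        if pd[c] == 1
                        and m.outcome.get((c, t)) == "active"
                        and all(
                            m.outcome.get((c, o)) == "inactive"
                            for o in tset
                            if o != t
                        )
                    ]
                    # all qualifying candidates must be in use elsewhere
                    assert set(qualifying) <= used


class TestVerifyCompleteness:
    @pytest.mark.parametrize("pd_min", [3, 5])
    def test_assembled_always_clean(self, pd_min):
        rng = random.Random(2)
        for _ in range(20):
            m = random_matrix(rng, n_compounds=25, n_targets=7)
            ds = assemble_groups(m, pd_min)
            assert verify_completeness(ds, m) == []

    def test_untested_member_detected(self):
        m = five_target_world()
        ds = assemble_groups(m, 5)
        del m.outcome[("s1", "t3")]
        violations = verify_completeness(ds, m)
        assert [v.rule for v in violations] == ["untested_on_group_target"]
        assert violations[0].compound_id == "s1"

    def test_reused_st_detected(self):
        m = five_target_world()
        ds = assemble_groups(m, 5)
        g = ds.groups[0]
        clone = type(g)(
            group_id=1,
            mt_compound="mt2",
            target_set=g.target_set,
            st_members={"t0": g.st_members["t0"]},
            n_tested_per_member={},
        )
        for j in range(5):
            m.outcome[("mt2", f"t{j}")] = "active"
        m.compounds.append("mt2")
        ds.groups.append(clone)
        rules = {v.rule for v in verify_completeness(ds, m)}
        assert "st_reused" in rules


class TestSyntheticRecovery:
    @pytest.mark.parametrize("seed", range(4))
    def test_pd_recovery_exact(self, seed):
        world = generate_world(tiny_config(seed))
        m = build_activity_matrix(world.records)
        for cid, planted in world.truth.pd.items():
            assert promiscuity_degree(m, cid) == planted

    def test_full_coverage_compute_test_frequency(self):
        cfg = WorldConfig(
            n_targets=5, n_compounds=20, n_scaffold_families=2, analogs_per_family=10,
            pd_distribution={1: 1.0}, test_coverage=1.0, seed=0,
        )
        world = generate_world(cfg)
        m = build_activity_matrix(world.records)
        assert all(compute_test_frequency(m, c) == 5 for c in m.compounds)

    def test_planted_contrast_direction(self):
        cfg = WorldConfig(
            n_targets=8, n_compounds=120, n_scaffold_families=6, analogs_per_family=20,
            pd_distribution={1: 0.8, 5: 0.2}, test_coverage=0.35,
            st_test_coverage=0.95, seed=4,
        )
        world = generate_world(cfg)
        m = build_activity_matrix(world.records)
        ds = assemble_groups(m, 5)
        st_median, mt_median = compute_tf_contrast(ds)
        assert st_median > mt_median
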