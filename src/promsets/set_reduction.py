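"""Reduced dataset generation: random and nearest-neighbor group removal.

The NN procedure iteratively removes, from the currently most similar pair
of groups, the group whose similarity to its next most similar remaining
group (excluding the partner) is higher. Pass 1 scores group pairs by the
maximum ST-ST fingerprint similarity, pass 2 by MT-MT similarity; each pass
removes ceil(fraction · n0) groups against the ORIGINAL group count, so the
default fractions leave exactly 50% of the groups.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np

from promsets.activity_data import (
    CompoundGroup,
    PromiscuityDataset,
    annotate_removal,
    subset_groups,
)
from promsets.chem import Fingerprint, tanimoto
from promsets.errors import ContractError


def group_similarity(
    g1: CompoundGroup,
    g2: CompoundGroup,
    mode: str,
    fingerprints: Mapping[str, Fingerprint],
    linkage: str = "max",
) -> float:
    """Inter-group similarity.

    ``mode='st'``: max (or mean, per ``linkage``) over pairwise Tanimoto
    between ST members of the two groups. ``mode='mt'``: Tanimoto between
    the two MT compounds.
    """
    if g1.group_id == g2.group_id:
        raise ContractError("group_similarity requires two distinct groups")
    if mode == "mt":
        return tanimoto(fingerprints[g1.mt_compound], fingerprints[g2.mt_compound])
    if mode != "st":
        raise ContractError(f"unknown mode {mode!r}")
    a = [fingerprints[c] for c in g1.st_members.values()]
    b = [fingerprints[c] for c in g2.st_members.values()]
    if not a or not b:
        raise ContractError("st mode requires >=1 ST member in both groups")
    sims = [tanimoto(x, y) for x in a for y in b]
    if linkage == "max":
        return max(sims)
    if linkage == "mean":
        return sum(sims) / len(sims)
    raise ContractError(f"unknown linkage {linkage!r}")


def _pairwise(
    groups: list[CompoundGroup],
    mode: str,
    fingerprints: Mapping[str, Fingerprint],
    linkage: str,
) -> dict[tuple[int, int], float]:
    by_id = sorted(groups, key=lambda g: g.group_id)
    sims: dict[tuple[int, int], float] = {}
    for i, ga in enumerate(by_id):
        for gb in by_id[i + 1 :]:
            sims[(ga.group_id, gb.group_id)] = group_similarity(
                ga, gb, mode, fingerprints, linkage
            )
    return sims


def _removal_pass(
    groups: list[CompoundGroup],
    n_remove: int,
    mode: str,
    fingerprints: Mapping[str, Fingerprint],
    linkage: str,
) -> list[int]:
    """One NN-removal pass; returns removed group ids in removal order."""
    remaining = {g.group_id for g in groups}
    sims = _pairwise(groups, mode, fingerprints, linkage)

    def sim(a: int, b: int) -> float:
        return sims[(a, b) if a < b else (b, a)]

    removed: list[int] = []
    for _ in range(n_remove):
        ids = sorted(remaining)
        # top pair: highest similarity; ties -> lexicographically smallest pair
        top = max(
            ((sim(a, b), (a, b)) for i, a in enumerate(ids) for b in ids[i + 1 :]),
            key=lambda x: (x[0], tuple(-i for i in x[1])),
        )[1]
        a, b = top

        def next_best(g: int, partner: int) -> float:
            others = [x for x in ids if x != g and x != partner]
            if not others:
                return -1.0
            return max(sim(g, x) for x in others)

        na, nb = next_best(a, b), next_best(b, a)
        if na > nb:
            victim = a
        elif nb > na:
            victim = b
        else:
            victim = max(a, b)  # tie-break: larger group id
        remaining.remove(victim)
        removed.append(victim)
    return removed


def nn_removal(
    dataset: PromiscuityDataset,
    fingerprints: Mapping[str, Fingerprint],
    fraction_per_pass: float = 0.25,
    linkage: str = "max",
) -> tuple[PromiscuityDataset, list[list[int]]]:
    """Iterative nearest-neighbor group removal (ST pass, then MT pass).

    Returns the reduced dataset (surviving groups, NN marks applied to the
    survivors' records are not needed — marks live on the annotated full
    dataset, see :func:`annotate_removal`) and the removed group ids per
    pass. Fully deterministic.
    """
    n0 = len(dataset.groups)
    if n0 < 4:
        raise ContractError("nn_removal requires at least 4 groups")
    if not (0.0 < fraction_per_pass <= 0.5):
        raise ContractError("fraction_per_pass must be in (0, 0.5]")
    quota = math.ceil(fraction_per_pass * n0)

    pass1 = _removal_pass(list(dataset.groups), quota, "st", fingerprints, linkage)
    survivors = [g for g in dataset.groups if g.group_id not in set(pass1)]
    pass2 = _removal_pass(survivors, quota, "mt", fingerprints, linkage)

    removed = set(pass1) | set(pass2)
    keep = [g.group_id for g in dataset.groups if g.group_id not in removed]
    reduced = subset_groups(dataset, keep, name=f"{dataset.name}_nn_removal")
    return reduced, [pass1, pass2]


def random_removal(
    dataset: PromiscuityDataset,
    fraction: float = 0.5,
    seed: int = 0,
) -> tuple[PromiscuityDataset, list[int]]:
    """Uniform removal of ceil(fraction · n0) groups; seed-reproducible."""
    n0 = len(dataset.groups)
    if n0 < 2:
        raise ContractError("random_removal requires at least 2 groups")
    n_remove = math.ceil(fraction * n0)
    rng = np.random.default_rng(seed)
    gids = sorted(g.group_id for g in dataset.groups)
    removed = sorted(int(g) for g in rng.choice(gids, size=n_remove, replace=False))
    keep = [g for g in gids if g not in set(removed)]
    reduced = subset_groups(dataset, keep, name=f"{dataset.name}_random_removal")
    return reduced, removed


def mark_removals(
    dataset: PromiscuityDataset,
    fingerprints: Mapping[str, Fingerprint],
    seed: int = 0,
    fraction_random: float = 0.5,
    fraction_per_pass: float = 0.25,
) -> PromiscuityDataset:
    """Full dataset annotated with both removal columns, deposited-style."""
    _, random_ids = random_removal(dataset, fraction_random, seed)
    _, nn_passes = nn_removal(dataset, fingerprints, fraction_per_pass)
    out = annotate_removal(dataset, random_ids, "random_removal_set")
    out = annotate_removal(out, [g for p in nn_passes for g in p], "nn_removal_set")
    return out


def mean_nn_similarity(
    dataset: PromiscuityDataset,
    fingerprints: Mapping[str, Fingerprint],
    mode: str = "st",
    linkage: str = "max",
) -> float:
    """Mean over groups of the similarity to their nearest neighbor group.

    Diagnostic for how strongly NN-related a dataset's groups are.
    """
    groups = dataset.groups
    if len(groups) < 2:
        raise ContractError("need at least 2 groups")
    sims = _pairwise(list(groups), mode, fingerprints, linkage)

    def sim(a: int, b: int) -> float:
        return sims[(a, b) if a < b else (b, a)]

    ids = sorted(g.group_id for g in groups)
    nn = [max(sim(g, o) for o in ids if o != g) for g in ids]
    return float(np.mean(nn))
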