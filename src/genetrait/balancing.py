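"""Class-imbalance correction by bagging.

Tree ensembles favour dominant phenotype classes; with e.g. 6 producers vs 36
non-producers the minority class can be classified at near-zero accuracy.
Multiple-covering bagging neutralizes this: every bag holds the entire
smallest class plus a capped draw from each larger class, and bags are added
until every larger-class sample has been used at least ``cover_l`` times.
Multiple down-sizing (equal class slices per bag) is provided as the
alternative for very large datasets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import BagPlan, ValidationError


def _class_pools(labels: pd.Series) -> dict[str, list[str]]:
    pools: dict[str, list[str]] = {}
    for s, c in labels.items():
        pools.setdefault(c, []).append(s)
    return pools


def _check_classes(labels: pd.Series, k_min_class: int) -> dict[str, list[str]]:
    pools = _class_pools(labels)
    if len(pools) < 2:
        raise ValidationError("bagging needs at least 2 phenotype classes")
    small = {c: len(v) for c, v in pools.items() if len(v) < k_min_class}
    if small:
        raise ValidationError(
            f"class(es) below k_min_class={k_min_class}: {small} (filter experiments first)")
    return pools


def plan_bags(labels: pd.Series, cover_l: int = 10, bag_multiplier: int = 2,
              k_min_class: int = 4, rng=None) -> BagPlan:
    """Multiple-covering bag plan.

    Each bag contains all samples of the smallest class and, from every other
    class, min(bag_multiplier x |smallest|, |class|) samples.  Per class, an
    "unused" pool is consumed without replacement across successive bags;
    when the pool is smaller than the quota it is flushed into the bag, the
    shortfall is drawn uniformly from previously used samples, and the pool
    resets.  Bags are added until every sample of every non-smallest class
    has been used at least ``cover_l`` times.

    When the largest class is at most bag_multiplier x the smallest class,
    classes are not considered disproportionate: the plan has mode "none"
    and a single bag holding every sample.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    pools = _check_classes(labels, k_min_class)
    sizes = {c: len(v) for c, v in pools.items()}
    smallest = min(sorted(sizes), key=lambda c: sizes[c])
    n_min = sizes[smallest]
    if max(sizes.values()) <= bag_multiplier * n_min:
        return BagPlan(bags=[list(labels.index)], labels=labels, mode="none")

    others = [c for c in sorted(sizes) if c != smallest]
    quota = {c: min(bag_multiplier * n_min, sizes[c]) for c in others}
    unused = {c: list(rng.permutation(pools[c])) for c in others}
    usage = pd.Series(0, index=labels.index, dtype=int)
    covered_ids = [s for c in others for s in pools[c]]

    bags: list[list[str]] = []
    while True:
        bag = list(pools[smallest])
        for c in others:
            q = quota[c]
            if len(unused[c]) >= q:
                take = unused[c][:q]
                unused[c] = unused[c][q:]
            else:
                take = list(unused[c])
                used_pool = [s for s in pools[c] if s not in take]
                extra = list(rng.choice(used_pool, size=q - len(take), replace=False))
                take += extra
                unused[c] = list(rng.permutation(pools[c]))
            bag += take
        bags.append(bag)
        usage[bag] += 1
        if int(usage[covered_ids].min()) >= cover_l:
            break
    return BagPlan(bags=bags, labels=labels, mode="multiple-covering")


def plan_downsized_bags(labels: pd.Series, n_bags: int, k_min_class: int = 4,
                        rng=None) -> BagPlan:
    """Multiple down-sizing: every bag holds |smallest| samples of each class
    (without replacement within a bag, independently across bags)."""
    if n_bags < 1:
        raise ValidationError("n_bags must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    pools = _check_classes(labels, k_min_class)
    n_min = min(len(v) for v in pools.values())
    bags = []
    for _ in range(int(n_bags)):
        bag: list[str] = []
        for c in sorted(pools):
            bag += list(rng.choice(pools[c], size=n_min, replace=False))
        bags.append(bag)
    return BagPlan(bags=bags, labels=labels, mode="multiple-downsizing")
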