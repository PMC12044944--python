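"""Balanced training subsets by disjoint under-sampling of the majority class.

With an imbalanced training set (e.g. ~5 actives per inactive) the
majority class is shuffled once and partitioned into K disjoint,
near-equal slices; each slice is paired with the full minority class to
form one balanced training subset.  Unlike random under-sampling with
replacement, every majority example appears in exactly one subset, so no
information is discarded overall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InfeasibleSubsetsError, InputError, InvariantViolationError


@dataclass
class BalancedSubset:
    """One balanced subset: a majority slice plus the shared minority set."""

    index_k: int                 # 1-based subset index
    majority_ids: list           # this subset's slice of the majority class
    minority_ids: list           # identical across subsets
    seed: int

    @property
    def ids(self) -> list:
        return list(self.majority_ids) + list(self.minority_ids)

    @property
    def labels(self) -> np.ndarray:
        """1 for majority-class members, 0 for minority-class members."""
        return np.array(
            [1] * len(self.majority_ids) + [0] * len(self.minority_ids)
        )


def auto_k(n_majority: int, n_minority: int) -> int:
    """Number of subsets implied by the imbalance ratio (round, min 1)."""
    return max(1, round(n_majority / n_minority))


def make_balanced_subsets(
    majority_ids, minority_ids, k: int | None = None, seed: int = 0
) -> list[BalancedSubset]:
    """Partition the majority class into K disjoint balanced subsets.

    ``k=None`` selects K automatically from the imbalance ratio
    (e.g. 790/159 ≈ 4.97 → 5).  The majority class is shuffled once
    under ``seed`` and split into K near-equal slices (sizes differ by
    at most one); exact equality is generally impossible (790 is not a
    multiple of 5) and near-equal partitioning keeps every majority
    example in exactly one subset.
    """
    majority_ids = list(majority_ids)
    minority_ids = list(minority_ids)
    n_maj, n_min = len(majority_ids), len(minority_ids)
    if n_min == 0:
        raise InputError("minority class is empty")
    if n_maj < n_min:
        raise InputError(
            f"majority class ({n_maj}) smaller than minority class ({n_min})"
        )
    if k is None:
        k = auto_k(n_maj, n_min)
    if k < 1:
        raise InfeasibleSubsetsError(f"k must be >= 1, got {k}")
    if k > n_maj:
        raise InfeasibleSubsetsError(
            f"cannot build {k} disjoint subsets from {n_maj} majority members"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_maj)
    slices = np.array_split(order, k)
    return [
        BalancedSubset(
            index_k=i + 1,
            majority_ids=[majority_ids[j] for j in sl],
            minority_ids=minority_ids,
            seed=seed,
        )
        for i, sl in enumerate(slices)
    ]


def subset_coverage_report(subsets) -> dict:
    """Audit the subsets: slice sizes, disjointness, unused majority count.

    Raises when majority slices overlap — that breaks the design
    invariant the partition exists to guarantee.
    """
    if not subsets:
        raise InputError("no subsets to audit")
    sizes = [len(s.majority_ids) for s in subsets]
    seen: set = set()
    total = 0
    for s in subsets:
        ids = set(s.majority_ids)
        if ids & seen:
            raise InvariantViolationError(
                f"majority slices overlap (subset {s.index_k})"
            )
        seen |= ids
        total += len(ids)
    minority_sets = {frozenset(s.minority_ids) for s in subsets}
    return {
        "k": len(subsets),
        "slice_sizes": sizes,
        "disjoint": True,
        "max_size_spread": max(sizes) - min(sizes),
        "n_majority_covered": total,
        "minority_shared": len(minority_sets) == 1,
        "n_minority": len(subsets[0].minority_ids),
    }


def subsets_to_frame(subsets) -> pd.DataFrame:
    """Subset membership table (compound_id, subset_index, class) for audit."""
    rows = []
    for s in subsets:
        rows += [(cid, s.index_k, "majority") for cid in s.majority_ids]
        rows += [(cid, s.index_k, "minority") for cid in s.minority_ids]
    return pd.DataFrame(rows, columns=["compound_id", "subset_index", "class"])
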