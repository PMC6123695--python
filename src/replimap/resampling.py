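"""Pseudo-replicate resampling structure.

A :class:`SplitPlan` holds repeated random disjoint P/Q partitions of the
participant pool; each sort's first-``k`` prefixes are nested across the
sample-size grid, and one plan can be shared verbatim across tasks with the
same participants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = ["SplitPlan", "PseudoPair", "make_split_plan", "iterate_pseudo_pairs"]


@dataclass(frozen=True)
class PseudoPair:
    sort_index: int
    k: int
    P_ids: tuple[int, ...]
    Q_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.P_ids) != self.k or len(self.Q_ids) != self.k:
            raise ValueError("|P_ids| and |Q_ids| must both equal k")
        if set(self.P_ids) & set(self.Q_ids):
            raise ValueError("P and Q overlap")


@dataclass
class SplitPlan:
    n_total: int
    k_grid: tuple[int, ...]
    sorts: list[tuple[np.ndarray, np.ndarray]]
    seed: int

    @property
    def n_sorts(self) -> int:
        return len(self.sorts)

    @property
    def half(self) -> int:
        return self.n_total // 2

    # ------------------------------------------------------------- serialize
    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_total": self.n_total,
            "k_grid": list(self.k_grid),
            "seed": self.seed,
            "sorts": [[p.tolist(), q.tolist()] for p, q in self.sorts],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        with open(path) as fh:
            payload = json.load(fh)
        sorts = [
            (np.asarray(p, dtype=np.intp), np.asarray(q, dtype=np.intp))
            for p, q in payload["sorts"]
        ]
        return cls(
            n_total=payload["n_total"],
            k_grid=tuple(payload["k_grid"]),
            sorts=sorts,
            seed=payload["seed"],
        )


def make_split_plan(
    n_total: int, n_sorts: int, k_grid: Sequence[int], seed: int
) -> SplitPlan:
    """Draw ``n_sorts`` independent uniform permutations; the first half of
    each becomes the P order and the second half the Q order.

    With odd ``n_total`` the leftover participant is never used in that sort,
    keeping |P| = |Q| = ⌊N/2⌋.
    """
    if n_sorts < 1:
        raise ValueError("n_sorts must be >= 1")
    half = n_total // 2
    k_grid = tuple(sorted(int(k) for k in k_grid))
    bad = [k for k in k_grid if k > half]
    if bad:
        raise ValueError(
            f"k values {bad} exceed floor(n_total/2) = {half}"
        )
    if any(k < 1 for k in k_grid):
        raise ValueError("k values must be >= 1")
    rng = np.random.default_rng(seed)
    sorts = []
    for _ in range(n_sorts):
        perm = rng.permutation(n_total)
        sorts.append((perm[:half].copy(), perm[half : 2 * half].copy()))
    return SplitPlan(n_total=n_total, k_grid=k_grid, sorts=sorts, seed=seed)


def iterate_pseudo_pairs(plan: SplitPlan) -> Iterator[PseudoPair]:
    """Yield every (sort, k) combination exactly once, ordered by sort then k."""
    for sort_index, (p_order, q_order) in enumerate(plan.sorts):
        for k in plan.k_grid:
            yield PseudoPair(
                sort_index=sort_index,
                k=k,
                P_ids=tuple(int(i) for i in p_order[:k]),
                Q_ids=tuple(int(i) for i in q_order[:k]),
            )
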