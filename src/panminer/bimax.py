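"""Enumeration of inclusion-maximal all-ones biclusters in a binary matrix.

A bicluster is an (item set, sample set) pair whose submatrix is all ones.
We report every bicluster that (a) involves at least ``min_pathways``
distinct pathways, (b) covers at least a minimum fraction of the mined
class's samples, and (c) is inclusion-maximal among biclusters meeting
those thresholds.  Because each reported sample set is the full support of
its item set, the admissible maximal biclusters are exactly the *closed*
frequent itemsets, which we enumerate by depth-first search with
prefix-preserving closure extensions.  A brute-force subset enumeration
over small item spaces serves as the reference oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .activity import UP_SUFFIX, DOWN_SUFFIX, BinaryTransactionMatrix
from .io_formats import CASE, CONTROL


@dataclass(frozen=True)
class Bicluster:
    """All-ones submatrix: signed pathway items x supporting samples."""

    items: tuple[str, ...]
    samples: tuple[str, ...]
    klass: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(sorted(self.items)))
        object.__setattr__(self, "samples", tuple(sorted(self.samples)))

    @property
    def pathways(self) -> tuple[str, ...]:
        """Distinct pathways, collapsing :up/:down item decorations."""
        return tuple(sorted({_pathway_of(i) for i in self.items}))


def _pathway_of(item: str) -> str:
    for suffix in (UP_SUFFIX, DOWN_SUFFIX):
        if item.endswith(suffix):
            return item[: -len(suffix)]
    return item


def _as_bool_array(bits) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(bits, BinaryTransactionMatrix):
        df = bits.bits
    elif isinstance(bits, pd.DataFrame):
        df = bits
    else:
        raise TypeError("bits must be a BinaryTransactionMatrix or DataFrame")
    return df.to_numpy(dtype=bool), [str(i) for i in df.index], [str(c) for c in df.columns]


def _canonical(biclusters: list[Bicluster]) -> list[Bicluster]:
    return sorted(set(biclusters),
                  key=lambda b: (-len(b.samples), -len(b.items), b.items))


def _closed_itemsets(B: np.ndarray, min_samples: int):
    """Yield (item index tuple, sample index array) for every closed itemset
    with support >= min_samples, via LCM-style ppc extension."""
    n_items, n_samples = B.shape
    if n_samples < min_samples:
        return
    all_tid = np.arange(n_samples)

    def closure(tid: np.ndarray) -> np.ndarray:
        return np.flatnonzero(B[:, tid].all(axis=1))

    out = []

    def recurse(items: np.ndarray, tid: np.ndarray, start: int) -> None:
        out.append((items, tid))
        in_items = np.zeros(n_items, dtype=bool)
        in_items[items] = True
        for j in range(start, n_items):
            if in_items[j]:
                continue
            new_tid = tid[B[j, tid]]
            if new_tid.size < min_samples:
                continue
            clos = closure(new_tid)
            # prefix-preserving check: closure must add no item before j
            # that is not already in the current itemset
            smaller = clos[clos < j]
            if not in_items[smaller].all():
                continue
            recurse(clos, new_tid, j + 1)

    root_items = closure(all_tid)
    recurse(root_items, all_tid, 0)
    for items, tid in out:
        if items.size:
            yield tuple(items.tolist()), tid


def bimax(bits, min_pathways: int = 2, min_support: float = 0.25,
          klass: str | None = None) -> list[Bicluster]:
    """Mine maximal all-ones biclusters from a class-restricted binary matrix.

    Parameters
    ----------
    bits : BinaryTransactionMatrix or DataFrame
        0/1 items-by-samples matrix; the columns should already be
        restricted to one class's samples.
    min_pathways : int
        Minimum number of distinct pathways per bicluster.
    min_support : float
        Minimum fraction of the matrix's samples each bicluster must cover
        (``ceil(min_support * n_samples)`` samples).
    """
    if not (0 < min_support <= 1):
        raise ValueError("min_support must be in (0, 1]")
    B, items, samples = _as_bool_array(bits)
    if B.size == 0:
        raise ValueError("empty binary matrix")
    min_samples = math.ceil(min_support * len(samples))
    found = []
    for idx, tid in _closed_itemsets(B, min_samples):
        names = tuple(items[i] for i in idx)
        if len({_pathway_of(i) for i in names}) < min_pathways:
            continue
        found.append(Bicluster(names, tuple(samples[t] for t in tid), klass))
    return _canonical(found)


def brute_force_biclusters(bits, min_pathways: int = 2, min_samples: int = 1,
                           klass: str | None = None) -> list[Bicluster]:
    """Reference oracle: exhaustive item-subset enumeration (<= 16 items).

    For each item subset the sample set is the intersection of supporting
    samples; subsets meeting the thresholds are kept and non-maximal ones
    (contained in another kept bicluster on both axes) discarded.
    """
    B, items, samples = _as_bool_array(bits)
    n_items = len(items)
    if n_items > 16:
        raise ValueError("brute force limited to 16 items")
    candidates: dict[tuple[int, ...], frozenset[int]] = {}
    for mask in range(1, 1 << n_items):
        idx = [i for i in range(n_items) if mask >> i & 1]
        names = [items[i] for i in idx]
        if len({_pathway_of(i) for i in names}) < min_pathways:
            continue
        tid = np.flatnonzero(B[idx].all(axis=0))
        if tid.size < min_samples:
            continue
        candidates[tuple(idx)] = frozenset(tid.tolist())
    kept = []
    entries = list(candidates.items())
    for i, (idx_a, tid_a) in enumerate(entries):
        set_a = frozenset(idx_a)
        maximal = True
        for j, (idx_b, tid_b) in enumerate(entries):
            if i == j:
                continue
            if set_a <= frozenset(idx_b) and tid_a <= tid_b \
                    and (set_a != frozenset(idx_b) or tid_a != tid_b):
                maximal = False
                break
        if maximal:
            kept.append(Bicluster(tuple(items[i] for i in idx_a),
                                  tuple(samples[t] for t in tid_a), klass))
    return _canonical(kept)


def mine_class_biclusters(bits: BinaryTransactionMatrix,
                          labels, min_pathways: int = 2,
                          min_support: float = 0.25,
                          classes: Sequence[str] = (CASE, CONTROL),
                          ) -> dict[str, list[Bicluster]]:
    """Run the miner separately on each class's sample columns."""
    out: dict[str, list[Bicluster]] = {}
    for klass in classes:
        cols = [s for s in bits.samples if labels.get(s) == klass]
        if not cols:
            raise ValueError(f"no samples labelled {klass!r}")
        sub = bits.bits[cols]
        out[klass] = bimax(sub, min_pathways, min_support, klass=klass)
    return out
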