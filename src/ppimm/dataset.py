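"""Balanced dataset construction: location-aware negatives and splitting.

Negative pairs are drawn by rejection sampling over uniformly random
protein pairs, accepting only pairs whose subcellular-location label sets
are disjoint and which collide with no positive, no earlier negative and
no self-pair. Exactly ``len(positives)`` negatives are produced so the
emitted dataset is balanced 1:1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fusion import PairExample

logger = logging.getLogger(__name__)


class NegativeSamplingError(RuntimeError):
    """Quota of valid negative pairs could not be reached."""

    def __init__(self, requested: int, achieved: int):
        super().__init__(
            f"could not generate {requested} valid negative pairs "
            f"(achieved {achieved}); not enough cross-location protein pairs"
        )
        self.requested = requested
        self.achieved = achieved


@dataclass
class LocationTable:
    """protein_id -> set of subcellular-location labels."""

    locations: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [pid for pid, locs in self.locations.items() if not locs]
        if empty:
            raise ValueError(f"proteins with no location: {sorted(empty)[:5]}")

    def __getitem__(self, pid: str) -> set[str]:
        return self.locations[pid]

    def __contains__(self, pid: str) -> bool:
        return pid in self.locations

    @classmethod
    def read(cls, path) -> "LocationTable":
        """TSV ``id  location``, one row per (id, location) pair."""
        locs: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                pid, loc = line.split("\t")
                locs.setdefault(pid, set()).add(loc)
        return cls(locs)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for pid in self.locations:
                for loc in sorted(self.locations[pid]):
                    fh.write(f"{pid}\t{loc}\n")


def generate_negatives(
    positives: list[PairExample],
    locs: LocationTable,
    seed: int = 0,
    retry_factor: int = 1000,
) -> list[PairExample]:
    """Sample ``len(positives)`` location-disjoint negative pairs.

    Raises :class:`NegativeSamplingError` (reporting the achieved count)
    if the quota cannot be met within ``retry_factor * quota`` draws.
    """
    quota = len(positives)
    proteins = sorted({pid for p in positives for pid in (p.m, p.n)})
    missing = [pid for pid in proteins if pid not in locs]
    if missing:
        raise KeyError(f"proteins without location info: {missing[:5]}")
    taken = {p.key for p in positives}
    rng = np.random.default_rng(seed)
    negatives: list[PairExample] = []
    draws = 0
    limit = retry_factor * max(quota, 1)
    while len(negatives) < quota and draws < limit:
        i, j = rng.integers(len(proteins), size=2)
        draws += 1
        if i == j:
            continue
        m, n = proteins[i], proteins[j]
        if locs[m] & locs[n]:
            continue
        key = frozenset((m, n))
        if key in taken:
            continue
        taken.add(key)
        negatives.append(PairExample(m, n, 0))
    if len(negatives) < quota:
        raise NegativeSamplingError(quota, len(negatives))
    logger.info("generated %d negatives in %d draws", quota, draws)
    return negatives


def verify_negatives(
    negatives: list[PairExample], positives: list[PairExample], locs: LocationTable
) -> None:
    """Independent post-hoc check of the negative-set contract."""
    pos_keys = {p.key for p in positives}
    seen: set[frozenset[str]] = set()
    for p in negatives:
        if p.label != 0:
            raise AssertionError(f"negative with label {p.label}: {p}")
        if p.key in pos_keys:
            raise AssertionError(f"negative duplicates a positive: {p}")
        if p.key in seen:
            raise AssertionError(f"duplicate negative: {p}")
        if locs[p.m] & locs[p.n]:
            raise AssertionError(f"negative pair shares a location: {p}")
        seen.add(p.key)


def split_dataset(examples: list, ratio: float = 0.8, seed: int = 0) -> tuple[list, list]:
    """Shuffle then split; train gets ``floor(n * ratio)`` examples."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    if len(examples) < 2:
        raise ValueError("need at least 2 examples to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(examples))
    n_train = int(len(examples) * ratio)
    train = [examples[i] for i in order[:n_train]]
    test = [examples[i] for i in order[n_train:]]
    return train, test
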