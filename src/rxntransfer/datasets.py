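"""Corpus handling: splits, deduplication, subsampling, multitask mixing.

The multitask stream implements the corpus-weighting scheme central to
simultaneous training on a large generic and a small specialized corpus:
weights (a, b) mean each training example is drawn from corpus A with
probability a/(a+b), so weight (1, 1) shows one specialized reaction per
generic reaction and weight (9, 1) shows one in ten.  Each corpus is
cycled in reshuffled epochs, so every example is eventually seen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .chem_io import ReactionRecord, canonicalize_reaction, reaction_smiles

logger = logging.getLogger(__name__)

__all__ = [
    "SplitSpec",
    "SamplerSpec",
    "split_random",
    "split_time",
    "carve_validation",
    "deduplicate",
    "subsample",
    "multitask_stream",
]


@dataclass(frozen=True)
class SplitSpec:
    """How to partition a corpus: random fractions or a publication-year cutoff."""

    mode: str
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    cutoff_year: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("random", "time"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if self.mode == "random":
            if any(f < 0 for f in self.fractions):
                raise ValueError("fractions must be non-negative")
            if abs(sum(self.fractions) - 1.0) > 1e-9:
                raise ValueError("fractions must sum to 1")
        if (self.cutoff_year is not None) != (self.mode == "time"):
            raise ValueError("cutoff_year must be present iff mode='time'")


@dataclass(frozen=True)
class SamplerSpec:
    """Multitask mixture weights and batch size."""

    weight_a: int
    weight_b: int
    batch_size: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weight_a < 1:
            raise ValueError("weight_a must be a positive integer")
        if self.weight_b < 0:
            raise ValueError("weight_b must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")


def split_random(
    records: Sequence[ReactionRecord], spec: SplitSpec
) -> tuple[list[ReactionRecord], list[ReactionRecord], list[ReactionRecord]]:
    """Seeded random partition into (train, valid, test) by ``spec.fractions``."""
    if spec.mode != "random":
        raise ValueError("split_random requires mode='random'")
    if not records:
        raise ValueError("cannot split an empty corpus")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(records))
    n = len(records)
    n_train = round(n * spec.fractions[0])
    n_valid = round(n * spec.fractions[1])
    n_valid = min(n_valid, n - n_train)
    train = [records[i] for i in order[:n_train]]
    valid = [records[i] for i in order[n_train:n_train + n_valid]]
    test = [records[i] for i in order[n_train + n_valid:]]
    return train, valid, test


def split_time(
    records: Sequence[ReactionRecord], spec: SplitSpec
) -> tuple[list[ReactionRecord], list[ReactionRecord]]:
    """Publication-year split: year < cutoff -> train+valid, year >= cutoff -> test.

    Records without a year are excluded (count logged): a time split
    simulates prospective prediction and an undated record cannot be placed
    on either side without leaking.
    """
    if spec.mode != "time":
        raise ValueError("split_time requires mode='time'")
    train_valid, test, excluded = [], [], 0
    for rec in records:
        if rec.year is None:
            excluded += 1
        elif rec.year < spec.cutoff_year:
            train_valid.append(rec)
        else:
            test.append(rec)
    if excluded:
        logger.warning("time split excluded %d records without a year", excluded)
    if excluded == len(records):
        raise ValueError("no record has a publication year; cannot time-split")
    return train_valid, test


def carve_validation(
    records: Sequence[ReactionRecord], fraction: float = 0.05, seed: int = 0
) -> tuple[list[ReactionRecord], list[ReactionRecord]]:
    """Seeded random (train, valid) carve-out, used after a time split."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_valid = round(len(records) * fraction)
    valid = [records[i] for i in order[:n_valid]]
    train = [records[i] for i in order[n_valid:]]
    return train, valid


def deduplicate(
    records: Sequence[ReactionRecord],
    against: Sequence[ReactionRecord] | None = None,
) -> list[ReactionRecord]:
    """Drop exact duplicate canonical reactions, keeping first occurrences.

    The key is the full canonical reaction string (fragments canonicalized
    and sorted on both sides).  Records that fail canonicalization are
    passed through untouched and logged.  ``against`` enables cross-corpus
    deduplication (off by default): records whose canonical reaction also
    occurs in that corpus are dropped too, e.g. to purge a specialized test
    set of reactions present in the generic train set.
    """
    seen: set[str] = set()
    if against is not None:
        for rec in against:
            try:
                seen.add(reaction_smiles(canonicalize_reaction(rec)))
            except ValueError:
                continue
    out = []
    n_invalid = 0
    for rec in records:
        try:
            key = reaction_smiles(canonicalize_reaction(rec))
        except ValueError:
            n_invalid += 1
            out.append(rec)
            continue
        if key not in seen:
            seen.add(key)
            out.append(rec)
    if n_invalid:
        logger.warning("deduplicate passed through %d uncanonicalizable records", n_invalid)
    return out


def subsample(
    records: Sequence[ReactionRecord], n: int, seed: int
) -> list[ReactionRecord]:
    """First ``n`` of a seeded permutation: uniform without replacement and
    *nested* — subsample(n1, seed) is a prefix-subset of subsample(n2, seed)
    for n1 < n2, which makes accuracy-vs-size curves comparable."""
    if not 1 <= n <= len(records):
        raise ValueError(f"n must be in [1, {len(records)}], got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    return [records[i] for i in order[:n]]


def multitask_stream(
    corpus_a: Sequence[ReactionRecord],
    corpus_b: Sequence[ReactionRecord],
    spec: SamplerSpec,
) -> Iterator[list[ReactionRecord]]:
    """Unbounded seeded stream of mixed batches.

    Each example is drawn from corpus A with probability
    ``weight_a / (weight_a + weight_b)``, else from corpus B; within each
    corpus, examples cycle in reshuffled epochs.
    """
    if not corpus_a:
        raise ValueError("corpus_a must be non-empty")
    if spec.weight_b > 0 and not corpus_b:
        raise ValueError("corpus_b is empty but weight_b > 0")
    p_a = spec.weight_a / (spec.weight_a + spec.weight_b)

    def stream() -> Iterator[list[ReactionRecord]]:
        rng = np.random.default_rng(spec.seed)
        orders: dict[str, list[int]] = {"a": [], "b": []}

        def draw(which: str, corpus: Sequence[ReactionRecord]) -> ReactionRecord:
            if not orders[which]:
                orders[which] = list(rng.permutation(len(corpus)))
            return corpus[orders[which].pop()]

        while True:
            batch = []
            for _ in range(spec.batch_size):
                if spec.weight_b == 0 or rng.random() < p_a:
                    batch.append(draw("a", corpus_a))
                else:
                    batch.append(draw("b", corpus_b))
            yield batch

    return stream()
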