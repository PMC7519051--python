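"""Exact-match evaluation and confidence calibration for reaction predictions.

A prediction is counted correct only if its canonicalized, fragment-sorted
product multiset equals that of the reference — multiset, not set, because
stoichiometrically distinct outcomes (single vs. double substitution of the
same site) differ only in fragment multiplicity.  An unparseable prediction
is simply wrong (and counted in the invalid-SMILES fraction); it never
raises.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .chem_io import InvalidSmilesError, ReactionRecord, canonicalize_smiles
from .model import Prediction

__all__ = ["EvalReport", "is_match", "evaluate", "calibration_bins"]

DEFAULT_BIN_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
# The 0.8 edge is highlighted in reports: empirically most correct
# predictions carry a confidence above it.
HIGHLIGHT_EDGE = 0.8


@dataclass(frozen=True)
class CalibrationBin:
    lower: float
    upper: float
    n: int
    accuracy: float


@dataclass
class EvalReport:
    """Aggregate accuracy metrics for one model on one test set."""

    n_examples: int
    top_k_accuracy: dict[int, float]
    invalid_top1_fraction: float
    per_example: list[tuple[str | None, int | None, float, bool]]
    calibration: list[CalibrationBin]

    def __post_init__(self) -> None:
        ks = sorted(self.top_k_accuracy)
        accs = [self.top_k_accuracy[k] for k in ks]
        if any(b < a for a, b in zip(accs, accs[1:])):
            raise ValueError("top-k accuracy must be non-decreasing in k")
        if not all(0.0 <= a <= 1.0 for a in accs):
            raise ValueError("accuracies must be fractions in [0, 1]")
        if self.calibration and sum(b.n for b in self.calibration) != self.n_examples:
            raise ValueError("calibration bin counts must sum to n_examples")

    def to_dict(self) -> dict:
        return {
            "n_examples": self.n_examples,
            "top_k_accuracy": {str(k): v for k, v in self.top_k_accuracy.items()},
            "invalid_top1_fraction": self.invalid_top1_fraction,
            "per_example": [
                {"record_id": rid, "match_rank": rank,
                 "top1_confidence": conf, "top1_valid": valid}
                for rid, rank, conf, valid in self.per_example
            ],
            "calibration": [
                {"lower": b.lower, "upper": b.upper, "n": b.n, "accuracy": b.accuracy}
                for b in self.calibration
            ],
        }


def _canonical_multiset(fragments: Sequence[str]) -> Counter:
    return Counter(canonicalize_smiles(f) for f in fragments)


def is_match(predicted: str, reference_products: Sequence[str]) -> bool:
    """Exact product match after canonicalization, order- and
    spelling-invariant; an unparseable prediction is False, an unparseable
    reference is a data error."""
    try:
        ref = _canonical_multiset(reference_products)
    except InvalidSmilesError as exc:
        raise InvalidSmilesError(
            f"reference products are not canonicalizable: {exc}"
        ) from exc
    try:
        pred = _canonical_multiset([f for f in predicted.split(".") if f])
    except InvalidSmilesError:
        return False
    if not pred:
        return False
    return pred == ref


def evaluate(
    predictions: Sequence[Sequence[Prediction]],
    references: Sequence[ReactionRecord],
    ks: Sequence[int] = (1,),
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> EvalReport:
    """Top-k accuracies, invalid-top-1 fraction and calibration table.

    ``predictions[i]`` is the rank-ordered candidate list for
    ``references[i]``; top-k accuracy is the fraction of examples with a
    match at rank <= k.
    """
    if len(predictions) != len(references):
        raise ValueError(
            f"{len(predictions)} prediction lists vs {len(references)} references"
        )
    if not references:
        raise ValueError("empty test set")
    per_example = []
    n_invalid_top1 = 0
    for preds, ref in zip(predictions, references):
        if not preds:
            raise ValueError(f"no predictions for record {ref.record_id!r}")
        match_rank = None
        for pred in preds:
            if is_match(pred.product_smiles, ref.products):
                match_rank = pred.rank
                break
        top1 = preds[0]
        if not top1.is_valid:
            n_invalid_top1 += 1
        per_example.append((ref.record_id, match_rank, top1.confidence, top1.is_valid))
    n = len(references)
    top_k = {
        k: sum(1 for _, rank, _, _ in per_example if rank is not None and rank <= k) / n
        for k in ks
    }
    calibration = calibration_bins(per_example, bin_edges)
    return EvalReport(
        n_examples=n,
        top_k_accuracy=top_k,
        invalid_top1_fraction=n_invalid_top1 / n,
        per_example=per_example,
        calibration=calibration,
    )


def calibration_bins(
    per_example: Sequence[tuple[str | None, int | None, float, bool]],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> list[CalibrationBin]:
    """Count and top-1 accuracy per confidence bin (left-open, right-closed).

    Relates the model's self-estimated confidence (probability product) to
    actual correctness of its rank-1 prediction.
    """
    edges = list(bin_edges)
    if edges != sorted(edges) or len(set(edges)) != len(edges):
        raise ValueError("bin_edges must be strictly ascending")
    if edges[0] > 0.0 or edges[-1] < 1.0:
        raise ValueError("bin_edges must cover (0, 1]")
    bins = []
    for lo, hi in zip(edges, edges[1:]):
        members = []
        for _, rank, conf, _ in per_example:
            if not 0.0 < conf <= 1.0:
                raise ValueError(f"confidence {conf!r} outside (0, 1]")
            if lo < conf <= hi:
                members.append(rank == 1)
        acc = sum(members) / len(members) if members else 0.0
        bins.append(CalibrationBin(lo, hi, len(members), acc))
    return bins
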