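"""Experiment recipes for the two transfer-learning scenarios.

``single`` trains on one corpus only; ``multitask`` trains on a weighted
mixture of the generic and specialized corpora; ``finetune`` continues a
checkpoint pretrained on the generic corpus with a short training run on
the specialized corpus alone, extending the vocabulary first so that
tokens absent from pretraining (typically the stereocenter tokens) become
learnable.  Every run evaluates the final checkpoint on both held-out test
sets and can write a manifest sufficient for exact re-execution.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Sequence

from .chem_io import ReactionRecord, Vocabulary, build_vocab
from .datasets import SamplerSpec, multitask_stream, subsample
from .evaluation import EvalReport, evaluate
from .model import (
    Checkpoint,
    ModelConfig,
    extend_vocab,
    fine_tune,
    init_model,
    predict_batch,
    save_checkpoint,
    single_corpus_stream,
    train,
)
from .toy_grammar import token_inventory

logger = logging.getLogger(__name__)

__all__ = ["ScenarioSpec", "CorpusSplits", "ScenarioResult", "run_scenario",
           "size_ablation"]

# Desk-scale step budgets: the pretrain/fine-tune ratio mirrors the
# long-pretraining / short-adaptation asymmetry of full-scale practice.
DEFAULT_STEPS_PRETRAIN = 3000
DEFAULT_STEPS_FINETUNE = 1000


@dataclass(frozen=True)
class CorpusSplits:
    """Pre-split corpus: train / valid / test record lists."""

    train: tuple[ReactionRecord, ...]
    valid: tuple[ReactionRecord, ...]
    test: tuple[ReactionRecord, ...]

    @staticmethod
    def make(train, valid=(), test=()) -> "CorpusSplits":
        return CorpusSplits(tuple(train), tuple(valid), tuple(test))


@dataclass(frozen=True)
class ScenarioSpec:
    """One experiment: scenario kind, budgets, sampler, seed."""

    scenario: str
    sampler: SamplerSpec | None = None
    pretrain_checkpoint: Checkpoint | None = None
    steps_pretrain: int = DEFAULT_STEPS_PRETRAIN
    steps_finetune: int = DEFAULT_STEPS_FINETUNE
    finetune_set_size: int | None = None
    single_corpus: str = "special"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("multitask", "finetune", "single"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if (self.sampler is not None) != (self.scenario == "multitask"):
            raise ValueError("sampler must be present iff scenario='multitask'")
        if (self.pretrain_checkpoint is not None) != (self.scenario == "finetune"):
            raise ValueError(
                "pretrain_checkpoint must be present iff scenario='finetune'")
        if self.single_corpus not in ("general", "special"):
            raise ValueError("single_corpus must be 'general' or 'special'")
        if self.steps_pretrain < 0 or self.steps_finetune < 0:
            raise ValueError("step budgets must be >= 0")


@dataclass
class ScenarioResult:
    checkpoint: Checkpoint
    report_general: EvalReport
    report_special: EvalReport

    def to_dict(self) -> dict:
        return {
            "step": self.checkpoint.step,
            "general_test": self.report_general.to_dict(),
            "special_test": self.report_special.to_dict(),
        }


def _evaluate_checkpoint(
    ckpt: Checkpoint,
    test: Sequence[ReactionRecord],
    ks: Sequence[int],
    beam_size: int,
) -> EvalReport:
    preds = predict_batch(ckpt, list(test), beam_size=beam_size,
                          n_best=min(max(ks), beam_size))
    return evaluate(preds, list(test), ks=ks)


def run_scenario(
    spec: ScenarioSpec,
    corpus_general: CorpusSplits,
    corpus_special: CorpusSplits,
    config: ModelConfig | None = None,
    out_dir: str | Path | None = None,
    eval_ks: Sequence[int] = (1,),
    eval_beam_size: int = 1,
) -> ScenarioResult:
    """Train per the scenario recipe and evaluate on both test sets."""
    config = config if config is not None else ModelConfig(seed=spec.seed)
    special_train = list(corpus_special.train)
    if spec.finetune_set_size is not None:
        special_train = subsample(special_train, spec.finetune_set_size, spec.seed)

    if spec.scenario == "single":
        records = list(corpus_general.train) if spec.single_corpus == "general" \
            else special_train
        vocab = build_vocab(records)
        ckpt = init_model(config, vocab)
        stream = single_corpus_stream(records, config.batch_size, spec.seed + 1)
        ckpt = train(ckpt, stream, spec.steps_pretrain)
    elif spec.scenario == "multitask":
        vocab = build_vocab(list(corpus_general.train) + special_train)
        ckpt = init_model(config, vocab)
        stream = multitask_stream(list(corpus_general.train), special_train,
                                  spec.sampler)
        ckpt = train(ckpt, stream, spec.steps_pretrain)
    else:  # finetune
        pre = spec.pretrain_checkpoint
        union = Vocabulary(set(pre.vocab.tokens) | token_inventory(special_train))
        ckpt = extend_vocab(pre, union)
        ckpt = fine_tune(ckpt, special_train, spec.steps_finetune,
                         stream_seed=spec.seed + 2)

    result = ScenarioResult(
        checkpoint=ckpt,
        report_general=_evaluate_checkpoint(ckpt, corpus_general.test, eval_ks,
                                            eval_beam_size),
        report_special=_evaluate_checkpoint(ckpt, corpus_special.test, eval_ks,
                                            eval_beam_size),
    )
    if out_dir is not None:
        _write_run_artifacts(Path(out_dir), spec, config, result)
    return result


def size_ablation(
    spec: ScenarioSpec,
    sizes: Sequence[int],
    corpus_general: CorpusSplits,
    corpus_special: CorpusSplits,
    config: ModelConfig | None = None,
    eval_ks: Sequence[int] = (1,),
) -> list[dict]:
    """Repeat ``run_scenario`` at increasing specialized-train-set sizes.

    Subsamples are nested (same seed), so each larger set contains the
    smaller ones; the expectation at full scale is that more specialized
    data gives better specialized-test accuracy.
    """
    if list(sizes) != sorted(sizes):
        raise ValueError("sizes must be ascending")
    if not all(1 <= s <= len(corpus_special.train) for s in sizes):
        raise ValueError("each size must be in [1, |specialized train|]")
    table = []
    for size in sizes:
        sized = replace(spec, finetune_set_size=size)
        result = run_scenario(sized, corpus_general, corpus_special, config,
                              eval_ks=eval_ks)
        table.append({
            "size": size,
            "top1": result.report_special.top_k_accuracy[min(eval_ks)],
        })
        logger.info("size %d -> specialized top-1 %.3f", size, table[-1]["top1"])
    return table


# ---------------------------------------------------------------------------
# Run directory + manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _spec_dict(spec: ScenarioSpec) -> dict:
    d = asdict(spec)
    # a checkpoint is not JSON-serializable; record its identity instead
    if spec.pretrain_checkpoint is not None:
        d["pretrain_checkpoint"] = {"step": spec.pretrain_checkpoint.step,
                                    "vocab_size": len(spec.pretrain_checkpoint.vocab)}
    return d


def _write_run_artifacts(out_dir: Path, spec: ScenarioSpec, config: ModelConfig,
                         result: ScenarioResult) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(result.to_dict(), indent=2), encoding="utf-8")
    ckpt_path = out_dir / "checkpoint.npz"
    save_checkpoint(result.checkpoint, ckpt_path)
    manifest = {
        "spec": _spec_dict(spec),
        "config": asdict(config),
        "artifacts": {p.name: _sha256(p) for p in (report_path, ckpt_path)},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2),
                                           encoding="utf-8")
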