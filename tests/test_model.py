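"""Transformer mechanics: gradients, determinism, decoding, confidence."""

import math

import numpy as np
import pytest

from rxntransfer.chem_io import ReactionRecord, Vocabulary, build_vocab
from rxntransfer.model import (
    Checkpoint,
    ModelConfig,
    Prediction,
    _forward_backward,
    beam_predict,
    confidence,
    encode_batch,
    evaluate_loss,
    extend_vocab,
    fine_tune,
    init_model,
    load_checkpoint,
    noam_lr,
    predict_batch,
    save_checkpoint,
    single_corpus_stream,
    train,
)
from rxntransfer.toy_grammar import ToyGrammarSpec, generate

TINY = ModelConfig(num_layers=2, num_heads=2, model_dim=16, feedforward_dim=24,
                   dropout=0.0, max_src_len=48, max_tgt_len=48, warmup_steps=50,
                   batch_size=8, seed=5)


@pytest.fixture(scope="module")
def tiny_corpus():
    records = generate(ToyGrammarSpec("general", 120, seed=31))
    return records


@pytest.fixture(scope="module")
def tiny_vocab(tiny_corpus):
    return build_vocab(tiny_corpus)


# ---------------------------------------------------------------------------
# initialization / serialization
# ---------------------------------------------------------------------------

def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(model_dim=30, num_heads=4)  # not divisible
    with pytest.raises(ValueError):
        ModelConfig(num_layers=0)
    with pytest.raises(ValueError):
        ModelConfig(dropout=1.0)


def test_seeded_init_is_deterministic_and_sized_by_vocab(tiny_vocab):
    a = init_model(TINY, tiny_vocab)
    b = init_model(TINY, tiny_vocab)
    assert a.params.keys() == b.params.keys()
    for k in a.params:
        np.testing.assert_array_equal(a.params[k], b.params[k])
    assert a.params["emb"].shape == (len(tiny_vocab), TINY.model_dim)
    assert a.step == 0


def test_checkpoint_save_load_roundtrip(tmp_path, tiny_corpus, tiny_vocab):
    ckpt = init_model(TINY, tiny_vocab)
    stream = single_corpus_stream(tiny_corpus, TINY.batch_size, 1)
    ckpt = train(ckpt, stream, 5, log_every=0)
    path = tmp_path / "model.npz"
    save_checkpoint(ckpt, path)
    loaded = load_checkpoint(path)
    assert loaded.step == ckpt.step
    assert loaded.vocab == ckpt.vocab
    assert loaded.config == ckpt.config
    for k in ckpt.params:
        np.testing.assert_array_equal(loaded.params[k], ckpt.params[k])
    rec = tiny_corpus[0]
    before = beam_predict(ckpt, rec, beam_size=2, n_best=2)
    after = beam_predict(loaded, rec, beam_size=2, n_best=2)
    assert [p.product_smiles for p in before] == [p.product_smiles for p in after]


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------

def test_backward_matches_finite_differences():
    """Spot-check analytic gradients against central differences (float64)."""
    cfg = ModelConfig(num_layers=1, num_heads=2, model_dim=8, feedforward_dim=12,
                      dropout=0.0, label_smoothing=0.1, max_src_len=16,
                      max_tgt_len=16, batch_size=2, seed=3, dtype="float64")
    vocab = Vocabulary(list("CON()=.") + ["Cl"])
    ckpt = init_model(cfg, vocab)
    recs = [ReactionRecord.make(["CCO", "CC(=O)Cl"], ["COC(C)=O"]),
            ReactionRecord.make(["CC(O)C"], ["CC(C)=O"])]
    batch = encode_batch(recs, vocab, cfg)
    _, grads = _forward_backward(ckpt.params, cfg, batch, None)
    rng = np.random.default_rng(0)
    eps = 1e-6
    checked = 0
    for name, P in ckpt.params.items():
        flat = P.ravel()
        for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            lp, _ = _forward_backward(ckpt.params, cfg, batch, None,
                                      compute_grads=False)
            flat[i] = orig - eps
            lm, _ = _forward_backward(ckpt.params, cfg, batch, None,
                                      compute_grads=False)
            flat[i] = orig
            numeric = (lp - lm) / (2 * eps)
            analytic = grads[name].ravel()[i]
            assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-7), name
            checked += 1
    assert checked > 50


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def test_train_zero_steps_is_identity(tiny_corpus, tiny_vocab):
    ckpt = init_model(TINY, tiny_vocab)
    out = train(ckpt, single_corpus_stream(tiny_corpus, 8, 1), 0)
    for k in ckpt.params:
        np.testing.assert_array_equal(out.params[k], ckpt.params[k])
    assert out.step == 0


def test_train_lowers_heldout_loss_and_is_repeatable(tiny_corpus, tiny_vocab):
    heldout = tiny_corpus[:32]
    train_set = tiny_corpus[32:]
    ckpt = init_model(TINY, tiny_vocab)
    loss0 = evaluate_loss(ckpt, heldout)
    run1 = train(ckpt, single_corpus_stream(train_set, 8, 2), 150, log_every=0)
    run2 = train(ckpt, single_corpus_stream(train_set, 8, 2), 150, log_every=0)
    loss1 = evaluate_loss(run1, heldout)
    assert loss1 < loss0
    assert evaluate_loss(run2, heldout) == pytest.approx(loss1, rel=1e-6)
    assert run1.step == 150


def test_train_rejects_out_of_vocabulary_tokens(tiny_corpus):
    narrow = Vocabulary(["C"])  # misses most corpus tokens
    ckpt = init_model(TINY, narrow)
    stream = single_corpus_stream(tiny_corpus, 4, 1)
    with pytest.raises(KeyError):
        train(ckpt, stream, 1)


def test_noam_schedule_warms_up_then_decays():
    cfg = ModelConfig(warmup_steps=100)
    lrs = [noam_lr(s, cfg) for s in (1, 50, 100, 400, 1600)]
    assert lrs[0] < lrs[1] < lrs[2]
    assert lrs[2] > lrs[3] > lrs[4]
    assert lrs[3] == pytest.approx(lrs[2] / 2, rel=1e-9)


# ---------------------------------------------------------------------------
# vocabulary extension
# ---------------------------------------------------------------------------

def test_extend_vocab_identity_when_vocab_unchanged(tiny_corpus, tiny_vocab):
    ckpt = init_model(TINY, tiny_vocab)
    out = extend_vocab(ckpt, tiny_vocab)
    for k in ckpt.params:
        np.testing.assert_array_equal(out.params[k], ckpt.params[k])


def test_extend_vocab_preserves_old_token_predictions(tiny_corpus, tiny_vocab):
    ckpt = train(init_model(TINY, tiny_vocab),
                 single_corpus_stream(tiny_corpus, 8, 3), 100, log_every=0)
    bigger = Vocabulary(set(tiny_vocab.tokens) | {"[C@H]", "[C@@H]"})
    extended = extend_vocab(ckpt, bigger)
    assert len(extended.vocab) == len(tiny_vocab) + 2
    for rec in tiny_corpus[:10]:
        old = beam_predict(ckpt, rec, beam_size=1)[0]
        new = beam_predict(extended, rec, beam_size=1)[0]
        # logits of shared tokens are copied exactly, so the decoded
        # sequence is unchanged (probabilities renormalize over the
        # enlarged vocabulary and may shift slightly)
        assert old.product_smiles == new.product_smiles


def test_extend_vocab_requires_superset():
    ckpt = init_model(TINY, Vocabulary(["C", "O"]))
    with pytest.raises(ValueError):
        extend_vocab(ckpt, Vocabulary(["C", "N"]))


def test_model_without_a_token_cannot_emit_it(tiny_corpus, tiny_vocab):
    """Vocabulary closure: stereo-token-free model assigns stereo tokens
    probability exactly zero (they are not in the output space at all)."""
    ckpt = init_model(TINY, tiny_vocab)
    assert "[C@H]" not in ckpt.vocab
    preds = beam_predict(ckpt, tiny_corpus[0], beam_size=2, n_best=2)
    for p in preds:
        assert "@" not in p.product_smiles


# ---------------------------------------------------------------------------
# fine-tuning / memorization
# ---------------------------------------------------------------------------

def test_fine_tune_zero_steps_is_identity(tiny_corpus, tiny_vocab):
    ckpt = init_model(TINY, tiny_vocab)
    out = fine_tune(ckpt, tiny_corpus, 0)
    for k in ckpt.params:
        np.testing.assert_array_equal(out.params[k], ckpt.params[k])


def test_fine_tune_rejects_architecture_overrides(tiny_corpus, tiny_vocab):
    ckpt = init_model(TINY, tiny_vocab)
    with pytest.raises(ValueError):
        fine_tune(ckpt, tiny_corpus, 1, model_dim=32)


def test_overfit_single_reaction_is_memorized(tiny_vocab):
    rec = ReactionRecord.make(["CCCO", "CC(=O)Cl"], ["CCCOC(C)=O"])
    ckpt = init_model(TINY, tiny_vocab)
    ckpt = fine_tune(ckpt, [rec], 250, stream_seed=1)
    top = beam_predict(ckpt, rec, beam_size=2, n_best=2)
    assert top[0].product_smiles == "CCCOC(C)=O"
    assert top[0].rank == 1
    # beam scores non-increasing with rank
    assert top[0].confidence >= top[1].confidence


# ---------------------------------------------------------------------------
# decoding & confidence
# ---------------------------------------------------------------------------

def test_beam_size_one_equals_greedy(tiny_corpus, tiny_vocab):
    ckpt = train(init_model(TINY, tiny_vocab),
                 single_corpus_stream(tiny_corpus, 8, 4), 60, log_every=0)
    for rec in tiny_corpus[:6]:
        beam = beam_predict(ckpt, rec, beam_size=1)[0]
        greedy = predict_batch(ckpt, [rec], beam_size=1)[0][0]
        assert beam.product_smiles == greedy.product_smiles
        assert beam.confidence == pytest.approx(greedy.confidence, rel=1e-9)


def test_beam_predict_validates_arguments(tiny_vocab):
    ckpt = init_model(TINY, tiny_vocab)
    with pytest.raises(ValueError):
        beam_predict(ckpt, ["CC"], beam_size=0)
    with pytest.raises(ValueError):
        beam_predict(ckpt, ["CC"], beam_size=2, n_best=3)


def test_unknown_source_tokens_allowed_only_at_inference(tiny_corpus, tiny_vocab):
    ckpt = init_model(TINY, tiny_vocab)
    stereo_rec = ReactionRecord.make(["C[C@H](O)CCO", "CC(=O)Cl"], ["CCO"])
    preds = beam_predict(ckpt, stereo_rec, beam_size=1)  # must not raise
    assert len(preds) == 1
    with pytest.raises(KeyError):
        encode_batch([stereo_rec], tiny_vocab, TINY, strict=True)


def test_confidence_is_log_space_product():
    assert confidence([0.9, 0.8]) == pytest.approx(0.72, abs=1e-12)
    assert confidence([1.0] * 17) == 1.0
    # long products do not underflow and match a high-precision oracle
    expected = math.exp(500 * math.log(0.99))
    assert confidence([0.99] * 500) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("bad", [[], [0.0], [1.2], [0.5, -0.1]])
def test_confidence_rejects_invalid_probabilities(bad):
    with pytest.raises(ValueError):
        confidence(bad)


def test_prediction_validates_confidence_consistency():
    with pytest.raises(ValueError):
        Prediction(rank=1, product_smiles="CC", token_probabilities=(0.5, 0.5),
                   confidence=0.9, is_valid=True)
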