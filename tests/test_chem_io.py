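"""Parsing, canonicalization, tokenization and vocabulary construction."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

from rxntransfer.chem_io import (
    InvalidSmilesError,
    ReactionParseError,
    ReactionRecord,
    TokenizationError,
    Vocabulary,
    build_vocab,
    canonicalize_corpus,
    canonicalize_reaction,
    canonicalize_smiles,
    detokenize,
    format_src_tgt,
    parse_reaction_line,
    read_reaction_file,
    reaction_smiles,
    tokenize,
    write_reaction_file,
)
from rxntransfer.toy_grammar import ToyGrammarSpec, generate


# ---------------------------------------------------------------------------
# parse_reaction_line
# ---------------------------------------------------------------------------

def test_parse_full_line_with_year_and_id():
    rec = parse_reaction_line("CCO.CC(=O)Cl>>CCOC(C)=O\t2015\tr1")
    assert rec.precursors == ("CCO", "CC(=O)Cl")
    assert rec.products == ("CCOC(C)=O",)
    assert rec.year == 2015
    assert rec.record_id == "r1"


def test_parse_line_without_metadata():
    rec = parse_reaction_line("CC>>CO")
    assert rec.year is None and rec.record_id is None


@pytest.mark.parametrize("line", [
    "CCO>>",            # empty product side
    ">>CCO",            # empty precursor side
    "A>B>C",            # no '>>' separator
    "CC",               # no separator at all
    "CC>>CO\tnineteen", # non-integer year
    "CC..CO>>CC",       # empty fragment between dots
])
def test_parse_rejects_malformed_lines(line):
    with pytest.raises(ReactionParseError):
        parse_reaction_line(line)


def test_parse_merges_agent_field_into_precursors():
    rec = parse_reaction_line("CCO>CC(=O)Cl>>CCOC(C)=O")
    assert rec.precursors == ("CCO", "CC(=O)Cl")


def test_reaction_file_roundtrip(tmp_path):
    records = [
        ReactionRecord.make(["CCO", "CC(=O)Cl"], ["CCOC(C)=O"], 2015, "r1"),
        ReactionRecord.make(["CCBr", "N"], ["CCN"]),
    ]
    path = tmp_path / "rxn.txt"
    write_reaction_file(records, path)
    assert read_reaction_file(path) == records


# ---------------------------------------------------------------------------
# canonicalization
# ---------------------------------------------------------------------------

def test_canonicalize_maps_to_unique_form():
    assert canonicalize_smiles("OC") == "CO"


def test_canonicalize_is_idempotent_and_rerooting_invariant():
    rng_smiles = []
    mol = Chem.MolFromSmiles("CC(C)OC(=O)CCl")
    for i in range(25):
        rng_smiles.append(Chem.MolToSmiles(mol, canonical=False, doRandom=True))
    canon = {canonicalize_smiles(s) for s in rng_smiles}
    assert len(canon) == 1
    only = canon.pop()
    assert canonicalize_smiles(only) == only


def test_canonicalize_preserves_stereo():
    out = canonicalize_smiles("C[C@H](O)CCO")
    assert "@" in out
    assert canonicalize_smiles("C[C@@H](O)CCO") != out


def test_canonicalize_rejects_invalid():
    with pytest.raises(InvalidSmilesError):
        canonicalize_smiles("C(")


def test_canonicalize_reaction_sorts_fragments():
    rec = ReactionRecord.make(["OCC", "OC"], ["OCC"])
    out = canonicalize_reaction(rec)
    # canonical forms CCO and CO, in lexicographic order ("C" < "O")
    assert out.precursors == ("CCO", "CO")


def test_canonicalize_reaction_fixed_point_and_order_invariance():
    a = canonicalize_reaction(ReactionRecord.make(["OC", "OCC"], ["COC"]))
    b = canonicalize_reaction(ReactionRecord.make(["OCC", "OC"], ["COC"]))
    assert a.precursors == b.precursors
    assert canonicalize_reaction(a) == a


def test_canonicalize_reaction_names_bad_fragment():
    rec = ReactionRecord.make(["CC", "C("], ["CO"])
    with pytest.raises(InvalidSmilesError, match=r"C\("):
        canonicalize_reaction(rec)


def test_canonicalize_reaction_keeps_duplicate_fragments():
    rec = ReactionRecord.make(["CC"], ["CO", "OC"])
    out = canonicalize_reaction(rec)
    assert out.products == ("CO", "CO")


def test_canonicalize_corpus_drops_unlearnable_records():
    good = ReactionRecord.make(["CC"], ["CO"])
    bad = ReactionRecord.make(["CC"], ["C("])
    kept, dropped = canonicalize_corpus([good, bad, good])
    assert dropped == 1 and len(kept) == 2


# ---------------------------------------------------------------------------
# tokenization
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("smiles,expected", [
    ("CC(=O)O", ["C", "C", "(", "=", "O", ")", "O"]),
    ("[C@H]", ["[C@H]"]),
    ("", []),
    ("CCl", ["C", "Cl"]),
    ("CBr", ["C", "Br"]),
    ("C%12CC%12", ["C", "%12", "C", "C", "%12"]),
    ("C[C@@H](O)C", ["C", "[C@@H]", "(", "O", ")", "C"]),
])
def test_tokenize_atomwise(smiles, expected):
    assert list(tokenize(smiles).tokens) == expected


def test_tokenize_reports_position_of_bad_span():
    with pytest.raises(TokenizationError, match="position 1"):
        tokenize("CXC")


def test_detokenize_inverts_tokenize_on_generated_corpora():
    records = generate(ToyGrammarSpec("general", 300, seed=5))
    records += generate(ToyGrammarSpec("specialized", 300, seed=6))
    seen = 0
    for rec in records:
        for frag in rec.precursors + rec.products:
            assert detokenize(tokenize(frag)) == frag
            seen += 1
    assert seen >= 1000


_TOKEN_ALPHABET = ["C", "O", "N", "Cl", "Br", "c", "n", "(", ")", "=", "#",
                   ".", "/", "\\", "@", "1", "2", "9", "%12", "%99",
                   "[C@H]", "[C@@H]", "[nH]", "[O-]"]


@settings(max_examples=150, derandomize=True)
@given(st.lists(st.sampled_from(_TOKEN_ALPHABET), max_size=40))
def test_tokenizer_roundtrip_recovers_token_lists(tokens):
    """Any concatenation of pattern tokens retokenizes to the same list,
    so detokenize is a strict left inverse of tokenize."""
    text = "".join(tokens)
    seq = tokenize(text)
    assert list(seq.tokens) == tokens
    assert detokenize(seq) == text


def test_format_src_tgt_space_separates_single_tokens():
    rec = ReactionRecord.make(["CCO", "CC(=O)Cl"], ["CCOC(C)=O"])
    src, tgt = format_src_tgt(rec)
    assert src.split(" ")[-1] == "Cl"  # two-letter element is one token
    assert src == "C C O . C C ( = O ) Cl"
    assert tgt == "C C O C ( C ) = O"


# ---------------------------------------------------------------------------
# vocabulary
# ---------------------------------------------------------------------------

def test_build_vocab_contains_only_observed_tokens_plus_specials():
    vocab = build_vocab([parse_reaction_line("CC>>CC")])
    assert set(vocab.tokens) == set(Vocabulary.SPECIALS) | {"C"}
    assert ">" not in vocab


def test_vocab_indices_contiguous_with_specials_first():
    vocab = build_vocab([parse_reaction_line("CC(=O)Cl>>CCl")])
    indices = sorted(vocab.token_to_index.values())
    assert indices == list(range(len(vocab)))
    for i, tok in enumerate(Vocabulary.SPECIALS):
        assert vocab.index(tok) == i


def test_general_corpus_vocab_has_no_stereo_tokens():
    vocab = build_vocab(generate(ToyGrammarSpec("general", 400, seed=7)))
    assert not any("@" in t for t in vocab.tokens)
    assert not any(t.startswith("[") for t in vocab.tokens if t not in Vocabulary.SPECIALS)


def test_vocab_encode_strict_raises_on_oov_and_nonstrict_maps_to_unk():
    vocab = Vocabulary(["C", "O"])
    with pytest.raises(KeyError):
        vocab.encode(["C", "N"], strict=True)
    assert vocab.encode(["C", "N"], strict=False)[1] == vocab.unk_index


def test_vocab_save_load_roundtrip(tmp_path):
    vocab = Vocabulary(["C", "O", "[C@H]", "Cl"])
    path = tmp_path / "vocab.txt"
    vocab.save(path)
    assert Vocabulary.load(path) == vocab


def test_record_invariants_reject_bad_fragments():
    with pytest.raises(ValueError):
        ReactionRecord.make([], ["CO"])
    with pytest.raises(ValueError):
        ReactionRecord.make(["C>C"], ["CO"])
    with pytest.raises(ValueError):
        ReactionRecord.make(["C C"], ["CO"])
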