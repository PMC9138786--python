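"""Tokeniser and CBOW embedding tests for the chemical-sequence channel."""

import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ddifuse.smiles import (SmilesVectorizer, TokenizedSmiles,
                            build_drug_matrix, cbow_loss,
                            context_probability, tokenize_smiles,
                            train_cbow)

# independent oracle: regex over the SMILES atom-token grammar
_ATOM_RE = re.compile(r"\[[^\]]*\]|Cl|Br|.")


@pytest.mark.parametrize("smiles,mode,expected", [
    ("CCO", "char", ["C", "C", "O"]),
    ("C(Cl)Br", "atomwise", ["C", "(", "Cl", ")", "Br"]),
    ("C(Cl)Br", "char", ["C", "(", "C", "l", ")", "B", "r"]),
    ("[nH]1ccc1Br", "atomwise", ["[nH]", "1", "c", "c", "c", "1", "Br"]),
])
def test_tokenize_examples(smiles, mode, expected):
    assert tokenize_smiles(smiles, mode=mode).tokens == expected


@settings(max_examples=200, deadline=None)
@given(st.text(alphabet="CNOScnos()=#123ClBr", min_size=1, max_size=40))
def test_atomwise_matches_regex_oracle_and_reconstructs(s):
    toks = tokenize_smiles(s, mode="atomwise").tokens
    assert toks == _ATOM_RE.findall(s)
    assert "".join(toks) == s


@settings(max_examples=100, deadline=None)
@given(st.text(min_size=1, max_size=30))
def test_char_mode_reconstructs_any_text(s):
    assert "".join(tokenize_smiles(s, mode="char").tokens) == s


def test_tokenize_errors():
    with pytest.raises(ValueError, match="empty sequence"):
        tokenize_smiles("")
    with pytest.raises(ValueError, match="position 1"):
        tokenize_smiles("C[nH", mode="atomwise")
    with pytest.raises(ValueError, match="position 0"):
        tokenize_smiles("]C", mode="atomwise")


@pytest.fixture(scope="module")
def tiny_table():
    corpus = [["A", "B", "A", "B", "A", "B"]] * 30
    return train_cbow(corpus, dim=8, window=2, epochs=5, seed=0)


def test_predicted_distribution_normalises(tiny_table):
    p = context_probability(tiny_table, ["A", "B"])
    assert p.shape == (2,)
    assert abs(p.sum() - 1.0) < 1e-6
    assert (p >= 0).all()


def _inout_cosine(table, tok_in, tok_out):
    u = table.input_weights[table.vocab[tok_in]]
    v = table.output_weights[table.vocab[tok_out]]
    return u @ v / (np.linalg.norm(u) * np.linalg.norm(v))


def test_cooccurring_tokens_beat_shuffled_control():
    """Tokens that always co-occur align far above the shuffled baseline.

    CBOW rewards a context token's input vector for pointing along its
    centre neighbour's output vector, so co-occurrence similarity is read
    on the input-output geometry and compared against the mean over
    random token pairs of a shuffled-corpus control run.
    """
    rng = np.random.default_rng(0)
    alphabet = list("DEFGHIJ")
    cos_real, cos_ctrl = [], []
    for rep in range(20):
        sents = []
        for _ in range(40):
            toks = list(rng.choice(alphabet, size=8))
            pos = rng.integers(0, 7)
            toks[pos:pos + 2] = ["A", "B"]       # A and B only co-occur
            sents.append(toks)
        table = train_cbow(sents, dim=8, window=2, epochs=40,
                           batch_size=32, seed=rep)
        cos_real.append(_inout_cosine(table, "A", "B"))
        flat = [t for s in sents for t in s]
        perm = rng.permutation(len(flat))
        shuffled = np.array(flat)[perm].reshape(40, 8).tolist()
        ctrl = train_cbow(shuffled, dim=8, window=2, epochs=40,
                          batch_size=32, seed=rep)
        pairs = [(a, b) for a in ctrl.tokens for b in ctrl.tokens if a < b]
        cos_ctrl.append(np.mean([_inout_cosine(ctrl, a, b)
                                 for a, b in pairs]))
    assert np.mean(cos_real) > np.mean(cos_ctrl)


def test_loss_decreases_on_fixed_corpus():
    rng = np.random.default_rng(3)
    corpus = [list(rng.choice(list("ABCDEFGH"), size=10))
              for _ in range(100)]
    early = train_cbow(corpus, dim=8, window=3, epochs=1, seed=1)
    late = train_cbow(corpus, dim=8, window=3, epochs=15, seed=1)
    assert cbow_loss(late, corpus) <= cbow_loss(early, corpus)


def test_training_is_bit_reproducible():
    corpus = [["A", "B", "C", "A"]] * 20
    t1 = train_cbow(corpus, dim=4, epochs=3, seed=7)
    t2 = train_cbow(corpus, dim=4, epochs=3, seed=7)
    assert np.array_equal(t1.input_weights, t2.input_weights)
    assert np.array_equal(t1.output_weights, t2.output_weights)


def test_train_cbow_errors():
    with pytest.raises(ValueError):
        train_cbow([])
    with pytest.raises(ValueError, match="min_count"):
        train_cbow([["A", "B"]], min_count=5)


class TestDrugMatrix:
    def test_padding_rule(self, tiny_table):
        t = TokenizedSmiles("d", ["A", "B", "A"])
        m = build_drug_matrix(t, tiny_table, L_max=64)
        assert m.shape == (64, 8)
        assert np.array_equal(m[0], tiny_table.vector("A"))
        assert np.array_equal(m[1], tiny_table.vector("B"))
        assert not m[:3].sum() == 0
        assert np.all(m[3:] == 0)

    def test_truncation_rule(self, tiny_table):
        t = TokenizedSmiles("d", ["A", "B"] * 50)   # 100 tokens
        m = build_drug_matrix(t, tiny_table, L_max=64)
        assert m.shape == (64, 8)
        assert np.all(np.abs(m).sum(axis=1) > 0)    # all 64 rows populated

    def test_unknown_tokens_zero(self, tiny_table):
        t = TokenizedSmiles("d", ["X", "Y", "Z"])
        m = build_drug_matrix(t, tiny_table, L_max=16)
        assert np.all(m == 0)

    def test_padding_adds_no_norm(self, tiny_table):
        toks = ["A", "B", "A", "B"]
        m = build_drug_matrix(TokenizedSmiles("d", toks), tiny_table,
                              L_max=32)
        stacked = np.stack([tiny_table.vector(t) for t in toks])
        assert np.isclose(np.linalg.norm(m), np.linalg.norm(stacked))


def test_vectorizer_roundtrip():
    smiles = ["CCO", "C(Cl)Br", "c1ccccc1", "CCNCC"]
    vec = SmilesVectorizer(dim=8, max_len=16, epochs=3, seed=0)
    out = vec.fit(smiles).transform(smiles)
    assert out.shape == (4, 16, 8)
    # same seed, same corpus: identical transform
    out2 = (SmilesVectorizer(dim=8, max_len=16, epochs=3, seed=0)
            .fit(smiles).transform(smiles))
    assert np.array_equal(out, out2)
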