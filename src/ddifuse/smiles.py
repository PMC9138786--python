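"""Chemical-sequence channel: SMILES tokenisation and CBOW token embedding.

A SMILES string is treated as a sentence whose words are chemical symbols.
A continuous bag-of-words (CBOW) model is trained over the corpus of all
drug strings: the hidden vector is the arithmetic mean of the context
tokens' input embeddings, and the negative log-probability of the true
centre token under a full softmax over the vocabulary is minimised by
mini-batch gradient descent.  SMILES vocabularies are tiny (tens of
symbols), so the exact softmax is used throughout — no hierarchical
softmax or negative sampling.

Each drug is then represented by a fixed-shape L_max x d matrix: the first
rows are its token vectors in sequence order, zero-padded (or truncated)
to exactly L_max rows.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

#: two-letter organic-subset elements kept as single tokens in atomwise mode
TWO_CHAR_ELEMENTS = ("Cl", "Br")


@dataclass
class TokenizedSmiles:
    """A SMILES string split into an ordered list of symbol tokens."""

    drug_id: str
    tokens: list[str]

    def __len__(self) -> int:
        return len(self.tokens)


def tokenize_smiles(smiles: str, mode: str = "atomwise",
                    drug_id: str = "") -> TokenizedSmiles:
    """Split a SMILES string into symbol tokens.

    Parameters
    ----------
    smiles : str
        Non-empty SMILES string.
    mode : {"atomwise", "char"}
        ``char`` splits into single characters.  ``atomwise`` keeps bracket
        atoms (``[nH]``) and the two-letter organic-subset halogens
        (``Cl``, ``Br``) as single tokens; every other character is its own
        token.  In both modes concatenating the tokens reconstructs the
        input exactly.

    Raises
    ------
    ValueError
        On an empty string, an unknown mode, or (atomwise) an unbalanced
        square bracket, reported with its position.
    """
    if not smiles:
        raise ValueError("empty sequence")
    if mode == "char":
        return TokenizedSmiles(drug_id, list(smiles))
    if mode != "atomwise":
        raise ValueError(f"unknown tokenizer mode: {mode!r}")

    tokens: list[str] = []
    i, n = 0, len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "[":
            j = smiles.find("]", i + 1)
            if j < 0:
                raise ValueError(f"unbalanced '[' at position {i}")
            tokens.append(smiles[i:j + 1])
            i = j + 1
        elif ch == "]":
            raise ValueError(f"unbalanced ']' at position {i}")
        elif smiles[i:i + 2] in TWO_CHAR_ELEMENTS:
            tokens.append(smiles[i:i + 2])
            i += 2
        else:
            tokens.append(ch)
            i += 1
    return TokenizedSmiles(drug_id, tokens)


@dataclass
class TokenEmbeddingTable:
    """Vocabulary-to-vector map learned by CBOW.

    ``input_weights`` holds one input (context) embedding per vocabulary
    token; ``output_weights`` the output (centre-prediction) embeddings.
    """

    vocab: dict[str, int]
    input_weights: np.ndarray   # (V, d)
    output_weights: np.ndarray  # (V, d)
    window: int = 5
    tokens: list[str] = field(default_factory=list)

    @property
    def dim(self) -> int:
        return self.input_weights.shape[1]

    def vector(self, token: str) -> np.ndarray:
        """Input embedding of ``token``; zero vector if out of vocabulary."""
        idx = self.vocab.get(token)
        if idx is None:
            return np.zeros(self.dim)
        return self.input_weights[idx]


def _as_token_lists(corpus) -> list[list[str]]:
    out = []
    for item in corpus:
        if isinstance(item, TokenizedSmiles):
            out.append(item.tokens)
        else:
            out.append(list(item))
    return out


def context_probability(table: TokenEmbeddingTable,
                        context_tokens) -> np.ndarray:
    """Exact softmax distribution over the vocabulary for one context.

    The hidden vector is the arithmetic mean of the context tokens' input
    embeddings (out-of-vocabulary tokens are dropped); the returned vector
    is ``softmax(output_weights @ h)`` and sums to one.
    """
    idx = [table.vocab[t] for t in context_tokens if t in table.vocab]
    if not idx:
        raise ValueError("no in-vocabulary context tokens")
    h = table.input_weights[idx].mean(axis=0)
    logits = table.output_weights @ h
    logits -= logits.max()
    p = np.exp(logits)
    return p / p.sum()


def _build_examples(sentences: list[list[str]], vocab: dict[str, int],
                    window: int):
    """Centre/context training pairs as padded index arrays."""
    centers: list[int] = []
    ctx_rows: list[list[int]] = []
    for sent in sentences:
        idx = [vocab[t] for t in sent if t in vocab]
        for i in range(len(idx)):
            lo = max(0, i - window)
            ctx = idx[lo:i] + idx[i + 1:i + 1 + window]
            if ctx:
                centers.append(idx[i])
                ctx_rows.append(ctx)
    if not centers:
        return None
    max_c = max(len(c) for c in ctx_rows)
    C = np.zeros((len(centers), max_c), dtype=np.int64)
    mask = np.zeros((len(centers), max_c), dtype=np.float64)
    for r, ctx in enumerate(ctx_rows):
        C[r, :len(ctx)] = ctx
        mask[r, :len(ctx)] = 1.0
    return np.asarray(centers, dtype=np.int64), C, mask


def cbow_loss(table: TokenEmbeddingTable, corpus) -> float:
    """Mean exact-softmax CBOW loss (negative log-likelihood) on a corpus."""
    sentences = _as_token_lists(corpus)
    built = _build_examples(sentences, table.vocab, table.window)
    if built is None:
        raise ValueError("corpus yields no context windows")
    centers, C, mask = built
    counts = mask.sum(axis=1, keepdims=True)
    h = (table.input_weights[C] * mask[:, :, None]).sum(axis=1) / counts
    logits = h @ table.output_weights.T
    logits -= logits.max(axis=1, keepdims=True)
    logZ = np.log(np.exp(logits).sum(axis=1))
    nll = logZ - logits[np.arange(len(centers)), centers]
    return float(nll.mean())


def train_cbow(corpus, dim: int = 64, window: int = 5, min_count: int = 1,
               epochs: int = 10, lr: float = 0.05, batch_size: int = 512,
               seed: int = 0) -> TokenEmbeddingTable:
    """Train a CBOW token-embedding table with an exact softmax output.

    Gradient descent on the mean negative log-probability of the centre
    token given the averaged context, with a learning rate decaying
    linearly to 1% of its initial value.  Bit-reproducible for a fixed
    ``(corpus, seed, epochs)`` in single-threaded mode.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    sentences = _as_token_lists(corpus)
    if not sentences:
        raise ValueError("empty corpus")
    counts = Counter(tok for s in sentences for tok in s)
    tokens = sorted(t for t, c in counts.items() if c >= min_count)
    if not tokens:
        raise ValueError(
            f"no tokens retained at min_count={min_count}")
    vocab = {t: i for i, t in enumerate(tokens)}
    built = _build_examples(sentences, vocab, window)
    if built is None:
        raise ValueError("corpus yields no context windows")
    centers, C, mask = built
    n = len(centers)
    ctx_counts = mask.sum(axis=1, keepdims=True)

    rng = np.random.default_rng(seed)
    V = len(vocab)
    W_in = (rng.random((V, dim)) - 0.5) / dim
    W_out = np.zeros((V, dim))

    steps_per_epoch = math.ceil(n / batch_size)
    total_steps = max(epochs * steps_per_epoch, 1)
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n)
        for s in range(steps_per_epoch):
            rows = order[s * batch_size:(s + 1) * batch_size]
            cur_lr = lr * max(1.0 - step / total_steps, 0.01)
            step += 1
            Cb, Mb = C[rows], mask[rows]
            cnt = ctx_counts[rows]
            h = (W_in[Cb] * Mb[:, :, None]).sum(axis=1) / cnt
            logits = h @ W_out.T
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            p[np.arange(len(rows)), centers[rows]] -= 1.0
            p /= len(rows)
            g_out = p.T @ h
            g_h = p @ W_out
            W_out -= cur_lr * g_out
            # each context token receives g_h / |context|
            contrib = (g_h / cnt)[:, None, :] * Mb[:, :, None]
            np.add.at(W_in, Cb.ravel(),
                      (-cur_lr * contrib).reshape(-1, dim))
    return TokenEmbeddingTable(vocab=vocab, input_weights=W_in,
                               output_weights=W_out, window=window,
                               tokens=tokens)


def build_drug_matrix(t: TokenizedSmiles, table: TokenEmbeddingTable,
                      L_max: int = 64) -> np.ndarray:
    """Stack a drug's token vectors into a fixed L_max x d matrix.

    The first ``min(len, L_max)`` rows are the token vectors in sequence
    order; remaining rows are zero; longer sequences are truncated to the
    first ``L_max`` tokens.  Out-of-vocabulary tokens map to a zero row.
    """
    mat = np.zeros((L_max, table.dim))
    unknown = 0
    for r, tok in enumerate(t.tokens[:L_max]):
        idx = table.vocab.get(tok)
        if idx is None:
            unknown += 1
            continue
        mat[r] = table.input_weights[idx]
    if unknown:
        logger.debug("drug %s: %d unknown token(s) mapped to zero rows",
                     t.drug_id, unknown)
    return mat


class SmilesVectorizer(BaseEstimator, TransformerMixin):
    """CBOW-based SMILES encoder producing fixed-shape drug matrices.

    Parameters
    ----------
    dim : int, default 64
        Token-embedding dimensionality.
    window : int, default 5
        Context half-window (tokens each side of the centre).
    min_count : int, default 1
        Minimum corpus frequency for a token to enter the vocabulary.
    epochs, lr, batch_size :
        CBOW optimisation budget.
    max_len : int, default 64
        Number of rows of the per-drug matrix (pad/truncate length).
    tokenizer : {"atomwise", "char"}, default "atomwise"
    seed : int, default 0

    Attributes
    ----------
    table_ : TokenEmbeddingTable
        The trained vocabulary-to-vector map.
    """

    def __init__(self, dim=64, window=5, min_count=1, epochs=10, lr=0.05,
                 batch_size=512, max_len=64, tokenizer="atomwise", seed=0):
        self.dim = dim
        self.window = window
        self.min_count = min_count
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.max_len = max_len
        self.tokenizer = tokenizer
        self.seed = seed

    def _tokenize_all(self, X) -> list[TokenizedSmiles]:
        return [tokenize_smiles(s, mode=self.tokenizer, drug_id=str(i))
                for i, s in enumerate(X)]

    def fit(self, X, y=None):
        """Train the CBOW table on an iterable of SMILES strings."""
        corpus = self._tokenize_all(X)
        self.table_ = train_cbow(
            corpus, dim=self.dim, window=self.window,
            min_count=self.min_count, epochs=self.epochs, lr=self.lr,
            batch_size=self.batch_size, seed=self.seed)
        return self

    def transform(self, X) -> np.ndarray:
        """Encode SMILES strings as an (n, max_len, dim) array."""
        if not hasattr(self, "table_"):
            raise ValueError("SmilesVectorizer is not fitted")
        mats = [build_drug_matrix(t, self.table_, L_max=self.max_len)
                for t in self._tokenize_all(X)]
        return np.stack(mats) if mats else np.zeros((0, self.max_len,
                                                     self.dim))
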