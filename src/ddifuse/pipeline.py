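"""Experiment orchestration: feature building, splits, CV, ranking.

The order of operations mirrors the evaluation protocol: balanced
negatives are sampled once per experiment, the balanced set is then split
(70/20/10 or into k folds), and for each training portion the interaction
graph — hence the network channel — is rebuilt from that portion's
positive pairs only, so test edges are never seen during feature
construction.  The CBOW table and receptor profiles are drug attributes
and are shared across folds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biosim import build_profiles, euclid_distance, snf_fuse, SimilarityView
from .evaluate import (MetricsReport, compute_metrics, kfold_indices,
                       sample_negatives, summarize_reports)
from .graph import build_graph, embed_or_fallback, harp_embed
from .model import DDIClassifier, DrugFeatures
from .smiles import SmilesVectorizer

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully resolved hyperparameters of one run (written next to outputs)."""

    # chemical-sequence channel
    cbow_dim: int = 64
    cbow_window: int = 5
    cbow_min_count: int = 1
    cbow_epochs: int = 8
    cbow_lr: float = 0.05
    smiles_tokenizer: str = "atomwise"
    max_len: int = 64
    # network-structure channel
    emb_dim: int = 64
    coarsen_threshold: int | None = None
    line_epochs: int = 200
    neg_k: int = 5
    line_lr: float = 0.025
    # biological-function channel
    snf_K: int = 20
    snf_T: int = 20
    snf_mu: float = 0.5
    # fusion model
    hidden: tuple = (256, 128, 64)
    dropout: float = 0.3
    lr: float = 1e-3
    epochs: int = 40
    batch_size: int = 1024
    patience: int = 8
    val_fraction: float = 0.1
    use_attention: bool = True
    channels: tuple = ("chem", "net", "bio")
    # protocol
    protocol: str = "cv5"   # or "split_70_20_10"
    k: int = 5
    threshold: float = 0.5
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hidden"] = list(d["hidden"])
        d["channels"] = list(d["channels"])
        return d

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def classifier_kwargs(self) -> dict:
        return dict(hidden=tuple(self.hidden), dropout=self.dropout,
                    lr=self.lr, epochs=self.epochs,
                    batch_size=self.batch_size, patience=self.patience,
                    val_fraction=self.val_fraction,
                    use_attention=self.use_attention,
                    channels=tuple(self.channels))


def _child_seed(seed: int, *keys: int) -> int:
    """Deterministic sub-seed below 2**31."""
    ss = np.random.SeedSequence([int(seed)] + [int(k) for k in keys])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def canonical_drugs(drugs_df: pd.DataFrame) -> list[str]:
    """Canonical drug ordering: sorted drug_id (shared by all artifacts)."""
    return sorted(drugs_df["drug_id"].astype(str))


def make_balanced_samples(edges_df: pd.DataFrame, drugs: list[str],
                          seed: int = 0):
    """Positive pairs + equally many sampled negatives, as index pairs.

    Returns ``(pairs, labels)`` with ``pairs`` an (n, 2) integer array
    into the canonical drug ordering; positives first.
    """
    index = {d: i for i, d in enumerate(drugs)}
    pos = set()
    for a, b in zip(edges_df["drug_id_a"].astype(str),
                    edges_df["drug_id_b"].astype(str)):
        if a != b:
            pos.add((a, b) if a <= b else (b, a))
    neg = sample_negatives(pos, drugs, seed=seed)
    pos_sorted = sorted(pos)
    neg_sorted = sorted(neg)
    pairs = np.array([[index[a], index[b]]
                      for a, b in pos_sorted + neg_sorted], dtype=np.int64)
    labels = np.concatenate([np.ones(len(pos_sorted)),
                             np.zeros(len(neg_sorted))])
    return pairs, labels


def build_features(drugs_df: pd.DataFrame, train_pos_edges,
                   assoc_df: pd.DataFrame, cfg: RunConfig,
                   seed: int = 0, return_artifacts: bool = False):
    """Compute the three frozen channel inputs for every drug.

    ``train_pos_edges`` is the edge list (id pairs) of the training
    portion's positives; only these enter the interaction graph.
    """
    drugs = canonical_drugs(drugs_df)
    n = len(drugs)
    smiles = (drugs_df.astype({"drug_id": str})
              .set_index("drug_id").loc[drugs, "smiles"].tolist())

    vec = SmilesVectorizer(dim=cfg.cbow_dim, window=cfg.cbow_window,
                           min_count=cfg.cbow_min_count,
                           epochs=cfg.cbow_epochs, lr=cfg.cbow_lr,
                           max_len=cfg.max_len,
                           tokenizer=cfg.smiles_tokenizer,
                           seed=_child_seed(seed, 1))
    chem = vec.fit(smiles).transform(smiles)

    g = build_graph(list(train_pos_edges), node_universe=drugs)
    active = [d for d in drugs if g.degree(d) > 0]
    emb = None
    if len(active) >= 2 and g.number_of_edges() > 0:
        emb = harp_embed(g.subgraph(active).copy(), dim=cfg.emb_dim,
                         threshold=cfg.coarsen_threshold,
                         epochs=cfg.line_epochs, neg_k=cfg.neg_k,
                         lr=cfg.line_lr, seed=_child_seed(seed, 2))
        net = np.array([embed_or_fallback(d, g, emb) for d in drugs])
    else:
        logger.warning("training graph has no edges; network channel zero")
        net = np.zeros((n, cfg.emb_dim))

    assoc_rows = list(zip(assoc_df["drug_id"].astype(str),
                          assoc_df["receptor_id"].astype(str),
                          assoc_df["function_type"].astype(str)))
    profiles = build_profiles(assoc_rows, drugs)
    fused = None
    if profiles:
        views = [SimilarityView(p.function_type, euclid_distance(p))
                 for p in profiles]
        fused = snf_fuse(views, K=cfg.snf_K, T=cfg.snf_T, mu=cfg.snf_mu,
                         drugs=drugs)
        # SNF kernels are row-stochastic with a 1/2 diagonal: the self-
        # similarity entry carries no pair information and dwarfs the rest,
        # and off-diagonal entries scale like 1/N.  Drop the diagonal and
        # rescale to O(1) so the dense reducer starts well-conditioned.
        bio = fused.matrix.copy()
        np.fill_diagonal(bio, 0.0)
        off_mean = bio.mean()
        if off_mean > 0:
            bio = bio / off_mean
    else:
        logger.warning("no receptor associations; biological channel zero")
        bio = np.zeros((n, n))

    feats = DrugFeatures(drugs=drugs, chem=chem, net=net, bio=bio)
    if return_artifacts:
        return feats, {"vectorizer": vec, "graph": g, "embedding": emb,
                       "fused": fused}
    return feats


def _pairs_to_edges(pairs: np.ndarray, labels: np.ndarray,
                    drugs: list[str]) -> list[tuple]:
    """Id edge list of the positive pairs in an index-pair array."""
    return [(drugs[a], drugs[b])
            for (a, b), lab in zip(pairs, labels) if lab == 1]


def train_test_val(drugs_df, edges_df, assoc_df, cfg: RunConfig,
                   seed: int = 0, labels_override=None,
                   return_artifacts: bool = False):
    """The 70/20/10 protocol: one split, one model, one metrics report.

    ``labels_override`` replaces the balanced set's labels (after
    sampling) — used for permutation-null experiments.
    """
    drugs = canonical_drugs(drugs_df)
    pairs, labels = make_balanced_samples(edges_df, drugs,
                                          seed=_child_seed(seed, 10))
    if labels_override is not None:
        labels = np.asarray(labels_override, dtype=np.float64)
        if len(labels) != len(pairs):
            raise ValueError("labels_override length mismatch")
    rng = np.random.default_rng(_child_seed(seed, 11))
    order = rng.permutation(len(pairs))
    n = len(pairs)
    n_train = int(round(0.7 * n))
    n_test = int(round(0.2 * n))
    tr, te, va = (order[:n_train], order[n_train:n_train + n_test],
                  order[n_train + n_test:])
    feats = build_features(
        drugs_df, _pairs_to_edges(pairs[tr], labels[tr], drugs),
        assoc_df, cfg, seed=_child_seed(seed, 12))
    clf = DDIClassifier(features=feats, seed=_child_seed(seed, 13),
                        **cfg.classifier_kwargs())
    clf.fit(pairs[tr], labels[tr], X_val=pairs[va], y_val=labels[va])
    scores = clf.decision_scores(pairs[te])
    report = compute_metrics(labels[te], scores, threshold=cfg.threshold)
    result = {"report": report, "summary": summarize_reports([report]),
              "config": cfg.to_dict(), "protocol": "split_70_20_10"}
    if return_artifacts:
        result.update(model=clf, features=feats, pairs=pairs,
                      labels=labels, split={"train": tr, "test": te,
                                            "val": va})
    return result


def kfold_cv(drugs_df, edges_df, assoc_df, cfg: RunConfig, seed: int = 0,
             k: int | None = None, return_artifacts: bool = False):
    """k-fold cross-validation over the balanced sample set.

    Folds partition the balanced set; each fold's training graph contains
    only that fold's training positives, so its test positives are unseen
    during network embedding.
    """
    k = k or cfg.k
    drugs = canonical_drugs(drugs_df)
    pairs, labels = make_balanced_samples(edges_df, drugs,
                                          seed=_child_seed(seed, 10))
    folds = kfold_indices(len(pairs), k, seed=_child_seed(seed, 11))
    reports: list[MetricsReport] = []
    fold_info = []
    for fi, test_idx in enumerate(folds):
        train_mask = np.ones(len(pairs), dtype=bool)
        train_mask[test_idx] = False
        tr = np.where(train_mask)[0]
        if len(np.unique(labels[test_idx])) < 2:
            raise ValueError(f"fold {fi} contains a single class")
        train_edges = _pairs_to_edges(pairs[tr], labels[tr], drugs)
        feats = build_features(drugs_df, train_edges, assoc_df, cfg,
                               seed=_child_seed(seed, 20, fi))
        clf = DDIClassifier(features=feats,
                            seed=_child_seed(seed, 21, fi),
                            **cfg.classifier_kwargs())
        clf.fit(pairs[tr], labels[tr])
        scores = clf.decision_scores(pairs[test_idx])
        reports.append(compute_metrics(labels[test_idx], scores,
                                       threshold=cfg.threshold))
        fold_info.append({"test_idx": test_idx, "train_idx": tr,
                          "train_edges": train_edges})
    result = {"folds": [r.as_dict() for r in reports],
              "summary": summarize_reports(reports),
              "config": cfg.to_dict(), "protocol": f"cv{k}"}
    if return_artifacts:
        result.update(reports=reports, pairs=pairs, labels=labels,
                      fold_info=fold_info, drugs=drugs)
    return result


def rank_candidates(model: DDIClassifier, features: DrugFeatures,
                    query_drug: str, exclude=(),
                    top: int | None = None) -> pd.DataFrame:
    """Score and rank all non-excluded partners of a query drug.

    ``exclude`` is an iterable of known pairs (either ids or id pairs
    involving the query); the returned frame is sorted by descending
    score with 1-based ranks.
    """
    if query_drug not in features.index:
        raise ValueError(f"unknown query drug {query_drug!r}")
    qi = features.index[query_drug]
    excluded_partners = set()
    for item in exclude:
        if isinstance(item, str):
            excluded_partners.add(item)
        else:
            a, b = item
            if a == query_drug:
                excluded_partners.add(b)
            elif b == query_drug:
                excluded_partners.add(a)
    partners = [d for d in features.drugs
                if d != query_drug and d not in excluded_partners]
    if not partners:
        return pd.DataFrame(columns=["rank", "partner", "score"])
    X = np.array([[qi, features.index[d]] for d in partners])
    scores = model.decision_scores(X)
    order = np.argsort(-scores, kind="stable")
    df = pd.DataFrame({
        "rank": np.arange(1, len(partners) + 1),
        "partner": [partners[i] for i in order],
        "score": scores[order],
    })
    if top is not None:
        df = df.head(top)
    return df


def permutation_null_run(drugs_df, edges_df, assoc_df, cfg: RunConfig,
                         seed: int = 0):
    """Run the 70/20/10 protocol with labels shuffled over the balanced set.

    Destroys any pair-label association while preserving class balance;
    the held-out AUC of a sound pipeline is then compatible with chance.
    """
    from .synthetic import gen_null_labels
    drugs = canonical_drugs(drugs_df)
    _, labels = make_balanced_samples(edges_df, drugs,
                                      seed=_child_seed(seed, 10))
    null = gen_null_labels(labels, seed=_child_seed(seed, 99))
    return train_test_val(drugs_df, edges_df, assoc_df, cfg, seed=seed,
                          labels_override=null)


def ablation_experiment(drugs_df, edges_df, assoc_df, cfg: RunConfig,
                        seed: int = 0, arms=None) -> dict:
    """Held-out AUC per ablation arm on one shared split and feature set.

    Channel-ablation arms run without attention (so channel contributions
    are compared on equal footing); the attention arm is compared against
    the same all-channel configuration without attention.
    """
    if arms is None:
        arms = {
            "full_attention": {"use_attention": True,
                               "channels": ("chem", "net", "bio")},
            "full_plain": {"use_attention": False,
                           "channels": ("chem", "net", "bio")},
            "no_chem": {"use_attention": False, "channels": ("net", "bio")},
            "no_net": {"use_attention": False, "channels": ("chem", "bio")},
            "no_bio": {"use_attention": False, "channels": ("chem", "net")},
        }
    drugs = canonical_drugs(drugs_df)
    pairs, labels = make_balanced_samples(edges_df, drugs,
                                          seed=_child_seed(seed, 10))
    rng = np.random.default_rng(_child_seed(seed, 11))
    order = rng.permutation(len(pairs))
    n = len(pairs)
    n_train = int(round(0.7 * n))
    n_test = int(round(0.2 * n))
    tr, te, va = (order[:n_train], order[n_train:n_train + n_test],
                  order[n_train + n_test:])
    feats = build_features(
        drugs_df, _pairs_to_edges(pairs[tr], labels[tr], drugs),
        assoc_df, cfg, seed=_child_seed(seed, 12))
    out = {}
    for name, overrides in arms.items():
        kwargs = cfg.classifier_kwargs()
        kwargs.update(overrides)
        clf = DDIClassifier(features=feats, seed=_child_seed(seed, 13),
                            **kwargs)
        clf.fit(pairs[tr], labels[tr], X_val=pairs[va], y_val=labels[va])
        scores = clf.decision_scores(pairs[te])
        out[name] = compute_metrics(labels[te], scores,
                                    threshold=cfg.threshold)
    return out
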