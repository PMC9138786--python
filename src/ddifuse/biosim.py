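"""Biological-function channel: receptor profiles, distances, SNF fusion.

Each receptor function type (carrier, target, enzyme, transporter, ...)
yields a binary drug x receptor incidence matrix.  Pairwise Euclidean
distances between profile rows give one distance view per type; distances
are converted to affinities with the scaled-exponential kernel of
similarity network fusion (local scale from K-nearest-neighbour mean
distances, bandwidth mu) and the views are merged by T rounds of SNF
cross-diffusion into a single N x N consensus similarity matrix.  A drug's
biological-function descriptor is its row of the fused matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist


@dataclass
class ReceptorProfile:
    """Binary drug-receptor incidence matrix for one function type."""

    function_type: str
    drugs: list[str]
    receptors: list[str]
    matrix: np.ndarray  # (N, R) in {0, 1}

    @property
    def n_receptors(self) -> int:
        return self.matrix.shape[1]


@dataclass
class SimilarityView:
    """One function type's pairwise distance (and optional affinity)."""

    function_type: str
    dist: np.ndarray
    affinity: np.ndarray | None = None


@dataclass
class FusedSimilarity:
    """SNF consensus similarity over the canonical drug ordering."""

    matrix: np.ndarray
    drugs: list[str]
    views_used: int
    params: dict = field(default_factory=dict)
    index: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {d: i for i, d in enumerate(self.drugs)}


def build_profiles(associations, drugs, types=None) -> list[ReceptorProfile]:
    """Binary N x R profile per function type from (drug, receptor, type) rows.

    Drugs with no association of a type get an all-zero row; duplicate
    associations are idempotent; a type with no receptors is skipped with
    a warning.  Associations naming a drug outside ``drugs`` raise an
    error listing the offenders.
    """
    drugs = list(drugs)
    idx = {d: i for i, d in enumerate(drugs)}
    rows = [tuple(a) for a in associations]
    unknown = sorted({d for d, _, _ in rows if d not in idx})
    if unknown:
        raise ValueError(f"associations name unknown drugs: {unknown}")
    if types is None:
        types = sorted({t for _, _, t in rows})
    profiles = []
    for t in types:
        recs = sorted({r for _, r, tt in rows if tt == t})
        if not recs:
            warnings.warn(f"function type {t!r} has no receptors; skipped")
            continue
        ridx = {r: j for j, r in enumerate(recs)}
        M = np.zeros((len(drugs), len(recs)), dtype=np.uint8)
        for d, r, tt in rows:
            if tt == t:
                M[idx[d], ridx[r]] = 1
        profiles.append(ReceptorProfile(function_type=t, drugs=drugs,
                                        receptors=recs, matrix=M))
    return profiles


def euclid_distance(p: ReceptorProfile) -> np.ndarray:
    """Pairwise Euclidean distance between profile rows (symmetric, zero
    diagonal)."""
    if p.matrix.shape[0] < 2:
        return np.zeros((p.matrix.shape[0],) * 2)
    return squareform(pdist(p.matrix.astype(np.float64), metric="euclidean"))


def affinity_from_distance(dist: np.ndarray, K: int = 20,
                           mu: float = 0.5) -> np.ndarray:
    """Scaled-exponential affinity kernel with local K-NN bandwidth.

    W_ij = exp(-d_ij^2 / (mu * eps_ij)) with
    eps_ij = (mean_knn(i) + mean_knn(j) + d_ij) / 3, the K-NN means taken
    over each row's K smallest off-diagonal distances.
    """
    n = dist.shape[0]
    K = min(K, n - 1)
    d = np.asarray(dist, dtype=np.float64)
    sorted_d = np.sort(d, axis=1)
    # column 0 is the zero self-distance
    T = sorted_d[:, 1:K + 1].mean(axis=1)
    eps = (T[:, None] + T[None, :] + d) / 3.0
    eps = np.maximum(eps, 1e-12)
    W = np.exp(-(d ** 2) / (mu * eps))
    return (W + W.T) / 2.0


def _p_normalize(W: np.ndarray) -> np.ndarray:
    """Full-kernel normalisation: off-diagonal mass 1/2, diagonal 1/2.

    Rows sum to one exactly, which keeps the diffusion a stochastic
    operation.
    """
    n = W.shape[0]
    off = W - np.diag(np.diag(W))
    rowsum = off.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    P = off / (2.0 * rowsum)
    P[np.arange(n), np.arange(n)] = 0.5
    return P


def _knn_kernel(W: np.ndarray, K: int) -> np.ndarray:
    """Row-normalised K-nearest-neighbour sparse kernel S."""
    n = W.shape[0]
    K = min(K, n - 1)
    S = np.zeros_like(W)
    off = W - np.diag(np.diag(W))
    for i in range(n):
        order = np.argsort(off[i])[::-1][:K]
        S[i, order] = off[i, order]
    rowsum = S.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    return S / rowsum


def snf_fuse(views, K: int = 20, T: int = 20, mu: float = 0.5,
             drugs=None) -> FusedSimilarity:
    """Fuse M distance views into one consensus similarity matrix.

    Per view: full normalised kernel P_v and K-NN sparse kernel S_v; then
    T rounds of cross-diffusion ``P_v <- S_v @ mean(P_other) @ S_v.T``
    followed by row renormalisation; with a single view the diffusion runs
    against the view itself (the M-identical-copies fixed point).  The
    output is the symmetrised mean of the final P_v.
    """
    views = list(views)
    if not views:
        raise ValueError("snf_fuse requires at least one view")
    n = views[0].dist.shape[0]
    for v in views:
        if v.dist.shape != (n, n):
            raise ValueError("all views must be N x N over the same drugs")
    if K >= n:
        warnings.warn(f"K={K} >= N={n}; clamped to N-1")
        K = n - 1
    Ws = []
    for v in views:
        if v.affinity is None:
            v.affinity = affinity_from_distance(v.dist, K=K, mu=mu)
        Ws.append(v.affinity)
    Ps = [_p_normalize(W) for W in Ws]
    Ss = [_knn_kernel(W, K) for W in Ws]
    M = len(views)
    for _ in range(T):
        new = []
        for vi in range(M):
            if M == 1:
                Pbar = Ps[0]
            else:
                Pbar = sum(Ps[vj] for vj in range(M) if vj != vi) / (M - 1)
            Pn = Ss[vi] @ Pbar @ Ss[vi].T
            new.append(_p_normalize(Pn))
        Ps = new
    fused = sum(Ps) / M
    fused = (fused + fused.T) / 2.0
    if drugs is None:
        drugs = [str(i) for i in range(n)]
    return FusedSimilarity(matrix=fused, drugs=list(drugs), views_used=M,
                           params={"K": K, "T": T, "mu": mu})


def bio_feature(fused: FusedSimilarity, drug) -> np.ndarray:
    """The drug's row of the fused matrix (zero vector for unknown drugs)."""
    i = fused.index.get(drug)
    if i is None:
        warnings.warn(f"drug {drug!r} not in fused similarity; zero vector")
        return np.zeros(fused.matrix.shape[0])
    return fused.matrix[i].copy()


class SimilarityNetworkFusion:
    """Estimator wrapper: receptor profiles in, fused similarity out.

    ``fit`` accepts a list of :class:`ReceptorProfile` (or raw N x N
    distance matrices) and stores the consensus matrix as ``fused_``.
    """

    def __init__(self, K=20, T=20, mu=0.5):
        self.K = K
        self.T = T
        self.mu = mu

    def get_params(self, deep=True):
        return {"K": self.K, "T": self.T, "mu": self.mu}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y=None, drugs=None):
        views = []
        for item in X:
            if isinstance(item, ReceptorProfile):
                views.append(SimilarityView(item.function_type,
                                            euclid_distance(item)))
                if drugs is None:
                    drugs = item.drugs
            else:
                views.append(SimilarityView("view%d" % len(views),
                                            np.asarray(item, dtype=float)))
        self.fused_ = snf_fuse(views, K=self.K, T=self.T, mu=self.mu,
                               drugs=drugs)
        return self

    def transform(self, drug_ids) -> np.ndarray:
        if not hasattr(self, "fused_"):
            raise ValueError("SimilarityNetworkFusion is not fitted")
        return np.array([bio_feature(self.fused_, d) for d in drug_ids])
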