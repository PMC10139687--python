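"""TF-IDF vectors, spherical k-means, elbow selection, cosine/MDS geometry.

TF-IDF uses the unsmoothed definition weight(d, w) = tf(d, w) * ln(N / df(w)),
so a word present in every document gets weight 0 everywhere.  Cosine
k-means is realized as Euclidean k-means on L2-normalized rows (the
standard spherical-k-means equivalence); the best of ``n_restarts`` random
initializations by sum of squared distances (SSE) is kept.  The elbow
rule is formalized as the smallest k whose relative SSE decrease to k+1
falls below a threshold (default 0.15).  The 2-D embedding is classical
(Torgerson) metric MDS of the cosine-distance matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.metrics.pairwise import cosine_similarity
from sklearn.preprocessing import normalize

from .preprocess import ProcessedDoc

logger = logging.getLogger(__name__)


@dataclass
class TfidfMatrix:
    """Sparse document x stem matrix of tf * ln(N/df) weights."""

    matrix: sp.csr_matrix
    vocabulary: list[str]
    doc_ids: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


@dataclass
class ClusteringResult:
    k: int
    assignments: dict[str, int]
    centroids: np.ndarray  # k x vocab, unit-norm rows
    sse: float


def tfidf_matrix(corpus: Sequence[ProcessedDoc]) -> TfidfMatrix:
    """Vectorize *corpus* with raw term counts scaled by ln(N/df).

    N counts all documents in the corpus (including empty ones, which
    contribute all-zero rows); df(w) is the number of documents containing
    w at least once.  No smoothing and no row normalization is applied —
    normalization for cosine geometry happens in the consumers.
    """
    if not corpus:
        raise ValueError("corpus is empty")
    if all(not doc.tokens for doc in corpus):
        raise ValueError("all documents are empty after preprocessing")
    vocab = sorted({t for doc in corpus for t in doc.tokens})
    col = {w: j for j, w in enumerate(vocab)}
    n_docs = len(corpus)
    rows, cols, data = [], [], []
    df = np.zeros(len(vocab))
    for i, doc in enumerate(corpus):
        counts: dict[str, int] = {}
        for t in doc.tokens:
            counts[t] = counts.get(t, 0) + 1
        for w, c in counts.items():
            rows.append(i)
            cols.append(col[w])
            data.append(float(c))
            df[col[w]] += 1
    idf = np.log(n_docs / df)
    mat = sp.csr_matrix((data, (rows, cols)),
                        shape=(n_docs, len(vocab)))
    mat = mat.multiply(idf[None, :]).tocsr()
    mat.eliminate_zeros()
    return TfidfMatrix(mat, vocab, [doc.video_id for doc in corpus])


def kmeans_cluster(tfidf: TfidfMatrix, k: int, n_restarts: int = 10,
                   seed: int = 0) -> ClusteringResult:
    """Best-of-restarts k-means on L2-normalized TF-IDF rows.

    Documents whose vector is all-zero (empty or stop-word-only text, or
    text made solely of corpus-universal words) are excluded from
    clustering and logged; they do not receive an assignment.
    """
    norms = np.asarray(tfidf.matrix.multiply(tfidf.matrix).sum(axis=1)).ravel()
    usable = np.where(norms > 0)[0]
    if len(usable) < len(tfidf.doc_ids):
        logger.warning("excluding %d all-zero documents from clustering",
                       len(tfidf.doc_ids) - len(usable))
    if not 1 <= k <= len(usable):
        raise ValueError(
            f"k={k} outside [1, {len(usable)}] usable documents")
    X = normalize(tfidf.matrix[usable])
    km = KMeans(n_clusters=k, n_init=n_restarts, init="random",
                random_state=seed & 0x7FFFFFFF)
    labels = km.fit_predict(X)
    centroids = normalize(km.cluster_centers_)
    assignments = {tfidf.doc_ids[i]: int(lab)
                   for i, lab in zip(usable, labels)}
    return ClusteringResult(k, assignments, centroids, float(km.inertia_))


def sse_curve(tfidf: TfidfMatrix, k_min: int = 1, k_max: int = 10,
              n_restarts: int = 10, seed: int = 0) -> dict[int, float]:
    """SSE of the best restart for each k in [k_min, k_max]."""
    return {k: kmeans_cluster(tfidf, k, n_restarts, seed).sse
            for k in range(k_min, k_max + 1)}


def elbow_select_k(sse_by_k: Mapping[int, float],
                   rel_threshold: float = 0.15) -> int:
    """First k at which the SSE curve stabilizes.

    Returns the smallest k with (sse[k] - sse[k+1]) / sse[k] below
    *rel_threshold*, i.e. the first point where adding a cluster no longer
    buys a meaningful SSE reduction; if no k stabilizes, returns the
    largest k evaluated.  Requires SSE for consecutive k starting at 1.
    """
    ks = sorted(sse_by_k)
    if len(ks) < 3:
        raise ValueError("need SSE for at least 3 values of k")
    if ks != list(range(1, len(ks) + 1)):
        raise ValueError("sse_by_k must cover consecutive k starting at 1")
    for k in ks[:-1]:
        sse_k = sse_by_k[k]
        if sse_k <= 0:
            return k
        rel = (sse_k - sse_by_k[k + 1]) / sse_k
        if rel < rel_threshold:
            return k
    return ks[-1]


def cosine_similarity_matrix(tfidf: TfidfMatrix | np.ndarray | sp.spmatrix
                             ) -> np.ndarray:
    """Pairwise cosine similarity; all-zero rows get similarity 0."""
    X = tfidf.matrix if isinstance(tfidf, TfidfMatrix) else tfidf
    if sp.issparse(X):
        norms = np.asarray(X.multiply(X).sum(axis=1)).ravel()
    else:
        X = np.asarray(X, dtype=float)
        norms = (X * X).sum(axis=1)
    nonzero = norms > 0
    if not nonzero.all():
        logger.warning("%d all-zero rows receive similarity 0",
                       int((~nonzero).sum()))
    S = cosine_similarity(X)
    S = np.clip(S, 0.0, 1.0)
    idx = np.where(nonzero)[0]
    S[idx, idx] = 1.0
    S = (S + S.T) / 2.0
    return S


def mds_embed(distances: np.ndarray) -> np.ndarray:
    """Classical (Torgerson) MDS of a distance matrix into 2 dimensions.

    Double-centers the squared distances, takes the top-2 eigenpairs and
    scales eigenvectors by the square root of their (non-negative part of
    the) eigenvalues.  Output is deterministic: each coordinate column's
    largest-magnitude entry is made positive, which fixes the sign
    ambiguity (rotation within ties remains arbitrary, as for any MDS).
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D ** 2) @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1][:2]
    lam = np.clip(eigvals[order], 0.0, None)
    X = eigvecs[:, order] * np.sqrt(lam)[None, :]
    for j in range(X.shape[1]):
        i = int(np.argmax(np.abs(X[:, j])))
        if X[i, j] < 0:
            X[:, j] = -X[:, j]
    return X


def mds_stress(distances: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal-style raw stress of an embedding against input distances."""
    D = np.asarray(distances, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    E = np.sqrt((diff ** 2).sum(axis=-1))
    denom = (D ** 2).sum()
    if denom == 0:
        return 0.0
    return float(math.sqrt(((E - D) ** 2).sum() / denom))
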