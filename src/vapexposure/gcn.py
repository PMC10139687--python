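"""Heterogeneous text-graph construction and 2-layer GCN classification.

The corpus is modeled as a single 2-mode graph: one node per document
(video) and one node per unique stem.  Document-word edges are weighted
by TF-IDF (same unsmoothed formula as the clustering stage); word-word
edges by positive pointwise mutual information (PMI) over fixed-length
sliding windows across the corpus; every node carries a unit self-loop.
With the feature matrix fixed to the identity (every node a one-hot
vector), a two-layer graph convolution

    Z = softmax( A_hat · relu(A_hat · W0) · W1 ),   A_hat = D^-1/2 (A) D^-1/2

propagates label information from the labeled document nodes through
shared words to unlabeled documents.  Training is full-batch Adam on the
cross-entropy of labeled documents with early stopping on a validation
split; everything is seeded and deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .cluster import TfidfMatrix, tfidf_matrix
from .preprocess import ProcessedDoc
from .synth import THEMES

logger = logging.getLogger(__name__)


@dataclass
class TextGraph:
    """2-mode word/document graph.

    Node order in the adjacency is documents first (in corpus order), then
    words (in vocabulary order).
    """

    doc_ids: list[str]
    words: list[str]
    doc_word: sp.csr_matrix      # n_docs x n_words, TF-IDF weights
    word_word: sp.csr_matrix     # n_words x n_words, positive PMI, zero diag

    @property
    def n_docs(self) -> int:
        return len(self.doc_ids)

    @property
    def n_words(self) -> int:
        return len(self.words)

    @property
    def n_nodes(self) -> int:
        return self.n_docs + self.n_words

    def adjacency(self, include_word_word: bool = True) -> sp.csr_matrix:
        """Full symmetric adjacency with unit self-loops on every node."""
        ww = self.word_word if include_word_word else \
            sp.csr_matrix((self.n_words, self.n_words))
        A = sp.bmat([
            [sp.identity(self.n_docs, format="csr"), self.doc_word],
            [self.doc_word.T, ww + sp.identity(self.n_words, format="csr")],
        ], format="csr")
        return A


@dataclass
class GcnConfig:
    hidden_dim: int = 200
    window: int = 20
    learning_rate: float = 0.02
    epochs: int = 200
    patience: int = 10
    weight_decay: float = 5e-4
    label_fraction: float = 0.6
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.hidden_dim < 1 or self.epochs < 1:
            raise ValueError("hidden_dim and epochs must be positive")
        if self.window < 2:
            raise ValueError(f"window must be >= 2, got {self.window}")
        if not 0.0 < self.label_fraction <= 1.0:
            raise ValueError("label_fraction must lie in (0, 1]")
        if self.val_fraction < 0 or \
                self.label_fraction + self.val_fraction > 1.0:
            raise ValueError("label and validation fractions must sum to <= 1")


def _window_counts(corpus: Sequence[ProcessedDoc], vocab_index: Mapping[str, int],
                   window: int) -> tuple[sp.csr_matrix, int]:
    """Binary window x word incidence matrix over all sliding windows."""
    rows, cols = [], []
    n_windows = 0
    for doc in corpus:
        idx = np.array([vocab_index[t] for t in doc.tokens], dtype=np.int64)
        L = len(idx)
        if L == 0:
            continue
        if L <= window:
            rows.append(np.full(L, n_windows, dtype=np.int64))
            cols.append(idx)
            n_windows += 1
        else:
            n_w = L - window + 1
            offsets = np.arange(n_w)[:, None] + np.arange(window)[None, :]
            rows.append((np.arange(n_w)[:, None] + n_windows)
                        .repeat(window, axis=1).ravel())
            cols.append(idx[offsets].ravel())
            n_windows += n_w
    if n_windows == 0:
        raise ValueError("corpus has no non-empty documents")
    data = np.ones(sum(len(r) for r in rows))
    B = sp.csr_matrix(
        (data, (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_windows, len(vocab_index)))
    B.data[:] = 1.0  # binarize duplicate within-window occurrences
    return B, n_windows


def pmi_word_graph(corpus: Sequence[ProcessedDoc], vocabulary: Sequence[str],
                   window: int = 20) -> sp.csr_matrix:
    """Positive-PMI word-word weights over sliding co-occurrence windows.

    PMI(i, j) = ln( #W(i,j) * #W / (#W(i) * #W(j)) ) with #W the number of
    windows; only strictly positive values are kept, and the diagonal is
    dropped.
    """
    vocab_index = {w: i for i, w in enumerate(vocabulary)}
    B, n_windows = _window_counts(corpus, vocab_index, window)
    pair = (B.T @ B).tocoo()  # pair counts; diagonal = single-word counts
    occ = np.asarray(B.sum(axis=0)).ravel()
    i, j, c = pair.row, pair.col, pair.data
    off = i != j
    i, j, c = i[off], j[off], c[off]
    pmi = np.log(c * n_windows / (occ[i] * occ[j]))
    keep = pmi > 0
    n = len(vocabulary)
    W = sp.csr_matrix((pmi[keep], (i[keep], j[keep])), shape=(n, n))
    return W


def build_text_graph(corpus: Sequence[ProcessedDoc],
                     window: int = 20) -> TextGraph:
    """Assemble the document/word graph from a preprocessed corpus."""
    if not corpus:
        raise ValueError("corpus is empty")
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    tfidf = tfidf_matrix(corpus)
    word_word = pmi_word_graph(corpus, tfidf.vocabulary, window)
    return TextGraph(doc_ids=list(tfidf.doc_ids),
                     words=list(tfidf.vocabulary),
                     doc_word=tfidf.matrix.tocsr(),
                     word_word=word_word)


def normalize_adjacency(graph: TextGraph | sp.spmatrix,
                        include_word_word: bool = True) -> sp.csr_matrix:
    """Symmetric normalization D^-1/2 A D^-1/2 of the self-looped adjacency."""
    A = graph.adjacency(include_word_word) if isinstance(graph, TextGraph) \
        else sp.csr_matrix(graph)
    deg = np.asarray(A.sum(axis=1)).ravel()
    assert (deg > 0).all(), "self-loops guarantee positive degree"
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    D = sp.diags(d_inv_sqrt)
    return (D @ A @ D).tocsr()


@dataclass
class GcnModel:
    W0: np.ndarray
    W1: np.ndarray
    classes: tuple[str, ...]
    doc_ids: list[str]
    train_ids: list[str]
    val_ids: list[str]
    history: dict = field(default_factory=dict)

    def propagate(self, A_hat: sp.csr_matrix) -> np.ndarray:
        """Class-probability matrix over all nodes."""
        H1 = np.maximum(A_hat @ self.W0, 0.0)
        Z = A_hat @ (H1 @ self.W1)
        Z -= Z.max(axis=1, keepdims=True)
        P = np.exp(Z)
        P /= P.sum(axis=1, keepdims=True)
        return P


def stratified_split(labels: Mapping[str, str], train_frac: float,
                     val_frac: float, seed: int,
                     classes: Sequence[str] = THEMES
                     ) -> tuple[list[str], list[str], list[str]]:
    """Seeded stratified train/validation/test split of labeled doc ids."""
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    train, val, test = [], [], []
    for c in classes:
        ids = sorted(d for d, y in labels.items() if y == c)
        if not ids:
            continue
        rng.shuffle(ids)
        n_train = max(1, round(train_frac * len(ids)))
        n_val = round(val_frac * len(ids))
        train.extend(ids[:n_train])
        val.extend(ids[n_train:n_train + n_val])
        test.extend(ids[n_train + n_val:])
    return train, val, test


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def train_gcn(graph: TextGraph, labels: Mapping[str, str],
              config: GcnConfig | None = None) -> GcnModel:
    """Train the 2-layer GCN on a partially labeled document set.

    *labels* maps a subset of ``graph.doc_ids`` to theme labels; it is
    split stratified-by-class into ``label_fraction`` training,
    ``val_fraction`` validation and the remainder test (the model records
    the split; evaluation helpers use it).  Raises if any theme class has
    no training document.
    """
    config = config or GcnConfig()
    doc_pos = {d: i for i, d in enumerate(graph.doc_ids)}
    unknown = set(labels) - set(doc_pos)
    if unknown:
        raise ValueError(f"labels refer to unknown documents: "
                         f"{sorted(unknown)[:5]}")
    classes = THEMES if set(labels.values()) <= set(THEMES) \
        else tuple(sorted(set(labels.values())))
    train_ids, val_ids, test_ids = stratified_split(
        labels, config.label_fraction, config.val_fraction, config.seed,
        classes)
    present = {labels[d] for d in train_ids}
    missing = [c for c in classes if c not in present]
    if missing:
        raise ValueError(
            f"no training documents for class(es): {', '.join(missing)}")

    A_hat = normalize_adjacency(graph)
    n = graph.n_nodes
    cls_index = {c: k for k, c in enumerate(classes)}
    train_idx = np.array([doc_pos[d] for d in train_ids])
    y_train = np.array([cls_index[labels[d]] for d in train_ids])
    val_idx = np.array([doc_pos[d] for d in val_ids])
    y_val = np.array([cls_index[labels[d]] for d in val_ids])

    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 7])
    W0 = _glorot(rng, n, config.hidden_dim)
    W1 = _glorot(rng, config.hidden_dim, len(classes))

    # Adam state
    m0 = np.zeros_like(W0); v0 = np.zeros_like(W0)
    m1 = np.zeros_like(W1); v1 = np.zeros_like(W1)
    b1, b2, eps = 0.9, 0.999, 1e-8

    def forward(W0, W1):
        pre = A_hat @ W0
        H1 = np.maximum(pre, 0.0)
        M = A_hat @ H1
        Z = M @ W1
        Zs = Z - Z.max(axis=1, keepdims=True)
        P = np.exp(Zs)
        P /= P.sum(axis=1, keepdims=True)
        return pre, H1, M, P

    def ce(P, idx, y):
        if len(idx) == 0:
            return 0.0
        return float(-np.mean(np.log(P[idx, y] + 1e-12)))

    best = {"val": np.inf, "W0": W0.copy(), "W1": W1.copy(), "epoch": 0}
    bad_epochs = 0
    history = {"train_loss": [], "val_loss": []}
    for epoch in range(1, config.epochs + 1):
        pre, H1, M, P = forward(W0, W1)
        train_loss = ce(P, train_idx, y_train)
        val_loss = ce(P, val_idx, y_val) if len(val_idx) else train_loss
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)

        dZ = np.zeros_like(P)
        dZ[train_idx] = P[train_idx]
        dZ[train_idx, y_train] -= 1.0
        dZ /= len(train_idx)
        dW1 = M.T @ dZ
        dH1 = A_hat @ (dZ @ W1.T)   # A_hat is symmetric
        dH1[pre <= 0] = 0.0
        dW0 = A_hat @ dH1 + config.weight_decay * W0

        t = epoch
        for W, dW, mom, vel in ((W0, dW0, m0, v0), (W1, dW1, m1, v1)):
            mom *= b1; mom += (1 - b1) * dW
            vel *= b2; vel += (1 - b2) * dW * dW
            m_hat = mom / (1 - b1 ** t)
            v_hat = vel / (1 - b2 ** t)
            W -= config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)

        if val_loss < best["val"] - 1e-6:
            best = {"val": val_loss, "W0": W0.copy(), "W1": W1.copy(),
                    "epoch": epoch}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                logger.info("early stop at epoch %d (best %d)",
                            epoch, best["epoch"])
                break

    history["stopped_epoch"] = len(history["train_loss"])
    history["best_epoch"] = best["epoch"]
    return GcnModel(W0=best["W0"], W1=best["W1"], classes=tuple(classes),
                    doc_ids=list(graph.doc_ids), train_ids=train_ids,
                    val_ids=val_ids, history=history)


def classify(model: GcnModel, graph: TextGraph
             ) -> tuple[dict[str, str], dict[str, np.ndarray]]:
    """Predicted theme (and class probabilities) for every document node.

    Ties in the probability row break toward the lowest class index via
    argmax.  Raises if *graph* is not the graph the model was trained on.
    """
    if graph.doc_ids != model.doc_ids or \
            model.W0.shape[0] != graph.n_nodes:
        raise ValueError("graph does not match the model's training graph")
    A_hat = normalize_adjacency(graph)
    P = model.propagate(A_hat)
    preds, probs = {}, {}
    for i, d in enumerate(graph.doc_ids):
        row = P[i]
        preds[d] = model.classes[int(np.argmax(row))]
        probs[d] = row
    return preds, probs


def write_edgelist(graph: TextGraph, path) -> None:
    """Serialize the graph as a weighted edge list.

    Columns: node_type_a, node_a, node_type_b, node_b, weight, kind —
    one line per doc-word and word-word edge (self-loops implicit).
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_type_a,node_a,node_type_b,node_b,weight,kind\n")
        dw = graph.doc_word.tocoo()
        for i, j, w in zip(dw.row, dw.col, dw.data):
            fh.write(f"doc,{graph.doc_ids[i]},word,{graph.words[j]},"
                     f"{w:.6f},doc_word\n")
        ww = graph.word_word.tocoo()
        for i, j, w in zip(ww.row, ww.col, ww.data):
            if i < j:
                fh.write(f"word,{graph.words[i]},word,{graph.words[j]},"
                         f"{w:.6f},word_word\n")


def evaluate_split(model: GcnModel, graph: TextGraph,
                   labels: Mapping[str, str]) -> dict[str, float]:
    """Accuracy on the model's train/validation/test partitions of *labels*."""
    preds, _ = classify(model, graph)
    held = set(model.train_ids) | set(model.val_ids)
    test_ids = [d for d in labels if d not in held]

    def acc(ids):
        if not ids:
            return float("nan")
        return float(np.mean([preds[d] == labels[d] for d in ids]))

    return {"train_accuracy": acc(model.train_ids),
            "val_accuracy": acc(model.val_ids),
            "test_accuracy": acc(test_ids),
            "n_test": len(test_ids)}
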