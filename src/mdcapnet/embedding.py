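"""Random-walk graph embeddings (node2vec-style).

Biased second-order random walks (return parameter ``p``, in-out parameter
``q``) generate node sequences; a skip-gram objective with negative sampling
maximizes sum_u log Pr(N_S(u) | f(u)) over the walk corpus, yielding one
embedding vector per node.  The trainer is a compact batched SGNS
implementation in numpy: vocabulary sizes here are graph node counts (tens
to hundreds), so dense batched updates are both exact enough and fast.

All randomness flows from one ``numpy.random.Generator``; a fixed seed gives
bit-identical walks and reproducible embeddings.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np

from .config import WalkParams

__all__ = ["simulate_walks", "train_skipgram", "embed_adjacency"]


def simulate_walks(
    neighbors: Sequence[np.ndarray],
    params: WalkParams,
    rng: np.random.Generator,
) -> List[np.ndarray]:
    """Second-order biased random walks over an adjacency-list graph.

    ``neighbors[i]`` is the sorted integer array of node i's neighbors.
    Nodes without neighbors start no walks.  With p = q = 1 the walk is a
    plain first-order random walk (fast path).
    """
    unbiased = params.p == 1.0 and params.q == 1.0
    neighbor_sets = [set(nb.tolist()) for nb in neighbors] if not unbiased else None
    walks: List[np.ndarray] = []
    n = len(neighbors)
    for _ in range(params.walks_per_node):
        for start in range(n):
            if neighbors[start].size == 0:
                continue
            walk = np.empty(params.walk_length, dtype=np.int64)
            walk[0] = start
            prev = -1
            cur = start
            for step in range(1, params.walk_length):
                nbrs = neighbors[cur]
                if nbrs.size == 0:  # dead end (cannot happen on undirected graphs)
                    walk = walk[:step]
                    break
                if unbiased or prev < 0:
                    nxt = int(nbrs[rng.integers(nbrs.size)])
                else:
                    w = np.empty(nbrs.size)
                    prev_set = neighbor_sets[prev]
                    for k, x in enumerate(nbrs):
                        if x == prev:
                            w[k] = 1.0 / params.p
                        elif x in prev_set:
                            w[k] = 1.0
                        else:
                            w[k] = 1.0 / params.q
                    w /= w.sum()
                    nxt = int(rng.choice(nbrs, p=w))
                walk[step] = nxt
                prev, cur = cur, nxt
            walks.append(walk)
    return walks


def _walk_pairs(
    walks: Sequence[np.ndarray], window: int, rng: np.random.Generator
) -> tuple:
    """(center, context) index pairs with per-token sampled window size."""
    centers: List[np.ndarray] = []
    contexts: List[np.ndarray] = []
    for walk in walks:
        L = walk.size
        spans = rng.integers(1, window + 1, size=L)
        for t in range(L):
            lo = max(0, t - int(spans[t]))
            hi = min(L, t + int(spans[t]) + 1)
            ctx = np.concatenate([walk[lo:t], walk[t + 1:hi]])
            if ctx.size:
                centers.append(np.full(ctx.size, walk[t], dtype=np.int64))
                contexts.append(ctx.astype(np.int64))
    if not centers:
        raise ValueError("walk corpus produced no training pairs")
    return np.concatenate(centers), np.concatenate(contexts)


def train_skipgram(
    walks: Sequence[np.ndarray],
    n_nodes: int,
    params: WalkParams,
    rng: np.random.Generator,
    batch_size: int = 1024,
) -> np.ndarray:
    """Skip-gram with negative sampling over a walk corpus.

    Returns the input-embedding matrix (n_nodes x dimension).  Negative
    contexts are drawn from the corpus unigram distribution raised to 3/4.
    The learning rate decays linearly to 10% of its initial value.
    """
    def scatter_mean(target: np.ndarray, idx: np.ndarray, grads: np.ndarray,
                     lr: float) -> None:
        # per-row mean gradient: nodes recur many times per batch in a small
        # vocabulary, and summed updates would blow up the step size
        acc = np.zeros_like(target)
        np.add.at(acc, idx, grads)
        cnt = np.bincount(idx, minlength=target.shape[0]).astype(float)
        nz = cnt > 0
        target[nz] -= lr * acc[nz] / cnt[nz, None]

    centers, contexts = _walk_pairs(walks, params.window, rng)
    counts = np.bincount(np.concatenate([w for w in walks]), minlength=n_nodes)
    noise = counts.astype(float) ** 0.75
    if noise.sum() == 0:
        raise ValueError("empty walk corpus")
    noise /= noise.sum()

    dim = params.dimension
    W = (rng.random((n_nodes, dim)) - 0.5) / dim  # input vectors
    C = np.zeros((n_nodes, dim))  # output (context) vectors
    n_pairs = centers.size
    total_batches = max(1, -(-n_pairs // batch_size)) * params.epochs
    batch_no = 0
    for _ in range(params.epochs):
        order = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, batch_size):
            idx = order[lo:lo + batch_size]
            u = centers[idx]
            v = contexts[idx]
            neg = rng.choice(n_nodes, size=(idx.size, params.negative), p=noise)
            lr = params.learning_rate * (1.0 - 0.9 * batch_no / total_batches)
            batch_no += 1

            Wu = W[u]  # (B, d)
            Cv = C[v]
            Cn = C[neg]  # (B, k, d)
            pos_err = _sigmoid(np.einsum("bd,bd->b", Wu, Cv)) - 1.0  # (B,)
            neg_err = _sigmoid(np.einsum("bd,bkd->bk", Wu, Cn))  # (B, k)

            grad_u = pos_err[:, None] * Cv + np.einsum("bk,bkd->bd", neg_err, Cn)
            grad_v = pos_err[:, None] * Wu
            grad_n = neg_err[:, :, None] * Wu[:, None, :]

            scatter_mean(W, u, grad_u, lr)
            scatter_mean(C, np.concatenate([v, neg.ravel()]),
                         np.vstack([grad_v, grad_n.reshape(-1, dim)]), lr)
    return W


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def embed_adjacency(
    adjacency: np.ndarray, params: WalkParams, seed: int
) -> np.ndarray:
    """Walks + skip-gram over a symmetric {0,1} adjacency matrix.

    Isolated nodes keep the zero vector.
    """
    params.validate()
    n = adjacency.shape[0]
    neighbors = [np.flatnonzero(adjacency[i]) for i in range(n)]
    if not any(nb.size for nb in neighbors):
        raise ValueError("cannot embed an edgeless graph")
    rng = np.random.default_rng(seed)
    walks = simulate_walks(neighbors, params, rng)
    W = train_skipgram(walks, n, params, rng)
    isolated = np.array([nb.size == 0 for nb in neighbors])
    if isolated.any():
        W[isolated] = 0.0
    return W
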