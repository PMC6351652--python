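"""Latent Dirichlet allocation over subject x code count matrices.

Each subject's record is treated as a document whose tokens are diagnostic
codes; a count of c for a code contributes c tokens.  Inference is by
collapsed Gibbs sampling over token-level topic assignments, with
posterior-mean estimates of the topic-code distributions (phi) and the
per-subject topic membership scores (theta) averaged over retained sweeps
after burn-in.  The membership scores are the quantitative traits consumed
by the association stage.

Topic labels are arbitrary (label switching); comparisons against a
reference model should go through :func:`align_topics`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from numba import njit

from .code_mapping import CodeCountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TopicModelFit",
    "fit_lda",
    "topic_scores",
    "top_codes",
    "align_topics",
    "save_fit",
    "load_fit",
]


@dataclass
class TopicModelFit:
    """A fitted topic model.

    ``phi`` is the K x V topic-code distribution, ``theta`` the N x K
    subject topic membership scores; both row-stochastic.  ``alpha`` and
    ``beta`` are the symmetric Dirichlet priors on theta and phi.
    """

    n_topics: int
    phi: np.ndarray
    theta: np.ndarray
    alpha: float
    beta: float
    n_iterations: int
    burn_in: int
    thin: int
    seed: int
    log_likelihood_trace: np.ndarray
    subject_ids: list[str] = field(default_factory=list)
    code_vocab: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.phi is None or self.theta is None:
            raise ValueError("fit requires phi and theta")
        for name, mat in (("phi", self.phi), ("theta", self.theta)):
            if np.any(mat < 0):
                raise ValueError(f"{name} has negative entries")
            if np.max(np.abs(mat.sum(axis=1) - 1.0)) > 1e-8:
                raise ValueError(f"{name} rows do not sum to 1")


@njit(cache=True)
def _gibbs_kernel(doc_ids, word_ids, K, V, D, alpha, beta,
                  n_iterations, burn_in, thin, seed):
    np.random.seed(seed)
    T = doc_ids.shape[0]
    n_dk = np.zeros((D, K), np.int64)
    n_kv = np.zeros((K, V), np.int64)
    n_k = np.zeros(K, np.int64)
    n_d = np.zeros(D, np.int64)
    z = np.empty(T, np.int64)
    for t in range(T):
        k = np.random.randint(0, K)
        z[t] = k
        n_dk[doc_ids[t], k] += 1
        n_kv[k, word_ids[t]] += 1
        n_k[k] += 1
        n_d[doc_ids[t]] += 1

    theta_sum = np.zeros((D, K), np.float64)
    phi_sum = np.zeros((K, V), np.float64)
    loglik = np.empty(n_iterations, np.float64)
    p = np.empty(K, np.float64)
    Vbeta = V * beta
    Kalpha = K * alpha
    lga = math.lgamma(alpha)
    lgb = math.lgamma(beta)
    lgVb = math.lgamma(Vbeta)
    lgKa = math.lgamma(Kalpha)
    n_retained = 0

    for it in range(n_iterations):
        for t in range(T):
            d = doc_ids[t]
            w = word_ids[t]
            k = z[t]
            n_dk[d, k] -= 1
            n_kv[k, w] -= 1
            n_k[k] -= 1
            total = 0.0
            for kk in range(K):
                total += (
                    (n_dk[d, kk] + alpha)
                    * (n_kv[kk, w] + beta)
                    / (n_k[kk] + Vbeta)
                )
                p[kk] = total
            u = np.random.random() * total
            knew = K - 1
            for kk in range(K):
                if u < p[kk]:
                    knew = kk
                    break
            z[t] = knew
            n_dk[d, knew] += 1
            n_kv[knew, w] += 1
            n_k[knew] += 1

        # collapsed joint log p(w, z); lgamma only on nonzero cells
        ll = 0.0
        for k in range(K):
            ll += lgVb - math.lgamma(n_k[k] + Vbeta)
            for v in range(V):
                if n_kv[k, v] > 0:
                    ll += math.lgamma(n_kv[k, v] + beta) - lgb
        for d in range(D):
            ll += lgKa - math.lgamma(n_d[d] + Kalpha)
            for k in range(K):
                if n_dk[d, k] > 0:
                    ll += math.lgamma(n_dk[d, k] + alpha) - lga
        loglik[it] = ll

        if it >= burn_in and (it - burn_in) % thin == 0:
            n_retained += 1
            for d in range(D):
                denom = n_d[d] + Kalpha
                for k in range(K):
                    theta_sum[d, k] += (n_dk[d, k] + alpha) / denom
            for k in range(K):
                denom = n_k[k] + Vbeta
                for v in range(V):
                    phi_sum[k, v] += (n_kv[k, v] + beta) / denom

    return theta_sum, phi_sum, n_retained, loglik


def fit_lda(
    counts: CodeCountMatrix,
    n_topics: int = 50,
    alpha: float | None = None,
    beta: float = 0.1,
    n_iterations: int = 500,
    burn_in: int = 200,
    thin: int = 10,
    seed: int = 0,
) -> TopicModelFit:
    """Fit LDA to a code count matrix by collapsed Gibbs sampling.

    Parameters
    ----------
    counts
        Subject x code count matrix; must contain at least one token.
        All-zero subject rows are allowed — their scores equal the prior
        mean 1/K exactly.
    n_topics
        Number of topics K (>= 2); default 50.
    alpha, beta
        Symmetric Dirichlet priors on theta and phi.  ``alpha`` defaults to
        50/K, ``beta`` to 0.1.
    n_iterations, burn_in, thin
        Gibbs sweeps in total, sweeps discarded, and the thinning interval
        for the retained posterior-mean averages.
    seed
        RNG seed; a fixed seed yields a bit-identical fit.
    """
    if n_topics < 2:
        raise ValueError("n_topics must be >= 2")
    if counts.n_subjects == 0 or counts.token_total() == 0:
        raise ValueError("count matrix has no tokens to model")
    if alpha is None:
        alpha = 50.0 / n_topics
    if alpha <= 0 or beta <= 0:
        raise ValueError("priors must be strictly positive")
    if burn_in >= n_iterations:
        raise ValueError("burn_in must be smaller than n_iterations")
    if counts.n_codes < n_topics:
        logger.warning(
            "vocabulary size %d < n_topics %d; topics will be poorly resolved",
            counts.n_codes, n_topics,
        )
    if not 0 <= seed < 2**32:
        raise ValueError("seed must be a nonnegative 32-bit integer")

    coo = counts.counts.tocoo()
    doc_ids = np.repeat(coo.row.astype(np.int64), coo.data.astype(np.int64))
    word_ids = np.repeat(coo.col.astype(np.int64), coo.data.astype(np.int64))
    # canonical token order so the sampler stream depends only on content
    order = np.lexsort((word_ids, doc_ids))
    doc_ids, word_ids = doc_ids[order], word_ids[order]

    theta_sum, phi_sum, n_retained, loglik = _gibbs_kernel(
        doc_ids, word_ids, n_topics, counts.n_codes, counts.n_subjects,
        float(alpha), float(beta), int(n_iterations), int(burn_in), int(thin),
        int(seed),
    )
    theta = theta_sum / n_retained
    phi = phi_sum / n_retained
    # tighten row sums; zero-token subjects get the prior mean exactly
    theta /= theta.sum(axis=1, keepdims=True)
    phi /= phi.sum(axis=1, keepdims=True)
    doc_len = np.asarray(counts.counts.sum(axis=1)).ravel()
    theta[doc_len == 0, :] = 1.0 / n_topics

    return TopicModelFit(
        n_topics=n_topics,
        phi=phi,
        theta=theta,
        alpha=float(alpha),
        beta=float(beta),
        n_iterations=int(n_iterations),
        burn_in=int(burn_in),
        thin=int(thin),
        seed=int(seed),
        log_likelihood_trace=loglik,
        subject_ids=list(counts.subject_ids),
        code_vocab=list(counts.code_vocab),
    )


def topic_scores(fit: TopicModelFit) -> np.ndarray:
    """Per-subject topic membership scores (N x K, rows sum to 1)."""
    if fit.theta is None:
        raise RuntimeError("model is not fitted")
    return fit.theta.copy()


def top_codes(
    fit: TopicModelFit,
    topic: int,
    min_weight: float = 0.01,
    comparison: str = ">=",
) -> list[tuple[str, float]]:
    """Codes loading onto ``topic`` with weight at or above ``min_weight``.

    Returns (code, weight) pairs sorted by weight descending, ties broken by
    code string ascending.  ``comparison`` selects ``">="`` (default) or
    ``">"`` against the threshold.
    """
    if not 0 <= topic < fit.n_topics:
        raise ValueError(f"topic index {topic} out of range [0, {fit.n_topics})")
    if comparison not in (">=", ">"):
        raise ValueError(f"comparison must be '>=' or '>', got {comparison!r}")
    row = fit.phi[topic]
    if comparison == ">=":
        idx = np.nonzero(row >= min_weight)[0]
    else:
        idx = np.nonzero(row > min_weight)[0]
    pairs = [(fit.code_vocab[v] if fit.code_vocab else str(v), float(row[v]))
             for v in idx]
    return sorted(pairs, key=lambda cw: (-cw[1], cw[0]))


def align_topics(
    phi_ref: np.ndarray, phi_est: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy one-to-one topic alignment by cosine similarity.

    Repeatedly matches the globally most similar (reference, estimated)
    topic pair until every reference topic is matched.  Returns
    ``(mapping, cosines)`` where ``mapping[i]`` is the estimated topic
    matched to reference topic i and ``cosines[i]`` its cosine similarity.
    Requires at least as many estimated topics as reference topics.
    """
    ref = np.asarray(phi_ref, float)
    est = np.asarray(phi_est, float)
    if est.shape[0] < ref.shape[0]:
        raise ValueError("need at least as many estimated topics as reference")
    rn = ref / np.linalg.norm(ref, axis=1, keepdims=True)
    en = est / np.linalg.norm(est, axis=1, keepdims=True)
    sim = rn @ en.T
    mapping = np.full(ref.shape[0], -1, dtype=int)
    cosines = np.zeros(ref.shape[0])
    work = sim.copy()
    for _ in range(ref.shape[0]):
        i, j = np.unravel_index(np.argmax(work), work.shape)
        mapping[i] = j
        cosines[i] = sim[i, j]
        work[i, :] = -np.inf
        work[:, j] = -np.inf
    return mapping, cosines


def save_fit(fit: TopicModelFit, directory) -> None:
    """Serialize a fit to ``directory``: phi.tsv, theta.tsv, meta.yaml."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    codes = fit.code_vocab or [f"v{j}" for j in range(fit.phi.shape[1])]
    subjects = fit.subject_ids or [f"d{i}" for i in range(fit.theta.shape[0])]
    with open(directory / "phi.tsv", "w", newline="\n") as fh:
        fh.write("topic\t" + "\t".join(codes) + "\n")
        for k in range(fit.n_topics):
            fh.write(f"{k}\t" + "\t".join(repr(float(x)) for x in fit.phi[k]) + "\n")
    with open(directory / "theta.tsv", "w", newline="\n") as fh:
        fh.write("subject_id\t"
                 + "\t".join(f"topic{k}" for k in range(fit.n_topics)) + "\n")
        for i, s in enumerate(subjects):
            fh.write(f"{s}\t" + "\t".join(repr(float(x)) for x in fit.theta[i]) + "\n")
    meta = {
        "n_topics": fit.n_topics,
        "alpha": fit.alpha,
        "beta": fit.beta,
        "n_iterations": fit.n_iterations,
        "burn_in": fit.burn_in,
        "thin": fit.thin,
        "seed": fit.seed,
        "log_likelihood_trace": [float(x) for x in fit.log_likelihood_trace],
    }
    with open(directory / "meta.yaml", "w", newline="\n") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def load_fit(directory) -> TopicModelFit:
    """Load a fit serialized by :func:`save_fit`."""
    import pandas as pd

    directory = Path(directory)
    with open(directory / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    phi_df = pd.read_csv(directory / "phi.tsv", sep="\t", index_col=0,
                         float_precision="round_trip")
    theta_df = pd.read_csv(directory / "theta.tsv", sep="\t", index_col=0,
                           float_precision="round_trip")
    return TopicModelFit(
        n_topics=int(meta["n_topics"]),
        phi=phi_df.to_numpy(float),
        theta=theta_df.to_numpy(float),
        alpha=float(meta["alpha"]),
        beta=float(meta["beta"]),
        n_iterations=int(meta["n_iterations"]),
        burn_in=int(meta["burn_in"]),
        thin=int(meta["thin"]),
        seed=int(meta["seed"]),
        log_likelihood_trace=np.asarray(meta["log_likelihood_trace"], float),
        subject_ids=[str(s) for s in theta_df.index],
        code_vocab=[str(c) for c in phi_df.columns],
    )
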