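"""Robust K-mer seed discovery.

Probe intensities are modelled as a weighted sum of oligomer counts,

    y(S) = sum_m beta_m * X_m(S),

where X_m(S) counts occurrences of oligomer m in S on both strands.  The
coefficients are estimated by a trimmed-mean iteration designed for the
sparse design matrix: for every probe carrying m, the value beta'_m(S)
that would make the prediction exact is computed, the top and bottom 15%
of these per-probe values are discarded, and beta_m moves a step alpha
toward the trimmed mean.  After convergence the oligomer with the largest
coefficient becomes the seed (reference sequence) for the free-energy fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy import sparse

from .core import BASES, ProbeTable, revcomp

__all__ = [
    "KmerCoefficients",
    "count_kmers",
    "exact_coefficient",
    "trimmed_mean",
    "find_seed",
    "kmer_to_index",
    "index_to_kmer",
]


def kmer_to_index(kmer: str) -> int:
    idx = 0
    for b in kmer:
        idx = 4 * idx + BASES.index(b)
    return idx


def index_to_kmer(idx: int, K: int) -> str:
    out = []
    for _ in range(K):
        out.append(BASES[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def _kmer_codes(enc: np.ndarray, K: int) -> np.ndarray:
    """Rolling 4-ary codes of all forward K-mers: (n, plen-K+1) intp."""
    n, plen = enc.shape
    e = enc.astype(np.intp)
    codes = np.zeros((n, plen - K + 1), dtype=np.intp)
    for j in range(K):
        codes = codes * 4 + e[:, j : plen - K + 1 + j]
    return codes


def count_kmers(probe_seq: str, K: int) -> Dict[str, int]:
    """Occurrence counts X_m of every K-mer in a probe, scanning the
    forward sequence and its reverse complement; overlaps counted."""
    if K > len(probe_seq):
        raise ValueError("K longer than probe")
    counts: Dict[str, int] = {}
    for s in (probe_seq, revcomp(probe_seq)):
        for i in range(len(s) - K + 1):
            m = s[i : i + K]
            counts[m] = counts.get(m, 0) + 1
    return counts


def exact_coefficient(
    y: float, counts: Dict[str, int], m: str, beta: Dict[str, float]
) -> float:
    """The coefficient value beta'_m that makes the K-mer model prediction
    for this probe exact, holding every other coefficient fixed."""
    if counts.get(m, 0) == 0:
        raise ValueError("feature absent from probe")
    rest = sum(beta.get(k, 0.0) * x for k, x in counts.items() if k != m)
    return (y - rest) / counts[m]


def trimmed_mean(values, trim_frac: float) -> float:
    """Mean after removing floor(trim_frac*n) smallest and largest values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty list")
    if not 0 <= trim_frac < 0.5:
        raise ValueError("trim_frac must be in [0, 0.5)")
    k = int(np.floor(trim_frac * v.size))
    v = np.sort(v)
    if k > 0:
        v = v[k:-k]
    return float(v.mean())


@dataclass
class KmerCoefficients:
    """Converged per-oligomer coefficients from the seed iteration."""

    K: int
    beta: np.ndarray  # length 4**K
    n_iter: int = 0
    converged: bool = False

    def get(self, kmer: str) -> float:
        return float(self.beta[kmer_to_index(kmer)])

    def top(self, n: int = 10):
        order = np.argsort(self.beta)[::-1][:n]
        return [(index_to_kmer(i, self.K), float(self.beta[i])) for i in order]


def _count_matrix(enc: np.ndarray, K: int) -> sparse.csc_matrix:
    n = enc.shape[0]
    fwd = _kmer_codes(enc, K)
    rev = _kmer_codes((3 - enc)[:, ::-1], K)
    cols = np.concatenate([fwd, rev], axis=1)
    rows = np.repeat(np.arange(n), cols.shape[1])
    data = np.ones(cols.size)
    X = sparse.coo_matrix(
        (data, (rows, cols.ravel())), shape=(n, 4**K)
    ).tocsc()
    X.sum_duplicates()
    return X


def _grouped_trimmed_means(
    cols: np.ndarray, vals: np.ndarray, trim_frac: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Trimmed mean of vals grouped by column index; fully vectorised.

    Returns (unique_cols, means)."""
    order = np.lexsort((vals, cols))
    c = cols[order]
    v = vals[order]
    uniq, starts = np.unique(c, return_index=True)
    ends = np.append(starts[1:], c.size)
    counts = ends - starts
    k = np.floor(trim_frac * counts).astype(np.intp)
    cs = np.concatenate([[0.0], np.cumsum(v)])
    sums = cs[ends - k] - cs[starts + k]
    means = sums / (counts - 2 * k)
    return uniq, means


def find_seed(
    probes: ProbeTable,
    K: int = 8,
    *,
    alpha: float = 0.1,
    trim_frac: float = 0.15,
    beta_init: float = 1e-4,
    tol: float = 1e-6,
    max_iter: int = 200,
    min_support: int = 20,
) -> Tuple[str, KmerCoefficients]:
    """Pick the highest-affinity K-mer seed by trimmed-mean iteration.

    All 4**K coefficients start at a small non-specific value and are
    updated in parallel each round:

        beta_m <- (1 - alpha) * beta_m + alpha * clip(trimmed_mean, 0)

    Convergence: max |delta beta| / max beta < tol.  The returned seed is
    the argmax coefficient among oligomers observed in at least
    `min_support` probes — a K-mer seen in only a few probes can explain
    them exactly no matter what, so its trimmed mean carries no evidence;
    requiring support keeps the choice identifiable on sparse designs
    (when no oligomer reaches the threshold the global argmax is used).
    Because counts are strand-merged the seed and its reverse complement
    score identically; the lexicographically smaller of the two is
    returned.
    """
    if len(probes) == 0:
        raise ValueError("no probes")
    if K > probes.probe_length:
        raise ValueError("K longer than probe")
    enc = probes.encoded()
    y = probes.intensities
    X = _count_matrix(enc, K)
    Xcoo = X.tocoo()
    rows, cols, xvals = Xcoo.row, Xcoo.col, Xcoo.data

    beta = np.full(4**K, beta_init)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        yhat = X @ beta
        resid = y - yhat
        # exact per-probe coefficient: beta_m + residual / X_m
        vals = beta[cols] + resid[rows] / xvals
        uniq, means = _grouped_trimmed_means(cols, vals, trim_frac)
        new_beta = beta.copy()
        new_beta[uniq] = (1 - alpha) * beta[uniq] + alpha * np.maximum(means, 0.0)
        delta = np.abs(new_beta - beta).max()
        beta = new_beta
        if delta < tol * max(beta.max(), 1e-300):
            converged = True
            break

    support = np.diff(X.indptr)  # probes containing each oligomer
    eligible = support >= min_support
    if eligible.any():
        masked = np.where(eligible, beta, -np.inf)
        best = int(np.argmax(masked))
    else:
        best = int(np.argmax(beta))
    seed = index_to_kmer(best, K)
    rc = revcomp(seed)
    if rc < seed and np.isclose(beta[kmer_to_index(rc)], beta[best]):
        seed = rc
    return seed, KmerCoefficients(K=K, beta=beta, n_iter=n_iter, converged=converged)
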