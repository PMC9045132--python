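"""Entropy and fractal-dimension features of an EEG segment.

Eight measures per segment, in fixed order: permutation entropy, singular
value decomposition entropy, sample entropy, the detrended fluctuation
analysis scaling exponent, Petrosian fractal dimension, Katz fractal
dimension, Higuchi fractal dimension, and normalized Lempel-Ziv
complexity.

Conventions (none dictated by the problem; all configurable):
  * ordinal/embedding measures use order m=3, delay 1; entropies are
    normalized to [0, 1];
  * sample entropy uses m=2, tolerance r = 0.2 x SD, counted with a
    Chebyshev KD-tree; for long segments it is evaluated on a centered
    3000-sample window — the estimate is stable at that length and keeps
    cohort-scale extraction fast;
  * DFA detrends linearly over window sizes log-spaced in [4, n/10];
  * Higuchi uses k_max = 10;
  * Lempel-Ziv binarizes at the median and normalizes the LZ76 phrase
    count by n/log2(n).

A constant segment (sample entropy and several others undefined) returns
zeros with a QC flag instead of raising, so one degenerate segment cannot
abort a cohort run.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial, log

import numpy as np
from scipy.spatial import cKDTree

FEATURE_NAMES = ["perm_entropy", "svd_entropy", "sample_entropy", "dfa",
                 "petrosian_fd", "katz_fd", "higuchi_fd", "lzc"]


@dataclass
class ComplexityParams:
    order: int = 3          # embedding order for permutation/SVD entropy
    delay: int = 1
    sampen_m: int = 2
    sampen_r: float = 0.2   # fraction of SD
    sampen_max_n: int = 3000
    dfa_min_win: int = 4
    dfa_n_scales: int = 16
    higuchi_kmax: int = 10

    def __post_init__(self) -> None:
        if self.order < 2 or self.delay < 1:
            raise ValueError("need order >= 2 and delay >= 1")
        if self.sampen_r <= 0 or self.higuchi_kmax < 2:
            raise ValueError("need r > 0 and k_max >= 2")


def _embed(x, order, delay):
    n = x.size - (order - 1) * delay
    return np.lib.stride_tricks.sliding_window_view(x, (order - 1) * delay + 1)[:, ::delay][:n]


def permutation_entropy(x, order=3, delay=1, normalize=True) -> float:
    emb = _embed(np.asarray(x, float), order, delay)
    patterns = emb.argsort(axis=1, kind="stable")
    # hash each ordinal pattern to an integer
    mult = (order ** np.arange(order)).astype(np.int64)
    codes = patterns @ mult
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = -(p * np.log(p)).sum()
    return float(h / log(factorial(order))) if normalize else float(h)


def svd_entropy(x, order=3, delay=1, normalize=True) -> float:
    emb = _embed(np.asarray(x, float), order, delay)
    sv = np.linalg.svd(emb, compute_uv=False)
    sv = sv / sv.sum()
    sv = sv[sv > 0]
    h = -(sv * np.log(sv)).sum()
    return float(h / log(order)) if normalize else float(h)


def sample_entropy(x, m=2, r=0.2, max_n=None) -> float:
    """SampEn(m, r): -ln of the conditional probability that sequences
    close for m points remain close for m+1, Chebyshev distance,
    self-matches excluded. r is a fraction of the series SD."""
    x = np.asarray(x, dtype=float)
    if max_n is not None and x.size > max_n:
        mid = x.size // 2
        x = x[mid - max_n // 2: mid + max_n // 2]
    sd = x.std()
    if sd == 0:
        return 0.0
    tol = r * sd

    def count_pairs(order):
        emb = _embed(x, order, 1)
        tree = cKDTree(emb)
        # count_neighbors includes self-pairs (n of them) and both orderings
        pairs = tree.count_neighbors(tree, tol, p=np.inf)
        return (pairs - emb.shape[0]) / 2.0

    b = count_pairs(m)
    a = count_pairs(m + 1)
    if b == 0 or a == 0:
        return 0.0
    return float(-log(a / b))


def dfa_exponent(x, min_win=4, n_scales=16) -> float:
    """First-order detrended fluctuation analysis scaling exponent."""
    x = np.asarray(x, dtype=float)
    n = x.size
    y = np.cumsum(x - x.mean())
    max_win = n // 10
    if max_win <= min_win:
        raise ValueError("series too short for DFA")
    scales = np.unique(np.geomspace(min_win, max_win, n_scales).astype(int))
    flucts = np.empty(scales.size)
    for i, s in enumerate(scales):
        k = n // s
        segs = y[:k * s].reshape(k, s)
        t = np.arange(s, dtype=float)
        design = np.vstack([t, np.ones(s)]).T          # s x 2
        coef, *_ = np.linalg.lstsq(design, segs.T, rcond=None)
        resid = segs.T - design @ coef
        flucts[i] = np.sqrt((resid ** 2).mean())
    alpha = np.polyfit(np.log(scales), np.log(flucts), 1)[0]
    return float(alpha)


def petrosian_fd(x) -> float:
    x = np.asarray(x, dtype=float)
    n = x.size
    diff = np.diff(x)
    n_delta = int(((diff[:-1] * diff[1:]) < 0).sum())  # sign changes
    if n_delta == 0:
        return 0.0
    return float(np.log10(n) / (np.log10(n) + np.log10(n / (n + 0.4 * n_delta))))


def katz_fd(x) -> float:
    x = np.asarray(x, dtype=float)
    dists = np.abs(np.diff(x))
    length = dists.sum()
    if length == 0:
        return 0.0
    a = dists.mean()
    # farthest point from the first sample, in the (index, value) plane
    t = np.arange(x.size)
    d = np.sqrt((t - 0) ** 2 + (x - x[0]) ** 2).max()
    n = length / a
    return float(np.log10(n) / (np.log10(n) + np.log10(d / length)))


def higuchi_fd(x, kmax=10) -> float:
    x = np.asarray(x, dtype=float)
    n = x.size
    lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            ll = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / (idx.size - 1) / k
            lengths.append(ll * norm / k)
        lk[k - 1] = np.mean(lengths)
    if np.any(lk <= 0):
        return 0.0
    ks = np.arange(1, kmax + 1)
    slope = np.polyfit(np.log(1.0 / ks), np.log(lk), 1)[0]
    return float(slope)


def lz76_phrases(bits) -> int:
    """LZ76 exhaustive-history phrase count of a binary string."""
    s = "".join("1" if b else "0" for b in bits)
    n = len(s)
    if n == 0:
        return 0
    c = 1
    i = 1  # start of the current phrase
    while i < n:
        k = 1
        # longest prefix of s[i:] occurring in s[:i+k-1] (reproducibility scan)
        while i + k <= n and s.find(s[i:i + k], 0, i + k - 1) != -1:
            k += 1
        c += 1
        i += k
    return c


def lempel_ziv_complexity(x, normalize=True) -> float:
    """Median-binarized LZ76 complexity, normalized by n/log2(n)."""
    x = np.asarray(x, dtype=float)
    bits = x > np.median(x)
    c = lz76_phrases(bits)
    if not normalize:
        return float(c)
    n = bits.size
    return float(c * np.log2(n) / n) if n > 1 else 0.0


def compute_complexity(segment, params: ComplexityParams | None = None):
    """The 8 complexity features in fixed order, plus QC flags.

    Returns (features: ndarray of 8, flags: list of str).
    """
    params = params or ComplexityParams()
    x = np.asarray(segment, dtype=float)
    if x.size < 100:
        raise ValueError("segment must have at least 100 samples")
    flags: list[str] = []
    if np.ptp(x) == 0:
        flags.append("constant_segment")
        return np.zeros(8), flags
    feats = np.array([
        permutation_entropy(x, params.order, params.delay),
        svd_entropy(x, params.order, params.delay),
        sample_entropy(x, params.sampen_m, params.sampen_r, params.sampen_max_n),
        dfa_exponent(x, params.dfa_min_win, params.dfa_n_scales),
        petrosian_fd(x),
        katz_fd(x),
        higuchi_fd(x, params.higuchi_kmax),
        lempel_ziv_complexity(x),
    ])
    if not np.all(np.isfinite(feats)):
        flags.append("nonfinite_feature")
        feats = np.nan_to_num(feats)
    return feats, flags
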