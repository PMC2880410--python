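"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive — brute-force enumeration, per-window
loops, textbook formulas — and shares no code with the implementation
paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from promgram.bayesnet import BNModel
from promgram.features import MISSING, FeatureVector
from promgram.pwm import PWM, score_window


def enumerate_posterior(model: BNModel, v: FeatureVector) -> float:
    """P(histone | v) by exhaustive summation over the full joint.

    Enumerates every assignment of every node (class, all M, S, L),
    multiplies the factored joint, and sums assignments consistent with
    the evidence.  Exponential in the node count; only for tiny models.
    """
    p = model.structure.n_positions
    K = len(model.motif_states)
    B = len(model.spacer_states)
    naive = model.structure.naive
    outer = model.structure.l_parent_outer

    def factor_product(c, m, s, l) -> float:
        prob = model.class_prior[c]
        prob *= model.cpts["M1"][c][m[0]]
        for i in range(1, p):
            t = model.cpts[f"M{i + 1}"][c]
            prob *= t[m[i]] if naive else t[m[i - 1]][m[i]]
        for i in range(p):
            t = model.cpts[f"S{i + 1}"][c]
            prob *= t[s[i]] if naive else t[m[i]][s[i]]
        for i in range(p - 1):
            t = model.cpts[f"L{i + 2}_{i + 1}"][c]
            parent = m[i + 1] if outer else m[i]
            prob *= t[l[i]] if naive else t[parent][l[i]]
        return prob

    m_obs = [None if x == MISSING else model.motif_states.index(x)
             for x in v.M]
    s_obs = [None if x == MISSING else model.strand_states.index(x)
             for x in v.S]
    l_obs = [None if x == MISSING else model.spacer_states.index(x)
             for x in v.L]
    totals = [0.0, 0.0]
    for c in range(2):
        for m in itertools.product(range(K), repeat=p):
            if any(o is not None and o != mi for o, mi in zip(m_obs, m)):
                continue
            for s in itertools.product(range(2), repeat=p):
                if any(o is not None and o != si
                       for o, si in zip(s_obs, s)):
                    continue
                for l in itertools.product(range(B), repeat=p - 1):
                    if any(o is not None and o != li
                           for o, li in zip(l_obs, l)):
                        continue
                    totals[c] += factor_product(c, m, s, l)
    return totals[0] / (totals[0] + totals[1])


def naive_scan(pwm: PWM, seq: str, threshold: float | None = None
               ) -> list[tuple[int, str, float]]:
    """Per-window loop scan on both strands; (start, strand, score)."""
    from promgram.pwm import reverse_complement

    t = pwm.threshold if threshold is None else threshold
    w = len(pwm)
    out = []
    for start in range(len(seq) - w + 1):
        window = seq[start:start + w]
        s = score_window(pwm, window)
        if s >= t:
            out.append((start, "+", s))
        s = score_window(pwm, reverse_complement(window))
        if s >= t:
            out.append((start, "-", s))
    out.sort(key=lambda h: (h[0], h[1]))
    return out


def bh_stepup(pvals: np.ndarray, q: float) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up: boolean rejection flags."""
    m = len(pvals)
    order = np.argsort(pvals)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= q * rank / m:
            k_max = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject


def bh_adjusted(pvals: np.ndarray) -> np.ndarray:
    """Textbook BH adjusted p-values (step-up with running minimum)."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, pvals[idx] * m / rank)
        adj[idx] = running
    return adj


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by direct summation of exact binomial-coefficient terms."""
    total = 0.0
    for j in range(k, min(n, K) + 1):
        total += (math.comb(K, j) * math.comb(N - K, n - j)
                  / math.comb(N, n))
    return total


def welch_t(a: np.ndarray, b: np.ndarray) -> float:
    """Welch's t statistic (mean(a) - mean(b)) / pooled-unequal SE."""
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    return (a.mean() - b.mean()) / math.sqrt(va + vb)


def union_find_clusters(intervals: list[tuple[str, int, int]]
                        ) -> list[tuple[str, int, int]]:
    """Brute-force single-linkage overlap clustering via union-find."""
    parent = list(range(len(intervals)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(intervals)):
        for j in range(i + 1, len(intervals)):
            ci, si, ei = intervals[i]
            cj, sj, ej = intervals[j]
            if ci == cj and si < ej and sj < ei:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(len(intervals)):
        groups.setdefault(find(i), []).append(i)
    spans = []
    for members in groups.values():
        chrom = intervals[members[0]][0]
        spans.append((chrom,
                      min(intervals[i][1] for i in members),
                      max(intervals[i][2] for i in members)))
    return sorted(spans)


def random_model(seed: int, n_positions: int = 2, K: int = 3, B: int = 2,
                 naive: bool = False, conc: float = 1.0) -> BNModel:
    """A random fully-specified model over small state spaces."""
    from promgram.bayesnet import BNStructure
    from promgram.features import bin_labels

    rng = np.random.default_rng(seed)
    bins = tuple([0] + [25 * (i + 1) for i in range(B - 1)] + [np.inf])

    def rc(shape):
        a = rng.gamma(conc, size=shape) + 1e-6
        return a / a.sum(-1, keepdims=True)

    p = n_positions
    cpts = {"class": rc((2,)), "M1": rc((2, K))}
    for i in range(2, p + 1):
        cpts[f"M{i}"] = rc((2, K) if naive else (2, K, K))
        cpts[f"L{i}_{i - 1}"] = rc((2, B) if naive else (2, K, B))
    for i in range(1, p + 1):
        cpts[f"S{i}"] = rc((2, 2) if naive else (2, K, 2))
    return BNModel(BNStructure(p, naive), [f"m{i}" for i in range(K)],
                   bin_labels(bins), cpts, spacer_bins=bins)


def random_vector(seed: int, model: BNModel, p_missing: float = 0.3
                  ) -> FeatureVector:
    """A random feature vector over a model's state spaces.

    Missing slots respect the M/S/L coupling (a slot's S and incident L
    are missing along with its M).
    """
    rng = np.random.default_rng(seed)
    p = model.structure.n_positions
    M, S = [], []
    for i in range(p):
        if rng.random() < p_missing:
            M.append(MISSING)
            S.append(MISSING)
        else:
            M.append(model.motif_states[rng.integers(
                len(model.motif_states))])
            S.append(model.strand_states[rng.integers(2)])
    L = []
    for i in range(p - 1):
        if M[i] == MISSING or M[i + 1] == MISSING:
            L.append(MISSING)
        else:
            L.append(model.spacer_states[rng.integers(
                len(model.spacer_states))])
    return FeatureVector("rv", "unknown", M, S, L)
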