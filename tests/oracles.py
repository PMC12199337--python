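"""Independent naive reference implementations used as test oracles.

Everything here works from first principles with dictionary counting and
explicit loops — no shared code with the package's optimized kernels.
"""

from __future__ import annotations

import math
from collections import Counter
from itertools import combinations


def naive_entropy(seq) -> float:
    counts = Counter(seq)
    n = len(seq)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def naive_mi(x, y) -> float:
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    n = len(x)
    mi = 0.0
    for (a, b), c in joint.items():
        p_ab = c / n
        mi += p_ab * math.log2(p_ab * n * n / (px[a] * py[b]))
    return max(mi, 0.0)


def naive_specific_info(t_seq, r_seq, t) -> float:
    """I_spec(T=t; R) = sum_r p(r|t) log2(p(t|r)/p(t)) from raw samples."""
    n = len(t_seq)
    pt = sum(1 for v in t_seq if v == t) / n
    if pt == 0:
        raise ValueError("p(t) = 0")
    val = 0.0
    r_values = set(r_seq)
    for r in r_values:
        n_r = sum(1 for v in r_seq if v == r)
        n_tr = sum(1 for a, b in zip(t_seq, r_seq) if a == t and b == r)
        if n_tr == 0:
            continue
        p_r_given_t = n_tr / (pt * n)
        p_t_given_r = n_tr / n_r
        val += p_r_given_t * (math.log2(1 / pt) - math.log2(1 / p_t_given_r))
    return val


def naive_redundancy(t_seq, r_seq, p_seq) -> float:
    n = len(t_seq)
    rdn = 0.0
    for t in set(t_seq):
        pt = sum(1 for v in t_seq if v == t) / n
        rdn += pt * min(
            naive_specific_info(t_seq, r_seq, t),
            naive_specific_info(t_seq, p_seq, t),
        )
    return rdn


def naive_pid(t_seq, r_seq, p_seq) -> dict:
    rdn = naive_redundancy(t_seq, r_seq, p_seq)
    mi_r = naive_mi(t_seq, r_seq)
    mi_p = naive_mi(t_seq, p_seq)
    unq_r = mi_r - rdn
    unq_p = mi_p - rdn
    joint_src = list(zip(r_seq, p_seq))
    mi_joint = naive_mi(t_seq, joint_src)
    return {
        "mi": mi_r,
        "rdn": rdn,
        "unq_r": unq_r,
        "unq_p": unq_p,
        "syn": mi_joint - unq_r - unq_p - rdn,
    }


def naive_puc(bins_by_gene: dict, regulator, target) -> float:
    """PUC(R;T) = sum over partners P of (I(T;R) - Rdn(T;R,P)) / I(R;T)."""
    t_seq = bins_by_gene[target]
    r_seq = bins_by_gene[regulator]
    i_rt = naive_mi(r_seq, t_seq)
    if i_rt <= 0:
        return 0.0
    total = 0.0
    for partner, p_seq in bins_by_gene.items():
        if partner in (regulator, target):
            continue
        unq = i_rt - naive_redundancy(t_seq, r_seq, p_seq)
        total += max(unq, 0.0)
    return total / i_rt


def naive_symmetrized_puc(bins_by_gene: dict, regulators, targets) -> dict:
    """Stored score per (R, T): directional PUC, averaged with the reverse
    direction whenever the regulator is itself in the target set."""
    target_set = set(targets)
    out = {}
    for r in regulators:
        for t in targets:
            if r == t:
                continue
            score = naive_puc(bins_by_gene, r, t)
            if r in target_set:
                score = 0.5 * (score + naive_puc(bins_by_gene, t, r))
            out[(r, t)] = score
    return out


def naive_ecdf_weights(scores: dict) -> dict:
    """Eq-by-eq ECDF normalization of a {(R, T): score} map."""
    pools: dict = {}
    for (r, t), v in scores.items():
        pools.setdefault(r, []).append(v)
        pools.setdefault(t, []).append(v)
    out = {}
    for (r, t), v in scores.items():
        f_r = sum(1 for x in pools[r] if x <= v) / len(pools[r])
        f_t = sum(1 for x in pools[t] if x <= v) / len(pools[t])
        out[(r, t)] = 0.5 * (f_r + f_t)
    return out


def pair_count_auroc(scores, positive) -> float:
    """AUROC by exhaustive positive-negative pair enumeration."""
    pos = [s for s, p in zip(scores, positive) if p]
    neg = [s for s, p in zip(scores, positive) if not p]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def hypergeom_tail_bruteforce(n_universe, n_a, n_b, overlap) -> float:
    """P(X >= overlap) by summing exact hypergeometric terms."""
    total = 0.0
    for k in range(overlap, min(n_a, n_b) + 1):
        total += (
            math.comb(n_b, k)
            * math.comb(n_universe - n_b, n_a - k)
            / math.comb(n_universe, n_a)
        )
    return total
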