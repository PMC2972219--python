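"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (itertools enumeration, grid/hill
climbing on the raw likelihood, closed-form arithmetic) and shares no
code path with the package implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def fisher_rx2_enumeration(table) -> float:
    """Two-sided Fisher p for an r x 2 table by direct enumeration."""
    t = np.asarray(table, dtype=int)
    rows = t.sum(axis=1)
    n1 = int(t[:, 0].sum())

    def prob(x):
        num = 1.0
        for ri, xi in zip(rows, x):
            num *= math.comb(int(ri), int(xi))
        return num / math.comb(int(rows.sum()), n1)

    p_obs = prob(t[:, 0])
    total = 0.0
    ranges = [range(int(r) + 1) for r in rows]
    for x in itertools.product(*ranges):
        if sum(x) != n1:
            continue
        p = prob(x)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return total


def hwe_exact_enumeration(genotype_counts: dict) -> float:
    """Exact conditional HWE p-value by enumerating genotype tables.

    ``genotype_counts`` maps unordered allele pairs to counts.
    """
    alleles = sorted({a for pair in genotype_counts for a in pair})
    k = len(alleles)
    aidx = {a: i for i, a in enumerate(alleles)}
    n = sum(genotype_counts.values())
    allele_counts = [0] * k
    for (a, b), c in genotype_counts.items():
        allele_counts[aidx[a]] += c
        allele_counts[aidx[b]] += c
    pair_list = [(i, j) for i in range(k) for j in range(i, k)]

    def table_prob(counts_by_pair):
        from fractions import Fraction

        het = sum(c for (i, j), c in zip(pair_list, counts_by_pair) if i != j)
        num = Fraction(math.factorial(n) * (2**het))
        for c in counts_by_pair:
            num /= math.factorial(c)
        for ac in allele_counts:
            num *= math.factorial(ac)
        return float(num / math.factorial(2 * n))

    obs = [genotype_counts.get((alleles[i], alleles[j]), 0) for i, j in pair_list]
    p_obs = table_prob(obs)

    total = 0.0
    # enumerate all genotype tables with the observed allele counts
    def rec(pos, rem, acc):
        nonlocal total
        if pos == len(pair_list):
            if all(r == 0 for r in rem):
                p = table_prob(acc)
                if p <= p_obs * (1 + 1e-9):
                    total += p
            return
        i, j = pair_list[pos]
        if i == j:
            top = rem[i] // 2
        else:
            top = min(rem[i], rem[j])
        for c in range(top + 1):
            if i == j:
                rem[i] -= 2 * c
            else:
                rem[i] -= c
                rem[j] -= c
            rec(pos + 1, rem, acc + [c])
            if i == j:
                rem[i] += 2 * c
            else:
                rem[i] += c
                rem[j] += c

    rec(0, list(allele_counts), [])
    return total


def pair_likelihood(freq: np.ndarray, genos: list) -> float:
    """Log-likelihood of unphased two-locus genotypes given haplotype
    frequencies ``freq[(i, j)]`` over allele index pairs."""
    ll = 0.0
    for (a1, a2), (b1, b2) in genos:
        if a1 != a2 and b1 != b2:
            p = 2 * freq[a1, b1] * freq[a2, b2] + 2 * freq[a1, b2] * freq[a2, b1]
        elif a1 == a2 and b1 == b2:
            p = freq[a1, b1] ** 2
        else:
            p = 2 * freq[a1, b1] * freq[a2, b2]
        ll += math.log(max(p, 1e-300))
    return ll


def grid_mle(genos: list, k: int, l: int, coarse: float = 0.1) -> tuple[np.ndarray, float]:
    """Maximize the two-locus haplotype likelihood by a coarse simplex
    grid followed by pairwise mass-shift hill climbing.

    ``genos`` is a list of ((a1, a2), (b1, b2)) allele-index genotypes.
    Returns (frequency matrix, log-likelihood).
    """
    # support: haplotypes appearing in some resolution of some genotype
    support = set()
    for (a1, a2), (b1, b2) in genos:
        support |= {(a1, b1), (a2, b2), (a1, b2), (a2, b1)}
    support = sorted(support)
    h = len(support)

    def to_matrix(weights):
        f = np.zeros((k, l))
        for (i, j), w in zip(support, weights):
            f[i, j] = w
        return f

    # coarse grid over the simplex
    steps = int(round(1 / coarse))
    best_w, best_ll = None, -np.inf
    tops = []
    for comp in itertools.combinations(range(steps + h - 1), h - 1):
        parts = []
        prev = -1
        for c in comp:
            parts.append(c - prev - 1)
            prev = c
        parts.append(steps + h - 1 - prev - 1)
        w = np.array(parts, dtype=float) / steps
        ll = pair_likelihood(to_matrix(w), genos)
        tops.append((ll, w))
    tops.sort(key=lambda t: -t[0])
    candidates = [w for _, w in tops[:10]]

    for w0 in candidates:
        w = w0.copy()
        ll = pair_likelihood(to_matrix(w), genos)
        delta = coarse / 2
        while delta > 1e-7:
            improved = True
            while improved:
                improved = False
                for i in range(h):
                    for j in range(h):
                        if i == j or w[j] < delta:
                            continue
                        w2 = w.copy()
                        w2[i] += delta
                        w2[j] -= delta
                        ll2 = pair_likelihood(to_matrix(w2), genos)
                        if ll2 > ll + 1e-13:
                            w, ll = w2, ll2
                            improved = True
            delta /= 2
        if ll > best_ll:
            best_w, best_ll = w, ll
    return to_matrix(best_w), best_ll


def random_pair_instance(rng: np.random.Generator, max_alleles: int = 3,
                         n_individuals: int = 8):
    """Random small two-locus genotype sample (allele indices)."""
    k = int(rng.integers(2, max_alleles + 1))
    l = int(rng.integers(2, max_alleles + 1))
    # draw true haplotype frequencies, then genotypes
    f = rng.dirichlet(np.ones(k * l)).reshape(k, l)
    genos = []
    for _ in range(n_individuals):
        h1 = rng.choice(k * l, p=f.ravel())
        h2 = rng.choice(k * l, p=f.ravel())
        a = tuple(sorted((h1 // l, h2 // l)))
        b = tuple(sorted((h1 % l, h2 % l)))
        genos.append((a, b))
    return genos, k, l


def genos_to_arrays(genos):
    """Allele-index genotypes -> 1-based allele-code arrays."""
    ga = np.array([[a1 + 1, a2 + 1] for (a1, a2), _ in genos])
    gb = np.array([[b1 + 1, b2 + 1] for _, (b1, b2) in genos])
    return ga, gb
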