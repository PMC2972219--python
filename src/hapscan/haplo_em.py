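"""Two-locus haplotype frequency estimation by expectation-maximization.

For a pair of linked multiallelic markers typed on unphased diploids,
the only phase-ambiguous individuals are double heterozygotes: a
genotype (a1/a2, b1/b2) with a1 != a2 and b1 != b2 is consistent with
the two haplotype resolutions {a1-b1, a2-b2} and {a1-b2, a2-b1}.  The
EM algorithm distributes each double heterozygote across its two
resolutions proportionally to the current haplotype-frequency products
(E-step) and re-estimates frequencies as expected haplotype counts over
2n (M-step).  All other genotypes have a unique resolution and
contribute fixed counts.

Only two-locus estimation is provided; the association scan consumes
consecutive marker pairs and never longer windows.  Individuals missing
either marker of the pair are excluded pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class EMError(ValueError):
    """Raised when a pair has no usable individuals."""


@dataclass
class PairHaplotypeResults:
    """Fitted two-locus haplotype frequencies.

    Attributes
    ----------
    alleles_a, alleles_b : ndarray
        Sorted allele codes observed at each locus among usable
        individuals.
    freq : ndarray of shape (k, l)
        Haplotype frequencies; ``freq[i, j]`` is the frequency of the
        haplotype carrying ``alleles_a[i]`` and ``alleles_b[j]``.
    loglike : float
        Final log-likelihood of the unphased genotype sample.
    n : int
        Individuals with both markers non-missing.
    """

    alleles_a: np.ndarray
    alleles_b: np.ndarray
    freq: np.ndarray
    loglike: float
    iterations: int
    converged: bool
    n: int
    loglike_path: np.ndarray = field(repr=False, default=None)

    @property
    def p(self) -> np.ndarray:
        """Marginal allele frequencies at locus A."""
        return self.freq.sum(axis=1)

    @property
    def q(self) -> np.ndarray:
        """Marginal allele frequencies at locus B."""
        return self.freq.sum(axis=0)

    def frequencies(self) -> pd.Series:
        """Haplotype frequencies as a Series indexed by (allele_a, allele_b)."""
        idx = pd.MultiIndex.from_product(
            [self.alleles_a, self.alleles_b], names=["allele_a", "allele_b"]
        )
        return pd.Series(self.freq.ravel(), index=idx, name="frequency")

    def summary(self) -> str:
        lines = [
            "Two-locus haplotype EM",
            f"  n individuals : {self.n}",
            f"  alleles       : {len(self.alleles_a)} x {len(self.alleles_b)}",
            f"  log-likelihood: {self.loglike:.6f}",
            f"  iterations    : {self.iterations} "
            f"({'converged' if self.converged else 'NOT converged'})",
            "  haplotype frequencies (> 1e-6):",
        ]
        ser = self.frequencies()
        for (a, b), f in ser[ser > 1e-6].sort_values(ascending=False).items():
            lines.append(f"    {a}-{b}: {f:.6f}")
        return "\n".join(lines)


class PairHaplotypeEM:
    """EM model for one marker pair.

    Parameters
    ----------
    genotypes_a, genotypes_b : array-like of shape (n, 2)
        Unordered allele pairs per individual (codes sorted ascending;
        negative codes mean missing).
    """

    def __init__(self, genotypes_a, genotypes_b):
        ga = np.asarray(genotypes_a, dtype=np.int64)
        gb = np.asarray(genotypes_b, dtype=np.int64)
        if ga.ndim != 2 or ga.shape[1] != 2 or ga.shape != gb.shape:
            raise ValueError("genotype arrays must both have shape (n, 2)")
        ga = np.sort(ga, axis=1)
        gb = np.sort(gb, axis=1)
        self._usable = (ga >= 0).all(axis=1) & (gb >= 0).all(axis=1)
        self._ga, self._gb = ga, gb

    def fit(
        self, tol: float = 1e-8, max_iter: int = 1000, init: np.ndarray | None = None
    ) -> PairHaplotypeResults:
        """Run EM to convergence on the maximum absolute frequency change.

        The default start is the linkage-equilibrium product of observed
        allele frequencies, perturbed by +1e-6 on the lexicographically
        first haplotype supported by a double heterozygote; the pure
        product form is an EM fixed point (a saddle when every usable
        individual is a double heterozygote) and the perturbation breaks
        it deterministically.
        """
        if not self._usable.any():
            raise EMError("no individuals with both markers non-missing")
        A = self._ga[self._usable]
        B = self._gb[self._usable]
        n = A.shape[0]
        alleles_a = np.unique(A)
        alleles_b = np.unique(B)
        k, l = len(alleles_a), len(alleles_b)
        ai = np.searchsorted(alleles_a, A)
        bi = np.searchsorted(alleles_b, B)

        # collapse to genotype classes for speed
        rows = np.column_stack([ai, bi])
        uniq, counts = np.unique(rows, axis=0, return_counts=True)
        a1, a2, b1, b2 = uniq[:, 0], uniq[:, 1], uniq[:, 2], uniq[:, 3]
        m = counts.astype(float)
        dh = (a1 != a2) & (b1 != b2)
        # unique resolution {a1-b1, a2-b2} covers every unambiguous class
        base = np.zeros((k, l))
        np.add.at(base, (a1[~dh], b1[~dh]), m[~dh])
        np.add.at(base, (a2[~dh], b2[~dh]), m[~dh])
        het_mult = np.where((a1 == a2) & (b1 == b2), 0.0, np.log(2.0))

        d_a1, d_a2, d_b1, d_b2, d_m = a1[dh], a2[dh], b1[dh], b2[dh], m[dh]

        if init is not None:
            f = np.array(init, dtype=float)
            if f.shape != (k, l):
                raise ValueError(f"init must have shape ({k}, {l})")
            f = f / f.sum()
        else:
            pa = np.bincount(ai.ravel(), minlength=k) / (2.0 * n)
            qb = np.bincount(bi.ravel(), minlength=l) / (2.0 * n)
            f = pa[:, None] * qb[None, :]
            if dh.any():
                cand = np.concatenate(
                    [
                        np.column_stack([d_a1, d_b1]),
                        np.column_stack([d_a2, d_b2]),
                        np.column_stack([d_a1, d_b2]),
                        np.column_stack([d_a2, d_b1]),
                    ]
                )
                order = np.lexsort((cand[:, 1], cand[:, 0]))
                first = cand[order[0]]
                f[first[0], first[1]] += 1e-6
                f /= f.sum()

        def loglike(freq: np.ndarray) -> float:
            p1 = freq[a1, b1] * freq[a2, b2]
            if dh.any():
                p1 = p1.copy()
                p1[dh] += freq[d_a1, d_b2] * freq[d_a2, d_b1]
            return float(np.sum(m * (het_mult + np.log(np.maximum(p1, 1e-300)))))

        ll = loglike(f)
        path = [ll]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            C = base.copy()
            if d_m.size:
                w1 = f[d_a1, d_b1] * f[d_a2, d_b2]
                w2 = f[d_a1, d_b2] * f[d_a2, d_b1]
                tot = w1 + w2
                r1 = np.where(tot > 0, w1 / np.where(tot > 0, tot, 1.0), 0.5)
                np.add.at(C, (d_a1, d_b1), d_m * r1)
                np.add.at(C, (d_a2, d_b2), d_m * r1)
                np.add.at(C, (d_a1, d_b2), d_m * (1.0 - r1))
                np.add.at(C, (d_a2, d_b1), d_m * (1.0 - r1))
            f_new = C / (2.0 * n)
            ll_new = loglike(f_new)
            if not np.isfinite(ll_new) or not np.all(np.isfinite(f_new)):
                raise AssertionError("non-finite EM state")
            if ll_new < ll - 1e-9 * (1.0 + abs(ll)):
                raise AssertionError(
                    f"EM log-likelihood decreased: {ll} -> {ll_new}"
                )
            delta = float(np.max(np.abs(f_new - f)))
            f, ll = f_new, ll_new
            path.append(ll)
            if delta < tol:
                converged = True
                break

        assert abs(f.sum() - 1.0) < 1e-12
        return PairHaplotypeResults(
            alleles_a=alleles_a,
            alleles_b=alleles_b,
            freq=f,
            loglike=ll,
            iterations=it,
            converged=converged,
            n=n,
            loglike_path=np.asarray(path),
        )


def em_pair(genotypes_a, genotypes_b, **kwargs) -> PairHaplotypeResults:
    """Convenience wrapper: ``PairHaplotypeEM(ga, gb).fit(**kwargs)``."""
    return PairHaplotypeEM(genotypes_a, genotypes_b).fit(**kwargs)


def assign_best_phase(
    results: PairHaplotypeResults, genotypes_a, genotypes_b
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each individual its most likely two-haplotype resolution.

    Unambiguous individuals get their unique resolution; double
    heterozygotes get the resolution with the larger haplotype-frequency
    product, breaking exact ties toward the lexicographically smaller
    haplotype pair (which is the {a1-b1, a2-b2} resolution, since allele
    codes are canonically sorted).

    Returns
    -------
    phases : ndarray of shape (n, 2, 2)
        ``phases[i, h]`` is the (allele_a, allele_b) pair of haplotype h
        of individual i; rows of -1 mark individuals missing either
        marker (no assignment).
    tie : ndarray of bool, shape (n,)
        True where a double heterozygote had an exact product tie.
    """
    ga = np.sort(np.asarray(genotypes_a, dtype=np.int64), axis=1)
    gb = np.sort(np.asarray(genotypes_b, dtype=np.int64), axis=1)
    n = ga.shape[0]
    phases = np.full((n, 2, 2), -1, dtype=np.int64)
    tie = np.zeros(n, dtype=bool)
    usable = (ga >= 0).all(axis=1) & (gb >= 0).all(axis=1)
    if not usable.any():
        return phases, tie

    ai = np.searchsorted(results.alleles_a, ga[usable])
    bi = np.searchsorted(results.alleles_b, gb[usable])
    known = (
        (ai < len(results.alleles_a))
        & (results.alleles_a[np.minimum(ai, len(results.alleles_a) - 1)] == ga[usable])
    ).all(axis=1) & (
        (bi < len(results.alleles_b))
        & (results.alleles_b[np.minimum(bi, len(results.alleles_b) - 1)] == gb[usable])
    ).all(axis=1)
    if not known.all():
        raise ValueError("genotype carries an allele absent from the fitted model")

    a1, a2 = ai[:, 0], ai[:, 1]
    b1, b2 = bi[:, 0], bi[:, 1]
    f = results.freq
    dh = (a1 != a2) & (b1 != b2)
    w1 = f[a1, b1] * f[a2, b2]
    w2 = f[a1, b2] * f[a2, b1]
    swap = dh & (w2 > w1)
    tied = dh & (w1 == w2)

    ca = np.stack([results.alleles_a[a1], results.alleles_a[a2]], axis=1)
    cb1 = np.where(swap, results.alleles_b[b2], results.alleles_b[b1])
    cb2 = np.where(swap, results.alleles_b[b1], results.alleles_b[b2])
    out = np.stack(
        [np.stack([ca[:, 0], cb1], axis=1), np.stack([ca[:, 1], cb2], axis=1)],
        axis=1,
    )
    phases[usable] = out
    tie[usable] = tied
    return phases, tie
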