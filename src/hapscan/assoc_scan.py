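"""The association engine: HWE screening, haplotype count tables,
Fisher's exact test on r x 2 tables, Yates-corrected chi-square, and
the consecutive-pair scan.

The scan contrasts tail-selected "high" and "low" phenotype groups.
For every consecutive marker pair on a chromosome, two-locus haplotype
frequencies are estimated by EM on the pooled sample, minor haplotypes
(combined frequency below a threshold, default 5%) are removed, and the
remaining haplotype counts per group form an r x 2 table tested with
Fisher's exact test.  Significance is judged against Bonferroni
chromosome-wise (alpha / tests on the chromosome) and genome-wise
(alpha / tests genome-wide) thresholds.  Yates-corrected chi-square
values of the same tables, with their degrees of freedom r - 1, feed
the genomic-control computation in :mod:`hapscan.popgen`.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .genio import GeneticMap, GenotypeMatrix
from .haplo_em import EMError, PairHaplotypeEM, PairHaplotypeResults, assign_best_phase

logger = logging.getLogger("hapscan")

_LOG2 = np.log(2.0)


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact / Monte-Carlo test (multiallelic)
# ---------------------------------------------------------------------------

@dataclass
class HWEResult:
    marker: str | None
    group: str | None
    p: float
    method: str                     # "exact-enumeration" | "monte-carlo"
    genotype_counts: dict
    n_tables: int = 0
    reps: int = 0
    mc_se: float = 0.0

    def __float__(self) -> float:
        return self.p


class _EnumLimit(Exception):
    pass


def _hwe_log_prob_const(allele_counts: np.ndarray, n_ind: int) -> float:
    # log [ n! * prod a_i! / (2n)! ]; the table-dependent part is
    # H*log2 - sum log n_ij!
    return float(
        gammaln(n_ind + 1) + gammaln(allele_counts + 1).sum() - gammaln(2 * n_ind + 1)
    )


def _hwe_enumerate(allele_counts: np.ndarray, limit: int):
    """Yield (het_count, sum_log_fact_nij) over all genotype tables with
    the given allele counts.  Raises _EnumLimit beyond `limit` tables."""
    k = len(allele_counts)
    out: list[tuple[int, float]] = []
    rem = allele_counts.astype(int).copy()

    def rec(i: int, j: int, het: int, slf: float):
        if len(out) > limit:
            raise _EnumLimit
        if i == k:
            out.append((het, slf))
            return
        if j == k:
            rec(i + 1, i + 1, het, slf)
            return
        if i == j:
            if i == k - 1:
                # last diagonal cell: forced
                if rem[i] % 2 == 0:
                    nii = rem[i] // 2
                    out.append((het, slf + float(gammaln(nii + 1))))
                    if len(out) > limit:
                        raise _EnumLimit
                return
            for nii in range(rem[i] // 2 + 1):
                rem[i] -= 2 * nii
                rec(i, j + 1, het, slf + float(gammaln(nii + 1)))
                rem[i] += 2 * nii
        else:
            if j == k - 1:
                # last cell of row i: forced to exhaust allele i
                nij = rem[i]
                if nij <= rem[j]:
                    rem[i] -= nij
                    rem[j] -= nij
                    rec(i + 1, i + 1, het + nij, slf + float(gammaln(nij + 1)))
                    rem[i] += nij
                    rem[j] += nij
                return
            for nij in range(min(rem[i], rem[j]) + 1):
                rem[i] -= nij
                rem[j] -= nij
                rec(i, j + 1, het + nij, slf + float(gammaln(nij + 1)))
                rem[i] += nij
                rem[j] += nij

    rec(0, 0, 0, 0.0)
    return out


def _genotype_table(genotypes) -> tuple[np.ndarray, np.ndarray, int]:
    """Reduce genotypes to (allele codes, genotype count matrix, n)."""
    if isinstance(genotypes, dict):
        pairs = []
        for (x, y), cnt in genotypes.items():
            pairs.extend([(min(x, y), max(x, y))] * int(cnt))
        g = np.array(pairs, dtype=np.int64).reshape(-1, 2)
    else:
        g = np.sort(np.asarray(genotypes, dtype=np.int64), axis=1)
        g = g[(g >= 0).all(axis=1)]
    if g.shape[0] == 0:
        raise ValueError("no genotyped individuals")
    alleles = np.unique(g)
    idx = np.searchsorted(alleles, g)
    k = len(alleles)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (idx[:, 0], idx[:, 1]), 1)
    return alleles, counts, g.shape[0]


def hwe_test(
    genotypes,
    mc_reps: int = 10_000,
    seed: int = 0,
    enum_limit: int = 1_000_000,
    marker: str | None = None,
    group: str | None = None,
) -> HWEResult:
    """Exact conditional test for Hardy-Weinberg deviation at one marker.

    Conditions on the observed allele counts and sums the probabilities
    of all genotype tables no more probable than the observed one
    (enumeration when at most ``enum_limit`` tables, otherwise a
    Monte-Carlo version of the same test with reported standard error).

    ``genotypes`` is either an (n, 2) array of unordered allele pairs
    (negative codes = missing, excluded) or a dict mapping allele pairs
    to counts.  A monomorphic marker returns p = 1.
    """
    alleles, counts, n = _genotype_table(genotypes)
    k = len(alleles)
    iu = np.triu_indices(k)
    table_counts = {
        (int(alleles[i]), int(alleles[j])): int(counts[i, j])
        for i, j in zip(*iu)
        if counts[i, j] > 0
    }
    if k == 1:
        return HWEResult(marker, group, 1.0, "exact-enumeration", table_counts, 1)

    # row+col sums count the diagonal twice = the two copies of a homozygote
    allele_counts = counts.sum(axis=0) + counts.sum(axis=1)
    n_het = int(counts.sum() - np.trace(counts))
    stat_obs = n_het * _LOG2 - float(gammaln(counts[iu] + 1).sum())
    tol = 1e-12 * max(1.0, abs(stat_obs))

    try:
        tables = _hwe_enumerate(allele_counts, enum_limit)
    except (_EnumLimit, RecursionError):
        tables = None

    if tables is not None:
        stats = np.array([h * _LOG2 - s for h, s in tables])
        const = _hwe_log_prob_const(allele_counts.astype(float), n)
        logp = const + stats
        # sanity: probabilities sum to 1
        assert abs(np.exp(logsumexp(logp)) - 1.0) < 1e-8
        mask = stats <= stat_obs + tol
        p = float(np.exp(logsumexp(logp[mask])))
        return HWEResult(
            marker, group, min(p, 1.0), "exact-enumeration", table_counts,
            n_tables=len(tables),
        )

    # Monte-Carlo: random re-pairings of the allele pool
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(k), allele_counts)
    perms = rng.permuted(np.tile(pool, (mc_reps, 1)), axis=1)
    g1 = np.minimum(perms[:, 0::2], perms[:, 1::2])
    g2 = np.maximum(perms[:, 0::2], perms[:, 1::2])
    het = (g1 != g2).sum(axis=1)
    comb = g1 * k + g2 + np.arange(mc_reps)[:, None] * (k * k)
    bc = np.bincount(comb.ravel(), minlength=mc_reps * k * k).reshape(mc_reps, k * k)
    stats = het * _LOG2 - gammaln(bc + 1).sum(axis=1)
    hits = int((stats <= stat_obs + tol).sum())
    p = (hits + 1) / (mc_reps + 1)
    mc_se = float(np.sqrt(p * (1 - p) / mc_reps))
    return HWEResult(
        marker, group, p, "monte-carlo", table_counts, reps=mc_reps, mc_se=mc_se
    )


# ---------------------------------------------------------------------------
# Fisher's exact test on r x 2 tables
# ---------------------------------------------------------------------------

@dataclass
class FisherExactResult:
    p: float
    method: str                    # "enumeration" | "monte-carlo"
    n_tables: int = 0
    reps: int = 0
    mc_se: float = 0.0

    def __float__(self) -> float:
        return self.p


def _validate_rx2(table) -> np.ndarray:
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[1] != 2 or t.shape[0] < 2:
        raise ValueError("table must be r x 2 with r >= 2")
    if (t < 0).any():
        raise ValueError("negative counts")
    if (t.sum(axis=0) == 0).any():
        raise ValueError("empty column")
    return t


def fisher_exact_rx2(
    table, *, enum_limit: float = 1e7, mc_reps: int = 20_000, seed: int = 0
) -> FisherExactResult:
    """Two-sided Fisher exact test for an r x 2 contingency table.

    Under the multivariate hypergeometric null with both margins fixed,
    the two-sided p-value sums the probabilities of all tables whose
    probability does not exceed the observed table's (relative tie
    tolerance 1e-12).  Full enumeration is used when the table-count
    bound prod(row_i + 1) is at most ``enum_limit``; otherwise
    Monte-Carlo sampling of tables with fixed seed, with the observed
    table included in the count ((hits+1)/(reps+1)) and a reported
    standard error.
    """
    t = _validate_rx2(table)
    R = t.sum(axis=1)
    n1 = int(t[:, 0].sum())
    lp_obs = float(_log_comb(R, t[:, 0]).sum())
    tol = 1e-12 * max(1.0, abs(lp_obs))
    log_norm = float(_log_comb(R.sum(), n1))

    if float(np.prod(R + 1.0)) <= enum_limit:
        rem_after = np.concatenate([np.cumsum(R[::-1])[::-1][1:], [0]])
        s = np.zeros(1, dtype=np.int64)
        lp = np.zeros(1)
        for i in range(len(R)):
            lo = np.maximum(0, n1 - s - rem_after[i])
            hi = np.minimum(R[i], n1 - s)
            cnt = hi - lo + 1
            keep = cnt > 0
            s, lp, lo, cnt = s[keep], lp[keep], lo[keep], cnt[keep]
            idx = np.repeat(np.arange(len(s)), cnt)
            ends = np.cumsum(cnt)
            offs = np.arange(ends[-1]) - np.repeat(ends - cnt, cnt)
            x = lo[idx] + offs
            lp = lp[idx] + _log_comb(R[i], x)
            s = s[idx] + x
        assert (s == n1).all()
        # sanity: total probability mass is 1
        assert abs(np.exp(logsumexp(lp) - log_norm) - 1.0) < 1e-8
        mask = lp <= lp_obs + tol
        p = float(np.exp(logsumexp(lp[mask]) - log_norm))
        return FisherExactResult(min(p, 1.0), "enumeration", n_tables=len(lp))

    rng = np.random.default_rng(seed)
    x = rng.multivariate_hypergeometric(R, n1, size=mc_reps)
    lp = _log_comb(R[None, :], x).sum(axis=1)
    hits = int((lp <= lp_obs + tol).sum())
    p = (hits + 1) / (mc_reps + 1)
    mc_se = float(np.sqrt(p * (1 - p) / mc_reps))
    return FisherExactResult(p, "monte-carlo", reps=mc_reps, mc_se=mc_se)


def yates_chi2(table) -> tuple[float, int]:
    """Yates continuity-corrected chi-square of an r x 2 table.

    chi2 = sum over cells of (max(|O - E| - 0.5, 0))^2 / E with expected
    counts from the margins; df = r - 1.  A zero expected cell means an
    empty haplotype row survived upstream filtering and is an error.
    """
    t = _validate_rx2(table).astype(float)
    E = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if (E == 0).any():
        raise ValueError("zero expected cell; filter empty rows upstream")
    adj = np.maximum(np.abs(t - E) - 0.5, 0.0)
    chi2 = float((adj**2 / E).sum())
    return chi2, t.shape[0] - 1


def pearson_chi2(table) -> tuple[float, int]:
    """Uncorrected Pearson chi-square of an r x 2 table; df = r - 1."""
    t = _validate_rx2(table).astype(float)
    E = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if (E == 0).any():
        raise ValueError("zero expected cell; filter empty rows upstream")
    return float(((t - E) ** 2 / E).sum()), t.shape[0] - 1


# ---------------------------------------------------------------------------
# Haplotype count tables
# ---------------------------------------------------------------------------

@dataclass
class PairTable:
    """Filtered haplotype x group count table for one marker pair."""

    haplotypes: list[tuple[int, int]]       # retained, by descending combined freq
    counts: np.ndarray                      # (r, 2) ints, columns (high, low)
    retained_freq: np.ndarray               # combined EM frequency of each row
    dropped_mass: float                     # combined frequency mass removed
    n_dropped: int
    testable: bool

    @property
    def df(self) -> int:
        return len(self.haplotypes) - 1


def build_pair_table(
    model: PairHaplotypeResults,
    genotypes_a,
    genotypes_b,
    groups,
    min_freq: float = 0.05,
    mode: str = "best-phase",
) -> PairTable:
    """Build the r x 2 haplotype count table for a fitted pair.

    Haplotypes with combined-sample EM frequency below ``min_freq`` are
    removed (the filter is applied on the pooled frequencies, never per
    group).  ``mode='best-phase'`` (default) counts integer haplotypes
    from most-likely phase assignments under the pooled model;
    ``mode='em-expected'`` refits EM within each group and rounds the
    expected haplotype counts 2 n_g f_g(h) to the nearest integer.
    """
    groups = np.asarray(groups)
    if not set(np.unique(groups)) <= {"high", "low"}:
        raise ValueError("groups must be 'high'/'low' labels")
    k, l = model.freq.shape
    flat = model.freq.ravel()
    retained = np.flatnonzero(flat >= min_freq)
    # order by descending combined frequency, lexicographic tie-break
    retained = retained[np.lexsort((retained, -flat[retained]))]
    n_dropped = int((flat < min_freq).sum())
    dropped_mass = float(flat[flat < min_freq].sum())
    haps = [
        (int(model.alleles_a[r // l]), int(model.alleles_b[r % l])) for r in retained
    ]

    counts = np.zeros((len(haps), 2), dtype=np.int64)
    if mode == "best-phase":
        phases, _tie = assign_best_phase(model, genotypes_a, genotypes_b)
        hap_index = {h: i for i, h in enumerate(haps)}
        for col, label in enumerate(("high", "low")):
            sel = (groups == label) & (phases[:, 0, 0] >= 0)
            for hap in phases[sel].reshape(-1, 2):
                i = hap_index.get((int(hap[0]), int(hap[1])))
                if i is not None:
                    counts[i, col] += 1
    elif mode == "em-expected":
        ga = np.asarray(genotypes_a)
        gb = np.asarray(genotypes_b)
        for col, label in enumerate(("high", "low")):
            sel = groups == label
            try:
                sub = PairHaplotypeEM(ga[sel], gb[sel]).fit()
            except EMError:
                continue
            for i, (a, b) in enumerate(haps):
                ia = np.searchsorted(sub.alleles_a, a)
                ib = np.searchsorted(sub.alleles_b, b)
                if (
                    ia < len(sub.alleles_a)
                    and sub.alleles_a[ia] == a
                    and ib < len(sub.alleles_b)
                    and sub.alleles_b[ib] == b
                ):
                    counts[i, col] = int(round(2 * sub.n * sub.freq[ia, ib]))
    else:
        raise ValueError(f"unknown table mode {mode!r}")

    nonzero_cols = (counts.sum(axis=0) > 0).all()
    testable = len(haps) >= 2 and bool(nonzero_cols)
    return PairTable(
        haplotypes=haps,
        counts=counts,
        retained_freq=flat[retained],
        dropped_mass=dropped_mass,
        n_dropped=n_dropped,
        testable=testable,
    )


# ---------------------------------------------------------------------------
# Scan orchestration
# ---------------------------------------------------------------------------

@dataclass
class ScanResults:
    """Results of a consecutive-pair haplotype association scan."""

    pairs: pd.DataFrame
    hwe: pd.DataFrame
    genome_threshold: float
    chromosome_thresholds: dict[str, float]
    n_tests: int
    alpha: float
    tables: dict[tuple[str, str], PairTable] = field(repr=False, default_factory=dict)

    @property
    def chi2_tests(self) -> list[tuple[float, int]]:
        """(Yates chi-square, df) of every testable pair, for genomic control."""
        sub = self.pairs[self.pairs["testable"]]
        return list(zip(sub["chi2_yates"], sub["df"].astype(int)))

    def top_pair(self) -> pd.Series:
        sub = self.pairs[self.pairs["testable"]]
        return sub.loc[sub["p"].idxmin()]

    def plot(self, ax=None):
        """Scan plot: -log10 p per pair midpoint, with Bonferroni lines.

        Requires matplotlib; returns the axes.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        offset = 0.0
        ticks, labels = [], []
        for i, (chrom, sub) in enumerate(
            self.pairs.groupby("chromosome", sort=False)
        ):
            sub = sub[sub["testable"]]
            x = sub["midpoint_cm"] + offset
            ax.scatter(x, -np.log10(sub["p"]), s=12,
                       color=f"C{i % 10}", label=None)
            ticks.append(offset + sub["midpoint_cm"].median())
            labels.append(chrom)
            offset += self.pairs.loc[
                self.pairs["chromosome"] == chrom, "pos_b_cm"
            ].max() + 5.0
        ax.axhline(-np.log10(self.genome_threshold), color="red", lw=1,
                   label="genome-wise")
        ax.set_xticks(ticks, labels)
        ax.set_xlabel("chromosome")
        ax.set_ylabel("-log10 p")
        ax.legend(frameon=False)
        return ax

    def summary(self) -> str:
        sub = self.pairs[self.pairs["testable"]]
        lines = [
            "Haplotype-pair association scan",
            f"  testable pairs       : {self.n_tests} "
            f"(of {len(self.pairs)} consecutive pairs)",
            f"  genome-wise threshold: {self.genome_threshold:.3e} "
            f"(alpha = {self.alpha})",
            f"  genome-wise hits     : {int(sub['genome_significant'].sum())}",
            f"  chromosome-wise hits : {int(sub['chromosome_significant'].sum())}",
        ]
        if len(sub):
            top = self.top_pair()
            lines.append(
                f"  smallest p           : {top['p']:.3e} at "
                f"{top['marker_a']}-{top['marker_b']} "
                f"(chr {top['chromosome']}, {top['midpoint_cm']:.1f} cM)"
            )
        failed = self.hwe[self.hwe["failed"]] if len(self.hwe) else self.hwe
        lines.append(f"  HWE screen failures  : {len(failed)}")
        return "\n".join(lines)


class HaplotypeAssociationScan:
    """Consecutive-pair haplotype association scan over a genetic map.

    Parameters
    ----------
    genotypes : GenotypeMatrix
    gmap : GeneticMap
    groups : mapping or Series
        Individual id -> 'high' / 'low' (anything else is unselected and
        excluded from the scan).
    min_freq : float
        Minor-haplotype removal threshold on combined EM frequencies.
    hwe_alpha : float
        Markers failing the HWE screen in either tail group at this
        level are reported (and dropped only if ``drop_hwe_failures``).
    alpha : float
        Family-wise level for the Bonferroni thresholds.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        gmap: GeneticMap,
        groups,
        *,
        min_freq: float = 0.05,
        hwe_alpha: float = 0.002,
        alpha: float = 0.05,
        drop_hwe_failures: bool = False,
        table_mode: str = "best-phase",
        run_hwe: bool = True,
        hwe_mc_reps: int = 5_000,
        em_tol: float = 1e-8,
        em_max_iter: int = 1000,
        fisher_enum_limit: float = 1e7,
        fisher_mc_reps: int = 20_000,
        seed: int = 0,
    ):
        for m in genotypes.markers:
            if m not in gmap:
                raise ValueError(f"genotyped marker {m!r} is not on the map")
        groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
        selected = [i for i in genotypes.ids if groups.get(i) in ("high", "low")]
        if not selected:
            raise ValueError("no individuals labeled 'high' or 'low'")
        self.genotypes = genotypes.subset_individuals(selected)
        self.labels = np.array([groups[i] for i in selected])
        self.gmap = gmap
        self.min_freq = min_freq
        self.hwe_alpha = hwe_alpha
        self.alpha = alpha
        self.drop_hwe_failures = drop_hwe_failures
        self.table_mode = table_mode
        self.run_hwe = run_hwe
        self.hwe_mc_reps = hwe_mc_reps
        self.em_tol = em_tol
        self.em_max_iter = em_max_iter
        self.fisher_enum_limit = fisher_enum_limit
        self.fisher_mc_reps = fisher_mc_reps
        self.seed = int(seed)

    def _pair_seed(self, index: int) -> int:
        return int((self.seed * 1_000_003 + 7919 * index + 1) % (2**31 - 1))

    def fit(self) -> ScanResults:
        logger.info(
            "scan: %d high / %d low individuals, %d markers",
            int((self.labels == "high").sum()),
            int((self.labels == "low").sum()),
            self.genotypes.n_markers,
        )

        hwe_rows = []
        failed_markers: set[str] = set()
        if self.run_hwe:
            for mi, marker in enumerate(self.genotypes.markers):
                if marker not in self.gmap:
                    continue
                col = self.genotypes.pair(marker)
                for gi, grp in enumerate(("high", "low", "combined")):
                    sub = col if grp == "combined" else col[self.labels == grp]
                    sub = sub[(sub >= 0).all(axis=1)]
                    if sub.shape[0] == 0:
                        continue
                    res = hwe_test(
                        sub,
                        mc_reps=self.hwe_mc_reps,
                        seed=self._pair_seed(3 * mi + gi + 100_000),
                        marker=marker,
                        group=grp,
                    )
                    fail = grp in ("high", "low") and res.p <= self.hwe_alpha
                    if fail:
                        failed_markers.add(marker)
                    hwe_rows.append(
                        {
                            "marker": marker,
                            "group": grp,
                            "p": res.p,
                            "method": res.method,
                            "mc_se": res.mc_se,
                            "failed": fail,
                        }
                    )
            if failed_markers:
                action = "dropped" if self.drop_hwe_failures else "retained (flagged)"
                logger.warning(
                    "%d markers fail HWE at %g in a tail group; %s: %s",
                    len(failed_markers), self.hwe_alpha, action,
                    sorted(failed_markers),
                )
        hwe_frame = pd.DataFrame(
            hwe_rows, columns=["marker", "group", "p", "method", "mc_se", "failed"]
        )

        skip = failed_markers if self.drop_hwe_failures else set()
        rows = []
        tables: dict[tuple[str, str], PairTable] = {}
        pair_idx = 0
        for chrom in self.gmap.chromosomes:
            names, pos = self.gmap.chromosome_markers(chrom)
            names = [m for m in names if m in self.genotypes.markers and m not in skip]
            if len(names) < 2:
                logger.warning("chromosome %s has <2 usable markers; skipped", chrom)
                continue
            for a, b in itertools.pairwise(names):
                pair_idx += 1
                row = {
                    "chromosome": chrom,
                    "marker_a": a,
                    "marker_b": b,
                    "pos_a_cm": self.gmap.position(a),
                    "pos_b_cm": self.gmap.position(b),
                    "midpoint_cm": 0.5 * (self.gmap.position(a) + self.gmap.position(b)),
                    "testable": False,
                    "p": np.nan,
                    "df": 0,
                    "chi2_yates": np.nan,
                    "chi2_pearson": np.nan,
                    "n_haplotypes": 0,
                    "n_used": 0,
                    "fisher_method": "",
                    "haplotypes": "",
                    "counts_high": "",
                    "counts_low": "",
                }
                ga = self.genotypes.pair(a)
                gb = self.genotypes.pair(b)
                try:
                    model = PairHaplotypeEM(ga, gb).fit(
                        tol=self.em_tol, max_iter=self.em_max_iter
                    )
                except EMError:
                    logger.warning("pair %s-%s has no usable individuals", a, b)
                    rows.append(row)
                    continue
                table = build_pair_table(
                    model, ga, gb, self.labels,
                    min_freq=self.min_freq, mode=self.table_mode,
                )
                tables[(a, b)] = table
                row["n_used"] = model.n
                row["n_haplotypes"] = len(table.haplotypes)
                if not table.testable:
                    logger.warning(
                        "pair %s-%s untestable (%d retained haplotypes)",
                        a, b, len(table.haplotypes),
                    )
                    rows.append(row)
                    continue
                fisher = fisher_exact_rx2(
                    table.counts,
                    enum_limit=self.fisher_enum_limit,
                    mc_reps=self.fisher_mc_reps,
                    seed=self._pair_seed(pair_idx),
                )
                chi2, df = yates_chi2(table.counts)
                chi2_raw, _ = pearson_chi2(table.counts)
                row.update(
                    testable=True,
                    p=fisher.p,
                    df=df,
                    chi2_yates=chi2,
                    chi2_pearson=chi2_raw,
                    fisher_method=fisher.method,
                    haplotypes=";".join(f"{x}-{y}" for x, y in table.haplotypes),
                    counts_high=";".join(map(str, table.counts[:, 0])),
                    counts_low=";".join(map(str, table.counts[:, 1])),
                )
                rows.append(row)

        pairs = pd.DataFrame(rows)
        if len(pairs) == 0 or not pairs["testable"].any():
            raise ValueError("no testable marker pairs")
        n_tests = int(pairs["testable"].sum())
        genome_thr = self.alpha / n_tests
        chrom_thr = {
            chrom: self.alpha / max(int(sub["testable"].sum()), 1)
            for chrom, sub in pairs.groupby("chromosome", sort=False)
            if sub["testable"].any()
        }
        pairs["chromosome_significant"] = pairs["testable"] & (
            pairs["p"] <= pairs["chromosome"].map(chrom_thr).astype(float)
        )
        pairs["genome_significant"] = pairs["testable"] & (pairs["p"] <= genome_thr)
        logger.info(
            "scan: %d testable pairs, genome-wise threshold %.3e",
            n_tests, genome_thr,
        )
        return ScanResults(
            pairs=pairs,
            hwe=hwe_frame,
            genome_threshold=genome_thr,
            chromosome_thresholds=chrom_thr,
            n_tests=n_tests,
            alpha=self.alpha,
            tables=tables,
        )


def scan(genotypes, gmap, groups, **kwargs) -> ScanResults:
    """Convenience wrapper: ``HaplotypeAssociationScan(...).fit()``."""
    return HaplotypeAssociationScan(genotypes, gmap, groups, **kwargs).fit()
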