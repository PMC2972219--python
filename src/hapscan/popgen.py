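"""Multiallelic linkage disequilibrium, LD-decay effective population
size, and the df-weighted genomic-control inflation factor.

LD between two multiallelic loci is summarized by the standardized
chi-square

    chi2' = [ sum_ij D_ij^2 / (p_i q_j) ] / min(k - 1, l - 1),

with D_ij = f_ij - p_i q_j the haplotype-frequency departure from
independence and k, l the allele counts.  chi2' is bounded in [0, 1]
and reduces to the classical r^2 for a pair of biallelic loci.

Under drift-recombination equilibrium in a closed population of
effective size Ne, the expected LD between loci at genetic distance c
Morgans follows Sved's curve 1 / (1 + 4 Ne c); Ne is estimated by
non-linear least squares of chi2' on c with a residual-error intercept:

    chi2' = 1 / (1 + 4 Ne c) + e.

The genomic-control inflation factor lambda is the observed median of
chi-square statistics divided by the median of the null chi-square
distribution at the same degrees of freedom; when the scan mixes
degrees of freedom, per-df lambdas are averaged weighted by the number
of tests at each df.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genio import GeneticMap, GenotypeMatrix
from .haplo_em import EMError, PairHaplotypeEM, PairHaplotypeResults

logger = logging.getLogger("hapscan")


def chi2prime(model: PairHaplotypeResults) -> float:
    """Standardized multiallelic LD coefficient of a fitted pair.

    Alleles with zero marginal frequency (present in the model only
    through vanished EM mass) are dropped before normalization.  Raises
    ``ValueError`` for a monomorphic locus.
    """
    p = model.p
    q = model.q
    keep_a = p > 1e-12
    keep_b = q > 1e-12
    k = int(keep_a.sum())
    l = int(keep_b.sum())
    if k < 2 or l < 2:
        raise ValueError("chi2prime undefined for a monomorphic locus")
    f = model.freq[np.ix_(keep_a, keep_b)]
    p = p[keep_a]
    q = q[keep_b]
    D = f - np.outer(p, q)
    value = float((D**2 / np.outer(p, q)).sum() / min(k - 1, l - 1))
    return float(np.clip(value, 0.0, 1.0))


def ld_window_pairs(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    window_cm: float = 15.0,
    autosomes_only: bool = True,
    em_tol: float = 1e-8,
    em_max_iter: int = 1000,
) -> pd.DataFrame:
    """chi2' for all within-chromosome marker pairs within a cM window.

    All pairs (not only consecutive ones) are EM-fitted on the full
    provided sample.  Chromosomes named like the X are excluded when
    ``autosomes_only`` (the Sved regression uses autosomes only).
    Returns a frame with columns chromosome, marker_a, marker_b,
    distance_cm, c (Morgans), chi2prime, n.
    """
    x_names = {"x", "chrx", "chr_x"}
    chroms = [
        c for c in gmap.chromosomes
        if not (autosomes_only and c.lower() in x_names)
    ]
    typed = set(genotypes.markers)
    # pairs with a sample-monomorphic member carry no LD information
    poly: dict[str, bool] = {}
    for m in genotypes.markers:
        col = genotypes.pair(m)
        col = col[(col >= 0).all(axis=1)]
        poly[m] = col.size > 0 and len(np.unique(col)) > 1
    rows = []
    n_skipped = 0
    for chrom, a, b, d in gmap.window_pairs(window_cm, chromosomes=chroms):
        if a not in typed or b not in typed:
            continue
        if not (poly[a] and poly[b]):
            n_skipped += 1
            continue
        try:
            model = PairHaplotypeEM(genotypes.pair(a), genotypes.pair(b)).fit(
                tol=em_tol, max_iter=em_max_iter
            )
            value = chi2prime(model)
        except (EMError, ValueError):
            n_skipped += 1
            continue
        rows.append(
            {
                "chromosome": chrom,
                "marker_a": a,
                "marker_b": b,
                "distance_cm": d,
                "c": d / 100.0,
                "chi2prime": value,
                "n": model.n,
            }
        )
    if n_skipped:
        logger.warning("ld_window_pairs: %d pairs skipped (monomorphic/unusable)",
                       n_skipped)
    logger.info("ld_window_pairs: %d pairs within %.1f cM", len(rows), window_cm)
    return pd.DataFrame(
        rows,
        columns=["chromosome", "marker_a", "marker_b", "distance_cm", "c",
                 "chi2prime", "n"],
    )


@dataclass
class SvedFitResults:
    """Least-squares fit of chi2' = 1/(1 + 4 Ne c) + e."""

    ne: float
    e: float
    rss: float
    n_pairs: int
    window_cm: float | None = None
    converged: bool = True

    def predict(self, c) -> np.ndarray:
        return 1.0 / (1.0 + 4.0 * self.ne * np.asarray(c, dtype=float)) + self.e

    def plot(self, records: pd.DataFrame | None = None, ax=None):
        """LD-decay plot: fitted Sved curve, with the chi2' cloud if
        ``records`` (a frame from ``ld_window_pairs``) is given.

        Requires matplotlib; returns the axes.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.5))
        if records is not None:
            ax.scatter(records["c"], records["chi2prime"], s=6, alpha=0.3,
                       color="gray", label="marker pairs")
        grid = np.linspace(1e-4, 0.15, 200)
        ax.plot(grid, self.predict(grid), color="C3",
                label=f"Ne = {self.ne:.1f}, e = {self.e:.3f}")
        ax.set_xlabel("genetic distance c (Morgans)")
        ax.set_ylabel("chi2'")
        ax.legend(frameon=False)
        return ax

    def summary(self) -> str:
        return "\n".join(
            [
                "Sved LD-decay regression  chi2' = 1/(1 + 4 Ne c) + e",
                f"  Ne (effective size): {self.ne:.4f}",
                f"  e  (residual error): {self.e:.6f}",
                f"  pairs used         : {self.n_pairs}"
                + (f" (window {self.window_cm} cM)" if self.window_cm else ""),
                f"  residual SS        : {self.rss:.6f}",
            ]
        )


class SvedLDModel:
    """Non-linear regression of LD on genetic distance.

    Parameters
    ----------
    c : array-like
        Genetic distances in Morgans.
    chi2p : array-like
        LD coefficients (chi2', or r^2 for biallelic panels).
    """

    #: deterministic multi-start grid
    NE_STARTS = (1.0, 10.0, 100.0, 1e3, 1e4)
    E_STARTS = (0.0, 0.05, 0.1)

    def __init__(self, c, chi2p, window_cm: float | None = None):
        self.c = np.asarray(c, dtype=float)
        self.y = np.asarray(chi2p, dtype=float)
        if self.c.shape != self.y.shape or self.c.ndim != 1:
            raise ValueError("c and chi2p must be 1-d arrays of equal length")
        if len(self.c) < 3:
            raise ValueError("need at least 3 records")
        if np.ptp(self.c) == 0:
            raise ValueError("all distances equal: Ne is unidentifiable")
        self.window_cm = window_cm

    @classmethod
    def from_records(cls, records: pd.DataFrame, window_cm: float | None = None):
        return cls(records["c"].to_numpy(), records["chi2prime"].to_numpy(),
                   window_cm=window_cm)

    def _residuals(self, params: np.ndarray) -> np.ndarray:
        ne, e = params
        return 1.0 / (1.0 + 4.0 * ne * self.c) + e - self.y

    def fit(self) -> SvedFitResults:
        best = None
        for ne0 in self.NE_STARTS:
            for e0 in self.E_STARTS:
                sol = optimize.least_squares(
                    self._residuals,
                    x0=np.array([ne0, e0]),
                    bounds=([1e-12, -np.inf], [np.inf, np.inf]),
                    method="trf",
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                )
                if best is None or sol.cost < best.cost:
                    best = sol
        ne, e = best.x
        return SvedFitResults(
            ne=float(ne),
            e=float(e),
            rss=float(2.0 * best.cost),
            n_pairs=len(self.c),
            window_cm=self.window_cm,
            converged=bool(best.success),
        )


def fit_sved(records, window_cm: float | None = None) -> SvedFitResults:
    """Fit Sved's curve to LD records (a frame from ``ld_window_pairs``
    or a pair of arrays)."""
    if isinstance(records, pd.DataFrame):
        return SvedLDModel.from_records(records, window_cm=window_cm).fit()
    c, y = records
    return SvedLDModel(c, y, window_cm=window_cm).fit()


@dataclass
class LambdaReport:
    """Genomic-control inflation, per degree of freedom and overall."""

    per_df: pd.DataFrame     # df, n_tests, observed_median, expected_median, lam
    overall: float
    median: str              # "lower" | "mid"

    def summary(self) -> str:
        lines = [
            "Genomic control",
            f"  overall lambda (test-count weighted): {self.overall:.4f}",
            f"  median convention: {self.median}",
        ]
        for _, row in self.per_df.iterrows():
            lines.append(
                f"  df {int(row['df'])}: n = {int(row['n_tests'])}, "
                f"median {row['observed_median']:.4f} / "
                f"{row['expected_median']:.4f} -> lambda {row['lam']:.4f}"
            )
        return "\n".join(lines)


def _median(values: np.ndarray, convention: str) -> float:
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if convention == "lower":
        # lower of the two central order statistics for even n
        return float(v[(n - 1) // 2])
    if convention == "mid":
        return float(np.median(v))
    raise ValueError(f"unknown median convention {convention!r}")


def genomic_control_lambda(tests, median: str = "lower") -> LambdaReport:
    """Df-weighted genomic-control lambda from (chi-square, df) tests.

    For each degree of freedom d, lambda_d is the observed median of the
    chi-square values divided by the median of the chi-square_d
    distribution (inverse CDF at 0.5); the overall lambda is the mean of
    the lambda_d weighted by the number of tests at each df.  With no
    stratification lambda is 1.  The per-df median uses the lower of the
    two central order statistics for even counts by default
    (``median='mid'`` averages them instead).
    """
    arr = [(float(chi2), int(df)) for chi2, df in tests]
    if not arr:
        raise ValueError("no tests supplied")
    if any(df < 1 for _, df in arr):
        raise ValueError("df must be >= 1")
    frame = pd.DataFrame(arr, columns=["chi2", "df"])
    rows = []
    for df, sub in frame.groupby("df", sort=True):
        observed = _median(sub["chi2"].to_numpy(), median)
        expected = float(stats.chi2.ppf(0.5, df))
        rows.append(
            {
                "df": int(df),
                "n_tests": len(sub),
                "observed_median": observed,
                "expected_median": expected,
                "lam": observed / expected,
            }
        )
    per_df = pd.DataFrame(rows)
    overall = float(
        (per_df["lam"] * per_df["n_tests"]).sum() / per_df["n_tests"].sum()
    )
    return LambdaReport(per_df=per_df, overall=overall, median=median)
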