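"""Candidate-locus genotype-phenotype summary.

Once a biallelic candidate variant is typed in the full (unselected)
cohort, its effect is summarized per genotype class (0, 1 or 2 copies
of the minor allele; for a Ser/Asn substitution these are the S/S, S/N
and N/N classes): class sizes, means and standard errors, pairwise
two-sample t-tests, the additive effect per minor-allele copy as the
least-squares slope of phenotype on allele count, and a Hardy-Weinberg
check of the genotype counts.

Effects are estimated on the full sample by design: tail-selected
samples exaggerate effect sizes (selective genotyping inflates the
allele-frequency contrast), so the scan's tails are for detection only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc_scan import HWEResult, hwe_test


def pooled_t_test(x, y) -> tuple[float, int, float]:
    """Classical pooled-variance two-sided Student t-test.

    Returns (t, df, p).  Degenerate zero-variance samples give t = 0,
    p = 1 when the means agree and t = +/-inf, p = 0 otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs n >= 2")
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if s2 == 0:
        if diff == 0:
            return 0.0, df, 1.0
        return float(np.sign(diff) * np.inf), df, 0.0
    t = diff / np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


@dataclass
class GenotypeEffectResults:
    """Per-genotype phenotype summary and additive-effect estimate."""

    class_table: pd.DataFrame   # label, copies, n, fraction, mean, sem
    t_tests: pd.DataFrame       # class_a, class_b, t, df, p
    additive_effect: float
    additive_effect_se: float
    hwe: HWEResult | None
    n: int

    def class_fraction(self, copies: int) -> float:
        sub = self.class_table[self.class_table["copies"] == copies]
        return float(sub["fraction"].iloc[0]) if len(sub) else 0.0

    def summary(self) -> str:
        lines = ["Candidate-locus genotype effect", "  class   n  fraction   mean    SEM"]
        for _, r in self.class_table.iterrows():
            sem = f"{r['mean']:7.3f} {r['sem']:6.3f}" if np.isfinite(r["sem"]) else \
                f"{r['mean']:7.3f}    n/a"
            lines.append(
                f"  {r['label']:<5} {int(r['n']):4d}  {100 * r['fraction']:6.1f}%  {sem}"
            )
        for _, r in self.t_tests.iterrows():
            lines.append(
                f"  t-test {r['class_a']} vs {r['class_b']}: "
                f"t = {r['t']:.3f}, df = {int(r['df'])}, p = {r['p']:.4g}"
            )
        lines.append(
            f"  additive effect per minor-allele copy: "
            f"{self.additive_effect:.3f} (SE {self.additive_effect_se:.3f})"
        )
        if self.hwe is not None:
            lines.append(f"  HWE p (full sample): {self.hwe.p:.4g}")
        return "\n".join(lines)


class GenotypeEffectModel:
    """Phenotype on minor-allele count at a biallelic candidate locus.

    Parameters
    ----------
    allele_counts : array-like of int
        Per-individual number of minor-allele copies (0, 1 or 2).
    phenotypes : array-like of float
        Aligned quantitative phenotype values.
    labels : tuple of str
        Display names for the 0-, 1- and 2-copy classes.
    """

    def __init__(self, allele_counts, phenotypes,
                 labels: tuple[str, str, str] = ("S/S", "S/N", "N/N")):
        counts = np.asarray(allele_counts, dtype=np.int64)
        pheno = np.asarray(phenotypes, dtype=float)
        if counts.shape != pheno.shape or counts.ndim != 1:
            raise ValueError("allele counts and phenotypes must align 1-d")
        if not np.isin(counts, [0, 1, 2]).all():
            raise ValueError("allele counts must be 0, 1 or 2")
        if not np.isfinite(pheno).all():
            raise ValueError("non-finite phenotype")
        self.counts = counts
        self.pheno = pheno
        self.labels = labels

    def fit(self, welch: bool = False, hwe: bool = True) -> GenotypeEffectResults:
        n = len(self.counts)
        rows = []
        groups: dict[int, np.ndarray] = {}
        for copies in (0, 1, 2):
            vals = self.pheno[self.counts == copies]
            if len(vals) == 0:
                continue
            groups[copies] = vals
            rows.append(
                {
                    "label": self.labels[copies],
                    "copies": copies,
                    "n": len(vals),
                    "fraction": len(vals) / n,
                    "mean": float(vals.mean()),
                    "sem": float(vals.std(ddof=1) / np.sqrt(len(vals)))
                    if len(vals) > 1 else np.nan,
                }
            )
        class_table = pd.DataFrame(rows)
        if (class_table["n"] >= 2).sum() < 2:
            raise ValueError("need >= 2 genotype classes with n >= 2")

        t_rows = []
        testable = [c for c in groups if len(groups[c]) >= 2]
        for i, a in enumerate(testable):
            for b in testable[i + 1:]:
                if welch:
                    res = stats.ttest_ind(groups[a], groups[b], equal_var=False)
                    t, df, p = float(res.statistic), float(res.df), float(res.pvalue)
                else:
                    t, df, p = pooled_t_test(groups[a], groups[b])
                t_rows.append(
                    {"class_a": self.labels[a], "class_b": self.labels[b],
                     "t": t, "df": df, "p": p}
                )
        t_tests = pd.DataFrame(t_rows, columns=["class_a", "class_b", "t", "df", "p"])

        # additive effect: OLS slope of phenotype on copy number
        x = self.counts.astype(float)
        xc = x - x.mean()
        sxx = float((xc**2).sum())
        if sxx == 0:
            raise ValueError("allele count is constant; no slope estimable")
        beta = float((xc * self.pheno).sum() / sxx)
        resid = self.pheno - self.pheno.mean() - beta * xc
        sigma2 = float((resid**2).sum() / (n - 2))
        se = float(np.sqrt(sigma2 / sxx))

        hwe_res = None
        if hwe:
            geno = np.column_stack(
                [np.where(self.counts >= 1, 2, 1), np.where(self.counts == 2, 2, 1)]
            )
            hwe_res = hwe_test(geno, marker="candidate", group="full")

        return GenotypeEffectResults(
            class_table=class_table,
            t_tests=t_tests,
            additive_effect=beta,
            additive_effect_se=se,
            hwe=hwe_res,
            n=n,
        )


def genotype_effect(allele_counts, phenotypes, **kwargs) -> GenotypeEffectResults:
    """Convenience wrapper: ``GenotypeEffectModel(...).fit(**kwargs)``."""
    return GenotypeEffectModel(allele_counts, phenotypes).fit(**kwargs)
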