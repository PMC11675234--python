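"""Case/control allelic association of sex on genotypes.

The basic allelic test: each non-missing diploid genotype contributes two
allele observations to a 2x2 sex-by-allele table, scored with the Pearson
chi-square (1 df, no continuity correction).  Degenerate tables — any zero
row or column margin, i.e. monomorphic sites or single-sex data at a site —
score chi2 = 0, p = 1 rather than erroring, because monomorphic sites are
routine in a genome scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from sdscan.variant_io import MISSING, PhenotypeTable, VariantSite


@dataclass
class AllelicTable:
    """2x2 allele counts; rows = (M, F), columns = (ref, alt)."""

    m_ref: int
    m_alt: int
    f_ref: int
    f_alt: int

    def __post_init__(self):
        if min(self.m_ref, self.m_alt, self.f_ref, self.f_alt) < 0:
            raise ValueError("allele counts must be non-negative")

    @property
    def total(self) -> int:
        return self.m_ref + self.m_alt + self.f_ref + self.f_alt

    def as_array(self) -> np.ndarray:
        return np.array([[self.m_ref, self.m_alt], [self.f_ref, self.f_alt]])


@dataclass
class AssociationResult:
    site: VariantSite | None
    chi2: float
    p: float
    counts: AllelicTable


def allelic_counts(site: VariantSite, phen: PhenotypeTable) -> AllelicTable:
    """Count ref/alt alleles by sex; missing genotypes contribute nothing."""
    male = phen.male_mask(site.samples)
    g = site.genotypes
    ok = g != MISSING
    alt = np.where(ok, g, 0)
    ref = np.where(ok, 2 - g, 0)
    return AllelicTable(
        m_ref=int(ref[male].sum()),
        m_alt=int(alt[male].sum()),
        f_ref=int(ref[~male].sum()),
        f_alt=int(alt[~male].sum()),
    )


def chi2_allelic(table: AllelicTable) -> AssociationResult:
    """Pearson chi-square on the 2x2 allelic table, 1 df, no correction.

    chi2 = N (ad - bc)^2 / (r1 r2 c1 c2); degenerate margins give (0, 1).
    """
    a, b, c, d = table.m_ref, table.m_alt, table.f_ref, table.f_alt
    n = a + b + c + d
    if n <= 0:
        raise ValueError("empty allelic table")
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if 0 in (r1, r2, c1, c2):
        return AssociationResult(site=None, chi2=0.0, p=1.0, counts=table)
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(chi2, df=1))
    return AssociationResult(site=None, chi2=float(chi2), p=p, counts=table)


def _chi2_vector(a, b, c, d):
    """Vectorized closed-form chi-square over parallel count arrays."""
    a, b, c, d = (np.asarray(x, dtype=np.float64) for x in (a, b, c, d))
    n = a + b + c + d
    den = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(den > 0, n * (a * d - b * c) ** 2 / np.where(den > 0, den, 1), 0.0)
    p = np.where(den > 0, stats.chi2.sf(chi2, df=1), 1.0)
    return chi2, p


def genome_scan(
    sites: list[VariantSite], phen: PhenotypeTable
) -> tuple[list[AssociationResult], pd.DataFrame]:
    """Allelic test at every site, input order preserved.

    Returns per-site results plus a Manhattan-ready table (chrom, pos, id,
    counts, chi2, p, -log10 p).  Requires at least one individual of each
    sex; the scan is undefined otherwise.
    """
    if not sites:
        raise ValueError("no sites to scan")
    samples = sites[0].samples
    male = phen.male_mask(samples)
    if male.all() or not male.any():
        raise ValueError("association scan needs both sexes present")

    g = np.vstack([s.genotypes for s in sites]).astype(np.int16)
    ok = g != MISSING
    alt = np.where(ok, g, 0)
    ref = np.where(ok, 2 - g, 0)
    a = ref[:, male].sum(axis=1)
    b = alt[:, male].sum(axis=1)
    c = ref[:, ~male].sum(axis=1)
    d = alt[:, ~male].sum(axis=1)
    chi2, p = _chi2_vector(a, b, c, d)

    results = [
        AssociationResult(
            site=s,
            chi2=float(chi2[i]),
            p=float(p[i]),
            counts=AllelicTable(int(a[i]), int(b[i]), int(c[i]), int(d[i])),
        )
        for i, s in enumerate(sites)
    ]
    with np.errstate(divide="ignore"):
        mlog = np.where(p > 0, -np.log10(np.maximum(p, np.finfo(float).tiny)), np.inf)
    table = pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "id": [s.id or "." for s in sites],
            "a": a,
            "b": b,
            "c": c,
            "d": d,
            "chi2": chi2,
            "p": p,
            "minus_log10_p": mlog,
        }
    )
    return results, table


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance level alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests
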