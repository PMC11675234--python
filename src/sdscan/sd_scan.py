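"""Genotype–sex concordance scan and sex-determination-region calling.

For each SNP, two scores over the non-missing individuals:

* ``xy_score`` — fraction matching the XX/XY expectation: males
  heterozygous, females homozygous (either homozygote; restricting to
  hom-ref would silently depend on reference-allele polarity).
* ``zw_score`` — the mirror: females heterozygous, males homozygous.

The heterogametic system is inferred from which hypothesis accumulates
high-scoring SNPs ("over 90%" is read strictly, score > threshold), and the
region is the min–max envelope of the winning high scorers on their
majority chromosome after merging runs separated by at most ``max_gap``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from sdscan.variant_io import HET, HOM_ALT, HOM_REF, MISSING, PhenotypeTable, VariantSite


@dataclass(frozen=True)
class ScanConfig:
    threshold: float = 0.90  # strict: a score must exceed this
    min_snps: int = 5  # support needed to call a system / region
    max_gap: int = 1_000_000  # bp; merge distance for region calling
    system_factor: float = 2.0  # winning system needs this multiple of the loser

    def __post_init__(self):
        if not 0 < self.threshold <= 1:
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")
        if self.min_snps < 1:
            raise ValueError(f"min_snps must be >= 1, got {self.min_snps}")
        if self.max_gap < 0:
            raise ValueError(f"max_gap must be >= 0, got {self.max_gap}")


@dataclass
class ConcordanceResult:
    site: VariantSite
    xy_score: float
    zw_score: float
    n_used: int


@dataclass
class SdRegion:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    n_support: int
    system: str

    @property
    def span(self) -> int:
        return self.end - self.start + 1


class NoRegionError(ValueError):
    """Too few high-scoring SNPs to call a region."""


def _scores(genotypes: np.ndarray, male: np.ndarray) -> tuple[float, float, int]:
    ok = genotypes != MISSING
    n_used = int(ok.sum())
    if n_used == 0:
        return np.nan, np.nan, 0
    het = genotypes == HET
    hom = (genotypes == HOM_REF) | (genotypes == HOM_ALT)
    xy = int((het & male & ok).sum() + (hom & ~male & ok).sum())
    zw = int((het & ~male & ok).sum() + (hom & male & ok).sum())
    return xy / n_used, zw / n_used, n_used


def xy_concordance(site: VariantSite, phen: PhenotypeTable) -> float:
    """Fraction of non-missing individuals matching the XX/XY pattern.

    NaN when every genotype is missing (site unusable).
    """
    male = phen.male_mask(site.samples)
    return _scores(site.genotypes, male)[0]


def zw_concordance(site: VariantSite, phen: PhenotypeTable) -> float:
    """Mirror of :func:`xy_concordance`: females het, males homozygous."""
    male = phen.male_mask(site.samples)
    return _scores(site.genotypes, male)[1]


def scan(
    sites: list[VariantSite],
    phen: PhenotypeTable,
    config: ScanConfig | None = None,
) -> list[ConcordanceResult]:
    """Score every biallelic site with at least one non-missing genotype."""
    if not sites:
        raise ValueError("no sites to scan")
    samples = sites[0].samples
    male = phen.male_mask(samples)

    g = np.vstack([s.genotypes for s in sites])
    ok = g != MISSING
    n_used = ok.sum(axis=1)
    het = g == HET
    hom = (g == HOM_REF) | (g == HOM_ALT)
    xy = (het[:, male]).sum(axis=1) + (hom[:, ~male]).sum(axis=1)
    zw = (het[:, ~male]).sum(axis=1) + (hom[:, male]).sum(axis=1)

    results = []
    for i, site in enumerate(sites):
        if not site.is_biallelic or n_used[i] == 0:
            continue
        results.append(
            ConcordanceResult(
                site=site,
                xy_score=float(xy[i] / n_used[i]),
                zw_score=float(zw[i] / n_used[i]),
                n_used=int(n_used[i]),
            )
        )
    return results


def scan_table(results: list[ConcordanceResult]) -> pd.DataFrame:
    """Concordance results as a plot-ready table."""
    return pd.DataFrame(
        {
            "chrom": [r.site.chrom for r in results],
            "pos": [r.site.pos for r in results],
            "xy_score": [r.xy_score for r in results],
            "zw_score": [r.zw_score for r in results],
            "n_used": [r.n_used for r in results],
        }
    )


def infer_system(
    results: list[ConcordanceResult], config: ScanConfig | None = None
) -> str:
    """'XY', 'ZW', or 'undetermined' from counts of high-scoring SNPs.

    The winner needs at least ``min_snps`` supporters and a
    ``system_factor``-fold majority over the mirror hypothesis — a 2x
    default so noisy data cannot produce a coin-flip call.
    """
    cfg = config or ScanConfig()
    n_xy = sum(1 for r in results if r.xy_score > cfg.threshold)
    n_zw = sum(1 for r in results if r.zw_score > cfg.threshold)
    if n_xy >= cfg.min_snps and n_xy > cfg.system_factor * n_zw:
        return "XY"
    if n_zw >= cfg.min_snps and n_zw > cfg.system_factor * n_xy:
        return "ZW"
    return "undetermined"


def call_sd_region(
    results: list[ConcordanceResult],
    config: ScanConfig | None = None,
    system: str = "XY",
) -> tuple[SdRegion, list[ConcordanceResult]]:
    """Call the sex-determination region from the winning high scorers.

    High scorers (winning-model score > threshold) vote for a chromosome;
    on the majority chromosome, positions are merged into runs separated by
    at most ``max_gap`` and the best-supported run's min–max envelope is the
    region.  High scorers outside it — other chromosomes or losing runs —
    are returned as flagged outliers.
    """
    cfg = config or ScanConfig()
    if system not in ("XY", "ZW"):
        raise ValueError(f"system must be XY or ZW, got {system!r}")
    score = (lambda r: r.xy_score) if system == "XY" else (lambda r: r.zw_score)
    high = [r for r in results if score(r) > cfg.threshold]
    if len(high) < cfg.min_snps:
        raise NoRegionError(
            f"only {len(high)} SNPs exceed {cfg.threshold:.2f}; "
            f"need {cfg.min_snps} to call a region"
        )
    chroms = pd.Series([r.site.chrom for r in high])
    majority = chroms.value_counts().index[0]
    on_chrom = sorted(
        (r for r in high if r.site.chrom == majority), key=lambda r: r.site.pos
    )
    # split into runs by gap
    runs: list[list[ConcordanceResult]] = [[on_chrom[0]]]
    for r in on_chrom[1:]:
        if r.site.pos - runs[-1][-1].site.pos <= cfg.max_gap:
            runs[-1].append(r)
        else:
            runs.append([r])
    best = max(
        runs, key=lambda run: (len(run), run[-1].site.pos - run[0].site.pos)
    )
    if len(best) < cfg.min_snps:
        raise NoRegionError(
            f"largest run on {majority} has only {len(best)} supporting SNPs"
        )
    region = SdRegion(
        chrom=majority,
        start=best[0].site.pos,
        end=best[-1].site.pos,
        n_support=len(best),
        system=system,
    )
    in_best = set(id(r) for r in best)
    outliers = [r for r in high if id(r) not in in_best]
    return region, outliers
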