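"""Readers and writers for the formats the pipeline touches.

VCF parsing goes through pysam; genotypes are collapsed to a four-state
code (hom-ref / het / hom-alt / missing) because every downstream scan is
biallelic.  All internal coordinates are 1-based inclusive; BED export is
the only 0-based half-open surface.
"""

from __future__ import annotations

import re
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

# genotype codes used throughout the package
HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

#: site INFO annotations the hard filter understands
INFO_KEYS = ("QD", "MQ", "FS", "ReadPosRankSum", "MQRankSum")


class VcfParseError(ValueError):
    """A VCF record could not be interpreted."""


class PhenotypeError(ValueError):
    """The phenotype table is malformed."""


@dataclass
class VariantSite:
    """One VCF record with genotypes collapsed to biallelic codes.

    ``genotypes`` is an int8 vector aligned with ``samples`` (a tuple shared
    across the sites of one file).  Diploid calls involving only the REF and
    first ALT allele map to ``HOM_REF``/``HET``/``HOM_ALT``; anything
    touching a later ALT allele, or any missing allele, maps to ``MISSING``.
    """

    chrom: str
    pos: int  # 1-based
    id: str | None
    ref: str
    alt: tuple[str, ...]
    info: dict[str, float]
    genotypes: np.ndarray
    samples: tuple[str, ...]

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.alt) > 0 and len(self.ref) != len(self.alt[0])

    @property
    def indel_len(self) -> int:
        """Unsigned indel length; 0 for a SNP/MNP."""
        if not self.alt:
            return 0
        return abs(len(self.alt[0]) - len(self.ref))

    @property
    def signed_indel_len(self) -> int:
        """len(alt) - len(ref): positive for insertions, negative for deletions."""
        if not self.alt:
            return 0
        return len(self.alt[0]) - len(self.ref)

    def genotype_of(self, sample: str) -> int:
        return int(self.genotypes[self.samples.index(sample)])


class PhenotypeTable(Mapping):
    """Immutable sample -> sex map, sex in {'M', 'F'}."""

    def __init__(self, sexes: Mapping[str, str]):
        clean = {}
        for sample, sex in sexes.items():
            token = _parse_sex(sex)
            if token is None:
                raise PhenotypeError(f"unrecognized sex {sex!r} for sample {sample!r}")
            clean[str(sample)] = token
        self._sexes: dict[str, str] = clean

    def __getitem__(self, sample: str) -> str:
        return self._sexes[sample]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sexes)

    def __len__(self) -> int:
        return len(self._sexes)

    @property
    def n_males(self) -> int:
        return sum(1 for s in self._sexes.values() if s == "M")

    @property
    def n_females(self) -> int:
        return sum(1 for s in self._sexes.values() if s == "F")

    def male_mask(self, samples: tuple[str, ...]) -> np.ndarray:
        """Boolean mask (True = male) aligned with ``samples``.

        Raises ``KeyError`` for any sample absent from the table.
        """
        return np.array([self._sexes[s] == "M" for s in samples], dtype=bool)

    def swapped(self) -> "PhenotypeTable":
        """Mirror table with every M relabelled F and vice versa."""
        flip = {"M": "F", "F": "M"}
        return PhenotypeTable({s: flip[x] for s, x in self._sexes.items()})


def _parse_sex(token: str) -> str | None:
    t = str(token).strip().lower()
    if t in ("m", "male"):
        return "M"
    if t in ("f", "female"):
        return "F"
    return None


_REGION_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (1-based inclusive)."""
    m = _REGION_RE.match(region)
    if not m:
        raise ValueError(f"malformed region {region!r}; expected chrom:start-end")
    chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    if start < 1 or end < start:
        raise ValueError(f"invalid region bounds in {region!r}")
    return chrom, start, end


def _encode_genotype(gt: tuple[int | None, ...]) -> int:
    if gt is None or len(gt) == 0 or any(a is None for a in gt):
        return MISSING
    if any(a > 1 for a in gt):
        # multi-allelic call: unusable in a biallelic analysis
        return MISSING
    if len(gt) != 2:
        return MISSING
    return int(gt[0] + gt[1])  # 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2


def read_vcf(
    path: str, region: str | None = None
) -> tuple[list[VariantSite], tuple[str, ...]]:
    """Read a VCF into a list of sites plus the sample ordering.

    ``region`` is ``chrom:start-end``, 1-based inclusive on both ends.
    Heterozygotes are phase- and order-insensitive; any call touching an ALT
    allele beyond the first is returned as missing.
    """
    want = parse_region(region) if region else None
    sites: list[VariantSite] = []
    with pysam.VariantFile(path) as vf:
        samples = tuple(vf.header.samples)
        for i, rec in enumerate(vf):
            try:
                if want is not None:
                    chrom, start, end = want
                    if rec.chrom != chrom or not (start <= rec.pos <= end):
                        continue
                info = {}
                for key in INFO_KEYS:
                    if key in rec.info:
                        val = rec.info[key]
                        if isinstance(val, tuple):
                            val = val[0]
                        info[key] = float(val)
                codes = np.fromiter(
                    (_encode_genotype(rec.samples[s].get("GT")) for s in samples),
                    dtype=np.int8,
                    count=len(samples),
                )
                sites.append(
                    VariantSite(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        id=rec.id,
                        ref=rec.ref,
                        alt=tuple(rec.alts or ()),
                        info=info,
                        genotypes=codes,
                        samples=samples,
                    )
                )
            except (ValueError, TypeError) as exc:  # pragma: no cover - defensive
                raise VcfParseError(f"record {i + 1} of {path}: {exc}") from exc
    return sites, samples


def read_phenotypes(path: str) -> PhenotypeTable:
    """Read a two-column TSV (``sample_id<TAB>sex``, with header).

    Sex tokens M/F/male/female are accepted case-insensitively; duplicates
    and unknown tokens raise ``PhenotypeError`` naming the offender.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise PhenotypeError(f"{path}: expected two tab-separated columns")
    samples = df.iloc[:, 0]
    dup = samples[samples.duplicated()]
    if not dup.empty:
        raise PhenotypeError(f"{path}: duplicate sample id {dup.iloc[0]!r}")
    table = {}
    for row_idx, (sample, sex) in enumerate(zip(samples, df.iloc[:, 1]), start=2):
        token = _parse_sex(sex)
        if token is None:
            raise PhenotypeError(
                f"{path} line {row_idx}: unrecognized sex {sex!r} for sample {sample!r}"
            )
        table[sample] = token
    return PhenotypeTable(table)


def write_phenotypes(sexes: Mapping[str, str], path: str) -> str:
    with open(path, "w") as fh:
        fh.write("sample_id\tsex\n")
        for sample, sex in sexes.items():
            fh.write(f"{sample}\t{sex}\n")
    return path


def write_region_bed(region, path: str) -> str:
    """Write one BED3 line for a region held in 1-based inclusive coordinates.

    BED is 0-based half-open, so start is decremented; a zero- or
    negative-length region is rejected.
    """
    if region.end < region.start or region.start < 1:
        raise ValueError(f"invalid region {region.chrom}:{region.start}-{region.end}")
    with open(path, "w") as fh:
        fh.write(f"{region.chrom}\t{region.start - 1}\t{region.end}\n")
    return path


def read_region_bed(path: str) -> tuple[str, int, int]:
    """Read the first BED3 line back into (chrom, start, end), 1-based inclusive."""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            return chrom, int(start) + 1, int(end)
    raise ValueError(f"{path}: no BED interval found")


_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}

_VCF_HEADER_LINES = [
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Variant confidence normalized by depth">',
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
    '##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled strand-bias Fisher p">',
    '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Rank-sum of alt vs ref read position">',
    '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Rank-sum of alt vs ref mapping quality">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]


def write_vcf(
    sites: list[VariantSite],
    samples: tuple[str, ...],
    path: str,
    contigs: Mapping[str, int] | None = None,
) -> str:
    """Write sites as an uncompressed VCF v4.2.

    A plain text emitter is used so that a fixed seed yields byte-identical
    files: INFO floats are printed at two decimals in a fixed key order.
    Sites must already be sorted by (chrom, pos).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sdscan\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for site in sites:
            info = ";".join(
                f"{k}={site.info[k]:.2f}" for k in INFO_KEYS if k in site.info
            )
            gts = "\t".join(_GT_STR[int(g)] for g in site.genotypes)
            alt = ",".join(site.alt) if site.alt else "."
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.id or '.'}\t{site.ref}\t{alt}"
                f"\t.\tPASS\t{info or '.'}\tGT\t{gts}\n"
            )
    return path
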