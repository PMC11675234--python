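"""Synthetic diploid population with a sex-determination region.

Generates a reference genome, a genotyped male/female cohort, and ground
truth, written to standard formats (FASTA, VCF v4.2, TSV, JSON) so every
downstream stage of the pipeline is testable without sequencing data.

Generative model
----------------
A single sex-determination locus sits inside a configured region of one
chromosome.  A sex-linked SNP at physical distance ``d`` from the locus
retains its linkage to the sex-determining allele with fidelity
``f(d) = exp(-d / decay_length)`` — exponential decay with one
interpretable parameter, standing in for recombination during the history
of the population.  Under an XY system:

* a male (heterogametic carrier) is heterozygous with probability
  ``f(d) * (1 - male_error)``, otherwise hom-ref;
* a female is hom-ref with probability ``1 - female_error``, otherwise het.

The ZW system is the exact sex-swapped mirror: females take the carrier
role (and with it ``male_error``, which is named for the XY default but
attaches to the heterogametic carrier).  The reference allele is the
X(/Z)-linked allele by convention; the alternate allele is Y(/W)-linked.

Autosomal SNPs draw a minor-allele frequency uniformly from ``maf_range``
and genotypes from Hardy–Weinberg.  Every call is independently set
missing with probability ``missing_rate``.  Marker indels (Y-linked
insertions inside PCR amplicons embedded in the region) are perfectly
linked (``f = 1``) but still subject to genotyping error and missingness.

Site INFO annotations (QD, MQ, FS, ReadPosRankSum, MQRankSum) are drawn
from a two-component model per field: a "passing" uniform range with
probability ``1 - fail_prob`` and a "failing" range otherwise, spanning the
standard hard-filter thresholds.

Default scale
-------------
The defaults are a 1/100 desk-scale replica of a 38-fish resequencing
study: 18 males + 20 females, 24 chromosomes of 295 kb, and a
sex-determination region at 197.4–226.0 kb on chr9 (the 19.74–22.60 Mb
interval scaled by 100), with 18 bp and 14 bp Y-linked marker insertions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from sdscan.marker_dev import PrimerPair, reverse_complement
from sdscan.variant_io import (
    HET,
    HOM_REF,
    MISSING,
    PhenotypeTable,
    VariantSite,
    write_phenotypes,
    write_vcf,
)


class ConfigError(ValueError):
    pass


class EmptyDatasetError(ValueError):
    pass


@dataclass(frozen=True)
class MarkerDef:
    """An indel PCR marker to embed: primer pair, female product, insertion."""

    name: str
    forward: str
    reverse: str
    x_product: int  # bp amplified from the X-linked allele
    insertion_len: int  # bp inserted on the Y-linked allele
    sex_linked: bool = True

    @property
    def primer_pair(self) -> PrimerPair:
        return PrimerPair(self.name, self.forward, self.reverse)

    @property
    def y_product(self) -> int:
        return self.x_product + self.insertion_len


# the two dmrt1-intron marker assays: female products 346/412 bp,
# Y insertions 18/14 bp -> male-specific 364/426 bp bands
DEFAULT_MARKERS = (
    MarkerDef("MFS-1", "TATGTCTGGAGGTCACTG", "GCTTATTTGGAGGATTGT", 346, 18),
    MarkerDef("MFS-2", "TGTGAATGGGTGAATGAG", "TAGCTTTGTACTTTGTTCC", 412, 14),
)


@dataclass(frozen=True)
class FieldModel:
    """Two-component uniform model for one INFO annotation."""

    fail_prob: float
    pass_range: tuple[float, float]
    fail_range: tuple[float, float]

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        fail = rng.random(n) < self.fail_prob
        lo_p, hi_p = self.pass_range
        lo_f, hi_f = self.fail_range
        values = np.where(
            fail,
            rng.uniform(lo_f, hi_f, n),
            rng.uniform(lo_p, hi_p, n),
        )
        return np.round(values, 2)


def default_annotation_model() -> dict[str, FieldModel]:
    """Per-field distributions spanning the hard-filter thresholds.

    1% of sites fail each field independently, mimicking a callset that is
    mostly clean after upstream genotyping.
    """
    return {
        "QD": FieldModel(0.01, (8.0, 35.0), (0.0, 1.9)),
        "MQ": FieldModel(0.01, (50.0, 60.0), (20.0, 39.5)),
        "FS": FieldModel(0.01, (0.0, 10.0), (61.0, 200.0)),
        "ReadPosRankSum": FieldModel(0.01, (-4.0, 4.0), (-20.0, -8.5)),
        "MQRankSum": FieldModel(0.01, (-5.0, 5.0), (-25.0, -13.0)),
    }


def _default_chromosomes() -> tuple[tuple[str, int], ...]:
    return tuple((f"chr{i}", 295_000) for i in range(1, 25))


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_males: int = 18
    n_females: int = 20
    chromosomes: tuple[tuple[str, int], ...] = field(
        default_factory=_default_chromosomes
    )
    sd_chrom: str = "chr9"
    sd_locus: int = 211_700
    sd_region: tuple[int, int] = (197_400, 226_000)
    system: str = "XY"
    n_sex_linked_snps: int = 60
    n_autosomal_snps: int = 500
    decay_length: float = 150_000.0  # bp; linkage fidelity f(d) = exp(-d/lambda)
    male_error: float = 0.01  # genotyping error of the heterogametic carrier
    female_error: float = 0.01  # genotyping error of the homogametic sex
    missing_rate: float = 0.02
    maf_range: tuple[float, float] = (0.05, 0.5)
    markers: tuple[MarkerDef, ...] = DEFAULT_MARKERS
    annotation_model: dict[str, FieldModel] = field(
        default_factory=default_annotation_model
    )

    def validate(self) -> None:
        if self.n_males < 0 or self.n_females < 0 or self.n_males + self.n_females < 2:
            raise ConfigError("need at least 2 individuals in total")
        for p, name in (
            (self.male_error, "male_error"),
            (self.female_error, "female_error"),
            (self.missing_rate, "missing_rate"),
        ):
            if not 0 <= p <= 1:
                raise ConfigError(f"{name} must be a probability, got {p}")
        if self.decay_length <= 0:
            raise ConfigError("decay_length must be positive")
        if self.system not in ("XY", "ZW"):
            raise ConfigError(f"system must be XY or ZW, got {self.system!r}")
        lengths = dict(self.chromosomes)
        if self.sd_chrom not in lengths:
            raise ConfigError(f"sd_chrom {self.sd_chrom!r} not among chromosomes")
        start, end = self.sd_region
        if not (1 <= start <= end <= lengths[self.sd_chrom]):
            raise ConfigError("sd_region must lie within the sd chromosome")
        if not (start <= self.sd_locus <= end):
            raise ConfigError("sd_locus must lie inside sd_region")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        if min(self.n_sex_linked_snps, self.n_autosomal_snps) < 0:
            raise ConfigError("SNP counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.n_males + self.n_females

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class AmpliconTruth:
    """Ground truth for one embedded marker amplicon."""

    name: str
    chrom: str
    start: int  # 1-based genomic start of the X-allele template
    x_template: str
    y_template: str
    insert_pos: int  # 1-based genomic position of the base before the insertion
    inserted_seq: str
    x_product: int
    y_product: int
    sex_linked: bool

    @property
    def indel_len(self) -> int:
        return len(self.inserted_seq)


@dataclass
class ReferenceSet:
    sequences: dict[str, str]
    sd_truth: dict  # chrom, start, end, locus, system
    amplicon_truth: list[AmpliconTruth]


@dataclass
class GenotypeDataset:
    samples: tuple[str, ...]
    sexes: dict[str, str]
    sites: list[VariantSite]

    def phenotypes(self) -> PhenotypeTable:
        return PhenotypeTable(self.sexes)

    @property
    def genotype_matrix(self) -> np.ndarray:
        return np.vstack([s.genotypes for s in self.sites])


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASE_BYTES[rng.integers(0, 4, length)].tobytes().decode("ascii")


def build_marker_templates(
    marker: MarkerDef, rng: np.random.Generator
) -> tuple[str, str]:
    """X- and Y-allele amplicon templates for a marker definition.

    The X template is exactly ``x_product`` bp — forward primer, random
    filler, reverse-complemented reverse primer — so the primer pair
    amplifies the female product size; the Y template carries the marker's
    insertion between the primer sites.
    """
    x_template, y_template, _, _ = _build_template(marker, rng)
    return x_template, y_template


def _build_template(marker: MarkerDef, rng: np.random.Generator):
    """X-allele template (F ... rc(R), total x_product bp) and its Y mirror."""
    f = marker.forward.upper()
    r_rc = reverse_complement(marker.reverse.upper())
    inner_len = marker.x_product - len(f) - len(r_rc)
    if inner_len < 1:
        raise ConfigError(
            f"{marker.name}: x_product {marker.x_product} too short for its primers"
        )
    inner = _random_sequence(rng, inner_len)
    x_template = f + inner + r_rc
    insert_at = len(f) + inner_len // 2  # bases preceding the insertion point
    inserted = _random_sequence(rng, marker.insertion_len)
    y_template = x_template[:insert_at] + inserted + x_template[insert_at:]
    return x_template, y_template, insert_at, inserted


def build_reference(config: SimulationConfig, rng: np.random.Generator | None = None) -> ReferenceSet:
    """Random chromosome sequences with marker amplicons embedded in the SD region."""
    config.validate()
    rng = rng if rng is not None else config.rng()
    sequences = {name: _random_sequence(rng, length) for name, length in config.chromosomes}

    start, end = config.sd_region
    span = end - start + 1
    k = len(config.markers)
    amplicons: list[AmpliconTruth] = []
    if k:
        spacing = max(span // (2 * k), 1)
        for i, marker in enumerate(config.markers):
            x_template, y_template, insert_at, inserted = _build_template(marker, rng)
            offset = int((i - (k - 1) / 2) * spacing)
            a_start = config.sd_locus + offset - len(x_template) // 2
            a_end = a_start + len(x_template) - 1
            if a_start < start or a_end > end:
                raise ConfigError(
                    f"{marker.name}: amplicon [{a_start}, {a_end}] does not fit "
                    f"inside sd_region [{start}, {end}]"
                )
            seq = sequences[config.sd_chrom]
            sequences[config.sd_chrom] = (
                seq[: a_start - 1] + x_template + seq[a_end:]
            )
            amplicons.append(
                AmpliconTruth(
                    name=marker.name,
                    chrom=config.sd_chrom,
                    start=a_start,
                    x_template=x_template,
                    y_template=y_template,
                    insert_pos=a_start + insert_at - 1,
                    inserted_seq=inserted,
                    x_product=marker.x_product,
                    y_product=marker.y_product,
                    sex_linked=marker.sex_linked,
                )
            )
        spans = sorted((a.start, a.start + len(a.x_template) - 1) for a in amplicons)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ConfigError("marker amplicons overlap; widen sd_region or spacing")

    return ReferenceSet(
        sequences=sequences,
        sd_truth={
            "chrom": config.sd_chrom,
            "start": start,
            "end": end,
            "locus": config.sd_locus,
            "system": config.system,
        },
        amplicon_truth=amplicons,
    )


def _sample_ids(config: SimulationConfig) -> tuple[tuple[str, ...], dict[str, str]]:
    width = max(2, len(str(max(config.n_males, config.n_females))))
    males = [f"M{i:0{width}d}" for i in range(1, config.n_males + 1)]
    females = [f"F{i:0{width}d}" for i in range(1, config.n_females + 1)]
    sexes = {s: "M" for s in males} | {s: "F" for s in females}
    return tuple(males + females), sexes


def _carrier_mask(config: SimulationConfig, samples, sexes) -> np.ndarray:
    """Heterogametic-carrier mask: males under XY, females under ZW."""
    carrier_sex = "M" if config.system == "XY" else "F"
    return np.array([sexes[s] == carrier_sex for s in samples], dtype=bool)


def _sex_linked_genotypes(
    fidelity: np.ndarray, carrier: np.ndarray, config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    n_sites, n = len(fidelity), len(carrier)
    u = rng.random((n_sites, n))
    g = np.full((n_sites, n), HOM_REF, dtype=np.int8)
    p_car = fidelity[:, None] * (1.0 - config.male_error)
    g[:, carrier] = np.where(u[:, carrier] < p_car, HET, HOM_REF)
    g[:, ~carrier] = np.where(u[:, ~carrier] < 1.0 - config.female_error, HOM_REF, HET)
    return g


def expected_xy_concordance(config: SimulationConfig, distance: float) -> float:
    """Closed-form expected XY concordance of a sex-linked site at distance d.

    [n_m f(d)(1-e_m) + n_f (1-e_f)] / (n_m + n_f) — used as the analytic
    oracle for the generator (for ZW, the same value applies to the
    ZW score with the sexes swapped).
    """
    f = float(np.exp(-distance / config.decay_length))
    n_car = config.n_males if config.system == "XY" else config.n_females
    n_hom = config.n_samples - n_car
    return (
        n_car * f * (1.0 - config.male_error) + n_hom * (1.0 - config.female_error)
    ) / config.n_samples


_BASES = np.array(list("ACGT"))
_OTHER = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


def _alt_base(ref_base: str, rng: np.random.Generator) -> str:
    return _OTHER.get(ref_base, list("ACGT"))[rng.integers(0, 3)]


def simulate_genotypes(
    config: SimulationConfig,
    ref: ReferenceSet,
    rng: np.random.Generator | None = None,
) -> GenotypeDataset:
    """Genotype the cohort at sex-linked, autosomal, and marker-indel sites.

    All randomness flows from one generator; calling with the generator
    that built the reference (or reusing ``config.rng()`` streams) keeps the
    whole dataset reproducible from the single config seed.
    """
    config.validate()
    rng = rng if rng is not None else config.rng()
    n_indels = len(ref.amplicon_truth)
    if config.n_sex_linked_snps + config.n_autosomal_snps + n_indels == 0:
        raise EmptyDatasetError("no sites configured")

    samples, sexes = _sample_ids(config)
    carrier = _carrier_mask(config, samples, sexes)
    start, end = config.sd_region
    chrom_len = dict(config.chromosomes)
    chrom_order = {name: i for i, (name, _) in enumerate(config.chromosomes)}

    # positions occupied by marker amplicons are off-limits to SNPs
    blocked = np.zeros(end - start + 1, dtype=bool)
    for amp in ref.amplicon_truth:
        a_end = amp.start + len(amp.x_template) - 1
        blocked[amp.start - start : a_end - start + 1] = True
    region_positions = np.arange(start, end + 1)[~blocked]

    records: list[tuple[str, int, str, tuple[str, ...], np.ndarray, str | None]] = []

    # --- sex-linked SNPs inside the SD region
    if config.n_sex_linked_snps:
        if config.n_sex_linked_snps > len(region_positions):
            raise ConfigError("sd_region too small for n_sex_linked_snps")
        pos_sl = np.sort(
            rng.choice(region_positions, config.n_sex_linked_snps, replace=False)
        )
        dist = np.abs(pos_sl - config.sd_locus).astype(float)
        fidelity = np.exp(-dist / config.decay_length)
        g_sl = _sex_linked_genotypes(fidelity, carrier, config, rng)
        seq = ref.sequences[config.sd_chrom]
        for i, pos in enumerate(pos_sl):
            rb = seq[pos - 1]
            records.append(
                (config.sd_chrom, int(pos), rb, (_alt_base(rb, rng),), g_sl[i], None)
            )

    # --- autosomal (background) SNPs everywhere outside the SD region
    if config.n_autosomal_snps:
        avail = {
            name: (length - (end - start + 1) if name == config.sd_chrom else length)
            for name, length in config.chromosomes
        }
        total_avail = sum(avail.values())
        alloc = {
            name: int(round(config.n_autosomal_snps * avail[name] / total_avail))
            for name, _ in config.chromosomes
        }
        # fix rounding drift on the first chromosome
        drift = config.n_autosomal_snps - sum(alloc.values())
        first = config.chromosomes[0][0]
        alloc[first] += drift
        auto_positions: list[tuple[str, int]] = []
        for name, length in config.chromosomes:
            n_here = alloc[name]
            if n_here <= 0:
                continue
            if name == config.sd_chrom:
                candidates = np.concatenate(
                    [np.arange(1, start), np.arange(end + 1, length + 1)]
                )
            else:
                candidates = np.arange(1, length + 1)
            pos = np.sort(rng.choice(candidates, n_here, replace=False))
            auto_positions.extend((name, int(p)) for p in pos)
        maf = rng.uniform(*config.maf_range, len(auto_positions))
        g_auto = rng.binomial(2, maf[:, None], (len(auto_positions), len(samples))).astype(np.int8)
        for i, (chrom, pos) in enumerate(auto_positions):
            rb = ref.sequences[chrom][pos - 1]
            records.append((chrom, pos, rb, (_alt_base(rb, rng),), g_auto[i], None))

    # --- marker indels (perfect linkage for sex-linked markers)
    for amp in ref.amplicon_truth:
        if amp.sex_linked:
            g = _sex_linked_genotypes(np.ones(1), carrier, config, rng)[0]
        else:
            maf = rng.uniform(*config.maf_range)
            g = rng.binomial(2, maf, len(samples)).astype(np.int8)
        rb = ref.sequences[amp.chrom][amp.insert_pos - 1]
        records.append(
            (amp.chrom, amp.insert_pos, rb, (rb + amp.inserted_seq,), g, amp.name)
        )

    # --- missingness and annotations, then assemble sorted sites
    records.sort(key=lambda r: (chrom_order[r[0]], r[1]))
    n_sites = len(records)
    if config.missing_rate > 0:
        drop = rng.random((n_sites, len(samples))) < config.missing_rate
    else:
        drop = np.zeros((n_sites, len(samples)), dtype=bool)
    annotations = {
        key: model.draw(rng, n_sites) for key, model in config.annotation_model.items()
    }

    sites = []
    for i, (chrom, pos, rb, alt, g, site_id) in enumerate(records):
        g = np.where(drop[i], MISSING, g).astype(np.int8)
        info = {key: float(annotations[key][i]) for key in annotations}
        sites.append(
            VariantSite(
                chrom=chrom, pos=pos, id=site_id, ref=rb, alt=alt,
                info=info, genotypes=g, samples=samples,
            )
        )
    return GenotypeDataset(samples=samples, sexes=sexes, sites=sites)


def simulate(config: SimulationConfig) -> tuple[ReferenceSet, GenotypeDataset]:
    """Build reference and genotypes from one seeded generator."""
    rng = config.rng()
    ref = build_reference(config, rng)
    dataset = simulate_genotypes(config, ref, rng)
    return ref, dataset


def write_dataset(
    dataset: GenotypeDataset, ref: ReferenceSet, out_dir: str
) -> dict[str, str]:
    """Write FASTA + VCF + phenotype TSV + truth JSON; returns the paths."""
    if not dataset.sites:
        raise EmptyDatasetError("dataset has no sites")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    fasta = out / "reference.fa"
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in ref.sequences.items()),
        str(fasta),
        "fasta",
    )
    contigs = {name: len(seq) for name, seq in ref.sequences.items()}
    vcf = out / "variants.vcf"
    write_vcf(dataset.sites, dataset.samples, str(vcf), contigs=contigs)
    phen = out / "phenotypes.tsv"
    write_phenotypes(dataset.sexes, str(phen))
    truth = out / "truth.json"
    truth_doc = {
        "sd_region": ref.sd_truth,
        "markers": [
            {
                "name": a.name,
                "chrom": a.chrom,
                "amplicon_start": a.start,
                "insert_pos": a.insert_pos,
                "inserted_seq": a.inserted_seq,
                "x_template": a.x_template,
                "y_template": a.y_template,
                "x_product": a.x_product,
                "y_product": a.y_product,
                "indel_len": a.indel_len,
                "sex_linked": a.sex_linked,
            }
            for a in ref.amplicon_truth
        ],
    }
    truth.write_text(json.dumps(truth_doc, indent=2, sort_keys=True) + "\n")
    return {
        "reference": str(fasta),
        "vcf": str(vcf),
        "phenotypes": str(phen),
        "truth": str(truth),
    }
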