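"""Indel PCR sex-marker development.

Screens the called sex-determination region for large, sex-concordant
indels; models the PCR assay they support (allele-specific product sizes
separable on a gel); predicts per-sample band patterns; calls sex from
bands; and scores assay accuracy against known phenotypes.

Product-length convention: a product spans from the 5' end of the forward
primer to the 5' end of the reverse primer inclusive — primers are part of
the amplicon, which is how gel sizes are reported (the male product is the
female product plus the Y insertion length only under a consistent
convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from sdscan.sd_scan import SdRegion, xy_concordance, zw_concordance
from sdscan.variant_io import HET, HOM_ALT, HOM_REF, PhenotypeTable, VariantSite

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str  # 5'->3'
    reverse: str  # 5'->3'

    def __post_init__(self):
        for label, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if not seq or any(c not in "ACGT" for c in seq.upper()):
                raise ValueError(f"{self.name}: {label} primer must be non-empty ACGT")


@dataclass(frozen=True)
class MarkerAssay:
    name: str
    primer_pair: PrimerPair
    x_product: int  # bp, homogametic (X- or Z-linked) allele
    y_product: int  # bp, heterogametic-carrier (Y- or W-linked) allele
    indel_len: int
    system: str = "XY"

    def __post_init__(self):
        if self.x_product <= 0 or self.y_product <= 0:
            raise ValueError(f"{self.name}: product sizes must be positive")
        if abs(self.y_product - self.x_product) != self.indel_len:
            raise ValueError(
                f"{self.name}: |y_product - x_product| must equal indel_len"
            )


@dataclass
class SexCall:
    sample: str
    predicted: str  # 'M', 'F', or 'no_call'
    bands: frozenset[int] = field(default_factory=frozenset)


def _find_all(template: str, query: str) -> list[int]:
    hits, start = [], template.find(query)
    while start != -1:
        hits.append(start)
        start = template.find(query, start + 1)
    return hits


def amplicon_spans(
    template: str, primers: PrimerPair, max_product: int = 3000
) -> list[tuple[int, int]]:
    """1-based inclusive spans of every predicted product, in plus-strand coordinates.

    A product requires the forward primer matching exactly and the reverse
    complement of the reverse primer matching exactly downstream on the
    same strand; both strands are searched and minus-strand hits are mapped
    back to plus-strand coordinates.  Exact matching keeps the prediction
    deterministic; no mismatch tolerance is applied.
    """
    if not template:
        raise ValueError("empty template")
    template = template.upper()
    fwd = primers.forward.upper()
    rev_rc = reverse_complement(primers.reverse.upper())
    length = len(template)
    spans = []
    for minus, strand in ((False, template), (True, reverse_complement(template))):
        f_hits = _find_all(strand, fwd)
        r_hits = _find_all(strand, rev_rc)
        for f in f_hits:
            for r in r_hits:
                end = r + len(rev_rc) - 1
                if r >= f and end - f + 1 <= max_product:
                    if minus:
                        spans.append((length - end, length - f))
                    else:
                        spans.append((f + 1, end + 1))
    return sorted(spans)


def in_silico_pcr(
    template: str, primers: PrimerPair, max_product: int = 3000
) -> list[int]:
    """Predict PCR product lengths on a template by exact primer matching.

    Product length spans from the 5' end of the forward match to the 3'
    end of the reverse-primer match (primers included).  All qualifying
    lengths up to ``max_product`` are returned ascending (empty list = no
    amplification); see :func:`amplicon_spans` for coordinates.
    """
    return sorted(
        e - s + 1 for s, e in amplicon_spans(template, primers, max_product)
    )


def predict_allele_sizes(
    x_product: int, indel_len: int, on_y: bool = True
) -> tuple[int, int]:
    """Product sizes (x, y) when the heterogametic allele carries the indel.

    ``indel_len`` is signed: positive for an insertion on the Y (or W)
    allele, negative for a deletion.
    """
    if x_product <= 0:
        raise ValueError(f"x_product must be positive, got {x_product}")
    y_product = x_product + indel_len if on_y else x_product
    if y_product <= 0:
        raise ValueError("predicted y product is non-positive")
    return x_product, y_product


def genotype_to_sex(bands, assay: MarkerAssay) -> str:
    """Sex from a band pattern: the heterogametic sex shows both alleles.

    XY: {x, y} -> M, {x} -> F; ZW mirrored ({x, y} -> F, {x} -> M).
    Anything else — no bands, y alone, unexpected sizes — is 'no_call'.
    """
    bands = frozenset(int(b) for b in bands)
    both = frozenset((assay.x_product, assay.y_product))
    x_only = frozenset((assay.x_product,))
    if bands == both:
        return "M" if assay.system == "XY" else "F"
    if bands == x_only:
        return "F" if assay.system == "XY" else "M"
    return "no_call"


_GT_BANDS = {
    HOM_REF: lambda a: frozenset((a.x_product,)),
    HET: lambda a: frozenset((a.x_product, a.y_product)),
    HOM_ALT: lambda a: frozenset((a.y_product,)),
}


def call_samples(site: VariantSite, assay: MarkerAssay) -> list[SexCall]:
    """Band patterns and sex calls implied by the VCF genotypes at an indel.

    Hom-ref shows the X band, het both bands, hom-alt the Y band alone
    (which is not a valid pattern in either system and yields no_call), and
    a missing genotype yields no bands.
    """
    calls = []
    for sample, g in zip(site.samples, site.genotypes):
        bands = _GT_BANDS.get(int(g), lambda a: frozenset())(assay)
        calls.append(
            SexCall(sample=sample, predicted=genotype_to_sex(bands, assay), bands=bands)
        )
    return calls


def assay_accuracy(
    calls: list[SexCall], phen: PhenotypeTable
) -> tuple[float, dict[str, int]]:
    """Accuracy over scorable calls, plus a confusion summary.

    no_call samples are excluded from the denominator (only band-readable
    samples are scored); they are counted separately in the summary along
    with the full true-by-predicted confusion matrix.
    """
    confusion = {"MM": 0, "MF": 0, "FM": 0, "FF": 0, "no_call": 0}
    correct = incorrect = 0
    for call in calls:
        truth = phen[call.sample]
        if call.predicted == "no_call":
            confusion["no_call"] += 1
            continue
        confusion[truth + call.predicted] += 1
        if call.predicted == truth:
            correct += 1
        else:
            incorrect += 1
    if correct + incorrect == 0:
        raise ValueError("no scorable calls (every sample was no_call)")
    return correct / (correct + incorrect), confusion


def screen_indels(
    sites: list[VariantSite],
    region: SdRegion,
    phen: PhenotypeTable,
    system: str = "XY",
    min_len: int = 10,
    score_threshold: float = 0.9,
) -> list[tuple[VariantSite, float]]:
    """Candidate marker indels inside the sex-determination region.

    Keeps biallelic indels with length strictly greater than ``min_len``
    whose winning-model concordance strictly exceeds ``score_threshold``,
    sorted by concordance then length, both descending.  An empty list is a
    legitimate outcome.
    """
    score_fn = xy_concordance if system == "XY" else zw_concordance
    candidates = []
    for site in sites:
        if not site.is_biallelic or not site.is_indel:
            continue
        if site.chrom != region.chrom or not (region.start <= site.pos <= region.end):
            continue
        if site.indel_len <= min_len:
            continue
        score = score_fn(site, phen)
        if score == score and score > score_threshold:  # NaN-safe
            candidates.append((site, float(score)))
    candidates.sort(key=lambda t: (-t[1], -t[0].indel_len))
    return candidates
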