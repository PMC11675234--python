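"""Genome-size estimation from a k-mer depth histogram.

The classic coverage-peak arithmetic: count canonical k-mers, locate the
modal depth of the homozygous component of the depth histogram, and divide
the total number of k-mer instances by that peak.  The quotient is rounded
half-up to the nearest base pair.  Heterozygosity/repeat mixture modelling
(the GenomeScope model) is deliberately out of scope — only the size
arithmetic is provided.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal


class EmptyHistogramError(ValueError):
    pass


class NoPeakError(ValueError):
    """The histogram decreases monotonically: no diploid coverage peak."""


@dataclass
class KmerHistogram:
    """Depth histogram: ``counts[d]`` = number of distinct k-mers seen d times."""

    k: int
    counts: dict[int, int]

    def __post_init__(self):
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if any(d < 1 for d in self.counts) or any(c < 0 for c in self.counts.values()):
            raise ValueError("depths must be >= 1 and counts >= 0")

    @property
    def total_kmers(self) -> int:
        """Total k-mer instances: sum of depth * count."""
        return sum(d * c for d, c in self.counts.items())

    @classmethod
    def from_tsv(cls, path: str, k: int) -> "KmerHistogram":
        """Load a ``depth<TAB>count`` table (jellyfish/KMC histo export)."""
        counts: dict[int, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                depth, count = line.split()[:2]
                counts[int(depth)] = int(count)
        return cls(k=k, counts=counts)

    def to_tsv(self, path: str) -> str:
        with open(path, "w") as fh:
            for depth in sorted(self.counts):
                fh.write(f"{depth}\t{self.counts[depth]}\n")
        return path


@dataclass
class GenomeSizeEstimate:
    genome_size: int
    peak: int
    total_kmers: int
    k: int | None = None
    single_copy_size: int | None = None

    @property
    def proportion(self) -> float | None:
        if self.single_copy_size is None:
            return None
        return single_copy_proportion(self.single_copy_size, self.genome_size)


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _canonical(kmer: str) -> str:
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


def count_canonical_kmers(sequences, k: int) -> KmerHistogram:
    """Histogram of canonical (strand-collapsed) k-mer multiplicities.

    A k-mer and its reverse complement count as one key (the
    lexicographically smaller spelling); windows containing any non-ACGT
    character are skipped.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if isinstance(sequences, str):
        sequences = [sequences]
    multiplicity: Counter[str] = Counter()
    for seq in sequences:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if any(c not in "ACGT" for c in window):
                continue
            multiplicity[_canonical(window)] += 1
    if not multiplicity:
        raise EmptyHistogramError(
            f"no {k}-mers could be extracted (k longer than every sequence?)"
        )
    hist: Counter[int] = Counter(multiplicity.values())
    return KmerHistogram(k=k, counts=dict(hist))


def find_coverage_peak(hist: KmerHistogram) -> int:
    """Modal depth of the histogram after excluding the low-depth error slope.

    Walking depths in ascending order, the sequencing-error component is a
    decreasing slope; the first local minimum marks its end.  The peak is
    the argmax of counts at depths beyond that valley.  A monotonically
    decreasing histogram has no such peak and raises ``NoPeakError``.
    """
    if not hist.counts:
        raise EmptyHistogramError("empty histogram")
    depths = sorted(hist.counts)
    counts = [hist.counts[d] for d in depths]
    valley = None
    for i in range(1, len(counts)):
        if counts[i] > counts[i - 1]:
            valley = i - 1
            break
    if valley is None:
        raise NoPeakError("histogram decreases monotonically; no coverage peak")
    tail = range(valley + 1, len(depths))
    peak_idx = max(tail, key=lambda i: (counts[i], -depths[i]))
    return depths[peak_idx]


def estimate_genome_size(total_kmers: int, peak: int) -> int:
    """Genome size in bp: total k-mer instances / coverage peak, rounded half-up.

    Computed in exact integer arithmetic so 10-digit totals round correctly.
    """
    if peak < 1:
        raise ZeroDivisionError(f"coverage peak must be >= 1, got {peak}")
    if total_kmers <= 0:
        raise ValueError(f"total_kmers must be positive, got {total_kmers}")
    return (2 * total_kmers + peak) // (2 * peak)


def single_copy_proportion(single_copy_size: int, genome_size: int) -> float:
    """single_copy_size / genome_size, rounded half-up to 3 decimals."""
    if genome_size == 0:
        raise ZeroDivisionError("genome_size is zero")
    if single_copy_size < 0:
        raise ValueError("single_copy_size must be non-negative")
    q = (Decimal(single_copy_size) / Decimal(genome_size)).quantize(
        Decimal("0.001"), rounding=ROUND_HALF_UP
    )
    return float(q)


def estimate_from_histogram(
    hist: KmerHistogram,
    single_copy_bounds: tuple[int, int] | None = None,
) -> GenomeSizeEstimate:
    """Peak detection + size arithmetic in one call.

    ``single_copy_bounds`` (inclusive depth window) defines which depths
    count as the single-copy component; there is no universal default, so
    it is optional and explicit.
    """
    peak = find_coverage_peak(hist)
    total = hist.total_kmers
    single = None
    if single_copy_bounds is not None:
        lo, hi = single_copy_bounds
        single_total = sum(
            d * c for d, c in hist.counts.items() if lo <= d <= hi
        )
        single = estimate_genome_size(single_total, peak) if single_total else 0
    return GenomeSizeEstimate(
        genome_size=estimate_genome_size(total, peak),
        peak=peak,
        total_kmers=total,
        k=hist.k,
        single_copy_size=single,
    )
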