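"""GATK-style hard filtering of variant sites.

A site passes iff every annotation it *carries* satisfies its inequality
strictly: QD > qd_min, MQ > mq_min, FS < fs_max, ReadPosRankSum >
read_pos_rank_sum_min, MQRankSum > mq_rank_sum_min.  A value exactly equal
to its threshold fails.  An absent annotation never fails a site — the
rank-sum annotations are undefined at sites with no heterozygote, and such
sites must not be excluded for it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from sdscan.variant_io import VariantSite


class AnnotationError(ValueError):
    """A site annotation could not be interpreted as a number."""


@dataclass(frozen=True)
class FilterThresholds:
    qd_min: float = 2.0
    mq_min: float = 40.0
    fs_max: float = 60.0
    read_pos_rank_sum_min: float = -8.0
    mq_rank_sum_min: float = -12.5

    def __post_init__(self):
        for name, value in self.__dict__.items():
            if not math.isfinite(value):
                raise ValueError(f"threshold {name} must be finite, got {value}")


# (INFO key, threshold attribute, comparison) — True means "greater than"
_RULES = (
    ("QD", "qd_min", True),
    ("MQ", "mq_min", True),
    ("FS", "fs_max", False),
    ("ReadPosRankSum", "read_pos_rank_sum_min", True),
    ("MQRankSum", "mq_rank_sum_min", True),
)


def site_filter_reasons(
    site: VariantSite, thresholds: FilterThresholds | None = None
) -> set[str]:
    """Names of every annotation the site violates (empty set = pass)."""
    thr = thresholds or FilterThresholds()
    reasons: set[str] = set()
    for key, attr, greater in _RULES:
        if key not in site.info:
            continue
        raw = site.info[key]
        try:
            value = float(raw)
        except (TypeError, ValueError) as exc:
            raise AnnotationError(
                f"{site.chrom}:{site.pos}: non-numeric {key}={raw!r}"
            ) from exc
        bound = getattr(thr, attr)
        ok = value > bound if greater else value < bound
        if not ok:
            reasons.add(key)
    return reasons


def apply_hard_filters(
    sites: list[VariantSite], thresholds: FilterThresholds | None = None
) -> tuple[list[VariantSite], list[tuple[VariantSite, set[str]]]]:
    """Partition sites into (passing, failing-with-reasons).

    Idempotent: re-filtering the passing set returns it unchanged.
    """
    passed: list[VariantSite] = []
    failed: list[tuple[VariantSite, set[str]]] = []
    for site in sites:
        reasons = site_filter_reasons(site, thresholds)
        if reasons:
            failed.append((site, reasons))
        else:
            passed.append(site)
    return passed, failed
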