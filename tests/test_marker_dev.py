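"""PCR assay modelling: in-silico PCR, allele sizes, sex calls, accuracy."""

import numpy as np
import pytest

from conftest import make_site
from sdscan.marker_dev import (
    MarkerAssay,
    PrimerPair,
    SexCall,
    amplicon_spans,
    assay_accuracy,
    call_samples,
    genotype_to_sex,
    in_silico_pcr,
    predict_allele_sizes,
    reverse_complement,
    screen_indels,
)
from sdscan.sd_scan import SdRegion
from sdscan.variant_io import HET, HOM_ALT, HOM_REF, MISSING, PhenotypeTable

MFS1 = PrimerPair("MFS-1", "TATGTCTGGAGGTCACTG", "GCTTATTTGGAGGATTGT")
MFS2 = PrimerPair("MFS-2", "TGTGAATGGGTGAATGAG", "TAGCTTTGTACTTTGTTCC")


def phen_for(samples, n_males):
    return PhenotypeTable(
        {s: ("M" if i < n_males else "F") for i, s in enumerate(samples)}
    )


def test_pcr_on_truth_templates_recovers_gel_sizes(default_sim):
    _, ref, _ = default_sim
    by_name = {a.name: a for a in ref.amplicon_truth}
    assert in_silico_pcr(by_name["MFS-1"].x_template, MFS1) == [346]
    assert in_silico_pcr(by_name["MFS-1"].y_template, MFS1) == [364]
    assert in_silico_pcr(by_name["MFS-2"].x_template, MFS2) == [412]
    assert in_silico_pcr(by_name["MFS-2"].y_template, MFS2) == [426]


def test_pcr_finds_amplicon_on_either_strand(default_sim):
    _, ref, _ = default_sim
    amp = ref.amplicon_truth[0]
    flipped = reverse_complement(amp.x_template)
    assert in_silico_pcr(flipped, MFS1) == [346]


def test_pcr_without_binding_sites_is_silent():
    assert in_silico_pcr("ACGT" * 100, MFS1) == []


def test_pcr_reports_all_products_ascending():
    fwd, rev = "ACGTACGTACGTACGT", "TTTTCCCCGGGGAAAA"
    rev_rc = reverse_complement(rev)
    template = fwd + "A" * 10 + fwd + "C" * 20 + rev_rc
    products = in_silico_pcr(template, PrimerPair("p", fwd, rev))
    inner = len(fwd) + 10 + len(fwd) + 20 + len(rev_rc)
    assert products == sorted(products)
    assert products == [len(fwd) + 20 + len(rev_rc), inner]
    spans = amplicon_spans(template, PrimerPair("p", fwd, rev))
    assert sorted(e - s + 1 for s, e in spans) == products


def test_pcr_respects_max_product():
    template = MFS1.forward + "A" * 400 + reverse_complement(MFS1.reverse)
    assert in_silico_pcr(template, MFS1, max_product=100) == []


@pytest.mark.parametrize(
    "x,indel,expected",
    [(346, 18, (346, 364)), (412, 14, (412, 426)), (300, 0, (300, 300))],
)
def test_predict_allele_sizes(x, indel, expected):
    assert predict_allele_sizes(x, indel) == expected


def test_predict_allele_sizes_rejects_non_positive():
    with pytest.raises(ValueError):
        predict_allele_sizes(0, 18)
    with pytest.raises(ValueError):
        predict_allele_sizes(10, -12)


MFS1_ASSAY = MarkerAssay("MFS-1", MFS1, x_product=346, y_product=364, indel_len=18)


def test_band_pattern_to_sex_xy():
    assert genotype_to_sex({346, 364}, MFS1_ASSAY) == "M"
    assert genotype_to_sex({346}, MFS1_ASSAY) == "F"
    assert genotype_to_sex(set(), MFS1_ASSAY) == "no_call"
    assert genotype_to_sex({364}, MFS1_ASSAY) == "no_call"
    assert genotype_to_sex({346, 999}, MFS1_ASSAY) == "no_call"


def test_band_pattern_to_sex_zw_mirrors():
    zw = MarkerAssay("m", MFS1, x_product=346, y_product=364, indel_len=18,
                     system="ZW")
    assert genotype_to_sex({346, 364}, zw) == "F"
    assert genotype_to_sex({346}, zw) == "M"


def test_assay_inconsistent_products_rejected():
    with pytest.raises(ValueError):
        MarkerAssay("m", MFS1, x_product=346, y_product=360, indel_len=18)


def test_genotypes_imply_band_patterns():
    site = make_site([HET, HOM_REF, HOM_ALT, MISSING])
    calls = call_samples(site, MFS1_ASSAY)
    assert [c.predicted for c in calls] == ["M", "F", "no_call", "no_call"]
    assert calls[0].bands == {346, 364}
    assert calls[1].bands == {346}


def test_accuracy_excludes_no_calls():
    phen = PhenotypeTable({f"s{i}": ("M" if i < 18 else "F") for i in range(38)})
    calls = [SexCall(f"s{i}", "M" if i < 18 else "F") for i in range(37)]
    calls[0] = SexCall("s0", "F")  # one discordant fish
    calls.append(SexCall("s37", "no_call"))
    accuracy, confusion = assay_accuracy(calls, phen)
    assert accuracy == pytest.approx(36 / 37)
    assert round(accuracy * 100, 2) == 97.30
    assert confusion["no_call"] == 1 and confusion["MF"] == 1


def test_accuracy_edge_rates():
    phen = PhenotypeTable({f"s{i}": "M" for i in range(10)})
    perfect = [SexCall(f"s{i}", "M") for i in range(10)]
    assert assay_accuracy(perfect, phen)[0] == 1.0
    wrong = [SexCall(f"s{i}", "F") for i in range(5)]
    assert assay_accuracy(wrong, phen)[0] == 0.0
    with pytest.raises(ValueError):
        assay_accuracy([SexCall("s0", "no_call")], phen)


REGION = SdRegion("chr9", 19_740_000, 22_600_000, n_support=10, system="XY")


def _indel(pos, length, genotypes, chrom="chr9"):
    return make_site(
        genotypes, chrom=chrom, pos=pos, ref="A", alt=("A" + "G" * length,)
    )


def test_screen_keeps_large_concordant_indels_in_order():
    perfect = [HET] * 5 + [HOM_REF] * 5
    sites = [
        _indel(20_000_000, 18, perfect),
        _indel(20_100_000, 14, perfect),
        _indel(20_200_000, 8, perfect),             # too short
        _indel(5_000_000, 20, perfect, chrom="chr2"),  # outside region
        _indel(20_300_000, 12, [HET] * 5 + [HET] * 5),  # concordance 0.5
    ]
    phen = phen_for(sites[0].samples, 5)
    hits = screen_indels(sites, REGION, phen, system="XY")
    assert [(s.indel_len, score) for s, score in hits] == [(18, 1.0), (14, 1.0)]


def test_screen_allows_empty_result():
    phen = PhenotypeTable({"s0": "M", "s1": "F"})
    assert screen_indels([], REGION, phen) == []


def test_end_to_end_assay_quality_degrades_with_missingness(small_config):
    """Zero-noise runs are perfect; rising missingness costs scorable samples.

    Dropped genotypes become no_call (no bands), so accuracy over scorable
    samples stays high while the no_call burden grows with mu — accuracy
    must never improve and the number of unreadable samples must rise.
    """
    from dataclasses import replace

    from sdscan.synthetic_data import DEFAULT_MARKERS, simulate

    mean_acc, no_calls = [], []
    for mu in (0.0, 0.05, 0.1):
        accs, dropped = [], 0
        for seed in range(20):
            config = replace(
                small_config, seed=seed, markers=DEFAULT_MARKERS,
                sd_region=(10_000, 50_000), male_error=0.0, female_error=0.0,
                missing_rate=mu, n_autosomal_snps=0,
            )
            _, ds = simulate(config)
            phen = ds.phenotypes()
            for site in (s for s in ds.sites if s.is_indel):
                assay = MarkerAssay(
                    site.id, MFS1, x_product=346,
                    y_product=346 + site.indel_len, indel_len=site.indel_len,
                )
                calls = call_samples(site, assay)
                accuracy, confusion = assay_accuracy(calls, phen)
                accs.append(accuracy)
                dropped += confusion["no_call"]
        mean_acc.append(float(np.mean(accs)))
        no_calls.append(dropped)
    assert mean_acc[0] == 1.0  # no noise, no error: every sample correct
    assert mean_acc[0] >= mean_acc[1] >= mean_acc[2]
    assert no_calls[0] == 0 < no_calls[1] < no_calls[2]
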