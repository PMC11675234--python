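"""Generator behavior: determinism, closed-form concordance, system mirror."""

import numpy as np
import pytest
from scipy import stats

from sdscan.sd_scan import scan
from sdscan.synthetic_data import (
    ConfigError,
    DEFAULT_MARKERS,
    EmptyDatasetError,
    MarkerDef,
    SimulationConfig,
    build_marker_templates,
    build_reference,
    expected_xy_concordance,
    simulate,
    simulate_genotypes,
    write_dataset,
)
from sdscan.variant_io import HET, HOM_REF, MISSING, read_vcf


def bare_config(**kw):
    defaults = dict(
        seed=0,
        chromosomes=(("chr1", 50_000),),
        sd_chrom="chr1",
        sd_locus=25_000,
        sd_region=(15_000, 35_000),
        n_sex_linked_snps=10,
        n_autosomal_snps=10,
        markers=(),
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


def test_reference_has_one_sequence_per_chromosome():
    config = bare_config(chromosomes=(("chr1", 1_000),), sd_locus=600,
                         sd_region=(400, 800))
    ref = build_reference(config)
    assert set(ref.sequences) == {"chr1"}
    assert len(ref.sequences["chr1"]) == 1_000
    assert set(ref.sequences["chr1"]) <= set("ACGT")


def test_marker_templates_differ_only_by_insertion():
    rng = np.random.default_rng(0)
    for marker, (x_len, y_len) in zip(DEFAULT_MARKERS, [(346, 364), (412, 426)]):
        x, y = build_marker_templates(marker, rng)
        assert (len(x), len(y)) == (x_len, y_len)
        # Y is X with insertion_len extra bases at one position
        j = next(i for i, (a, b) in enumerate(zip(x, y)) if a != b)
        assert y[:j] + y[j + marker.insertion_len :] == x


def test_same_seed_gives_identical_reference():
    config = bare_config()
    a = build_reference(config).sequences["chr1"]
    b = build_reference(config).sequences["chr1"]
    assert a == b


def test_amplicon_must_fit_inside_region():
    config = bare_config(
        sd_region=(24_900, 25_100), sd_locus=25_000, markers=DEFAULT_MARKERS
    )
    with pytest.raises(ConfigError, match="does not fit"):
        build_reference(config)


def test_perfect_linkage_limit():
    """lambda -> infinity with zero error/missingness: textbook XY pattern."""
    config = bare_config(
        decay_length=1e12, male_error=0, female_error=0, missing_rate=0,
        n_autosomal_snps=0,
    )
    ref = build_reference(config)
    ds = simulate_genotypes(config, ref)
    males = ds.phenotypes().male_mask(ds.samples)
    for site in ds.sites:
        assert (site.genotypes[males] == HET).all()
        assert (site.genotypes[~males] == HOM_REF).all()


def test_no_males_degenerate_cohort():
    config = bare_config(n_males=0, n_females=6)
    _, ds = simulate(config)
    assert set(ds.sexes.values()) == {"F"}
    assert len(ds.samples) == 6


def test_zero_sites_rejected():
    config = bare_config(n_sex_linked_snps=0, n_autosomal_snps=0)
    ref = build_reference(config)
    with pytest.raises(EmptyDatasetError):
        simulate_genotypes(config, ref)


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        bare_config(n_males=1, n_females=0).validate()
    with pytest.raises(ConfigError):
        bare_config(missing_rate=1.5).validate()
    with pytest.raises(ConfigError):
        bare_config(sd_region=(1, 90_000)).validate()
    with pytest.raises(ConfigError):
        bare_config(maf_range=(0.0, 0.5)).validate()
    with pytest.raises(ConfigError):
        bare_config(system="XZ").validate()


def test_observed_concordance_matches_closed_form():
    """Aggregate z-test of simulated XY matches against the analytic model.

    For every sex-linked site, each individual matches the XY pattern with
    probability f(d)(1-e_m) (carrier) or 1-e_f (homogametic); summing
    means and Bernoulli variances over 50 seeds gives a 3-sigma band for
    the total match count.
    """
    total_obs = total_exp = total_var = 0.0
    for seed in range(50):
        config = bare_config(
            seed=seed, missing_rate=0.0, decay_length=8_000.0,
            male_error=0.02, female_error=0.02, n_autosomal_snps=0,
        )
        ref = build_reference(config)
        ds = simulate_genotypes(config, ref)
        males = ds.phenotypes().male_mask(ds.samples)
        for site in ds.sites:
            d = abs(site.pos - config.sd_locus)
            f = np.exp(-d / config.decay_length)
            p_m = f * (1 - config.male_error)
            p_f = 1 - config.female_error
            matched = (site.genotypes[males] == HET).sum() + (
                site.genotypes[~males] == HOM_REF
            ).sum()
            total_obs += matched
            total_exp += config.n_males * p_m + config.n_females * p_f
            total_var += config.n_males * p_m * (1 - p_m) + (
                config.n_females * p_f * (1 - p_f)
            )
            # per-site expectation is the public closed form
            assert expected_xy_concordance(config, d) == pytest.approx(
                (config.n_males * p_m + config.n_females * p_f) / 38
            )
    assert abs(total_obs - total_exp) < 3 * np.sqrt(total_var)


def test_carrier_het_rate_decays_like_exponential():
    """At distance == lambda the carrier het rate is e^-1 within 3 SE."""
    n_trials = 0
    n_het = 0
    for seed in range(50):
        config = bare_config(
            seed=seed, decay_length=5_000.0, male_error=0.0, female_error=0.0,
            missing_rate=0.0, n_autosomal_snps=0, n_sex_linked_snps=40,
            n_males=20, n_females=2,
        )
        ref = build_reference(config)
        ds = simulate_genotypes(config, ref)
        males = ds.phenotypes().male_mask(ds.samples)
        for site in ds.sites:
            d = abs(site.pos - config.sd_locus)
            if abs(d - config.decay_length) > 500:  # keep d within 10% of lambda
                continue
            n_trials += config.n_males
            n_het += int((site.genotypes[males] == HET).sum())
    p0 = np.exp(-1)
    assert n_trials > 500
    se = np.sqrt(p0 * (1 - p0) / n_trials)
    assert n_het / n_trials == pytest.approx(p0, abs=3 * se)


def test_zw_mirror_matches_xy_distribution():
    """Pooled concordance scores: ZW + label swap ~ XY (two-sample KS)."""
    xy_scores, zw_scores = [], []
    for seed in range(12):
        cfg_xy = bare_config(seed=seed, system="XY", n_autosomal_snps=0)
        _, ds_xy = simulate(cfg_xy)
        xy_scores += [r.xy_score for r in scan(ds_xy.sites, ds_xy.phenotypes())]
        cfg_zw = bare_config(seed=seed + 1000, system="ZW", n_autosomal_snps=0)
        _, ds_zw = simulate(cfg_zw)
        swapped = ds_zw.phenotypes().swapped()
        zw_scores += [r.xy_score for r in scan(ds_zw.sites, swapped)]
    ks = stats.ks_2samp(xy_scores, zw_scores)
    assert ks.pvalue > 0.01


def test_write_dataset_round_trip_many_configs(tmp_path):
    rng = np.random.default_rng(123)
    for i in range(20):
        config = bare_config(
            seed=int(rng.integers(0, 2**31)),
            n_males=int(rng.integers(1, 8)),
            n_females=int(rng.integers(1, 8)),
            n_sex_linked_snps=int(rng.integers(1, 15)),
            n_autosomal_snps=int(rng.integers(0, 15)),
            missing_rate=float(rng.uniform(0, 0.2)),
        )
        ref, ds = simulate(config)
        paths = write_dataset(ds, ref, str(tmp_path / f"rt{i}"))
        sites, samples = read_vcf(paths["vcf"])
        assert samples == ds.samples
        assert np.array_equal(
            np.vstack([s.genotypes for s in sites]), ds.genotype_matrix
        )


def test_vcf_is_deterministic_and_sorted(tmp_path):
    config = SimulationConfig(seed=7)
    for run in ("a", "b"):
        ref, ds = simulate(config)
        write_dataset(ds, ref, str(tmp_path / run))
    a = (tmp_path / "a" / "variants.vcf").read_bytes()
    b = (tmp_path / "b" / "variants.vcf").read_bytes()
    assert a == b

    sites, _ = read_vcf(str(tmp_path / "a" / "variants.vcf"))
    n_records = sum(
        1
        for line in (tmp_path / "a" / "variants.vcf").read_text().splitlines()
        if line and not line.startswith("#")
    )
    assert n_records == len(sites)  # independent line-count oracle
    by_chrom: dict[str, int] = {}
    for site in sites:
        assert site.pos > by_chrom.get(site.chrom, 0)
        by_chrom[site.chrom] = site.pos


def test_marker_indels_present_and_sex_linked(default_sim):
    config, ref, ds = default_sim
    indels = [s for s in ds.sites if s.is_indel]
    assert sorted(s.indel_len for s in indels) == [14, 18]
    for site in indels:
        assert site.chrom == config.sd_chrom
        assert config.sd_region[0] <= site.pos <= config.sd_region[1]


def test_missingness_rate_is_respected():
    config = bare_config(
        seed=4, n_sex_linked_snps=200, n_autosomal_snps=200, missing_rate=0.1,
    )
    _, ds = simulate(config)
    frac = (ds.genotype_matrix == MISSING).mean()
    n = ds.genotype_matrix.size
    assert frac == pytest.approx(0.1, abs=4 * np.sqrt(0.1 * 0.9 / n))
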