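# Methods

This note documents the models, parameter choices, and numerical rules
behind `sdscan`, and what the synthetic benchmark does and does not show
about real data.

## Concordance model and system inference

For a biallelic site with genotypes over `n` phenotypically sexed
diploids, the XY concordance score is

    xy_score = (#{males het} + #{females hom_ref or hom_alt}) / n_used

over the `n_used` non-missing genotypes, and the ZW score is the exact
mirror (females het, males homozygous). "Homozygous" deliberately means
*either* homozygote: a Y-linked (or W-linked) allele may be recorded as
REF or ALT depending on which haplotype the assembly captured, and
restricting the homogametic sex to hom-ref would couple the score to
reference polarity.

A site supports a system when its score strictly exceeds the threshold
(default 0.90, read as "over 90 %"). At the default cohort size of 38
this means at least 35 of 38 individuals must match — a property the test
suite asserts combinatorially. The system call requires at least
`min_snps` (default 5) supporting SNPs *and* a 2× majority over the
mirror hypothesis (`system_factor`, configurable); the 2× margin exists
so that a handful of noisy sites cannot flip a call, and anything short
of it returns `undetermined` rather than guessing.

The region is the min–max envelope of the winning high scorers on their
majority chromosome, after splitting runs separated by more than
`max_gap` (default 1 Mb) and keeping the best-supported run. The
envelope matches how such regions are reported ("located between X and Y
Mb"); density-weighted alternatives were considered and rejected as
harder to interpret with no accuracy benefit at these SNP densities.
High scorers outside the winning run are reported as outliers, never
silently dropped.

## Allelic association

The association scan is the basic allelic (2N-allele) case/control test:
each non-missing genotype contributes two alleles to a 2×2 sex-by-allele
table scored with the Pearson chi-square without continuity correction
(1 df). This matches the default basic association mode of standard
GWAS tooling when run without covariates; genotypic and logistic
variants are deliberately out of scope. Degenerate tables (any zero
margin — monomorphic sites, single-sex strata) return χ² = 0, p = 1
instead of raising, because monomorphic sites are routine in a genome
scan and must not halt it. Multiple testing uses Bonferroni (α/m) only;
no FDR machinery is provided because the scan's consumer is a single
region call, not a discovery list.

## Hard filters

Thresholds follow the GATK hard-filtering convention: QD > 2.0,
MQ > 40.0, FS < 60.0, ReadPosRankSum > −8.0, MQRankSum > −12.5, all
strict, all configurable. Two boundary rules matter: a value exactly
equal to its threshold *fails* (the kept set is defined by strict
inequalities, and a deterministic boundary is required for testing), and
a site *missing* an annotation passes that sub-filter (rank-sum
annotations are undefined at sites without both ref and alt reads;
failing them would systematically exclude hom-alt sites). One threshold
set applies to SNPs and indels alike, with per-field overrides exposed.

## Synthetic cohort generator

The generator emulates the statistical structure the scans assume, at a
desk scale where 100-seed experiments run in seconds.

* **Linkage decay.** A sex-linked SNP at distance `d` from the
  sex-determination locus stays linked to the sex-determining allele
  with fidelity `f(d) = exp(−d/λ)`. Exponential decay in physical
  distance is the simplest one-parameter model producing the observed
  pattern (concordance falling off away from the locus); it is not a
  pedigree-accurate recombination model.
* **Genotype model.** Under XY, a male is het with probability
  `f(d)·(1−e_m)`, else hom-ref; a female is hom-ref with probability
  `1−e_f`, else het. The REF allele is the X-linked allele by
  convention. Autosomal SNPs draw MAF ~ U(0.05, 0.5) and genotypes from
  Hardy–Weinberg. Every call is set missing independently with
  probability μ.
* **ZW mirror.** ZW is generated by swapping which sex is the
  heterogametic carrier. The error knobs follow the *role*, not the
  label: `male_error` (named for the XY default) is the carrier error,
  `female_error` the homogametic error. This makes "simulate ZW, swap
  the labels" distributionally identical to XY — a property the tests
  check with a two-sample KS test — which would fail for unequal errors
  under a label-bound reading.
* **Defaults.** 18 males + 20 females; 24 chromosomes of 295 kb (a 1/100
  scale model of a ~708 Mb, 24-chromosome genome); SD region
  197,400–226,000 bp on chr9 (19.74–22.60 Mb scaled), locus at its
  midpoint; 60 sex-linked + 500 autosomal SNPs; e_m = e_f = 0.01,
  μ = 0.02. λ defaults to 150 kb at this scale, chosen so that linkage
  fidelity is ≈ 0.91 at the region edges — the regime implied by a study
  design in which every >90 %-concordance SNP falls inside the region.
  No empirical decay estimate exists for this system; λ is a simulator
  parameter, documented as such, and moves with the scenario under
  study.
* **Markers.** Two PCR amplicons are embedded near the locus: X-allele
  templates of exactly 346 and 412 bp whose primer pairs bracket the
  full template, with perfectly sex-linked (f = 1) Y insertions of 18
  and 14 bp between the primer sites — so male/female products are
  364/346 and 426/412 bp. Marker indels still experience genotyping
  error and missingness.
* **Annotations.** Each INFO field (QD, MQ, FS, ReadPosRankSum,
  MQRankSum) is drawn from a two-component uniform model: a passing
  range with probability 0.99 and a clearly failing range otherwise,
  giving ≈ 5 % of sites at least one failing field — a mostly clean
  post-calling callset.
* **Determinism.** The seed is mandatory; all randomness flows through
  one `numpy` generator, and a fixed seed yields byte-identical FASTA
  and VCF output.

**What the benchmark does not emulate:** read-level noise and alignment
artifacts, LD between background SNPs, coalescent population structure,
relatedness, sex-biased coverage, and structural variation beyond the
two marker insertions. Passing the synthetic benchmark therefore
demonstrates the *statistical machinery* — calibration under the null,
recovery under the stated generative model — not robustness to every
real-data pathology upstream of the VCF.

## In-silico PCR and assay scoring

Primer matching is exact (0 mismatches), on both strands, reporting all
qualifying products up to `max_product` (default 3 kb). Exactness keeps
the operation deterministic; a mismatch allowance is a natural extension
but is not needed for markers designed against their own reference.
Product length runs from the 5′ end of the forward primer to the 5′ end
of the reverse primer inclusive — primers are part of the amplicon, the
convention under which gel sizes satisfy `male = female + insertion`.

Band patterns map to sex by the heterogametic-carrier rule (XY: both
bands → M, X band only → F; ZW mirrored); anything else — no bands, the
Y band alone, unexpected sizes — is a `no_call`. Assay accuracy is
computed over scorable calls only, with `no_call`s and the full
confusion matrix reported separately, so both "discordant" and "failed
to amplify" interpretations of an imperfect assay remain computable.

Indel screening keeps biallelic indels inside the called region with
length strictly greater than 10 bp and winning-model concordance above
the scan threshold, ranked by concordance then length — the "large,
perfectly sex-linked indels first" order in which PCR markers are
chosen in practice.

## K-mer genome size

Genome size is `round_half_up(total k-mer instances / coverage peak)`,
computed in exact integer arithmetic (`(2T + P) // 2P`) because 10-digit
totals overflow the precision where float rounding becomes untrustworthy.
Half-up rounding is the rule that reproduces published tables of this
arithmetic. The single-copy proportion is rounded half-up to 3 decimals
(banker's rounding would differ on exact .0005 boundaries). Peak
detection walks depths in ascending order, treats the initial decreasing
slope as the sequencing-error component, and returns the argmax beyond
the first local minimum; a monotonically decreasing histogram raises a
no-peak error. This simple rule is adequate for the well-separated
error/diploid components of high-coverage histograms; it is not a
mixture-model fit, and heterozygosity/repeat decomposition is explicitly
out of scope. Note that a Poisson depth profile with *integer* mean has
two tied modal depths (mean and mean−1), so the detected peak on
simulated integer-mean data legitimately lands on either; the
single-copy depth window has no universal default and must be supplied
explicitly.

## Numerical and engineering choices

* Genotypes are a four-state int8 code (hom-ref/het/hom-alt/missing);
  het is phase- and order-insensitive, and any call touching an ALT
  allele beyond the first is treated as missing for these biallelic
  analyses (such sites are retained and flagged, not dropped).
* All internal coordinates are 1-based inclusive; BED export is the only
  0-based half-open surface.
* VCF reading goes through pysam/htslib. VCF *writing* is a small text
  emitter with fixed float formatting (two decimals, fixed INFO key
  order) because the pipeline guarantees byte-identical output under a
  fixed seed, which htslib float formatting does not.
* The pipeline summary and manifest are JSON with sorted keys and no
  timestamps; the manifest lists every input and output with a SHA-256
  content hash.
* Test problem sizes (100-seed region-recovery sweeps, 10⁵-site null
  calibration, margin-≤30 exhaustive chi-square sweeps) were chosen so
  the full suite completes in well under a minute per scientific claim
  while keeping Monte-Carlo bands at 3 standard errors.

## Known limitations

* The association test is allelic only; structured cohorts need a
  mixed-model tool upstream.
* Region calling assumes a single sex-determination region; two distant
  true regions would be reported as winner + outliers.
* In-silico PCR does not model primer thermodynamics, dimers, or
  mismatch-tolerant annealing.
* The genome-size module reproduces the division arithmetic; it does not
  estimate heterozygosity or repeat content.
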