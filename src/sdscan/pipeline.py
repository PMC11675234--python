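"""End-to-end orchestration: filter -> assoc -> scan -> region -> markers.

Every run writes its stage outputs plus a deterministic ``summary.json``
(no timestamps, sorted keys) and a ``manifest.json`` listing each artifact
with a content hash, the parameters used, and the package version — so a
rerun with the same inputs is byte-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

import sdscan
from sdscan.hard_filter import FilterThresholds, apply_hard_filters
from sdscan.marker_dev import (
    MarkerAssay,
    PrimerPair,
    amplicon_spans,
    assay_accuracy,
    call_samples,
)
from sdscan.marker_dev import screen_indels as _screen_indels
from sdscan.sd_scan import ScanConfig, call_sd_region, infer_system, scan, scan_table
from sdscan.sex_association import bonferroni_threshold, genome_scan
from sdscan.synthetic_data import (
    FieldModel,
    MarkerDef,
    SimulationConfig,
    simulate,
    write_dataset,
)
from sdscan.variant_io import read_phenotypes, read_vcf, write_region_bed, write_vcf

log = logging.getLogger("sdscan")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    vcf: str
    phenotypes: str
    outdir: str
    reference: str | None = None
    primers: str | None = None  # TSV: name, forward, reverse (with header)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    scan: ScanConfig = field(default_factory=ScanConfig)
    marker_min_len: int = 10
    alpha: float = 0.05
    max_product: int = 3000


def read_primers(path: str) -> list[PrimerPair]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        PrimerPair(row["name"], row["forward"].upper(), row["reverse"].upper())
        for _, row in df.iterrows()
    ]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _marker_stage(config: RunConfig, sites, region, system, phen):
    """Screen region indels, pair them with primer amplicons, genotype samples."""
    candidates = _screen_indels(
        sites, region, phen, system=system,
        min_len=config.marker_min_len, score_threshold=config.scan.threshold,
    )
    markers = []
    if not (config.reference and config.primers and candidates):
        return candidates, markers
    seqs = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(config.reference, "fasta")
    }
    if region.chrom not in seqs:
        raise PipelineError("markers", f"{region.chrom} absent from reference FASTA")
    chrom_seq = seqs[region.chrom]
    for primers in read_primers(config.primers):
        spans = amplicon_spans(chrom_seq, primers, config.max_product)
        for start, end in spans:
            hits = [
                (site, score)
                for site, score in candidates
                if start <= site.pos <= end
            ]
            if not hits:
                continue
            site, score = hits[0]  # best-ranked indel in this amplicon
            x_product = end - start + 1
            assay = MarkerAssay(
                name=primers.name,
                primer_pair=primers,
                x_product=x_product,
                y_product=x_product + site.signed_indel_len,
                indel_len=site.indel_len,
                system=system,
            )
            calls = call_samples(site, assay)
            accuracy, confusion = assay_accuracy(calls, phen)
            markers.append(
                {
                    "name": assay.name,
                    "chrom": site.chrom,
                    "pos": site.pos,
                    "x_product": assay.x_product,
                    "y_product": assay.y_product,
                    "indel_len": assay.indel_len,
                    "concordance": round(score, 6),
                    "accuracy": round(accuracy, 6),
                    "confusion": confusion,
                    "calls": [
                        {"sample": c.sample, "predicted": c.predicted,
                         "bands": sorted(c.bands)}
                        for c in calls
                    ],
                }
            )
    return candidates, markers


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages, write artifacts under ``config.outdir``, return the summary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    try:
        sites, samples = read_vcf(config.vcf)
        phen = read_phenotypes(config.phenotypes)
    except Exception as exc:
        raise PipelineError("input", str(exc)) from exc
    log.info("input: %d sites, %d samples (%dM/%dF)",
             len(sites), len(samples), phen.n_males, phen.n_females)

    # --- filter
    try:
        passed, failed = apply_hard_filters(sites, config.thresholds)
    except Exception as exc:
        raise PipelineError("filter", str(exc)) from exc
    contigs = None
    artifacts["pass_vcf"] = Path(
        write_vcf(passed, samples, str(out / "pass.vcf"), contigs)
    )
    fail_df = pd.DataFrame(
        {
            "chrom": [s.chrom for s, _ in failed],
            "pos": [s.pos for s, _ in failed],
            "reasons": [",".join(sorted(r)) for _, r in failed],
        }
    )
    fail_df.to_csv(out / "fail.tsv", sep="\t", index=False)
    artifacts["fail_tsv"] = out / "fail.tsv"
    log.info("filter: %d pass, %d fail", len(passed), len(failed))
    if not passed:
        raise PipelineError("scan", "no variants passed hard filtering; nothing to scan")

    # --- association
    try:
        assoc_results, assoc_df = genome_scan(passed, phen)
    except Exception as exc:
        raise PipelineError("assoc", str(exc)) from exc
    assoc_df.to_csv(out / "assoc.tsv", sep="\t", index=False)
    artifacts["assoc_tsv"] = out / "assoc.tsv"
    n_tests = len(assoc_results)
    threshold_line = bonferroni_threshold(config.alpha, n_tests)
    top = assoc_df.loc[assoc_df["p"].idxmin()]
    log.info("assoc: %d tests, top hit %s:%d (p=%.3g)",
             n_tests, top["chrom"], int(top["pos"]), top["p"])

    # --- concordance scan + system
    try:
        results = scan(passed, phen, config.scan)
        scan_table(results).to_csv(out / "scan.tsv", sep="\t", index=False)
        artifacts["scan_tsv"] = out / "scan.tsv"
        system = infer_system(results, config.scan)
    except Exception as exc:
        raise PipelineError("scan", str(exc)) from exc
    log.info("scan: %d sites scored, system=%s", len(results), system)
    if system == "undetermined":
        raise PipelineError("region", "heterogametic system is undetermined")

    # --- region
    try:
        region, outliers = call_sd_region(results, config.scan, system)
    except Exception as exc:
        raise PipelineError("region", str(exc)) from exc
    artifacts["region_bed"] = Path(
        write_region_bed(region, str(out / "region.bed"))
    )
    log.info("region: %s:%d-%d (%d supporting SNPs, %d outliers)",
             region.chrom, region.start, region.end, region.n_support, len(outliers))

    # --- markers
    try:
        candidates, markers = _marker_stage(config, passed, region, system, phen)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("markers", str(exc)) from exc
    if markers:
        (out / "markers.json").write_text(
            json.dumps(markers, indent=2, sort_keys=True) + "\n"
        )
        artifacts["markers_json"] = out / "markers.json"
    log.info("markers: %d candidate indels, %d assays", len(candidates), len(markers))

    summary = {
        "counts": {
            "input_sites": len(sites),
            "filter_pass": len(passed),
            "filter_fail": len(failed),
            "association_tests": n_tests,
            "scan_sites": len(results),
            "candidate_indels": len(candidates),
        },
        "association": {
            "bonferroni_alpha": threshold_line,
            "top_chrom": str(top["chrom"]),
            "top_pos": int(top["pos"]),
            "top_p": float(top["p"]),
        },
        "system": system,
        "region": {
            "chrom": region.chrom,
            "start": region.start,
            "end": region.end,
            "span": region.span,
            "n_support": region.n_support,
            "n_outliers": len(outliers),
        },
        "markers": [
            {k: m[k] for k in
             ("name", "chrom", "pos", "x_product", "y_product", "indel_len",
              "concordance", "accuracy")}
            for m in markers
        ],
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    artifacts["summary_json"] = out / "summary.json"

    manifest = {
        "version": sdscan.__version__,
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in (
                ("vcf", config.vcf),
                ("phenotypes", config.phenotypes),
                ("reference", config.reference),
                ("primers", config.primers),
            )
            if p
        },
        "parameters": {
            "thresholds": config.thresholds.__dict__,
            "scan": config.scan.__dict__,
            "marker_min_len": config.marker_min_len,
            "alpha": config.alpha,
            "max_product": config.max_product,
        },
        "outputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in artifacts.items()
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return summary


# --------------------------------------------------------------------------
# simulation entry point


def _config_from_yaml(path: str, seed: int | None) -> SimulationConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if seed is not None:
        doc["seed"] = seed
    if "seed" not in doc:
        raise ValueError("simulation config needs a seed")
    if "chromosomes" in doc:
        doc["chromosomes"] = tuple(
            (str(name), int(length)) for name, length in doc["chromosomes"]
        )
    if "markers" in doc:
        doc["markers"] = tuple(MarkerDef(**m) for m in doc["markers"])
    if "annotation_model" in doc:
        doc["annotation_model"] = {
            key: FieldModel(
                fail_prob=spec["fail_prob"],
                pass_range=tuple(spec["pass_range"]),
                fail_range=tuple(spec["fail_range"]),
            )
            for key, spec in doc["annotation_model"].items()
        }
    for key in ("sd_region", "maf_range"):
        if key in doc:
            doc[key] = tuple(doc[key])
    return SimulationConfig(**doc)


def simulate_command(
    out_dir: str, seed: int | None = None, config_path: str | None = None
) -> dict[str, str]:
    """Generate and write a synthetic dataset; returns the file paths."""
    if config_path:
        config = _config_from_yaml(config_path, seed)
    else:
        if seed is None:
            raise ValueError("a seed is required")
        config = SimulationConfig(seed=seed)
    config.validate()
    ref, dataset = simulate(config)
    paths = write_dataset(dataset, ref, out_dir)
    log.info("simulated %d sites x %d samples under %s into %s",
             len(dataset.sites), len(dataset.samples), config.system, out_dir)
    return paths
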