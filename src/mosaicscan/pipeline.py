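"""End-to-end orchestration: simulate -> call -> filter -> quantify -> summarize.

A :class:`RunConfig` names every tunable threshold of the pipeline with its
default operating value; :func:`run_pipeline` executes the stages over
synthetic inputs (or user-provided SAM/FASTA) and writes a VCF of SNV/indel
calls, a deletion VCF, an amplicon quantification TSV, a cohort summary TSV
and a JSON manifest recording parameters, seed and output hashes.
Re-running with the same config reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .amplicon import compare_to_panel, make_query_kmers, quantify
from .caller import TierConfig, call_sample
from .cohort import group_medians, load_table1, summarize_cohort
from .deletions import cluster_flagged, deletion_af, flag_discordant_pairs
from .io import Reference, write_alignments, write_variant_calls
from .simulate import (
    SimulationProfile,
    VariantSpec,
    child_seed,
    random_reference,
    simulate_amplicon_pool,
    simulate_control_panel,
    simulate_deletion_library,
    simulate_reads,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one pipeline run; every threshold is a named key."""

    seed: int = 0
    out_dir: str = "mosaicscan_run"
    # mosaic calling
    tier: str = "sensitive"
    review_af: float = 0.01
    snv_af: float = 0.005
    snv_min_reads: int = 3
    indel_af: float = 0.002
    indel_min_reads: int = 2
    redundancy_cap: int = 50
    min_base_quality: int = 20
    min_mapping_quality: int = 20
    # deletion calling
    min_insert: int = 1200
    large_insert: int = 2000
    cluster_window: int = 500
    min_large_pairs: int = 3
    min_intermediate_pairs: int = 5
    # amplicon
    kmer_size: int = 20
    panel_alpha: float = 0.01
    # splice / expression
    distortion_threshold: float = 0.43
    # demo-simulation knobs
    demo_depth: float = 2000.0
    demo_read_length: int = 75
    demo_per_base_error: float = 0.001
    demo_variant_af: float = 0.03
    demo_deletion_af: float = 0.03
    demo_amplicon_reads: int = 50000
    include_panel: bool = True

    def tier_config(self) -> TierConfig:
        return TierConfig(
            review_af=self.review_af,
            snv_af=self.snv_af,
            snv_min_reads=self.snv_min_reads,
            indel_af=self.indel_af,
            indel_min_reads=self.indel_min_reads,
            redundancy_cap=self.redundancy_cap,
            min_base_quality=self.min_base_quality,
            min_mapping_quality=self.min_mapping_quality,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the demo pipeline end to end; returns the run manifest.

    Stages: (1) simulate a mosaic SNV read set and call it; (2) simulate a
    deletion library, cluster discordant pairs and estimate deletion AF;
    (3) simulate an amplicon pool plus control panel and quantify the
    variant; (4) tabulate the packaged study cohort.  A stage failure is
    reported with completed-stage artifacts retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, status: str, **info) -> None:
        manifest["stages"][stage] = {"status": status, **info}

    # stage 1: mosaic SNV calling on simulated reads
    try:
        ref = random_reference(400, child_seed(config.seed, "reference"))
        profile = SimulationProfile(
            depth=config.demo_depth,
            read_length=config.demo_read_length,
            per_base_error=config.demo_per_base_error,
            seed=child_seed(config.seed, "reads"),
        )
        pos = 200
        variant = VariantSpec(
            contig=ref.name,
            position=pos,
            ref_allele=ref.base(pos),
            alt_allele={"A": "G", "C": "T", "G": "A", "T": "C"}[ref.base(pos)],
            type="SNV",
            target_af=config.demo_variant_af,
        )
        reads = simulate_reads(ref, [variant], profile)
        sam_path = out / "reads.sam"
        write_alignments(reads, sam_path, {ref.name: len(ref)})
        calls = call_sample(
            reads, ref, config.tier_config(), tier=config.tier, sample_id="demo"
        )
        vcf_path = out / "calls.vcf"
        write_variant_calls(calls, vcf_path, {ref.name: len(ref)})
        record("call", "ok", n_reads=len(reads), n_calls=len(calls))
        manifest["outputs"]["calls_vcf"] = str(vcf_path)
    except Exception as exc:  # pragma: no cover - defensive
        record("call", "error", message=str(exc))
        raise

    # stage 2: deletion detection
    try:
        del_ref = random_reference(16000, child_seed(config.seed, "del_reference"))
        del_start, del_end = 1000, 14281  # 13,282 nt
        pairs = simulate_deletion_library(
            del_ref,
            del_start,
            del_end,
            n_pairs=1500,
            carrier_fraction=config.demo_deletion_af,
            profile=SimulationProfile(seed=child_seed(config.seed, "pairs")),
        )
        lefts = [p[0] for p in pairs]
        flagged = flag_discordant_pairs(lefts, min_insert=config.min_insert)
        del_calls = cluster_flagged(
            flagged,
            window=config.cluster_window,
            min_large=config.min_large_pairs,
            min_intermediate=config.min_intermediate_pairs,
            contig=del_ref.name,
        )
        for call in del_calls:
            deletion_af(lefts, call, min_insert=config.min_insert)
        del_vcf = out / "deletions.vcf"
        write_variant_calls(del_calls, del_vcf, {del_ref.name: len(del_ref)})
        record("sv", "ok", n_flagged=len(flagged), n_calls=len(del_calls))
        manifest["outputs"]["deletions_vcf"] = str(del_vcf)
    except Exception as exc:  # pragma: no cover
        record("sv", "error", message=str(exc))
        raise

    # stage 3: amplicon quantification
    try:
        amp_ref = random_reference(120, child_seed(config.seed, "amplicon_ref"), name="amplicon")
        apos = 60
        avar = VariantSpec(
            contig=amp_ref.name,
            position=apos,
            ref_allele=amp_ref.base(apos),
            alt_allele={"A": "G", "C": "T", "G": "A", "T": "C"}[amp_ref.base(apos)],
            type="SNV",
            target_af=config.demo_variant_af,
        )
        queries = make_query_kmers(amp_ref.sequence, avar, k=config.kmer_size)
        mut_seq = (
            amp_ref.sequence[: apos - 1] + avar.alt_allele + amp_ref.sequence[apos:]
        )
        pool = simulate_amplicon_pool(
            amp_ref.sequence,
            mut_seq,
            af=config.demo_variant_af,
            n_reads=config.demo_amplicon_reads,
            per_base_error=config.demo_per_base_error,
            seed=child_seed(config.seed, "amplicon"),
        )
        result = quantify(pool, queries)
        if config.include_panel:
            panel = simulate_control_panel(
                amp_ref.sequence,
                queries.mut_kmer,
                queries.wt_kmer,
                seed=child_seed(config.seed, "panel"),
            )
            compare_to_panel(result, panel, alpha=config.panel_alpha)
        else:
            logger.warning("no control panel configured; above_noise left unset")
        amp_tsv = out / "amplicon.tsv"
        with open(amp_tsv, "w") as fh:
            fh.write("mut_kmer\twt_kmer\tmut_count\twt_count\taf\tpanel_mean\tpanel_max\tabove_noise\tbinomial_p\n")
            fh.write(
                f"{queries.mut_kmer}\t{queries.wt_kmer}\t{result.mutant_count}\t"
                f"{result.wt_count}\t{result.af:.6f}\t"
                f"{'' if result.panel_mean is None else f'{result.panel_mean:.6f}'}\t"
                f"{'' if result.panel_max is None else f'{result.panel_max:.6f}'}\t"
                f"{'' if result.above_noise is None else result.above_noise}\t"
                f"{'' if result.binomial_p is None else f'{result.binomial_p:.3e}'}\n"
            )
        record("amplicon", "ok", af=result.af, above_noise=result.above_noise)
        manifest["outputs"]["amplicon_tsv"] = str(amp_tsv)
    except Exception as exc:  # pragma: no cover
        record("amplicon", "error", message=str(exc))
        raise

    # stage 4: cohort tabulation (packaged study table)
    try:
        subjects = load_table1()
        summary = summarize_cohort(subjects)
        medians = group_medians(subjects)
        cohort_tsv = out / "cohort_summary.tsv"
        with open(cohort_tsv, "w") as fh:
            fh.write("metric\tvalue\n")
            for key, value in dataclasses.asdict(summary).items():
                fh.write(f"{key}\t{value}\n")
            for status, med in sorted(medians.items()):
                fh.write(f"median_major_features_{status}\t{med}\n")
        record("cohort", "ok", n_subjects=summary.n_subjects)
        manifest["outputs"]["cohort_tsv"] = str(cohort_tsv)
    except Exception as exc:  # pragma: no cover
        record("cohort", "error", message=str(exc))
        raise

    manifest["output_sha256"] = {
        name: _sha256(Path(path)) for name, path in manifest["outputs"].items()
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
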