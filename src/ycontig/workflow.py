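"""End-to-end simulated benchmark: simulate, featurize, classify, evaluate.

Runs the whole pipeline through its file-based interfaces on a synthetic
~5 Mb male genome: error-free 30x-haploid male reads, the exact female
reference for the k-mer set, dual-threshold (female+male) classification,
and length-weighted evaluation against the simulator's truth manifest. A
second classification pass with the depth ceiling raised above the
ampliconic copy depth quantifies the multi-copy trade-off.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd

from .classify import Thresholds, classify_female_male
from .evaluate import (EvaluationReport, precision_recall, recall_by_region,
                       truth_from_manifest)
from .features import compute_features, filter_contigs
from .kmers import KmerParams, build_female_kmer_set, count_male_kmers
from .simulate import (GenomeSpec, ReadSimParams, default_copy_numbers,
                       fragment_contigs, simulate_genomes, simulate_reads)

__all__ = ["BenchmarkResult", "run_simulated_benchmark"]


@dataclass
class BenchmarkResult:
    report: EvaluationReport          # female+male at (p_thresh, c_thresh)
    region_recall: pd.DataFrame       # per-region recall at (p, c)
    region_recall_high_c: pd.DataFrame  # per-region recall at the raised ceiling
    features: pd.DataFrame
    truth: pd.DataFrame
    spec: GenomeSpec
    n_reads: int
    p_thresh: float
    c_thresh: float
    c_thresh_high: float

    def region_recall_value(self, regions, high_c: bool = False) -> float:
        """Combined length-weighted recall over the given region classes."""
        table = self.region_recall_high_c if high_c else self.region_recall
        sub = table[table["region"].isin(list(regions))]
        if sub.empty or sub["total_bp"].sum() == 0:
            return float("nan")
        return float(sub["recovered_bp"].sum() / sub["total_bp"].sum())


def run_simulated_benchmark(workdir: str | os.PathLike,
                            seed: int = 1,
                            spec: GenomeSpec | None = None,
                            k: int = 25,
                            min_abundance: int = 3,
                            haploid_depth: float = 30.0,
                            read_length: int = 150,
                            error_rate: float = 0.0,
                            target_contig_bp: int = 10_000,
                            min_contig_length: int = 1_000,
                            p_thresh: float = 0.6,
                            c_thresh: float = 45.0,
                            backend: str = "bloom",
                            female_from_reads_depth: float | None = None,
                            ) -> BenchmarkResult:
    """Run the simulated benchmark and return all reports.

    ``seed`` drives every stochastic stage through derived sub-seeds. With
    ``female_from_reads_depth`` set, the female k-mer store is built from
    simulated female reads at that haploid depth (abundance-filtered)
    instead of from the reference FASTA.
    """
    workdir = os.fspath(workdir)
    os.makedirs(workdir, exist_ok=True)
    seed = int(seed) % (2 ** 31)
    if spec is None:
        spec = GenomeSpec(seed=seed)
    params = KmerParams(k=k, min_abundance=min_abundance)

    genomes = simulate_genomes(spec, k=k)
    paths = genomes.write(workdir)

    contigs, manifest = fragment_contigs(
        genomes.male, genomes.region_map,
        target_contig_bp=target_contig_bp, seed=seed + 1, min_k=k)
    contigs = filter_contigs(contigs, min_contig_length)
    kept = {c.id for c in contigs}
    manifest = manifest[manifest["contig_id"].isin(kept)].reset_index(drop=True)
    manifest.to_csv(os.path.join(workdir, "truth_manifest.tsv"),
                    sep="\t", index=False)

    male_fastq = os.path.join(workdir, "male_reads.fastq")
    n_reads = simulate_reads(
        genomes.male, default_copy_numbers(genomes.male, "male"),
        ReadSimParams(read_length=read_length, haploid_depth=haploid_depth,
                      substitution_error_rate=error_rate, seed=seed + 2),
        male_fastq)

    if female_from_reads_depth is not None:
        female_fastq = os.path.join(workdir, "female_reads.fastq")
        simulate_reads(
            genomes.female, default_copy_numbers(genomes.female, "female"),
            ReadSimParams(read_length=read_length,
                          haploid_depth=female_from_reads_depth,
                          substitution_error_rate=error_rate, seed=seed + 3),
            female_fastq)
        female = build_female_kmer_set([female_fastq], params,
                                       input_kind="reads", backend=backend)
    else:
        female = build_female_kmer_set([paths["female_fasta"]], params,
                                       input_kind="reference", backend=backend)

    male_counts = count_male_kmers([male_fastq], params)
    features = compute_features(contigs, female, male_counts, params)

    truth = truth_from_manifest(manifest)
    lengths = manifest[["contig_id", "length"]]

    result = classify_female_male(features, Thresholds(p_thresh, c_thresh))
    report = precision_recall(result, truth, lengths)
    regions = recall_by_region(result, truth, lengths)

    c_high = 1.5 * spec.y_amp_copies * haploid_depth
    result_high = classify_female_male(features, Thresholds(p_thresh, c_high))
    regions_high = recall_by_region(result_high, truth, lengths)

    return BenchmarkResult(report=report, region_recall=regions,
                           region_recall_high_c=regions_high,
                           features=features, truth=truth, spec=spec,
                           n_reads=n_reads, p_thresh=p_thresh,
                           c_thresh=c_thresh, c_thresh_high=c_high)
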