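"""Synthetic genome/read generator and the end-to-end recovery geometry."""

import numpy as np
import pytest

from ycontig.classify import Thresholds, classify_female_male
from ycontig.evaluate import precision_recall, recall_by_region, \
    truth_from_manifest
from ycontig.features import compute_features
from ycontig.kmers import (ExactKmerSet, KmerParams, count_male_kmers,
                           encode_sequence, kmer_codes)
from ycontig.simulate import (GenomeSpec, ReadSimParams, default_copy_numbers,
                              fragment_contigs, simulate_genomes,
                              simulate_reads)
from ycontig.workflow import run_simulated_benchmark

K = 25

SMALL_SPEC = GenomeSpec(autosome_total_bp=240_000, x_bp=120_000,
                        y_xdeg_bp=60_000, y_amp_unit_bp=8_000,
                        y_amp_copies=3, y_xtr_bp=12_000, par_bp=6_000,
                        seed=7)


def test_male_genome_length_conservation():
    genomes = simulate_genomes(SMALL_SPEC, k=K)
    male_len = sum(len(s) for s in genomes.male.values())
    assert male_len == SMALL_SPEC.male_bp
    female_len = sum(len(s) for s in genomes.female.values())
    assert female_len == SMALL_SPEC.autosome_total_bp + SMALL_SPEC.x_bp
    # region map tiles the whole Y
    y_covered = sum(e - s for _c, s, e, _r in genomes.region_map)
    assert y_covered == len(genomes.male["chrY"]) == SMALL_SPEC.y_bp


def test_zero_xtr_region_is_absent():
    spec = GenomeSpec(autosome_total_bp=60_000, x_bp=40_000,
                      y_xdeg_bp=20_000, y_amp_unit_bp=5_000, y_amp_copies=2,
                      y_xtr_bp=0, par_bp=5_000, seed=1)
    genomes = simulate_genomes(spec, k=K)
    regions = {r for _c, _s, _e, r in genomes.region_map}
    assert "Y_Xtransposed" not in regions
    assert genomes.xtr_empirical_share is None


def test_par_is_identical_to_x_and_amp_is_tiled():
    genomes = simulate_genomes(SMALL_SPEC, k=K)
    y = genomes.male["chrY"]
    x = genomes.male["chrX"]
    par = dict((r, (s, e)) for _c, s, e, r in genomes.region_map)
    s, e = par["Y_PAR"]
    assert y[s:e] == x[-SMALL_SPEC.par_bp:]
    s, e = par["Y_ampliconic"]
    amp = y[s:e]
    unit = amp[:SMALL_SPEC.y_amp_unit_bp]
    assert amp == unit * SMALL_SPEC.y_amp_copies


def test_xtr_kmer_share_lies_in_configured_range():
    genomes = simulate_genomes(SMALL_SPEC, k=K)
    x_set = ExactKmerSet(K)
    x_set.add(kmer_codes(encode_sequence(genomes.female["chrX"]), K, True))
    (s, e) = next((s, e) for _c, s, e, r in genomes.region_map
                  if r == "Y_Xtransposed")
    xtr_kmers = kmer_codes(encode_sequence(genomes.male["chrY"][s:e]), K, True)
    share = float(x_set.contains(xtr_kmers).mean())
    assert 0.55 <= share <= 0.95
    assert genomes.xtr_empirical_share == pytest.approx(share, abs=1e-9)


def test_spec_validation():
    with pytest.raises(ValueError, match="y_amp_copies"):
        GenomeSpec(y_amp_copies=1)
    with pytest.raises(ValueError, match="x_bp"):
        GenomeSpec(x_bp=50_000, y_xtr_bp=40_000, par_bp=20_000)
    with pytest.raises(ValueError, match="shorter than k"):
        simulate_genomes(GenomeSpec(autosome_total_bp=10_000, x_bp=10_000,
                                    y_xdeg_bp=10, y_amp_unit_bp=0,
                                    y_xtr_bp=0, par_bp=0), k=K)


# ---------------------------------------------------------------------------
# fragmentation


def test_fragment_zero_jitter_tiles_exactly():
    male = {"chr1": "A" * 100_000}
    contigs, manifest = fragment_contigs(male, [], target_contig_bp=10_000,
                                         jitter_fraction=0.0, seed=0)
    assert len(contigs) == 10
    assert all(c.length == 10_000 for c in contigs)
    assert manifest["region"].unique().tolist() == ["autosome"]


def test_fragment_conserves_chromosome_lengths():
    genomes = simulate_genomes(SMALL_SPEC, k=K)
    contigs, manifest = fragment_contigs(genomes.male, genomes.region_map,
                                         target_contig_bp=7_000, seed=3)
    per_chrom = manifest.groupby("chromosome")["length"].sum().to_dict()
    assert per_chrom == {c: len(s) for c, s in genomes.male.items()}
    # contigs never span chromosome boundaries and appear exactly once
    assert manifest["contig_id"].is_unique
    assert sum(c.length for c in contigs) == SMALL_SPEC.male_bp


def test_boundary_contig_gets_majority_class():
    region_map = [("chrY", 0, 6_000, "Y_Xdegenerate"),
                  ("chrY", 6_000, 20_000, "Y_ampliconic")]
    male = {"chrY": "A" * 20_000}
    # with 10 kb tiles the first contig is 6 kb X-degenerate + 4 kb ampliconic
    _contigs, manifest = fragment_contigs(male, region_map,
                                          target_contig_bp=10_000,
                                          jitter_fraction=0.0, seed=0)
    assert manifest["region"].tolist() == ["Y_Xdegenerate", "Y_ampliconic"]


# ---------------------------------------------------------------------------
# reads


def test_reads_are_deterministic_given_seed(tmp_path):
    genome = {"chr1": "ACGT" * 5_000}
    params = ReadSimParams(read_length=100, haploid_depth=5, seed=11)
    a, b = tmp_path / "a.fastq", tmp_path / "b.fastq"
    simulate_reads(genome, {"chr1": 2.0}, params, a)
    simulate_reads(genome, {"chr1": 2.0}, params, b)
    assert a.read_bytes() == b.read_bytes()
    assert a.stat().st_size > 0


def test_autosome_mean_depth_concentrates_at_copy_times_haploid(tmp_path, rng):
    n = 500_000
    genome = {"chrA": "".join(rng.choice(list("ACGT"), size=n))}
    params = ReadSimParams(read_length=150, haploid_depth=30, seed=5)
    out = tmp_path / "reads.fastq"
    n_reads = simulate_reads(genome, {"chrA": 2.0}, params, out)
    mean_depth = n_reads * 150 / n
    assert 57 <= mean_depth <= 63


def test_substitution_error_rate_is_realized(tmp_path, rng):
    # a read k-mer matches the genome iff all its bases escape mutation, so
    # the mean genomic k-mer share across reads estimates (1 - e)^k
    genome_seq = "".join(rng.choice(list("ACGT"), size=50_000))
    e, k = 0.01, 15
    params = ReadSimParams(read_length=100, haploid_depth=20,
                           substitution_error_rate=e, seed=2)
    out = tmp_path / "err.fastq"
    simulate_reads({"chr1": genome_seq}, {"chr1": 1.0}, params, out)
    genome_set = ExactKmerSet(k)
    genome_set.add(kmer_codes(encode_sequence(genome_seq), k, True))
    from ycontig.io import iter_sequences
    shares = [float(genome_set.contains(
        kmer_codes(encode_sequence(read), k, True)).mean())
        for _name, read in iter_sequences(out)]
    e_hat = 1.0 - float(np.mean(shares)) ** (1.0 / k)
    assert 0.007 <= e_hat <= 0.013


def test_read_longer_than_chromosome_warns_and_skips(tmp_path):
    genome = {"tiny": "ACGTACGT"}
    params = ReadSimParams(read_length=100, haploid_depth=5, seed=0)
    out = tmp_path / "none.fastq"
    with pytest.warns(UserWarning, match="skipped"):
        n = simulate_reads(genome, {"tiny": 1.0}, params, out)
    assert n == 0


# ---------------------------------------------------------------------------
# end-to-end geometry on the simulated data


@pytest.fixture(scope="module")
def small_benchmark(tmp_path_factory):
    work = tmp_path_factory.mktemp("bench")
    return run_simulated_benchmark(work, seed=7, spec=SMALL_SPEC,
                                   target_contig_bp=5_000,
                                   min_contig_length=1_000)


def test_end_to_end_recovery_geometry(small_benchmark):
    r = small_benchmark
    by_region = dict(zip(r.region_recall["region"], r.region_recall["recall"]))
    # single-copy male-specific sequence is recovered...
    assert by_region["Y_Xdegenerate"] >= 0.95
    # ...X-transposed contigs are predominantly missed (share >= 0.6 with X)
    assert by_region.get("Y_Xtransposed", 0.0) <= 0.15
    # ...PAR contigs look female and are missed
    assert by_region.get("Y_PAR", 0.0) <= 0.15
    # no autosome or X contig sneaks in: precision stays near 1
    assert r.report.precision >= 0.99


def test_ampliconic_depth_and_dual_threshold_tradeoff(small_benchmark):
    r = small_benchmark
    amp_ids = set(r.truth.loc[r.truth["region"] == "Y_ampliconic",
                              "contig_id"])
    feats = r.features[r.features["contig_id"].isin(amp_ids)]
    # read k-mer depth: haploid_depth scaled by the fraction of read
    # positions that cover a whole k-mer window
    kmer_depth = 30.0 * (150 - 25 + 1) / 150
    expected = SMALL_SPEC.y_amp_copies * kmer_depth
    assert np.median(feats["male_depth"]) == pytest.approx(expected, rel=0.2)
    # lost when the depth ceiling is below the ampliconic depth...
    low = dict(zip(r.region_recall["region"], r.region_recall["recall"]))
    assert low["Y_ampliconic"] <= 0.05
    # ...recovered when it is above
    high = dict(zip(r.region_recall_high_c["region"],
                    r.region_recall_high_c["recall"]))
    assert high["Y_ampliconic"] >= 0.95


def test_female_reads_pathway_close_to_reference(tmp_path_factory,
                                                 small_benchmark):
    work = tmp_path_factory.mktemp("bench_reads")
    from_reads = run_simulated_benchmark(work, seed=7, spec=SMALL_SPEC,
                                         target_contig_bp=5_000,
                                         min_contig_length=1_000,
                                         female_from_reads_depth=30.0)
    delta = abs(from_reads.report.recall - small_benchmark.report.recall)
    assert delta < 0.05
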