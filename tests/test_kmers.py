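"""k-merization, the female membership set, and male abundance counting."""

import collections

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_kmers, random_seq
from ycontig.kmers import (BloomKmerSet, ExactKmerSet, KmerParams,
                           MaleKmerCounts, build_female_kmer_set,
                           count_male_kmers, decode_kmer, encode_sequence,
                           kmer_codes, kmerize, load_kmer_set,
                           reverse_complement, save_kmer_set)


@pytest.mark.parametrize("seq,k,canonical,expected", [
    ("ACGT", 3, False, ["ACG", "CGT"]),
    ("ACNGT", 3, True, []),                    # every window contains an N
    ("TTT", 3, True, ["AAA"]),                 # revcomp("TTT") is smaller
    ("ACGT", 5, True, []),                     # shorter than k
    ("acgt", 3, False, ["ACG", "CGT"]),        # case-insensitive
    ("AANCC", 2, False, ["AA", "CC"]),         # only N-free windows survive
])
def test_kmerize_window_enumeration(seq, k, canonical, expected):
    assert kmerize(seq, k=k, canonical=canonical) == expected


@settings(max_examples=200, derandomize=True)
@given(seq=st.text(alphabet="ACGTN", max_size=60),
       k=st.integers(min_value=1, max_value=8),
       canonical=st.booleans())
def test_kmerize_matches_brute_force_enumeration(seq, k, canonical):
    assert kmerize(seq, k=k, canonical=canonical) == \
        brute_force_kmers(seq, k, canonical)


def test_kmerize_oracle_on_long_sequence(rng):
    seq = random_seq(rng, 10_000, with_n=0.01)
    assert kmerize(seq, KmerParams(k=25)) == brute_force_kmers(seq, 25)


def test_packed_codes_roundtrip(rng):
    seq = random_seq(rng, 500)
    packed = kmer_codes(encode_sequence(seq), 25, canonical=False)
    decoded = [decode_kmer(x, 25) for x in packed]
    assert decoded == [seq[i:i + 25] for i in range(len(seq) - 24)]


def test_kmer_params_validation():
    with pytest.raises(ValueError):
        KmerParams(k=0)
    with pytest.raises(ValueError):
        KmerParams(min_abundance=0)
    with pytest.raises(ValueError):
        KmerParams(k=40)  # beyond the packed representation


# ---------------------------------------------------------------------------
# counting


def test_count_male_kmers_triple_A(write_fasta_file):
    # "AAAAA" has 3 windows of k=3, all canonical "AAA"
    path = write_fasta_file([("r1", "AAAAA")])
    counts = count_male_kmers([path], KmerParams(k=3, min_abundance=3))
    assert counts.get_kmer("AAA") == 3
    assert counts.get_kmer("ACG") == 0


def test_count_male_kmers_abundance_floor(write_fasta_file):
    path = write_fasta_file([("r1", "ACGTA")])
    counts = count_male_kmers([path], KmerParams(k=3, min_abundance=3))
    assert len(counts) == 0
    assert counts.get_kmer("ACG") == 0


def test_count_exactness_against_dictionary(rng, write_fasta_file):
    reads = [(f"r{i}", random_seq(rng, rng.integers(30, 120), with_n=0.01))
             for i in range(300)]
    path = write_fasta_file(reads)
    oracle = collections.Counter()
    for _rid, seq in reads:
        oracle.update(brute_force_kmers(seq, 25))
    counts = count_male_kmers([path], KmerParams(k=25, min_abundance=1))
    assert len(counts) == len(oracle)
    for kmer, n in oracle.items():
        assert counts.get_kmer(kmer) == n


def test_counts_save_load_roundtrip(tmp_path, write_fasta_file, rng):
    path = write_fasta_file([("r1", random_seq(rng, 200))])
    counts = count_male_kmers([path], KmerParams(k=11, min_abundance=1))
    out = tmp_path / "counts.npz"
    counts.save(out)
    loaded = MaleKmerCounts.load(out)
    assert loaded.k == 11 and len(loaded) == len(counts)
    with pytest.raises(ValueError, match="k="):
        MaleKmerCounts.load(out, expected_k=25)


def test_count_errors_name_the_path(tmp_path):
    missing = tmp_path / "nope.fa"
    with pytest.raises(FileNotFoundError, match="nope.fa"):
        count_male_kmers([missing])
    empty = tmp_path / "empty.fa"
    empty.write_text("")
    with pytest.raises(ValueError, match="empty.fa"):
        count_male_kmers([empty])


# ---------------------------------------------------------------------------
# female set construction


def test_reference_shorter_than_k_yields_empty_set(write_fasta_file):
    path = write_fasta_file([("r", "ACGTACGT")])
    store = build_female_kmer_set([path], KmerParams(k=25), backend="exact")
    assert store.n_inserted == 0
    assert not store.contains_kmer("A" * 25)


def test_reads_abundance_filter_boundary_at_three(write_fasta_file, rng):
    kmer = random_seq(rng, 25)
    twice = write_fasta_file([("a", kmer), ("b", kmer)], "twice.fa")
    thrice = write_fasta_file([("a", kmer), ("b", kmer), ("c", kmer)],
                              "thrice.fa")
    params = KmerParams(k=25, min_abundance=3)
    low = build_female_kmer_set([twice], params, input_kind="reads",
                                backend="exact")
    high = build_female_kmer_set([thrice], params, input_kind="reads",
                                 backend="exact")
    assert not low.contains_kmer(kmer)
    assert high.contains_kmer(kmer)


def test_reference_kmers_not_abundance_filtered(write_fasta_file, rng):
    # a reference k-mer present once must still be inserted
    kmer = random_seq(rng, 25)
    path = write_fasta_file([("chr1", kmer)])
    store = build_female_kmer_set([path], KmerParams(k=25, min_abundance=3),
                                  input_kind="reference", backend="exact")
    assert store.contains_kmer(kmer)


def test_strand_invariance_of_reference_set(write_fasta_file, rng):
    seq = random_seq(rng, 2_000)
    fwd = write_fasta_file([("chr1", seq)], "fwd.fa")
    rev = write_fasta_file([("chr1", reverse_complement(seq))], "rev.fa")
    params = KmerParams(k=25, canonical=True)
    set_fwd = build_female_kmer_set([fwd], params, backend="exact")
    set_rev = build_female_kmer_set([rev], params, backend="exact")
    probes = kmer_codes(encode_sequence(random_seq(rng, 5_000)), 25, True)
    probes = np.concatenate([probes,
                             kmer_codes(encode_sequence(seq), 25, True)])
    assert np.array_equal(set_fwd.contains(probes), set_rev.contains(probes))


# ---------------------------------------------------------------------------
# Bloom filter contract


def _random_kmers(rng, n, k=25):
    return np.unique(rng.integers(0, 4 ** k, size=n, dtype=np.uint64))


def test_bloom_one_sidedness_and_fp_bound(rng):
    target_fp = 0.001
    inserted = _random_kmers(rng, 100_000)
    bloom = BloomKmerSet(25, capacity=150_000, target_fp_rate=target_fp)
    bloom.add(inserted)
    # zero false negatives
    assert bloom.contains(inserted).all()
    # empirical FP rate over >= 1e5 never-inserted probes
    probes = _random_kmers(rng, 120_000)
    probes = probes[~np.isin(probes, inserted)]
    assert probes.size >= 100_000
    fp_rate = bloom.contains(probes).mean()
    assert fp_rate <= 2 * target_fp


def test_bloom_capacity_exceeded_is_an_error(rng):
    bloom = BloomKmerSet(25, capacity=100, target_fp_rate=0.01)
    with pytest.raises(ValueError, match="capacity"):
        bloom.add(_random_kmers(rng, 1_000))


def test_bloom_roundtrip_is_lossless(tmp_path, rng):
    inserted = _random_kmers(rng, 10_000)
    bloom = BloomKmerSet(25, capacity=20_000, target_fp_rate=0.001)
    bloom.add(inserted)
    path = tmp_path / "female.bloom"
    save_kmer_set(bloom, path)
    loaded = load_kmer_set(path)
    probes = np.concatenate([inserted, _random_kmers(rng, 10_000)])
    assert np.array_equal(bloom.contains(probes), loaded.contains(probes))
    assert (loaded.k, loaded.n_inserted, loaded.n_hashes, loaded.n_bits) == \
        (bloom.k, bloom.n_inserted, bloom.n_hashes, bloom.n_bits)


def test_exact_set_roundtrip(tmp_path, rng):
    inserted = _random_kmers(rng, 5_000)
    store = ExactKmerSet(25)
    store.add(inserted)
    path = tmp_path / "female.exact"
    save_kmer_set(store, path)
    loaded = load_kmer_set(path, expected_k=25)
    probes = np.concatenate([inserted, _random_kmers(rng, 5_000)])
    assert np.array_equal(store.contains(probes), loaded.contains(probes))


def test_load_rejects_k_mismatch_truncation_and_bad_magic(tmp_path, rng):
    bloom = BloomKmerSet(21, capacity=1_000, target_fp_rate=0.01)
    bloom.add(_random_kmers(rng, 500, k=21))
    path = tmp_path / "set.bloom"
    save_kmer_set(bloom, path)
    with pytest.raises(ValueError, match="k=21"):
        load_kmer_set(path, expected_k=25)
    data = path.read_bytes()
    trunc = tmp_path / "trunc.bloom"
    trunc.write_bytes(data[:len(data) // 2])
    with pytest.raises(ValueError, match="truncated|corrupt"):
        load_kmer_set(trunc)
    bad = tmp_path / "bad.bloom"
    bad.write_bytes(b"NOTASET!" + data[8:])
    with pytest.raises(ValueError, match="magic"):
        load_kmer_set(bad)
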