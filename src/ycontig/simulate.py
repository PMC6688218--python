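"""Synthetic genomes, contigs and shotgun reads with a truth manifest.

The generator emulates the data a Y-contig classifier sees in practice:

* a female genome of autosomes plus an X chromosome (the diploid female is
  represented by a single X copy in the reference, with copy number 2 used
  for read simulation, the way references collapse homologs);
* a male genome adding a haploid Y composed of the sequence classes of a
  mammalian Y: an X-degenerate block of novel single-copy sequence, an
  ampliconic block made of one novel unit repeated several times, an
  X-transposed block copied from the X and mutated so that its k-mer sharing
  with the female lies in a configurable range (default 60-90%), and a PAR
  identical to the end of the X;
* non-overlapping fragmentation of the male genome into contig-sized pieces
  with a manifest recording each contig's chromosome and majority region
  class ("assembly" is emulated by fragmentation, not by assembling reads);
* uniform shotgun reads with per-chromosome copy numbers, substitution-only
  errors and a constant quality string.

Everything is deterministic given the seeds carried in the parameter
objects.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import Contig
from .io import open_text, read_fasta, write_fasta
from .kmers import ExactKmerSet, encode_sequence, kmer_codes

__all__ = [
    "GenomeSpec",
    "ReadSimParams",
    "SimulatedGenomes",
    "simulate_genomes",
    "fragment_contigs",
    "simulate_reads",
    "default_copy_numbers",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GenomeSpec:
    """Layout of the synthetic genomes (defaults give a ~5 Mb male genome).

    The Y is dominated by single-copy X-degenerate sequence, with a smaller
    multi-copy ampliconic component, an X-transposed block under 10% of the
    Y, and a short PAR — a desk-scale caricature of a euchromatic mammalian
    Y. ``gc_fraction`` 0.41 matches a typical mammalian genome-wide GC.
    """
    autosome_total_bp: int = 3_000_000
    n_autosomes: int = 2
    x_bp: int = 1_000_000
    y_xdeg_bp: int = 650_000
    y_amp_unit_bp: int = 40_000
    y_amp_copies: int = 3
    y_xtr_bp: int = 50_000
    xtr_share_range: tuple[float, float] = (0.60, 0.90)
    par_bp: int = 30_000
    gc_fraction: float = 0.41
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("autosome_total_bp", "x_bp", "y_xdeg_bp",
                     "y_amp_unit_bp", "y_xtr_bp", "par_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_autosomes < 1:
            raise ValueError("n_autosomes must be >= 1")
        if self.y_amp_copies < 2:
            raise ValueError("y_amp_copies must be >= 2 (ampliconic sequence "
                             "is multi-copy by definition)")
        lo, hi = self.xtr_share_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"xtr_share_range must be an interval within "
                             f"[0, 1], got {self.xtr_share_range}")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.x_bp < self.y_xtr_bp + self.par_bp:
            raise ValueError("x_bp must cover the X-transposed source segment "
                             "plus the PAR")

    @property
    def y_bp(self) -> int:
        return (self.y_xdeg_bp + self.y_amp_unit_bp * self.y_amp_copies
                + self.y_xtr_bp + self.par_bp)

    @property
    def male_bp(self) -> int:
        return self.autosome_total_bp + self.x_bp + self.y_bp


@dataclass(frozen=True)
class ReadSimParams:
    """Shotgun read simulation parameters.

    ``haploid_depth`` is the expected per-base depth contributed by a single
    chromosome copy; autosomes therefore receive twice it and the sex
    chromosomes of a male once.
    """
    read_length: int = 150
    haploid_depth: float = 30.0
    substitution_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.haploid_depth < 0:
            raise ValueError("haploid_depth must be >= 0")
        if not 0.0 <= self.substitution_error_rate <= 0.1:
            raise ValueError("substitution_error_rate must be in [0, 0.1]")


@dataclass
class SimulatedGenomes:
    """Female/male chromosome sequences plus the Y region map."""
    female: dict[str, str]
    male: dict[str, str]
    # (chrom, start, end, region_class), 0-based half-open, Y regions only
    region_map: list[tuple[str, int, int, str]]
    spec: GenomeSpec
    xtr_empirical_share: float | None = None

    def write(self, out_dir: str | os.PathLike) -> dict[str, str]:
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "female_fasta": os.path.join(out_dir, "female.fa"),
            "male_fasta": os.path.join(out_dir, "male.fa"),
            "region_map": os.path.join(out_dir, "y_regions.bed"),
            "spec_json": os.path.join(out_dir, "genome_spec.json"),
        }
        write_fasta(self.female.items(), paths["female_fasta"])
        write_fasta(self.male.items(), paths["male_fasta"])
        with open(paths["region_map"], "w") as fh:
            for chrom, start, end, region in self.region_map:
                fh.write(f"{chrom}\t{start}\t{end}\t{region}\n")
        with open(paths["spec_json"], "w") as fh:
            json.dump({**asdict(self.spec),
                       "xtr_empirical_share": self.xtr_empirical_share},
                      fh, indent=2)
        return paths


def _random_sequence(rng: np.random.Generator, n: int,
                     gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, codes: np.ndarray,
            rate: float) -> np.ndarray:
    out = codes.copy()
    hit = np.nonzero(rng.random(codes.shape[0]) < rate)[0]
    if hit.size:
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size,
                                            dtype=np.uint8)) % 4
    return out


def _kmer_share(query: np.ndarray, reference: np.ndarray, k: int) -> float:
    """Fraction of query k-mers present in the reference k-mer set."""
    ref_set = ExactKmerSet(k)
    ref_set.add(kmer_codes(reference.view(np.uint8), k, True))
    q = kmer_codes(query.view(np.uint8), k, True)
    if q.size == 0:
        return float("nan")
    return float(ref_set.contains(q).mean())


def simulate_genomes(spec: GenomeSpec, k: int = 25,
                     max_calibration_tries: int = 10) -> SimulatedGenomes:
    """Generate the female and male genomes and the Y region map.

    The X-transposed block is a copy of an X segment mutated at a per-base
    substitution rate r solving (1 - r)^k = s for the midpoint s of
    ``xtr_share_range`` (a k-mer survives only if all k bases escape
    mutation); the realized k-mer share against the female X is measured and
    the mutation stream re-drawn if it misses the range by more than 0.05.
    """
    for name in ("y_xdeg_bp", "y_amp_unit_bp", "y_xtr_bp", "par_bp"):
        value = getattr(spec, name)
        if 0 < value < k:
            raise ValueError(f"{name}={value} is shorter than k={k}; use 0 "
                             f"to disable the region or a length >= k")
    rng = np.random.default_rng(spec.seed)

    female: dict[str, str] = {}
    male: dict[str, str] = {}
    per_autosome = spec.autosome_total_bp // spec.n_autosomes
    remainder = spec.autosome_total_bp - per_autosome * (spec.n_autosomes - 1)
    for i in range(spec.n_autosomes):
        n = remainder if i == spec.n_autosomes - 1 else per_autosome
        seq = _to_str(_random_sequence(rng, n, spec.gc_fraction))
        female[f"chrA{i + 1}"] = seq
        male[f"chrA{i + 1}"] = seq

    # X layout: [ random core | XTR source | PAR ] (PAR telomeric)
    x_codes = _random_sequence(rng, spec.x_bp, spec.gc_fraction)
    xtr_src_start = spec.x_bp - spec.par_bp - spec.y_xtr_bp
    xtr_source = x_codes[xtr_src_start:xtr_src_start + spec.y_xtr_bp]
    par_codes = x_codes[spec.x_bp - spec.par_bp:]
    x_seq = _to_str(x_codes)
    female["chrX"] = x_seq
    male["chrX"] = x_seq

    # XTR mutation-rate calibration
    xtr_codes = np.empty(0, dtype=np.uint8)
    empirical_share: float | None = None
    if spec.y_xtr_bp:
        lo, hi = spec.xtr_share_range
        target = (lo + hi) / 2
        rate = 1.0 - target ** (1.0 / k)
        for _attempt in range(max_calibration_tries):
            candidate = _mutate(rng, xtr_source, rate)
            share = _kmer_share(candidate, x_codes, k)
            if lo - 0.05 <= share <= hi + 0.05:
                xtr_codes = candidate
                empirical_share = share
                break
        else:
            raise RuntimeError(
                f"X-transposed k-mer share calibration failed after "
                f"{max_calibration_tries} tries (target range "
                f"{spec.xtr_share_range}, last measured {share:.3f})")

    parts = []
    region_map: list[tuple[str, int, int, str]] = []
    pos = 0

    def add(codes: np.ndarray, region: str) -> None:
        nonlocal pos
        if codes.shape[0] == 0:
            return
        parts.append(codes)
        region_map.append(("chrY", pos, pos + codes.shape[0], region))
        pos += codes.shape[0]

    add(_random_sequence(rng, spec.y_xdeg_bp, spec.gc_fraction),
        "Y_Xdegenerate")
    if spec.y_amp_unit_bp:
        unit = _random_sequence(rng, spec.y_amp_unit_bp, spec.gc_fraction)
        add(np.tile(unit, spec.y_amp_copies), "Y_ampliconic")
    add(xtr_codes, "Y_Xtransposed")
    add(par_codes.copy(), "Y_PAR")
    if parts:
        male["chrY"] = _to_str(np.concatenate(parts))

    return SimulatedGenomes(female=female, male=male, region_map=region_map,
                            spec=spec, xtr_empirical_share=empirical_share)


def fragment_contigs(male: Mapping[str, str] | str | os.PathLike,
                     region_map: Sequence[tuple[str, int, int, str]],
                     target_contig_bp: int = 10_000,
                     jitter_fraction: float = 0.1,
                     seed: int = 0,
                     min_k: int = 25,
                     ) -> tuple[list[Contig], pd.DataFrame]:
    """Tile each male chromosome into non-overlapping contigs.

    Contig lengths are ``target_contig_bp`` perturbed by a uniform jitter;
    contigs never span chromosome boundaries. The manifest labels each
    contig with the region class covering the majority of its bases
    (autosomes -> ``autosome``, X -> ``X``, Y positions via ``region_map``).
    A trailing fragment shorter than 2*min_k is still emitted, flagged.
    """
    if target_contig_bp < 2 * min_k:
        raise ValueError(f"target_contig_bp must be >= {2 * min_k}")
    if not 0.0 <= jitter_fraction < 1.0:
        raise ValueError("jitter_fraction must be in [0, 1)")
    if not isinstance(male, Mapping):
        male = dict(read_fasta(male))
    rng = np.random.default_rng(seed)

    y_intervals = [(s, e, r) for chrom, s, e, r in region_map
                   if chrom == "chrY"]

    def majority_region(chrom: str, start: int, end: int) -> str:
        if chrom == "chrY":
            best, best_ov = "Y_other", 0
            for s, e, r in y_intervals:
                ov = min(end, e) - max(start, s)
                if ov > best_ov:
                    best, best_ov = r, ov
            return best
        if chrom == "chrX":
            return "X"
        return "autosome"

    contigs: list[Contig] = []
    rows = []
    for chrom, seq in male.items():
        n = len(seq)
        pos = 0
        idx = 0
        while pos < n:
            jitter = rng.uniform(-jitter_fraction, jitter_fraction)
            size = max(2 * min_k, int(round(target_contig_bp * (1 + jitter))))
            end = min(pos + size, n)
            if n - end < 2 * min_k and n - end > 0 and end == pos + size:
                end = n  # absorb a tiny tail into the last contig
            cid = f"{chrom}_c{idx:04d}"
            contigs.append(Contig(cid, seq[pos:end]))
            rows.append({"contig_id": cid, "chromosome": chrom,
                         "region": majority_region(chrom, pos, end),
                         "start": pos, "end": end,
                         "length": end - pos,
                         "flagged_short": (end - pos) < 2 * min_k})
            pos = end
            idx += 1
    manifest = pd.DataFrame(rows, columns=["contig_id", "chromosome",
                                           "region", "start", "end",
                                           "length", "flagged_short"])
    return contigs, manifest


def default_copy_numbers(genome: Mapping[str, str],
                         sex: str = "male") -> dict[str, float]:
    """Copy numbers per chromosome: autosomes 2; X/Y 1 in a male, X 2 in a
    female (the single reference X standing for both homologs)."""
    out: dict[str, float] = {}
    for chrom in genome:
        if chrom == "chrY":
            out[chrom] = 1.0
        elif chrom == "chrX":
            out[chrom] = 1.0 if sex == "male" else 2.0
        else:
            out[chrom] = 2.0
    return out


def simulate_reads(genome: Mapping[str, str] | str | os.PathLike,
                   copy_numbers: Mapping[str, float],
                   params: ReadSimParams,
                   out_path: str | os.PathLike,
                   batch_size: int = 50_000) -> int:
    """Write uniform shotgun reads as FASTQ(.gz); returns the read count.

    Expected per-base depth on a chromosome is copy_number * haploid_depth;
    strands are sampled uniformly and substitution errors are i.i.d. Byte
    deterministic given ``params.seed``.
    """
    if not isinstance(genome, Mapping):
        genome = dict(read_fasta(genome))
    rng = np.random.default_rng(params.seed)
    rl = params.read_length
    qual = "I" * rl
    total = 0
    with open_text(out_path, "wt") as fh:
        for chrom, seq in genome.items():
            copy = float(copy_numbers.get(chrom, 0.0))
            n = len(seq)
            if copy <= 0:
                continue
            if rl > n:
                warnings.warn(f"read length {rl} exceeds {chrom} length {n}; "
                              f"chromosome skipped")
                continue
            n_reads = int(round(copy * params.haploid_depth * n / rl))
            codes = encode_sequence(seq)
            starts = rng.integers(0, n - rl + 1, size=n_reads)
            strands = rng.integers(0, 2, size=n_reads)
            for lo in range(0, n_reads, batch_size):
                hi = min(lo + batch_size, n_reads)
                batch = codes[starts[lo:hi, None] + np.arange(rl)]
                rev = strands[lo:hi] == 1
                if rev.any():
                    batch[rev] = (3 - batch[rev])[:, ::-1]
                if params.substitution_error_rate > 0:
                    err = rng.random(batch.shape) < params.substitution_error_rate
                    offs = rng.integers(1, 4, size=batch.shape,
                                        dtype=np.uint8)
                    batch = np.where(err, (batch + offs) % 4, batch)
                text = _BASES[batch].tobytes().decode("ascii")
                lines = []
                for j in range(hi - lo):
                    lines.append(f"@{chrom}_r{total + lo + j}\n"
                                 f"{text[j * rl:(j + 1) * rl]}\n+\n{qual}\n")
                fh.write("".join(lines))
            total += n_reads
    return total
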