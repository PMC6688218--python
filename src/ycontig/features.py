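"""Per-contig features: proportion shared with female and male depth of coverage.

Each contig of a male assembly is decomposed into its constituent canonical
k-mers. Two features summarize a contig:

* ``proportion_female`` — the fraction of the contig's k-mer windows found in
  the female k-mer set (per-occurrence, not deduplicated);
* ``male_depth`` — the median abundance of the contig's k-mers in the male
  read dataset, with absent k-mers contributing abundance 0. The median, not
  the mean, keeps the estimate robust to repeat-induced outliers.

Contigs with no valid k-mer window (shorter than k, or all-N) have undefined
features: they are flagged and classified non-Y downstream rather than given
a silent 0.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import iter_sequences
from .kmers import (BloomKmerSet, ExactKmerSet, KmerParams, MaleKmerCounts,
                    encode_sequence, kmer_codes)

__all__ = [
    "Contig",
    "read_contigs",
    "filter_contigs",
    "proportion_shared",
    "depth_of_coverage",
    "compute_features",
    "write_features",
    "read_features",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = ["contig_id", "length", "n_kmers",
                   "proportion_female", "male_depth", "undefined"]


@dataclass(frozen=True)
class Contig:
    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_contigs(path: str | os.PathLike) -> list[Contig]:
    """Load an assembly FASTA(.gz) as a list of contigs; ids must be unique."""
    contigs = [Contig(name, seq) for name, seq in iter_sequences(path)]
    if not contigs:
        raise ValueError(f"empty assembly file: {path}")
    seen: set[str] = set()
    for c in contigs:
        if c.id in seen:
            raise ValueError(f"duplicate contig id {c.id!r} in {path}")
        seen.add(c.id)
    return contigs


def filter_contigs(contigs: Iterable[Contig], min_length: int) -> list[Contig]:
    """Keep contigs with length >= ``min_length``, preserving order.

    Short contigs carry little k-mer signal and are discarded before feature
    computation (1000 bp for typical assemblies, 10 kb for highly fragmented
    raw graph assemblies).
    """
    if min_length < 1:
        raise ValueError(f"min_length must be >= 1, got {min_length}")
    return [c for c in contigs if c.length >= min_length]


def _contig_kmers(contig: Contig, params: KmerParams) -> np.ndarray:
    return kmer_codes(encode_sequence(contig.sequence), params.k,
                      params.canonical)


def proportion_shared(contig: Contig, female: BloomKmerSet | ExactKmerSet,
                      params: KmerParams | None = None) -> float:
    """Fraction of the contig's k-mer windows present in the female set.

    Returns NaN (undefined) when the contig has no valid k-mer window.
    """
    params = params or KmerParams()
    if female.k != params.k:
        raise ValueError(f"female set k={female.k} != params k={params.k}")
    kmers = _contig_kmers(contig, params)
    if kmers.size == 0:
        return math.nan
    return float(female.contains(kmers).sum() / kmers.size)


def depth_of_coverage(contig: Contig, male: MaleKmerCounts,
                      params: KmerParams | None = None) -> float:
    """Median abundance of the contig's k-mers in the male reads.

    Absent k-mers count as abundance 0; an even number of windows yields the
    mean of the two central values. NaN when no valid window exists.
    """
    params = params or KmerParams()
    if male.k != params.k:
        raise ValueError(f"male counts k={male.k} != params k={params.k}")
    kmers = _contig_kmers(contig, params)
    if kmers.size == 0:
        return math.nan
    return float(np.median(male.get(kmers)))


def compute_features(contigs: Sequence[Contig],
                     female: BloomKmerSet | ExactKmerSet,
                     male: MaleKmerCounts | None = None,
                     params: KmerParams | None = None) -> pd.DataFrame:
    """Feature table with one row per contig, in input order.

    The ``male_depth`` column is present only when male counts are supplied
    (female-only use omits it). Contigs with undefined features keep NaN in
    the feature columns and True in ``undefined``.
    """
    params = params or KmerParams()
    if female.k != params.k:
        raise ValueError(f"female set k={female.k} != params k={params.k}")
    if male is not None and male.k != params.k:
        raise ValueError(f"male counts k={male.k} != params k={params.k}")

    rows = []
    for contig in contigs:
        kmers = _contig_kmers(contig, params)
        n = int(kmers.size)
        if n == 0:
            prop = math.nan
            depth = math.nan
        else:
            prop = float(female.contains(kmers).sum() / n)
            depth = float(np.median(male.get(kmers))) if male is not None \
                else math.nan
        row = {"contig_id": contig.id, "length": contig.length,
               "n_kmers": n, "proportion_female": prop}
        if male is not None:
            row["male_depth"] = depth
        row["undefined"] = n == 0
        rows.append(row)

    columns = [c for c in FEATURE_COLUMNS
               if male is not None or c != "male_depth"]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows, columns=columns)


def write_features(features: pd.DataFrame, path: str | os.PathLike,
                   metadata: dict | None = None) -> None:
    """Write the feature table as TSV with '#'-prefixed metadata lines."""
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        out = features.copy()
        if "proportion_female" in out.columns:
            out["proportion_female"] = out["proportion_female"].map(
                lambda v: "" if pd.isna(v) else f"{v:.6f}")
        out.to_csv(fh, sep="\t", index=False)


def read_features(path: str | os.PathLike) -> pd.DataFrame:
    """Read a feature TSV written by :func:`write_features`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "contig_id" not in df.columns:
        raise ValueError(f"not a feature table (no contig_id column): {path}")
    if "undefined" in df.columns:
        df["undefined"] = df["undefined"].astype(bool)
    return df
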