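"""Truth labeling and length-weighted precision/recall.

Truth labels come either from alignments of contigs to an annotated male
reference (PAF, minimap2 dialect) or directly from the simulator's manifest.
Alignment-based labeling follows two filters: alignments whose mapping
fraction (alignment block length / query length) is below 50% are discarded,
and a contig that still maps to several places keeps the alignment with the
highest identity (matches / alignment block length).

Accuracy is length-weighted: with x the total length of contigs both
predicted Y and truly Y, precision = x / (length of predicted-Y contigs) and
recall = x / (length of true-Y contigs). Per-region recall stratifies the
true-Y contigs by Y sequence class (X-degenerate, ampliconic, X-transposed,
PAR). All coordinates are 0-based half-open.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import ClassificationResult, Y_LABEL

__all__ = [
    "REGION_CLASSES",
    "Y_REGION_CLASSES",
    "parse_paf",
    "read_region_bed",
    "label_truth_from_paf",
    "truth_from_manifest",
    "EvaluationReport",
    "precision_recall",
    "recall_by_region",
]

Y_REGION_CLASSES = ("Y_Xdegenerate", "Y_ampliconic", "Y_Xtransposed",
                    "Y_PAR", "Y_other")
REGION_CLASSES = ("autosome", "X") + Y_REGION_CLASSES + ("unplaced",)

_PAF_COLUMNS = ["query_name", "query_length", "query_start", "query_end",
                "strand", "target_name", "target_length", "target_start",
                "target_end", "n_matches", "alignment_block_length",
                "mapping_quality"]
_PAF_INT = ["query_length", "query_start", "query_end", "target_length",
            "target_start", "target_end", "n_matches",
            "alignment_block_length", "mapping_quality"]


def parse_paf(path: str | os.PathLike) -> pd.DataFrame:
    """Parse a PAF file (columns 1-12; extra tag columns ignored)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"malformed PAF line {lineno} in {path}: expected >= 12 "
                    f"tab-separated fields, found {len(fields)}")
            row = dict(zip(_PAF_COLUMNS, fields[:12]))
            try:
                for key in _PAF_INT:
                    row[key] = int(row[key])
            except ValueError as exc:
                raise ValueError(
                    f"malformed PAF line {lineno} in {path}: {exc}") from None
            rows.append(row)
    return pd.DataFrame(rows, columns=_PAF_COLUMNS)


def read_region_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BED3+1 file mapping reference intervals to Y region classes."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      names=["chrom", "start", "end", "region"],
                      dtype={"chrom": str, "start": int, "end": int,
                             "region": str})
    if (bed["end"] <= bed["start"]).any():
        raise ValueError(f"region BED {path} has intervals with end <= start")
    return bed


def _chromosome_class(target_name: str) -> str:
    name = target_name.removeprefix("chr").removeprefix("Chr")
    if name.upper() == "Y":
        return "Y"
    if name.upper() == "X":
        return "X"
    return "autosome"


def _region_for_interval(bed: pd.DataFrame, chrom: str, start: int,
                         end: int) -> str:
    """Region class with maximal overlap with [start, end); Y_other if none."""
    sub = bed[bed["chrom"] == chrom]
    best_region, best_overlap = "Y_other", 0
    for _, iv in sub.iterrows():
        overlap = min(end, iv["end"]) - max(start, iv["start"])
        if overlap > best_overlap:
            best_overlap = overlap
            best_region = iv["region"]
    return best_region


def label_truth_from_paf(paf_path: str | os.PathLike,
                         min_map_fraction: float = 0.5,
                         region_bed: str | os.PathLike | pd.DataFrame | None = None,
                         ) -> pd.DataFrame:
    """Assign one truth label per aligned contig.

    Per contig: discard alignments with mapping fraction below
    ``min_map_fraction``; among survivors keep the single alignment with the
    highest identity (ties: larger alignment block, then lexicographically
    smaller target name); label with its chromosome. Contigs with no
    surviving alignment are ``unplaced``. Y-chromosome contigs get a region
    class from ``region_bed`` by maximal interval overlap (``Y_other`` when
    nothing overlaps).
    """
    paf = parse_paf(paf_path)
    if region_bed is not None and not isinstance(region_bed, pd.DataFrame):
        region_bed = read_region_bed(region_bed)

    rows = []
    for query, sub in sorted(paf.groupby("query_name")):
        frac = sub["alignment_block_length"] / sub["query_length"]
        sub = sub[frac >= min_map_fraction]
        if sub.empty:
            rows.append({"contig_id": query, "chromosome": "unplaced",
                         "region": "unplaced"})
            continue
        identity = sub["n_matches"] / sub["alignment_block_length"]
        sub = sub.assign(identity=identity)
        sub = sub.sort_values(
            ["identity", "alignment_block_length", "target_name"],
            ascending=[False, False, True], kind="stable")
        best = sub.iloc[0]
        chrom_class = _chromosome_class(best["target_name"])
        if chrom_class == "Y":
            region = "Y_other"
            if region_bed is not None:
                region = _region_for_interval(
                    region_bed, best["target_name"],
                    int(best["target_start"]), int(best["target_end"]))
        else:
            region = chrom_class
        rows.append({"contig_id": query, "chromosome": chrom_class,
                     "region": region})
    return pd.DataFrame(rows, columns=["contig_id", "chromosome", "region"])


def truth_from_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Truth table from a simulator manifest (no alignment needed)."""
    required = {"contig_id", "chromosome", "region"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")
    out = manifest[["contig_id", "chromosome", "region"]].copy()
    out["chromosome"] = [
        _chromosome_class(c) if not str(r).startswith("Y_") else "Y"
        for c, r in zip(out["chromosome"], out["region"])]
    return out


@dataclass(frozen=True)
class EvaluationReport:
    """Length-weighted accuracy of a Y-contig prediction."""
    x: int                    # bp both predicted Y and truly Y
    predicted_y_length: int   # bp predicted Y
    true_y_length: int        # bp truly Y
    precision: float          # x / predicted_y_length (NaN if nothing predicted)
    recall: float             # x / true_y_length (NaN if no true Y)

    def as_dict(self) -> dict:
        return {"x_bp": self.x,
                "predicted_Y_bp": self.predicted_y_length,
                "true_Y_bp": self.true_y_length,
                "precision": self.precision, "recall": self.recall}


def _predicted_ids(predicted) -> set[str]:
    if isinstance(predicted, ClassificationResult):
        return set(predicted.y_ids)
    if isinstance(predicted, pd.DataFrame):
        if {"contig_id", "label"} <= set(predicted.columns):
            return set(predicted.loc[predicted["label"] == Y_LABEL,
                                     "contig_id"])
        raise ValueError("prediction table needs contig_id and label columns")
    return set(predicted)


def _lengths_map(lengths) -> Mapping[str, int]:
    if isinstance(lengths, pd.DataFrame):
        return dict(zip(lengths["contig_id"], lengths["length"]))
    if isinstance(lengths, pd.Series):
        return lengths.to_dict()
    return dict(lengths)


def precision_recall(predicted, truth: pd.DataFrame,
                     lengths) -> EvaluationReport:
    """Length-weighted precision and recall against a truth table.

    ``predicted`` may be a ClassificationResult, a (contig_id, label) table
    or an iterable of predicted-Y contig ids; ``lengths`` maps contig ids to
    bp (a feature table works). Every predicted contig must have a truth
    label and a length.
    """
    pred = _predicted_ids(predicted)
    lengths = _lengths_map(lengths)
    truth_map = dict(zip(truth["contig_id"], truth["chromosome"]))

    missing = sorted(cid for cid in pred
                     if cid not in truth_map or cid not in lengths)
    if missing:
        raise ValueError(f"predicted contigs missing truth label or length: "
                         f"{missing[:10]}{'...' if len(missing) > 10 else ''}")

    true_y = {cid for cid, chrom in truth_map.items() if chrom == "Y"}
    missing_len = sorted(cid for cid in true_y if cid not in lengths)
    if missing_len:
        raise ValueError(f"true-Y contigs missing length: {missing_len[:10]}")

    x = sum(lengths[cid] for cid in pred & true_y)
    pred_len = sum(lengths[cid] for cid in pred)
    true_len = sum(lengths[cid] for cid in true_y)
    precision = x / pred_len if pred_len else math.nan
    recall = x / true_len if true_len else math.nan
    if pred_len == 0 and true_len:
        recall = 0.0
    return EvaluationReport(x=int(x), predicted_y_length=int(pred_len),
                            true_y_length=int(true_len),
                            precision=precision, recall=recall)


def recall_by_region(predicted, truth: pd.DataFrame,
                     lengths) -> pd.DataFrame:
    """Length-weighted recall for each Y region class present in the truth.

    Regions with zero true length are absent from the result, not reported
    as 0/0. Overall recall equals the length-weighted mean of these rows.
    """
    pred = _predicted_ids(predicted)
    lengths = _lengths_map(lengths)
    rows = []
    for region in Y_REGION_CLASSES:
        ids = truth.loc[truth["region"] == region, "contig_id"]
        total = sum(lengths[cid] for cid in ids)
        if total == 0:
            continue
        recovered = sum(lengths[cid] for cid in ids if cid in pred)
        rows.append({"region": region, "total_bp": int(total),
                     "recovered_bp": int(recovered),
                     "recall": recovered / total})
    return pd.DataFrame(rows, columns=["region", "total_bp",
                                       "recovered_bp", "recall"])
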