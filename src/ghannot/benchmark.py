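"""Precision/recall scoring of annotations against a gold-standard repertoire.

A gold standard is an expert-curated list of HMG-utilization genes per genome.
True positives are gold records matched by an annotation with the same genome
(and protein id, when the gold provides one) and an equivalent label; false
negatives are unmatched gold records.  False positives count only unmatched
annotations carrying an HMG-associated label (hmg_status yes/unknown) on gold
genomes: calls absorbed by non-HMG clusters are the annotator's intended
false-positive sink, not errors.

Gold records without protein ids fall back to per-genome label-multiset
matching (published repertoires are often gene lists without stable ids).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .annotate import Annotation
from .calibrate import f1_score
from .io import CLUSTER_UNDEFINED


@dataclass(frozen=True)
class GoldStandardRecord:
    genome_id: str
    expected_label: str
    protein_id: str | None = None


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class BenchmarkResult:
    counts: ConfusionCounts
    precision: float
    recall: float
    f1: float


def label_equivalence(annotation_label: str, gold_label: str,
                      synonym_table: Mapping[str, set[str]] | None = None) -> bool:
    """True iff the labels match after case-folding or are linked as synonyms."""
    a, g = annotation_label.casefold().strip(), gold_label.casefold().strip()
    if a == g:
        return True
    if synonym_table:
        return g in synonym_table.get(a, set())
    return False


def read_synonyms(path) -> dict[str, set[str]]:
    """Synonym TSV (label_a, label_b) as a symmetric case-folded lookup."""
    table: dict[str, set[str]] = {}
    with open(Path(path), encoding="utf-8", newline="") as fh:
        reader = csv.DictReader((l for l in fh if not l.startswith("#")), delimiter="\t")
        for row in reader:
            a, b = row["label_a"].casefold().strip(), row["label_b"].casefold().strip()
            table.setdefault(a, set()).add(b)
            table.setdefault(b, set()).add(a)
    return table


def read_gold_standard(path) -> list[GoldStandardRecord]:
    """Gold TSV: genome_id, expected_label, optional protein_id column."""
    out = []
    with open(Path(path), encoding="utf-8", newline="") as fh:
        reader = csv.DictReader((l for l in fh if not l.startswith("#")), delimiter="\t")
        for row in reader:
            pid = row.get("protein_id") or None
            out.append(GoldStandardRecord(row["genome_id"], row["expected_label"], pid))
    return out


def _annotation_labels(a: Annotation, mode: str) -> list[str]:
    if mode == "family":
        return [a.family]
    labels = [a.cluster_id]
    if a.enzyme_label:
        labels.append(a.enzyme_label)
    return labels


def _is_hmg_call(a: Annotation) -> bool:
    return a.hmg_status in ("yes", "unknown")


def score(
    annotations: Sequence[Annotation],
    gold: Sequence[GoldStandardRecord],
    mode: str = "cluster",
    synonyms: Mapping[str, set[str]] | None = None,
) -> BenchmarkResult:
    """Confusion counts and precision/recall/F1 in ``family`` or ``cluster`` mode.

    In cluster mode an annotation matches a gold label through either its
    cluster id or its enzyme label (gold standards use free-text enzyme names).
    """
    if not gold:
        raise ValueError("empty gold standard")
    if mode not in ("family", "cluster"):
        raise ValueError("mode must be 'family' or 'cluster'")
    gold_genomes = {g.genome_id for g in gold}
    candidates = [a for a in annotations if a.genome_id in gold_genomes]
    matched: set[int] = set()
    tp = fn = 0

    def match_one(record: GoldStandardRecord) -> bool:
        for idx, a in enumerate(candidates):
            if idx in matched or a.genome_id != record.genome_id:
                continue
            if record.protein_id is not None and a.protein_id != record.protein_id:
                continue
            if any(
                label_equivalence(lab, record.expected_label, synonyms)
                for lab in _annotation_labels(a, mode)
            ):
                matched.add(idx)
                return True
        return False

    # protein-id records first: they are the most specific
    ordered = sorted(gold, key=lambda g: g.protein_id is None)
    for record in ordered:
        if match_one(record):
            tp += 1
        else:
            fn += 1
    fp = sum(
        1 for idx, a in enumerate(candidates)
        if idx not in matched and _is_hmg_call(a)
    )
    counts = ConfusionCounts(tp=tp, fp=fp, fn=fn)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return BenchmarkResult(counts, precision, recall, f1_score(precision, recall))


def write_report(result: BenchmarkResult, path) -> None:
    """Machine-readable TSV plus a human-readable summary line."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("tp\tfp\tfn\tprecision\trecall\tf1\n")
        c = result.counts
        fh.write(
            f"{c.tp}\t{c.fp}\t{c.fn}\t{result.precision:.6f}\t{result.recall:.6f}\t{result.f1:.6f}\n"
        )
    summary = path.with_suffix(".txt")
    with open(summary, "w", encoding="utf-8") as fh:
        fh.write(
            f"TP={c.tp} FP={c.fp} FN={c.fn} | "
            f"precision={100 * result.precision:.1f}% recall={100 * result.recall:.1f}% "
            f"F1={100 * result.f1:.1f}%\n"
        )
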