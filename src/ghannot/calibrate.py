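"""Percent-identity threshold calibration from a labelled reference database.

Family thresholds come from a one-vs-rest F1 sweep: for each reference
sequence we record the identity of its best non-self hit inside its own family
and its best hit into every other family; at each candidate threshold t a
family's true positives are members whose intra-family best hit reaches t,
false negatives those that do not, and false positives non-members whose best
hit *into* the family reaches t.  The chosen threshold maximizes
F1 = 2PR/(P+R), ties broken toward the more stringent (larger) value.

Cluster thresholds are the tenth percentile of each cluster's distribution of
best non-self intra-cluster hit identities, then harmonized upward to the
family threshold (max rule) so cluster assignment is always at least as
stringent as family assignment.

Calibration hits are gated by the query-coverage cutoff (default 0.50), the
same gate the annotator applies; ungated local alignment would otherwise let
high-identity micro-alignments between unrelated proteins act as negatives.
Self-hits are excluded everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .align import AlignerConfig, search_best_hits
from .io import ReferenceBundle, ThresholdSet, validate_threshold_hierarchy

DEFAULT_GRID = [30.0 + 0.5 * i for i in range(141)]  # 30..100 step 0.5


@dataclass
class CalibrationPoint:
    """Best-hit identities for one reference sequence.

    ``cross_family_identity`` maps each *other* family to the identity of this
    sequence's best hit into that family; ``best_inter_identity`` is its
    maximum.  ``None`` means no qualifying positive hit exists.
    """

    seq_id: str
    family: str
    best_intra_identity: float | None = None
    best_inter_identity: float | None = None
    cross_family_identity: dict[str, float] = field(default_factory=dict)


@dataclass
class FamilySweepRow:
    family: str
    threshold: float
    precision: float
    recall: float
    f1: float
    sweep_table: pd.DataFrame


@dataclass
class CalibrationReport:
    """Full provenance of a calibration run."""

    family_rows: dict[str, FamilySweepRow]
    cluster_percentiles: dict[str, float]
    cluster_thresholds: dict[str, float]

    def family_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "family": r.family,
                    "threshold": r.threshold,
                    "precision": r.precision,
                    "recall": r.recall,
                    "f1": r.f1,
                }
                for r in self.family_rows.values()
            ]
        )

    def cluster_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cluster_id": cid,
                    "tenth_percentile": self.cluster_percentiles.get(cid, float("nan")),
                    "harmonized_threshold": thr,
                }
                for cid, thr in sorted(self.cluster_thresholds.items())
            ]
        )


def percentile_linear(values, percentile: float) -> float:
    """Percentile with linear interpolation between closest order statistics."""
    if len(values) == 0:
        raise ValueError("empty distribution")
    if not (0.0 <= percentile <= 1.0):
        raise ValueError("percentile must be a fraction in [0, 1]")
    return float(np.percentile(values, 100.0 * percentile, method="linear"))


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must be in [0, 1]")
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def compute_calibration_points(
    db: ReferenceBundle,
    aligner: AlignerConfig | None = None,
    min_coverage: float = 0.50,
) -> list[CalibrationPoint]:
    """Best non-self intra-family and per-family cross identities for every sequence.

    Hits below ``min_coverage`` query coverage are ignored (see module notes).
    """
    families = db.families
    if len(families) < 2:
        raise ValueError("calibration needs >= 2 families (no negative examples)")
    family_of = {s.seq_id: s.family for s in db.sequences}
    pairs = [(s.seq_id, s.sequence) for s in db.sequences]
    # exhaustive all-vs-all: the k-mer prefilter would silently drop the weak
    # cross-family hits that are exactly the negatives being calibrated
    aligner = replace(aligner or AlignerConfig(), use_prefilter=False)
    hits = search_best_hits(pairs, db.sequences, aligner)
    points = []
    for s in db.sequences:
        point = CalibrationPoint(seq_id=s.seq_id, family=s.family)
        best_by_family: dict[str, float] = {}
        for h in hits[s.seq_id]:
            if h.target_id == s.seq_id or h.query_coverage < min_coverage:
                continue
            fam = family_of[h.target_id]
            # hits are bitscore-ranked: the first hit seen per family is its best hit
            if fam not in best_by_family:
                best_by_family[fam] = h.percent_identity
        point.best_intra_identity = best_by_family.get(s.family)
        point.cross_family_identity = {
            f: v for f, v in best_by_family.items() if f != s.family
        }
        if point.cross_family_identity:
            point.best_inter_identity = max(point.cross_family_identity.values())
        points.append(point)
    return points


def sweep_family_threshold(
    points: list[CalibrationPoint],
    family: str,
    grid: list[float] | None = None,
) -> tuple[float, FamilySweepRow]:
    """One-vs-rest F1 sweep for one family over an identity grid."""
    grid = sorted(grid) if grid else list(DEFAULT_GRID)
    if not grid:
        raise ValueError("empty grid")
    members = [p for p in points if p.family == family]
    if not members:
        raise ValueError(f"family {family!r} has no members")
    others = [p for p in points if p.family != family]
    rows = []
    for t in grid:
        tp = sum(1 for p in members if p.best_intra_identity is not None and p.best_intra_identity >= t)
        fn = len(members) - tp
        fp = sum(
            1
            for p in others
            if p.cross_family_identity.get(family) is not None
            and p.cross_family_identity[family] >= t
        )
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        rows.append((t, precision, recall, f1_score(precision, recall)))
    table = pd.DataFrame(rows, columns=["threshold", "precision", "recall", "f1"])
    best_f1 = table["f1"].max()
    # ties broken toward the larger (more stringent) threshold
    best = table[table["f1"] == best_f1].iloc[-1]
    row = FamilySweepRow(
        family=family,
        threshold=float(best["threshold"]),
        precision=float(best["precision"]),
        recall=float(best["recall"]),
        f1=float(best["f1"]),
        sweep_table=table,
    )
    return row.threshold, row


def cluster_percentile_threshold(
    db: ReferenceBundle,
    cluster_id: str,
    aligner: AlignerConfig | None = None,
    percentile: float = 0.10,
    min_coverage: float = 0.50,
) -> float:
    """Percentile of the intra-cluster best non-self hit identity distribution.

    Linear interpolation between closest order statistics; percentile 0 is the
    distribution minimum.  Singleton clusters raise (the caller falls back to
    the family threshold).
    """
    members = db.sequences_of_cluster(cluster_id)
    if len(members) < 2:
        raise ValueError(f"cluster {cluster_id!r} has < 2 members; percentile undefined")
    identities = _intra_cluster_best_identities(members, aligner, min_coverage)
    if not identities:
        raise ValueError(f"cluster {cluster_id!r}: no positive intra-cluster hits")
    return percentile_linear(identities, percentile)


def _intra_cluster_best_identities(members, aligner, min_coverage) -> list[float]:
    pairs = [(s.seq_id, s.sequence) for s in members]
    hits = search_best_hits(pairs, members, aligner)
    out = []
    for sid, _ in pairs:
        best = None
        for h in hits[sid]:
            if h.target_id == sid or h.query_coverage < min_coverage:
                continue
            best = h.percent_identity
            break
        if best is not None:
            out.append(best)
    return out


def harmonize_thresholds(
    family_thresholds: dict[str, float],
    raw_cluster_thresholds: dict[str, float],
    cluster_to_family: dict[str, str],
    coverage_cutoff: float = 0.50,
    bitscore_cutoff: float = 200.0,
) -> ThresholdSet:
    """Apply the max rule: cluster threshold = max(family threshold, percentile value).

    Clusters present in ``cluster_to_family`` but without a raw percentile
    value (singletons) inherit the family threshold.
    """
    cluster_thresholds = {}
    for cid, fam in cluster_to_family.items():
        if fam not in family_thresholds:
            raise KeyError(f"cluster {cid}: family {fam!r} has no threshold")
        raw = raw_cluster_thresholds.get(cid)
        fam_thr = family_thresholds[fam]
        cluster_thresholds[cid] = fam_thr if raw is None else max(fam_thr, raw)
    return ThresholdSet(
        dict(family_thresholds),
        cluster_thresholds,
        coverage_cutoff=coverage_cutoff,
        bitscore_cutoff=bitscore_cutoff,
    )


class ThresholdCalibrator(BaseEstimator):
    """Fit per-family and per-cluster identity thresholds from a labelled database.

    Parameters
    ----------
    grid : list of percent identities swept for family thresholds
        (default 30–100 in 0.5 steps).
    percentile : fraction for the intra-cluster threshold (default 0.10).
    min_coverage : query-coverage gate applied to calibration hits.
    aligner : optional :class:`AlignerConfig`.

    After ``fit(bundle)``: ``thresholds_`` (a harmonized
    :class:`~ghannot.io.ThresholdSet`), ``points_``, ``report_``.
    """

    def __init__(self, grid=None, percentile: float = 0.10,
                 min_coverage: float = 0.50, coverage_cutoff: float = 0.50,
                 bitscore_cutoff: float = 200.0, aligner: AlignerConfig | None = None):
        self.grid = grid
        self.percentile = percentile
        self.min_coverage = min_coverage
        self.coverage_cutoff = coverage_cutoff
        self.bitscore_cutoff = bitscore_cutoff
        self.aligner = aligner

    def fit(self, X: ReferenceBundle, y=None):
        db = X
        self.points_ = compute_calibration_points(db, self.aligner, self.min_coverage)
        family_rows: dict[str, FamilySweepRow] = {}
        family_thresholds: dict[str, float] = {}
        for fam in db.families:
            thr, row = sweep_family_threshold(self.points_, fam, self.grid)
            family_thresholds[fam] = thr
            family_rows[fam] = row
        raw_cluster: dict[str, float] = {}
        cluster_to_family = {c.cluster_id: c.family for c in db.clusters}
        for c in db.clusters:
            if len(db.sequences_of_cluster(c.cluster_id)) >= 2:
                raw_cluster[c.cluster_id] = cluster_percentile_threshold(
                    db, c.cluster_id, self.aligner, self.percentile, self.min_coverage
                )
        self.thresholds_ = harmonize_thresholds(
            family_thresholds, raw_cluster, cluster_to_family,
            self.coverage_cutoff, self.bitscore_cutoff,
        )
        assert not validate_threshold_hierarchy(self.thresholds_, db.clusters)
        self.report_ = CalibrationReport(family_rows, raw_cluster,
                                         dict(self.thresholds_.cluster_thresholds))
        return self

    def write_report(self, out_dir) -> None:
        """CalibrationReport as TSVs: per-family, per-cluster and full sweep tables."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.report_.family_table().to_csv(out / "calibration_families.tsv", sep="\t", index=False)
        self.report_.cluster_table().to_csv(out / "calibration_clusters.tsv", sep="\t", index=False)
        sweep = pd.concat(
            [r.sweep_table.assign(family=f) for f, r in self.report_.family_rows.items()],
            ignore_index=True,
        )
        sweep.to_csv(out / "calibration_sweep.tsv", sep="\t", index=False)
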