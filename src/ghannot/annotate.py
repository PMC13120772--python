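"""Two-stage hierarchical GH annotation and transporter annotation.

Each query protein competes against the whole reference database (including
non-HMG clusters — competitive mapping: a spurious query is absorbed by its
true non-HMG homologue instead of inflating an HMG cluster).  Hits failing the
query-coverage or bitscore gate are discarded; the single best surviving hit
decides everything.  Stage 1 assigns the hit's GH family when the hit identity
reaches that family's calibrated threshold; stage 2 assigns the hit's
functional cluster when it also reaches the cluster threshold, otherwise the
sentinel "cluster undefined".  A best hit that fails its family threshold
yields no annotation; no fallback to the next-best hit is attempted.

Transporter annotation is a flat best-hit assignment against the transporter
references at a fixed identity threshold (default 80%) with the same coverage
gate but no bitscore gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .align import AlignerConfig, SearchHit, search_best_hits
from .io import (
    CLUSTER_UNDEFINED,
    ReferenceBundle,
    SampleSheet,
    TransporterReference,
    read_proteome,
    validate_threshold_hierarchy,
)

HMG_FILTERS = ("hmg_unknown", "hmg_only", "all_genes")


@dataclass(frozen=True)
class AnnotationConfig:
    """Runtime gates of the annotator."""

    coverage_cutoff: float = 0.50
    bitscore_cutoff: float = 200.0
    transporter_identity: float = 80.0
    hmg_filter: str = "hmg_unknown"

    def __post_init__(self) -> None:
        if not (0.0 < self.coverage_cutoff <= 1.0):
            raise ValueError("coverage_cutoff must be in (0, 1]")
        if self.bitscore_cutoff < 0:
            raise ValueError("bitscore_cutoff must be non-negative")
        if not (0.0 <= self.transporter_identity <= 100.0):
            raise ValueError("transporter_identity must be in [0, 100]")
        if self.hmg_filter not in HMG_FILTERS:
            raise ValueError(f"hmg_filter must be one of {HMG_FILTERS}")


@dataclass(frozen=True)
class Annotation:
    """Two-stage assignment for one query protein.

    Cluster-level fields are ``None`` iff ``cluster_id`` is the
    "cluster undefined" sentinel.
    """

    genome_id: str
    protein_id: str
    family: str
    cluster_id: str
    hit: SearchHit
    enzyme_label: str | None = None
    validation_status: str | None = None
    hmg_status: str | None = None
    localization: str | None = None

    @property
    def cluster_defined(self) -> bool:
        return self.cluster_id != CLUSTER_UNDEFINED


@dataclass(frozen=True)
class TransporterAnnotation:
    genome_id: str
    protein_id: str
    transporter_gene: str
    substrate_class: str
    hit: SearchHit


def _best_surviving_hit(hits: list[SearchHit], config: AnnotationConfig) -> SearchHit | None:
    for h in hits:
        if h.query_coverage >= config.coverage_cutoff and h.bitscore >= config.bitscore_cutoff:
            return h
    return None


def annotate_proteome(
    genome_id: str,
    proteins: Sequence[tuple[str, str]],
    db: ReferenceBundle,
    config: AnnotationConfig | None = None,
    aligner: AlignerConfig | None = None,
) -> list[Annotation]:
    """Annotate one proteome against a loaded, validated bundle.

    Queries whose best surviving hit fails its family threshold emit nothing.
    The hmg_filter never affects assignment — only downstream reporting.
    """
    config = config or AnnotationConfig()
    hits = search_best_hits(list(proteins), db.sequences, aligner)
    sequence_by_id = {s.seq_id: s for s in db.sequences}
    cluster_by_id = db.cluster_by_id
    out: list[Annotation] = []
    for pid, _seq in proteins:
        best = _best_surviving_hit(hits[pid], config)
        if best is None:
            continue
        ref = sequence_by_id[best.target_id]
        fam_thr = db.thresholds.family_thresholds.get(ref.family)
        if fam_thr is None or best.percent_identity < fam_thr:
            continue
        cluster = cluster_by_id.get(ref.cluster_id) if ref.cluster_id else None
        clu_thr = (
            db.thresholds.cluster_thresholds.get(ref.cluster_id)
            if ref.cluster_id
            else None
        )
        if clu_thr is None and cluster is not None:
            clu_thr = cluster.identity_threshold
        if cluster is not None and clu_thr is not None and best.percent_identity >= clu_thr:
            out.append(
                Annotation(
                    genome_id=genome_id,
                    protein_id=pid,
                    family=ref.family,
                    cluster_id=cluster.cluster_id,
                    hit=best,
                    enzyme_label=cluster.enzyme_label,
                    validation_status=cluster.validation_status,
                    hmg_status=cluster.hmg_status,
                    localization=cluster.localization,
                )
            )
        else:
            out.append(
                Annotation(
                    genome_id=genome_id,
                    protein_id=pid,
                    family=ref.family,
                    cluster_id=CLUSTER_UNDEFINED,
                    hit=best,
                )
            )
    return out


def annotate_transporters(
    genome_id: str,
    proteins: Sequence[tuple[str, str]],
    transporters: Sequence[TransporterReference],
    config: AnnotationConfig | None = None,
    aligner: AlignerConfig | None = None,
) -> list[TransporterAnnotation]:
    """Best-hit transporter assignment at the identity threshold (default 80%)."""
    config = config or AnnotationConfig()
    if not transporters:
        raise ValueError("empty transporter reference")
    hits = search_best_hits(list(proteins), [(t.seq_id, t.sequence) for t in transporters], aligner)
    by_id = {t.seq_id: t for t in transporters}
    out = []
    for pid, _seq in proteins:
        best = None
        for h in hits[pid]:
            if h.query_coverage >= config.coverage_cutoff:
                best = h
                break
        if best is None or best.percent_identity < config.transporter_identity:
            continue
        ref = by_id[best.target_id]
        out.append(
            TransporterAnnotation(
                genome_id=genome_id,
                protein_id=pid,
                transporter_gene=ref.transporter_gene,
                substrate_class=ref.substrate_class,
                hit=best,
            )
        )
    return out


@dataclass
class BatchResult:
    """Per-genome annotation sets plus recorded failures."""

    annotations: dict[str, list[Annotation]] = field(default_factory=dict)
    transporter_annotations: dict[str, list[TransporterAnnotation]] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def all_annotations(self) -> list[Annotation]:
        return [a for g in sorted(self.annotations) for a in self.annotations[g]]

    @property
    def all_transporter_annotations(self) -> list[TransporterAnnotation]:
        return [
            a for g in sorted(self.transporter_annotations)
            for a in self.transporter_annotations[g]
        ]

    @property
    def ok(self) -> bool:
        return not self.failures


def run_batch(
    samples: SampleSheet,
    db: ReferenceBundle,
    config: AnnotationConfig | None = None,
    aligner: AlignerConfig | None = None,
    with_transporters: bool = False,
) -> BatchResult:
    """Annotate every genome in a sample sheet.

    An unreadable sample is recorded as a failure and the batch continues;
    results do not depend on sample-sheet order.
    """
    config = config or AnnotationConfig()
    result = BatchResult()
    for entry in samples.entries:
        try:
            proteins = read_proteome(entry.fasta_path)
        except (OSError, ValueError) as exc:
            result.failures[entry.genome_id] = str(exc)
            continue
        result.annotations[entry.genome_id] = annotate_proteome(
            entry.genome_id, proteins, db, config, aligner
        )
        if with_transporters and db.transporters:
            result.transporter_annotations[entry.genome_id] = annotate_transporters(
                entry.genome_id, proteins, db.transporters, config, aligner
            )
    return result


class GHAnnotator(BaseEstimator):
    """Hierarchical best-hit GH family/cluster classifier.

    ``fit`` takes a loaded :class:`~ghannot.io.ReferenceBundle`; ``predict``
    takes protein sequences (list of strings or of ``(id, sequence)`` pairs)
    and returns composite labels ``"<family>|<cluster_id>"``, with
    ``"<family>|cluster undefined"`` for family-only assignments and
    ``"unannotated"`` when the best hit fails every gate.  ``annotate``
    returns the full :class:`Annotation` records instead.
    """

    def __init__(self, coverage_cutoff: float = 0.50, bitscore_cutoff: float = 200.0,
                 transporter_identity: float = 80.0, hmg_filter: str = "hmg_unknown",
                 aligner: AlignerConfig | None = None):
        self.coverage_cutoff = coverage_cutoff
        self.bitscore_cutoff = bitscore_cutoff
        self.transporter_identity = transporter_identity
        self.hmg_filter = hmg_filter
        self.aligner = aligner

    def _config(self) -> AnnotationConfig:
        return AnnotationConfig(
            coverage_cutoff=self.coverage_cutoff,
            bitscore_cutoff=self.bitscore_cutoff,
            transporter_identity=self.transporter_identity,
            hmg_filter=self.hmg_filter,
        )

    def fit(self, X: ReferenceBundle, y=None):
        validate_threshold_hierarchy(X.thresholds, X.clusters)
        self.db_ = X
        self.families_ = X.families
        return self

    def annotate(self, proteins, genome_id: str = "query") -> list[Annotation]:
        check_is_fitted(self, "db_")
        proteins = _as_pairs(proteins)
        return annotate_proteome(genome_id, proteins, self.db_, self._config(), self.aligner)

    def annotate_transporters(self, proteins, genome_id: str = "query"):
        check_is_fitted(self, "db_")
        proteins = _as_pairs(proteins)
        return annotate_transporters(
            genome_id, proteins, self.db_.transporters, self._config(), self.aligner
        )

    def predict(self, X) -> np.ndarray:
        proteins = _as_pairs(X)
        annotations = {a.protein_id: a for a in self.annotate(proteins)}
        labels = []
        for pid, _ in proteins:
            a = annotations.get(pid)
            labels.append("unannotated" if a is None else f"{a.family}|{a.cluster_id}")
        return np.array(labels, dtype=object)


class TransporterAnnotator(BaseEstimator):
    """Flat best-hit transporter classifier (identity-thresholded)."""

    def __init__(self, identity_threshold: float = 80.0, coverage_cutoff: float = 0.50,
                 aligner: AlignerConfig | None = None):
        self.identity_threshold = identity_threshold
        self.coverage_cutoff = coverage_cutoff
        self.aligner = aligner

    def fit(self, X: Sequence[TransporterReference], y=None):
        if not X:
            raise ValueError("empty transporter reference")
        self.references_ = list(X)
        return self

    def annotate(self, proteins, genome_id: str = "query") -> list[TransporterAnnotation]:
        check_is_fitted(self, "references_")
        config = AnnotationConfig(
            coverage_cutoff=self.coverage_cutoff,
            transporter_identity=self.identity_threshold,
        )
        return annotate_transporters(
            genome_id, _as_pairs(proteins), self.references_, config, self.aligner
        )

    def predict(self, X) -> np.ndarray:
        proteins = _as_pairs(X)
        hits = {a.protein_id: a.transporter_gene for a in self.annotate(proteins)}
        return np.array([hits.get(pid, "unannotated") for pid, _ in proteins], dtype=object)


def _as_pairs(proteins) -> list[tuple[str, str]]:
    out = []
    for i, p in enumerate(proteins):
        if isinstance(p, str):
            out.append((f"q{i + 1}", p))
        else:
            out.append((p[0], p[1]))
    return out
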