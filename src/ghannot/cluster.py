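"""Database-construction computations.

Greedy set-cover clustering of reference proteins within one GH family,
minimum-cluster-size filtering, and merging of clusters that share a conserved
gene neighbourhood.  These are the steps that turn a raw per-family sequence
collection into the functional clusters the annotator assigns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .align import AlignerConfig, align_pair
from .io import ReferenceSequence


@dataclass(frozen=True)
class ClusteringConfig:
    """Greedy set-cover parameters.

    ``min_seq_id`` and ``coverage`` are fractions; a member belongs to a
    centroid's cover when it aligns to the centroid at identity >=
    ``min_seq_id`` with query coverage >= ``coverage`` (coverage measured on
    the member).  Clusters smaller than ``min_cluster_size`` are dropped by
    :func:`filter_min_size`.
    """

    min_seq_id: float = 0.70
    coverage: float = 0.80
    min_cluster_size: int = 5

    def __post_init__(self) -> None:
        if not (0.0 < self.min_seq_id <= 1.0):
            raise ValueError("min_seq_id must be in (0, 1]")
        if not (0.0 < self.coverage <= 1.0):
            raise ValueError("coverage must be in (0, 1]")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be positive")


@dataclass(frozen=True)
class LocusNeighbourhood:
    """Gene content of the flanking window around one anchor GH gene."""

    locus_id: str
    genome_id: str
    anchor_seq_id: str
    anchor_cluster_id: str
    gene_content: frozenset[str]
    family: str = ""


def _covers(member: ReferenceSequence, centroid: ReferenceSequence,
            config: ClusteringConfig, aligner: AlignerConfig) -> bool:
    hit = align_pair(member.sequence, centroid.sequence, aligner)
    if hit is None:
        return False
    return (
        hit.percent_identity >= 100.0 * config.min_seq_id
        and hit.query_coverage >= config.coverage
    )


def greedy_cluster(
    sequences: Sequence[ReferenceSequence],
    config: ClusteringConfig | None = None,
    aligner: AlignerConfig | None = None,
) -> dict[str, list[str]]:
    """Greedy set-cover clustering of one family's sequences.

    Repeatedly selects the unassigned sequence whose cover (itself plus every
    unassigned sequence aligning to it above the identity/coverage cutoffs)
    is largest, makes it a centroid and assigns its cover, until every
    sequence is clustered.  Ties are broken toward the longer sequence, then
    the lexicographically smaller id, so builds are deterministic.  The
    centroid's seq_id names the cluster; returns cluster_id -> member seq_ids
    (centroid first).
    """
    config = config or ClusteringConfig()
    aligner = aligner or AlignerConfig()
    if not sequences:
        return {}
    families = {s.family for s in sequences}
    if len(families) > 1:
        raise ValueError(f"greedy_cluster expects one family, got {sorted(families)}")
    seqs = list(sequences)
    # precompute covers: cover[c] = ids covered by candidate centroid c
    cover: dict[str, set[str]] = {}
    by_id = {s.seq_id: s for s in seqs}
    for c in seqs:
        cov = {c.seq_id}
        for m in seqs:
            if m.seq_id != c.seq_id and _covers(m, c, config, aligner):
                cov.add(m.seq_id)
        cover[c.seq_id] = cov
    unassigned = {s.seq_id for s in seqs}
    clusters: dict[str, list[str]] = {}
    while unassigned:
        best = None
        best_key = None
        for sid in sorted(unassigned):  # ascending id => smallest id wins ties
            key = (len(cover[sid] & unassigned), len(by_id[sid].sequence))
            if best_key is None or key > best_key:
                best, best_key = sid, key
        members = sorted(cover[best] & unassigned)
        members.remove(best)
        clusters[best] = [best] + members
        unassigned -= set(clusters[best])
    return clusters


class GreedySetCoverClustering(ClusterMixin, BaseEstimator):
    """Sklearn-style wrapper over :func:`greedy_cluster`.

    ``fit(X)`` accepts a sequence of :class:`ReferenceSequence` (or
    ``(seq_id, family, sequence)`` triples) from one GH family.  After
    fitting, ``labels_`` holds integer cluster labels in input order,
    ``clusters_`` the cluster_id -> member map and ``centroids_`` the
    centroid seq_ids.
    """

    def __init__(self, min_seq_id: float = 0.70, coverage: float = 0.80,
                 min_cluster_size: int = 5, aligner: AlignerConfig | None = None):
        self.min_seq_id = min_seq_id
        self.coverage = coverage
        self.min_cluster_size = min_cluster_size
        self.aligner = aligner

    def fit(self, X, y=None):
        seqs = [
            s if isinstance(s, ReferenceSequence)
            else ReferenceSequence(seq_id=s[0], genome_id="", family=s[1], sequence=s[2])
            for s in X
        ]
        config = ClusteringConfig(self.min_seq_id, self.coverage, self.min_cluster_size)
        self.clusters_ = greedy_cluster(seqs, config, self.aligner)
        self.centroids_ = list(self.clusters_)
        label_of = {
            sid: i for i, (cid, members) in enumerate(self.clusters_.items()) for sid in members
        }
        self.labels_ = [label_of[s.seq_id] for s in seqs]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def filter_min_size(
    clusters: Mapping[str, list[str]], min_cluster_size: int
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Partition clusters into (retained, removed) by member count."""
    retained = {cid: list(m) for cid, m in clusters.items() if len(m) >= min_cluster_size}
    removed = {cid: list(m) for cid, m in clusters.items() if len(m) < min_cluster_size}
    return retained, removed


def deduplicate_loci(loci: Sequence[LocusNeighbourhood]) -> list[LocusNeighbourhood]:
    """Collapse loci with the same (genome_id, locus_id), keeping the first.

    The same genomic locus can be detected by seed queries from several
    clusters; each locus must be represented once before grouping.
    """
    seen: set[tuple[str, str]] = set()
    out = []
    for locus in loci:
        key = (locus.genome_id, locus.locus_id)
        if key not in seen:
            seen.add(key)
            out.append(locus)
    return out


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # keep the lexicographically smaller id as the representative
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def merge_by_neighbourhood(
    loci: Sequence[LocusNeighbourhood],
    max_gene_diff: int = 2,
    function_groups: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Merge clusters whose loci share (nearly) the same flanking gene content.

    Two clusters merge when some pair of their loci has gene-content sets
    whose symmetric difference is <= ``max_gene_diff``; merging is transitive
    (union-find) and the merged cluster keeps the lexicographically smallest
    constituent id.  When ``function_groups`` maps cluster ids to predicted-
    function groups, only clusters in the same group may merge — a shared
    neighbourhood is evidence of orthology only between enzymes with similar
    predicted functions.  Loci must all come from one family.  Returns the
    old-id -> merged-id map for every cluster seen.
    """
    loci = list(loci)
    if not loci:
        return {}
    families = {l.family for l in loci if l.family}
    if len(families) > 1:
        raise ValueError(f"loci span multiple families: {sorted(families)}")
    cluster_ids = sorted({l.anchor_cluster_id for l in loci})
    uf = _UnionFind(cluster_ids)
    by_cluster: dict[str, list[LocusNeighbourhood]] = {}
    for l in loci:
        by_cluster.setdefault(l.anchor_cluster_id, []).append(l)
    for i, ca in enumerate(cluster_ids):
        for cb in cluster_ids[i + 1:]:
            if function_groups is not None and (
                function_groups.get(ca) != function_groups.get(cb)
            ):
                continue
            if any(
                len(la.gene_content ^ lb.gene_content) <= max_gene_diff
                for la in by_cluster[ca]
                for lb in by_cluster[cb]
            ):
                uf.union(ca, cb)
    # representative = smallest id in each component
    components: dict[str, list[str]] = {}
    for cid in cluster_ids:
        components.setdefault(uf.find(cid), []).append(cid)
    mapping = {}
    for members in components.values():
        rep = min(members)
        for cid in members:
            mapping[cid] = rep
    return mapping


# ---------------------------------------------------------------------------
# Neighbourhood extraction from annotated gene tables

GENE_TABLE_COLUMNS = ["genome_id", "contig_id", "gene_id", "orthologue_label", "start", "end", "strand"]


def read_gene_table(path) -> pd.DataFrame:
    """Per-genome gene table TSV (1-based inclusive coordinates)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: gene table missing columns {missing}")
    return df


def extract_neighbourhoods(
    gene_table: pd.DataFrame,
    anchors: Mapping[str, tuple[str, str]],
    window: int = 20_000,
) -> list[LocusNeighbourhood]:
    """Build locus neighbourhoods around anchor genes.

    ``anchors`` maps gene_id -> (cluster_id, family).  The gene content of a
    locus is the set of orthologue labels of genes overlapping the window
    ``window`` bp up- and downstream of the anchor gene on its contig, the
    anchor's own label excluded.
    """
    out = []
    indexed = gene_table.set_index("gene_id", drop=False)
    for gene_id, (cluster_id, family) in sorted(anchors.items()):
        if gene_id not in indexed.index:
            raise KeyError(f"anchor gene {gene_id!r} absent from gene table")
        row = indexed.loc[gene_id]
        lo, hi = int(row["start"]) - window, int(row["end"]) + window
        same_contig = gene_table[
            (gene_table["genome_id"] == row["genome_id"])
            & (gene_table["contig_id"] == row["contig_id"])
        ]
        flank = same_contig[(same_contig["end"] >= lo) & (same_contig["start"] <= hi)]
        content = frozenset(
            flank.loc[flank["gene_id"] != gene_id, "orthologue_label"].astype(str)
        ) - {str(row["orthologue_label"])}
        out.append(
            LocusNeighbourhood(
                locus_id=f"{row['contig_id']}:{int(row['start'])}-{int(row['end'])}",
                genome_id=str(row["genome_id"]),
                anchor_seq_id=gene_id,
                anchor_cluster_id=cluster_id,
                gene_content=content,
                family=family,
            )
        )
    return out


def write_cluster_map(clusters: Mapping[str, list[str]], path) -> None:
    """Cluster map TSV: cluster_id, seq_id, is_centroid."""
    with open(Path(path), "w", encoding="utf-8") as fh:
        fh.write("cluster_id\tseq_id\tis_centroid\n")
        for cid in sorted(clusters):
            for sid in clusters[cid]:
                fh.write(f"{cid}\t{sid}\t{int(sid == cid)}\n")
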