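"""Synthetic reference bundles, query proteomes and gold standards.

Every module in the package is testable without downloads: this generator
plants a family/cluster hierarchy with known identity bands and emits queries
whose annotation outcome is known by construction.

Sequences evolve by substitution only (no indels), so the exact-position
identity of a mutant to its source is controlled to the residue and, for
anchored mutants, equals the alignment identity the search engine measures.
Family ancestors are drawn independently and uniformly over the 20 canonical
residues (expected pairwise identity ~5%, far below any cross-family band);
cluster centroids are mutated from their family ancestor to the within-family
identity; members are mutated from their centroid to the within-cluster
identity.  The bundle is calibrated on generation so its thresholds satisfy
the hierarchy invariant, and planted queries are placed relative to those
*measured* thresholds — the generator never consults the annotator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .align import AlignerConfig, align_pair, search_best_hits
from .calibrate import ThresholdCalibrator
from .io import (
    HMG_STATUSES,
    LOCALIZATIONS,
    VALIDATION_STATUSES,
    ClusterRecord,
    ReferenceBundle,
    ReferenceSequence,
    ThresholdSet,
    TransporterReference,
)

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"  # canonical 20; X never generated

#: GH families associated with HMO and N-glycan utilization
GH_FAMILIES = [
    "GH2", "GH5_18", "GH18", "GH20", "GH29", "GH33", "GH38",
    "GH42", "GH85", "GH95", "GH112", "GH125", "GH136",
]

OUTCOMES = ("cluster_assigned", "cluster_undefined", "unannotated")

_TRANSPORTER_GENES = [
    ("FucP", "free fucose"),
    ("FL2", "fucosylated HMO"),
    ("GltA", "HMO"),
    ("NanB", "sialic acid"),
    ("MnaA", "N-glycan"),
]


@dataclass(frozen=True)
class SyntheticDesign:
    """Identity-band design of a synthetic reference database.

    Percent identities are exact-position fractions of the mutated sequence to
    its source: members sit at ``within_cluster_identity`` to their centroid,
    centroids at ``within_family_identity`` to the family ancestor, and
    distinct families are unrelated (pairwise identity far below
    ``cross_family_identity_max``).
    """

    n_families: int = 2
    clusters_per_family: int = 3
    members_per_cluster: int = 8
    sequence_length: int = 240
    within_cluster_identity: float = 90.0
    within_family_identity: float = 75.0
    cross_family_identity_max: float = 45.0
    n_decoys: int = 10
    n_transporters: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_families, self.clusters_per_family, self.members_per_cluster,
               self.sequence_length) < 1:
            raise ValueError("all counts must be positive")
        if not (
            self.within_cluster_identity >= self.within_family_identity
            > self.cross_family_identity_max
        ):
            raise ValueError(
                "identity bands must satisfy within_cluster >= within_family > cross_family_max"
            )
        if self.within_cluster_identity > 100 or self.cross_family_identity_max < 0:
            raise ValueError("identity bands must lie in [0, 100]")
        # substitution-only evolution: two sequences at identity a to a common
        # source can be no less than 2a - 100 identical to each other
        if 2 * self.within_cluster_identity - 100 < 0:
            raise ValueError("within_cluster_identity below 50 leaves no cluster signal")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth record for one generated sequence."""

    genome_id: str
    protein_id: str
    true_family: str | None
    true_cluster: str | None
    expected_outcome: str


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(RESIDUES), size=length))


def mutate_to_identity(sequence: str, target_identity: float,
                       rng: np.random.Generator) -> str:
    """Substitute uniformly chosen positions to hit an exact positional identity.

    The returned sequence matches the input at exactly
    ``round(L * target_identity / 100)`` positions; length is preserved and
    every substitution picks a residue different from the original.
    """
    if not (0.0 <= target_identity <= 100.0):
        raise ValueError("target_identity must be in [0, 100]")
    L = len(sequence)
    n_keep = round(L * target_identity / 100.0)
    return _substitute(sequence, L - n_keep, rng, protect_ends=0)


def _substitute(sequence: str, n_sub: int, rng: np.random.Generator,
                protect_ends: int = 0) -> str:
    """Substitute ``n_sub`` interior positions, optionally sparing both ends.

    Sparing the terminal residues keeps the optimal local alignment of mutant
    vs. source full-length, so positional identity equals alignment identity.
    """
    L = len(sequence)
    lo, hi = protect_ends, L - protect_ends
    candidates = np.arange(lo, hi)
    if n_sub > len(candidates):
        raise ValueError("not enough mutable positions")
    positions = rng.choice(candidates, size=n_sub, replace=False)
    out = list(sequence)
    for p in positions:
        choices = [r for r in RESIDUES if r != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


def generate_reference_db(
    design: SyntheticDesign,
    aligner: AlignerConfig | None = None,
) -> tuple[ReferenceBundle, list[SyntheticTruth]]:
    """Generate and calibrate a synthetic bundle; returns it with member truths.

    Cluster metadata cycles through the declared validation/HMG/localization
    vocabularies so every enumerated value is exercised.  Thresholds are
    fitted with :class:`~ghannot.calibrate.ThresholdCalibrator` on the
    generated sequences, so the bundle always satisfies the cluster >= family
    hierarchy.
    """
    rng = np.random.default_rng(design.seed)
    families = [
        GH_FAMILIES[i] if i < len(GH_FAMILIES) else f"GHX{i}"
        for i in range(design.n_families)
    ]
    sequences: list[ReferenceSequence] = []
    cluster_meta: list[dict] = []
    truths: list[SyntheticTruth] = []
    for fi, family in enumerate(families):
        ancestor = random_sequence(design.sequence_length, rng)
        for ci in range(design.clusters_per_family):
            cluster_id = f"{family}_C{ci + 1}"
            centroid = mutate_to_identity(ancestor, design.within_family_identity, rng)
            for mi in range(design.members_per_cluster):
                seq = mutate_to_identity(centroid, design.within_cluster_identity, rng)
                seq_id = f"{cluster_id}_m{mi + 1:03d}"
                genome_id = f"g{mi + 1:03d}"
                sequences.append(
                    ReferenceSequence(
                        seq_id=seq_id,
                        genome_id=genome_id,
                        family=family,
                        sequence=seq,
                        cluster_id=cluster_id,
                    )
                )
                truths.append(
                    SyntheticTruth(genome_id, seq_id, family, cluster_id, "cluster_assigned")
                )
            k = fi * design.clusters_per_family + ci
            cluster_meta.append(
                {
                    "cluster_id": cluster_id,
                    "family": family,
                    "enzyme_label": f"{family} synthetic enzyme {ci + 1}",
                    "validation_status": VALIDATION_STATUSES[k % 3],
                    "hmg_status": HMG_STATUSES[k % 3],
                    "localization": LOCALIZATIONS[k % 3],
                    "member_count": design.members_per_cluster,
                }
            )
    transporters = [
        TransporterReference(
            seq_id=f"T{i + 1:02d}",
            transporter_gene=_TRANSPORTER_GENES[i % len(_TRANSPORTER_GENES)][0],
            substrate_class=_TRANSPORTER_GENES[i % len(_TRANSPORTER_GENES)][1],
            sequence=random_sequence(design.sequence_length, rng),
        )
        for i in range(design.n_transporters)
    ]

    # provisional bundle for calibration (thresholds not yet known)
    provisional = ReferenceBundle(
        sequences,
        [ClusterRecord(**m, identity_threshold=100.0) for m in cluster_meta],
        ThresholdSet(),
        transporters,
    )
    calibrator = ThresholdCalibrator(aligner=aligner).fit(provisional)
    thresholds = calibrator.thresholds_
    clusters = [
        ClusterRecord(**m, identity_threshold=thresholds.cluster_thresholds[m["cluster_id"]])
        for m in cluster_meta
    ]
    return ReferenceBundle(sequences, clusters, thresholds, transporters), truths


def _achievable_band_identity(L: int, lower: float, upper: float) -> float | None:
    """Best achievable positional identity strictly inside [lower, upper).

    Identities are multiples of 100/L; returns the one maximizing the margin
    to both band edges, or None when the band holds no achievable point with
    a margin of at least 0.2 points to the upper edge.
    """
    candidates = [
        100.0 * k / L
        for k in range(L + 1)
        if lower <= 100.0 * k / L < upper - 0.2
    ]
    if not candidates:
        return None
    return max(candidates, key=lambda v: min(v - lower, upper - v))


def generate_query_set(
    bundle: ReferenceBundle,
    truth_design: dict[str, int],
    thresholds: ThresholdSet | None = None,
    rng: np.random.Generator | None = None,
    genome_id: str = "synthetic_genome",
    aligner: AlignerConfig | None = None,
) -> tuple[list[tuple[str, str]], list[SyntheticTruth], list]:
    """Plant queries with known annotation outcomes against a calibrated bundle.

    ``truth_design`` maps outcome -> count over ``cluster_assigned`` (mutant of
    a member above its cluster threshold), ``cluster_undefined`` (identity
    between the family and cluster thresholds; skipped with a warning when no
    cluster leaves an achievable band) and ``unannotated`` (random decoys
    verified post hoc to have no qualifying hit).  Returns the query
    (protein_id, sequence) list, the truth records and gold-standard records
    for the cluster-assigned queries.
    """
    from .benchmark import GoldStandardRecord

    thresholds = thresholds or bundle.thresholds
    rng = rng or np.random.default_rng(0)
    aligner = aligner or AlignerConfig()
    anchor = 5  # unmutated terminal residues keep alignments full-length
    queries: list[tuple[str, str]] = []
    truths: list[SyntheticTruth] = []
    gold: list[GoldStandardRecord] = []
    unknown = set(truth_design) - set(OUTCOMES)
    if unknown:
        raise ValueError(f"unknown outcomes requested: {sorted(unknown)}")

    members_by_cluster = {
        c.cluster_id: bundle.sequences_of_cluster(c.cluster_id) for c in bundle.clusters
    }
    cluster_ids = [c.cluster_id for c in bundle.clusters if members_by_cluster[c.cluster_id]]
    family_of = {c.cluster_id: c.family for c in bundle.clusters}

    n_assigned = truth_design.get("cluster_assigned", 0)
    for i in range(n_assigned):
        cid = cluster_ids[i % len(cluster_ids)]
        members = members_by_cluster[cid]
        source = members[i % len(members)]
        clu_thr = thresholds.cluster_thresholds[cid]
        target = max(clu_thr + 3.0, (clu_thr + 100.0) / 2.0)
        target = min(target, 100.0)
        L = len(source.sequence)
        n_sub = L - round(L * target / 100.0)
        seq = _planted_mutant(source.sequence, n_sub, rng, anchor, aligner,
                              lambda pid: pid >= clu_thr,
                              thresholds.coverage_cutoff, thresholds.bitscore_cutoff)
        pid = f"q_assigned_{i + 1:03d}"
        queries.append((pid, seq))
        truths.append(SyntheticTruth(genome_id, pid, family_of[cid], cid, "cluster_assigned"))
        gold.append(GoldStandardRecord(genome_id, cid, pid))

    n_undef = truth_design.get("cluster_undefined", 0)
    if n_undef:
        # clusters with a usable gap between the family and cluster thresholds
        usable = []
        for cid in cluster_ids:
            fam_thr = thresholds.family_thresholds[family_of[cid]]
            clu_thr = thresholds.cluster_thresholds[cid]
            L = len(members_by_cluster[cid][0].sequence)
            v = _achievable_band_identity(L, fam_thr, clu_thr)
            if v is not None:
                usable.append((cid, v, fam_thr, clu_thr))
        if not usable:
            warnings.warn(
                "cluster_undefined outcome skipped: no cluster threshold exceeds "
                "its family threshold by an achievable margin"
            )
        else:
            usable.sort(key=lambda u: -(min(u[1] - u[2], u[3] - u[1])))
            for i in range(n_undef):
                cid, v, fam_thr, clu_thr = usable[i % len(usable)]
                source = members_by_cluster[cid][i % len(members_by_cluster[cid])]
                L = len(source.sequence)
                n_sub = L - round(L * v / 100.0)
                seq = _planted_mutant(
                    source.sequence, n_sub, rng, anchor, aligner,
                    lambda pid, lo=fam_thr, hi=clu_thr: lo <= pid < hi,
                    thresholds.coverage_cutoff, thresholds.bitscore_cutoff,
                )
                pid = f"q_undefined_{i + 1:03d}"
                queries.append((pid, seq))
                truths.append(
                    SyntheticTruth(genome_id, pid, family_of[cid], None, "cluster_undefined")
                )

    n_decoys = truth_design.get("unannotated", 0)
    for i in range(n_decoys):
        L = len(bundle.sequences[0].sequence)
        seq = _verified_decoy(L, bundle, thresholds, rng, aligner)
        pid = f"q_decoy_{i + 1:03d}"
        queries.append((pid, seq))
        truths.append(SyntheticTruth(genome_id, pid, None, None, "unannotated"))
    return queries, truths, gold


def _planted_mutant(source: str, n_sub: int, rng, anchor: int,
                    aligner: AlignerConfig, identity_ok,
                    min_coverage: float = 0.5, min_bitscore: float = 200.0,
                    max_tries: int = 20) -> str:
    """Mutate with anchored ends; verify the planted hit passes every gate.

    The verification aligns the mutant back to its source only (never to the
    whole database): identity in the requested band, coverage and bitscore
    above the annotator's gates.  Short sequences at low band identities can
    make the bitscore gate unreachable; that is reported rather than papered
    over.
    """
    last = None
    for _ in range(max_tries):
        seq = _substitute(source, n_sub, rng, protect_ends=anchor)
        hit = align_pair(seq, source, aligner)
        if hit is not None and identity_ok(hit.percent_identity) and (
            hit.query_coverage >= min_coverage
        ):
            if hit.bitscore >= min_bitscore:
                return seq
            last = hit
    if last is not None:
        raise RuntimeError(
            f"planted mutant cannot reach the {min_bitscore}-bit gate "
            f"(got {last.bitscore:.0f} bits at length {len(source)}); "
            "use longer sequences or a higher identity band"
        )
    raise RuntimeError("could not plant a mutant in the requested identity band")


def _verified_decoy(L: int, bundle: ReferenceBundle, thresholds: ThresholdSet,
                    rng, aligner: AlignerConfig, max_tries: int = 20) -> str:
    family_of_seq = {s.seq_id: s.family for s in bundle.sequences}
    for _ in range(max_tries):
        seq = random_sequence(L, rng)
        hits = search_best_hits([("decoy", seq)], bundle.sequences, aligner)["decoy"]
        qualifying = any(
            h.query_coverage >= thresholds.coverage_cutoff
            and h.bitscore >= thresholds.bitscore_cutoff
            and h.percent_identity
            >= thresholds.family_thresholds.get(family_of_seq[h.target_id], 101.0)
            for h in hits
        )
        if not qualifying:
            return seq
    raise RuntimeError("could not generate a decoy without qualifying hits")


def write_query_fasta(queries: list[tuple[str, str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid, seq in queries:
            fh.write(f">{pid}\n{seq}\n")


def write_truth_tsv(truths: list[SyntheticTruth], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("genome_id\tprotein_id\ttrue_family\ttrue_cluster\texpected_outcome\n")
        for t in truths:
            fh.write(
                f"{t.genome_id}\t{t.protein_id}\t{t.true_family or ''}\t"
                f"{t.true_cluster or ''}\t{t.expected_outcome}\n"
            )


def write_gold_tsv(gold, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("genome_id\tprotein_id\texpected_label\n")
        for g in gold:
            fh.write(f"{g.genome_id}\t{g.protein_id or ''}\t{g.expected_label}\n")
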