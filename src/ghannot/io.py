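"""Data model and I/O for the reference bundle and query-side inputs.

A reference bundle is one directory with fixed file names:

* ``sequences.faa``   — curated reference proteins; each FASTA header carries
  ``seq_id genome=<id> family=<GH family> [cluster=<cluster_id>]``
* ``clusters.tsv``    — one row per functional cluster (metadata + threshold)
* ``thresholds.tsv``  — family/cluster identity thresholds and global cutoffs
* ``transporters.faa`` / ``transporters.tsv`` — optional transporter references

TSVs are tab-separated UTF-8 with a header row; ``#`` comment lines are
ignored.  Sequences are parsed case-insensitively and stored uppercase; any
letter outside the 20 canonical residues plus X is rejected because
substitution-matrix scoring is undefined for it.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .align import ALPHABET

VALIDATION_STATUSES = ("experimentally_validated", "putative", "hypothetical")
HMG_STATUSES = ("yes", "no", "unknown")
LOCALIZATIONS = ("intracellular", "extracellular", "unknown")

#: sentinel emitted when a query passes the family but fails the cluster threshold
CLUSTER_UNDEFINED = "cluster undefined"

_ALPHABET_SET = set(ALPHABET)


class BundleLoadError(OSError):
    """A required bundle file is missing or unreadable."""


class BundleValidationError(ValueError):
    """Cross-reference or field validation failed; ``errors`` lists offenders."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


def _check_sequence(seq_id: str, sequence: str) -> str:
    if not sequence:
        raise BundleValidationError([f"{seq_id}: empty sequence"])
    seq = sequence.upper()
    bad = set(seq) - _ALPHABET_SET
    if bad:
        raise BundleValidationError(
            [f"{seq_id}: non-canonical residues {sorted(bad)}"]
        )
    return seq


@dataclass(frozen=True)
class ReferenceSequence:
    """One curated reference protein with its family/cluster labels."""

    seq_id: str
    genome_id: str
    family: str
    sequence: str
    cluster_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_sequence(self.seq_id, self.sequence))


@dataclass(frozen=True)
class ClusterRecord:
    """Per-cluster curation metadata and calibrated identity threshold."""

    cluster_id: str
    family: str
    enzyme_label: str
    validation_status: str
    hmg_status: str
    localization: str
    member_count: int
    identity_threshold: float

    def __post_init__(self) -> None:
        errors = []
        if self.validation_status not in VALIDATION_STATUSES:
            errors.append(
                f"{self.cluster_id}: validation_status {self.validation_status!r} "
                f"not in {VALIDATION_STATUSES}"
            )
        if self.hmg_status not in HMG_STATUSES:
            errors.append(
                f"{self.cluster_id}: hmg_status {self.hmg_status!r} not in {HMG_STATUSES}"
            )
        if self.localization not in LOCALIZATIONS:
            errors.append(
                f"{self.cluster_id}: localization {self.localization!r} not in {LOCALIZATIONS}"
            )
        if self.member_count < 0:
            errors.append(f"{self.cluster_id}: negative member_count")
        if not (0.0 <= self.identity_threshold <= 100.0):
            errors.append(f"{self.cluster_id}: identity_threshold outside [0, 100]")
        if errors:
            raise BundleValidationError(errors)


@dataclass(frozen=True)
class TransporterReference:
    """One curated transporter protein (e.g. FucP, FL2) with its substrate class."""

    seq_id: str
    transporter_gene: str
    substrate_class: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_sequence(self.seq_id, self.sequence))


@dataclass
class ThresholdSet:
    """Per-family and per-cluster percent-identity cutoffs plus global gates."""

    family_thresholds: dict[str, float] = field(default_factory=dict)
    cluster_thresholds: dict[str, float] = field(default_factory=dict)
    coverage_cutoff: float = 0.50
    bitscore_cutoff: float = 200.0

    def __post_init__(self) -> None:
        for name, value in {**self.family_thresholds, **self.cluster_thresholds}.items():
            if not (0.0 <= value <= 100.0):
                raise ValueError(f"threshold for {name!r} outside [0, 100]")
        if not (0.0 < self.coverage_cutoff <= 1.0):
            raise ValueError("coverage_cutoff must be in (0, 1]")
        if self.bitscore_cutoff < 0:
            raise ValueError("bitscore_cutoff must be non-negative")


@dataclass(frozen=True)
class SampleEntry:
    genome_id: str
    fasta_path: str
    metadata: Mapping[str, str] = field(default_factory=dict)


@dataclass
class SampleSheet:
    """Batch input: genome identifiers, proteome paths and free metadata."""

    entries: list[SampleEntry]

    def __post_init__(self) -> None:
        ids = [e.genome_id for e in self.entries]
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        if dupes:
            raise ValueError(f"duplicate genome_id in sample sheet: {dupes}")


@dataclass
class ReferenceBundle:
    """Loaded, cross-referenced reference database."""

    sequences: list[ReferenceSequence]
    clusters: list[ClusterRecord]
    thresholds: ThresholdSet
    transporters: list[TransporterReference] = field(default_factory=list)

    @property
    def families(self) -> list[str]:
        return sorted({s.family for s in self.sequences})

    @property
    def cluster_by_id(self) -> dict[str, ClusterRecord]:
        return {c.cluster_id: c for c in self.clusters}

    def sequences_of_cluster(self, cluster_id: str) -> list[ReferenceSequence]:
        return [s for s in self.sequences if s.cluster_id == cluster_id]


# ---------------------------------------------------------------------------
# TSV plumbing


def _read_tsv(path: Path) -> list[dict[str, str]]:
    with open(path, encoding="utf-8", newline="") as fh:
        rows = [line for line in fh if not line.startswith("#")]
    reader = csv.DictReader(rows, delimiter="\t")
    if reader.fieldnames is None:
        raise BundleLoadError(f"{path}: empty file, header row required")
    return list(reader)


def _write_tsv(path: Path, fieldnames: list[str], rows: Iterable[Mapping]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames, delimiter="\t", lineterminator="\n")
        writer.writeheader()
        for row in rows:
            writer.writerow(row)


# ---------------------------------------------------------------------------
# FASTA


def read_proteome(fasta_path) -> list[tuple[str, str]]:
    """Read a query proteome FASTA into (protein_id, sequence) pairs.

    Order is preserved; trailing ``*`` stop characters are stripped; duplicate
    ids and empty files are errors.
    """
    path = Path(fasta_path)
    if not path.exists():
        raise BundleLoadError(f"proteome FASTA not found: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    out: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    for rec in records:
        seq = str(rec.seq).upper().rstrip("*")
        if not rec.id or not seq:
            raise ValueError(f"{path}: record with empty id or sequence")
        seen[rec.id] = seen.get(rec.id, 0) + 1
        out.append((rec.id, seq))
    dupes = sorted(pid for pid, n in seen.items() if n > 1)
    if dupes:
        raise ValueError(f"{path}: duplicate protein ids {dupes}")
    return out


def _parse_reference_header(description: str) -> tuple[str, dict[str, str]]:
    tokens = description.split()
    seq_id = tokens[0]
    attrs = {}
    for tok in tokens[1:]:
        if "=" in tok:
            key, _, value = tok.partition("=")
            attrs[key] = value
    return seq_id, attrs


# ---------------------------------------------------------------------------
# Bundle load / write


def load_reference_bundle(directory_path) -> ReferenceBundle:
    """Load and cross-validate a reference bundle directory.

    Raises :class:`BundleLoadError` when a required file is missing and
    :class:`BundleValidationError` (listing every offender) when
    cross-references fail: dangling cluster ids, duplicate seq ids, or a
    ``member_count`` that disagrees with the FASTA.
    """
    directory = Path(directory_path)
    seq_path = directory / "sequences.faa"
    clu_path = directory / "clusters.tsv"
    thr_path = directory / "thresholds.tsv"
    for p in (seq_path, clu_path, thr_path):
        if not p.exists():
            raise BundleLoadError(f"missing bundle file: {p}")

    sequences: list[ReferenceSequence] = []
    errors: list[str] = []
    seen_ids: set[str] = set()
    for rec in SeqIO.parse(str(seq_path), "fasta"):
        seq_id, attrs = _parse_reference_header(rec.description)
        if seq_id in seen_ids:
            errors.append(f"duplicate seq_id: {seq_id}")
            continue
        seen_ids.add(seq_id)
        try:
            sequences.append(
                ReferenceSequence(
                    seq_id=seq_id,
                    genome_id=attrs.get("genome", ""),
                    family=attrs.get("family", ""),
                    sequence=str(rec.seq).rstrip("*"),
                    cluster_id=attrs.get("cluster") or None,
                )
            )
        except BundleValidationError as exc:
            errors.extend(exc.errors)

    clusters: list[ClusterRecord] = []
    for row in _read_tsv(clu_path):
        try:
            clusters.append(
                ClusterRecord(
                    cluster_id=row["cluster_id"],
                    family=row["family"],
                    enzyme_label=row["enzyme_label"],
                    validation_status=row["validation_status"],
                    hmg_status=row["hmg_status"],
                    localization=row["localization"],
                    member_count=int(row["member_count"]),
                    identity_threshold=float(row["identity_threshold"]),
                )
            )
        except BundleValidationError as exc:
            errors.extend(exc.errors)
        except (KeyError, ValueError) as exc:
            errors.append(f"clusters.tsv: malformed row {row!r} ({exc})")

    thresholds = _read_thresholds(thr_path)

    transporters: list[TransporterReference] = []
    tfa = directory / "transporters.faa"
    ttsv = directory / "transporters.tsv"
    if tfa.exists() and ttsv.exists():
        meta = {row["seq_id"]: row for row in _read_tsv(ttsv)}
        for rec in SeqIO.parse(str(tfa), "fasta"):
            row = meta.get(rec.id)
            if row is None:
                errors.append(f"transporter {rec.id} missing from transporters.tsv")
                continue
            transporters.append(
                TransporterReference(
                    seq_id=rec.id,
                    transporter_gene=row["transporter_gene"],
                    substrate_class=row.get("substrate_class", ""),
                    sequence=str(rec.seq).rstrip("*"),
                )
            )
        tids = [t.seq_id for t in transporters]
        dupes = sorted({x for x in tids if tids.count(x) > 1})
        errors.extend(f"duplicate transporter seq_id: {x}" for x in dupes)

    # cross-references
    known_clusters = {c.cluster_id for c in clusters}
    for s in sequences:
        if s.cluster_id is not None and s.cluster_id not in known_clusters:
            errors.append(f"{s.seq_id}: dangling cluster_id {s.cluster_id!r}")
    counts: dict[str, int] = {}
    for s in sequences:
        if s.cluster_id is not None:
            counts[s.cluster_id] = counts.get(s.cluster_id, 0) + 1
    for c in clusters:
        actual = counts.get(c.cluster_id, 0)
        if actual != c.member_count:
            errors.append(
                f"{c.cluster_id}: member_count {c.member_count} != {actual} sequences in FASTA"
            )
    if errors:
        raise BundleValidationError(sorted(errors))
    return ReferenceBundle(sequences, clusters, thresholds, transporters)


def _read_thresholds(path: Path) -> ThresholdSet:
    family: dict[str, float] = {}
    cluster: dict[str, float] = {}
    coverage = 0.50
    bitscore = 200.0
    for row in _read_tsv(path):
        scope, label, value = row["scope"], row["label"], float(row["value"])
        if scope == "family":
            family[label] = value
        elif scope == "cluster":
            cluster[label] = value
        elif scope == "global" and label == "coverage_cutoff":
            coverage = value
        elif scope == "global" and label == "bitscore_cutoff":
            bitscore = value
        else:
            raise BundleValidationError([f"thresholds.tsv: unknown row {row!r}"])
    return ThresholdSet(family, cluster, coverage_cutoff=coverage, bitscore_cutoff=bitscore)


def write_reference_bundle(bundle: ReferenceBundle, directory_path) -> Path:
    """Write a bundle directory that :func:`load_reference_bundle` round-trips."""
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "sequences.faa", "w", encoding="utf-8") as fh:
        for s in bundle.sequences:
            attrs = f"genome={s.genome_id} family={s.family}"
            if s.cluster_id is not None:
                attrs += f" cluster={s.cluster_id}"
            fh.write(f">{s.seq_id} {attrs}\n{s.sequence}\n")
    _write_tsv(
        directory / "clusters.tsv",
        [
            "cluster_id",
            "family",
            "enzyme_label",
            "validation_status",
            "hmg_status",
            "localization",
            "member_count",
            "identity_threshold",
        ],
        [
            {
                "cluster_id": c.cluster_id,
                "family": c.family,
                "enzyme_label": c.enzyme_label,
                "validation_status": c.validation_status,
                "hmg_status": c.hmg_status,
                "localization": c.localization,
                "member_count": c.member_count,
                "identity_threshold": format(c.identity_threshold, ".17g"),
            }
            for c in bundle.clusters
        ],
    )
    rows = [
        {"scope": "global", "label": "coverage_cutoff", "value": format(bundle.thresholds.coverage_cutoff, ".17g")},
        {"scope": "global", "label": "bitscore_cutoff", "value": format(bundle.thresholds.bitscore_cutoff, ".17g")},
    ]
    rows += [
        {"scope": "family", "label": fam, "value": format(v, ".17g")}
        for fam, v in sorted(bundle.thresholds.family_thresholds.items())
    ]
    rows += [
        {"scope": "cluster", "label": cid, "value": format(v, ".17g")}
        for cid, v in sorted(bundle.thresholds.cluster_thresholds.items())
    ]
    _write_tsv(directory / "thresholds.tsv", ["scope", "label", "value"], rows)
    if bundle.transporters:
        with open(directory / "transporters.faa", "w", encoding="utf-8") as fh:
            for t in bundle.transporters:
                fh.write(f">{t.seq_id}\n{t.sequence}\n")
        _write_tsv(
            directory / "transporters.tsv",
            ["seq_id", "transporter_gene", "substrate_class"],
            [
                {
                    "seq_id": t.seq_id,
                    "transporter_gene": t.transporter_gene,
                    "substrate_class": t.substrate_class,
                }
                for t in bundle.transporters
            ],
        )
    return directory


# ---------------------------------------------------------------------------
# Thresholds & sample sheets


def validate_threshold_hierarchy(
    thresholds: ThresholdSet, clusters: list[ClusterRecord]
) -> list[tuple[str, float, float]]:
    """Clusters whose identity threshold is laxer than their family's.

    Returns ``(cluster_id, cluster_threshold, family_threshold)`` triples;
    an empty list means the hierarchy ("cluster at least as stringent as
    family") holds.
    """
    violations = []
    for c in clusters:
        if c.family not in thresholds.family_thresholds:
            raise KeyError(f"cluster {c.cluster_id}: no family threshold for {c.family!r}")
        fam_thr = thresholds.family_thresholds[c.family]
        clu_thr = thresholds.cluster_thresholds.get(c.cluster_id, c.identity_threshold)
        if clu_thr < fam_thr:
            violations.append((c.cluster_id, clu_thr, fam_thr))
    return violations


def read_sample_sheet(path) -> SampleSheet:
    """Read a batch sample sheet TSV: genome_id, fasta_path, free metadata columns."""
    rows = _read_tsv(Path(path))
    base = Path(path).parent
    entries = []
    for row in rows:
        genome_id = row.pop("genome_id")
        fasta = row.pop("fasta_path")
        fasta_path = fasta if os.path.isabs(fasta) else str(base / fasta)
        entries.append(SampleEntry(genome_id, fasta_path, dict(row)))
    return SampleSheet(entries)


def read_genome_metadata(path) -> "pandas.DataFrame":  # noqa: F821
    """Genome metadata TSV (genome_id + free columns), indexed by genome_id."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "genome_id" not in df.columns:
        raise ValueError(f"{path}: genome metadata requires a genome_id column")
    return df.set_index("genome_id")
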