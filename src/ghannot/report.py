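"""Copy-number matrices, annotation tables and the three heatmaps.

The reporting level is ``family`` (GH family of every annotation), ``enzyme``
(cluster enzyme labels) or ``cluster`` (functional cluster ids).  The HMG
filter applies at the cluster level: ``hmg_unknown`` (default) keeps clusters
with HMG-association status yes or unknown, ``hmg_only`` keeps yes only, and
``all_genes`` keeps everything including "cluster undefined" as its own row.
The filter shapes reporting only — assignment upstream is always competitive
against the full database.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import pandas as pd

from .annotate import Annotation, TransporterAnnotation
from .io import CLUSTER_UNDEFINED

LEVELS = ("family", "enzyme", "cluster")

ANNOTATION_COLUMNS = [
    "genome_id",
    "protein_id",
    "family",
    "cluster_id",
    "enzyme_label",
    "validation_status",
    "hmg_status",
    "localization",
    "percent_identity",
    "query_coverage",
    "bitscore",
    "alignment_length",
]

TRANSPORTER_COLUMNS = [
    "genome_id",
    "protein_id",
    "transporter_gene",
    "substrate_class",
    "percent_identity",
    "query_coverage",
    "bitscore",
    "alignment_length",
]


@dataclass
class CopyNumberMatrix:
    """Genomes x labels count table (rows = labels, columns = genome ids)."""

    level: str
    data: pd.DataFrame  # integer counts

    @property
    def rows(self) -> list[str]:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def total(self) -> int:
        return int(self.data.to_numpy().sum())


def _keep(a: Annotation, level: str, hmg_filter: str) -> bool:
    if level == "family":
        return True
    if level == "enzyme":
        return a.cluster_defined and bool(a.enzyme_label)
    # cluster level
    if hmg_filter == "all_genes":
        return True
    if not a.cluster_defined:
        return False
    wanted = ("yes",) if hmg_filter == "hmg_only" else ("yes", "unknown")
    return a.hmg_status in wanted


def _label(a: Annotation, level: str) -> str:
    if level == "family":
        return a.family
    if level == "enzyme":
        return a.enzyme_label or CLUSTER_UNDEFINED
    return a.cluster_id


def build_matrix(
    annotations: Sequence[Annotation],
    level: str = "cluster",
    hmg_filter: str = "hmg_unknown",
    genomes: Sequence[str] | None = None,
) -> CopyNumberMatrix:
    """Count annotations per (label, genome) at the requested level.

    ``genomes`` forces the column set (zero columns for genomes without
    retained annotations); by default columns are the genomes present.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    kept = [a for a in annotations if _keep(a, level, hmg_filter)]
    genome_ids = sorted(genomes) if genomes is not None else sorted({a.genome_id for a in kept})
    labels = sorted({_label(a, level) for a in kept})
    data = pd.DataFrame(0, index=labels, columns=genome_ids, dtype=int)
    for a in kept:
        if a.genome_id in data.columns:
            data.loc[_label(a, level), a.genome_id] += 1
    data.index.name = level
    return CopyNumberMatrix(level=level, data=data)


def write_matrix(matrix: CopyNumberMatrix, path) -> None:
    matrix.data.to_csv(Path(path), sep="\t")


def read_matrix(path, level: str) -> CopyNumberMatrix:
    data = pd.read_csv(Path(path), sep="\t", index_col=0)
    data.index.name = level
    return CopyNumberMatrix(level=level, data=data.astype(int))


def _annotation_row(a: Annotation) -> dict:
    return {
        "genome_id": a.genome_id,
        "protein_id": a.protein_id,
        "family": a.family,
        "cluster_id": a.cluster_id,
        "enzyme_label": a.enzyme_label or "",
        "validation_status": a.validation_status or "",
        "hmg_status": a.hmg_status or "",
        "localization": a.localization or "",
        "percent_identity": f"{a.hit.percent_identity:.3f}",
        "query_coverage": f"{a.hit.query_coverage:.4f}",
        "bitscore": f"{a.hit.bitscore:.2f}",
        "alignment_length": a.hit.alignment_length,
    }


def _transporter_row(a: TransporterAnnotation) -> dict:
    return {
        "genome_id": a.genome_id,
        "protein_id": a.protein_id,
        "transporter_gene": a.transporter_gene,
        "substrate_class": a.substrate_class,
        "percent_identity": f"{a.hit.percent_identity:.3f}",
        "query_coverage": f"{a.hit.query_coverage:.4f}",
        "bitscore": f"{a.hit.bitscore:.2f}",
        "alignment_length": a.hit.alignment_length,
    }


def write_annotation_tables(
    annotations: Sequence[Annotation],
    transporter_annotations: Sequence[TransporterAnnotation],
    out_dir,
    hmg_filter: str = "hmg_unknown",
) -> Path:
    """Write per-genome and merged annotation tables plus copy-number matrices.

    Layout: ``tables/`` holds annotations.tsv, transporters.tsv,
    annotations_<genome>.tsv and matrix_{family,enzyme,cluster}.tsv.  Row order
    is deterministic (genome_id, protein_id) so reruns are byte-identical.
    """
    out = Path(out_dir)
    tables = out / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    rows = sorted(
        (_annotation_row(a) for a in annotations),
        key=lambda r: (r["genome_id"], r["protein_id"]),
    )
    merged = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    merged.to_csv(tables / "annotations.tsv", sep="\t", index=False)
    for genome_id, group in merged.groupby("genome_id", sort=True):
        group.to_csv(tables / f"annotations_{genome_id}.tsv", sep="\t", index=False)
    trows = sorted(
        (_transporter_row(a) for a in transporter_annotations),
        key=lambda r: (r["genome_id"], r["protein_id"]),
    )
    pd.DataFrame(trows, columns=TRANSPORTER_COLUMNS).to_csv(
        tables / "transporters.tsv", sep="\t", index=False
    )
    genomes = sorted({a.genome_id for a in annotations})
    for level in LEVELS:
        matrix = build_matrix(annotations, level, hmg_filter, genomes=genomes)
        write_matrix(matrix, tables / f"matrix_{level}.tsv")
    return tables


_HMG_ROWBAR_COLORS = {
    "yes": "#1b7837",
    "no": "#762a83",
    "unknown": "#b8b8b8",
    "undefined": "#f0f0f0",
}


def _categorical_colors(series: pd.Series) -> tuple[pd.Series, dict]:
    palette = plt.get_cmap("tab10")
    categories = sorted(series.dropna().unique())
    lut = {c: palette(i % 10) for i, c in enumerate(categories)}
    return series.map(lut), lut


def render_heatmaps(
    matrices: Mapping[str, CopyNumberMatrix],
    out_dir,
    genome_metadata: pd.DataFrame | None = None,
    hmg_by_cluster: Mapping[str, str] | None = None,
) -> list[Path]:
    """Render one white-to-blue heatmap per level (SVG + PNG) with its TSV.

    Genome metadata columns become column annotation bars; the cluster-level
    heatmap carries a row bar for HMG-association status.  Columns (and rows)
    are hierarchically clustered with average linkage on Euclidean distance
    whenever there are at least two of them.  Metadata genomes that do not
    match matrix columns trigger a warning and are rendered without bars.
    """
    import warnings

    import seaborn as sns

    out = Path(out_dir)
    viz = out / "visualizations"
    viz.mkdir(parents=True, exist_ok=True)
    plt.rcParams["svg.hashsalt"] = "ghannot"
    written: list[Path] = []
    for level, matrix in matrices.items():
        df = matrix.data.astype(float)
        if df.empty:
            continue
        col_colors = None
        if genome_metadata is not None and not genome_metadata.empty:
            missing = [g for g in df.columns if g not in genome_metadata.index]
            if missing:
                warnings.warn(
                    f"genomes without metadata rendered without annotation bars: {missing}"
                )
            aligned = genome_metadata.reindex(df.columns)
            bars = {}
            for col in aligned.columns:
                colors, _ = _categorical_colors(aligned[col])
                bars[col] = colors
            if bars:
                col_colors = pd.DataFrame(bars)
        row_colors = None
        if level == "cluster" and hmg_by_cluster is not None:
            status = pd.Series(
                [
                    "undefined" if r == CLUSTER_UNDEFINED else hmg_by_cluster.get(r, "unknown")
                    for r in df.index
                ],
                index=df.index,
                name="HMG",
            )
            row_colors = status.map(_HMG_ROWBAR_COLORS)
        grid = sns.clustermap(
            df,
            cmap="Blues",
            method="average",
            metric="euclidean",
            col_cluster=df.shape[1] > 1,
            row_cluster=df.shape[0] > 1,
            col_colors=col_colors,
            row_colors=row_colors,
            linewidths=0.3,
            linecolor="#dddddd",
            figsize=(max(4, 0.6 * df.shape[1] + 3), max(4, 0.3 * df.shape[0] + 2)),
        )
        grid.ax_heatmap.set_xlabel("genome")
        grid.ax_heatmap.set_ylabel(level)
        for ext in ("svg", "png"):
            path = viz / f"heatmap_{level}.{ext}"
            grid.savefig(path, dpi=200, metadata={"Date": None} if ext == "svg" else None)
            written.append(path)
        plt.close(grid.figure)
        tsv = viz / f"heatmap_{level}.tsv"
        write_matrix(matrix, tsv)
        written.append(tsv)
    return written
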