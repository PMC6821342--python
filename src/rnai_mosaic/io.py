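"""File formats: variant TSV/VCF, coverage tracks, TIFF stacks, mosaic CSV.

Plain-text conventions throughout: variant tables are one TSV per mutant
with 1-based positions; coverage is BED-like TSV with half-open 0-based
starts (converted to 1-based closed internally); stacks are single-channel
multi-page TIFFs with voxel sizes in a JSON sidecar; mosaic matrices are
CSV with one row per animal and per-nucleus states comma-joined within a
cell ("on,on").
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imaging import VoxelGrid
from .mosaicism import LineageTable, MosaicMatrix, default_lineage
from .variants import CoverageTrack, MutantVariantSet, VariantCall, VariantRecordError

VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "qual", "depth", "alt_fraction", "gene_id", "effect",
]


def write_variant_tsv(mutant: MutantVariantSet, path: str | Path) -> None:
    rows = [
        {
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "qual": v.qual,
            "depth": v.depth,
            "alt_fraction": v.alt_fraction,
            "gene_id": v.gene_id if v.gene_id is not None else ".",
            "effect": v.effect,
        }
        for v in mutant.variants
    ]
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variant_tsv(path: str | Path, mutant_id: str | None = None) -> MutantVariantSet:
    path = Path(path)
    if mutant_id is None:
        mutant_id = path.stem
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str},
        float_precision="round_trip",
    )
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise VariantRecordError(f"{path}: missing columns {sorted(missing)}")
    variants = []
    for i, row in df.iterrows():
        try:
            gene = row["gene_id"]
            gene_id = None if pd.isna(gene) or gene == "." else str(gene)
            variants.append(
                VariantCall(
                    mutant_id=mutant_id,
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    ref=str(row["ref"]),
                    alt=str(row["alt"]),
                    qual=float(row["qual"]),
                    depth=int(row["depth"]),
                    alt_fraction=float(row["alt_fraction"]),
                    gene_id=gene_id,
                    effect=str(row["effect"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise VariantRecordError(f"{path} row {i + 2}: {exc}") from exc
    return MutantVariantSet(mutant_id=mutant_id, variants=variants)


def write_variant_vcf(mutant: MutantVariantSet, path: str | Path) -> None:
    """Minimal VCF 4.2 with depth/fraction/gene/effect in INFO."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Variant-read fraction">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">',
        '##INFO=<ID=EFF,Number=1,Type=String,Description="Effect class">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for v in mutant.variants:
        info = f"DP={v.depth};AF={v.alt_fraction:.4f};EFF={v.effect}"
        if v.gene_id is not None:
            info += f";GENE={v.gene_id}"
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{v.qual:.1f}\t.\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_coverage_tsv(path: str | Path, window_size: int | None = None) -> CoverageTrack:
    """Read a BED-like coverage TSV (chrom, start, end, mean_depth).

    Starts are half-open 0-based (BED convention) and converted to 1-based
    closed windows internally.
    """
    df = pd.read_csv(path, sep="\t", names=["chrom", "start", "end", "mean_depth"],
                     header=None, comment="#")
    if df.empty:
        raise ValueError(f"{path}: empty coverage track")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError(f"{path}: one chromosome per track (got {list(chroms)})")
    if window_size is None:
        window_size = int((df["end"] - df["start"]).iloc[0])
    return CoverageTrack(
        chrom=str(chroms[0]),
        starts=df["start"].to_numpy() + 1,
        mean_depth=df["mean_depth"].to_numpy(dtype=float),
        window_size=window_size,
    )


def write_stack(grid: VoxelGrid, tiff_path: str | Path, meta: dict | None = None) -> None:
    """Write a stack as multi-page TIFF plus a JSON voxel-size sidecar."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, grid.intensities.astype(np.float32))
    sidecar = {"voxel_size_um": list(grid.voxel_size)}
    if meta:
        sidecar.update(meta)
    tiff_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_stack(tiff_path: str | Path) -> tuple[VoxelGrid, dict]:
    tiff_path = Path(tiff_path)
    arr = tifffile.imread(tiff_path)
    if arr.ndim == 2:
        arr = arr[None, ...]
    sidecar_path = tiff_path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    voxel = tuple(meta.get("voxel_size_um", (0.125, 0.1, 0.1)))
    return VoxelGrid(np.asarray(arr, dtype=float), voxel), meta


def write_mosaic_csv(matrix: MosaicMatrix, path: str | Path) -> None:
    rows = []
    for animal in matrix.animals:
        row = {"animal": animal}
        for cell in matrix.lineage.names:
            row[cell] = ",".join(matrix.states[animal][cell])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_mosaic_csv(path: str | Path, lineage: LineageTable | None = None) -> MosaicMatrix:
    if lineage is None:
        lineage = default_lineage()
    df = pd.read_csv(path, dtype=str)
    if "animal" not in df.columns:
        raise ValueError(f"{path}: missing 'animal' column")
    animals = df["animal"].tolist()
    states: dict[str, dict[str, tuple[str, ...]]] = {}
    for _, row in df.iterrows():
        states[row["animal"]] = {
            cell: tuple(str(row[cell]).split(",")) for cell in lineage.names
        }
    matrix = MosaicMatrix(animals=animals, lineage=lineage, states=states)
    matrix.validate()
    return matrix


def write_lineage_csv(table: LineageTable, path: str | Path) -> None:
    pd.DataFrame(table.cells, columns=["cell", "nucleation_class"]).to_csv(
        path, index=False
    )


def read_lineage_csv(path: str | Path) -> LineageTable:
    df = pd.read_csv(path, dtype=str)
    table = LineageTable(
        cells=tuple(zip(df["cell"].tolist(), df["nucleation_class"].tolist()))
    )
    table.validate()
    return table
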