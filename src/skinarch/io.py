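"""Readers and writers for the plain-text interchange formats.

Cell tables, DEG tables, ligand-receptor pair lists and orientation angle
lists travel as delimited text; expression as MatrixMarket with gene/cell
sidecars; gene sets as GMT; interface contours as WKT LINESTRING with a
vertex-label sidecar; ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse
from shapely import wkt as shapely_wkt
from shapely.geometry import LineString

from .communication import LRPair
from .morphometry import InterfaceContour
from .scoring import GeneSet

__all__ = [
    "write_cell_table", "read_cell_table",
    "write_expression", "read_expression",
    "read_gmt", "write_gmt",
    "read_deg_table", "read_lr_pairs",
    "write_contour", "read_contour",
    "write_ground_truth",
    "read_angles", "write_density_map",
]


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, sep="\t", index=False)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression(
    counts: np.ndarray,
    genes: pd.DataFrame,
    cell_index: pd.DataFrame,
    prefix: str | Path,
) -> None:
    """Write counts as ``<prefix>.mtx`` with genes/cells TSV sidecars."""
    prefix = Path(prefix)
    scipy_io.mmwrite(str(prefix.with_suffix(".mtx")), sparse.coo_matrix(counts))
    genes.to_csv(prefix.parent / (prefix.name + "_genes.tsv"), sep="\t", index=False)
    cell_index.to_csv(prefix.parent / (prefix.name + "_cells.tsv"), sep="\t", index=False)


def read_expression(prefix: str | Path) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    prefix = Path(prefix)
    counts = scipy_io.mmread(str(prefix.with_suffix(".mtx"))).toarray()
    genes = pd.read_csv(prefix.parent / (prefix.name + "_genes.tsv"), sep="\t")
    cells = pd.read_csv(prefix.parent / (prefix.name + "_cells.tsv"), sep="\t")
    return counts, genes, cells


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        name, source, *genes = fields
        sets.append(GeneSet(name=name, genes=frozenset(g for g in genes if g),
                            source_id=source or None))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.source_id or ""] + sorted(s.genes)) + "\n")


def read_deg_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    table.columns = [c.lower() for c in table.columns]
    return table


def read_lr_pairs(path: str | Path) -> list[LRPair]:
    table = pd.read_csv(path, sep="\t")
    table.columns = [c.lower() for c in table.columns]
    return [
        LRPair(row["ligand"], row["receptor"], row["mode"])
        for _, row in table.iterrows()
    ]


def write_contour(contour: InterfaceContour, prefix: str | Path) -> None:
    """WKT LINESTRING plus a TSV sidecar with per-vertex labels."""
    prefix = Path(prefix)
    line = LineString(contour.vertices)
    prefix.with_suffix(".wkt").write_text(line.wkt + "\n")
    pd.DataFrame(
        {"vertex": range(len(contour.labels)), "label": contour.labels,
         "width_mm": contour.width_mm}
    ).to_csv(prefix.parent / (prefix.name + "_labels.tsv"), sep="\t", index=False)


def read_contour(prefix: str | Path) -> InterfaceContour:
    prefix = Path(prefix)
    line = shapely_wkt.loads(prefix.with_suffix(".wkt").read_text().strip())
    labels_df = pd.read_csv(prefix.parent / (prefix.name + "_labels.tsv"), sep="\t")
    return InterfaceContour(
        vertices=np.asarray(line.coords),
        labels=list(labels_df["label"]),
        width_mm=float(labels_df["width_mm"].iloc[0]),
    )


def write_ground_truth(truth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_json_dict(), indent=1))


def read_angles(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, ndmin=1)


def write_density_map(density_map, path: str | Path) -> None:
    """Plain-text raster with a small header of grid metadata."""
    header = (
        f"origin_x_um={density_map.origin[0]} origin_y_um={density_map.origin[1]} "
        f"spacing_um={density_map.spacing_um} bandwidth_um={density_map.bandwidth_um}"
    )
    np.savetxt(path, density_map.values, header=header)
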