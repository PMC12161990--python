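"""Readers and writers for the on-disk formats.

Matrices are accepted either as plain CSV/TSV (rows = spots or cells, header
row = gene ids, first column = row ids) or as matrix-market ``.mtx`` in the
10x-style orientation (genes × columns) with sidecar id files.  The format is
auto-detected from the file extension.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio

from .types import (
    ProportionMatrix,
    RegionAssignment,
    SingleCellReference,
    SpatialCounts,
    ValidationError,
)

logger = logging.getLogger("resort")


class LoadError(ValueError):
    """Raised when files cannot be assembled into a valid object."""


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def _sidecar_paths(path_matrix: Path) -> tuple[Path, Path]:
    """Locate gene/row id files next to an .mtx matrix.

    Two conventions are recognised: 10x-style ``genes.tsv`` + ``barcodes.tsv``
    in the same directory, or ``<stem>.genes.txt`` + ``<stem>.rows.txt``.
    """
    d = path_matrix.parent
    tenx = (d / "genes.tsv", d / "barcodes.tsv")
    if tenx[0].exists() and tenx[1].exists():
        return tenx
    stem = path_matrix.with_suffix("")
    ours = (Path(f"{stem}.genes.txt"), Path(f"{stem}.rows.txt"))
    if ours[0].exists() and ours[1].exists():
        return ours
    raise LoadError(
        f"no id files found for {path_matrix}: expected genes.tsv+barcodes.tsv "
        f"or {stem}.genes.txt+{stem}.rows.txt"
    )


def _read_matrix(path_matrix: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a counts matrix; returns (rows × genes array, gene ids, row ids)."""
    path_matrix = Path(path_matrix)
    if path_matrix.suffix.lower() == ".mtx":
        genes_path, rows_path = _sidecar_paths(path_matrix)
        mat = spio.mmread(path_matrix)
        mat = np.asarray(mat.todense()) if hasattr(mat, "todense") else np.asarray(mat)
        gene_ids = genes_path.read_text().split()
        row_ids = rows_path.read_text().split()
        # 10x orientation: genes are matrix rows, observations are columns.
        return mat.T, gene_ids, row_ids
    df = pd.read_csv(path_matrix, sep=_sep_for(path_matrix), index_col=0)
    return (
        df.to_numpy(),
        [str(c) for c in df.columns],
        [str(i) for i in df.index],
    )


def _write_matrix(
    path_matrix: str | Path,
    values: np.ndarray,
    gene_ids: Sequence[str],
    row_ids: Sequence[str],
) -> None:
    path_matrix = Path(path_matrix)
    path_matrix.parent.mkdir(parents=True, exist_ok=True)
    if path_matrix.suffix.lower() == ".mtx":
        stem = path_matrix.with_suffix("")
        spio.mmwrite(path_matrix, np.asarray(values).T.astype(int))
        Path(f"{stem}.genes.txt").write_text("\n".join(gene_ids) + "\n")
        Path(f"{stem}.rows.txt").write_text("\n".join(row_ids) + "\n")
        return
    df = pd.DataFrame(values, index=list(row_ids), columns=list(gene_ids))
    df.to_csv(path_matrix, sep=_sep_for(path_matrix))


def read_spatial_counts(path_matrix: str | Path, path_coords: str | Path) -> SpatialCounts:
    """Load a spots × genes count matrix plus a ``spot_id,row,col`` coords table."""
    counts, gene_ids, spot_ids = _read_matrix(path_matrix)
    path_coords = Path(path_coords)
    coords_df = pd.read_csv(path_coords, sep=_sep_for(path_coords))
    required = {"spot_id", "row", "col"}
    if not required.issubset(coords_df.columns):
        raise LoadError(
            f"coords table {path_coords} must have columns spot_id,row,col; "
            f"found {list(coords_df.columns)}"
        )
    coords_df["spot_id"] = coords_df["spot_id"].astype(str)
    if len(coords_df) != len(spot_ids) or set(coords_df["spot_id"]) != set(spot_ids):
        raise LoadError(
            f"coords table {path_coords} lists {len(coords_df)} spots but the "
            f"count matrix {path_matrix} has {len(spot_ids)} spot rows "
            "(spot id sets must match exactly)"
        )
    coords_df = coords_df.set_index("spot_id").loc[spot_ids]
    try:
        return SpatialCounts(
            counts=counts,
            gene_ids=gene_ids,
            spot_ids=spot_ids,
            coords=coords_df[["row", "col"]].to_numpy(),
        )
    except ValidationError as exc:
        raise LoadError(f"invalid spatial counts in {path_matrix}: {exc}") from exc


def write_spatial_counts(
    sc: SpatialCounts, path_matrix: str | Path, path_coords: str | Path
) -> None:
    _write_matrix(path_matrix, sc.counts, sc.gene_ids, sc.spot_ids)
    path_coords = Path(path_coords)
    path_coords.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"spot_id": sc.spot_ids, "row": sc.coords[:, 0], "col": sc.coords[:, 1]}
    ).to_csv(path_coords, sep=_sep_for(path_coords), index=False)


def read_reference(
    path_matrix: str | Path,
    path_labels: str | Path,
    path_grouping: str | Path,
) -> SingleCellReference:
    """Load a cells × genes reference with per-cell fine-type labels.

    ``path_labels`` maps ``cell_id`` → ``fine_type``; ``path_grouping`` maps
    ``fine_type`` → ``region_type``.  A fine type appearing in the labels but
    absent from the grouping is a load error listing the missing types.
    """
    counts, gene_ids, cell_ids = _read_matrix(path_matrix)
    path_labels = Path(path_labels)
    labels_df = pd.read_csv(path_labels, sep=_sep_for(path_labels))
    if not {"cell_id", "fine_type"}.issubset(labels_df.columns):
        raise LoadError(
            f"labels table {path_labels} must have columns cell_id,fine_type"
        )
    labels_df["cell_id"] = labels_df["cell_id"].astype(str)
    if set(labels_df["cell_id"]) != set(cell_ids):
        raise LoadError(
            f"cell ids in {path_labels} do not match the matrix rows of {path_matrix}"
        )
    fine = labels_df.set_index("cell_id").loc[cell_ids, "fine_type"].astype(str).to_numpy()

    path_grouping = Path(path_grouping)
    grp_df = pd.read_csv(path_grouping, sep=_sep_for(path_grouping))
    if not {"fine_type", "region_type"}.issubset(grp_df.columns):
        raise LoadError(
            f"grouping table {path_grouping} must have columns fine_type,region_type"
        )
    grouping = dict(
        zip(grp_df["fine_type"].astype(str), grp_df["region_type"].astype(str))
    )
    missing = sorted(set(fine) - set(grouping))
    if missing:
        raise LoadError(
            f"fine types with no grouping entry in {path_grouping}: {missing}"
        )
    try:
        return SingleCellReference(
            counts=counts,
            gene_ids=gene_ids,
            cell_ids=cell_ids,
            fine_type=fine,
            region_type_of=grouping,
        )
    except ValidationError as exc:
        raise LoadError(f"invalid reference in {path_matrix}: {exc}") from exc


def write_reference(
    ref: SingleCellReference,
    path_matrix: str | Path,
    path_labels: str | Path,
    path_grouping: str | Path,
) -> None:
    _write_matrix(path_matrix, ref.counts, ref.gene_ids, ref.cell_ids)
    path_labels = Path(path_labels)
    path_labels.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"cell_id": ref.cell_ids, "fine_type": ref.fine_type}).to_csv(
        path_labels, sep=_sep_for(path_labels), index=False
    )
    path_grouping = Path(path_grouping)
    pd.DataFrame(
        {
            "fine_type": list(ref.region_type_of),
            "region_type": [ref.region_type_of[k] for k in ref.region_type_of],
        }
    ).to_csv(path_grouping, sep=_sep_for(path_grouping), index=False)


def read_proportions(path: str | Path, level: str) -> ProportionMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    try:
        return ProportionMatrix(
            values=df.to_numpy(float),
            type_ids=[str(c) for c in df.columns],
            spot_ids=[str(i) for i in df.index],
            level=level,
        )
    except ValidationError as exc:
        raise LoadError(f"invalid proportion table {path}: {exc}") from exc


def write_proportions(props: ProportionMatrix, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = props.to_frame()
    df.index.name = "spot_id"
    df.to_csv(path, sep=_sep_for(path))


def read_regions(path: str | Path) -> RegionAssignment:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if not {"spot_id", "region_label"}.issubset(df.columns):
        raise LoadError(f"regions table {path} must have columns spot_id,region_label")
    return RegionAssignment(
        labels=df["region_label"].astype(str).to_numpy(),
        spot_ids=df["spot_id"].astype(str).tolist(),
    )


def write_regions(assignment: RegionAssignment, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"spot_id": assignment.spot_ids, "region_label": assignment.labels}
    ).to_csv(path, sep=_sep_for(path), index=False)


def read_mask(path: str | Path) -> pd.Series:
    """Read a ``spot_id,value`` boolean mask table as a Series indexed by spot."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if not {"spot_id", "value"}.issubset(df.columns):
        raise LoadError(f"mask table {path} must have columns spot_id,value")
    return pd.Series(
        df["value"].astype(int).astype(bool).to_numpy(),
        index=df["spot_id"].astype(str),
    )


def write_mask(mask: np.ndarray, spot_ids: Sequence[str], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"spot_id": list(spot_ids), "value": np.asarray(mask).astype(int)}
    ).to_csv(path, sep=_sep_for(path), index=False)
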