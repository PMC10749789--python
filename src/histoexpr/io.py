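"""Reading and writing spatial-transcriptomics file shapes.

A *section* is one tissue slice: a slide image, a spot table (array and
pixel coordinates per barcoded spot) and a spot×gene count matrix.  This
module loads the generic text formats (TSV/CSV counts, MatrixMarket with
sidecars, TSV spot tables), cuts fixed-size RGB patches centred on each
spot, and writes predictions back out as TSV or AnnData.

Conventions
-----------
* Counts are spots-as-rows, genes-as-columns (a ``transpose`` flag covers
  genes-as-rows sources).
* A patch of size S covers pixel rows ``[cy - S//2, cy + ceil(S/2))`` and
  the same for columns (half-open, 0-based) around the rounded spot centre;
  patches that overhang the slide are zero-padded to full size.
* Patch intensities are scaled to [0, 1] by dividing by 255; no stain
  normalisation is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpotTable", "ExpressionMatrix", "PatchStack", "ExpressionState",
    "load_counts", "load_spots", "load_image", "extract_patches",
    "write_counts", "write_predictions", "write_anndata",
]


class ExpressionState(str, Enum):
    RAW_COUNTS = "raw_counts"
    NORMALIZED = "normalized"


@dataclass
class SpotTable:
    """Spot identities and coordinates for one section.

    ``array_x``/``array_y`` are integer positions on the capture array
    (used for position embeddings); ``pixel_x``/``pixel_y`` are image
    coordinates (columns/rows, used for patches and the neighbour graph).
    """

    spot_id: np.ndarray          # str array, unique within the section
    array_x: np.ndarray          # int
    array_y: np.ndarray          # int
    pixel_x: np.ndarray          # float, image columns
    pixel_y: np.ndarray          # float, image rows
    section_id: str = "section"

    def __post_init__(self):
        self.spot_id = np.asarray(self.spot_id, dtype=str)
        self.array_x = np.asarray(self.array_x)
        self.array_y = np.asarray(self.array_y)
        self.pixel_x = np.asarray(self.pixel_x, dtype=float)
        self.pixel_y = np.asarray(self.pixel_y, dtype=float)
        n = len(self.spot_id)
        for name in ("array_x", "array_y", "pixel_x", "pixel_y"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name} has length mismatch")
        uniq, counts = np.unique(self.spot_id, return_counts=True)
        if (counts > 1).any():
            dups = uniq[counts > 1]
            raise ValueError(
                f"duplicate spot_id within section {self.section_id!r}: "
                f"{', '.join(dups[:5])}")
        arr_x = np.asarray(self.array_x, dtype=float)
        arr_y = np.asarray(self.array_y, dtype=float)
        if (arr_x < 0).any() or (arr_y < 0).any():
            raise ValueError("array coordinates must be non-negative")
        if not (np.equal(np.mod(arr_x, 1), 0).all()
                and np.equal(np.mod(arr_y, 1), 0).all()):
            raise ValueError("array coordinates must be integers")
        self.array_x = arr_x.astype(int)
        self.array_y = arr_y.astype(int)

    def __len__(self) -> int:
        return len(self.spot_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "spot_id": self.spot_id, "array_x": self.array_x,
            "array_y": self.array_y, "pixel_x": self.pixel_x,
            "pixel_y": self.pixel_y,
        })


@dataclass
class ExpressionMatrix:
    """Spot×gene expression values with a processing-state flag."""

    values: np.ndarray
    gene_names: list
    state: ExpressionState = ExpressionState.RAW_COUNTS
    spot_ids: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.gene_names = list(self.gene_names)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-D (spots × genes)")
        if self.values.shape[1] != len(self.gene_names):
            raise ValueError(
                f"{self.values.shape[1]} columns but "
                f"{len(self.gene_names)} gene names")
        if (self.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.state == ExpressionState.RAW_COUNTS:
            if not np.equal(np.mod(self.values, 1), 0).all():
                raise ValueError("raw counts must be integers")
            self.values = self.values.astype(np.int64)
        else:
            self.values = self.values.astype(np.float64)

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class PatchStack:
    """Per-spot RGB patches, shape (N, 3, H, W), values in [0, 1]."""

    patches: np.ndarray

    def __post_init__(self):
        self.patches = np.asarray(self.patches, dtype=np.float64)
        if self.patches.ndim != 4 or self.patches.shape[1] != 3:
            raise ValueError("patches must have shape (N, 3, H, W)")
        if self.patches.min() < 0 or self.patches.max() > 1:
            raise ValueError("patch values must lie in [0, 1]")

    def __len__(self) -> int:
        return self.patches.shape[0]


@dataclass
class Section:
    """One tissue slice: image + spots + expression, the LOOCV unit."""

    spots: SpotTable
    expr: ExpressionMatrix
    image: np.ndarray | None = None
    patches: PatchStack | None = None

    @property
    def section_id(self) -> str:
        return self.spots.section_id


# --------------------------------------------------------------------- counts

def load_counts(path, format: str | None = None, transpose: bool = False,
                genes_path=None, barcodes_path=None) -> ExpressionMatrix:
    """Load a raw spot×gene count matrix from TSV/CSV or MatrixMarket.

    Parameters
    ----------
    path
        Counts file.  TSV/CSV: first column spot ids, header row gene
        names.  MTX: sparse matrix with ``genes_path``/``barcodes_path``
        sidecars (defaults: ``genes.tsv``/``barcodes.tsv`` next to it).
    format
        ``"tsv"`` or ``"mtx"``; inferred from the suffix when omitted.
    transpose
        Set for genes-as-rows sources.
    """
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "tsv"
    if format == "mtx":
        from scipy.io import mmread
        try:
            mat = np.asarray(mmread(str(path)).todense())
        except Exception as exc:  # noqa: BLE001 - re-raise with file context
            raise ValueError(f"malformed MatrixMarket file {path}: {exc}") from exc
        genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
        gene_names = [ln.split("\t")[0].strip()
                      for ln in genes_path.read_text().splitlines() if ln.strip()]
        spot_ids = None
        bpath = Path(barcodes_path) if barcodes_path else path.parent / "barcodes.tsv"
        if bpath.exists():
            spot_ids = np.array([ln.strip() for ln in
                                 bpath.read_text().splitlines() if ln.strip()])
        if transpose:
            mat = mat.T
        if mat.shape[1] != len(gene_names):
            raise ValueError(
                f"{path}: matrix has {mat.shape[1]} gene columns but "
                f"{len(gene_names)} gene names in {genes_path}")
    else:
        sep = "," if path.suffix == ".csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"malformed counts file {path}: {exc}") from exc
        bad = df.columns[~df.apply(
            lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
        if len(bad):
            for i, row in enumerate(df.itertuples(index=False), start=2):
                if any(pd.isna(pd.to_numeric(v, errors="coerce")) for v in row):
                    raise ValueError(
                        f"parse error in {path} at line {i}: non-numeric entry")
        if transpose:
            df = df.T
        mat = df.to_numpy(dtype=float)
        gene_names = [str(g) for g in df.columns]
        spot_ids = df.index.to_numpy(dtype=str)
    if (mat < 0).any():
        raise ValueError(f"{path}: negative counts are invalid")
    return ExpressionMatrix(mat, gene_names,
                            state=ExpressionState.RAW_COUNTS, spot_ids=spot_ids)


def write_counts(expr: ExpressionMatrix, path) -> None:
    """Write an expression matrix as TSV (spots × genes); round-trips exactly."""
    idx = (expr.spot_ids if expr.spot_ids is not None
           else [f"spot{i}" for i in range(expr.n_spots)])
    pd.DataFrame(expr.values, index=idx, columns=expr.gene_names).to_csv(
        path, sep="\t")


# ---------------------------------------------------------------------- spots

_DEFAULT_COLS = dict(spot_id="spot_id", array_x="array_x", array_y="array_y",
                     pixel_x="pixel_x", pixel_y="pixel_y")


def load_spots(path, section_id: str | None = None,
               columns: dict | None = None) -> SpotTable:
    """Load a spot table from TSV/CSV; rows keep file order.

    ``columns`` remaps the expected logical names (spot_id, array_x,
    array_y, pixel_x, pixel_y) to the file's column names.
    """
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    cols = dict(_DEFAULT_COLS)
    if columns:
        cols.update(columns)
    for logical, actual in cols.items():
        if actual not in df.columns:
            raise ValueError(f"{path}: missing column {actual!r} (for {logical})")
    for logical in ("pixel_x", "pixel_y"):
        col = pd.to_numeric(df[cols[logical]], errors="coerce")
        if col.isna().any():
            row = int(col.isna().idxmax())
            raise ValueError(
                f"{path}: non-numeric {logical} at data row {row}")
    return SpotTable(
        spot_id=df[cols["spot_id"]].to_numpy(dtype=str),
        array_x=df[cols["array_x"]].to_numpy(),
        array_y=df[cols["array_y"]].to_numpy(),
        pixel_x=df[cols["pixel_x"]].to_numpy(dtype=float),
        pixel_y=df[cols["pixel_y"]].to_numpy(dtype=float),
        section_id=section_id or path.stem,
    )


# --------------------------------------------------------------------- images

def load_image(path) -> np.ndarray:
    """Read a TIFF/JPEG/PNG slide as an (H, W, 3) uint8 RGB array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        img = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio
        img = iio.imread(str(path))
    img = np.asarray(img)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[-1] == 4:
        img = img[..., :3]
    return img


def extract_patches(image: np.ndarray, spots: SpotTable,
                    patch_size: int = 112, scale: float = 1.0) -> PatchStack:
    """Cut one ``patch_size``-square RGB patch per spot, scaled to [0, 1].

    The patch is centred at the rounded pixel coordinates; ``scale``
    multiplies stored coordinates first (for spot tables that index a
    different pyramid level than the supplied image).  Patches overhanging
    the image are zero-padded; a spot whose centre falls outside the image
    is an error.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be (H, W, 3) RGB")
    H, W = image.shape[:2]
    cx = np.round(spots.pixel_x * scale).astype(int)
    cy = np.round(spots.pixel_y * scale).astype(int)
    outside = (cx < 0) | (cx >= W) | (cy < 0) | (cy >= H)
    if outside.any():
        bad = spots.spot_id[outside]
        raise ValueError(
            f"spot centre outside image for: {', '.join(bad[:10])}")
    lo, hi = patch_size // 2, math.ceil(patch_size / 2)
    img = image.astype(np.float64) / 255.0
    out = np.zeros((len(spots), 3, patch_size, patch_size))
    for i in range(len(spots)):
        y0, y1 = cy[i] - lo, cy[i] + hi
        x0, x1 = cx[i] - lo, cx[i] + hi
        sy0, sy1 = max(y0, 0), min(y1, H)
        sx0, sx1 = max(x0, 0), min(x1, W)
        patch = np.zeros((patch_size, patch_size, 3))
        patch[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = img[sy0:sy1, sx0:sx1]
        out[i] = patch.transpose(2, 0, 1)
    return PatchStack(out)


# ------------------------------------------------------------------- outputs

def write_predictions(pred: np.ndarray, gene_names: Sequence[str],
                      spot_ids: Sequence[str], path) -> None:
    """Write predicted expression as TSV (spots × genes)."""
    pd.DataFrame(np.asarray(pred), index=list(spot_ids),
                 columns=list(gene_names)).to_csv(path, sep="\t")


def write_anndata(pred: np.ndarray, gene_names: Sequence[str],
                  spots: SpotTable, path) -> None:
    """Write predictions as an AnnData ``.h5ad`` with spot coordinates in obs."""
    import anndata as ad
    adata = ad.AnnData(
        X=np.asarray(pred, dtype=np.float64),
        obs=pd.DataFrame({
            "array_x": spots.array_x, "array_y": spots.array_y,
            "pixel_x": spots.pixel_x, "pixel_y": spots.pixel_y,
        }, index=list(spots.spot_id)),
        var=pd.DataFrame(index=list(gene_names)),
    )
    adata.write_h5ad(path)
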