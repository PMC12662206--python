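"""Plain-file interchange: TIFF masks, CSV tables, MTX matrices, JSON sidecars.

Every pipeline stage reads and writes ordinary files so intermediate
results stay inspectable and language-agnostic.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import tifffile
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .midline import Mask, Midline
from .simulate import SimParams, SyntheticOrganoid


def write_mask(path: str | Path, mask: Mask | np.ndarray) -> None:
    grid = mask.grid if isinstance(mask, Mask) else np.asarray(mask, bool)
    tifffile.imwrite(str(path), (grid.astype(np.uint8) * 255))


def read_mask(path: str | Path) -> Mask:
    arr = tifffile.imread(str(path))
    return Mask(arr > 0)


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a float image in [0, 1] as uint16 TIFF."""
    scaled = np.clip(np.asarray(image, float), 0, 1) * np.iinfo(np.uint16).max
    tifffile.imwrite(str(path), scaled.astype(np.uint16))


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=float)


def write_midline(path: str | Path, midline: Midline) -> None:
    pd.DataFrame(
        {
            "index": np.arange(len(midline)),
            "row": midline.path[:, 0],
            "col": midline.path[:, 1],
            "arclen": midline.arclen,
        }
    ).to_csv(path, index=False)


def read_midline(path: str | Path) -> Midline:
    df = pd.read_csv(path)
    return Midline(df[["row", "col"]].to_numpy(dtype=int))


def write_cells(path: str | Path, cells: pd.DataFrame) -> None:
    cells.to_csv(path, index=False)


def read_cells(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_matrix(outdir: str | Path, adata: ad.AnnData) -> None:
    """Write counts as MTX triplet plus gene and cell lists."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(outdir / "matrix.mtx"), csr_matrix(np.asarray(adata.X)))
    (outdir / "genes.txt").write_text("\n".join(adata.var_names) + "\n")
    (outdir / "cells.txt").write_text("\n".join(adata.obs_names) + "\n")


def read_matrix(indir: str | Path) -> ad.AnnData:
    indir = Path(indir)
    X = np.asarray(mmread(str(indir / "matrix.mtx")).todense())
    genes = (indir / "genes.txt").read_text().splitlines()
    cells = (indir / "cells.txt").read_text().splitlines()
    return ad.AnnData(
        X=X.astype(np.int64),
        obs=pd.DataFrame(index=pd.Index(cells, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )


def write_organoid(outdir: str | Path, organoid: SyntheticOrganoid) -> None:
    """Persist a synthetic organoid: mask TIFF, cells CSV, MTX, JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_mask(outdir / "mask.tif", organoid.mask)
    np.savetxt(
        outdir / "true_midline.csv",
        organoid.true_midline,
        delimiter=",",
        header="row,col",
        comments="",
    )
    if organoid.cells is not None:
        write_cells(outdir / "cells.csv", organoid.cells)
    if organoid.counts is not None:
        write_matrix(outdir / "matrix", organoid.counts)
    sidecar = {
        "params": dataclasses.asdict(organoid.params),
        "true_orientation": organoid.true_orientation,
    }
    (outdir / "simulation.json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_organoid(indir: str | Path) -> SyntheticOrganoid:
    indir = Path(indir)
    sidecar = json.loads((indir / "simulation.json").read_text())
    organoid = SyntheticOrganoid(
        mask=read_mask(indir / "mask.tif"),
        true_midline=np.loadtxt(indir / "true_midline.csv", delimiter=",", skiprows=1),
        true_orientation=sidecar["true_orientation"],
        params=SimParams(**sidecar["params"]),
    )
    if (indir / "cells.csv").exists():
        organoid.cells = read_cells(indir / "cells.csv")
    if (indir / "matrix").exists():
        organoid.counts = read_matrix(indir / "matrix")
    return organoid
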