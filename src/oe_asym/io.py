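"""Readers and writers for the plain formats the pipeline exchanges.

Tabular data travel as TSV/CSV, images as multi-page TIFF (one page per
z-slice, one file per channel; masks as 0/1 stacks of the same shape),
parameters as YAML and fit results / ground truth as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .division_mixture import MixtureParams, RatioDataset
from .image_quant import ZStackROI
from .pair_expression import PairTable
from .regen_ode import EdUTimecourse, RegenParams, Trajectory

__all__ = [
    "read_edu_tsv", "write_edu_tsv",
    "write_trajectory_tsv",
    "read_ratio_tsv", "write_ratio_tsv",
    "read_params_yaml", "write_json",
    "read_zstack_tiff", "write_zstack_tiff",
    "read_pair_table",
]


def read_edu_tsv(path) -> EdUTimecourse:
    """EdU time course: ``day<TAB>n_total<TAB>n_positive`` or ``day<TAB>fraction``."""
    df = pd.read_csv(path, sep="\t")
    return EdUTimecourse(df)


def write_edu_tsv(data: EdUTimecourse, path) -> None:
    data.table.to_csv(path, sep="\t", index=False)


def write_trajectory_tsv(traj: Trajectory, path) -> None:
    traj.to_frame().to_csv(path, sep="\t", index=False)


def read_ratio_tsv(path) -> RatioDataset:
    """Ratios: ``cell_id<TAB>ratio`` or ``cell_id<TAB>intensity_a<TAB>intensity_b``."""
    df = pd.read_csv(path, sep="\t")
    if {"intensity_a", "intensity_b"} <= set(df.columns):
        return RatioDataset.from_pairs(df["intensity_a"], df["intensity_b"])
    if "ratio" in df.columns:
        return RatioDataset(ratio=df["ratio"].to_numpy(dtype=float))
    raise ValueError("expected columns (cell_id, ratio) or "
                     "(cell_id, intensity_a, intensity_b)")


def write_ratio_tsv(data: RatioDataset, path) -> None:
    df = pd.DataFrame({"cell_id": [f"cell{i:05d}" for i in range(len(data))],
                       "ratio": data.ratio})
    if data.x1 is not None and data.x2 is not None:
        df["intensity_a"] = data.x1
        df["intensity_b"] = data.x2
    df.to_csv(path, sep="\t", index=False)


def read_params_yaml(path) -> RegenParams | MixtureParams:
    """Parameter YAML; the key set decides which parameter type it is."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if {"p_s", "p_b", "sigma"} <= set(raw):
        return MixtureParams(**raw)
    return RegenParams(**raw)


def write_json(obj, path) -> None:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, default=default, indent=1)


def write_zstack_tiff(stack: ZStackROI, directory, prefix: str = "stack") -> dict:
    """Write image + masks as multi-page TIFFs; returns the path map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": directory / f"{prefix}_image.tif",
        "mask_a": directory / f"{prefix}_mask_a.tif",
        "mask_b": directory / f"{prefix}_mask_b.tif",
        "background": directory / f"{prefix}_bg.tif",
    }
    tifffile.imwrite(paths["image"], stack.image.astype(np.uint16),
                     photometric="minisblack")
    for key, mask in (("mask_a", stack.mask_a), ("mask_b", stack.mask_b),
                      ("background", stack.background_mask)):
        tifffile.imwrite(paths[key], mask.astype(np.uint8),
                         photometric="minisblack")
    return paths


def read_zstack_tiff(image_path, mask_a_path, mask_b_path, background_path,
                     channel: str = "") -> ZStackROI:
    return ZStackROI(
        image=tifffile.imread(image_path),
        mask_a=tifffile.imread(mask_a_path) > 0,
        mask_b=tifffile.imread(mask_b_path) > 0,
        background_mask=tifffile.imread(background_path) > 0,
        channel=channel,
    )


def read_pair_table(counts_path, meta_path) -> PairTable:
    """Counts as TSV/CSV/MTX (gene x cell) plus a cell-metadata TSV.

    MTX input expects sidecar ``<stem>_genes.tsv`` and ``<stem>_cells.tsv``
    files listing row and column names.
    """
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        from scipy.io import mmread

        mat = mmread(counts_path).toarray()
        genes = pd.read_csv(counts_path.with_name(counts_path.stem + "_genes.tsv"),
                            header=None)[0]
        cells = pd.read_csv(counts_path.with_name(counts_path.stem + "_cells.tsv"),
                            header=None)[0]
        counts = pd.DataFrame(mat, index=genes, columns=cells)
    else:
        sep = "," if counts_path.suffix == ".csv" else "\t"
        counts = pd.read_csv(counts_path, sep=sep, index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return PairTable(counts=counts, cell_meta=meta)
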