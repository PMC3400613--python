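"""Readers and writers: TIFF images with pixel-size metadata, ground-truth
JSON sidecars, event/metadata CSVs and the image manifest.

All tabular IO validates its schema strictly: a missing column is a hard error
naming the column; extra columns are preserved with a warning.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthgen.imaging import CellImage
from .synthgen.networks import NetworkGroundTruth

log = logging.getLogger(__name__)

EVENT_COLUMNS = ["subject_id", "condition", "FSC", "SSC", "CD14", "FL_green", "FL_red"]
METADATA_COLUMNS = ["subject_id", "group", "viral_load", "censored"]
MANIFEST_COLUMNS = ["path", "subject_id", "cell_id", "cell_type", "pixel_size_um"]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def _check_schema(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        log.warning("%s: extra columns preserved: %s", name, extra)


def write_events_csv(events: pd.DataFrame, path) -> None:
    _check_schema(events, EVENT_COLUMNS, "event table")
    events.to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_schema(df, EVENT_COLUMNS, str(path))
    return df


def write_metadata_csv(meta: pd.DataFrame, path) -> None:
    _check_schema(meta, METADATA_COLUMNS, "metadata table")
    meta.to_csv(path, index=False)


def read_metadata_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_schema(df, METADATA_COLUMNS, str(path))
    return df


def write_cell_image(img: CellImage, path) -> None:
    """Two-channel TIFF (mito, nucleus) with the pixel size in metadata and the
    network ground truth as a JSON sidecar next to the image."""
    path = Path(path)
    channels = [np.asarray(img.mito_channel, dtype=np.float32)]
    if img.nucleus_channel is not None:
        channels.append(np.asarray(img.nucleus_channel, dtype=np.float32))
    res = 1.0 / img.pixel_size_um
    tifffile.imwrite(
        path,
        np.stack(channels),
        resolution=(res, res),
        metadata={
            "pixel_size_um": img.pixel_size_um,
            "cell_id": img.cell_id,
            "cell_type": img.cell_type,
            "axes": "CYX",
        },
    )
    if img.truth is not None:
        write_truth_json(img.truth, path.with_suffix(".json"))


def read_cell_image(path, cell_id: str | None = None,
                    cell_type: str | None = None) -> CellImage:
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if arr.ndim == 2:
        arr = arr[None]
    truth = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        truth = read_truth_json(sidecar)
    return CellImage(
        mito_channel=arr[0].astype(float),
        nucleus_channel=arr[1].astype(float) if arr.shape[0] > 1 else None,
        pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
        cell_id=cell_id or meta.get("cell_id", path.stem),
        cell_type=cell_type or meta.get("cell_type", "monocyte"),
        truth=truth,
    )


def write_truth_json(truth: NetworkGroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "node_coords": truth.node_coords.tolist(),
                "edges": truth.edges.tolist(),
                "n_fragments": truth.n_fragments,
                "n_branch_nodes": truth.n_branch_nodes,
                "tube_radius_px": truth.tube_radius_px,
                "target_vv_pct": truth.target_vv_pct,
                "achieved_vv_pct": truth.achieved_vv_pct,
                "cell_radius_px": truth.cell_radius_px,
                "total_length_px": truth.total_length_px,
            },
            fh,
        )


def read_truth_json(path) -> NetworkGroundTruth:
    with open(path) as fh:
        d = json.load(fh)
    return NetworkGroundTruth(
        node_coords=np.asarray(d["node_coords"], dtype=float).reshape(-1, 2),
        edges=np.asarray(d["edges"], dtype=int).reshape(-1, 2),
        n_fragments=int(d["n_fragments"]),
        n_branch_nodes=int(d["n_branch_nodes"]),
        tube_radius_px=int(d["tube_radius_px"]),
        target_vv_pct=float(d["target_vv_pct"]),
        achieved_vv_pct=float(d.get("achieved_vv_pct", 0.0)),
        cell_radius_px=float(d["cell_radius_px"]),
        total_length_px=float(d["total_length_px"]),
    )


def write_manifest(rows: pd.DataFrame, path) -> None:
    _check_schema(rows, MANIFEST_COLUMNS, "manifest")
    rows.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_schema(df, MANIFEST_COLUMNS, str(path))
    bad = df[~df["cell_type"].isin(["lymphocyte", "monocyte"])]
    if len(bad):
        raise SchemaError(
            f"{path}: invalid cell_type in rows {list(bad.index + 2)}"  # 1-based + header
        )
    return df
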