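"""File formats: FASTA, measurement TSVs, ROI JSON, and TIFF stacks."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reporter import ImageStack, ROISet

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_measurements",
    "write_table",
    "read_roi_json",
    "write_roi_json",
    "read_stack",
    "write_stack",
]


def read_fasta(path) -> dict[str, str]:
    """Sequences keyed by record id, uppercased."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


MEASUREMENT_COLUMNS = ["embryo_id", "replicate_id", "construct_id", "reporter_mean", "control_mean"]
CELL_COLUMNS = ["cell_id", "embryo_id", "construct_id", "reporter_mean", "control_mean"]


def read_measurements(path, required=MEASUREMENT_COLUMNS) -> pd.DataFrame:
    """A pre-measured intensity table (TSV), bypassing the imaging steps."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_roi_json(path) -> ROISet:
    """ROI polygons: {"whole": [[x, y], ...], "primary": ..., "secondary": ...}."""
    data = json.loads(Path(path).read_text())
    if "whole" not in data:
        raise ValueError(f"{path}: ROI JSON needs a 'whole' polygon")

    def poly(key):
        return np.asarray(data[key], dtype=float) if data.get(key) is not None else None

    return ROISet(whole=poly("whole"), primary=poly("primary"), secondary=poly("secondary"))


def write_roi_json(path, rois: ROISet) -> None:
    def ser(p):
        return None if p is None else np.asarray(p, dtype=float).tolist()

    Path(path).write_text(
        json.dumps(
            {"whole": ser(rois.whole), "primary": ser(rois.primary), "secondary": ser(rois.secondary)},
            indent=1,
        )
    )


def read_stack(path, channel_roles: dict[str, int] | None = None) -> ImageStack:
    """A multi-channel TIFF with axes (C, Z, Y, X)."""
    voxels = np.asarray(tifffile.imread(str(path)), dtype=float)
    if voxels.ndim == 3:  # single channel stored as (Z, Y, X): not enough channels
        raise ValueError(f"{path}: expected a (C, Z, Y, X) stack, got shape {voxels.shape}")
    return ImageStack(voxels=voxels, channel_roles=channel_roles or {"reporter": 0, "control": 1})


def write_stack(path, stack: ImageStack) -> None:
    tifffile.imwrite(str(path), stack.voxels.astype(np.float32), photometric="minisblack")
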