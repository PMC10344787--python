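"""File formats: phosphopeptide TSV tables, calibrated TIFF stacks, JSON sidecars.

Table format (TSV): columns ``site_id``, ``protein_id`` then one intensity
column per sample named ``<group>:<sample>``. Empty cells are missing
values (never 0). A generic wide table without group-tagged headers can be
read by supplying a YAML design file mapping samples to groups.

Stacks are multi-page TIFFs carrying pixel size in the resolution tags
(pixels per micrometre) and the frame interval in the ImageJ-style
metadata; both can be overridden at read time.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import DataError
from .phospho import PhosphoPeptideTable
from .stack import LabeledStack
from .synthdata import GroundTruth


def write_table(table: PhosphoPeptideTable, path: str | Path) -> None:
    """Write a phosphopeptide table as TSV with group-tagged sample columns."""
    df = table.intensities.copy()
    df.columns = [f"{table.design[s]}:{s}" for s in df.columns]
    df.insert(0, "protein_id", table.proteins)
    df.index.name = "site_id"
    df.to_csv(path, sep="\t", na_rep="")


def read_table(
    path: str | Path, design: Mapping[str, str] | str | Path | None = None
) -> PhosphoPeptideTable:
    """Read a phosphopeptide TSV table.

    Without ``design``, sample columns must be named ``<group>:<sample>``.
    With a design (mapping or YAML file of ``sample: group``), plain
    sample column names are accepted.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "site_id" or "protein_id" not in df.columns:
        raise DataError(f"{path}: expected columns 'site_id' and 'protein_id'")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique()
        raise DataError(f"{path}: duplicate site ids: {list(dups[:5])}")
    proteins = df.pop("protein_id")
    if isinstance(design, (str, Path)):
        with open(design) as fh:
            design = yaml.safe_load(fh)
    if design is None:
        design_map: dict[str, str] = {}
        rename: dict[str, str] = {}
        for col in df.columns:
            if ":" not in col:
                raise DataError(
                    f"{path}: column {col!r} has no group tag and no design file was given"
                )
            group, sample = col.split(":", 1)
            design_map[sample] = group
            rename[col] = sample
        df = df.rename(columns=rename)
    else:
        missing = [c for c in df.columns if c not in design]
        if missing:
            raise DataError(f"{path}: samples missing from design: {missing}")
        design_map = dict(design)
    return PhosphoPeptideTable(intensities=df, proteins=proteins, design=design_map)


def write_stack(stack: LabeledStack, path: str | Path) -> None:
    """Write frames as a multi-page TIFF with calibration metadata.

    Pixel size goes into the resolution tags (pixels per micrometre);
    the frame interval into ImageJ-style metadata. Label masks, when
    present, are written alongside as ``<stem>_labels.tif``.
    """
    path = Path(path)
    ppu = 1.0 / stack.pixel_size  # pixels per micrometre
    tifffile.imwrite(
        path,
        stack.frames.astype(np.float32),
        resolution=(ppu, ppu),
        photometric="minisblack",
        imagej=False,
        metadata={"axes": "TYX"},
        description=json.dumps(
            {"pixel_size_um": stack.pixel_size, "frame_interval_s": stack.frame_interval}
        ),
    )
    if stack.labels is not None:
        tifffile.imwrite(path.with_name(path.stem + "_labels.tif"), stack.labels.astype(np.int32))


def read_stack(
    path: str | Path,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
) -> LabeledStack:
    """Read a TIFF stack with calibration from tags or explicit overrides.

    2D images are promoted to a single-frame stack. Missing calibration
    raises unless ``pixel_size``/``frame_interval`` are supplied.
    """
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        page = tif.pages[0]
        desc = page.description or ""
    meta: dict[str, Any] = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise DataError(f"{path}: ambiguous axes for shape {frames.shape}; expected (T, H, W)")
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    dt = frame_interval if frame_interval is not None else meta.get("frame_interval_s")
    if px is None:
        raise DataError(f"{path}: no pixel size in metadata; pass pixel_size explicitly")
    if dt is None:
        raise DataError(f"{path}: no frame interval in metadata; pass frame_interval explicitly")
    return LabeledStack(frames=frames, pixel_size=float(px), frame_interval=float(dt))


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=2, sort_keys=True)


def write_json_report(report: Mapping[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
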