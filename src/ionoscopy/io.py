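"""List-mode event tables and correlative image-pair I/O.

The instrument records list-mode events: for every beam position (pixel)
either an ionoluminescence (IL) photon count increment or the energy loss
(dE, keV) of a transmitted ion.  Events are accumulated offline into a
registered pair of maps: an integer photon-count map and a mean-energy-loss
map.  On disk, list-mode data is a headered tab-separated table, maps are
16-bit (IL) / 32-bit float (dE) TIFFs, and metadata is JSON.

Pixel coordinates are 0-based, row-major, origin at the top-left; the
header of every list-mode file declares the image shape and pixel size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

CHANNELS = ("IL", "STIM")


@dataclass
class EventList:
    """List-mode events plus the acquisition geometry they refer to."""

    records: pd.DataFrame  # columns: x, y, channel, value
    shape: tuple[int, int]  # (rows, cols)
    pixel_size_nm: float

    def __post_init__(self) -> None:
        df = self.records
        required = {"x", "y", "channel", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"event table must have columns {sorted(required)}")
        if len(df):
            bad = ~df["channel"].isin(CHANNELS)
            if bad.any():
                raise ValueError(f"invalid channel tags: {df.loc[bad, 'channel'].unique()}")
            if (df["value"] < 0).any():
                raise ValueError("event values must be nonnegative")
            rows, cols = self.shape
            if ((df["x"] < 0) | (df["x"] >= cols) | (df["y"] < 0) | (df["y"] >= rows)).any():
                raise ValueError("event coordinates outside the declared image shape")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class CorrelativePair:
    """Registered IL photon-count map and STIM mean-energy-loss map."""

    il_map: np.ndarray  # integer photons / pixel
    de_map: np.ndarray  # keV / pixel (mean energy loss)
    pixel_size_nm: float
    provenance: dict = field(default_factory=dict)
    ion_counts: np.ndarray | None = None  # STIM event multiplicity per pixel

    def __post_init__(self) -> None:
        self.il_map = np.asarray(self.il_map)
        self.de_map = np.asarray(self.de_map, dtype=float)
        if self.il_map.shape != self.de_map.shape:
            raise ValueError("IL and dE maps must share a shape")
        if np.any(self.il_map < 0) or np.any(self.de_map < 0):
            raise ValueError("maps must be nonnegative")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.il_map.shape


# ---------------------------------------------------------------------------
# list-mode TSV
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("rows", "cols", "pixel_size_nm")


def write_event_list(events: EventList, path) -> None:
    """Write a headered tab-separated list-mode file (lossless round trip)."""
    path = Path(path)
    with path.open("w") as fh:
        rows, cols = events.shape
        fh.write(f"# rows={rows}\n# cols={cols}\n")
        fh.write(f"# pixel_size_nm={events.pixel_size_nm!r}\n")
        fh.write("x\ty\tchannel\tvalue\n")
        for x, y, ch, v in events.records.itertuples(index=False):
            fh.write(f"{x}\t{y}\t{ch}\t{v!r}\n")


def read_event_list(path) -> EventList:
    """Read a list-mode TSV; raises with a line number on malformed rows."""
    path = Path(path)
    header: dict[str, float] = {}
    rows_out: list[tuple[int, int, str, float]] = []
    with path.open() as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        line = line.strip()
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition("=")
            header[key.strip()] = float(val)
            body_start = i + 1
        elif line.startswith("x\t"):
            body_start = i + 1
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise ValueError(f"{path}: missing header keys {missing}")
    shape = (int(header["rows"]), int(header["cols"]))
    for lineno, line in enumerate(lines[body_start:], start=body_start + 1):
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        try:
            if len(parts) != 4:
                raise ValueError("expected 4 tab-separated fields")
            x, y, ch, v = int(parts[0]), int(parts[1]), parts[2], float(parts[3])
            if ch not in CHANNELS:
                raise ValueError(f"bad channel {ch!r}")
            if v < 0:
                raise ValueError("negative value")
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed event row: {exc}") from None
        rows_out.append((x, y, ch, v))
    df = pd.DataFrame(rows_out, columns=["x", "y", "channel", "value"])
    if not len(df):
        df = df.astype({"x": int, "y": int, "channel": str, "value": float})
    return EventList(records=df, shape=shape, pixel_size_nm=header["pixel_size_nm"])


def accumulate_events(events: EventList) -> CorrelativePair:
    """Accumulate list-mode events pixel by pixel into a correlative pair.

    IL pixel value = sum of IL photon counts at the pixel; dE pixel value =
    mean of the STIM energy losses there (0 where no ion was recorded); the
    per-pixel ion multiplicity is kept for yield computation.
    """
    rows, cols = events.shape
    il_acc = np.zeros((rows, cols), dtype=float)
    de_sum = np.zeros((rows, cols), dtype=float)
    n_ion = np.zeros((rows, cols), dtype=np.int64)
    df = events.records
    if len(df):
        il_df = df[df["channel"] == "IL"]
        np.add.at(il_acc, (il_df["y"].to_numpy(), il_df["x"].to_numpy()),
                  il_df["value"].to_numpy())
        st = df[df["channel"] == "STIM"]
        np.add.at(de_sum, (st["y"].to_numpy(), st["x"].to_numpy()), st["value"].to_numpy())
        np.add.at(n_ion, (st["y"].to_numpy(), st["x"].to_numpy()), 1)
    with np.errstate(invalid="ignore"):
        de = np.where(n_ion > 0, de_sum / np.maximum(n_ion, 1), 0.0)
    il = np.rint(il_acc).astype(np.int64)  # photon counts are integral
    return CorrelativePair(
        il_map=il, de_map=de, pixel_size_nm=events.pixel_size_nm,
        provenance={"source": "list-mode"}, ion_counts=n_ion,
    )


# ---------------------------------------------------------------------------
# raster / tabular output
# ---------------------------------------------------------------------------

def write_pair(pair: CorrelativePair, directory, stem: str = "pair") -> dict:
    """Write a correlative pair as one 16-bit TIFF per channel + JSON metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    il_path = directory / f"{stem}_il.tif"
    de_path = directory / f"{stem}_de.tif"
    meta_path = directory / f"{stem}_meta.json"
    tifffile.imwrite(il_path, np.clip(pair.il_map, 0, 2**16 - 1).astype(np.uint16))
    tifffile.imwrite(de_path, pair.de_map.astype(np.float32))
    meta = {"pixel_size_nm": pair.pixel_size_nm, "shape": list(pair.shape),
            "provenance": pair.provenance}
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return {"il": il_path, "de": de_path, "meta": meta_path}


def read_pair(directory, stem: str = "pair") -> CorrelativePair:
    directory = Path(directory)
    il = tifffile.imread(directory / f"{stem}_il.tif")
    de = tifffile.imread(directory / f"{stem}_de.tif")
    meta = json.loads((directory / f"{stem}_meta.json").read_text())
    return CorrelativePair(il_map=il.astype(np.int64), de_map=de,
                           pixel_size_nm=meta["pixel_size_nm"],
                           provenance=meta.get("provenance", {}))


def write_mask(mask: np.ndarray, path) -> None:
    """8-bit TIFF mask (0 / 255)."""
    tifffile.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(Path(path)) > 0
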