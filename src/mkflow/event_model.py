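"""Data model and I/O for multichannel event-image galleries.

An imaging flow cytometer records, for every object ("event") passing the
flow cell, a set of co-registered single-channel images: brightfield,
side scatter (darkfield) and several fluorescence channels.  This module
defines the in-memory containers for such data — :class:`PanelConfig`
(marker-to-channel map plus acquisition geometry), :class:`EventImage`
(one event's rasters) and :class:`EventSet` (an ordered gallery) — and a
documented on-disk interchange format: a per-sample directory holding
multipage TIFF files plus a plain ``index.csv``.

Vendor formats (.rif/.cif/.daf) are deliberately not parsed; the TIFF +
CSV gallery is the normative format of this package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import fcs as _fcs

__all__ = [
    "PanelConfig",
    "EventImage",
    "EventSet",
    "DEFAULT_PANEL",
    "load_event_set",
    "save_event_set",
    "export_features_fcs",
    "export_features_csv",
]

_VALID_BIT_DEPTHS = (8, 12, 16)

INDEX_COLUMNS = ["object_id", "time_s", "channel", "file", "page"]


@dataclass(frozen=True)
class PanelConfig:
    """Marker-role → detection-channel map plus acquisition geometry.

    Parameters
    ----------
    channel_map
        Mapping from marker role (``"bf"``, ``"cd41"``, ...) to channel id
        (``"Ch01"``, ``"Ch03"``, ...).  All downstream code addresses
        channels by marker role, never by hard-coded channel id.
    pixel_size_um
        Physical pixel pitch in micrometres (0.5 µm at 40x).
    bit_depth
        Pixel dynamic range; 12-bit (0–4095) by default, consistent with
        the saturation gate threshold of 4030 counts.
    """

    channel_map: Mapping[str, str]
    pixel_size_um: float = 0.5
    bit_depth: int = 12

    def __post_init__(self) -> None:
        ids = list(self.channel_map.values())
        if len(set(ids)) != len(ids):
            raise ValueError("channel ids must be unique")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.bit_depth not in _VALID_BIT_DEPTHS:
            raise ValueError(f"bit_depth must be one of {_VALID_BIT_DEPTHS}")
        object.__setattr__(self, "channel_map", dict(self.channel_map))

    @property
    def markers(self) -> list[str]:
        return list(self.channel_map)

    @property
    def max_pixel(self) -> int:
        return 2**self.bit_depth - 1

    def channel(self, marker: str) -> str:
        try:
            return self.channel_map[marker]
        except KeyError:
            raise KeyError(f"marker {marker!r} not in panel {self.markers}") from None

    def to_dict(self) -> dict:
        return {
            "channel_map": dict(self.channel_map),
            "pixel_size_um": self.pixel_size_um,
            "bit_depth": self.bit_depth,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PanelConfig":
        return cls(
            channel_map=dict(d["channel_map"]),
            pixel_size_um=float(d.get("pixel_size_um", 0.5)),
            bit_depth=int(d.get("bit_depth", 12)),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PanelConfig":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text)
        return cls.from_dict(d)


#: Default panel: the five-colour megakaryocyte panel layout.
#: BF in Ch01, CD41 PE in Ch03, SSC in Ch06, CD45 in Ch08, dump
#: (CD3/CD19/CD15/CD64) in Ch10, DNA dye in Ch11, viability dye in Ch12.
DEFAULT_PANEL = PanelConfig(
    channel_map={
        "bf": "Ch01",
        "cd41": "Ch03",
        "ssc": "Ch06",
        "cd45": "Ch08",
        "dump": "Ch10",
        "dna": "Ch11",
        "viability": "Ch12",
    }
)


@dataclass
class EventImage:
    """One acquired object: co-registered per-channel rasters.

    ``rasters`` maps channel id → 2-D unsigned-integer array; all channels
    of one event share the same height × width.
    """

    object_id: int
    time: float
    rasters: dict[str, np.ndarray]

    def validate(self, max_pixel: int | None = None) -> None:
        if self.time < 0:
            raise ValueError(f"event {self.object_id}: negative time")
        shapes = {ch: r.shape for ch, r in self.rasters.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(
                f"event {self.object_id}: raster dimension mismatch {shapes}"
            )
        for ch, r in self.rasters.items():
            if r.ndim != 2:
                raise ValueError(f"event {self.object_id}/{ch}: raster must be 2-D")
            if np.issubdtype(r.dtype, np.signedinteger) and (r < 0).any():
                raise ValueError(f"event {self.object_id}/{ch}: negative pixels")
            if max_pixel is not None and r.max(initial=0) > max_pixel:
                raise ValueError(
                    f"event {self.object_id}/{ch}: pixel exceeds {max_pixel}"
                )

    def channel(self, channel_id: str) -> np.ndarray:
        try:
            return self.rasters[channel_id]
        except KeyError:
            raise KeyError(
                f"event {self.object_id}: channel {channel_id!r} missing"
            ) from None


@dataclass
class EventSet:
    """Ordered gallery of events plus the panel they were acquired with."""

    panel: PanelConfig
    events: list[EventImage]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        ids = [e.object_id for e in self.events]
        if len(set(ids)) != len(ids):
            raise ValueError("object_ids must be unique")
        if self.labels is not None and len(self.labels) != len(self.events):
            raise ValueError("labels must cover every event")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __getitem__(self, i: int) -> EventImage:
        return self.events[i]

    @property
    def object_ids(self) -> np.ndarray:
        return np.array([e.object_id for e in self.events])

    def raster(self, event: EventImage, marker: str) -> np.ndarray:
        """Raster of ``event`` addressed by marker role."""
        return event.channel(self.panel.channel(marker))

    def subset(self, object_ids: Sequence[int]) -> "EventSet":
        keep = set(int(i) for i in object_ids)
        idx = [i for i, e in enumerate(self.events) if e.object_id in keep]
        return EventSet(
            panel=self.panel,
            events=[self.events[i] for i in idx],
            labels=[self.labels[i] for i in idx] if self.labels is not None else None,
        )


# ---------------------------------------------------------------------------
# Gallery I/O: per-sample directory with index.csv + multipage TIFF
# ---------------------------------------------------------------------------

_IMAGES_TIFF = "images.tif"
_PANEL_FILE = "panel.json"


def save_event_set(events: EventSet, gallery_path: str | Path) -> Path:
    """Write a gallery directory: ``index.csv`` + one multipage TIFF.

    Pages are written event-major, channel-minor, in panel channel order;
    ``index.csv`` records one row per (event, channel) with the page
    number, so :func:`load_event_set` inverts this bit-exactly.
    """
    gallery = Path(gallery_path)
    gallery.mkdir(parents=True, exist_ok=True)
    channel_order = list(events.panel.channel_map.values())

    rows = []
    pages = []
    page_no = 0
    for ev in events.events:
        ev.validate(events.panel.max_pixel)
        for ch in channel_order:
            rows.append(
                {
                    "object_id": ev.object_id,
                    "time_s": ev.time,
                    "channel": ch,
                    "file": _IMAGES_TIFF,
                    "page": page_no,
                }
            )
            pages.append(np.ascontiguousarray(ev.channel(ch)))
            page_no += 1

    index = pd.DataFrame(rows, columns=INDEX_COLUMNS)
    index.to_csv(gallery / "index.csv", index=False)
    if pages:
        with tifffile.TiffWriter(gallery / _IMAGES_TIFF) as tif:
            for page in pages:
                tif.write(page, contiguous=False)
    events.panel.save(gallery / _PANEL_FILE)
    if events.labels is not None:
        pd.DataFrame(
            {"object_id": events.object_ids, "label": events.labels}
        ).to_csv(gallery / "labels.csv", index=False)
    return gallery


def load_event_set(
    gallery_path: str | Path, panel: PanelConfig | None = None
) -> EventSet:
    """Load a gallery directory written by :func:`save_event_set`.

    The order of ``index.csv`` is preserved.  A row referencing a missing
    TIFF page raises an error naming the object and channel.
    """
    gallery = Path(gallery_path)
    if not gallery.exists():
        raise FileNotFoundError(f"gallery path does not exist: {gallery}")
    index_path = gallery / "index.csv"
    if not index_path.exists():
        raise FileNotFoundError(f"missing index.csv in {gallery}")
    index = pd.read_csv(index_path)
    missing_cols = set(INDEX_COLUMNS) - set(index.columns)
    if missing_cols:
        raise ValueError(f"index.csv missing columns {sorted(missing_cols)}")

    if panel is None:
        panel_file = gallery / _PANEL_FILE
        if panel_file.exists():
            panel = PanelConfig.load(panel_file)
        else:
            raise ValueError("no panel.json in gallery; pass panel explicitly")

    page_cache: dict[str, list[np.ndarray]] = {}
    for fname in index["file"].unique():
        fpath = gallery / fname
        if not fpath.exists():
            raise FileNotFoundError(f"image file referenced by index missing: {fpath}")
        with tifffile.TiffFile(fpath) as tif:
            page_cache[fname] = [p.asarray() for p in tif.pages]

    events: list[EventImage] = []
    # groupby(sort=False) preserves first-appearance order of the index
    for object_id, grp in index.groupby("object_id", sort=False):
        rasters: dict[str, np.ndarray] = {}
        t = float(grp["time_s"].iloc[0])
        for _, row in grp.iterrows():
            pages = page_cache[row["file"]]
            page = int(row["page"])
            if page >= len(pages):
                raise ValueError(
                    f"object {object_id}, channel {row['channel']}: "
                    f"page {page} not present in {row['file']}"
                )
            rasters[str(row["channel"])] = pages[page]
        for ch in panel.channel_map.values():
            if ch not in rasters:
                raise ValueError(f"object {object_id}: channel {ch} missing from index")
        ev = EventImage(object_id=int(object_id), time=t, rasters=rasters)
        ev.validate()
        events.append(ev)

    labels = None
    labels_path = gallery / "labels.csv"
    if labels_path.exists():
        ldf = pd.read_csv(labels_path).set_index("object_id")
        labels = [str(ldf.loc[e.object_id, "label"]) for e in events]
    return EventSet(panel=panel, events=events, labels=labels)


# ---------------------------------------------------------------------------
# Feature-table export
# ---------------------------------------------------------------------------


def export_features_fcs(table: pd.DataFrame, path: str | Path) -> Path:
    """Export a feature table as an FCS 3.1 file (one parameter per column).

    Interoperability hook for conventional cytometry tooling: each numeric
    feature column becomes an FCS parameter, each row an event.
    """
    if len(table) == 0:
        raise ValueError("cannot export an empty feature table to FCS")
    numeric = table.select_dtypes(include=[np.number])
    data = numeric.to_numpy(dtype=np.float32)
    data = np.nan_to_num(data, nan=-1.0)
    _fcs.write_fcs(Path(path), data, list(numeric.columns))
    return Path(path)


def export_features_csv(
    table: pd.DataFrame, path: str | Path, units: Mapping[str, str] | None = None
) -> Path:
    """Write the feature table as CSV plus a units sidecar JSON."""
    path = Path(path)
    table.to_csv(path, index=True, index_label="object_id")
    if units is not None:
        sidecar = path.with_suffix(path.suffix + ".units.json")
        sidecar.write_text(json.dumps(dict(units), indent=2))
    return path
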