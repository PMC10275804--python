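"""Event tables, file I/O and run manifests.

An :class:`EventTable` holds per-event measurements for one sample under
canonical channel names (``FSC-A``, ``FSC-H``, ``SSC-A`` and ``FLUOR``).
Files may use instrument-specific names (e.g. the B2-A detector for GFP);
a *channel map* translates canonical names to source names at read time.

Two on-disk renderings are supported: FCS 3.0/3.1 (read) / FCS 3.1 (write)
and a plain CSV dialect (header row of channel names, one event per row).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .fcs import read_fcs, write_fcs

__all__ = [
    "EventTable",
    "CHANNELS",
    "DEFAULT_CHANNEL_MAP",
    "ROLES",
    "read_events",
    "write_events",
    "read_manifest",
    "write_manifest",
]

#: canonical channel names, in storage order
CHANNELS = ("FSC-A", "FSC-H", "SSC-A", "FLUOR")

#: canonical -> source-file channel name (B2-A: GFP detector area)
DEFAULT_CHANNEL_MAP: dict[str, str] = {
    "FSC-A": "FSC-A",
    "FSC-H": "FSC-H",
    "SSC-A": "SSC-A",
    "FLUOR": "B2-A",
}

#: sample roles understood by manifests and gating calibration
ROLES = ("experimental", "control_0", "control_1", "control_2")

#: true_class sentinel codes used by the simulator
DEBRIS_LABEL = -1
DOUBLET_LABEL = -2


@dataclass
class EventTable:
    """Per-event measurements for one flow-cytometry sample.

    ``data`` has the canonical channel columns plus, for simulated samples,
    a ``true_class`` integer column (class index; -1 debris, -2 doublet).
    """

    data: pd.DataFrame
    role: str | None = None
    generation: int | None = None
    population: str | None = None
    channel_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.data.columns]
        if missing:
            raise ValueError(f"EventTable is missing required channels: {missing}")
        for chan in ("FSC-A", "FSC-H", "SSC-A"):
            col = self.data[chan].to_numpy()
            if len(col) and np.nanmin(col) < 0:
                raise ValueError(f"scatter channel {chan} contains negative values")

    def __len__(self) -> int:
        return len(self.data)

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.data[channel].to_numpy(dtype=float)

    @property
    def true_class(self) -> np.ndarray | None:
        if "true_class" in self.data.columns:
            return self.data["true_class"].to_numpy()
        return None

    def subset(self, mask: np.ndarray) -> "EventTable":
        return replace(self, data=self.data.loc[np.asarray(mask)].reset_index(drop=True))


def _invert_map(channel_map: dict[str, str] | None) -> dict[str, str]:
    cmap = dict(DEFAULT_CHANNEL_MAP)
    if channel_map:
        cmap.update(channel_map)
    fluor = [k for k in cmap if k == "FLUOR"]
    if len(fluor) != 1:
        raise ValueError("channel map must name exactly one FLUOR channel")
    return cmap


def read_events(
    path: str | os.PathLike,
    channel_map: dict[str, str] | None = None,
    role: str | None = None,
    generation: int | None = None,
    population: str | None = None,
) -> EventTable:
    """Read a sample from an FCS or CSV file.

    ``channel_map`` maps canonical names (``FSC-A``, ``FSC-H``, ``SSC-A``,
    ``FLUOR``) to the names used in the file. Missing required channels
    raise ``KeyError`` naming the channel; extra channels are ignored
    (except a ``true_class`` column, which is preserved).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = _invert_map(channel_map)
    if path.suffix.lower() == ".fcs":
        raw, _ = read_fcs(path)
    else:
        raw = pd.read_csv(path)
    cols = {}
    for canonical, source in cmap.items():
        if source not in raw.columns:
            raise KeyError(
                f"{path.name}: required channel {canonical} "
                f"(source name {source!r}) not found in file"
            )
        cols[canonical] = raw[source].to_numpy(dtype=float)
    data = pd.DataFrame(cols)
    if "true_class" in raw.columns:
        data["true_class"] = raw["true_class"].to_numpy()
    return EventTable(
        data=data, role=role, generation=generation, population=population,
        channel_map=cmap,
    )


def write_events(
    table: EventTable,
    path: str | os.PathLike,
    fmt: str | None = None,
    include_true_class: bool = False,
) -> None:
    """Write a sample as FCS 3.1 or CSV (chosen by *fmt* or the extension)."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    cmap = table.channel_map or dict(DEFAULT_CHANNEL_MAP)
    out = pd.DataFrame(
        {cmap.get(c, c): table.data[c].to_numpy(dtype=float) for c in CHANNELS}
    )
    if include_true_class and "true_class" in table.data.columns:
        out["true_class"] = table.data["true_class"].to_numpy()
    if fmt == "fcs":
        extra = {}
        if table.role is not None:
            extra["CNVFLOW$ROLE"] = str(table.role)
        if table.generation is not None:
            extra["CNVFLOW$GENERATION"] = str(table.generation)
        write_fcs(path, out, extra_keywords=extra)
    elif fmt == "csv":
        out.to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported sample format {fmt!r}")


def write_manifest(manifest: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a run manifest (columns: file, role, generation[, population])."""
    required = {"file", "role", "generation"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest requires columns {sorted(required)}")
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    manifest = pd.read_csv(path, sep="\t")
    required = {"file", "role", "generation"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"{path}: manifest requires columns {sorted(required)}")
    bad = set(manifest["role"]) - set(ROLES)
    if bad:
        raise ValueError(f"{path}: unknown roles {sorted(bad)}")
    manifest["generation"] = manifest["generation"].astype(int)
    return manifest
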