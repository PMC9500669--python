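"""Reading and writing imaging stacks, mechanics traces and result tables.

Two-channel stacks are stored as multi-page TIFF (ImageJ-flavoured, axes
``ZCYX``) with the lateral pixel size in the resolution tags and the z-step in
the ImageJ ``spacing`` field.  Channel order on disk is never guessed: readers
take an explicit ``channel_map`` from channel role to page index.

Mechanics traces travel as plain CSV with ``time_s`` and ``force_mn`` columns;
strain-step annotations and geometry references live in ``#``-prefixed header
lines so a trace file is self-contained.  Strains are written as percent at the
I/O boundary and held as dimensionless fractions in memory.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "MechTrace",
    "read_stack",
    "write_stack",
    "read_mech_trace",
    "write_mech_trace",
    "write_results",
    "read_results",
    "write_ground_truth",
]

#: Channel roles every stack must carry.
CHANNEL_ROLES = ("shg_forward", "autofluorescence")

#: Default on-disk channel order (the package's own writer convention).
DEFAULT_CHANNEL_MAP: Mapping[str, int] = {"shg_forward": 0, "autofluorescence": 1}

RESULTS_SCHEMA_VERSION = 1


@dataclass
class ImageStack:
    """A two-channel 3D voxel stack (slices x rows x cols) with calibration.

    ``shg_forward`` holds the forward-scattered second-harmonic signal
    (myosin bands plus extracellular collagen); ``autofluorescence`` holds the
    backward-collected >460 nm cell-body signal used as the intracellular
    reference.
    """

    shg_forward: np.ndarray
    autofluorescence: np.ndarray
    pixel_size_um: float
    z_step_um: float = 1.0

    def __post_init__(self) -> None:
        self.shg_forward = _as_stack(self.shg_forward)
        self.autofluorescence = _as_stack(self.autofluorescence)
        if self.shg_forward.shape != self.autofluorescence.shape:
            raise ValueError(
                "channel shape mismatch: shg_forward "
                f"{self.shg_forward.shape} vs autofluorescence {self.autofluorescence.shape}"
            )
        if not np.isfinite(self.pixel_size_um) or self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be positive")

    @property
    def n_slices(self) -> int:
        return self.shg_forward.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.shg_forward.shape

    def channel(self, role: str) -> np.ndarray:
        if role not in CHANNEL_ROLES:
            raise KeyError(f"unknown channel role {role!r}; expected one of {CHANNEL_ROLES}")
        return getattr(self, role)


def _as_stack(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"channel data must be 2D or 3D, got ndim={arr.ndim}")
    return arr


@dataclass
class MechTrace:
    """A force-time trace with strain-step annotations.

    ``steps`` is a sequence of ``(onset_s, strain_fraction)`` pairs, strains
    strictly increasing across steps (the stretch protocol ramps upward).
    ``pcsa_cm2``/``l0_cm`` are optional geometry references carried with the
    trace so stress conversion happens exactly once.
    """

    time_s: np.ndarray
    force_mn: np.ndarray
    steps: tuple[tuple[float, float], ...] = ()
    l0_cm: float | None = None
    pcsa_cm2: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=np.float64)
        self.force_mn = np.asarray(self.force_mn, dtype=np.float64)
        if self.time_s.ndim != 1 or self.time_s.size == 0:
            raise ValueError("time_s must be a non-empty 1D array")
        if self.time_s.shape != self.force_mn.shape:
            raise ValueError("time_s and force_mn must have the same length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")
        self.steps = tuple((float(t), float(e)) for t, e in self.steps)
        if self.steps:
            onsets = np.array([t for t, _ in self.steps])
            strains = np.array([e for _, e in self.steps])
            if np.any(np.diff(onsets) <= 0):
                raise ValueError("step onsets must be strictly increasing (overlapping steps)")
            if np.any(np.diff(strains) <= 0):
                raise ValueError("step strains must be strictly increasing")
            if onsets[0] < self.time_s[0] or onsets[-1] > self.time_s[-1]:
                raise ValueError("step onsets must lie within the time range")

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------

def write_stack(path: str | Path, stack: ImageStack) -> Path:
    """Write a two-channel stack as an ImageJ-flavoured TIFF (axes ZCYX)."""
    path = Path(path)
    data = np.stack(
        [stack.shg_forward, stack.autofluorescence], axis=1
    ).astype(np.float32)  # (Z, C, Y, X)
    px = stack.pixel_size_um
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / px, 1.0 / px),
        metadata={"spacing": stack.z_step_um, "unit": "um", "axes": "ZCYX"},
    )
    return path


def read_stack(
    path: str | Path,
    channel_map: Mapping[str, int] = DEFAULT_CHANNEL_MAP,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
) -> ImageStack:
    """Read a multi-page two-channel TIFF into an :class:`ImageStack`.

    Parameters
    ----------
    channel_map
        Role -> channel index, e.g. ``{"shg_forward": 0, "autofluorescence": 1}``.
        Never inferred from the file: the two channels are semantically
        asymmetric and swapping them silently corrupts every downstream step.
    pixel_size_um, z_step_um
        Override the file's calibration.  If the file carries no pixel size and
        no override is given, reading fails loudly.
    """
    path = Path(path)
    for role in CHANNEL_ROLES:
        if role not in channel_map:
            raise ValueError(f"{role} channel required: channel_map is missing it")

    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        file_px = _pixel_size_from_tiff(tf)
        file_z = None
        if tf.imagej_metadata and "spacing" in tf.imagej_metadata:
            file_z = float(tf.imagej_metadata["spacing"])

    data = np.asarray(data, dtype=np.float64)
    # Normalise to (Z, C, Y, X)
    if data.ndim == 2:
        raise ValueError("autofluorescence channel required: file has a single page")
    if data.ndim == 3:
        # Either (C, Y, X) single slice or (Z, Y, X) single channel.
        if "C" in axes:
            data = data[None]
        elif data.shape[0] >= 2 and "Z" not in axes:
            data = data[None]
        else:
            raise ValueError("autofluorescence channel required: file has one channel")
    if data.ndim != 4:
        raise ValueError(f"cannot interpret TIFF with axes {axes!r} and shape {data.shape}")
    n_channels = data.shape[1]
    for role in CHANNEL_ROLES:
        idx = channel_map[role]
        if not 0 <= idx < n_channels:
            raise ValueError(
                f"{role} channel required: channel index {idx} out of range "
                f"for a {n_channels}-channel file"
            )

    px = pixel_size_um if pixel_size_um is not None else file_px
    if px is None:
        raise ValueError(
            "no pixel-size calibration in file and no override given; "
            "pass pixel_size_um explicitly"
        )
    px = float(px)
    if not np.isfinite(px) or px <= 0:
        raise ValueError(f"pixel size must be a positive number, got {px}")
    z = z_step_um if z_step_um is not None else (file_z if file_z is not None else 1.0)

    return ImageStack(
        shg_forward=data[:, channel_map["shg_forward"]],
        autofluorescence=data[:, channel_map["autofluorescence"]],
        pixel_size_um=px,
        z_step_um=float(z),
    )


def _pixel_size_from_tiff(tf: "tifffile.TiffFile") -> float | None:
    page = tf.pages[0]
    tag = page.tags.get("XResolution")
    if tag is None:
        return None
    num, den = tag.value
    # (1, 1) is the writer default for uncalibrated files, not a calibration
    if num == 0 or num == den:
        return None
    return float(den) / float(num)  # resolution is px per unit


# ---------------------------------------------------------------------------
# Mechanics traces
# ---------------------------------------------------------------------------

_STEP_RE = re.compile(r"#\s*step\s+onset_s=([0-9.eE+-]+)\s+strain_pct=([0-9.eE+-]+)")
_META_RE = re.compile(r"#\s*(l0_cm|pcsa_cm2)=([0-9.eE+-]+)")


def write_mech_trace(path: str | Path, trace: MechTrace) -> Path:
    """Write a trace as CSV with step/geometry annotations in header comments."""
    path = Path(path)
    lines = ["# sarcolattice mech trace v1"]
    if trace.l0_cm is not None:
        lines.append(f"# l0_cm={trace.l0_cm!r}")
    if trace.pcsa_cm2 is not None:
        lines.append(f"# pcsa_cm2={trace.pcsa_cm2!r}")
    for onset, strain in trace.steps:
        lines.append(f"# step onset_s={onset!r} strain_pct={100.0 * strain!r}")
    df = pd.DataFrame({"time_s": trace.time_s, "force_mn": trace.force_mn})
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False, float_format="%.12g")
    return path


def read_mech_trace(path: str | Path) -> MechTrace:
    """Read a trace CSV; validates monotone time and well-ordered steps."""
    path = Path(path)
    steps: list[tuple[float, float]] = []
    meta: dict = {}
    with open(path) as fh:
        header_lines = []
        for line in fh:
            if line.startswith("#"):
                header_lines.append(line)
            else:
                break
    for line in header_lines:
        m = _STEP_RE.match(line)
        if m:
            steps.append((float(m.group(1)), float(m.group(2)) / 100.0))
            continue
        m = _META_RE.match(line)
        if m:
            meta[m.group(1)] = float(m.group(2))
    df = pd.read_csv(path, comment="#")
    for col in ("time_s", "force_mn"):
        if col not in df.columns:
            raise ValueError(f"trace CSV must have a {col!r} column")
    return MechTrace(
        time_s=df["time_s"].to_numpy(),
        force_mn=df["force_mn"].to_numpy(),
        steps=tuple(steps),
        l0_cm=meta.get("l0_cm"),
        pcsa_cm2=meta.get("pcsa_cm2"),
    )


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_results(path: str | Path, records: Sequence[Mapping]) -> Path:
    """Write result records as long-format CSV, one row per analysis unit.

    The schema version is carried in a ``schema_version`` column so files stay
    self-describing; an empty record list produces a header-only file.
    """
    path = Path(path)
    rows = [dict(r) for r in records]
    for r in rows:
        r.setdefault("schema_version", RESULTS_SCHEMA_VERSION)
    if rows:
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame(columns=["schema_version"])
    cols = ["schema_version"] + [c for c in df.columns if c != "schema_version"]
    df = df[cols]
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ground_truth(path: str | Path, payload: Mapping) -> Path:
    """Write a ground-truth / config sidecar as JSON (arrays listified)."""
    path = Path(path)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(dict(payload), fh, indent=2, default=_default, sort_keys=True)
    return path
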