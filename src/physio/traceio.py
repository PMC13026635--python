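"""Sweep / stack containers, file round-tripping and recording conventions.

Canonical units repo-wide: mV, pA, ms, pF, MΩ, nS.  All unit conversions
happen at I/O boundaries; in-memory arrays are always in canonical units.

The canonical exchange format for sweeps is delimited text: header lines of
the form ``# key: value`` followed by one column per sweep (time implicit
from the sample interval).  Image stacks are multi-page TIFF.  Results are
JSON per cell plus TSV per-group tables.

Voltage convention: recorded potentials carry a liquid-junction-potential
(LJP) correction flag.  :func:`apply_ljp_correction` shifts every sample by
``-ljp`` (standard direction for a K-gluconate internal solution) and sets
the flag; applying it twice is refused.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile

from .errors import (
    AlreadyCorrectedError,
    InsufficientDepthError,
    InvalidParameterError,
    MalformedFileError,
    SignalKindError,
)

VOLTAGE = "voltage"
CURRENT = "current"

#: Closed set of cohort group labels: wild type, untreated knockout, and
#: low-/high-dose treated knockout.
GROUPS = ("WT", "KO", "LD", "HD")

DEFAULT_LJP_MV = 16.0


@dataclass
class Sweep:
    """One uniformly sampled recording trace.

    Parameters
    ----------
    samples
        Sample values in canonical units (mV for voltage, pA for current).
    sample_interval
        Time between samples in ms (0.01 ms ≡ 100 kHz).
    kind
        ``"voltage"`` or ``"current"``.
    stimulus
        Protocol descriptor (name, amplitudes, onsets, durations).  Time
        convention: t = 0 at sweep start; the stimulus onset lives here and
        is never inferred from the trace.
    ljp_corrected
        Whether the liquid junction potential has been subtracted.  Only
        meaningful for voltage sweeps.
    """

    samples: np.ndarray
    sample_interval: float
    kind: str = VOLTAGE
    stimulus: dict = field(default_factory=dict)
    cell_id: str | None = None
    group: str | None = None
    ljp_corrected: bool = False

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_interval <= 0:
            raise InvalidParameterError("sample_interval must be > 0")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise InvalidParameterError("a sweep needs >= 2 samples")
        if self.kind not in (VOLTAGE, CURRENT):
            raise InvalidParameterError(f"unknown signal kind {self.kind!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def sample_rate_khz(self) -> float:
        return 1.0 / self.sample_interval

    @property
    def duration(self) -> float:
        """Sweep duration in ms."""
        return self.n_samples * self.sample_interval

    @property
    def time(self) -> np.ndarray:
        """Time axis in ms, t = 0 at the first sample."""
        return np.arange(self.n_samples) * self.sample_interval

    def slice_time(self, t0: float, t1: float) -> np.ndarray:
        """Samples in the half-open window [t0, t1) ms."""
        i0 = max(0, int(np.ceil(t0 / self.sample_interval - 1e-9)))
        i1 = min(self.n_samples, int(np.ceil(t1 / self.sample_interval - 1e-9)))
        return self.samples[i0:i1]


@dataclass
class SweepSet:
    """A homogeneous list of repetitions of one protocol."""

    sweeps: list[Sweep]

    def __post_init__(self):
        if not self.sweeps:
            raise InvalidParameterError("SweepSet must be non-empty")
        s0 = self.sweeps[0]
        for s in self.sweeps[1:]:
            if s.sample_interval != s0.sample_interval:
                raise InvalidParameterError("heterogeneous sample_interval")
            if s.n_samples != s0.n_samples:
                raise InvalidParameterError("heterogeneous sweep lengths")
            if s.kind != s0.kind:
                raise InvalidParameterError("heterogeneous signal kinds")

    def __len__(self) -> int:
        return len(self.sweeps)

    def __iter__(self):
        return iter(self.sweeps)

    def __getitem__(self, i) -> Sweep:
        return self.sweeps[i]

    @property
    def sample_interval(self) -> float:
        return self.sweeps[0].sample_interval

    @property
    def kind(self) -> str:
        return self.sweeps[0].kind

    def as_array(self) -> np.ndarray:
        """(n_sweeps, n_samples) array view of the set."""
        return np.stack([s.samples for s in self.sweeps])


@dataclass
class ImageStack:
    """Ordered confocal planes with voxel geometry.

    ``planes`` is a (z, y, x) array; bit depth is carried by the dtype
    (uint8 or uint16).  Voxel size in nm, default matching the confocal
    acquisition convention of 320 nm x/y steps and 290 nm z steps.
    """

    planes: np.ndarray
    voxel_size_nm: tuple[float, float, float] = (320.0, 320.0, 290.0)

    def __post_init__(self):
        self.planes = np.asarray(self.planes)
        if self.planes.ndim != 3:
            raise InvalidParameterError("ImageStack planes must be 3-D (z, y, x)")
        if self.planes.dtype not in (np.uint8, np.uint16):
            raise InvalidParameterError("bit depth must be 8 or 16 (uint8/uint16)")

    @property
    def depth(self) -> int:
        return self.planes.shape[0]

    @property
    def bit_depth(self) -> int:
        return 8 if self.planes.dtype == np.uint8 else 16


@dataclass
class CellRecord:
    """Pointers from one cell to its protocol data on disk."""

    cell_id: str
    group: str
    sweep_paths: dict = field(default_factory=dict)  # protocol name -> path
    stack_path: str | None = None
    truth_path: str | None = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise InvalidParameterError(
                f"group must be one of {GROUPS}, got {self.group!r}"
            )


# ---------------------------------------------------------------------------
# Sweep file dialect
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("sample_interval_ms", "kind", "ljp_corrected", "stimulus",
                "cell_id", "group")


def write_sweeps(sweep_set: SweepSet, path: str | Path) -> None:
    """Write a sweep set as delimited text: ``# key: value`` headers, then
    one column per sweep at full float precision."""
    path = Path(path)
    s0 = sweep_set.sweeps[0]
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path, "w") as fh:
        fh.write(f"# sample_interval_ms: {s0.sample_interval!r}\n")
        fh.write(f"# kind: {s0.kind}\n")
        fh.write(f"# ljp_corrected: {str(s0.ljp_corrected).lower()}\n")
        fh.write(f"# stimulus: {json.dumps(s0.stimulus)}\n")
        if s0.cell_id is not None:
            fh.write(f"# cell_id: {s0.cell_id}\n")
        if s0.group is not None:
            fh.write(f"# group: {s0.group}\n")
        data = sweep_set.as_array().T  # (n_samples, n_sweeps)
        for row in data:
            fh.write(sep.join(f"{v:.17g}" for v in row))
            fh.write("\n")


def read_sweeps(path: str | Path) -> SweepSet:
    """Read the delimited-text sweep dialect back into a :class:`SweepSet`.

    Raises :class:`MalformedFileError` on ragged columns or a missing
    ``sample_interval_ms`` header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    headers: dict[str, str] = {}
    rows: list[list[float]] = []
    ncol = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                try:
                    key, value = line[1:].split(":", 1)
                except ValueError:
                    raise MalformedFileError(
                        f"{path}:{lineno}: malformed header line"
                    ) from None
                headers[key.strip()] = value.strip()
                continue
            sep = "," if "," in line else "\t" if "\t" in line else None
            parts = line.split(sep) if sep else line.split()
            if ncol is None:
                ncol = len(parts)
            elif len(parts) != ncol:
                raise MalformedFileError(
                    f"{path}:{lineno}: expected {ncol} columns, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise MalformedFileError(
                    f"{path}:{lineno}: non-numeric sample value"
                ) from None
    if "sample_interval_ms" not in headers:
        raise MalformedFileError(f"{path}: missing sample_interval_ms header")
    if not rows:
        raise MalformedFileError(f"{path}: no data rows")
    dt = float(headers["sample_interval_ms"])
    kind = headers.get("kind", VOLTAGE)
    ljp = headers.get("ljp_corrected", "false").lower() == "true"
    stimulus = json.loads(headers["stimulus"]) if "stimulus" in headers else {}
    cell_id = headers.get("cell_id")
    group = headers.get("group")
    data = np.asarray(rows, dtype=float)  # (n_samples, n_sweeps)
    sweeps = [
        Sweep(data[:, j], dt, kind=kind, stimulus=stimulus,
              cell_id=cell_id, group=group, ljp_corrected=ljp)
        for j in range(data.shape[1])
    ]
    return SweepSet(sweeps)


# ---------------------------------------------------------------------------
# Recording conventions
# ---------------------------------------------------------------------------

def apply_ljp_correction(sweep: Sweep, ljp: float = DEFAULT_LJP_MV,
                         sign: float = -1.0) -> Sweep:
    """Shift every sample of a voltage sweep by ``sign * ljp`` mV.

    The default (sign = -1) subtracts the junction potential, the standard
    direction for a K-gluconate internal solution.  The correction flag is
    stored on the result; re-applying to a flagged sweep is refused so the
    16 mV can never be subtracted twice.
    """
    if sweep.kind != VOLTAGE:
        raise SignalKindError("LJP correction applies to voltage sweeps only")
    if sweep.ljp_corrected:
        raise AlreadyCorrectedError("sweep already LJP-corrected")
    return replace(sweep, samples=sweep.samples + sign * ljp,
                   ljp_corrected=True)


def correct_set(sweep_set: SweepSet, ljp: float = DEFAULT_LJP_MV) -> SweepSet:
    """LJP-correct every sweep of a voltage set (no-op flag check per sweep)."""
    return SweepSet([apply_ljp_correction(s, ljp) for s in sweep_set])


# ---------------------------------------------------------------------------
# Image stacks and result tables
# ---------------------------------------------------------------------------

def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write the stack as a multi-page TIFF (one page per z plane)."""
    tifffile.imwrite(str(path), stack.planes, photometric="minisblack")


def read_stack(path: str | Path,
               voxel_size_nm: tuple[float, float, float] = (320.0, 320.0, 290.0)
               ) -> ImageStack:
    """Read a multi-page TIFF into an :class:`ImageStack` in page order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        planes = tifffile.imread(str(path))
    except Exception as exc:  # tifffile raises several types for bad input
        raise MalformedFileError(f"{path}: not a readable TIFF ({exc})") from exc
    planes = np.asarray(planes)
    if planes.ndim == 2:
        planes = planes[None, :, :]
    if planes.ndim != 3:
        raise MalformedFileError(f"{path}: expected single-channel planes")
    return ImageStack(planes, voxel_size_nm=voxel_size_nm)


def require_depth(stack: ImageStack, depth: int) -> None:
    if stack.depth < depth:
        raise InsufficientDepthError(
            f"stack depth {stack.depth} < required {depth}"
        )


def write_results(records: Sequence[dict], path: str | Path) -> None:
    """Write per-cell result dicts as a TSV table (JSON for nested values)."""
    import pandas as pd

    path = Path(path)
    df = pd.DataFrame(list(records))
    df.to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
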