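"""Domain types and container I/O for multispectral autofluorescence
lifetime imaging (maFLIM) data.

A maFLIM acquisition records, at every image pixel, a fluorescence
intensity decay ``y(x, y, t)`` in each of three emission bands chosen to
preferentially capture collagen (390 ± 20 nm), NADH (452 ± 22.5 nm) and
FAD (>500 nm) autofluorescence.  The types here hold one such multi-band
time-resolved datacube (:class:`MaflimImage`), the instrument response
function measured per band (:class:`InstrumentResponse`), a per-pixel
validity mask (:class:`PixelMask`), and a paired lesion/healthy cohort
(:class:`Dataset`).

On disk each image lives in a single self-describing HDF5 container::

    /bands/{b390,b452,b500}/decay   float64 (rows, cols, n_time)
    /irf/{b390,b452,b500}           float64 (n_time_irf,)
    /mask/valid                     bool    (rows, cols)
    /mask/reason                    uint8   (rows, cols)
    root attrs: dt_ns, rows, cols, n_time, subject_id, site, label,
                instrument_id, full_scale (optional)

Coordinates are row-major, 0-based ``(row, col)``; time index 0 is the
start of the record.
"""

from __future__ import annotations

import enum
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import h5py
import numpy as np

#: Fixed band order: 390 ± 20 nm, 452 ± 22.5 nm, >500 nm.
BANDS: tuple[str, str, str] = ("b390", "b452", "b500")

#: Band label -> feature subscript used throughout (the open-ended
#: ">500 nm" band is subscripted 500).
BAND_SUBSCRIPTS = {"b390": "390", "b452": "452", "b500": "500"}

LABELS = ("healthy", "dysplasia/cancer", "unknown")


class MaflimError(Exception):
    """Base class for all package errors."""


class ValidationError(MaflimError, ValueError):
    """A domain-type invariant is violated."""


class FormatError(MaflimError, ValueError):
    """A container file does not conform to the documented layout."""


class ConfigError(MaflimError, ValueError):
    """A configuration value is out of its admissible range."""


class MaskReason(enum.IntEnum):
    """Why a pixel is (in)valid; ``OK`` iff the pixel is usable."""

    OK = 0
    SATURATED = 1
    LOW_SNR = 2
    MANUAL = 3


@dataclass
class MaflimImage:
    """One multispectral time-resolved datacube.

    Parameters
    ----------
    decay
        Mapping band label -> float array of shape ``(rows, cols, n_time)``.
        All three bands must be present with identical shapes.
    dt
        Time step in ns (reciprocal of the sampling rate; 0.25 ns at
        4 GS/s, 0.16 ns at 6.25 GS/s).
    meta
        Free-form metadata; recognised keys are ``subject_id``, ``site``,
        ``label`` (one of ``healthy | dysplasia/cancer | unknown``) and
        ``instrument_id``.
    full_scale
        Digitizer full scale in the decay's intensity units, if known.
        Required for saturation masking of raw data.
    """

    decay: dict[str, np.ndarray]
    dt: float
    meta: dict = field(default_factory=dict)
    full_scale: float | None = None

    def __post_init__(self) -> None:
        if set(self.decay) != set(BANDS):
            raise ValidationError(
                f"decay must contain exactly the bands {BANDS}, "
                f"got {sorted(self.decay)}"
            )
        shapes = {b: np.asarray(self.decay[b]).shape for b in BANDS}
        ref = shapes[BANDS[0]]
        if len(ref) != 3:
            raise ValidationError(f"decay arrays must be 3-D, got shape {ref}")
        for b, s in shapes.items():
            if s != ref:
                raise ValidationError(f"band {b} shape {s} != {ref}")
        for b in BANDS:
            arr = np.ascontiguousarray(np.asarray(self.decay[b], dtype=np.float64))
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"band {b} contains non-finite values")
            self.decay[b] = arr
        if not (np.isfinite(self.dt) and self.dt > 0):
            raise ValidationError(f"dt must be a positive finite number, got {self.dt}")
        self.dt = float(self.dt)
        label = self.meta.get("label", "unknown")
        if label not in LABELS:
            raise ValidationError(f"label must be one of {LABELS}, got {label!r}")

    @property
    def rows(self) -> int:
        return self.decay[BANDS[0]].shape[0]

    @property
    def cols(self) -> int:
        return self.decay[BANDS[0]].shape[1]

    @property
    def n_time(self) -> int:
        return self.decay[BANDS[0]].shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def time(self) -> np.ndarray:
        """Sample times in ns, starting at 0."""
        return np.arange(self.n_time) * self.dt

    def copy(self) -> "MaflimImage":
        return MaflimImage(
            decay={b: self.decay[b].copy() for b in BANDS},
            dt=self.dt,
            meta=dict(self.meta),
            full_scale=self.full_scale,
        )

    def total_intensity(self) -> np.ndarray:
        """Time- and band-summed intensity map (for display backgrounds)."""
        return sum(self.decay[b].sum(axis=2) for b in BANDS)


@dataclass
class InstrumentResponse:
    """Measured instrument response function (IRF), one trace per band.

    The IRF is the system's temporal response to an instantaneous
    emission event; it must share the time step of the images it is used
    to deconvolve.
    """

    u: dict[str, np.ndarray]
    dt: float

    def __post_init__(self) -> None:
        if set(self.u) != set(BANDS):
            raise ValidationError(
                f"IRF must contain exactly the bands {BANDS}, got {sorted(self.u)}"
            )
        for b in BANDS:
            arr = np.ascontiguousarray(np.asarray(self.u[b], dtype=np.float64))
            if arr.ndim != 1:
                raise ValidationError(f"IRF band {b} must be 1-D")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"IRF band {b} contains non-finite values")
            if np.any(arr < 0):
                raise ValidationError(f"IRF band {b} is negative after baseline removal")
            if arr.sum() * self.dt <= 0:
                raise ValidationError(f"IRF band {b} has non-positive integral")
            peak = int(np.argmax(arr))
            if peak == 0 or peak == arr.size - 1:
                raise ValidationError(f"IRF band {b} peak lies at the record edge")
            self.u[b] = arr
        if not (np.isfinite(self.dt) and self.dt > 0):
            raise ValidationError(f"dt must be positive, got {self.dt}")
        self.dt = float(self.dt)


@dataclass
class PixelMask:
    """Per-pixel validity map with a reason code per pixel."""

    valid: np.ndarray
    reason: np.ndarray

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)
        self.reason = np.asarray(self.reason, dtype=np.uint8)
        if self.valid.shape != self.reason.shape or self.valid.ndim != 2:
            raise ValidationError("valid and reason must be 2-D arrays of equal shape")
        if not np.array_equal(self.valid, self.reason == MaskReason.OK):
            raise ValidationError("invariant violated: valid must equal (reason == OK)")

    @classmethod
    def all_valid(cls, shape: tuple[int, int]) -> "PixelMask":
        return cls(
            valid=np.ones(shape, dtype=bool),
            reason=np.zeros(shape, dtype=np.uint8),
        )

    def copy(self) -> "PixelMask":
        return PixelMask(self.valid.copy(), self.reason.copy())

    def invalidate(self, where: np.ndarray, reason: MaskReason) -> "PixelMask":
        """Return a new mask with ``where`` pixels additionally invalidated.

        Already-invalid pixels keep their original reason (masks only grow).
        """
        where = np.asarray(where, dtype=bool)
        if where.shape != self.valid.shape:
            raise ValidationError("mask shape mismatch")
        new_reason = self.reason.copy()
        newly = where & self.valid
        new_reason[newly] = int(reason)
        return PixelMask(valid=self.valid & ~where, reason=new_reason)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class SubjectRecord:
    """One subject's paired acquisition: a lesion image and a clinically
    healthy contralateral image, plus the biopsy-confirmed grade."""

    subject_id: str
    lesion: MaflimImage
    healthy: MaflimImage
    grade: str = "SCC"  # MiD | MoD | HiD | SCC

    def __post_init__(self) -> None:
        if self.lesion.meta.get("label") == "healthy":
            raise ValidationError("lesion image carries a 'healthy' label")
        if self.healthy.meta.get("label") == "dysplasia/cancer":
            raise ValidationError("healthy image carries a lesion label")


@dataclass
class Dataset:
    """Paired cohort: each subject contributes exactly one lesion image and
    one contralateral healthy image."""

    subjects: list[SubjectRecord]

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate subject ids in dataset")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.subjects)

    @property
    def n_images(self) -> int:
        return 2 * len(self.subjects)


# ---------------------------------------------------------------------------
# Container I/O
# ---------------------------------------------------------------------------

_META_KEYS = ("subject_id", "site", "label", "instrument_id")


def write_maflim(
    image: MaflimImage,
    irf: InstrumentResponse,
    mask: PixelMask,
    path: str | os.PathLike,
) -> None:
    """Write an image, its IRF and mask to one HDF5 container.

    The write is atomic: data land in a temporary sibling file which is
    renamed over ``path`` only after a successful flush, so a crash never
    leaves a half-written container. Invariants are validated (by the
    type constructors) before any bytes are written.
    """
    if mask.valid.shape != image.shape:
        raise ValidationError(
            f"mask shape {mask.valid.shape} != image shape {image.shape}"
        )
    if abs(irf.dt - image.dt) > 1e-12:
        raise ValidationError(f"IRF dt {irf.dt} != image dt {image.dt}")

    path = os.fspath(path)
    dirname = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(suffix=".h5", dir=dirname)
    os.close(fd)
    try:
        with h5py.File(tmp, "w") as f:
            for b in BANDS:
                f.create_dataset(f"bands/{b}/decay", data=image.decay[b])
                f.create_dataset(f"irf/{b}", data=irf.u[b])
            f.create_dataset("mask/valid", data=mask.valid)
            f.create_dataset("mask/reason", data=mask.reason)
            f.attrs["dt_ns"] = image.dt
            f.attrs["rows"] = image.rows
            f.attrs["cols"] = image.cols
            f.attrs["n_time"] = image.n_time
            if image.full_scale is not None:
                f.attrs["full_scale"] = float(image.full_scale)
            for key in _META_KEYS:
                f.attrs[key] = str(image.meta.get(key, ""))
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_maflim(
    path: str | os.PathLike,
) -> tuple[MaflimImage, InstrumentResponse, PixelMask]:
    """Read a container written by :func:`write_maflim`.

    Raises :class:`FormatError` naming the first missing dataset or
    attribute, and :class:`ValidationError` if the stored arrays violate
    the type invariants (e.g. band shape mismatch).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        for required in ("bands", "irf", "mask"):
            if required not in f:
                raise FormatError(f"missing group '{required}' in {path}")
        decay = {}
        u = {}
        for b in BANDS:
            if f"bands/{b}/decay" not in f:
                raise FormatError(f"missing dataset 'bands/{b}/decay' in {path}")
            if f"irf/{b}" not in f:
                raise FormatError(f"missing dataset 'irf/{b}' in {path}")
            decay[b] = f[f"bands/{b}/decay"][()]
            u[b] = f[f"irf/{b}"][()]
        for name in ("mask/valid", "mask/reason"):
            if name not in f:
                raise FormatError(f"missing dataset '{name}' in {path}")
        valid = f["mask/valid"][()]
        reason = f["mask/reason"][()]
        if "dt_ns" not in f.attrs:
            raise FormatError(f"missing attribute 'dt_ns' in {path}")
        dt = float(f.attrs["dt_ns"])
        meta = {k: str(f.attrs[k]) for k in _META_KEYS if k in f.attrs}
        if meta.get("label", "") == "":
            meta["label"] = "unknown"
        full_scale = float(f.attrs["full_scale"]) if "full_scale" in f.attrs else None

    image = MaflimImage(decay=decay, dt=dt, meta=meta, full_scale=full_scale)
    irf = InstrumentResponse(u=u, dt=dt)
    mask = PixelMask(valid=valid, reason=reason)
    if mask.valid.shape != image.shape:
        raise ValidationError("stored mask shape does not match image shape")
    return image, irf, mask
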