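"""Raw-decay preprocessing.

Raw maFLIM decays carry a DC offset from the digitizer, occasional
saturated (clipped) pixels, broadband noise, and non-tissue regions
(teeth) that must be excluded before lifetime fitting.  The chain applied
here, in fixed order:

1. offset/background subtraction (per-pixel leading-baseline mean),
2. saturation masking (threshold on raw maximum amplitude),
3. 5 × 5 spatial averaging to boost temporal SNR,
4. SNR masking at 15 dB,
5. manual masking of user-supplied regions (e.g. tooth areas).

Masks only grow along the chain.  An extra utility resamples decays and
IRF onto a coarser common grid so data from instruments digitizing at
4 GS/s and 6.25 GS/s can be analysed together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image as _PILImage, ImageDraw as _PILDraw
from scipy.ndimage import uniform_filter

from .core import (
    BANDS,
    ConfigError,
    InstrumentResponse,
    MaflimImage,
    MaskReason,
    PixelMask,
    ValidationError,
)


@dataclass
class PreprocessConfig:
    """Knobs of the preprocessing chain.

    baseline_window
        Number of leading pre-pulse samples used to estimate the DC
        offset and the baseline noise level.
    saturation_fraction
        Fraction of the digitizer full scale at or above which a sample
        counts as clipped (default 0.98, tolerant of quantization at the
        rail).
    kernel_size
        Spatial averaging order (kernel side length, default 5).
    snr_threshold_db
        Pixels whose worst-band SNR falls below this are masked
        (default 15 dB).
    target_dt_ns
        Optional common time step for cross-instrument harmonization.
    """

    baseline_window: int = 16
    saturation_fraction: float = 0.98
    kernel_size: int = 5
    snr_threshold_db: float = 15.0
    target_dt_ns: float | None = None

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ConfigError(f"kernel_size must be odd and >= 1, got {self.kernel_size}")
        if not np.isfinite(self.snr_threshold_db):
            raise ConfigError("snr_threshold_db must be finite")
        if not (0 < self.saturation_fraction <= 1):
            raise ConfigError(
                f"saturation_fraction must be in (0, 1], got {self.saturation_fraction}"
            )
        if self.baseline_window < 1:
            raise ConfigError("baseline_window must be >= 1")


def subtract_background(image: MaflimImage, cfg: PreprocessConfig) -> MaflimImage:
    """Subtract the per-pixel DC offset estimated from the leading baseline.

    The mean of the first ``cfg.baseline_window`` (pre-pulse) samples is
    removed from the whole trace, per pixel and per band.  The output may
    contain small negative values (noise around zero).
    """
    if cfg.baseline_window >= image.n_time:
        raise ConfigError(
            f"baseline_window ({cfg.baseline_window}) must be < n_time ({image.n_time})"
        )
    out = image.copy()
    for b in BANDS:
        baseline = out.decay[b][:, :, : cfg.baseline_window].mean(axis=2, keepdims=True)
        out.decay[b] = out.decay[b] - baseline
    return out


def mask_saturated(image: MaflimImage, cfg: PreprocessConfig) -> PixelMask:
    """Mask pixels whose raw amplitude reaches the digitizer rail.

    A pixel is saturated iff its maximum over time and bands is at or
    above ``saturation_fraction × full_scale``.  Must be run on raw
    (pre-background-subtraction) amplitudes.
    """
    if image.full_scale is None:
        raise ConfigError("image.full_scale is unknown; saturation masking needs it")
    thresh = cfg.saturation_fraction * image.full_scale
    peak = np.max([image.decay[b].max(axis=2) for b in BANDS], axis=0)
    mask = PixelMask.all_valid(image.shape)
    return mask.invalidate(peak >= thresh, MaskReason.SATURATED)


def spatial_average(
    image: MaflimImage,
    cfg: PreprocessConfig,
    mask: PixelMask | None = None,
) -> MaflimImage:
    """Replace each temporal sample by its spatial-neighborhood mean.

    The mean is taken over the ``kernel_size²`` neighborhood, per band,
    excluding masked pixels and out-of-bounds positions (shrink-to-valid:
    the mean runs over the remaining members, no padding is invented at
    the field-of-view rim).  Pixels with no valid neighbor keep their
    original trace.
    """
    k = cfg.kernel_size
    if image.rows < k or image.cols < k:
        raise ConfigError(
            f"image {image.shape} smaller than kernel {k}x{k} in a spatial dim"
        )
    if k == 1:
        return image.copy()
    valid = mask.valid if mask is not None else np.ones(image.shape, dtype=bool)
    w = valid.astype(np.float64)
    # uniform_filter computes a neighborhood mean with zero padding; the
    # ratio of (masked data mean) to (mask mean) is the shrink-to-valid mean.
    counts = uniform_filter(w, size=k, mode="constant", cval=0.0)
    out = image.copy()
    for b in BANDS:
        masked = out.decay[b] * w[:, :, None]
        num = uniform_filter(masked, size=(k, k, 1), mode="constant", cval=0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            avg = num / counts[:, :, None]
        keep = counts <= 0
        if keep.any():
            avg[keep, :] = out.decay[b][keep, :]
        out.decay[b] = avg
    return out


def pixel_snr_db(image: MaflimImage, cfg: PreprocessConfig) -> np.ndarray:
    """Worst-band SNR map in dB: ``20·log10(peak / baseline noise std)``.

    Expects background-subtracted (and typically spatially averaged)
    decays; the noise std is estimated from the leading baseline window.
    Zero noise yields +inf (the pixel is trivially kept).
    """
    snr = np.full(image.shape, np.inf)
    for b in BANDS:
        d = image.decay[b]
        peak = d.max(axis=2)
        noise = d[:, :, : cfg.baseline_window].std(axis=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            band_snr = np.where(
                noise > 0,
                20.0 * np.log10(np.maximum(peak, 1e-300) / np.where(noise > 0, noise, 1.0)),
                np.inf,
            )
        band_snr = np.where(peak <= 0, -np.inf, band_snr)
        snr = np.minimum(snr, band_snr)
    return snr


def mask_low_snr(
    image: MaflimImage, cfg: PreprocessConfig, mask: PixelMask | None = None
) -> PixelMask:
    """Mask pixels whose worst-band SNR is below the threshold (kept iff
    SNR ≥ threshold, inclusive)."""
    snr = pixel_snr_db(image, cfg)
    base = mask if mask is not None else PixelMask.all_valid(image.shape)
    return base.invalidate(snr < cfg.snr_threshold_db, MaskReason.LOW_SNR)


def _rasterize_regions(regions: list[dict], shape: tuple[int, int]) -> np.ndarray:
    rows, cols = shape
    hit = np.zeros(shape, dtype=bool)
    for reg in regions:
        kind = reg.get("type")
        if kind == "rect":
            r0, c0, r1, c1 = (int(reg[k]) for k in ("r0", "c0", "r1", "c1"))
            if not (0 <= r0 <= r1 <= rows and 0 <= c0 <= c1 <= cols):
                raise ValidationError(f"rect region out of bounds: {reg}")
            hit[r0:r1, c0:c1] = True
        elif kind == "poly":
            verts = [(float(c), float(r)) for r, c in reg["vertices"]]
            for c, r in verts:
                if not (0 <= r <= rows and 0 <= c <= cols):
                    raise ValidationError(f"polygon vertex out of bounds: {reg}")
            img = _PILImage.new("1", (cols, rows), 0)
            _PILDraw.Draw(img).polygon(verts, outline=1, fill=1)
            hit |= np.asarray(img, dtype=bool)
        else:
            raise ValidationError(f"unknown region type: {kind!r}")
    return hit


def apply_manual_mask(mask: PixelMask, regions: list[dict]) -> PixelMask:
    """Invalidate manually specified regions (tooth areas etc.).

    Regions are dicts: ``{"type": "rect", "r0", "c0", "r1", "c1"}``
    (half-open in both axes) or ``{"type": "poly", "vertices": [(r, c), ...]}``.
    Idempotent; already-masked pixels keep their original reason.
    """
    if not regions:
        return mask.copy()
    hit = _rasterize_regions(regions, mask.valid.shape)
    return mask.invalidate(hit, MaskReason.MANUAL)


def harmonize_sampling(
    image: MaflimImage, irf: InstrumentResponse, target_dt_ns: float
) -> tuple[MaflimImage, InstrumentResponse]:
    """Resample decays and IRF onto a coarser common grid.

    Linear interpolation onto ``t = 0, target_dt, 2·target_dt, …`` up to
    the original record end.  Only downsampling (``target_dt ≥ dt``) is
    supported: interpolating onto a finer grid would fabricate temporal
    information the instrument never recorded.
    """
    if target_dt_ns < image.dt - 1e-12:
        raise ConfigError(
            f"upsampling requested (target {target_dt_ns} < source {image.dt} ns)"
        )
    if abs(target_dt_ns - image.dt) <= 1e-12:
        return image.copy(), InstrumentResponse(
            u={b: irf.u[b].copy() for b in BANDS}, dt=irf.dt
        )
    t_max = (image.n_time - 1) * image.dt
    n_new = int(np.floor(t_max / target_dt_ns)) + 1
    # fractional positions of the new samples on the old grid
    pos = np.arange(n_new) * (target_dt_ns / image.dt)
    i0 = np.minimum(pos.astype(int), image.n_time - 2)
    frac = pos - i0
    out = image.copy()
    for b in BANDS:
        d = out.decay[b]
        out.decay[b] = d[:, :, i0] * (1 - frac) + d[:, :, i0 + 1] * frac
    out.dt = float(target_dt_ns)
    t_irf_max = (irf.u[BANDS[0]].size - 1) * irf.dt
    t_new_irf = np.arange(int(np.floor(t_irf_max / target_dt_ns)) + 1) * target_dt_ns
    t_old_irf = np.arange(irf.u[BANDS[0]].size) * irf.dt
    new_u = {b: np.interp(t_new_irf, t_old_irf, irf.u[b]) for b in BANDS}
    return out, InstrumentResponse(u=new_u, dt=float(target_dt_ns))


def preprocess(
    image: MaflimImage,
    cfg: PreprocessConfig | None = None,
    manual_regions: list[dict] | None = None,
) -> tuple[MaflimImage, PixelMask]:
    """Run the full fixed-order chain on a raw image.

    Order: background subtraction → saturation mask (from raw
    amplitudes) → spatial averaging → SNR mask → manual mask.  Returns
    the processed image and the final mask.  If ``image.full_scale`` is
    unknown the saturation step is skipped (nothing can clip without a
    known rail).
    """
    cfg = cfg or PreprocessConfig()
    if image.full_scale is not None:
        mask = mask_saturated(image, cfg)
    else:
        mask = PixelMask.all_valid(image.shape)
    sub = subtract_background(image, cfg)
    avg = spatial_average(sub, cfg, mask=mask)
    mask = mask_low_snr(avg, cfg, mask=mask)
    mask = apply_manual_mask(mask, manual_regions or [])
    return avg, mask
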