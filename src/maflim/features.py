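"""The 21 per-pixel maFLIM features.

Per pixel the feature inventory comprises, in canonical order:

* 3 normalized intensities  — ``I390n, I452n, I500n`` (each band's
  time-integrated intensity divided by the across-band sum),
* 6 absolute-intensity ratios — ``I390/I452, I390/I500, I452/I500,
  (I452+I500)/I390, (I390+I500)/I452, (I390+I452)/I500``,
* 12 time-resolved features — ``τ_fast, τ_slow, α_fast, τ_avg`` per band.

Absolute intensities are intermediates only (they depend on gain and
working distance); the ratios and normalized intensities are invariant
to uniform gain, and the time-resolved features are invariant to
intensity scaling altogether.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BANDS, BAND_SUBSCRIPTS, MaflimImage, PixelMask, ValidationError
from .fitting import BiExpFitMaps

#: Canonical ordered inventory of the 21 per-pixel features.
FEATURE_NAMES: tuple[str, ...] = (
    "I390n", "I452n", "I500n",
    "R_390_452", "R_390_500", "R_452_500",
    "R_452p500_390", "R_390p500_452", "R_390p452_500",
    "tau_fast_390", "tau_fast_452", "tau_fast_500",
    "tau_slow_390", "tau_slow_452", "tau_slow_500",
    "alpha_fast_390", "alpha_fast_452", "alpha_fast_500",
    "tau_avg_390", "tau_avg_452", "tau_avg_500",
)

#: Spectral-only pool (9): normalized intensities + intensity ratios.
SPECTRAL_FEATURES: tuple[str, ...] = FEATURE_NAMES[:9]
#: Time-resolved-only pool (12): lifetimes and fast-component fractions.
TIME_RESOLVED_FEATURES: tuple[str, ...] = FEATURE_NAMES[9:]


def absolute_intensity(image: MaflimImage, band: str) -> np.ndarray:
    """Per-pixel absolute intensity: trapezoid-rule time integral of the
    decay over the full record, in intensity·ns."""
    return np.trapezoid(image.decay[band], dx=image.dt, axis=2)


def normalized_intensity(
    i390: np.ndarray, i452: np.ndarray, i500: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Each band's intensity divided by the across-band sum.

    Pixels whose intensities sum to zero are undefined and come back NaN
    (callers invalidate them).
    """
    total = i390 + i452 + i500
    with np.errstate(invalid="ignore", divide="ignore"):
        out = tuple(np.where(total != 0, i / total, np.nan) for i in (i390, i452, i500))
    return out  # type: ignore[return-value]


def intensity_ratios(
    i390: np.ndarray, i452: np.ndarray, i500: np.ndarray
) -> dict[str, np.ndarray]:
    """The six absolute-intensity ratios; zero denominators yield NaN."""
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = {
            "R_390_452": i390 / i452,
            "R_390_500": i390 / i500,
            "R_452_500": i452 / i500,
            "R_452p500_390": (i452 + i500) / i390,
            "R_390p500_452": (i390 + i500) / i452,
            "R_390p452_500": (i390 + i452) / i500,
        }
    return {k: np.where(np.isfinite(v), v, np.nan) for k, v in ratios.items()}


@dataclass
class FeatureStack:
    """The 21 named per-pixel feature maps plus the validity mask."""

    maps: dict[str, np.ndarray]
    valid: np.ndarray
    names: tuple[str, ...] = field(default=FEATURE_NAMES)

    def __post_init__(self) -> None:
        if tuple(self.maps) != tuple(self.names):
            raise ValidationError(
                "feature maps must carry exactly the canonical 21 names in order"
            )
        for name, m in self.maps.items():
            if m.shape != self.valid.shape:
                raise ValidationError(f"feature {name} shape mismatch")

    def matrix(self) -> np.ndarray:
        """(n_valid_pixels, 21) matrix in canonical feature order."""
        return np.column_stack([self.maps[n][self.valid] for n in self.names])

    def submatrix(self, names: list[str] | tuple[str, ...]) -> np.ndarray:
        missing = [n for n in names if n not in self.maps]
        if missing:
            raise ValidationError(f"missing features: {missing}")
        return np.column_stack([self.maps[n][self.valid] for n in names])

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def build_feature_stack(
    image: MaflimImage, fits: BiExpFitMaps, mask: PixelMask
) -> FeatureStack:
    """Assemble the full 21-feature stack from a preprocessed image and
    its per-pixel fits.

    Pixels where any feature is undefined (zero intensity sum, zero
    ratio denominator, missing fit) are invalidated in the returned
    stack rather than carrying NaN into classification.
    """
    if not np.array_equal(fits.valid, mask.valid):
        raise ValidationError("fit coverage does not match the supplied mask")
    i390 = absolute_intensity(image, "b390")
    i452 = absolute_intensity(image, "b452")
    i500 = absolute_intensity(image, "b500")
    maps: dict[str, np.ndarray] = {}
    n390, n452, n500 = normalized_intensity(i390, i452, i500)
    maps["I390n"], maps["I452n"], maps["I500n"] = n390, n452, n500
    maps.update(intensity_ratios(i390, i452, i500))
    for param, stem in (
        ("tau_fast", "tau_fast"),
        ("tau_slow", "tau_slow"),
        ("alpha_fast", "alpha_fast"),
        ("tau_avg", "tau_avg"),
    ):
        for b in BANDS:
            maps[f"{stem}_{BAND_SUBSCRIPTS[b]}"] = fits.maps[b][param]
    ordered = {n: maps[n] for n in FEATURE_NAMES}

    finite = np.ones_like(mask.valid)
    for m in ordered.values():
        finite &= np.isfinite(m) | ~mask.valid
    valid = mask.valid & finite
    return FeatureStack(maps=ordered, valid=valid)


def save_feature_stack(path, stack: FeatureStack) -> None:
    """Persist feature maps into a container under ``/features/{name}``."""
    import h5py

    with h5py.File(path, "a") as f:
        for existing in ("features", "features_valid"):
            if existing in f:
                del f[existing]
        for name in stack.names:
            f.create_dataset(f"features/{name}", data=stack.maps[name])
        f.create_dataset("features_valid", data=stack.valid)


def load_feature_stack(path) -> FeatureStack:
    """Load a stack stored by :func:`save_feature_stack`."""
    import h5py

    from .core import FormatError

    with h5py.File(path, "r") as f:
        if "features" not in f:
            raise FormatError(f"no /features group in {path}; run the features step first")
        maps = {n: f[f"features/{n}"][()] for n in FEATURE_NAMES}
        valid = f["features_valid"][()]
    return FeatureStack(maps=maps, valid=valid)
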