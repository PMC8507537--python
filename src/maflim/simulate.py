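"""Synthetic maFLIM scenes and paired lesion/healthy cohorts.

Generates multispectral time-resolved datacubes with known per-pixel
ground truth so every pipeline stage can be exercised without clinical
data.  A scene emulates the imaging physics at desk scale: per-pixel
bi-exponential fluorescence kinetics drawn from spatially correlated
parameter fields, convolved with a ~1 ns Gaussian instrument response,
plus a DC offset, shot-like noise (Gaussian with variance growing with
the signal plus a floor), occasional saturated (clipped) pixels, and
optional near-dark "tooth" rectangles that carry no tissue fluorescence.

Class-conditional parameter shifts follow the biomarker directions
reported for dysplastic/cancerous vs. healthy oral tissue: lower
collagen-band relative intensity (↓I390,n) and faster 390 nm decay
(↓τavg,390), higher NADH-band relative intensity (↑I452,n) with a
shorter, more dominant fast component (↓τfast,452, ↑αfast,452), and a
lower collagen-to-FAD intensity ratio (↓I390/I500).  Effect magnitudes
are expressed in units of the healthy population spread (0.5σ moderate,
1.5σ strong), since only directions — not clinical magnitudes — are
established.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import (
    BANDS,
    ConfigError,
    Dataset,
    InstrumentResponse,
    MaflimImage,
    SubjectRecord,
)

#: Digitizer full scale used by all synthetic scenes (intensity units).
FULL_SCALE = 4.0

_GRADES = ("MiD", "MoD", "HiD", "SCC")
#: Histopathology grade mix of the emulated training cohort.
_GRADE_P = (1 / 34, 1 / 34, 3 / 34, 29 / 34)


def make_irf(
    dt: float, fwhm_ns: float = 1.0, n_time: int = 256, peak_ns: float = 5.0
) -> InstrumentResponse:
    """Unit-area Gaussian IRF (same trace in all bands) on the image grid.

    ``peak_ns`` places the pulse after the pre-pulse baseline window.
    The pulse must be resolved: ``fwhm > 2·dt``.
    """
    if fwhm_ns <= 2 * dt:
        raise ConfigError(
            f"IRF FWHM {fwhm_ns} ns is under-resolved at dt {dt} ns (need > 2·dt)"
        )
    sigma = fwhm_ns / (2 * np.sqrt(2 * np.log(2)))
    t = np.arange(n_time) * dt
    u = np.exp(-0.5 * ((t - peak_ns) / sigma) ** 2)
    u /= u.sum() * dt
    return InstrumentResponse(u={b: u.copy() for b in BANDS}, dt=dt)


@dataclass
class TissueClassParams:
    """Population parameters of one tissue class.

    Per-band dicts give the mean and pixel-to-pixel spread of the
    kinetic parameters and the mean peak amplitude (fraction of the
    amplitude spread is relative).  ``corr_length_px`` sets the spatial
    correlation of the parameter fields; ``snr_db`` the target
    peak-to-baseline-noise SNR.
    """

    amp_mean: dict[str, float]
    amp_rel_sd: float = 0.15
    alpha_fast_mean: dict[str, float] = field(
        default_factory=lambda: {"b390": 0.60, "b452": 0.55, "b500": 0.50}
    )
    alpha_fast_sd: float = 0.05
    tau_fast_mean: dict[str, float] = field(
        default_factory=lambda: {"b390": 0.80, "b452": 1.00, "b500": 0.90}
    )
    tau_fast_sd: float = 0.12
    tau_slow_mean: dict[str, float] = field(
        default_factory=lambda: {"b390": 4.50, "b452": 4.00, "b500": 3.80}
    )
    tau_slow_sd: float = 0.40
    corr_length_px: float = 2.0
    snr_db: float = 30.0
    shot_fraction: float = 0.3
    offset_frac: float = 0.05
    sat_prob: float = 0.01
    tooth_prob: float = 0.2

    def __post_init__(self) -> None:
        for b in BANDS:
            if self.amp_mean[b] <= 0:
                raise ConfigError(f"amplitude for {b} must be positive")
            if not (0 < self.alpha_fast_mean[b] < 1):
                raise ConfigError("alpha_fast means must lie in (0, 1)")
            if not (0 < self.tau_fast_mean[b] < self.tau_slow_mean[b]):
                raise ConfigError("need 0 < tau_fast < tau_slow")


@dataclass
class SyntheticScene:
    """A generated image plus its full ground truth."""

    image: MaflimImage
    irf: InstrumentResponse
    truth: dict[str, dict[str, np.ndarray]]  # band -> param -> map
    offset: np.ndarray
    noise_floor: dict[str, np.ndarray]
    true_saturated: np.ndarray
    true_tooth: np.ndarray
    label: str


def _correlated_field(rng: np.random.Generator, shape, corr: float) -> np.ndarray:
    """Zero-mean, unit-variance spatially correlated Gaussian field."""
    g = rng.standard_normal(shape)
    if corr > 0:
        g = gaussian_filter(g, sigma=corr, mode="reflect")
        sd = g.std()
        if sd > 0:
            g = g / sd
    return g


def generate_scene(
    params: TissueClassParams,
    rows: int = 64,
    cols: int = 64,
    dt: float = 0.25,
    n_time: int = 256,
    seed: int = 0,
    label: str = "unknown",
    irf: InstrumentResponse | None = None,
) -> SyntheticScene:
    """Draw one scene: correlated kinetic fields → reconvolved decays →
    offset + noise → injected saturation and tooth regions.

    Fully deterministic given ``(params, seed)``.
    """
    rng = np.random.default_rng(seed)
    irf = irf or make_irf(dt, n_time=n_time)
    t = np.arange(n_time) * dt

    tooth = np.zeros((rows, cols), dtype=bool)
    if rng.random() < params.tooth_prob:
        h = int(rng.integers(rows // 4, rows // 2 + 1))
        w = int(rng.integers(cols // 4, cols // 2 + 1))
        r0 = int(rng.integers(0, rows - h + 1))
        c0 = int(rng.integers(0, cols - w + 1))
        tooth[r0 : r0 + h, c0 : c0 + w] = True

    saturated = rng.random((rows, cols)) < params.sat_prob
    saturated &= ~tooth
    offset = params.offset_frac * np.mean(list(params.amp_mean.values())) * np.ones(
        (rows, cols)
    )

    decay: dict[str, np.ndarray] = {}
    truth: dict[str, dict[str, np.ndarray]] = {}
    noise_floor: dict[str, np.ndarray] = {}
    nfft = 1 << (2 * n_time - 2).bit_length()
    U = np.fft.rfft(irf.u[BANDS[0]], nfft)
    for b in BANDS:
        af = np.clip(
            params.alpha_fast_mean[b]
            + params.alpha_fast_sd * _correlated_field(rng, (rows, cols), params.corr_length_px),
            0.05,
            0.95,
        )
        tf = np.clip(
            params.tau_fast_mean[b]
            + params.tau_fast_sd * _correlated_field(rng, (rows, cols), params.corr_length_px),
            0.15,
            None,
        )
        ts = np.clip(
            params.tau_slow_mean[b]
            + params.tau_slow_sd * _correlated_field(rng, (rows, cols), params.corr_length_px),
            None,
            15.0,
        )
        ts = np.maximum(ts, tf * 1.5)
        amp = params.amp_mean[b] * np.clip(
            1.0 + params.amp_rel_sd * _correlated_field(rng, (rows, cols), params.corr_length_px),
            0.2,
            None,
        )
        amp = np.where(tooth, amp * 0.02, amp)
        amp = np.where(saturated, FULL_SCALE * 1.3, amp)

        # FIR per pixel, convolved with the IRF along time via FFT
        h_t = af[..., None] * np.exp(-t / tf[..., None]) + (1 - af[..., None]) * np.exp(
            -t / ts[..., None]
        )
        H = np.fft.rfft(h_t, nfft, axis=-1)
        y = np.fft.irfft(H * U, nfft, axis=-1)[..., :n_time] * dt
        peak = y.max(axis=-1, keepdims=True)
        y = y / np.maximum(peak, 1e-12) * amp[..., None]  # amp = noiseless peak

        floor = amp / 10 ** (params.snr_db / 20)
        var = floor[..., None] ** 2 * (
            1.0 + params.shot_fraction * np.maximum(y, 0) / amp[..., None]
        )
        y = y + offset[..., None] + rng.standard_normal(y.shape) * np.sqrt(var)
        y = np.clip(y, None, FULL_SCALE)

        decay[b] = y
        truth[b] = {"alpha_fast": af, "tau_fast": tf, "tau_slow": ts, "amp": amp}
        noise_floor[b] = floor

    image = MaflimImage(
        decay=decay,
        dt=dt,
        meta={"label": label, "instrument_id": "synthetic"},
        full_scale=FULL_SCALE,
    )
    return SyntheticScene(
        image=image,
        irf=irf,
        truth=truth,
        offset=offset,
        noise_floor=noise_floor,
        true_saturated=saturated,
        true_tooth=tooth,
        label=label,
    )


def default_class_params(
    effect_size: str = "strong",
) -> tuple[TissueClassParams, TissueClassParams]:
    """Healthy and lesion population parameters for a given effect size.

    ``null`` returns identical distributions; ``moderate`` / ``strong``
    shift the lesion means by 0.5σ / 1.5σ of the healthy spread along
    the six reported biomarker directions.
    """
    healthy = TissueClassParams(amp_mean={"b390": 1.00, "b452": 0.75, "b500": 0.55})
    shifts = {"null": 0.0, "moderate": 0.5, "strong": 1.5}
    if effect_size not in shifts:
        raise ConfigError(f"effect_size must be one of {sorted(shifts)}")
    s = shifts[effect_size]
    if s == 0:
        return healthy, replace(healthy)

    amp = dict(healthy.amp_mean)
    amp["b390"] -= s * healthy.amp_rel_sd * amp["b390"]  # ↓ I390,n and ↓ I390/I500
    amp["b452"] += s * healthy.amp_rel_sd * amp["b452"]  # ↑ I452,n
    tf = dict(healthy.tau_fast_mean)
    tf["b452"] -= s * healthy.tau_fast_sd  # ↓ τfast,452
    tf["b390"] -= 0.5 * s * healthy.tau_fast_sd  # contributes to ↓ τavg,390
    ts = dict(healthy.tau_slow_mean)
    ts["b390"] -= s * healthy.tau_slow_sd  # ↓ τavg,390
    af = dict(healthy.alpha_fast_mean)
    af["b452"] = min(af["b452"] + s * healthy.alpha_fast_sd, 0.92)  # ↑ αfast,452
    lesion = replace(
        healthy,
        amp_mean=amp,
        tau_fast_mean=tf,
        tau_slow_mean=ts,
        alpha_fast_mean=af,
    )
    return healthy, lesion


def generate_cohort(
    n_subjects: int = 20,
    effect_size: str = "strong",
    dt: float = 0.25,
    seed: int = 0,
    rows: int = 16,
    cols: int = 16,
    n_time: int = 160,
) -> tuple[Dataset, dict[str, SyntheticScene]]:
    """Paired cohort: one lesion and one contralateral healthy scene per
    subject, sharing a subject-level random offset (inter-subject
    variability affects both members of a pair equally).

    Returns the :class:`Dataset` and a mapping from image id
    (``"<subject>:lesion" / "<subject>:healthy"``) to its scene with
    ground truth.
    """
    if n_subjects < 2:
        raise ConfigError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    healthy_p, lesion_p = default_class_params(effect_size)
    subjects = []
    scenes: dict[str, SyntheticScene] = {}
    for i in range(n_subjects):
        sid = f"S{i:03d}"
        # subject-level random effects, shared by both images of the pair
        z_amp = 1.0 + 0.10 * rng.standard_normal()
        z_af = 0.03 * rng.standard_normal()
        z_tf = 0.06 * rng.standard_normal()
        z_ts = 0.20 * rng.standard_normal()

        def personalize(p: TissueClassParams) -> TissueClassParams:
            return replace(
                p,
                amp_mean={b: p.amp_mean[b] * max(z_amp, 0.3) for b in BANDS},
                alpha_fast_mean={
                    b: float(np.clip(p.alpha_fast_mean[b] + z_af, 0.08, 0.92))
                    for b in BANDS
                },
                tau_fast_mean={b: max(p.tau_fast_mean[b] + z_tf, 0.2) for b in BANDS},
                tau_slow_mean={
                    b: max(p.tau_slow_mean[b] + z_ts, p.tau_fast_mean[b] + z_tf + 0.8)
                    for b in BANDS
                },
            )

        seed_h = int(rng.integers(0, 2**31 - 1))
        seed_l = int(rng.integers(0, 2**31 - 1))
        grade = _GRADES[rng.choice(len(_GRADES), p=_GRADE_P)]
        sc_h = generate_scene(
            personalize(healthy_p), rows, cols, dt, n_time, seed_h, label="healthy"
        )
        sc_l = generate_scene(
            personalize(lesion_p), rows, cols, dt, n_time, seed_l,
            label="dysplasia/cancer",
        )
        for sc, kind in ((sc_h, "healthy"), (sc_l, "lesion")):
            sc.image.meta["subject_id"] = sid
            sc.image.meta["site"] = kind
            scenes[f"{sid}:{kind}"] = sc
        subjects.append(
            SubjectRecord(subject_id=sid, lesion=sc_l.image, healthy=sc_h.image, grade=grade)
        )
    return Dataset(subjects=subjects), scenes
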