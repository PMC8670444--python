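"""Synthetic fingertip-press data with attached ground truth.

Every analysis stage in this package can be exercised without any
recorded data: this module generates dual-illumination contact-image
sequences, synchronized force traces and 2AFC response tables whose
statistical structure mirrors a human pressing experiment —

* the apparent contact starts at the centre and expands radially with
  force;
* the skin displacement field is radially divergent,
  ``u_r = g(mu) * F * r`` with a gain that decreases with friction
  (low friction lets the skin expand more);
* the real-contact coverage drops with the ultrasonic vibration
  amplitude (38 % lower at 3 um than at rest, matching the lubrication
  calibration);
* peak force, press duration and force rate scatter like free active
  presses (5.5 +/- 3.5 N, 1.47 +/- 0.39 s, 3.6 +/- 3 N/s).

Each generated object carries a :class:`SyntheticTruth` with the exact
generating quantities, so recovery tests can close the loop.  All
generators are deterministic under a fixed seed; independent
sub-streams are derived by seeding ``default_rng([seed, stream])``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as _dc_field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DomainError, ParameterError
from .images import ContactFrame, TrialRecord

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "alpha_to_mu",
    "gen_ridge_image",
    "gen_press_trial",
    "gen_2afc_responses",
]

#: Friction-coefficient anchors of the ultrasonic-lubrication map:
#: mu at (essentially) zero vibration amplitude and at 3 um.
MU_HIGH_FRICTION = 0.81
MU_LOW_FRICTION = 0.18
ALPHA_REFERENCE_UM = 1e-3
ALPHA_MAX_UM = 3.0
#: Relative real-contact-area reduction at the maximal amplitude.
CONTACT_REDUCTION_AT_MAX = 0.38


def alpha_to_mu(
    alpha_um: float,
    mu_high: float = MU_HIGH_FRICTION,
    mu_low: float = MU_LOW_FRICTION,
    alpha_ref: float = ALPHA_REFERENCE_UM,
    alpha_max: float = ALPHA_MAX_UM,
) -> float:
    """Friction coefficient vs ultrasonic vibration amplitude (um).

    Monotone-decreasing exponential ``mu = A exp(-b alpha)`` anchored
    exactly at ``mu(alpha_ref) = mu_high`` and ``mu(alpha_max) =
    mu_low`` — a 78 % relative reduction over the amplitude range with
    the default anchors.
    """
    if alpha_um < 0:
        raise DomainError(f"vibration amplitude must be >= 0, got {alpha_um}")
    b = math.log(mu_high / mu_low) / (alpha_max - alpha_ref)
    A = mu_high * math.exp(b * alpha_ref)
    return A * math.exp(-b * alpha_um)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic-trial generator (units in docstrings)."""

    seed: int = 0
    alpha_um: float = ALPHA_REFERENCE_UM  # ultrasonic amplitude, um
    mu: float | None = None  # friction; derived from alpha when None
    divergence_gain: float = 0.008  # radial expansion per N at mu=0 (1/N)
    friction_sensitivity: float = 1.0  # g(mu) = gain * exp(-sensitivity*mu)
    saturating: bool = False  # flatten the expansion above 2 N
    image_size: int = 384  # px, square frames
    pixel_resolution: float = 0.02  # mm/px
    ridge_period_mm: float = 0.45  # fingerprint ridge spacing
    ridge_contrast: float = 0.35
    texture_amplitude: float = 0.18  # speckle that makes ridges trackable
    image_noise_sd: float = 0.01  # additive Gaussian, intensity units
    illumination_ramp: float = 0.06  # linear shading across the frame
    contact_radius_max_mm: float = 3.2  # apparent radius once saturated
    contact_saturation_force: float = 0.5  # N; gross footprint complete here
    real_contact_coverage: float = 0.35  # dot coverage at zero amplitude
    brightness_sign: float = 1.0  # +1: contact bright where skin held
    force_peak_mean: float = 5.5  # N
    force_peak_sd: float = 3.5
    force_duration_mean: float = 1.47  # s
    force_duration_sd: float = 0.39
    force_rate_mean: float = 3.6  # N/s (implied by peak/ramp; reported)
    force_rate_sd: float = 3.0
    force_noise_sd: float = 0.01  # N
    force_sample_rate: float = 1000.0  # Hz
    frame_rate: float = 20.0  # Hz
    global_drift_mm: tuple[float, float] = (0.0, 0.0)  # injected rigid drift
    fixed_peak_force: float | None = 3.5  # None -> sample from distribution

    def __post_init__(self) -> None:
        if self.mu is None:
            self.mu = alpha_to_mu(self.alpha_um)
        if self.image_size < 64:
            raise ParameterError("image_size must be at least 64 px")
        for name in ("pixel_resolution", "ridge_period_mm", "frame_rate",
                     "force_sample_rate", "contact_radius_max_mm"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("image_noise_sd", "force_noise_sd", "force_peak_sd",
                     "force_duration_sd", "force_rate_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    @property
    def gain(self) -> float:
        """Radial expansion coefficient per N at this friction level."""
        return self.divergence_gain * math.exp(-self.friction_sensitivity * self.mu)


@dataclass
class SyntheticTruth:
    """Generating quantities attached to a synthetic dataset."""

    alpha_um: float
    mu: float
    gain: float  # expansion per N
    times: np.ndarray | None = None
    force: np.ndarray | None = None  # clean frame-time force, N
    expansion: np.ndarray | None = None  # k(t) = gain * F_eff(t)
    divergence: np.ndarray | None = None  # onset-referenced field divergence
    divergence_final: float = np.nan
    real_area_mm2: np.ndarray | None = None
    apparent_radius_mm: np.ndarray | None = None
    global_drift_mm: tuple[float, float] = (0.0, 0.0)
    threshold_um: float | None = None  # for 2AFC sets
    slope_um: float | None = None
    p_correct: np.ndarray | None = None


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config_seed) % (2**31), stream])


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    sd = field.std()
    return field / sd if sd > 0 else field


def gen_ridge_image(config: GeneratorConfig) -> np.ndarray:
    """A quasi-concentric synthetic fingerprint ridge pattern.

    Band-pass oriented texture: cosine rings at the configured ridge
    spacing around the image centre, with a smooth random phase
    modulation and multiplicative speckle so that corner detectors find
    hundreds of stable features.  Intensities lie in [0, 1].  The same
    seed yields the identical image.
    """
    n = config.image_size
    rng = _rng(config.seed, 1)
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    cx = cy = (n - 1) / 2.0
    r_mm = np.hypot(xx - cx, yy - cy) * config.pixel_resolution
    phase_mod = 3.0 * _smooth_noise(rng, (n, n), n / 16)
    rings = np.cos(2 * np.pi * r_mm / config.ridge_period_mm + phase_mod)
    speckle = config.texture_amplitude * _smooth_noise(rng, (n, n), 1.5)
    pores = 0.5 * config.texture_amplitude * _smooth_noise(rng, (n, n), 0.8)
    img = (0.5 + config.ridge_contrast * rings * (1.0 + speckle)
           + speckle * 0.3 + pores)
    return np.clip(img, 0.0, 1.0)


def _force_profile(config: GeneratorConfig, rng: np.random.Generator):
    """Sampled press: dense force trace plus its clean envelope."""
    if config.fixed_peak_force is not None:
        peak = float(config.fixed_peak_force)
    else:
        peak = -1.0
        while peak < 0.5:
            peak = rng.normal(config.force_peak_mean, config.force_peak_sd)
    duration = -1.0
    while duration < 0.4:
        duration = rng.normal(config.force_duration_mean, config.force_duration_sd)
    t = np.arange(0.0, duration, 1.0 / config.force_sample_rate)
    t_ramp = 0.75 * duration
    envelope = np.where(
        t < t_ramp,
        0.5 * peak * (1.0 - np.cos(np.pi * t / t_ramp)),
        peak,
    )
    noisy = envelope + rng.normal(0.0, config.force_noise_sd, t.size)
    return t, noisy, envelope, peak, duration


def _expansion_coefficient(config: GeneratorConfig, force: np.ndarray) -> np.ndarray:
    """k(t): radial expansion u_r = k r, optionally saturating at 2 N."""
    if config.saturating:
        f_eff = np.minimum(force, 2.0) + 0.25 * np.maximum(force - 2.0, 0.0)
    else:
        f_eff = force
    return config.gain * f_eff


def _onset_referenced_divergence(
    k: np.ndarray, radius: np.ndarray, r_grid: np.ndarray
) -> np.ndarray:
    """True divergence an ideal onset-referencing tracker would report.

    A material ring with final radius ``r`` entered the apparent
    contact at the first frame ``t0(r)`` with ``radius(t0) >= r``; its
    measured displacement at frame ``T`` is ``x0 (k_T - k_{t0})`` where
    ``x0`` is the reference position.  The reported scalar is the
    median over rings of the axisymmetric divergence of that field —
    the same summary the image pipeline computes from its grid.
    """
    n_frames = k.size
    out = np.zeros(n_frames)
    for T in range(n_frames):
        kk = k[: T + 1]
        rad = radius[: T + 1]
        r_fin = r_grid * (1.0 + k[T])
        inside = r_fin <= rad[-1]
        if not inside.any():
            out[T] = 0.0
            continue
        r_in = r_grid[inside]
        # ring onset: first frame whose contact disk covers the ring's
        # then-current position x0 * (1 + k(t))
        covered = rad[None, :] >= r_in[:, None] * (1.0 + kk[None, :])
        onset = np.where(covered.any(axis=1), covered.argmax(axis=1), T)
        u = r_in * (kk[-1] - kk[onset])
        rr = r_in * (1.0 + kk[-1])
        if rr.size < 3:
            out[T] = 0.0
            continue
        du = np.gradient(u, rr)
        with np.errstate(divide="ignore", invalid="ignore"):
            div = du + np.where(rr > 1e-9, u / np.where(rr > 1e-9, rr, 1), du)
        out[T] = float(np.median(div))
    return out


def gen_press_trial(config: GeneratorConfig) -> tuple[TrialRecord, SyntheticTruth]:
    """One synthetic press: image pair sequence + force + ground truth.

    The ridge channel is the reference fingerprint warped by the
    radial expansion ``u_r = k(t) r`` (plus any configured rigid
    drift); the contact channel shows speckle "microjunctions" inside
    the growing apparent-contact disk, with a dot coverage reduced in
    proportion to the ultrasonic amplitude (38 % at 3 um).  The truth
    records the clean force, expansion coefficient, apparent radius,
    exact real-contact area of every emitted frame and the
    onset-referenced divergence an ideal tracker would measure.
    """
    cfg = config
    rng = _rng(cfg.seed, 2)
    n = cfg.image_size
    res = cfg.pixel_resolution
    t_force, f_noisy, f_clean, peak, duration = _force_profile(cfg, rng)

    frame_t = np.arange(0.0, duration - 1e-9, 1.0 / cfg.frame_rate)
    if frame_t.size < 2:
        frame_t = np.array([0.0, duration / 2])
    f_frames = np.interp(frame_t, t_force, f_clean)
    k = _expansion_coefficient(cfg, f_frames)

    # the gross footprint forms very early in the press: it grows like
    # sqrt(force) and is complete at the (low) saturation force, the way
    # a fingertip reaches ~80% of its final contact within ~1 mm of
    # indentation
    a_max = cfg.contact_radius_max_mm
    f_sat = cfg.contact_saturation_force
    radius = a_max * np.sqrt(np.clip(f_frames, 0.0, f_sat) / f_sat)

    ridge_ref = gen_ridge_image(cfg)
    speckle = _smooth_noise(_rng(cfg.seed, 3), (n, n), 1.2)
    coverage = cfg.real_contact_coverage * (
        1.0 - CONTACT_REDUCTION_AT_MAX * cfg.alpha_um / ALPHA_MAX_UM
    )
    dot_threshold = float(np.quantile(speckle, 1.0 - coverage))
    dots = speckle > dot_threshold

    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    cx = cy = (n - 1) / 2.0
    drift_px = np.asarray(cfg.global_drift_mm) / res

    frames: list[ContactFrame] = []
    real_area = np.zeros(frame_t.size)
    for i, (ti, fi) in enumerate(zip(frame_t, f_frames)):
        scale = 1.0 + k[i]
        prog = fi / max(peak, 1e-9)
        # inverse warp: current pixel x came from x0 = (x - c - drift)/scale
        sx = (xx - cx - prog * drift_px[0]) / scale + cx
        sy = (yy - cy - prog * drift_px[1]) / scale + cy
        ridge = ndimage.map_coordinates(ridge_ref, [sy, sx], order=1, mode="nearest")
        shade = cfg.illumination_ramp * ((xx / n - 0.5) + 0.5 * (yy / n - 0.5))
        ridge = np.clip(
            ridge + shade + rng.normal(0.0, cfg.image_noise_sd, (n, n)), 0, 1
        )
        dots_w = ndimage.map_coordinates(
            dots.astype(float), [sy, sx], order=0, mode="constant"
        )
        rr_mm = np.hypot(xx - cx - prog * drift_px[0], yy - cy - prog * drift_px[1]) * res
        inside = rr_mm <= radius[i]
        contact_mask = (dots_w > 0.5) & inside
        real_area[i] = contact_mask.sum() * res**2
        contact = np.where(contact_mask, 0.85, 0.03)
        contact = np.clip(
            contact + rng.normal(0.0, cfg.image_noise_sd, (n, n)), 0, 1
        )
        frames.append(
            ContactFrame(
                ridge_image=ridge.astype(np.float32),
                contact_image=contact.astype(np.float32),
                timestamp=float(ti),
                normal_force=float(np.interp(ti, t_force, f_noisy)),
                pixel_resolution=res,
            )
        )

    # rings sampled uniformly in enclosed area, so the median over rings
    # matches the area-weighted median a gridded 2-d analysis reports
    r_grid = a_max * np.sqrt(np.linspace(0.002, 1.0, 150))
    div_series = _onset_referenced_divergence(k, radius, r_grid)
    truth = SyntheticTruth(
        alpha_um=cfg.alpha_um,
        mu=cfg.mu,
        gain=cfg.gain,
        times=frame_t,
        force=f_frames,
        expansion=k,
        divergence=div_series,
        divergence_final=float(div_series[-1]),
        real_area_mm2=real_area,
        apparent_radius_mm=radius,
        global_drift_mm=tuple(cfg.global_drift_mm),
    )
    trial = TrialRecord(
        frames=frames,
        alpha_um=cfg.alpha_um,
        mu=cfg.mu,
        meta={
            "seed": cfg.seed,
            "peak_force_N": peak,
            "duration_s": duration,
            "force_t": t_force,
            "force_noisy": f_noisy,
        },
    )
    return trial, truth


def gen_2afc_responses(
    seed: int,
    threshold_um: float,
    slope_um: float,
    levels=np.arange(0.5, 3.01, 0.5),
    reps: int = 10,
    participant: str = "sim",
    lapse: float = 0.02,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Bernoulli 2AFC responses from a known psychometric curve.

    ``P(correct | x) = 0.5 + (0.5 - lapse) * Phi((x - threshold-ish)/s)``
    parameterised so that the generating 75 % threshold is exactly
    ``threshold_um`` (the location is back-computed from it).  Returns
    a tidy response table and the generating truth.
    """
    from .psychometrics import GUESS_RATE, _psi
    from scipy.stats import norm as _norm

    if reps < 1:
        raise ParameterError("reps must be >= 1")
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ParameterError("levels must be nonempty")
    rng = _rng(seed, 4)
    q = (0.75 - GUESS_RATE) / (1.0 - GUESS_RATE - lapse)
    location = threshold_um - slope_um * _norm.ppf(q)
    p = _psi(levels, location, slope_um, GUESS_RATE, lapse)
    rows = []
    for x, pi in zip(levels, p):
        correct = rng.random(reps) < pi
        for c in correct:
            rows.append({"participant": participant, "level_um": float(x),
                         "chose_comparison": bool(c)})
    rng.shuffle(rows)  # presentation order carries no information
    truth = SyntheticTruth(
        alpha_um=np.nan, mu=np.nan, gain=np.nan,
        threshold_um=float(threshold_um), slope_um=float(slope_um),
        p_correct=p,
    )
    return pd.DataFrame(rows), truth
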