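"""Seeded synthetic IMU walking trials with planted surface structure.

The generator is a harmonic gait proxy, not a biomechanical model: each
channel is a step-periodic sum of harmonics whose amplitude carries a
location x surface discriminability structure — strong at the shanks,
moderate at the thighs and trunk, near-absent at the wrist — plus
surface-specific signatures (cadence changes, a signed mediolateral offset
for banked surfaces, impact transients for stairs, an opposite
vertical/anterior-posterior amplitude re-weighting for slopes), a gravity
baseline on the vertical accelerometer, participant-level lognormal
amplitude multipliers, and additive Gaussian noise.  Everything is
deterministic given the config seed.

The emulated study design: 10 participants x 6 trials x 7 surfaces at
100 Hz, self-selected cadence near 1.67 steps/s (~1.5 m/s walking), with
recordings smoothed by a 2nd-order 6 Hz low-pass Butterworth filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import signal as sps
from scipy.spatial.transform import Rotation

from .core import AXES, BodyLocation, IMUTrial, SurfaceClass

__all__ = [
    "SurfaceEffect",
    "GaitSimConfig",
    "FilterSpec",
    "simulate_trials",
    "lowpass_filter",
    "generate_trials",
    "DEFAULT_SURFACE_EFFECTS",
    "DEFAULT_LOCATION_GAIN",
    "DEFAULT_ML_OFFSET_GAIN",
]


@dataclass(frozen=True)
class SurfaceEffect:
    """Per-surface signature applied on top of the base gait harmonics.

    ``amp`` multiplies the (vertical, mediolateral, anterior-posterior)
    oscillation amplitudes; ``cadence`` multiplies the step frequency;
    ``ml_asym`` is the signed mediolateral-offset weight (opposite sign for
    the two banked surfaces); ``impact`` weights a per-step transient
    (stairs); ``slope_shift`` re-weights vertical vs anterior-posterior
    amplitude with opposite sign for slope up vs down.
    """

    amp: tuple[float, float, float] = (1.0, 1.0, 1.0)
    cadence: float = 1.0
    ml_asym: float = 0.0
    impact: float = 0.0
    slope_shift: float = 0.0


DEFAULT_SURFACE_EFFECTS: dict[SurfaceClass, SurfaceEffect] = {
    SurfaceClass.FLAT_UNEVEN: SurfaceEffect(),
    SurfaceClass.BANKED_LEFT: SurfaceEffect(amp=(1.0, 1.15, 1.0), cadence=0.97, ml_asym=+1.0),
    SurfaceClass.BANKED_RIGHT: SurfaceEffect(amp=(1.0, 1.15, 1.0), cadence=0.97, ml_asym=-1.0),
    SurfaceClass.STAIR_UP: SurfaceEffect(amp=(1.30, 1.0, 1.20), cadence=0.80, impact=1.0),
    SurfaceClass.STAIR_DOWN: SurfaceEffect(amp=(1.40, 1.0, 1.10), cadence=0.85, impact=1.3),
    SurfaceClass.SLOPE_UP: SurfaceEffect(amp=(1.15, 1.0, 0.95), cadence=0.90, slope_shift=+1.0),
    SurfaceClass.SLOPE_DOWN: SurfaceEffect(amp=(0.95, 1.0, 1.15), cadence=0.95, slope_shift=-1.0),
}

#: discriminability hierarchy: lower-limb channels vary most across
#: surfaces, the wrist barely at all
DEFAULT_LOCATION_GAIN: dict[BodyLocation, float] = {
    BodyLocation.TRUNK: 0.5,
    BodyLocation.WRIST: 0.05,
    BodyLocation.LEFT_THIGH: 0.8,
    BodyLocation.RIGHT_THIGH: 0.8,
    BodyLocation.LEFT_SHANK: 1.0,
    BodyLocation.RIGHT_SHANK: 1.0,
}

#: the banked cross-slope lean is absorbed by the legs; the trunk stays
#: upright and the arm swings freely, so neither carries the signed offset
DEFAULT_ML_OFFSET_GAIN: dict[BodyLocation, float] = {
    BodyLocation.TRUNK: 0.0,
    BodyLocation.WRIST: 0.0,
    BodyLocation.LEFT_THIGH: 0.8,
    BodyLocation.RIGHT_THIGH: 0.8,
    BodyLocation.LEFT_SHANK: 1.0,
    BodyLocation.RIGHT_SHANK: 1.0,
}

GRAVITY = 9.81  # m/s^2


@dataclass
class GaitSimConfig:
    n_participants: int = 10
    trials_per_surface: int = 6
    duration_s: float = 6.0
    sample_rate: float = 100.0
    step_frequency_hz: float = 1.67
    n_harmonics: int = 4
    location_gain: dict[BodyLocation, float] = field(
        default_factory=lambda: dict(DEFAULT_LOCATION_GAIN)
    )
    ml_offset_gain: dict[BodyLocation, float] = field(
        default_factory=lambda: dict(DEFAULT_ML_OFFSET_GAIN)
    )
    surface_effects: dict[SurfaceClass, SurfaceEffect] = field(
        default_factory=lambda: dict(DEFAULT_SURFACE_EFFECTS)
    )
    participant_sd: float = 0.1
    noise_sd: float = 0.3
    accel_amp: float = 2.0  # base accel oscillation amplitude, m/s^2
    gyro_amp: float = 1.5  # base gyro oscillation amplitude, rad/s
    ml_offset: float = 0.6  # banked-surface mediolateral accel offset, m/s^2
    impact_scale: float = 0.8  # stair transient, in units of accel_amp
    slope_scale: float = 0.25  # vertical/AP re-weighting strength for slopes
    wrist_orientation_deg: float = 60.0  # arm-posture variability per trial
    cadence_jitter: float = 0.02  # per-trial fractional cadence spread
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.step_frequency_hz <= 0:
            raise ValueError("step_frequency_hz must be positive")
        if self.n_participants < 1 or self.trials_per_surface < 1:
            raise ValueError("need at least one participant and one trial")
        for loc in BodyLocation:
            g = self.location_gain.get(loc)
            if g is None or not 0.0 <= g <= 1.0:
                raise ValueError(f"location_gain[{loc.value}] must lie in [0, 1]")
        for surf in SurfaceClass:
            eff = self.surface_effects.get(surf)
            if eff is None:
                raise ValueError(f"surface_effects missing {surf.value}")
            if min(eff.amp) <= 0 or eff.cadence <= 0:
                raise ValueError(f"surface_effects[{surf.value}] multipliers must be > 0")


def simulate_trials(config: GaitSimConfig) -> list[IMUTrial]:
    """Generate n_participants x trials_per_surface x 7 seeded trials.

    Random structure: participant amplitude multipliers and per-channel
    harmonic phases are drawn once per participant; the wrist orientation
    and cadence jitter are drawn per (participant, trial index) — shared
    across surfaces, so with zero wrist gain and zero noise the wrist
    channels are identical across surfaces; measurement noise is drawn per
    trial.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    param_rng = np.random.default_rng(ss.spawn(1)[0])

    nP, nJ, H = config.n_participants, config.trials_per_surface, config.n_harmonics
    fs, T = config.sample_rate, int(round(config.duration_s * config.sample_rate))
    t = np.arange(T) / fs
    harmonics = np.arange(1, H + 1)
    weights = 1.0 / harmonics  # fundamental dominates

    # participant-level draws (order fixed, independent of surface)
    part_mult = np.exp(param_rng.normal(0.0, config.participant_sd, size=nP))
    phases = param_rng.uniform(0.0, 2.0 * np.pi, size=(nP, 36, H))
    wrist_rot = np.empty((nP, nJ, 3, 3))
    cad_jitter = np.empty((nP, nJ))
    for p in range(nP):
        for j in range(nJ):
            ang = param_rng.uniform(
                -config.wrist_orientation_deg, config.wrist_orientation_deg, size=3
            )
            wrist_rot[p, j] = Rotation.from_euler("xyz", ang, degrees=True).as_matrix()
            cad_jitter[p, j] = 1.0 + param_rng.uniform(
                -config.cadence_jitter, config.cadence_jitter
            )

    noise_root = ss.spawn(1)[0]
    gains = np.array([config.location_gain[loc] for loc in BodyLocation])
    ml_gains = np.array(
        [config.ml_offset_gain.get(loc, 0.0) for loc in BodyLocation]
    )

    trials: list[IMUTrial] = []
    for p in range(nP):
        for surf in SurfaceClass:
            eff = config.surface_effects[surf]
            # per-axis amplitude multipliers incl. the slope re-weighting
            ax_mult = np.array(
                [
                    eff.amp[0] * (1.0 + config.slope_scale * eff.slope_shift),
                    eff.amp[1],
                    eff.amp[2] * (1.0 - config.slope_scale * eff.slope_shift),
                ]
            )
            for j in range(nJ):
                f_eff = config.step_frequency_hz * eff.cadence * cad_jitter[p, j]
                # amplitude per channel: base(sensor) x gain(loc) x axis mult
                base = np.tile(
                    np.concatenate(
                        [config.accel_amp * ax_mult, config.gyro_amp * ax_mult]
                    ),
                    6,
                )
                amps = base * np.repeat(gains, 6) * part_mult[p]
                arg = (
                    2.0 * np.pi * f_eff * harmonics[None, :, None] * t[None, None, :]
                    + phases[p][:, :, None]
                )
                samples = np.einsum("h,cht->ct", weights, amps[:, None, None] * np.sin(arg))

                # banked surfaces: signed mediolateral accel offset
                if eff.ml_asym != 0.0:
                    ml_rows = np.arange(6) * 6 + 1
                    samples[ml_rows] += (
                        eff.ml_asym * config.ml_offset * ml_gains * part_mult[p]
                    )[:, None]
                # stairs: per-step impact transient on vertical + AP accel
                if eff.impact != 0.0:
                    cycle = (f_eff * t) % 1.0
                    bump = np.exp(-0.5 * ((cycle - 0.15) / 0.06) ** 2)
                    amp_i = eff.impact * config.impact_scale * config.accel_amp
                    v_rows = np.arange(6) * 6
                    samples[v_rows] += amp_i * gains[:, None] * bump[None, :]
                    samples[v_rows + 2] += 0.6 * amp_i * gains[:, None] * bump[None, :]

                # gravity baseline on the vertical accelerometer (sensor
                # vertical axis up at every mounting); the wrist's frame is
                # then rotated by the per-trial arm posture
                v_rows = np.arange(6) * 6
                samples[v_rows] += GRAVITY
                w = BodyLocation.WRIST.index * 6
                R = wrist_rot[p, j]
                samples[w : w + 3] = R @ samples[w : w + 3]
                samples[w + 3 : w + 6] = R @ samples[w + 3 : w + 6]

                if config.noise_sd > 0:
                    child = np.random.SeedSequence(
                        entropy=noise_root.entropy,
                        spawn_key=(1, p, surf.index, j),
                    )
                    noise_rng = np.random.default_rng(child)
                    samples += noise_rng.normal(0.0, config.noise_sd, size=samples.shape)

                trials.append(
                    IMUTrial(
                        participant_id=p + 1,
                        surface=surf,
                        trial_index=j + 1,
                        samples=samples,
                        sample_rate=fs,
                    )
                )
    return trials


@dataclass(frozen=True)
class FilterSpec:
    """2nd-order low-pass Butterworth smoothing of every channel."""

    order: int = 2
    cutoff_hz: float = 6.0
    phase: Literal["zero_phase", "causal"] = "zero_phase"

    def __post_init__(self) -> None:
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be positive")


def _analog_butter_apply(x: np.ndarray, order: int, cutoff_hz: float, fs: float):
    """Apply the exact analog Butterworth transfer function to sampled data.

    Any conventional IIR discretization (bilinear, impulse invariance)
    distorts the magnitude well above the cutoff at this sample rate, so
    the single-pass mode evaluates H(j2*pi*f) of the analog prototype —
    whose impulse response is causal and whose magnitude is the textbook
    (1 + (f/fc)^(2*order))^(-1/2) — on the band-limited signal via the
    FFT, with one second of edge padding to absorb wrap-around.
    """
    ba, aa = sps.butter(order, 2.0 * np.pi * cutoff_hz, btype="low", analog=True)
    pad = int(round(fs))
    xp = np.concatenate(
        [np.repeat(x[:, :1], pad, axis=1), x, np.repeat(x[:, -1:], pad, axis=1)],
        axis=1,
    )
    n = xp.shape[1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    _, H = sps.freqs(ba, aa, worN=2.0 * np.pi * freqs)
    y = np.fft.irfft(np.fft.rfft(xp, axis=1) * H[None, :], n=n, axis=1)
    return y[:, pad : pad + x.shape[1]]


def lowpass_filter(trial: IMUTrial, spec: FilterSpec = FilterSpec()) -> IMUTrial:
    """Low-pass each channel independently; length and DC level preserved.

    ``zero_phase`` runs the standard (bilinear-designed) filter forward and
    backward (no phase lag, squared magnitude: -6 dB at the cutoff);
    ``causal`` applies the analog prototype's causal response in a single
    pass, with the textbook -3 dB gain at the cutoff.
    """
    nyquist = trial.sample_rate / 2.0
    if spec.cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {spec.cutoff_hz} Hz must be below Nyquist {nyquist} Hz"
        )
    if spec.phase == "zero_phase":
        b, a = sps.butter(spec.order, spec.cutoff_hz, btype="low", fs=trial.sample_rate)
        filtered = sps.filtfilt(b, a, trial.samples, axis=1)
    elif spec.phase == "causal":
        filtered = _analog_butter_apply(
            trial.samples, spec.order, spec.cutoff_hz, trial.sample_rate
        )
    else:
        raise ValueError(f"unknown phase mode: {spec.phase!r}")
    return IMUTrial(
        participant_id=trial.participant_id,
        surface=trial.surface,
        trial_index=trial.trial_index,
        samples=filtered,
        sample_rate=trial.sample_rate,
    )


def generate_trials(
    config: GaitSimConfig, filter_spec: FilterSpec | None = FilterSpec()
) -> list[IMUTrial]:
    """Simulate and (optionally) low-pass smooth a full trial set."""
    trials = simulate_trials(config)
    if filter_spec is None:
        return trials
    return [lowpass_filter(t, filter_spec) for t in trials]
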