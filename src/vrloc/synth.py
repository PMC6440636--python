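"""Synthetic stand-ins for the study's raw data.

Three generators make every pipeline stage testable without measured data:

* :func:`spherical_head_brir` — a rigid-sphere binaural impulse response.
  The interaural delay follows the Woodworth frontal-incidence formula
  (a/c)(theta + sin theta), quantized to integer samples so the
  integer-lag ITD extractor recovers it exactly; the contralateral ear
  passes through a first-order low-pass head-shadow filter whose strength
  grows with lateral angle, producing an ILD that grows with |azimuth|
  and is largest at high frequencies.

* :func:`apply_hmd_model` — a parametric perturbation emulating what a
  head-mounted display does to the measured cues: an azimuth-dependent
  extra interaural delay (zero at 0 and 90 deg, peaking mid-laterally),
  region-specific attenuation of the contralateral ear (ILD magnitude
  boosts with the same end-point zeros), and a mid/high-frequency
  spectral ripple on the contralateral side that is attenuated below the
  horizontal plane.  The perturbation is deterministic given direction
  and config; the seed only sets the ripple phase.

* :func:`simulate_responses` — a synthetic subject cohort over the full
  condition x source x repetition design: per-subject pointing biases,
  condition-dependent angular noise, an HMD-specific lateral overshoot
  with asymmetric left/right gains, and a small lapse probability with
  lapses uniform over the frontal hemisphere.

* :func:`pink_noise_burst` — the acoustic stimulus: a 240 ms pink-noise
  burst with 20 ms raised-cosine ramps, presented at a nominal level with
  a +-3 dB uniform rove per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import conditions as cond
from .cues import BinauralIR
from .geometry import SourcePosition, build_source_array, wrap_azimuth

__all__ = [
    "HeadModelConfig",
    "HmdPerturbationConfig",
    "ResponseSimConfig",
    "spherical_head_brir",
    "woodworth_itd_us",
    "apply_hmd_model",
    "make_ir_dataset",
    "pink_noise_burst",
    "simulate_responses",
]


# --- spherical-head BRIR ----------------------------------------------------

@dataclass(frozen=True)
class HeadModelConfig:
    """Rigid-sphere head model parameters."""

    head_radius: float = 0.0875  # m
    speed_of_sound: float = 343.0  # m/s
    fs: float = 48000.0  # Hz
    ir_length: int = 128  # samples
    base_delay: int = 16  # samples of common lead-in, leaves room for filters
    shadow_strength: float = 0.6  # one-pole coefficient at 90 deg lateral
    shadow_gain_db: float = 6.0  # broadband contralateral attenuation at 90 deg

    def __post_init__(self) -> None:
        if min(self.head_radius, self.speed_of_sound, self.fs, self.ir_length) <= 0:
            raise ValueError("head model parameters must be positive")


def woodworth_itd_us(azimuth_deg: float, cfg: HeadModelConfig | None = None) -> float:
    """Woodworth frontal-incidence interaural delay (a/c)(theta + sin theta), us."""
    cfg = cfg or HeadModelConfig()
    theta = math.radians(min(abs(azimuth_deg), 90.0))
    return (
        cfg.head_radius / cfg.speed_of_sound * (theta + math.sin(theta)) * 1e6
    )


def _one_pole_lowpass_ir(alpha: float, n: int) -> np.ndarray:
    """Impulse response of y[k] = (1-alpha) x[k] + alpha y[k-1] (unity DC gain)."""
    return (1.0 - alpha) * alpha ** np.arange(n)


def spherical_head_brir(
    source: SourcePosition, cfg: HeadModelConfig | None = None
) -> BinauralIR:
    """Binaural impulse response of a rigid-sphere head for one direction.

    Frontal sources give zero ITD and near-zero ILD; with increasing
    |azimuth| the far (contralateral) ear is delayed per Woodworth and
    shadowed by a low-pass whose attenuation grows with lateral angle.
    Elevation tilts the shadow slightly so the three array rows are not
    acoustically identical.
    """
    cfg = cfg or HeadModelConfig()
    az = source.azimuth
    lateral = math.sin(math.radians(min(abs(az), 90.0)))
    itd_samples = int(round(woodworth_itd_us(az, cfg) * 1e-6 * cfg.fs))

    n = cfg.ir_length
    ipsi = np.zeros(n)
    ipsi[cfg.base_delay] = 1.0

    # contralateral: delayed, low-passed, attenuated
    alpha = cfg.shadow_strength * lateral
    elev_tilt = 1.0 - 0.1 * math.sin(math.radians(source.elevation))
    gain = 10.0 ** (-cfg.shadow_gain_db * lateral * elev_tilt / 20.0)
    start = cfg.base_delay + itd_samples
    contra = np.zeros(n)
    tail = _one_pole_lowpass_ir(alpha, n - start)
    contra[start:] = gain * tail

    if az >= 0:  # source on the right: left ear is contralateral (lags)
        left, right = contra, ipsi
    else:
        left, right = ipsi, contra
    if az == 0:
        left = right = ipsi
    return BinauralIR(
        fs=cfg.fs, left=left, right=right, condition="without_hmd", source=source
    )


# --- HMD acoustic perturbation ----------------------------------------------

@dataclass(frozen=True)
class HmdPerturbationConfig:
    """Parametric HMD perturbation of the binaural cues.

    Offsets are magnitudes (>= 0); azimuth profiles are tent-shaped, zero at
    0 and 90 deg with the peak at the stated azimuth, matching the measured
    pattern of largest errors at mid-lateral angles.  ``high_band_ripple``
    is the peak-to-mid amplitude (dB) of the mid/high-frequency spectral
    ripple applied on the contralateral side at elevations at or above the
    horizontal plane; below the plane it is scaled by
    ``below_plane_attenuation``.
    """

    max_itd_offset: float = 62.5  # us at the peak azimuth
    itd_peak_azimuth: float = 75.0  # deg
    max_ild_offset: float = 6.0  # dB peak boost, mid and high regions
    ild_peak_azimuths: dict = field(
        default_factory=lambda: {"low": 45.0, "mid": 60.0, "high": 30.0}
    )
    low_ild_offset: float = 1.0  # dB peak boost in the low region
    high_band_ripple: float = 6.3  # dB
    ripple_cycles_per_erb: float = 0.25
    below_plane_attenuation: float = 0.4

    def __post_init__(self) -> None:
        if self.max_itd_offset < 0 or self.max_ild_offset < 0 or self.low_ild_offset < 0:
            raise ValueError("offsets must be nonnegative")
        for label, pk in self.ild_peak_azimuths.items():
            if not 0.0 < pk < 90.0:
                raise ValueError(f"peak azimuth for '{label}' must be in (0, 90)")
        if not 0.0 < self.itd_peak_azimuth < 90.0:
            raise ValueError("itd_peak_azimuth must be in (0, 90)")


_REGION_EDGES = {"low": (200.0, 1000.0), "mid": (1000.0, 5000.0), "high": (5000.0, 16000.0)}


def _tent(abs_az: float, peak: float) -> float:
    """Piecewise-linear profile: 0 at 0 deg, 1 at ``peak``, 0 at 90 deg."""
    a = min(abs(abs_az), 90.0)
    if a <= peak:
        return a / peak
    return (90.0 - a) / (90.0 - peak)


def _band_bump(
    freqs: np.ndarray, lo: float, hi: float, taper: float = 0.2
) -> np.ndarray:
    """Flat-top window over [lo, hi] on a log-frequency axis.

    Unity inside, raised-cosine edges over the outer ``taper`` fraction of the
    log-band, zero outside — band-limited but without starving the band
    interior the way a full-cosine bump would.
    """
    w = np.zeros_like(freqs)
    inside = (freqs > lo) & (freqs < hi)
    x = (np.log(freqs[inside]) - np.log(lo)) / (np.log(hi) - np.log(lo))
    edge = np.minimum(x, 1.0 - x)
    w[inside] = np.where(
        edge >= taper, 1.0, np.sin(0.5 * np.pi * edge / taper) ** 2
    )
    return w


def apply_hmd_model(
    ir: BinauralIR,
    cfg: HmdPerturbationConfig | None = None,
    seed: int = 0,
) -> BinauralIR:
    """Perturb a BRIR the way wearing an HMD perturbs measured cues.

    Adds (i) an extra integer-sample delay on the contralateral ear whose
    microsecond value follows a tent over azimuth (zero at 0 and 90 deg,
    ``max_itd_offset`` at ``itd_peak_azimuth``); (ii) zero-phase,
    region-shaped attenuation of the contralateral ear (ILD boosts); and
    (iii) a slow spectral ripple over 1-16 kHz whose amplitude grows with
    how contralateral the source is to each ear and which is attenuated
    below the horizontal plane.  With all magnitudes zero the input is
    returned unchanged.
    """
    cfg = cfg or HmdPerturbationConfig()
    if ir.source is None:
        raise ValueError("the HMD model needs the source direction")
    az, el = ir.source.azimuth, ir.source.elevation
    abs_az = abs(az)
    n = len(ir)
    fs = ir.fs

    if (
        cfg.max_itd_offset == 0
        and cfg.max_ild_offset == 0
        and cfg.low_ild_offset == 0
        and cfg.high_band_ripple == 0
    ):
        return replace(ir, condition="with_hmd")

    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    rng = np.random.default_rng(seed)
    phases = {"left": rng.uniform(0, 2 * np.pi), "right": rng.uniform(0, 2 * np.pi)}

    # per-ear contralaterality in [0, 1]: how far the source sits on the
    # opposite side of this ear (plus a small direct-transmission floor)
    lat = math.sin(math.radians(np.clip(az, -90.0, 90.0)))
    contra_weight = {
        "left": 0.15 + 0.85 * max(lat, 0.0),
        "right": 0.15 + 0.85 * max(-lat, 0.0),
    }
    contra_ear = "left" if az > 0 else "right"

    # region-shaped ILD boosts: attenuate the contralateral ear
    ild_gain_db = np.zeros_like(freqs)
    if abs_az > 0:
        for label, (lo, hi) in _REGION_EDGES.items():
            peak_off = cfg.low_ild_offset if label == "low" else cfg.max_ild_offset
            depth = peak_off * _tent(abs_az, cfg.ild_peak_azimuths[label])
            ild_gain_db -= depth * _band_bump(freqs, lo, hi)

    # mid/high spectral ripple, slow on the ERB scale so its time-domain
    # kernel stays compact and does not disturb the integer-lag delay
    from .cues import erb_number  # local import to avoid cycle at module load

    elev_factor = 1.0 if el >= 0 else cfg.below_plane_attenuation
    ripple_band = _band_bump(freqs, 1000.0, 16000.0)
    erb_axis = np.zeros_like(freqs)
    erb_axis[1:] = erb_number(freqs[1:])

    itd_extra = int(round(cfg.max_itd_offset * _tent(abs_az, cfg.itd_peak_azimuth)
                          * 1e-6 * fs)) if abs_az > 0 else 0

    channels = {}
    for ear in ("left", "right"):
        x = getattr(ir, ear)
        if ear == contra_ear and itd_extra > 0:
            x = np.concatenate([np.zeros(itd_extra), x[: n - itd_extra]])
        gain_db = (
            cfg.high_band_ripple
            * contra_weight[ear]
            * elev_factor
            * ripple_band
            * np.sin(2 * np.pi * cfg.ripple_cycles_per_erb * erb_axis + phases[ear])
        )
        if ear == contra_ear:
            # the device sits in front of the face: the whole spectral
            # perturbation is weaker for sources below the horizontal plane
            gain_db = gain_db + elev_factor * ild_gain_db
        spec = np.fft.rfft(x) * 10.0 ** (gain_db / 20.0)
        channels[ear] = np.fft.irfft(spec, n=n)

    return BinauralIR(
        fs=fs,
        left=channels["left"],
        right=channels["right"],
        condition="with_hmd",
        source=ir.source,
    )


def make_ir_dataset(
    sources: list[SourcePosition] | None = None,
    head_cfg: HeadModelConfig | None = None,
    hmd_cfg: HmdPerturbationConfig | None = None,
    seed: int = 0,
) -> list[BinauralIR]:
    """Paired with/without-HMD BRIRs for a source list (default: the 27-speaker array)."""
    sources = sources if sources is not None else build_source_array()
    head_cfg = head_cfg or HeadModelConfig()
    hmd_cfg = hmd_cfg or HmdPerturbationConfig()
    out = []
    for i, src in enumerate(sources):
        base = spherical_head_brir(src, head_cfg)
        out.append(base)
        out.append(apply_hmd_model(base, hmd_cfg, seed=seed + i))
    return out


# --- acoustic stimulus ------------------------------------------------------

def pink_noise_burst(
    duration: float = 0.240,
    ramp: float = 0.020,
    fs: float = 48000.0,
    level_db: float = 65.0,
    rove_db: float = 3.0,
    seed: int | None = None,
    full_scale_db: float = 100.0,
) -> np.ndarray:
    """Pink-noise burst with raised-cosine onset/offset ramps and level rove.

    A fresh noise realization is drawn per call; the RMS level is
    ``level_db + u`` with ``u ~ uniform(-rove_db, +rove_db)``, interpreted
    relative to a digital full scale at ``full_scale_db`` (i.e. an RMS of 1.0
    corresponds to ``full_scale_db`` dB SPL under the rig's calibration).
    """
    n = int(round(duration * fs))
    if 2 * ramp > duration:
        raise ValueError("ramps may not overlap: need 2*ramp <= duration")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])  # 1/f power slope, -3 dB/octave
    x = np.fft.irfft(spec * shaping, n=n)

    from scipy.signal.windows import tukey

    x = x * tukey(n, alpha=2.0 * ramp / duration)
    rove = rng.uniform(-rove_db, rove_db)
    target_rms = 10.0 ** ((level_db + rove - full_scale_db) / 20.0)
    return x * (target_rms / np.sqrt(np.mean(x**2)))


# --- behavioral response simulation -----------------------------------------

def _default_noise_sd() -> dict[str, tuple[float, float]]:
    """Per-condition angular noise SD (azimuth, elevation), degrees.

    Elevation SDs are set so the post-pipeline mean absolute elevation errors
    fall near the study's reported condition means (sigma = E * sqrt(pi/2)
    for zero-mean Gaussian errors): ~10.2 deg blind-folded with HMD, ~8.4
    without (a ~1.8 deg HMD penalty), ~8.1 deg with room and hand visible,
    ~6.6 deg with loudspeakers visible, ~2.4 deg with the laser pointer.
    Visual-search conditions use 5 deg in both dimensions.
    """
    return {
        "I-blind-acoustic-nohmd": (10.0, 10.5),
        "I-blind-acoustic-hmd": (11.0, 12.8),
        "II-room-acoustic-hmd": (9.0, 10.15),
        "III-ve_ls-visual-hmd": (5.0, 5.0),
        "III-re-visual-nohmd": (5.0, 5.0),
        "III-re-acoustic-nohmd": (6.0, 8.3),
        "III-ve_ls-acoustic-hmd": (6.0, 8.3),
        "IV-laser-acoustic-hmd": (5.0, 3.0),
    }


@dataclass(frozen=True)
class ResponseSimConfig:
    """Synthetic-cohort parameters.

    Defaults encode the study-scale design (10 subjects, 27 sources, 5
    repetitions, 8 conditions -> 10,800 trials) and effect sizes on the
    scale of the reported group results: a group pointing bias of
    (-1.6, +19.0) deg, an HMD lateral overshoot larger on the left than on
    the right, and a lapse probability producing an outlier rate of a few
    per mille.  Per-subject biases are drawn around the group means and
    re-centered so the realized group bias equals the configured one.
    """

    n_subjects: int = 10
    n_left_handed: int = 1
    repetitions: int = 5
    bias_azimuth_mean: float = -1.6
    bias_azimuth_sd: float = 1.5
    bias_elevation_mean: float = 19.0
    bias_elevation_sd: float = 5.0
    noise_sd: dict = field(default_factory=_default_noise_sd)
    overshoot_gain_left: float = 0.06  # deg per deg of |azimuth|, sources left
    overshoot_gain_right: float = 0.03
    lapse_probability: float = 0.003

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse_probability < 1.0:
            raise ValueError("lapse probability must be in [0, 1)")
        if self.bias_azimuth_sd < 0 or self.bias_elevation_sd < 0:
            raise ValueError("bias SDs must be nonnegative")
        if not 0 <= self.n_left_handed <= self.n_subjects:
            raise ValueError("n_left_handed must be within the cohort size")


def _uniform_hemisphere(rng: np.random.Generator, size: int) -> tuple[np.ndarray, np.ndarray]:
    """(azimuth, elevation) uniform over the frontal hemisphere's solid angle."""
    az = rng.uniform(-90.0, 90.0, size)
    el = np.degrees(np.arcsin(rng.uniform(-1.0, 1.0, size)))
    return az, el


def simulate_responses(
    cfg: ResponseSimConfig | None = None,
    seed: int = 0,
    sources: list[SourcePosition] | None = None,
    conditions: tuple[cond.Condition, ...] = cond.CONDITIONS,
) -> pd.DataFrame:
    """Simulate a full cohort's response log (tidy, one row per trial).

    The response model in the right-handed (canonical) frame is
    ``response = target + subject bias + HMD lateral overshoot + noise``,
    with the overshoot ``gain_side * azimuth`` applied only in acoustic
    conditions where the HMD is worn (its left gain exceeds the right by
    default).  With probability ``lapse_probability`` the response is instead
    uniform over the frontal hemisphere.  Left-handed subjects' logged
    target and response azimuths are mirrored (and their overshoot gains
    swapped), which the analysis pipeline's handedness mirroring undoes.
    Fully reproducible from ``seed``.
    """
    cfg = cfg or ResponseSimConfig()
    sources = sources if sources is not None else build_source_array()
    rng = np.random.default_rng(seed)

    subjects = [f"S{i + 1:02d}" for i in range(cfg.n_subjects)]
    left_handed = set(subjects[cfg.n_subjects - cfg.n_left_handed :]) if cfg.n_left_handed else set()

    def centered(mean: float, sd: float, size: int) -> np.ndarray:
        z = rng.standard_normal(size)
        if size > 1:
            z = z - z.mean()
        return mean + sd * z

    bias_az = dict(zip(subjects, centered(cfg.bias_azimuth_mean, cfg.bias_azimuth_sd, len(subjects))))
    bias_el = dict(zip(subjects, centered(cfg.bias_elevation_mean, cfg.bias_elevation_sd, len(subjects))))

    src_az = np.array([s.azimuth for s in sources])
    src_el = np.array([s.elevation for s in sources])
    n_src = len(sources)
    reps = cfg.repetitions

    frames = []
    for subject in subjects:
        for c in conditions:
            az_sd, el_sd = cfg.noise_sd[c.slug]
            t_az = np.tile(src_az, reps)
            t_el = np.tile(src_el, reps)
            rep = np.repeat(np.arange(1, reps + 1), n_src)
            n_trials = n_src * reps

            shift = np.zeros(n_trials)
            if c.hmd and c.stimulus == "acoustic":
                gain = np.where(
                    t_az < 0, cfg.overshoot_gain_left, cfg.overshoot_gain_right
                )
                shift = gain * t_az
            # visual feedback of the pointing ray removes the controller-shape
            # bias, which is why the analysis exempts that condition from
            # bias correction; the generator must be consistent with it
            b_az = 0.0 if c.bias_exempt else bias_az[subject]
            b_el = 0.0 if c.bias_exempt else bias_el[subject]
            r_az = t_az + b_az + shift + rng.normal(0.0, az_sd, n_trials)
            r_el = t_el + b_el + rng.normal(0.0, el_sd, n_trials)

            lapse = rng.random(n_trials) < cfg.lapse_probability
            if lapse.any():
                la, le = _uniform_hemisphere(rng, int(lapse.sum()))
                r_az[lapse] = la
                r_el[lapse] = le

            r_az = wrap_azimuth(r_az)
            r_el = np.clip(r_el, -90.0, 90.0)

            frames.append(
                pd.DataFrame(
                    {
                        "subject": subject,
                        "condition": c.slug,
                        "block": c.block,
                        "target_azimuth_deg": t_az,
                        "target_elevation_deg": t_el,
                        "response_azimuth_deg": r_az,
                        "response_elevation_deg": r_el,
                        "repetition": rep,
                        "handedness": "left" if subject in left_handed else "right",
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)

    # left-handed subjects: their raw log is the canonical data mirrored on
    # the median plane (the pipeline's mirroring restores it)
    lh = out["handedness"] == "left"
    out.loc[lh, "target_azimuth_deg"] = -out.loc[lh, "target_azimuth_deg"]
    out.loc[lh, "response_azimuth_deg"] = wrap_azimuth(
        -out.loc[lh, "response_azimuth_deg"].to_numpy()
    )
    return out
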