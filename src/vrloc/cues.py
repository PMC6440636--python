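"""Binaural cue extraction from paired impulse responses.

Head-mounted displays perturb the acoustic path to the wearer's ears.  The
size of the perturbation is quantified from binaural impulse responses
(BRIRs) measured with and without the device on the same head:

* **Spectral difference (SD)** — per ear, the mean absolute difference of
  auditory-filter output powers between the two conditions, averaged
  within three frequency regions (200 Hz-1 kHz, 1-5 kHz, 5-16 kHz).
* **Interaural level difference (ILD)** — per region, the mean left-minus-
  right difference of auditory-filter powers of one BRIR; the HMD-induced
  ILD error is the change in ILD *magnitude* between conditions.
* **Interaural time difference (ITD)** — the difference of the per-ear
  pure delays, each estimated as the lag of the peak of the cross-
  correlation between an impulse response and its minimum-phase version.
  Delays are integer-sample (no subsample interpolation); at 48 kHz one
  sample is ~21 us.

Auditory filters are 4th-order gammatones spaced at one filter per ERB
(equivalent rectangular bandwidth) on the ERB-number scale, with unity
gain at their center frequencies.  Band power is the filter-magnitude-
weighted power of the signal spectrum, normalized by the filter's own
spectral energy, so a spectrally flat unit-magnitude input reads 0 dB in
every band and a broadband gain of g shifts every band by 20*log10(g).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .geometry import SourcePosition

__all__ = [
    "BinauralIR",
    "FrequencyRegions",
    "CueSet",
    "CueErrors",
    "DEFAULT_REGIONS",
    "SILENCE_FLOOR_DB",
    "truncate_ir",
    "erb_bandwidth",
    "erb_number",
    "erb_number_inverse",
    "erb_centers",
    "band_powers_db",
    "region_means",
    "spectral_difference",
    "ild_regions",
    "minimum_phase",
    "ear_delay",
    "itd_us",
    "extract_cues",
    "cue_errors",
    "sample_period_us",
    "duration_ms",
]

SILENCE_FLOOR_DB = -120.0


@dataclass(frozen=True)
class BinauralIR:
    """A left/right impulse-response pair for one source direction."""

    fs: float
    left: np.ndarray
    right: np.ndarray
    condition: str = "synthetic"
    source: SourcePosition | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        left = np.asarray(self.left, dtype=float)
        right = np.asarray(self.right, dtype=float)
        if left.ndim != 1 or right.ndim != 1 or len(left) != len(right):
            raise ValueError("left and right must be equal-length 1-D arrays")
        if len(left) < 1:
            raise ValueError("impulse responses must contain at least one sample")
        object.__setattr__(self, "left", left)
        object.__setattr__(self, "right", right)

    def __len__(self) -> int:
        return len(self.left)


@dataclass(frozen=True)
class FrequencyRegions:
    """Contiguous low/mid/high analysis regions (Hz)."""

    boundaries: tuple[float, ...] = (200.0, 1000.0, 5000.0, 16000.0)
    labels: tuple[str, ...] = ("low", "mid", "high")

    def __post_init__(self) -> None:
        b = self.boundaries
        if len(b) != len(self.labels) + 1 or any(
            b[i] >= b[i + 1] for i in range(len(b) - 1)
        ):
            raise ValueError("boundaries must be strictly increasing, one per label+1")

    def membership(self, frequencies: np.ndarray) -> list[np.ndarray]:
        """Boolean masks per region; half-open [lo, hi), final region closed."""
        f = np.asarray(frequencies, dtype=float)
        masks = []
        for i in range(len(self.labels)):
            lo, hi = self.boundaries[i], self.boundaries[i + 1]
            if i == len(self.labels) - 1:
                masks.append((f >= lo) & (f <= hi))
            else:
                masks.append((f >= lo) & (f < hi))
        return masks


DEFAULT_REGIONS = FrequencyRegions()


@dataclass(frozen=True)
class CueSet:
    """Cues for one direction: ILD per region (dB) and ITD (us)."""

    ild_db: dict[str, float]
    itd_us: float
    source: SourcePosition | None = None


@dataclass(frozen=True)
class CueErrors:
    """With-minus-without HMD cue errors for one direction."""

    sd_left_db: dict[str, float]
    sd_right_db: dict[str, float]
    ild_error_db: dict[str, float]
    itd_error_us: float
    source: SourcePosition | None = None


def sample_period_us(fs: float) -> float:
    """Duration of one sample in microseconds."""
    return 1e6 / fs


def duration_ms(n_samples: int, fs: float) -> float:
    """Duration of ``n_samples`` in milliseconds."""
    return 1e3 * n_samples / fs


def truncate_ir(ir: BinauralIR, n: int = 128) -> BinauralIR:
    """Cut both channels to ``n`` samples from the start (removes reflections).

    Shorter inputs are zero-padded to ``n`` with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(ir) >= n:
        return replace(ir, left=ir.left[:n], right=ir.right[:n])
    warnings.warn(
        f"impulse response shorter than {n} samples ({len(ir)}); zero-padding",
        stacklevel=2,
    )
    pad = n - len(ir)
    return replace(
        ir,
        left=np.pad(ir.left, (0, pad)),
        right=np.pad(ir.right, (0, pad)),
    )


# --- ERB scale (Glasberg & Moore) -------------------------------------------

def erb_bandwidth(f_hz):
    """Equivalent rectangular bandwidth (Hz) at center frequency ``f_hz``."""
    return 24.7 * (4.37 * np.asarray(f_hz, dtype=float) / 1000.0 + 1.0)


def erb_number(f_hz):
    """ERB-number (Cam) corresponding to frequency in Hz."""
    return 21.4 * np.log10(4.37 * np.asarray(f_hz, dtype=float) / 1000.0 + 1.0)


def erb_number_inverse(erb):
    """Frequency in Hz corresponding to an ERB-number."""
    return (10.0 ** (np.asarray(erb, dtype=float) / 21.4) - 1.0) / 4.37 * 1000.0


def erb_centers(
    fmin: float = 200.0,
    fmax: float = 16000.0,
    density: float = 1.0,
    fs: float = 48000.0,
) -> np.ndarray:
    """Filter center frequencies uniformly spaced on the ERB-number scale.

    ``density`` is filters per ERB.  Centers start at ``fmin`` and step by
    ``1/density`` ERB up to ``fmax`` inclusive.
    """
    if not 0 < fmin < fmax:
        raise ValueError("need 0 < fmin < fmax")
    if fmax >= fs / 2:
        raise ValueError(f"fmax ({fmax}) must be below the Nyquist frequency ({fs / 2})")
    e_lo, e_hi = float(erb_number(fmin)), float(erb_number(fmax))
    n = int(math.floor((e_hi - e_lo) * density + 1e-9)) + 1
    centers = erb_number_inverse(e_lo + np.arange(n) / density)
    return np.clip(centers, fmin, fmax)


@lru_cache(maxsize=8)
def _filterbank_weights(
    fs: float, nfft: int, centers: tuple[float, ...]
) -> np.ndarray:
    """Squared magnitude responses of the gammatone bank on the rfft grid.

    Rows: filters; columns: rfft bins.  Filters are 4th-order IIR gammatones
    with unity gain at their center frequency.
    """
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    weights = np.empty((len(centers), len(freqs)))
    for i, fc in enumerate(centers):
        b, a = sps.gammatone(fc, "iir", fs=fs)
        _, h = sps.freqz(b, a, worN=freqs, fs=fs)
        weights[i] = np.abs(h) ** 2
    return weights


def _nfft_for(n: int) -> int:
    return max(8192, 1 << (2 * n - 1).bit_length())


def band_powers_db(
    channel: np.ndarray,
    fs: float,
    centers: np.ndarray,
    floor_db: float = SILENCE_FLOOR_DB,
) -> np.ndarray:
    """Output power (dB) of each auditory filter for one channel.

    Power in band i is sum_k W_i(f_k) |X(f_k)|^2 / sum_k W_i(f_k) with W_i the
    squared gammatone magnitude response, i.e. the filter-weighted mean squared
    spectrum.  A flat unit-magnitude spectrum (unit impulse) reads 0 dB; a
    broadband gain g shifts every band by 20 log10 g.  Silence returns the
    floor value (default -120 dB re full scale) rather than raising.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.size == 0:
        raise ValueError("channel must be nonempty")
    nfft = _nfft_for(len(channel))
    weights = _filterbank_weights(float(fs), nfft, tuple(float(c) for c in centers))
    psd = np.abs(np.fft.rfft(channel, n=nfft)) ** 2
    power = (weights @ psd) / weights.sum(axis=1)
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(power)
    return np.maximum(db, floor_db)


def region_means(
    values: np.ndarray,
    centers: np.ndarray,
    regions: FrequencyRegions = DEFAULT_REGIONS,
) -> dict[str, float]:
    """Mean of per-filter values within each region (membership by center)."""
    out = {}
    for label, mask in zip(regions.labels, regions.membership(centers)):
        if not mask.any():
            raise ValueError(f"no filter centers fall in region '{label}'")
        out[label] = float(np.mean(np.asarray(values)[mask]))
    return out


def _check_pair(with_hmd: BinauralIR, without_hmd: BinauralIR) -> None:
    if with_hmd.fs != without_hmd.fs:
        raise ValueError(
            f"sample-rate mismatch: {with_hmd.fs} vs {without_hmd.fs}"
        )
    sw, so = with_hmd.source, without_hmd.source
    if sw is not None and so is not None and sw.azel != so.azel:
        raise ValueError(f"source mismatch: {sw.azel} vs {so.azel}")


def spectral_difference(
    with_hmd: BinauralIR,
    without_hmd: BinauralIR,
    ear: str = "left",
    centers: np.ndarray | None = None,
    regions: FrequencyRegions = DEFAULT_REGIONS,
) -> dict[str, float]:
    """Per-region mean absolute band-power difference between conditions (dB).

    Differences are taken per filter first, then averaged within regions, so
    the result is nonnegative and invariant to a common gain on both inputs.
    """
    if ear not in ("left", "right"):
        raise ValueError("ear must be 'left' or 'right'")
    _check_pair(with_hmd, without_hmd)
    if centers is None:
        centers = erb_centers(fs=with_hmd.fs)
    p_with = band_powers_db(getattr(with_hmd, ear), with_hmd.fs, centers)
    p_without = band_powers_db(getattr(without_hmd, ear), without_hmd.fs, centers)
    return region_means(np.abs(p_with - p_without), centers, regions)


def ild_regions(
    ir: BinauralIR,
    centers: np.ndarray | None = None,
    regions: FrequencyRegions = DEFAULT_REGIONS,
) -> dict[str, float]:
    """Per-region ILD (left minus right auditory-filter power, dB)."""
    if centers is None:
        centers = erb_centers(fs=ir.fs)
    p_left = band_powers_db(ir.left, ir.fs, centers)
    p_right = band_powers_db(ir.right, ir.fs, centers)
    return region_means(p_left - p_right, centers, regions)


def minimum_phase(channel: np.ndarray, pad_factor: int = 8) -> np.ndarray:
    """Minimum-phase counterpart of a signal via real-cepstrum folding.

    The output shares the input's magnitude spectrum (evaluated on the padded
    FFT grid) while its energy is maximally front-loaded.  The FFT length is
    at least ``pad_factor`` times the input length to limit cepstral
    wrap-around; the full padded-length signal is returned so the magnitude
    spectrum is preserved exactly.
    """
    x = np.asarray(channel, dtype=float)
    if x.size == 0 or not np.any(x):
        raise ValueError("cannot compute the minimum-phase version of silence")
    nfft = 1 << (pad_factor * len(x) - 1).bit_length()
    mag = np.abs(np.fft.fft(x, n=nfft))
    mag = np.maximum(mag, mag.max() * 1e-12)  # guard spectral zeros
    cep = np.fft.ifft(np.log(mag)).real
    fold = np.zeros_like(cep)
    fold[0] = cep[0]
    fold[1 : nfft // 2] = 2.0 * cep[1 : nfft // 2]
    fold[nfft // 2] = cep[nfft // 2]
    return np.fft.ifft(np.exp(np.fft.fft(fold))).real


def ear_delay(channel: np.ndarray, fs: float | None = None) -> int:
    """Pure delay (samples) of a channel: peak-lag of x correlated with minphase(x).

    Ties are broken toward the smallest lag.  ``fs`` is accepted for interface
    symmetry; the returned lag is in samples regardless.
    """
    x = np.asarray(channel, dtype=float)
    mp = minimum_phase(x)
    corr = sps.correlate(x, mp, mode="full")
    # lags run from -(len(mp)-1) to len(x)-1; argmax returns the first
    # (smallest-lag) maximum
    return int(np.argmax(corr)) - (len(mp) - 1)


def itd_us(ir: BinauralIR) -> float:
    """Interaural time difference in microseconds, left delay minus right delay.

    Positive when the left ear lags, i.e. the source is on the right.
    """
    d_left = ear_delay(ir.left)
    d_right = ear_delay(ir.right)
    return (d_left - d_right) / ir.fs * 1e6


def extract_cues(
    ir: BinauralIR,
    centers: np.ndarray | None = None,
    regions: FrequencyRegions = DEFAULT_REGIONS,
) -> CueSet:
    """ILD per region and ITD for one BRIR."""
    return CueSet(
        ild_db=ild_regions(ir, centers, regions),
        itd_us=itd_us(ir),
        source=ir.source,
    )


def cue_errors(
    with_hmd: BinauralIR,
    without_hmd: BinauralIR,
    centers: np.ndarray | None = None,
    regions: FrequencyRegions = DEFAULT_REGIONS,
    convention: str = "magnitude",
) -> CueErrors:
    """HMD-induced cue errors for one direction.

    With the default ``magnitude`` convention the ILD and ITD errors are
    differences of magnitudes, |cue_with| - |cue_without| (positive = the
    device makes the cue larger); ``signed`` gives plain with-minus-without
    differences instead.
    """
    if convention not in ("magnitude", "signed"):
        raise ValueError("convention must be 'magnitude' or 'signed'")
    _check_pair(with_hmd, without_hmd)
    if centers is None:
        centers = erb_centers(fs=with_hmd.fs)
    ild_w = ild_regions(with_hmd, centers, regions)
    ild_o = ild_regions(without_hmd, centers, regions)
    itd_w = itd_us(with_hmd)
    itd_o = itd_us(without_hmd)
    if convention == "magnitude":
        ild_err = {k: abs(ild_w[k]) - abs(ild_o[k]) for k in ild_w}
        itd_err = abs(itd_w) - abs(itd_o)
    else:
        ild_err = {k: ild_w[k] - ild_o[k] for k in ild_w}
        itd_err = itd_w - itd_o
    return CueErrors(
        sd_left_db=spectral_difference(with_hmd, without_hmd, "left", centers, regions),
        sd_right_db=spectral_difference(with_hmd, without_hmd, "right", centers, regions),
        ild_error_db=ild_err,
        itd_error_us=itd_err,
        source=with_hmd.source or without_hmd.source,
    )
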