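"""Band sound-pressure levels, acoustic presence, and noise–activity models.

Band SPL is measured from mono PCM audio by short-time Fourier analysis
(1024-point FFT, Blackman–Harris window, 50% overlap): for each requested
center frequency the windowed power-spectrum bin nearest the center is
averaged over frames and expressed in dB relative to digital full scale
(0 dBFS = full-scale sine).  Absolute calibration of field recorders is
typically unknown, so all values are relative noise proxies: the 1 kHz band
tracks geophony (wind, rain), the mean of the 4 and 5 kHz bands tracks the
daytime bird chorus.

Acoustic presence is the percentage of hourly records in a period
(daylight/night) in which advertisement calls were detected.  Calling
activity (CA, calls per minute) is related to noise with either a
square-root-y model (OLS of sqrt(CA) on SPL, reported as CA = (a + b·SPL)²)
or an ordinary linear model; R² is reported on the fitted scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.io import wavfile
from scipy.signal import get_window

from .annotation_io import (
    MinuteRecord,
    SPLProfile,
    SurveyDesign,
    as_frame,
)

__all__ = [
    "BandSPLRequest",
    "RegressionFit",
    "band_spl",
    "read_wav",
    "acoustic_presence",
    "fit_noise_regression",
    "rain_contrast",
    "bird_band_spl",
]

SPL_FLOOR_DB = -120.0


@dataclass(frozen=True)
class BandSPLRequest:
    """Analysis parameters for band-SPL extraction."""

    center_freqs: tuple[float, ...] = (1000.0, 2000.0, 3000.0, 4000.0, 5000.0)
    fft_size: int = 1024
    window: str = "blackmanharris"
    sample_rate: float = 44100.0

    def __post_init__(self) -> None:
        if self.fft_size < 2 or self.fft_size & (self.fft_size - 1):
            raise ValueError("fft_size must be a power of two")
        nyquist = self.sample_rate / 2
        for f in self.center_freqs:
            if not (0 < f < nyquist):
                raise ValueError(f"center frequency {f} Hz outside (0, {nyquist})")


def read_wav(path) -> tuple[float, np.ndarray]:
    """Read a RIFF/WAVE file to (sample_rate, mono float signal in [-1, 1]).

    Integer PCM is scaled by its full-scale value; stereo is averaged to
    mono.
    """
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max + 1)
    elif data.dtype.kind == "u":  # 8-bit WAV is unsigned
        info = np.iinfo(data.dtype)
        data = (data.astype(np.float64) - (info.max + 1) / 2) / ((info.max + 1) / 2)
    else:
        data = data.astype(np.float64)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return float(rate), data


def band_spl(audio: np.ndarray, req: BandSPLRequest = BandSPLRequest()) -> SPLProfile:
    """Mean band SPL (dBFS) at each requested center frequency.

    The band value is the single FFT bin nearest the center frequency,
    averaged (as power) over 50%-overlapping windowed frames.  Amplitudes
    are normalized by the window's coherent gain so a full-scale sine at a
    bin center reads 0 dBFS; digital silence reads the numeric floor of
    -120 dB.
    """
    x = np.asarray(audio, dtype=float)
    n = req.fft_size
    if x.size < n:
        raise ValueError(f"audio shorter ({x.size}) than fft_size ({n})")
    hop = n // 2
    n_frames = 1 + (x.size - n) // hop
    idx = np.arange(n)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * get_window(req.window, n, fftbins=True)
    spectrum = np.fft.rfft(frames, axis=1)
    coherent_gain = get_window(req.window, n, fftbins=True).sum()
    # power of an equivalent full-scale sine: |X| * 2 / sum(w) == amplitude
    power = (np.abs(spectrum) * 2.0 / coherent_gain) ** 2
    mean_power = power.mean(axis=0)
    levels = []
    for f in req.center_freqs:
        k = int(round(f * n / req.sample_rate))
        k = min(k, mean_power.size - 1)
        db = 10.0 * np.log10(max(mean_power[k], 10.0 ** (SPL_FLOOR_DB / 10.0)))
        levels.append(float(max(min(db, 0.0), SPL_FLOOR_DB)))
    fields = {}
    for f, db in zip(req.center_freqs, levels):
        khz = int(round(f / 1000.0))
        if 1 <= khz <= 5:
            fields[f"spl_{khz}k"] = db
    return SPLProfile(**fields)


def bird_band_spl(profile: SPLProfile) -> float | None:
    """Daytime bird-chorus noise proxy: mean of the 4 and 5 kHz bands."""
    if profile.spl_4k is None or profile.spl_5k is None:
        return None
    return (profile.spl_4k + profile.spl_5k) / 2.0


def acoustic_presence(
    records: Sequence[MinuteRecord] | pd.DataFrame,
    site: str,
    period: str,
    design: SurveyDesign | None = None,
    species: str | None = None,
) -> float:
    """Percentage of hourly records in a period with calls detected.

    An hourly record (one site/date/hour) counts as present when any of its
    annotated minutes has ``call_rate > 0`` — for any species, or for the
    given ``species`` (specific acoustic presence).
    """
    df = as_frame(records)
    at_site = df[df["site"] == site]
    if at_site.empty:
        raise ValueError(f"no records for site {site!r}")
    if design is None:
        hours = _default_period_hours(period)
    else:
        hours = design.period_hours(period)
    in_period = at_site[at_site["hour"].isin(hours)]
    if in_period.empty:
        raise ValueError(f"no hourly records at {site!r} in period {period!r}")
    grouped = in_period.groupby(["date", "hour"], sort=False)
    total = grouped.ngroups
    if species is None:
        present = grouped["call_rate"].max() > 0
    else:
        present = grouped.apply(
            lambda g: bool(((g["species"] == species) & (g["call_rate"] > 0)).any()),
            include_groups=False,
        )
    return 100.0 * float(present.sum()) / total


def _default_period_hours(period: str) -> frozenset[int]:
    if period == "daylight":
        return frozenset(range(6, 19))
    if period == "night":
        return frozenset(range(19, 24)) | frozenset(range(0, 6))
    raise ValueError(f"period must be 'daylight' or 'night', got {period!r}")


@dataclass(frozen=True)
class RegressionFit:
    """A fitted noise–activity regression.

    For ``model='sqrt_y'`` the fitted relation is CA = (intercept +
    slope·SPL)²; for ``model='linear'`` it is CA = intercept + slope·SPL.
    ``r2`` and ``p_slope`` refer to the fitted (possibly transformed) scale.
    """

    model: str
    intercept: float
    slope: float
    r2: float
    n: int
    p_slope: float

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("regression needs at least 3 points")
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError(f"r2={self.r2} outside [0, 1]")

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        yhat = self.intercept + self.slope * x
        return yhat**2 if self.model == "sqrt_y" else yhat


def fit_noise_regression(
    x: Sequence[float], y: Sequence[float], model: str = "sqrt_y"
) -> RegressionFit:
    """OLS fit of calling activity on a band-SPL noise proxy."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: zero variance")
    if model == "sqrt_y":
        if (y < 0).any():
            raise ValueError("sqrt_y model requires non-negative y")
        target = np.sqrt(y)
    elif model == "linear":
        target = y
    else:
        raise ValueError(f"unknown regression model {model!r}")
    res = stats.linregress(x, target)
    return RegressionFit(
        model=model,
        intercept=float(res.intercept),
        slope=float(res.slope),
        r2=float(res.rvalue**2),
        n=int(x.size),
        p_slope=float(res.pvalue),
    )


def rain_contrast(
    records: Sequence[MinuteRecord] | pd.DataFrame,
    species: str,
    site: str | None = None,
) -> tuple[float, float]:
    """Mean call rate of a species under (no/light rain, heavy rain).

    Means are per annotated minute, counting minutes in which the species
    was silent as zero — a species silenced by rain therefore pulls the
    rainy mean down rather than vanishing from the denominator.
    """
    df = as_frame(records)
    if site is not None:
        df = df[df["site"] == site]
    minutes = df.drop_duplicates(subset=["site", "date", "hour", "minute_index"])
    sp = df[df["species"] == species]
    out = []
    for stratum in ("dry", "rain"):
        mask_minutes = minutes["rain_index"] < 2 if stratum == "dry" else minutes["rain_index"] == 2
        mask_sp = sp["rain_index"] < 2 if stratum == "dry" else sp["rain_index"] == 2
        n = int(mask_minutes.sum())
        if n == 0:
            raise ValueError(f"empty {stratum} stratum")
        out.append(float(sp.loc[mask_sp, "call_rate"].sum()) / n)
    return out[0], out[1]
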