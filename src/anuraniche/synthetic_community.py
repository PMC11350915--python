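"""Synthetic anuran-community generator for annotation datasets.

Emulates the statistical structure of hourly passive-acoustic-monitoring
annotations: for every site, date, hour and minute a rain state is drawn,
band sound-pressure levels are composed from a baseline plus rain (1 kHz
dominated) and daylight bird-chorus (4–5 kHz) increments, and each species'
per-minute call count is drawn from a Poisson law whose mean is the product
of an hourly (diel) base rate, a monthly (seasonal) multiplier, a site
multiplier, a daytime bird-response factor and — during heavy rain — a
suppression factor.  Call features (dominant frequency, notes, pulses) are
drawn from species-specific distributions: truncated-normal frequency and
categorical note/pulse counts, the simplest laws with the right support.

One call feature is measured per active (minute, species), mirroring the
field protocol of annotating the first recognizable call of each species in
each minute.

Because every ingredient is analytic, :func:`expected_profiles` returns the
niche profiles the generator implies *without* simulation, which makes
parameter-recovery testing of the whole analysis chain possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import ndtr, ndtri

from .annotation_io import (
    CallFeature,
    MinuteRecord,
    SPLProfile,
    SurveyDesign,
    default_design,
)
from .niche_partitioning import (
    NicheProfile,
    bin_pulses,
    call_structure_scheme,
    diel_scheme,
    seasonal_scheme,
    FREQ_LO,
    FREQ_HI,
    FREQ_WIDTH,
    N_FREQ_CLASSES,
    N_NOTE_CLASSES,
    N_PULSE_CLASSES,
)

__all__ = [
    "SpeciesParams",
    "SPLModel",
    "GeneratorConfig",
    "generate_dataset",
    "expected_profiles",
    "virunga_community_config",
]


@dataclass(frozen=True)
class SpeciesParams:
    """Generator parameters for one synthetic species.

    ``diel_rate`` is the 24-vector of mean calls/min per hour; an optional
    per-site override (``diel_rate_by_site``) lets a species shift its diel
    pattern between sites while keeping the same call structure.
    ``day_bird_response`` scales the daytime rate by ``max(0, 1 + value)``
    — positive values model species that call more against the bird chorus,
    negative values species suppressed by it.
    """

    name: str
    freq_mean: float  # Hz
    freq_sd: float  # Hz
    freq_range: tuple[float, float]  # truncation bounds (lo, hi), Hz
    notes_probs: tuple[float, ...]  # P(1 note), P(2 notes), ... up to 5
    pulses_values: tuple[int, ...]
    pulses_probs: tuple[float, ...]
    diel_rate: tuple[float, ...]  # 24 mean calls/min
    seasonal_mult: Mapping[str, float]  # month -> multiplier
    site_mult: Mapping[str, float]  # site -> multiplier
    rain_suppression: float = 1.0  # factor on the mean during heavy rain
    day_bird_response: float = 0.0
    duration_range_ms: tuple[float, float] | None = None
    diel_rate_by_site: Mapping[str, tuple[float, ...]] | None = None

    def __post_init__(self) -> None:
        for label, probs in (("notes_probs", self.notes_probs),
                             ("pulses_probs", self.pulses_probs)):
            arr = np.asarray(probs, dtype=float)
            if (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: {label} must be a probability vector")
        if len(self.notes_probs) > 5:
            raise ValueError(f"{self.name}: notes_probs supports at most 5 note classes")
        if len(self.pulses_values) != len(self.pulses_probs):
            raise ValueError(f"{self.name}: pulses_values / pulses_probs length mismatch")
        if any(v < 0 for v in self.pulses_values):
            raise ValueError(f"{self.name}: pulse counts must be >= 0")
        if len(self.diel_rate) != 24 or any(r < 0 for r in self.diel_rate):
            raise ValueError(f"{self.name}: diel_rate must be 24 non-negative rates")
        if not (0.0 <= self.rain_suppression <= 1.0):
            raise ValueError(f"{self.name}: rain_suppression must lie in [0, 1]")
        if any(m < 0 for m in self.seasonal_mult.values()):
            raise ValueError(f"{self.name}: seasonal multipliers must be >= 0")
        if any(m < 0 for m in self.site_mult.values()):
            raise ValueError(f"{self.name}: site multipliers must be >= 0")
        if not (self.freq_range[0] < self.freq_range[1]):
            raise ValueError(f"{self.name}: empty frequency truncation range")
        if self.freq_sd <= 0:
            raise ValueError(f"{self.name}: freq_sd must be positive")
        if self.diel_rate_by_site is not None:
            for site, rates in self.diel_rate_by_site.items():
                if len(rates) != 24 or any(r < 0 for r in rates):
                    raise ValueError(
                        f"{self.name}: diel_rate_by_site[{site!r}] must be 24 "
                        "non-negative rates"
                    )

    def site_diel_rate(self, site: str) -> np.ndarray:
        if self.diel_rate_by_site and site in self.diel_rate_by_site:
            return np.asarray(self.diel_rate_by_site[site], dtype=float)
        return np.asarray(self.diel_rate, dtype=float)

    def bird_factor(self) -> float:
        return max(0.0, 1.0 + self.day_bird_response)


@dataclass(frozen=True)
class SPLModel:
    """Deterministic band-SPL composition plus Gaussian jitter (dBFS)."""

    baseline: tuple[float, float, float, float, float] = (-85.0, -82.0, -80.0, -78.0, -78.0)
    light_rain_increment: tuple[float, float, float, float, float] = (20.0, 10.0, 8.0, 6.0, 5.0)
    heavy_rain_increment: tuple[float, float, float, float, float] = (40.0, 25.0, 18.0, 15.0, 12.0)
    bird_increment: tuple[float, float, float, float, float] = (0.0, 3.0, 8.0, 15.0, 15.0)
    jitter_sd: float = 1.5


@dataclass(frozen=True)
class GeneratorConfig:
    """Complete specification of a synthetic survey."""

    design: SurveyDesign
    species: tuple[SpeciesParams, ...]
    rain_prob_per_hour: float = 0.15
    heavy_rain_prob: float = 0.3  # P(heavy | rain)
    days_per_month: int = 3
    spl_model: SPLModel = field(default_factory=SPLModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("config needs at least one species")
        if not (0.0 <= self.rain_prob_per_hour <= 1.0):
            raise ValueError("rain_prob_per_hour must lie in [0, 1]")
        if not (0.0 <= self.heavy_rain_prob <= 1.0):
            raise ValueError("heavy_rain_prob must lie in [0, 1]")
        if self.days_per_month < 1:
            raise ValueError("days_per_month must be >= 1")
        object.__setattr__(self, "species", tuple(self.species))

    def species_params(self, name: str) -> SpeciesParams:
        for sp in self.species:
            if sp.name == name:
                return sp
        raise KeyError(f"unknown species {name!r}")

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(sp.name for sp in self.species)


def _truncnorm_sample(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    """Inverse-CDF sampling of a truncated normal (vectorized, exact)."""
    a, b = ndtr((lo - mean) / sd), ndtr((hi - mean) / sd)
    u = rng.uniform(a, b, size=size)
    return mean + sd * ndtri(u)


def _expected_rate(sp: SpeciesParams, site: str, month: str, hour: int,
                   config: GeneratorConfig) -> float:
    """Poisson mean for one (species, site, month, hour), averaged over the
    rain process (used by tests comparing empirical to configured means)."""
    design = config.design
    base = sp.site_diel_rate(site)[hour] * sp.seasonal_mult.get(month, 0.0) \
        * sp.site_mult.get(site, 0.0)
    if hour in design.daylight_hours:
        base *= sp.bird_factor()
    p_heavy = config.rain_prob_per_hour * config.heavy_rain_prob
    return base * ((1.0 - p_heavy) + p_heavy * sp.rain_suppression)


def generate_dataset(
    config: GeneratorConfig, seed: int | None = None
) -> list[MinuteRecord]:
    """Generate a full annotation dataset; deterministic given config + seed.

    Returns one :class:`MinuteRecord` per active (minute, species) plus an
    empty-species record for every silent minute, in site/date/hour/minute
    order.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    design = config.design
    spl = config.spl_model
    records: list[MinuteRecord] = []

    for site in design.sites:
        site_daylight = np.array([h in design.daylight_hours for h in range(24)])
        for month in design.months[site]:
            n_days = config.days_per_month
            n_hours = n_days * 24
            n_minutes = n_hours * 5

            # hour-level rain process, shared by the 5 minutes of the hour
            rain_u = rng.random(n_hours)
            heavy_u = rng.random(n_hours)
            rain_hour = np.where(
                rain_u < config.rain_prob_per_hour,
                np.where(heavy_u < config.heavy_rain_prob, 2, 1),
                0,
            )

            day_idx = np.repeat(np.arange(n_days), 24 * 5)
            hour_idx = np.tile(np.repeat(np.arange(24), 5), n_days)
            minute_idx = np.tile(np.arange(1, 6), n_hours)
            rain_minute = np.repeat(rain_hour, 5)
            is_day = site_daylight[hour_idx]

            # band SPL: baseline + rain + (daylight, dry) bird chorus + jitter
            spl_bands = np.empty((n_minutes, 5))
            for b in range(5):
                level = np.full(n_minutes, spl.baseline[b])
                level += np.where(rain_minute == 1, spl.light_rain_increment[b], 0.0)
                level += np.where(rain_minute == 2, spl.heavy_rain_increment[b], 0.0)
                level += np.where(is_day & (rain_minute == 0), spl.bird_increment[b], 0.0)
                level += rng.normal(0.0, spl.jitter_sd, size=n_minutes)
                spl_bands[:, b] = np.clip(level, -120.0, 0.0)

            # per-species Poisson counts and one measured call per active minute
            counts: dict[str, np.ndarray] = {}
            features: dict[str, dict[int, CallFeature]] = {}
            for sp in config.species:
                rate_h = sp.site_diel_rate(site) * sp.seasonal_mult.get(month, 0.0) \
                    * sp.site_mult.get(site, 0.0)
                lam = rate_h[hour_idx].astype(float)
                lam[is_day] *= sp.bird_factor()
                lam[rain_minute == 2] *= sp.rain_suppression
                c = rng.poisson(lam)
                counts[sp.name] = c
                active = np.flatnonzero(c > 0)
                feats: dict[int, CallFeature] = {}
                if active.size:
                    freqs = _truncnorm_sample(
                        rng, sp.freq_mean, sp.freq_sd,
                        sp.freq_range[0], sp.freq_range[1], active.size,
                    )
                    notes = rng.choice(
                        np.arange(1, len(sp.notes_probs) + 1),
                        p=np.asarray(sp.notes_probs), size=active.size,
                    )
                    pulses = rng.choice(
                        np.asarray(sp.pulses_values),
                        p=np.asarray(sp.pulses_probs), size=active.size,
                    )
                    if sp.duration_range_ms is not None:
                        durs = rng.uniform(*sp.duration_range_ms, size=active.size)
                    else:
                        durs = None
                    for k, m in enumerate(active):
                        feats[int(m)] = CallFeature(
                            dominant_freq=float(freqs[k]),
                            n_notes=int(notes[k]),
                            n_pulses=int(pulses[k]),
                            duration_ms=None if durs is None else float(durs[k]),
                        )
                features[sp.name] = feats

            for m in range(n_minutes):
                date = f"{month}-{day_idx[m] + 1:02d}"
                prof = SPLProfile(*(float(x) for x in spl_bands[m]))
                common = dict(
                    site=site, date=date, month=month,
                    hour=int(hour_idx[m]), minute_index=int(minute_idx[m]),
                    spl=prof, rain_index=int(rain_minute[m]),
                )
                any_active = False
                for sp in config.species:
                    c = int(counts[sp.name][m])
                    if c > 0:
                        any_active = True
                        feat = features[sp.name].get(m)
                        records.append(MinuteRecord(
                            species=sp.name, call_rate=c,
                            calls=(feat,) if feat is not None else (),
                            **common,
                        ))
                if not any_active:
                    records.append(MinuteRecord(species="", call_rate=0, **common))
    return records


# ---------------------------------------------------------------------------
# analytic expectations


def _expected_call_structure(sp: SpeciesParams) -> np.ndarray:
    # frequency block: truncated-normal mass per 500 Hz class, with the
    # out-of-range tails accumulated onto the edge classes (the clamp rule)
    lo, hi = sp.freq_range
    a, b = ndtr((lo - sp.freq_mean) / sp.freq_sd), ndtr((hi - sp.freq_mean) / sp.freq_sd)

    def cdf(x: float) -> float:
        z = ndtr((x - sp.freq_mean) / sp.freq_sd)
        return float(np.clip((z - a) / (b - a), 0.0, 1.0))

    edges = [FREQ_LO + i * FREQ_WIDTH for i in range(N_FREQ_CLASSES + 1)]
    freq = np.array([cdf(edges[i + 1]) - cdf(edges[i]) for i in range(N_FREQ_CLASSES)])
    freq[0] += cdf(edges[0])  # mass below 500 Hz clamps to class 0
    freq[-1] += 1.0 - cdf(edges[-1])  # mass at/above 5000 Hz clamps to class 8

    notes = np.zeros(N_NOTE_CLASSES)
    notes[: len(sp.notes_probs)] = sp.notes_probs

    pulses = np.zeros(N_PULSE_CLASSES)
    for v, p in zip(sp.pulses_values, sp.pulses_probs):
        pulses[bin_pulses(v)] += p

    return np.concatenate([freq / 3.0, notes / 3.0, pulses / 3.0])


def expected_profiles(
    config: GeneratorConfig, species: str, site: str,
    months: Sequence[str] | None = None,
) -> dict[str, NicheProfile]:
    """The niche profiles analytically implied by the generator parameters.

    Computed without simulation: frequency mass from the truncated-normal
    CDF, note/pulse mass from the categorical laws, the diel profile from
    the normalized effective hourly rates (including the deterministic
    daytime bird-response factor; the rain process scales all hours equally
    and cancels), and the seasonal profile from the normalized monthly
    multipliers (the diel structure repeats identically in every month, so
    per-month *mean* rates are proportional to the multipliers).
    """
    sp = config.species_params(species)
    design = config.design

    cs = NicheProfile(species, site, call_structure_scheme(),
                      _expected_call_structure(sp))

    rate_h = sp.site_diel_rate(site).astype(float).copy()
    for h in range(24):
        if h in design.daylight_hours:
            rate_h[h] *= sp.bird_factor()
    total = rate_h.sum()
    diel = NicheProfile(species, site, diel_scheme(),
                        rate_h / total if total > 0 else None)

    if months is None:
        months = design.months[site]
    seas_w = np.array([
        sp.seasonal_mult.get(m, 0.0) if m in design.months[site] else 0.0
        for m in months
    ], dtype=float)
    s_total = seas_w.sum()
    seasonal = NicheProfile(species, site, seasonal_scheme(months),
                            seas_w / s_total if s_total > 0 else None)

    return {"call_structure": cs, "diel": diel, "seasonal": seasonal}


# ---------------------------------------------------------------------------
# packaged study-like configuration


def _diel(night: float, day: float, *, dusk: float | None = None,
          dawn: float | None = None,
          night_hours: Sequence[int] = tuple(range(19, 24)) + tuple(range(0, 6)),
          ) -> tuple[float, ...]:
    rates = [day] * 24
    for h in night_hours:
        rates[h] = night
    if dusk is not None:
        rates[18] = dusk
    if dawn is not None:
        rates[6] = dawn
    return tuple(rates)


def virunga_community_config(seed: int = 1, days_per_month: int = 3) -> GeneratorConfig:
    """A packaged six-species, two-site configuration qualitatively matching
    high-altitude wetland communities of the Virunga Massif: one dominant
    nocturnal high-frequency species, one diurnal tonal-call species, two
    low-frequency species with long vs short pulsed calls, one broad-band
    pulsed species active day and night, and one rare nocturnal species; the
    lower site supports higher calling rates for most species while the
    dominant species calls more at the high site.  Rates encode directions
    and orders of magnitude, not measured values.
    """
    design = default_design()
    months_sandi = design.months["Sandi"]
    seasonal_rise = dict(zip(months_sandi, (0.3, 0.4, 0.5, 0.7, 1.2, 1.6, 1.8)))
    seasonal_fall = dict(zip(months_sandi, (1.5, 1.2, 1.0, 0.8, 0.6, 0.6, 0.5)))
    seasonal_peak = dict(zip(months_sandi, (0.6, 0.8, 1.6, 1.5, 0.5, 0.3, 0.2)))
    seasonal_early = dict(zip(months_sandi, (1.0, 1.0, 0.3, 0.1, 0.1, 0.1, 0.1)))

    species = (
        SpeciesParams(
            name="hyperolius_castaneus",
            freq_mean=3400.0, freq_sd=150.0, freq_range=(3000.0, 3900.0),
            notes_probs=(1.0,),
            pulses_values=(6, 7, 8, 9, 10, 11),
            pulses_probs=(1 / 6,) * 6,
            diel_rate=_diel(night=60.0, day=0.05, dusk=0.5),
            diel_rate_by_site={"Sandi": _diel(night=60.0, day=0.3, dusk=2.0)},
            seasonal_mult=seasonal_rise,
            site_mult={"Sandi": 1.4, "Malalo": 1.0},
            rain_suppression=0.6,
            day_bird_response=-0.6,
            duration_range_ms=(26.0, 73.0),
        ),
        SpeciesParams(
            name="hyperolius_glandicolor",
            freq_mean=2900.0, freq_sd=120.0, freq_range=(2600.0, 3300.0),
            notes_probs=(1.0,),
            pulses_values=(0,), pulses_probs=(1.0,),  # tonal click
            diel_rate=_diel(night=0.05, day=0.05),
            diel_rate_by_site={
                "Malalo": tuple(2.0 if 6 <= h <= 12 else 0.05 for h in range(24)),
            },
            seasonal_mult=seasonal_fall,
            site_mult={"Sandi": 0.4, "Malalo": 1.2},
            rain_suppression=0.0,
            day_bird_response=0.5,
            duration_range_ms=(39.0, 77.0),
        ),
        SpeciesParams(
            name="leptopelis_karissimbensis",
            freq_mean=1800.0, freq_sd=120.0, freq_range=(1500.0, 2100.0),
            notes_probs=(1.0,),
            pulses_values=(60, 90, 120, 150), pulses_probs=(0.3, 0.3, 0.25, 0.15),
            diel_rate=_diel(night=2.5, day=0.0, dusk=1.0),
            seasonal_mult=seasonal_peak,
            site_mult={"Sandi": 0.8, "Malalo": 1.3},
            rain_suppression=0.0,
            duration_range_ms=(534.0, 1444.0),
        ),
        SpeciesParams(
            name="leptopelis_kivuensis",
            freq_mean=1500.0, freq_sd=130.0, freq_range=(1200.0, 1900.0),
            notes_probs=(1.0,),
            pulses_values=(5, 6, 7, 8, 9, 10, 11, 12), pulses_probs=(1 / 8,) * 8,
            diel_rate=_diel(night=12.0, day=0.0, dusk=3.0),
            seasonal_mult=seasonal_peak,
            site_mult={"Sandi": 0.9, "Malalo": 1.4},
            rain_suppression=0.1,
            duration_range_ms=(45.0, 83.0),
        ),
        SpeciesParams(
            name="phrynobatrachus_bequaerti",
            freq_mean=3100.0, freq_sd=700.0, freq_range=(2000.0, 4600.0),
            notes_probs=(0.2, 0.2, 0.2, 0.2, 0.2),  # long note + 1-5 clicks
            pulses_values=tuple(range(4, 30)), pulses_probs=(1 / 26,) * 26,
            diel_rate=_diel(night=0.4, day=0.3, dusk=1.0, dawn=0.1),
            seasonal_mult=seasonal_peak,
            site_mult={"Sandi": 1.0, "Malalo": 1.2},
            rain_suppression=0.0,
            duration_range_ms=(240.0, 980.0),
        ),
        SpeciesParams(
            name="amietia_desaegeri",
            freq_mean=1700.0, freq_sd=100.0, freq_range=(1400.0, 2000.0),
            notes_probs=(1.0,),
            pulses_values=(5,), pulses_probs=(1.0,),
            diel_rate=tuple(0.4 if h in (20, 21) else 0.0 for h in range(24)),
            seasonal_mult=seasonal_early,
            site_mult={"Sandi": 1.0, "Malalo": 0.5},
            rain_suppression=0.0,
            duration_range_ms=(250.0, 260.0),
        ),
    )
    return GeneratorConfig(
        design=design, species=species, rain_prob_per_hour=0.15,
        heavy_rain_prob=0.3, days_per_month=days_per_month, seed=seed,
    )
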