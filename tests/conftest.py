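"""Shared fixtures: hand-built toy records and synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from anuraniche import (
    CallFeature,
    MinuteRecord,
    SurveyDesign,
    default_design,
    generate_dataset,
    to_frame,
    virunga_community_config,
)
from anuraniche.synthetic_community import GeneratorConfig, SpeciesParams


@pytest.fixture(scope="session")
def design() -> SurveyDesign:
    return default_design()


@pytest.fixture(scope="session")
def small_dataset():
    """A small two-site, six-species synthetic survey (records + frame)."""
    cfg = virunga_community_config(seed=1, days_per_month=2)
    records = generate_dataset(cfg)
    return cfg, records, to_frame(records)


def _smooth_diel(night: float, day: float) -> tuple[float, ...]:
    night_hours = set(range(19, 24)) | set(range(0, 6))
    return tuple(night if h in night_hours else day for h in range(24))


def recovery_config(seed: int, days_per_month: int) -> GeneratorConfig:
    """Six-species, two-site config in which every species is sampled densely
    enough for its niche profiles to be estimable to a couple of percent —
    used for parameter-recovery and cross-site clustering checks.  Species
    parameters are site-consistent (only scalar site multipliers differ), so
    conspecific niches across sites coincide in expectation.
    """
    design = default_design()
    months = design.months["Sandi"]
    rise = dict(zip(months, (0.4, 0.5, 0.7, 0.9, 1.2, 1.4, 1.6)))
    fall = dict(zip(months, (1.6, 1.4, 1.2, 0.9, 0.7, 0.5, 0.4)))
    peak = dict(zip(months, (0.5, 0.8, 1.5, 1.4, 0.8, 0.5, 0.4)))
    mild = dict(zip(months, (0.7, 0.9, 1.1, 1.3, 1.1, 0.9, 0.7)))
    both = {"Sandi": 1.2, "Malalo": 0.8}
    species = (
        SpeciesParams(
            name="nocturnal_high", freq_mean=3400, freq_sd=150,
            freq_range=(3000, 3900), notes_probs=(1.0,),
            pulses_values=(6, 7, 8, 9, 10, 11), pulses_probs=(1 / 6,) * 6,
            diel_rate=_smooth_diel(8.0, 0.5), seasonal_mult=rise,
            site_mult=both, rain_suppression=0.5, day_bird_response=-0.3,
        ),
        SpeciesParams(
            name="diurnal_tonal", freq_mean=2900, freq_sd=120,
            freq_range=(2600, 3300), notes_probs=(1.0,),
            pulses_values=(0,), pulses_probs=(1.0,),
            diel_rate=_smooth_diel(0.5, 4.0), seasonal_mult=fall,
            site_mult={"Sandi": 0.9, "Malalo": 1.1},
            rain_suppression=0.2, day_bird_response=0.4,
        ),
        SpeciesParams(
            name="low_long_pulsed", freq_mean=1800, freq_sd=120,
            freq_range=(1500, 2100), notes_probs=(1.0,),
            pulses_values=(60, 90, 120), pulses_probs=(0.4, 0.35, 0.25),
            diel_rate=_smooth_diel(3.0, 0.4), seasonal_mult=peak,
            site_mult={"Sandi": 1.0, "Malalo": 1.0}, rain_suppression=0.0,
        ),
        SpeciesParams(
            name="low_short_pulsed", freq_mean=1500, freq_sd=130,
            freq_range=(1200, 1900), notes_probs=(1.0,),
            pulses_values=(5, 6, 7, 8, 9, 10, 11, 12), pulses_probs=(1 / 8,) * 8,
            diel_rate=_smooth_diel(6.0, 0.3), seasonal_mult=peak,
            site_mult={"Sandi": 0.8, "Malalo": 1.2}, rain_suppression=0.1,
        ),
        SpeciesParams(
            name="broadband_pulsed", freq_mean=3100, freq_sd=700,
            freq_range=(2000, 4600), notes_probs=(0.2,) * 5,
            pulses_values=tuple(range(4, 30)), pulses_probs=(1 / 26,) * 26,
            diel_rate=_smooth_diel(2.0, 2.0), seasonal_mult=mild,
            site_mult=both, rain_suppression=0.3,
        ),
        SpeciesParams(
            name="evening_caller", freq_mean=1700, freq_sd=100,
            freq_range=(1400, 2000), notes_probs=(1.0,),
            pulses_values=(5,), pulses_probs=(1.0,),
            diel_rate=tuple(1.5 if 19 <= h <= 23 else 0.2 for h in range(24)),
            seasonal_mult=mild, site_mult={"Sandi": 1.0, "Malalo": 0.9},
        ),
    )
    return GeneratorConfig(design=design, species=species,
                           rain_prob_per_hour=0.15, heavy_rain_prob=0.3,
                           days_per_month=days_per_month, seed=seed)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240816)


def minute(site="Sandi", date="2019-09-01", hour=0, minute_index=1, species="",
           call_rate=0, calls=(), rain_index=0, **kw) -> MinuteRecord:
    """Terse MinuteRecord builder for hand-constructed examples."""
    return MinuteRecord(site=site, date=date, hour=hour, minute_index=minute_index,
                        species=species, call_rate=call_rate, calls=tuple(calls),
                        rain_index=rain_index, **kw)


def call(freq=3400.0, notes=1, pulses=8) -> CallFeature:
    return CallFeature(dominant_freq=freq, n_notes=notes, n_pulses=pulses)
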