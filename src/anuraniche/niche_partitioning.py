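"""Acoustic niche breadth, overlap, and the randomization null model.

The acoustic niche of a calling anuran is described along three dimensions:

* **call structure** — 25 resource classes: 9 dominant-frequency classes
  (500 Hz wide, 500–5000 Hz), 5 note-count classes (1–5 notes), and 11
  pulse-count classes (class 0 for tonal calls, nine classes 3 pulses wide
  for 1–27 pulses, and a final class for > 27 pulses);
* **diel** — 24 hourly classes, each holding the mean call rate at that hour;
* **seasonal** — one class per study month at the site.

For a proportion vector ``p`` over ``r`` classes, niche breadth is the
inverse Simpson concentration ``NB = 1 / sum(p_i^2)`` and its standardized
form ``NB* = (NB - 1) / (r - 1)`` ranges from 0 (specialist, a single class)
to 1 (generalist, uniform use of all classes).  Pairwise niche overlap
defaults to Schoener's proportional similarity ``1 - 0.5 * sum(|p - q|)``
with Pianka's index available as an alternative.  The null expectation for
overlap in the absence of partitioning is the mean of 10 uniform(0, 1)
draws, replicated per species pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import MinuteRecord, SurveyDesign, as_frame, parse_calls

__all__ = [
    "ResourceClassScheme",
    "NicheProfile",
    "BreadthResult",
    "OverlapMatrix",
    "NullOverlap",
    "TFResult",
    "bin_frequency",
    "bin_notes",
    "bin_pulses",
    "call_structure_scheme",
    "diel_scheme",
    "seasonal_scheme",
    "call_structure_profile",
    "diel_profile",
    "seasonal_profile",
    "niche_breadth",
    "total_niche_profile",
    "niche_overlap",
    "community_overlap_matrix",
    "random_overlap_null",
    "empiric_vs_random_test",
    "equal_partition_breadth",
    "UndefinedNicheError",
]

N_FREQ_CLASSES = 9
N_NOTE_CLASSES = 5
N_PULSE_CLASSES = 11
N_CALL_STRUCTURE_CLASSES = N_FREQ_CLASSES + N_NOTE_CLASSES + N_PULSE_CLASSES  # 25

FREQ_LO, FREQ_HI, FREQ_WIDTH = 500.0, 5000.0, 500.0


class UndefinedNicheError(ValueError):
    """A niche quantity was requested for a species with zero activity."""


class BinClampWarning(UserWarning):
    """A call feature fell outside its binning range and was clamped."""


@dataclass(frozen=True)
class ResourceClassScheme:
    """An ordered set of resource classes for one niche dimension."""

    dimension: str  # call_structure | diel | seasonal | total
    class_labels: tuple[str, ...]

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)


def call_structure_scheme() -> ResourceClassScheme:
    labels = (
        tuple(f"freq_{int(FREQ_LO + i * FREQ_WIDTH)}-{int(FREQ_LO + (i + 1) * FREQ_WIDTH)}Hz"
              for i in range(N_FREQ_CLASSES))
        + tuple(f"notes_{i + 1}" for i in range(N_NOTE_CLASSES))
        + ("pulses_tonal",)
        + tuple(f"pulses_{3 * i + 1}-{3 * i + 3}" for i in range(9))
        + ("pulses_gt27",)
    )
    return ResourceClassScheme("call_structure", labels)


def diel_scheme() -> ResourceClassScheme:
    return ResourceClassScheme("diel", tuple(f"h{h:02d}" for h in range(24)))


def seasonal_scheme(months: Sequence[str]) -> ResourceClassScheme:
    if not months:
        raise ValueError("seasonal scheme needs at least one month")
    return ResourceClassScheme("seasonal", tuple(months))


@dataclass(frozen=True)
class NicheProfile:
    """Resource-use proportions of one species along one niche dimension.

    ``p`` is ``None`` for an undefined profile (zero recorded activity);
    downstream breadth/overlap computations refuse undefined profiles rather
    than silently treating them as zeros.
    """

    species: str
    site: str
    scheme: ResourceClassScheme
    p: np.ndarray | None

    def __post_init__(self) -> None:
        if self.p is not None:
            arr = np.asarray(self.p, dtype=float)
            if arr.shape != (self.scheme.n_classes,):
                raise ValueError(
                    f"profile length {arr.shape} does not match "
                    f"{self.scheme.n_classes} classes"
                )
            if (arr < -1e-12).any():
                raise ValueError("negative proportion in niche profile")
            if abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(f"proportions sum to {arr.sum()}, not 1")
            object.__setattr__(self, "p", arr)

    @property
    def defined(self) -> bool:
        return self.p is not None

    @property
    def dimension(self) -> str:
        return self.scheme.dimension


@dataclass(frozen=True)
class BreadthResult:
    """Raw (NB) and standardized (NB*) inverse-Simpson niche breadth."""

    species: str
    site: str
    dimension: str
    nb: float
    nb_star: float
    r: int


# ---------------------------------------------------------------------------
# binning


def bin_frequency(f: float) -> int:
    """Dominant-frequency class 0–8 (500 Hz classes over 500–5000 Hz).

    Out-of-range frequencies are clamped to the nearest edge class with a
    warning: silent truncation would bias profiles invisibly.
    """
    if f <= 0:
        raise ValueError(f"dominant frequency must be positive, got {f}")
    if f < FREQ_LO:
        warnings.warn(f"frequency {f} Hz below {FREQ_LO} Hz, clamped to class 0",
                      BinClampWarning, stacklevel=2)
        return 0
    if f >= FREQ_HI:
        warnings.warn(f"frequency {f} Hz at/above {FREQ_HI} Hz, clamped to class 8",
                      BinClampWarning, stacklevel=2)
        return N_FREQ_CLASSES - 1
    return int((f - FREQ_LO) // FREQ_WIDTH)


def bin_notes(n: int) -> int:
    """Note-count class 0–4 (1 note per class, range 1–5, clamp above)."""
    if n < 1:
        raise ValueError(f"note count must be >= 1, got {n}")
    if n > 5:
        warnings.warn(f"note count {n} above 5, clamped to class 4",
                      BinClampWarning, stacklevel=2)
        return N_NOTE_CLASSES - 1
    return n - 1


def bin_pulses(n: int) -> int:
    """Pulse-count class 0–10.

    Class 0 holds tonal (unpulsed) calls; 1–27 pulses fall into nine classes
    of width 3; anything above 27 pulses falls into the last class.
    """
    if n < 0:
        raise ValueError(f"pulse count must be >= 0, got {n}")
    if n == 0:
        return 0
    if n > 27:
        return N_PULSE_CLASSES - 1
    return 1 + (n - 1) // 3


# ---------------------------------------------------------------------------
# profiles


def call_structure_profile(
    records: Sequence[MinuteRecord] | pd.DataFrame, species: str, site: str
) -> NicheProfile:
    """25-class call-structure profile for one species at one site.

    Every measured call contributes one count to its frequency class, one to
    its note class and one to its pulse class; the three sub-blocks are each
    normalized to total 1/3 so that no block dominates by having more
    classes.
    """
    df = as_frame(records)
    sel = df[(df["site"] == site) & (df["species"] == species)]
    freq_counts = np.zeros(N_FREQ_CLASSES)
    note_counts = np.zeros(N_NOTE_CLASSES)
    pulse_counts = np.zeros(N_PULSE_CLASSES)
    for cell in sel["calls"]:
        for call in parse_calls(str(cell) if not pd.isna(cell) else ""):
            freq_counts[bin_frequency(call.dominant_freq)] += 1
            note_counts[bin_notes(call.n_notes)] += 1
            pulse_counts[bin_pulses(call.n_pulses)] += 1
    scheme = call_structure_scheme()
    if freq_counts.sum() == 0:
        return NicheProfile(species, site, scheme, None)
    p = np.concatenate([
        freq_counts / freq_counts.sum() / 3.0,
        note_counts / note_counts.sum() / 3.0,
        pulse_counts / pulse_counts.sum() / 3.0,
    ])
    return NicheProfile(species, site, scheme, p)


def _rate_profile(
    df: pd.DataFrame, species: str, site: str, class_col: str,
    class_values: Sequence,
) -> np.ndarray | None:
    """Mean call rate per class (silent minutes included), normalized."""
    at_site = df[df["site"] == site]
    if at_site.empty:
        return None
    # denominator: number of distinct recorded minutes per class
    minutes = at_site.drop_duplicates(subset=["date", "hour", "minute_index"])
    n_minutes = minutes.groupby(class_col, observed=True).size()
    # numerator: summed call rate of the focal species per class
    sp = at_site[at_site["species"] == species]
    totals = sp.groupby(class_col, observed=True)["call_rate"].sum()
    means = np.zeros(len(class_values), dtype=float)
    for i, c in enumerate(class_values):
        denom = float(n_minutes.get(c, 0))
        if denom > 0:
            means[i] = float(totals.get(c, 0.0)) / denom
    total = means.sum()
    if total == 0:
        return None
    return means / total


def diel_profile(
    records: Sequence[MinuteRecord] | pd.DataFrame, species: str, site: str
) -> NicheProfile:
    """24-class diel profile: normalized mean call rate per hour of day."""
    df = as_frame(records)
    p = _rate_profile(df, species, site, "hour", list(range(24)))
    return NicheProfile(species, site, diel_scheme(), p)


def seasonal_profile(
    records: Sequence[MinuteRecord] | pd.DataFrame,
    species: str,
    site: str,
    design: SurveyDesign | None = None,
    months: Sequence[str] | None = None,
) -> NicheProfile:
    """Per-month profile; the class list comes from the site's study months.

    Without a design, months are inferred from the data at the site (sorted),
    so a site lacking data in one month simply has fewer seasonal classes.
    An explicit ``months`` list overrides both — cross-site comparisons need
    a shared class scheme (the union of the sites' months, with unsampled
    months contributing zero use).
    """
    df = as_frame(records)
    if months is None:
        if design is not None:
            months = design.months[site]
        else:
            months = sorted(df.loc[df["site"] == site, "month"].unique())
    p = _rate_profile(df, species, site, "month", list(months))
    return NicheProfile(species, site, seasonal_scheme(months), p)


# ---------------------------------------------------------------------------
# breadth and overlap


def niche_breadth(profile: NicheProfile) -> BreadthResult:
    """Inverse-Simpson breadth NB = 1/Σp² and NB* = (NB−1)/(r−1)."""
    if not profile.defined:
        raise UndefinedNicheError(
            f"niche breadth undefined for {profile.species} at {profile.site} "
            f"({profile.dimension}): no recorded activity"
        )
    r = profile.scheme.n_classes
    nb = 1.0 / float(np.sum(profile.p**2))
    nb_star = (nb - 1.0) / (r - 1.0) if r > 1 else 0.0
    return BreadthResult(profile.species, profile.site, profile.dimension,
                         nb, nb_star, r)


def total_niche_profile(
    call_structure: NicheProfile,
    diel: NicheProfile,
    seasonal: NicheProfile,
    weights: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
) -> NicheProfile:
    """Additive total acoustic niche: weighted concatenation of the three
    dimension profiles into one vector over ``r_call + r_diel + r_seasonal``
    classes.  With degenerate weights it reduces to a single dimension
    (re-standardized by the total class count)."""
    parts = (call_structure, diel, seasonal)
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be 3 non-negative values summing to 1")
    for prof in parts:
        if not prof.defined:
            raise UndefinedNicheError(
                f"total niche undefined: {prof.dimension} profile of "
                f"{prof.species} at {prof.site} has no activity"
            )
    species = call_structure.species
    site = call_structure.site
    labels = tuple(
        f"{prof.dimension}:{lab}"
        for prof in parts
        for lab in prof.scheme.class_labels
    )
    p = np.concatenate([wi * prof.p for wi, prof in zip(w, parts)])
    return NicheProfile(species, site, ResourceClassScheme("total", labels), p)


def niche_overlap(p: NicheProfile, q: NicheProfile, method: str = "schoener") -> float:
    """Pairwise niche overlap in [0, 1].

    ``schoener``: proportional similarity ``1 - 0.5 Σ|p - q|`` (default);
    ``pianka``: ``Σ p q / sqrt(Σp² Σq²)``.
    """
    if p.scheme.class_labels != q.scheme.class_labels:
        raise ValueError("profiles use different resource-class schemes")
    if not (p.defined and q.defined):
        raise UndefinedNicheError("overlap of an undefined niche profile")
    if method == "schoener":
        return float(1.0 - 0.5 * np.abs(p.p - q.p).sum())
    if method == "pianka":
        denom = np.sqrt(np.sum(p.p**2) * np.sum(q.p**2))
        return float(np.sum(p.p * q.p) / denom)
    raise ValueError(f"unknown overlap method {method!r}")


@dataclass(frozen=True)
class OverlapMatrix:
    """Symmetric pairwise niche-overlap matrix for one community."""

    species: tuple[str, ...]
    values: np.ndarray
    method: str = "schoener"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.species)
        if v.shape != (n, n):
            raise ValueError("overlap matrix shape does not match species list")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("overlap matrix not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("overlap matrix diagonal must be 1")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("overlap values outside [0, 1]")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "species", tuple(self.species))

    @classmethod
    def from_pairs(
        cls, species: Sequence[str], pairs: Mapping[tuple[str, str], float],
        method: str = "schoener",
    ) -> "OverlapMatrix":
        n = len(species)
        v = np.eye(n)
        idx = {s: i for i, s in enumerate(species)}
        for (a, b), val in pairs.items():
            v[idx[a], idx[b]] = v[idx[b], idx[a]] = val
        return cls(tuple(species), v, method)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.species), k=1)
        return self.values[iu]

    def mean(self) -> float:
        return float(self.upper_triangle().mean())

    def sd(self) -> float:
        """Sample standard deviation (n−1) of the pairwise values."""
        return float(self.upper_triangle().std(ddof=1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species, columns=self.species)


def community_overlap_matrix(
    profiles: Mapping[str, NicheProfile] | Sequence[NicheProfile],
    method: str = "schoener",
) -> OverlapMatrix:
    """All pairwise overlaps among the (total-niche) profiles of a community."""
    if not isinstance(profiles, Mapping):
        profiles = {p.species: p for p in profiles}
    species = tuple(profiles)
    if len(species) < 2:
        raise ValueError("need at least two species for an overlap matrix")
    n = len(species)
    v = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            v[i, j] = v[j, i] = niche_overlap(
                profiles[species[i]], profiles[species[j]], method
            )
    return OverlapMatrix(species, v, method)


# ---------------------------------------------------------------------------
# randomization null


@dataclass(frozen=True)
class NullOverlap:
    """Null overlap values (each the mean of ``n_draws`` uniforms) and their
    summary statistics."""

    values: np.ndarray
    n_draws: int

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1))


def random_overlap_null(
    n_pairs: int, reps: int = 1, n_draws: int = 10, seed: int | None = None
) -> NullOverlap:
    """Randomization null for overlap in the absence of partitioning.

    Each null value is the mean of ``n_draws`` independent uniform(0, 1)
    draws (analytic expectation 1/2, standard deviation
    ``sqrt(1 / (12 n_draws))``); ``reps × n_pairs`` values are generated
    deterministically from ``seed``.
    """
    if n_pairs < 1 or reps < 1 or n_draws < 1:
        raise ValueError("n_pairs, reps and n_draws must all be >= 1")
    rng = np.random.default_rng(seed)
    values = rng.random((reps * n_pairs, n_draws)).mean(axis=1)
    return NullOverlap(values, n_draws)


@dataclass(frozen=True)
class TFResult:
    """Two-sample comparison of empiric vs null overlap distributions."""

    t: float  # pooled-variance two-sample t of (empiric - null) mean
    df: int
    f: float  # variance ratio, larger / smaller
    f_numerator: str  # which sample supplied the larger variance


def empiric_vs_random_test(
    empiric: Sequence[float], null: Sequence[float], welch: bool = False
) -> TFResult:
    """Location (t) and scatter (F) comparison of overlap distributions.

    The t statistic is the classical pooled-variance two-sample form (Welch
    by flag) for the difference empiric − null, so stronger-than-random
    partitioning yields a negative t.  F is the ratio of the larger to the
    smaller sample variance, with its orientation reported.
    """
    x = np.asarray(empiric, dtype=float)
    y = np.asarray(null, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need at least two values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both samples are degenerate (zero variance)")
    nx, ny = len(x), len(y)
    diff = x.mean() - y.mean()
    if welch:
        se = np.sqrt(vx / nx + vy / ny)
        df = int(np.floor((vx / nx + vy / ny) ** 2 /
                          ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))))
    else:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se = np.sqrt(sp2 * (1 / nx + 1 / ny))
        df = nx + ny - 2
    t = float(diff / se)
    if vx >= vy:
        f, numerator = (np.inf if vy == 0 else vx / vy), "empiric"
    else:
        f, numerator = vy / vx, "null"
    return TFResult(t=t, df=df, f=float(f), f_numerator=numerator)


def equal_partition_breadth(n_species: int) -> float:
    """Standardized breadth each species holds when the standardized niche
    space is split exclusively and equally among ``n_species`` species."""
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    return 1.0 / n_species
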