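"""Cross-site niche comparison, clustering and rarefaction.

To compare acoustic niches across sites, overlap is turned into a
dissimilarity (``d = 1 − overlap``; not necessarily metric) and clustered
agglomeratively with complete linkage (inter-cluster distance = maximum
pairwise distance), which guarantees monotone non-decreasing merge heights.
Ties are broken lexicographically on sorted leaf labels so dendrograms are
deterministic.

Sample-based rarefaction estimates how acoustic species richness accumulates
with sampling effort: species are coded as incidence (presence/absence) per
sample unit (a recording day or an annotated minute), the sample order is
randomized repeatedly, and the mean richness among the first *k* samples is
reported with a 95% band from the randomization spread.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import MinuteRecord, SurveyDesign, as_frame
from .niche_partitioning import NicheProfile, OverlapMatrix, niche_overlap

__all__ = [
    "Dendrogram",
    "IncidenceMatrix",
    "RarefactionCurve",
    "overlap_to_distance",
    "complete_linkage",
    "conspecific_cross_site_overlap",
    "build_incidence",
    "rarefy",
]


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative clustering result.

    ``merges`` lists, in order, the two clusters joined (each a tuple of
    leaf labels) and the height of the join; complete linkage makes heights
    non-decreasing.
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[tuple[str, ...], tuple[str, ...], float], ...]

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaves) - 1:
            raise ValueError("a dendrogram over n leaves needs n-1 merges")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    def cophenetic_matrix(self) -> np.ndarray:
        """Pairwise merge heights, ordered like ``leaves``."""
        idx = {lab: i for i, lab in enumerate(self.leaves)}
        n = len(self.leaves)
        coph = np.zeros((n, n))
        for left, right, h in self.merges:
            for a in left:
                for b in right:
                    coph[idx[a], idx[b]] = coph[idx[b], idx[a]] = h
        return coph

    def siblings(self) -> tuple[frozenset[str], ...]:
        """Leaf pairs joined directly with each other (both singletons)."""
        return tuple(
            frozenset((left[0], right[0]))
            for left, right, _ in self.merges
            if len(left) == 1 and len(right) == 1
        )

    def to_newick(self) -> str:
        """Newick string; branch lengths span child height to parent height
        (leaves sit at height 0), so the tree is ultrametric with node
        depths equal to merge heights."""
        node_of: dict[tuple[str, ...], tuple[str, float]] = {
            (leaf,): (leaf, 0.0) for leaf in self.leaves
        }
        rep = ""
        for left, right, h in self.merges:
            (ls, lh), (rs, rh) = node_of[left], node_of[right]
            rep = f"({ls}:{h - lh:.6g},{rs}:{h - rh:.6g})"
            node_of[tuple(sorted(left + right))] = (rep, h)
        return rep + ";"

    def to_json(self) -> str:
        return json.dumps(
            {
                "leaves": list(self.leaves),
                "merges": [
                    {"left": list(l), "right": list(r), "height": h}
                    for l, r, h in self.merges
                ],
            },
            indent=2,
        )


def overlap_to_distance(m: OverlapMatrix) -> np.ndarray:
    """Dissimilarity ``1 − overlap`` (zero diagonal, symmetric; the triangle
    inequality is *not* guaranteed)."""
    return 1.0 - m.values


def complete_linkage(
    d: np.ndarray, labels: Sequence[str]
) -> Dendrogram:
    """Agglomerative complete-linkage clustering of a distance matrix.

    At every step the pair of clusters at minimum distance is merged, the
    distance between clusters being the maximum leaf-pair distance.  Among
    tied pairs the one whose sorted-label identifiers are lexicographically
    smallest is merged, making the result deterministic.
    """
    d = np.asarray(d, dtype=float)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    if n < 2:
        raise ValueError("need at least two leaves")

    idx = {lab: i for i, lab in enumerate(labels)}
    clusters: list[tuple[str, ...]] = [(lab,) for lab in labels]

    def cluster_distance(a: tuple[str, ...], b: tuple[str, ...]) -> float:
        return max(d[idx[x], idx[y]] for x in a for y in b)

    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = sorted((clusters[i], clusters[j]))
                dist = cluster_distance(a, b)
                key = (dist, a, b)
                if best is None or key < best:
                    best = key
        dist, a, b = best
        merges.append((a, b, float(dist)))
        clusters = [c for c in clusters if c not in (a, b)]
        clusters.append(tuple(sorted(a + b)))
    return Dendrogram(tuple(labels), tuple(merges))


def conspecific_cross_site_overlap(
    profiles_a: Mapping[str, NicheProfile],
    profiles_b: Mapping[str, NicheProfile],
    method: str = "schoener",
) -> tuple[dict[str, float], float, float]:
    """Overlap of each shared species' niche between two sites.

    Returns the per-species overlaps plus their mean and sample standard
    deviation (``nan`` when only one species is shared).
    """
    shared = [s for s in profiles_a if s in profiles_b]
    if not shared:
        raise ValueError("no species shared between the two sites")
    overlaps = {
        s: niche_overlap(profiles_a[s], profiles_b[s], method) for s in shared
    }
    vals = np.array(list(overlaps.values()))
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
    return overlaps, float(vals.mean()), sd


@dataclass(frozen=True)
class IncidenceMatrix:
    """Binary samples × species presence matrix for one period."""

    samples: tuple[str, ...]
    species: tuple[str, ...]
    matrix: np.ndarray  # shape (n_samples, n_species), entries {0, 1}
    period: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=int)
        if m.shape != (len(self.samples), len(self.species)):
            raise ValueError("incidence matrix shape mismatch")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("incidence entries must be 0 or 1")
        object.__setattr__(self, "matrix", m)

    @property
    def richness(self) -> int:
        """Total species observed in at least one sample."""
        return int((self.matrix.any(axis=0)).sum())


def build_incidence(
    records: Sequence[MinuteRecord] | pd.DataFrame,
    unit: str = "day",
    period: str = "night",
    design: SurveyDesign | None = None,
    site: str | None = None,
) -> IncidenceMatrix:
    """Code records as presence/absence per sample unit.

    ``unit='day'`` pools a calendar date at a site into one sample (partial
    days are kept); ``unit='minute'`` uses each annotated minute.  Only
    hours belonging to ``period`` are used.
    """
    df = as_frame(records)
    if site is not None:
        df = df[df["site"] == site]
    if design is None:
        hours = _period_hours(period)
    else:
        hours = design.period_hours(period)
    df = df[df["hour"].isin(hours)]
    if df.empty:
        raise ValueError(f"no records in period {period!r}")
    if unit == "day":
        keys = df["site"].str.cat(df["date"], sep="|")
    elif unit == "minute":
        keys = (
            df["site"].str.cat(df["date"], sep="|")
            + "|" + df["hour"].astype(str) + "|" + df["minute_index"].astype(str)
        )
    else:
        raise ValueError(f"unit must be 'day' or 'minute', got {unit!r}")
    df = df.assign(_unit=keys)
    samples = tuple(dict.fromkeys(keys))  # first-appearance order
    species = tuple(sorted(s for s in df["species"].unique() if s))
    m = np.zeros((len(samples), len(species)), dtype=int)
    srow = {u: i for i, u in enumerate(samples)}
    scol = {s: j for j, s in enumerate(species)}
    active = df[(df["species"] != "") & (df["call_rate"] > 0)]
    for u, s in zip(active["_unit"], active["species"]):
        m[srow[u], scol[s]] = 1
    return IncidenceMatrix(samples, species, m, period)


def _period_hours(period: str) -> frozenset[int]:
    if period == "daylight":
        return frozenset(range(6, 19))
    if period == "night":
        return frozenset(range(19, 24)) | frozenset(range(0, 6))
    raise ValueError(f"period must be 'daylight' or 'night', got {period!r}")


@dataclass(frozen=True)
class RarefactionCurve:
    """Species accumulation: mean richness per number of samples, with a
    95% band (mean ± 1.96 sd over randomized sample orders)."""

    k: np.ndarray  # 1..n samples
    mean_richness: np.ndarray
    sd_richness: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    n_randomizations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "samples": self.k,
                "mean_richness": self.mean_richness,
                "sd_richness": self.sd_richness,
                "lower95": self.lower95,
                "upper95": self.upper95,
            }
        )


def rarefy(
    m: IncidenceMatrix, n_randomizations: int = 100, seed: int | None = None
) -> RarefactionCurve:
    """Sample-based rarefaction by randomization of sample order.

    For each randomized order, richness among the first *k* samples is the
    number of species present in at least one of them; the curve reports the
    mean and spread over ``n_randomizations`` orders and is non-decreasing
    in *k*.  At ``k = n`` every randomization equals the observed total
    richness.
    """
    if len(m.samples) < 1:
        raise ValueError("empty incidence matrix")
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(m.samples)
    richness = np.empty((n_randomizations, n))
    for r in range(n_randomizations):
        order = rng.permutation(n)
        seen = np.maximum.accumulate(m.matrix[order], axis=0)
        richness[r] = seen.sum(axis=1)
    mean = richness.mean(axis=0)
    sd = richness.std(axis=0, ddof=1) if n_randomizations > 1 else np.zeros(n)
    return RarefactionCurve(
        k=np.arange(1, n + 1),
        mean_richness=mean,
        sd_richness=sd,
        lower95=mean - 1.96 * sd,
        upper95=mean + 1.96 * sd,
        n_randomizations=n_randomizations,
    )
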