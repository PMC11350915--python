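"""Reference values from the Virunga Massif high-altitude wetland survey.

Published community-level results for the six-species anuran assemblages at
the Sandi (3188 m a.s.l.) and Malalo (2648 m a.s.l.) wetlands, Volcanoes
National Park, Rwanda: the pairwise standardized total-niche overlap
matrices and the per-species standardized call-structure niche breadths.
These small printed tables serve as worked-example inputs for the summary
statistics implemented here (they are community summaries, not raw
annotation data).
"""

from __future__ import annotations

from .niche_partitioning import OverlapMatrix

__all__ = [
    "SANDI_SPECIES",
    "MALALO_SPECIES",
    "sandi_overlap_matrix",
    "malalo_overlap_matrix",
    "SANDI_CALL_STRUCTURE_NB_STAR",
    "MALALO_CALL_STRUCTURE_NB_STAR",
]

SANDI_SPECIES = (
    "Amietia desaegeri",
    "Hyperolius castaneus",
    "Hyperolius glandicolor",
    "Leptopelis karissimbensis",
    "Leptopelis kivuensis",
    "Phrynobatrachus bequaerti",
)

MALALO_SPECIES = (
    "Arthroleptis schubotzi",
    "Hyperolius castaneus",
    "Hyperolius glandicolor",
    "Leptopelis karissimbensis",
    "Leptopelis kivuensis",
    "Phrynobatrachus bequaerti",
)

# upper-triangle pairwise overlaps, row-major over the species tuples above
_SANDI_PAIRS = {
    ("Amietia desaegeri", "Hyperolius castaneus"): 0.2398,
    ("Amietia desaegeri", "Hyperolius glandicolor"): 0.1211,
    ("Amietia desaegeri", "Leptopelis karissimbensis"): 0.2822,
    ("Amietia desaegeri", "Leptopelis kivuensis"): 0.2679,
    ("Amietia desaegeri", "Phrynobatrachus bequaerti"): 0.0741,
    ("Hyperolius castaneus", "Hyperolius glandicolor"): 0.2884,
    ("Hyperolius castaneus", "Leptopelis karissimbensis"): 0.3214,
    ("Hyperolius castaneus", "Leptopelis kivuensis"): 0.4050,
    ("Hyperolius castaneus", "Phrynobatrachus bequaerti"): 0.3856,
    ("Hyperolius glandicolor", "Leptopelis karissimbensis"): 0.4301,
    ("Hyperolius glandicolor", "Leptopelis kivuensis"): 0.4596,
    ("Hyperolius glandicolor", "Phrynobatrachus bequaerti"): 0.4535,
    ("Leptopelis karissimbensis", "Leptopelis kivuensis"): 0.7389,
    ("Leptopelis karissimbensis", "Phrynobatrachus bequaerti"): 0.3895,
    ("Leptopelis kivuensis", "Phrynobatrachus bequaerti"): 0.3710,
}

_MALALO_PAIRS = {
    ("Arthroleptis schubotzi", "Hyperolius castaneus"): 0.2585,
    ("Arthroleptis schubotzi", "Hyperolius glandicolor"): 0.1799,
    ("Arthroleptis schubotzi", "Leptopelis karissimbensis"): 0.2388,
    ("Arthroleptis schubotzi", "Leptopelis kivuensis"): 0.3738,
    ("Arthroleptis schubotzi", "Phrynobatrachus bequaerti"): 0.1422,
    ("Hyperolius castaneus", "Hyperolius glandicolor"): 0.3339,
    ("Hyperolius castaneus", "Leptopelis karissimbensis"): 0.4678,
    ("Hyperolius castaneus", "Leptopelis kivuensis"): 0.5766,
    ("Hyperolius castaneus", "Phrynobatrachus bequaerti"): 0.4402,
    ("Hyperolius glandicolor", "Leptopelis karissimbensis"): 0.2190,
    ("Hyperolius glandicolor", "Leptopelis kivuensis"): 0.2565,
    ("Hyperolius glandicolor", "Phrynobatrachus bequaerti"): 0.3455,
    ("Leptopelis karissimbensis", "Leptopelis kivuensis"): 0.6898,
    ("Leptopelis karissimbensis", "Phrynobatrachus bequaerti"): 0.4275,
    ("Leptopelis kivuensis", "Phrynobatrachus bequaerti"): 0.4185,
}

# published standardized call-structure niche breadths (NB*) per species
SANDI_CALL_STRUCTURE_NB_STAR = {
    "Amietia desaegeri": 0.12,
    "Hyperolius castaneus": 0.14,
    "Hyperolius glandicolor": 0.11,
    "Leptopelis karissimbensis": 0.07,
    "Leptopelis kivuensis": 0.14,
    "Phrynobatrachus bequaerti": 0.35,
}

MALALO_CALL_STRUCTURE_NB_STAR = {
    "Arthroleptis schubotzi": 0.12,
    "Hyperolius castaneus": 0.13,
    "Hyperolius glandicolor": 0.11,
    "Leptopelis karissimbensis": 0.08,
    "Leptopelis kivuensis": 0.14,
    "Phrynobatrachus bequaerti": 0.21,
}


def sandi_overlap_matrix() -> OverlapMatrix:
    """Pairwise total-niche overlap of the six Sandi species."""
    return OverlapMatrix.from_pairs(SANDI_SPECIES, _SANDI_PAIRS)


def malalo_overlap_matrix() -> OverlapMatrix:
    """Pairwise total-niche overlap of the six Malalo species."""
    return OverlapMatrix.from_pairs(MALALO_SPECIES, _MALALO_PAIRS)
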