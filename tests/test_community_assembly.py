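"""Cross-site clustering, incidence coding and rarefaction."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from anuraniche import (
    build_incidence,
    complete_linkage,
    conspecific_cross_site_overlap,
    overlap_to_distance,
    rarefy,
)
from anuraniche.community_assembly import Dendrogram, IncidenceMatrix
from anuraniche.niche_partitioning import OverlapMatrix

from conftest import call, minute
from test_niche_partitioning import profile_of


class TestOverlapToDistance:
    def test_complement(self):
        m = OverlapMatrix.from_pairs(("a", "b"), {("a", "b"): 0.74})
        d = overlap_to_distance(m)
        assert d[0, 1] == pytest.approx(0.26)
        assert d[0, 0] == 0.0
        assert np.allclose(d, d.T)


class TestCompleteLinkage:
    def test_three_point_example(self):
        labels = ("A", "B", "C")
        d = np.array([[0, 1, 4], [1, 0, 3], [4, 3, 0]], dtype=float)
        dend = complete_linkage(d, labels)
        assert dend.merges[0] == (("A",), ("B",), 1.0)
        assert dend.merges[1] == (("A", "B"), ("C",), 4.0)

    def test_tied_distances_break_deterministically(self):
        labels = ("b", "a", "c")
        d = np.ones((3, 3)) - np.eye(3)
        dend = complete_linkage(d, labels)
        # lexicographically smallest pair first
        assert dend.merges[0][:2] == (("a",), ("b",))

    def test_heights_non_decreasing_on_random_matrices(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 9))
            d = squareform(rng.uniform(0.1, 2.0, size=n * (n - 1) // 2))
            dend = complete_linkage(d, tuple(f"L{i}" for i in range(n)))
            heights = [h for *_, h in dend.merges]
            assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))

    def test_agreement_with_scipy_on_random_instances(self, rng):
        """Cophenetic distances match an independent implementation on 50
        random 8-leaf problems (continuous distances, so no ties)."""
        for _ in range(50):
            condensed = rng.uniform(0.01, 1.0, size=8 * 7 // 2)
            d = squareform(condensed)
            labels = tuple(f"L{i}" for i in range(8))
            dend = complete_linkage(d, labels)
            ours = squareform(dend.cophenetic_matrix())
            scipy_coph = cophenet(linkage(condensed, method="complete"))
            assert np.allclose(ours, scipy_coph, atol=1e-10)

    def test_newick_export_is_parseable_and_ultrametric(self):
        d = np.array([[0, 1, 4], [1, 0, 3], [4, 3, 0]], dtype=float)
        dend = complete_linkage(d, ("A", "B", "C"))
        nwk = dend.to_newick()
        assert nwk == "((A:1,B:1):3,C:4);"

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1], [2, 0]], dtype=float)
        with pytest.raises(ValueError):
            complete_linkage(d, ("a", "b"))


class TestConspecificOverlap:
    def test_identical_sites_give_unit_overlap(self, rng):
        profs = {f"s{i}": profile_of(rng.dirichlet(np.ones(10))) for i in range(4)}
        overlaps, mean, sd = conspecific_cross_site_overlap(profs, profs)
        assert all(v == pytest.approx(1.0) for v in overlaps.values())
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_site_shifted_niche_overlaps_less_than_itself(self, rng):
        base = rng.dirichlet(np.ones(12))
        shifted = np.roll(base, 3)
        a = {"sp": profile_of(base)}
        b = {"sp": profile_of(shifted)}
        overlaps, _, _ = conspecific_cross_site_overlap(a, b)
        assert overlaps["sp"] < 1.0

    def test_no_shared_species_raises(self, rng):
        with pytest.raises(ValueError):
            conspecific_cross_site_overlap(
                {"x": profile_of(rng.dirichlet(np.ones(4)))},
                {"y": profile_of(rng.dirichlet(np.ones(4)))},
            )


class TestIncidence:
    def toy_records(self):
        # 3 nights, 2 species: sp1 calls nights 1 and 3, sp2 only night 2
        recs = []
        for day, species in [(1, ["sp1"]), (2, ["sp2"]), (3, ["sp1"])]:
            date = f"2019-09-{day:02d}"
            for sp in species:
                recs.append(minute(date=date, hour=21, species=sp,
                                   call_rate=2, calls=[call()]))
            recs.append(minute(date=date, hour=22))  # silent minute
        return recs

    def test_hand_constructed_day_matrix(self):
        inc = build_incidence(self.toy_records(), unit="day", period="night")
        assert inc.species == ("sp1", "sp2")
        assert inc.matrix.tolist() == [[1, 0], [0, 1], [1, 0]]
        assert inc.richness == 2

    def test_all_silent_gives_zero_matrix(self):
        recs = [minute(date=f"2019-09-{d:02d}", hour=20) for d in (1, 2)]
        inc = build_incidence(recs, "day", "night")
        assert inc.matrix.sum() == 0
        assert inc.richness == 0

    def test_minute_unit_counts_each_minute(self):
        inc = build_incidence(self.toy_records(), unit="minute", period="night")
        assert len(inc.samples) == 6  # 3 days x (1 calling + 1 silent minute)

    def test_empty_period_raises(self):
        recs = [minute(hour=12)]
        with pytest.raises(ValueError):
            build_incidence(recs, "day", "night")


class TestRarefaction:
    def test_ubiquitous_species_give_flat_curve(self):
        m = IncidenceMatrix(
            samples=("a", "b", "c"), species=("x", "y"),
            matrix=np.ones((3, 2), dtype=int), period="night",
        )
        curve = rarefy(m, n_randomizations=20, seed=1)
        assert np.allclose(curve.mean_richness, 2.0)
        assert np.allclose(curve.sd_richness, 0.0)

    def test_full_sample_richness_exact_every_randomization(self, rng):
        mat = (rng.random((12, 5)) < 0.3).astype(int)
        m = IncidenceMatrix(tuple(f"s{i}" for i in range(12)),
                            tuple("abcde"), mat, "night")
        curve = rarefy(m, n_randomizations=50, seed=4)
        assert curve.mean_richness[-1] == m.richness
        assert curve.sd_richness[-1] == 0.0

    def test_monotone_non_decreasing(self, rng):
        mat = (rng.random((15, 6)) < 0.2).astype(int)
        m = IncidenceMatrix(tuple(f"s{i}" for i in range(15)),
                            tuple("abcdef"), mat, "daylight")
        curve = rarefy(m, n_randomizations=30, seed=9)
        assert (np.diff(curve.mean_richness) >= -1e-12).all()
        assert (curve.lower95 <= curve.mean_richness).all()
        assert (curve.upper95 >= curve.mean_richness).all()

    def test_hypergeometric_closed_form(self):
        # S species each occupying exactly one distinct sample of n:
        # E[richness at k] = S * k / n
        n, S = 10, 4
        mat = np.zeros((n, S), dtype=int)
        for j in range(S):
            mat[j, j] = 1
        m = IncidenceMatrix(tuple(f"s{i}" for i in range(n)),
                            tuple(f"sp{j}" for j in range(S)), mat, "night")
        R = 400
        curve = rarefy(m, n_randomizations=R, seed=12)
        for k in range(1, n + 1):
            expected = S * k / n
            var = k * (S / n) * (1 - S / n) * (n - k) / (n - 1)
            se = np.sqrt(var / R) if var > 0 else 0.0
            # 3.6 SE: Bonferroni-style allowance across the 10 joint checks
            assert abs(curve.mean_richness[k - 1] - expected) <= 3.6 * se + 1e-9

    def test_deterministic_per_seed(self, rng):
        mat = (rng.random((8, 3)) < 0.4).astype(int)
        m = IncidenceMatrix(tuple(f"s{i}" for i in range(8)),
                            tuple("abc"), mat, "night")
        a = rarefy(m, 25, seed=7)
        b = rarefy(m, 25, seed=7)
        assert np.array_equal(a.mean_richness, b.mean_richness)


class TestDendrogramValidation:
    def test_merge_count_enforced(self):
        with pytest.raises(ValueError):
            Dendrogram(("a", "b", "c"), ((("a",), ("b",), 1.0),))
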