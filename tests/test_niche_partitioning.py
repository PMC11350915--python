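"""Resource-class binning, niche breadth, overlap and the randomization null."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from anuraniche import (
    NicheProfile,
    OverlapMatrix,
    bin_frequency,
    bin_notes,
    bin_pulses,
    call_structure_profile,
    community_overlap_matrix,
    diel_profile,
    empiric_vs_random_test,
    equal_partition_breadth,
    niche_breadth,
    niche_overlap,
    random_overlap_null,
    seasonal_profile,
    total_niche_profile,
)
from anuraniche.niche_partitioning import (
    BinClampWarning,
    ResourceClassScheme,
    UndefinedNicheError,
    call_structure_scheme,
    diel_scheme,
)

from conftest import call, minute


def profile_of(p, dimension="diel"):
    """Wrap a raw proportion vector in a NicheProfile for breadth/overlap."""
    p = np.asarray(p, dtype=float)
    scheme = ResourceClassScheme(dimension, tuple(f"c{i}" for i in range(p.size)))
    return NicheProfile("sp", "site", scheme, p)


class TestBinning:
    @pytest.mark.parametrize("f,expected", [(500, 0), (999, 0), (1000, 1),
                                            (3400, 5), (4999, 8)])
    def test_frequency_classes(self, f, expected):
        assert bin_frequency(f) == expected

    @pytest.mark.parametrize("f,expected", [(300, 0), (5000, 8), (5800, 8)])
    def test_frequency_clamped_with_warning(self, f, expected):
        with pytest.warns(BinClampWarning):
            assert bin_frequency(f) == expected

    def test_nonpositive_frequency_is_an_error(self):
        with pytest.raises(ValueError):
            bin_frequency(0)

    @pytest.mark.parametrize("n,expected", [(1, 0), (5, 4)])
    def test_note_classes(self, n, expected):
        assert bin_notes(n) == expected

    def test_notes_clamped_above_five(self):
        with pytest.warns(BinClampWarning):
            assert bin_notes(7) == 4

    @pytest.mark.parametrize(
        "n,expected",
        [(0, 0), (1, 1), (3, 1), (4, 2), (27, 9), (28, 10), (156, 10)],
    )
    def test_pulse_classes(self, n, expected):
        assert bin_pulses(n) == expected

    def test_call_structure_scheme_has_25_classes(self):
        assert call_structure_scheme().n_classes == 25


class TestCallStructureProfile:
    def test_identical_calls_are_a_three_block_point_mass(self):
        records = [minute(minute_index=i, species="sp", call_rate=1,
                          calls=[call(3400, 1, 8)]) for i in (1, 2, 3)]
        prof = call_structure_profile(records, "sp", "Sandi")
        nz = prof.p[prof.p > 0]
        assert len(nz) == 3 and np.allclose(nz, 1 / 3)
        b = niche_breadth(prof)
        assert b.nb == pytest.approx(3.0)

    def test_uniform_use_of_every_class(self):
        # one call in each frequency, note and pulse class; the blocks have
        # different class counts so the profile is not globally uniform
        records = []
        k = 0
        freqs = [750 + 500 * i for i in range(9)]
        notes = list(range(1, 6))
        pulses = [0] + [3 * i + 2 for i in range(9)] + [30]
        n = max(len(freqs), len(notes), len(pulses))
        for i in range(np.lcm.reduce([9, 5, 11])):
            records.append(minute(
                date=f"2019-09-{i // 120 + 1:02d}", hour=(i // 5) % 24,
                minute_index=i % 5 + 1, species="sp", call_rate=1,
                calls=[call(freqs[i % 9], notes[i % 5], pulses[i % 11])],
            ))
        prof = call_structure_profile(records, "sp", "Sandi")
        expected_nb = 1 / (9 * (1 / 27) ** 2 + 5 * (1 / 15) ** 2 + 11 * (1 / 33) ** 2)
        assert niche_breadth(prof).nb == pytest.approx(expected_nb)
        assert expected_nb == pytest.approx(22.3869, abs=1e-4)

    def test_two_equiprobable_frequency_classes(self):
        records = [
            minute(minute_index=1, species="sp", call_rate=1, calls=[call(900, 1, 8)]),
            minute(minute_index=2, species="sp", call_rate=1, calls=[call(1600, 1, 8)]),
        ]
        prof = call_structure_profile(records, "sp", "Sandi")
        nb = niche_breadth(prof).nb
        assert nb == pytest.approx(1 / (2 * (1 / 6) ** 2 + (1 / 3) ** 2 + (1 / 3) ** 2))
        assert nb == pytest.approx(3.6)

    def test_no_features_gives_undefined_profile(self):
        prof = call_structure_profile([minute()], "sp", "Sandi")
        assert not prof.defined
        with pytest.raises(UndefinedNicheError):
            niche_breadth(prof)


class TestActivityProfiles:
    def test_single_hour_specialist(self):
        records = [minute(hour=20, species="sp", call_rate=5, calls=[call()])]
        b = niche_breadth(diel_profile(records, "sp", "Sandi"))
        assert (b.nb, b.nb_star) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_uniform_hours_generalist(self):
        records = [minute(hour=h, species="sp", call_rate=3, calls=[call()] * 3)
                   for h in range(24)]
        b = niche_breadth(diel_profile(records, "sp", "Sandi"))
        assert b.nb == pytest.approx(24.0)
        assert b.nb_star == pytest.approx(1.0)

    def test_hand_computed_diel_breadth(self):
        rates = {0: 2, 1: 1, 2: 1}
        records = [minute(hour=h, species="sp", call_rate=r, calls=[call()])
                   for h, r in rates.items()]
        prof = diel_profile(records, "sp", "Sandi")
        assert np.allclose(prof.p[:3], [0.5, 0.25, 0.25])
        b = niche_breadth(prof)
        assert b.nb == pytest.approx(1 / 0.375)
        assert b.nb_star == pytest.approx((1 / 0.375 - 1) / 23)

    def test_silent_minutes_dilute_hourly_means(self):
        # hour 0: rate 4 in one of two minutes (mean 2); hour 1: rate 1 in one
        records = [
            minute(hour=0, minute_index=1, species="sp", call_rate=4, calls=[call()]),
            minute(hour=0, minute_index=2),  # silent minute, same hour
            minute(hour=1, minute_index=1, species="sp", call_rate=1, calls=[call()]),
        ]
        prof = diel_profile(records, "sp", "Sandi")
        assert prof.p[0] == pytest.approx(2 / 3)
        assert prof.p[1] == pytest.approx(1 / 3)

    def test_seasonal_class_count_follows_site_months(self, design):
        records = [minute(site="Malalo", date=f"{m}-01", species="sp",
                          call_rate=1, calls=[call()])
                   for m in design.months["Malalo"]]
        prof = seasonal_profile(records, "sp", "Malalo", design)
        assert prof.scheme.n_classes == 6
        assert niche_breadth(prof).nb_star == pytest.approx(1.0)

    def test_single_month_specialist(self, design):
        records = [minute(species="sp", call_rate=2, calls=[call()])]
        assert niche_breadth(
            seasonal_profile(records, "sp", "Sandi", design)
        ).nb_star == pytest.approx(0.0)


class TestBreadth:
    def test_two_class_split_over_25(self):
        p = np.zeros(25)
        p[0] = p[1] = 0.5
        b = niche_breadth(profile_of(p, "call_structure"))
        assert b.nb == pytest.approx(2.0)
        assert b.nb_star == pytest.approx(1 / 24)

    @given(st.integers(2, 40), st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_breadth_bounds(self, r, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.full(r, 0.5))
        b = niche_breadth(profile_of(p))
        assert 1.0 - 1e-9 <= b.nb <= r + 1e-9
        assert -1e-9 <= b.nb_star <= 1.0 + 1e-9

    @given(st.integers(3, 30), st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_merging_classes_never_increases_breadth(self, r, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(r))
        nb = niche_breadth(profile_of(p)).nb
        i, j = rng.choice(r, size=2, replace=False)
        merged = np.delete(p, j)
        merged[i if i < j else i - 1] += p[j]
        assert niche_breadth(profile_of(merged)).nb <= nb + 1e-9


class TestTotalNiche:
    def make(self, p, dim):
        return profile_of(p, dim)

    def test_point_masses_concatenate(self):
        cs = self.make([1.0] + [0.0] * 24, "call_structure")
        diel = self.make([1.0] + [0.0] * 23, "diel")
        seas = self.make([1.0, 0, 0, 0, 0, 0, 0], "seasonal")
        total = total_niche_profile(cs, diel, seas)
        assert total.scheme.n_classes == 25 + 24 + 7
        b = niche_breadth(total)
        assert b.nb == pytest.approx(3.0)
        assert b.nb_star == pytest.approx(2 / (56 - 1))

    def test_all_uniform_closed_form(self):
        r1, r2, r3 = 25, 24, 7
        total = total_niche_profile(
            self.make(np.full(r1, 1 / r1), "call_structure"),
            self.make(np.full(r2, 1 / r2), "diel"),
            self.make(np.full(r3, 1 / r3), "seasonal"),
        )
        assert niche_breadth(total).nb == pytest.approx(9 / (1 / r1 + 1 / r2 + 1 / r3))

    def test_degenerate_weights_reduce_to_one_dimension(self, rng):
        p = rng.dirichlet(np.ones(25))
        cs = self.make(p, "call_structure")
        total = total_niche_profile(
            cs, self.make(np.full(24, 1 / 24), "diel"),
            self.make(np.full(7, 1 / 7), "seasonal"), weights=(1.0, 0.0, 0.0),
        )
        assert niche_breadth(total).nb == pytest.approx(niche_breadth(cs).nb)


class TestOverlap:
    def test_self_overlap_is_one(self, rng):
        p = profile_of(rng.dirichlet(np.ones(10)))
        for method in ("schoener", "pianka"):
            assert niche_overlap(p, p, method) == pytest.approx(1.0)

    def test_disjoint_supports_overlap_zero(self):
        p = profile_of([0.5, 0.5, 0, 0])
        q = profile_of([0, 0, 0.3, 0.7])
        for method in ("schoener", "pianka"):
            assert niche_overlap(p, q, method) == pytest.approx(0.0)

    def test_hand_computed_values(self):
        p = profile_of([1.0, 0.0])
        q = profile_of([0.5, 0.5])
        assert niche_overlap(p, q, "schoener") == pytest.approx(0.5)
        assert niche_overlap(p, q, "pianka") == pytest.approx(0.5 / np.sqrt(0.5))

    @given(st.integers(2, 20), st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_symmetry_and_bounds(self, r, seed):
        rng = np.random.default_rng(seed)
        p = profile_of(rng.dirichlet(np.ones(r)))
        q = profile_of(rng.dirichlet(np.ones(r)))
        for method in ("schoener", "pianka"):
            o = niche_overlap(p, q, method)
            assert o == pytest.approx(niche_overlap(q, p, method))
            assert -1e-9 <= o <= 1 + 1e-9

    def test_schoener_one_iff_identical(self, rng):
        p = rng.dirichlet(np.ones(6))
        q = p.copy()
        q[0] += 0.01
        q[1] -= 0.01
        assert niche_overlap(profile_of(p), profile_of(q)) < 1.0

    def test_scheme_mismatch_rejected(self):
        with pytest.raises(ValueError):
            niche_overlap(profile_of([1.0, 0.0]), profile_of([1.0, 0, 0]))

    def test_identical_species_community_matrix(self, rng):
        p = rng.dirichlet(np.ones(8))
        m = community_overlap_matrix({"a": profile_of(p), "b": profile_of(p)})
        assert np.allclose(m.values, 1.0)
        assert m.mean() == pytest.approx(1.0)


class TestRandomNull:
    def test_analytic_mean_and_sd(self):
        null = random_overlap_null(n_pairs=15, reps=667, n_draws=10, seed=11)
        assert null.values.size == 10_005
        assert null.mean == pytest.approx(0.5, abs=0.005)
        assert null.sd == pytest.approx(np.sqrt(1 / 120), rel=0.10)

    def test_deterministic_per_seed(self):
        a = random_overlap_null(5, reps=3, seed=42)
        b = random_overlap_null(5, reps=3, seed=42)
        assert np.array_equal(a.values, b.values)


class TestEmpiricVsRandom:
    def test_identical_samples_t_zero_f_one(self):
        res = empiric_vs_random_test([0.2, 0.3, 0.4], [0.2, 0.3, 0.4])
        assert res.t == pytest.approx(0.0)
        assert res.f == pytest.approx(1.0)

    def test_lower_empiric_gives_negative_t(self):
        res = empiric_vs_random_test([0.2, 0.201, 0.199],
                                     [0.5, 0.501, 0.499])
        assert res.t < -10

    def test_hand_sized_samples_match_textbook_formulas(self):
        x, y = [0.1, 0.2, 0.3], [0.4, 0.6, 0.8]
        res = empiric_vs_random_test(x, y)
        # pooled t against scipy as an independent oracle
        t_scipy = stats.ttest_ind(x, y, equal_var=True).statistic
        assert res.t == pytest.approx(t_scipy)
        assert res.df == 4
        assert res.f == pytest.approx(np.var(y, ddof=1) / np.var(x, ddof=1))
        assert res.f_numerator == "null"


class TestEqualPartition:
    @pytest.mark.parametrize("n,expected", [(6, 1 / 6), (1, 1.0), (4, 0.25)])
    def test_values(self, n, expected):
        assert equal_partition_breadth(n) == pytest.approx(expected)

    def test_six_species_rounds_to_017(self):
        assert round(equal_partition_breadth(6), 2) == 0.17


class TestOverlapMatrixValidation:
    def test_asymmetric_rejected(self):
        v = np.eye(2)
        v[0, 1] = 0.3
        with pytest.raises(ValueError):
            OverlapMatrix(("a", "b"), v)

    def test_sd_uses_n_minus_one(self):
        m = OverlapMatrix.from_pairs(
            ("a", "b", "c"),
            {("a", "b"): 0.2, ("a", "c"): 0.4, ("b", "c"): 0.6},
        )
        assert m.sd() == pytest.approx(np.std([0.2, 0.4, 0.6], ddof=1))
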