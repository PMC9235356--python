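"""Multiread rescue: prior fitting, posterior allocation and the two
accumulation modes, checked against independent direct evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duphic.matrix import ContactMatrix
from duphic.region import ReadPair, build_layout, simulate_contacts
from duphic.rescue import (accumulate_fractional, accumulate_stringent,
                           allocate_multireads, apply_stringent_filter,
                           bin_uni_reads, fit_distance_prior)

from conftest import naive_one_sweep_posteriors


def _uni(rid, i, j):
    return ReadPair(rid, (i, j), ((i, j),))


def _multi(rid, true, cands):
    return ReadPair(rid, true, tuple(cands))


class TestBinUniReads:
    def test_counts_unique_reads_only(self):
        reads = [_uni("a", 4, 10), _uni("b", 4, 10), _uni("c", 4, 10),
                 _multi("d", (1, 5), [(1, 5), (3, 7)])]
        m = bin_uni_reads(reads, 5000, 20)
        assert m.get(4, 10) == 3.0
        assert m.mass == 3.0

    def test_all_multireads_gives_empty_matrix(self):
        reads = [_multi("d", (1, 5), [(1, 5), (3, 7)])]
        assert bin_uni_reads(reads, 5000, 20).mass == 0.0

    def test_mass_equals_unique_read_count_on_simulation(self, small_sim):
        reads, _ = small_sim
        m = bin_uni_reads(reads, 5000, 200)
        assert m.mass == sum(not r.is_multi for r in reads)


class TestDistancePrior:
    def test_exact_power_law_recovers_slope(self):
        # mean count per pair at distance d set exactly to 10 / d
        n = 120
        m = ContactMatrix(5000, n)
        for d in range(1, n):
            for i in range(n - d):
                m.add(i, i + d, 10.0 / d)
        prior = fit_distance_prior(m, min_d=2)
        assert abs(prior.loglog_slope() - (-1.0)) < 0.02

    def test_flat_counts_give_uniform_prior(self):
        n = 60
        m = ContactMatrix(5000, n)
        for d in range(1, n):
            for i in range(n - d):
                m.add(i, i + d, 3.0)
        prior = fit_distance_prior(m, min_d=2)
        assert np.allclose(prior.probabilities,
                           1.0 / len(prior.distances), rtol=1e-6)

    def test_prior_normalised_and_positive(self, small_sim):
        reads, _ = small_sim
        prior = fit_distance_prior(bin_uni_reads(reads, 5000, 200))
        assert abs(prior.probabilities.sum() - 1.0) < 1e-9
        assert np.all(prior.probabilities > 0)

    def test_short_range_evaluates_to_floor(self, small_sim):
        reads, _ = small_sim
        prior = fit_distance_prior(bin_uni_reads(reads, 5000, 200), min_d=2)
        assert prior.evaluate(1) == prior.floor
        assert prior.evaluate(1) < prior.probabilities.min()

    def test_insufficient_distances_named_in_error(self):
        m = ContactMatrix(5000, 10)
        m.add(0, 5, 1.0)
        with pytest.raises(ValueError, match="distinct distances"):
            fit_distance_prior(m)


def _toy_prior(n=50):
    """Prior over a small grid built from a smooth synthetic decay."""
    m = ContactMatrix(5000, n)
    for d in range(1, n):
        for i in range(n - d):
            m.add(i, i + d, 20.0 / (d + 1.0))
    return fit_distance_prior(m, min_d=2)


class TestAllocate:
    def test_single_candidate_posterior_is_one(self):
        prior = _toy_prior()
        uni = ContactMatrix(5000, 50)
        uni.add(3, 30, 4.0)
        reads = [_uni("u", 3, 30)]
        table = allocate_multireads(reads, uni, prior)
        assert table.posteriors["u"] == [((3, 30), 1.0)]

    def test_symmetric_candidates_split_evenly(self):
        prior = _toy_prior()
        uni = ContactMatrix(5000, 50)
        uni.add(5, 15, 7.0)
        uni.add(25, 35, 7.0)
        reads = [_multi("m", (5, 15), [(5, 15), (25, 35)])]
        table = allocate_multireads(reads, uni, prior, pseudocount=0.0)
        ps = [p for _, p in table.posteriors["m"]]
        assert ps == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_worked_example_quarter_three_quarters(self):
        """Two equal-distance candidates with local unique counts 5 and
        15, pseudocount 0, one sweep: posteriors 0.25 / 0.75."""
        prior = _toy_prior()
        uni = ContactMatrix(5000, 50)
        uni.add(5, 15, 5.0)
        uni.add(25, 35, 15.0)
        reads = [_multi("m", (5, 15), [(5, 15), (25, 35)])]
        table = allocate_multireads(reads, uni, prior, pseudocount=0.0,
                                    max_iter=1)
        ps = [p for _, p in table.posteriors["m"]]
        assert ps == pytest.approx([0.25, 0.75], abs=1e-12)

    def test_one_sweep_matches_naive_oracle_on_random_instances(self):
        """100 random small instances: a single allocation sweep equals
        the loop-based direct evaluation of the posterior formula."""
        prior = _toy_prior()
        rng = np.random.default_rng(2024)
        for case in range(100):
            n = 50
            uni = ContactMatrix(5000, n)
            for _ in range(rng.integers(5, 40)):
                i, j = sorted(rng.integers(0, n, size=2))
                uni.add(i, j, float(rng.integers(1, 6)))
            reads = []
            for r in range(rng.integers(1, 51)):
                k = rng.integers(1, 5)
                cands = set()
                while len(cands) < k:
                    i, j = sorted(rng.integers(0, n, size=2))
                    cands.add((int(i), int(j)))
                cands = sorted(cands)
                reads.append(ReadPair(f"r{r}", cands[0], tuple(cands)))
            pc = float(rng.choice([0.0, 0.5, 1.0]))
            w = int(rng.choice([0, 1, 2]))
            table = allocate_multireads(reads, uni, prior, w=w,
                                        pseudocount=pc, max_iter=1)
            oracle = naive_one_sweep_posteriors(reads, uni.to_dense(),
                                                prior, w, pc)
            for r in reads:
                got = [p for _, p in table.posteriors[r.read_id]]
                assert got == pytest.approx(oracle[r.read_id], abs=1e-12)

    def test_posteriors_form_simplex_after_convergence(self, small_sim):
        reads, _ = small_sim
        uni = bin_uni_reads(reads, 5000, 200)
        prior = fit_distance_prior(uni)
        table = allocate_multireads(reads, uni, prior)
        assert table.converged
        for ps in table.posteriors.values():
            vals = [p for _, p in ps]
            assert abs(sum(vals) - 1.0) < 1e-9
            assert all(0.0 <= p <= 1.0 for p in vals)

    def test_increasing_local_count_never_lowers_posterior(self):
        prior = _toy_prior()
        reads = [_multi("m", (5, 15), [(5, 15), (25, 35)])]
        last = -1.0
        for boost in (0.0, 2.0, 10.0, 50.0):
            uni = ContactMatrix(5000, 50)
            uni.add(25, 35, 3.0)
            if boost:
                uni.add(5, 15, boost)
            table = allocate_multireads(reads, uni, prior, max_iter=1)
            p = table.posteriors["m"][0][1]
            assert p >= last
            last = p

    def test_invalid_parameters_rejected(self, small_sim):
        reads, _ = small_sim
        uni = bin_uni_reads(reads, 5000, 200)
        prior = fit_distance_prior(uni)
        with pytest.raises(ValueError):
            allocate_multireads(reads, uni, prior, w=-1)
        with pytest.raises(ValueError):
            allocate_multireads(reads, uni, prior, tol=0.0)


class TestAccumulation:
    def test_no_multireads_identity(self):
        prior = _toy_prior()
        uni = ContactMatrix(5000, 50)
        uni.add(2, 9, 3.0)
        reads = [_uni("u", 2, 9)]
        table = allocate_multireads(reads, uni, prior)
        out = accumulate_fractional(uni, table)
        assert out.entries == uni.entries

    def test_exact_fraction_addition(self):
        prior = _toy_prior()
        uni = ContactMatrix(5000, 50)
        uni.add(5, 15, 5.0)
        uni.add(25, 35, 15.0)
        reads = [_multi("m", (5, 15), [(5, 15), (25, 35)])]
        table = allocate_multireads(reads, uni, prior, pseudocount=0.0,
                                    max_iter=1)
        out = accumulate_fractional(uni, table)
        assert out.get(5, 15) == pytest.approx(5.25, abs=1e-12)
        assert out.get(25, 35) == pytest.approx(15.75, abs=1e-12)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_mass_conservation_any_posterior_state(self, max_iter):
        """Fractional mass equals #uni + #multi whether or not the
        allocation converged."""
        layout = build_layout()
        reads, _ = simulate_contacts(layout, n_reads=3_000, seed=17)
        uni = bin_uni_reads(reads, 5000, 200)
        prior = fit_distance_prior(uni)
        table = allocate_multireads(reads, uni, prior,
                                    max_iter=max(max_iter, 1))
        out = accumulate_fractional(uni, table)
        assert abs(out.mass - len(reads)) < 1e-9


class TestStringent:
    def _table(self, ps):
        prior = _toy_prior()
        uni = ContactMatrix(5000, 50)
        reads = [_uni("u", 1, 10)]
        table = allocate_multireads(reads, uni, prior)
        table.posteriors["m"] = ps
        return table

    def test_high_posterior_assigned_whole(self):
        table = self._table([((5, 15), 0.995), ((25, 35), 0.005)])
        res = apply_stringent_filter(table, 0.99)
        assert res.assignments == {"m": (5, 15)}
        assert (res.n_kept, res.n_dropped) == (1, 0)

    def test_sub_threshold_read_discarded(self):
        table = self._table([((5, 15), 0.90), ((25, 35), 0.10)])
        res = apply_stringent_filter(table, 0.99)
        assert res.assignments == {}
        assert res.n_dropped == 1

    def test_exact_threshold_tie_kept(self):
        table = self._table([((5, 15), 0.99), ((25, 35), 0.01)])
        assert apply_stringent_filter(table, 0.99).n_kept == 1

    def test_all_unique_input_modes_agree(self):
        prior = _toy_prior()
        uni = ContactMatrix(5000, 50)
        uni.add(4, 9, 2.0)
        reads = [_uni("a", 4, 9), _uni("b", 4, 9)]
        table = allocate_multireads(reads, uni, prior)
        frac = accumulate_fractional(uni, table)
        strict = accumulate_stringent(uni, apply_stringent_filter(table))
        assert frac.entries == strict.entries == uni.entries

    @pytest.mark.parametrize("bad", [0.5, 0.3, 1.01])
    def test_threshold_outside_half_one_rejected(self, bad):
        table = self._table([((5, 15), 0.9), ((25, 35), 0.1)])
        with pytest.raises(ValueError):
            apply_stringent_filter(table, bad)


def test_duplication_bins_rescued(default_layout):
    """Bins inside the duplication get zero unique coverage but strictly
    positive fractional coverage after rescue."""
    reads, _ = simulate_contacts(default_layout, n_reads=50_000, seed=8)
    uni = bin_uni_reads(reads, 5000, 200)
    prior = fit_distance_prior(uni)
    frac = accumulate_fractional(uni, allocate_multireads(reads, uni, prior))
    interior = list(default_layout.dup_interior_bins)
    assert np.all(uni.row_sums()[interior] == 0)
    assert np.all(frac.row_sums()[interior] > 0)
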