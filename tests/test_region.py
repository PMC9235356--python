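"""Synthetic duplicated-region generator: layout geometry, contact
sampling statistics and fixture round-trips."""

import numpy as np
import pytest

from duphic.region import (build_layout, read_fixture, simulate_contacts,
                           write_fixture)


class TestLayout:
    def test_default_duplicated_block_spans_two_tandem_copies(self):
        layout = build_layout(dup_unit_length=18_000, dup_copies=2)
        s, e = layout.dup_block
        assert e - s == 36_000
        c1, c2 = layout.copy_span(0), layout.copy_span(1)
        assert c1[1] == c2[0] and c2[1] == e  # tandem, contiguous

    def test_boundary_list_returned_sorted_and_unchanged(self):
        layout = build_layout(boundary_positions=(300_000, 520_000, 900_000),
                              dup_copies=1)
        assert layout.tad_boundaries_truth == (300_000, 520_000, 900_000)

    def test_default_boundary_at_second_copy_midpoint(self):
        layout = build_layout()
        c2 = layout.copy_span(1)
        assert layout.tad_boundaries_truth == ((c2[0] + c2[1]) // 2,)

    def test_every_copy_has_reverse_ctcf_site(self):
        layout = build_layout(dup_copies=3)
        for k in range(3):
            cs, ce = layout.copy_span(k)
            assert any(cs <= s.pos < ce and s.strand == "-"
                       for s in layout.ctcf_sites)

    @pytest.mark.parametrize("kwargs", [
        dict(region_length=1_000_001),               # not a bin multiple
        dict(boundary_positions=(2_000_000,)),       # outside region
        dict(dup_unit_length=6_000, bin_size=5_000),  # unit < 2 bins
        dict(dup_copies=2, boundary_positions=(100_000,)),  # none in block
    ])
    def test_invalid_layouts_rejected(self, kwargs):
        with pytest.raises(ValueError):
            build_layout(**kwargs)


class TestSimulate:
    def test_single_copy_full_insulation_has_no_multireads(self):
        layout = build_layout(dup_copies=1, boundary_positions=(578_000,))
        reads, truth = simulate_contacts(layout, n_reads=5_000,
                                         insulation=1.0, seed=3)
        assert not any(r.is_multi for r in reads)
        assert truth.mass == 5_000

    def test_truth_mass_equals_read_count(self, small_sim):
        reads, truth = small_sim
        assert truth.mass == len(reads)

    def test_true_pair_always_among_candidates(self, small_sim):
        reads, _ = small_sim
        assert all(r.true_bin_pair in r.candidates for r in reads)

    def test_multiread_candidates_are_unit_shifts_of_true_pair(self):
        """Homology structure: every candidate is the true bin pair with
        each end shifted by an integer number of duplication units (up
        to binning slack), i.e. equal within-copy offsets."""
        layout = build_layout()
        reads, _ = simulate_contacts(layout, n_reads=30_000, seed=2)
        unit, bs = layout.unit_length, layout.bin_size
        shifts = range(-(layout.dup_copies - 1), layout.dup_copies)

        def is_shift(c, t):
            return any(abs((c - t) * bs - k * unit) < bs for k in shifts)

        checked = 0
        for r in reads:
            if not r.is_multi:
                continue
            ti, tj = r.true_bin_pair
            for (i, j) in r.candidates:
                assert ((is_shift(i, ti) and is_shift(j, tj))
                        or (is_shift(j, ti) and is_shift(i, tj)))
            assert len(r.candidates) <= layout.dup_copies ** 2
            checked += 1
        assert checked > 0

    def test_multiread_fraction_matches_analytic_expectation(self):
        """Direct probability computation over the sampling law: a read
        is ambiguous iff either end's base pair lands in the duplicated
        block."""
        layout = build_layout()
        n_reads, seed, alpha, ins = 100_000, 7, 1.0, 0.2
        reads, _ = simulate_contacts(layout, n_reads=n_reads,
                                     decay_alpha=alpha, insulation=ins,
                                     seed=seed)
        observed = sum(r.is_multi for r in reads) / n_reads

        # independent re-derivation of the pair law and the block footprint
        n, bs = layout.n_bins, layout.bin_size
        iu, ju = np.triu_indices(n, k=1)
        w = (ju - iu + 1.0) ** (-alpha)
        mids = (np.arange(n) + 0.5) * bs
        for b in layout.tad_boundaries_truth:
            w = np.where((mids[iu] < b) & (mids[ju] > b), w * ins, w)
        p = w / w.sum()
        blk_s, blk_e = layout.dup_block
        f = np.array([max(0, min((k + 1) * bs, blk_e) - max(k * bs, blk_s))
                      for k in range(n)]) / bs
        q = float((p * (1.0 - (1.0 - f[iu]) * (1.0 - f[ju]))).sum())
        sd = np.sqrt(q * (1 - q) / n_reads)
        assert abs(observed - q) < 3 * sd

    def test_truth_decay_follows_power_law(self):
        """With alpha=1 and no insulation the mean truth count per pair
        falls with slope ~ -1 in log-log (closed-form OLS oracle)."""
        layout = build_layout(dup_copies=1, boundary_positions=(578_000,))
        _, truth = simulate_contacts(layout, n_reads=300_000,
                                     decay_alpha=1.0, insulation=1.0, seed=9)
        n = layout.n_bins
        totals = np.zeros(n)
        for (i, j), c in truth.entries.items():
            totals[j - i] += c
        d = np.arange(1, n)
        means = totals[1:] / (n - d)
        keep = means > 0
        slope = np.polyfit(np.log(d[keep] + 1.0), np.log(means[keep]), 1)[0]
        assert -1.1 < slope < -0.9

    def test_insulation_one_counts_depend_on_distance_only(self):
        """At insulation 1 the planted boundary leaves no signature:
        mean counts at one distance on either side agree within 4 SD of
        multinomial sampling noise."""
        layout = build_layout(dup_copies=1, boundary_positions=(500_000,))
        n_reads = 200_000
        _, truth = simulate_contacts(layout, n_reads=n_reads,
                                     insulation=1.0, seed=5)
        n, bs = layout.n_bins, layout.bin_size
        b = 500_000
        d = 10
        mids = (np.arange(n) + 0.5) * bs
        straddle, within = [], []
        for i in range(n - d):
            j = i + d
            (straddle if mids[i] < b < mids[j] else within).append(
                truth.get(i, j))
        # per-pair Poisson rate at this distance
        lam = (np.sum(straddle) + np.sum(within)) / (len(straddle)
                                                     + len(within))
        sd = np.sqrt(lam / len(straddle) + lam / len(within))
        assert abs(np.mean(straddle) - np.mean(within)) < 4 * sd

    def test_invalid_insulation_rejected(self, default_layout):
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                simulate_contacts(default_layout, n_reads=10,
                                  insulation=bad)


class TestFixtureIO:
    def test_round_trip_identity(self, tmp_path, default_layout):
        reads, _ = simulate_contacts(default_layout, n_reads=500, seed=1)
        write_fixture(reads, default_layout, tmp_path)
        back_reads, back_layout = read_fixture(tmp_path)
        assert back_layout == default_layout
        assert back_reads == reads

    def test_identical_seed_gives_byte_identical_fixtures(self, tmp_path,
                                                          default_layout):
        for d in ("a", "b"):
            reads, _ = simulate_contacts(default_layout, n_reads=2_000,
                                         seed=42)
            write_fixture(reads, default_layout, tmp_path / d)
        for name in ("pairs.tsv", "truth_pairs.tsv", "layout.yaml",
                     "ctcf_sites.bed"):
            assert ((tmp_path / "a" / name).read_bytes()
                    == (tmp_path / "b" / name).read_bytes())

    def test_empty_read_collection_writes_header_only(self, tmp_path,
                                                      default_layout):
        paths = write_fixture([], default_layout, tmp_path)
        assert paths["pairs"].read_text() == \
            "read_id\tbin_i\tbin_j\tn_candidates\n"

    def test_bed_intervals_zero_based_half_open(self, tmp_path,
                                                default_layout):
        paths = write_fixture([], default_layout, tmp_path)
        line = paths["boundaries"].read_text().splitlines()[0].split("\t")
        b = default_layout.tad_boundaries_truth[0]
        assert (line[0], int(line[1]), int(line[2])) == ("chrS", b, b + 1)
        ctcf = paths["ctcf"].read_text().splitlines()[0].split("\t")
        assert ctcf[5] in "+-"  # strand in column 6
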