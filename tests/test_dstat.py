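from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import homeoflow as hf
from homeoflow.dstat import SiteFrequencies

from conftest import random_window_counts


def freqs_from_arrays(p1, p2, p3, p4, chrom="chr1L"):
    n = len(p1)
    return SiteFrequencies(
        chrom=np.full(n, chrom, dtype=object),
        pos=np.arange(1, n + 1, dtype=np.int64),
        p1=np.asarray(p1, dtype=float),
        p2=np.asarray(p2, dtype=float),
        p3=np.asarray(p3, dtype=float),
        p4=np.asarray(p4, dtype=float),
        n_called={r: np.full(n, 4) for r in ("P1", "P2", "P3", "O")},
    )


def popmap_for(matrix_samples):
    # one sample prefix per role: p1_*, p2_*, p3_*, o_*
    assignments = {s: s.split("_")[0] for s in matrix_samples}
    return hf.PopulationMap(
        assignments=assignments,
        role_map={"P1": {"p1"}, "P2": {"p2"}, "P3": {"p3"}, "O": {"o"}},
    )


def make_matrix(doses, samples, positions=None, chrom="chr1L"):
    doses = np.asarray(doses, dtype=np.int8)
    n = doses.shape[0]
    pos = np.arange(1, n + 1) if positions is None else np.asarray(positions)
    return hf.GenotypeMatrix(
        samples=list(samples),
        chrom=np.full(n, chrom, dtype=object),
        pos=pos.astype(np.int64),
        ref=np.full(n, "A", dtype=object),
        alt=np.full(n, "T", dtype=object),
        doses=doses,
    )


class TestSiteFrequencies:
    def test_fixed_alt_role_gives_frequency_one(self):
        m = make_matrix([[2, 2, 0, 1, 1, 0, 0, 0]],
                        ["p1_a", "p1_b", "p2_a", "p2_b", "p3_a", "p3_b", "o_a", "o_b"])
        fr = hf.site_frequencies(m, popmap_for(m.samples))
        assert fr.p1[0] == 1.0 and fr.p2[0] == 0.25

    def test_all_missing_role_omits_site(self):
        m = make_matrix([[-1, -1, 1, 1, 1, 1, 0, 0]],
                        ["p1_a", "p1_b", "p2_a", "p2_b", "p3_a", "p3_b", "o_a", "o_b"])
        fr = hf.site_frequencies(m, popmap_for(m.samples), min_called=1)
        assert len(fr.pos) == 0

    def test_matches_bruteforce_tally(self):
        rng = np.random.default_rng(17)
        samples = [f"{r}_{k}" for r in ("p1", "p2", "p3", "o") for k in range(4)]
        doses = rng.integers(-1, 3, size=(60, 16)).astype(np.int8)
        m = make_matrix(doses, samples)
        fr = hf.site_frequencies(m, popmap_for(samples), min_called=2)
        # brute force per-sample tally
        role_cols = {r: [i for i, s in enumerate(samples) if s.startswith(r)]
                     for r in ("p1", "p2", "p3", "o")}
        kept_row = 0
        for i in range(60):
            expected = {}
            ok = True
            for role, cols in role_cols.items():
                called = [doses[i, j] for j in cols if doses[i, j] >= 0]
                if 2 * len(called) < 2:
                    ok = False
                    break
                expected[role] = sum(called) / (2 * len(called))
            if not ok:
                assert i + 1 not in fr.pos
                continue
            assert fr.pos[kept_row] == i + 1
            assert fr.p1[kept_row] == pytest.approx(expected["p1"])
            assert fr.p2[kept_row] == pytest.approx(expected["p2"])
            assert fr.p3[kept_row] == pytest.approx(expected["p3"])
            assert fr.p4[kept_row] == pytest.approx(expected["o"])
            kept_row += 1
        assert kept_row == len(fr.pos)


class TestPatternWeights:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ((0.0, 1.0, 1.0, 0.0), (1.0, 0.0)),  # pure ABBA
            ((1.0, 0.0, 1.0, 0.0), (0.0, 1.0)),  # pure BABA
        ],
    )
    def test_pure_configurations(self, p, expected):
        abba, baba = hf.pattern_weights(freqs_from_arrays(*[[x] for x in p]))
        assert (abba[0], baba[0]) == expected

    def test_equal_p1_p2_contributes_zero_to_numerator(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=(4, 50))
        abba, baba = hf.pattern_weights(freqs_from_arrays(p[0], p[0], p[2], p[3]))
        np.testing.assert_allclose(abba - baba, 0.0, atol=1e-15)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.tuples(*[st.fractions(min_value=0, max_value=1, max_denominator=64)] * 4),
            min_size=1,
            max_size=8,
        )
    )
    def test_matches_exact_rational_formula(self, sites):
        cols = list(zip(*sites))
        abba, baba = hf.pattern_weights(
            freqs_from_arrays(*[[float(x) for x in col] for col in cols])
        )
        for i, (q1, q2, q3, q4) in enumerate(sites):
            ex_abba = (1 - q1) * q2 * q3 * (1 - q4)
            ex_baba = q1 * (1 - q2) * q3 * (1 - q4)
            assert abs(abba[i] - float(ex_abba)) < 1e-12
            assert abs(baba[i] - float(ex_baba)) < 1e-12

    def test_count_mode_binarizes(self):
        abba, baba = hf.pattern_weights(
            freqs_from_arrays([0.2], [0.8], [0.6], [0.1]), mode="count"
        )
        assert (abba[0], baba[0]) == (1.0, 0.0)


class TestAggregateWindows:
    def _windows(self):
        return [
            hf.GenomicWindow("chr1L", 0, 100, "L"),
            hf.GenomicWindow("chr1L", 100, 200, "L"),
        ]

    def test_simple_sums(self):
        fr = freqs_from_arrays([0, 1, 0], [1, 0, 1], [1, 1, 1], [0, 0, 0])
        fr.pos = np.array([10, 20, 30])
        abba, baba = hf.pattern_weights(fr)
        counts = hf.aggregate_windows(fr, abba, baba, self._windows())
        assert (counts[0].n_abba, counts[0].n_baba, counts[0].n_sites) == (2.0, 1.0, 3)
        assert (counts[1].n_abba, counts[1].n_baba, counts[1].n_sites) == (0.0, 0.0, 0)

    def test_site_outside_windows_raises(self):
        fr = freqs_from_arrays([0.5], [0.5], [0.5], [0.5])
        fr.pos = np.array([500])
        with pytest.raises(ValueError, match="outside all windows"):
            hf.aggregate_windows(fr, np.array([0.1]), np.array([0.1]), self._windows())

    def test_matches_linear_scan(self, null_dataset):
        ds = null_dataset
        windows = hf.make_windows(ds.chrom_lengths, 5_000_000, ds.subgenome_map)
        fr = hf.site_frequencies(ds.matrix, ds.popmap)
        abba, baba = hf.pattern_weights(fr)
        counts = hf.aggregate_windows(fr, abba, baba, windows)
        # O(n*m) per-site scan
        exp_abba = np.zeros(len(windows))
        exp_sites = np.zeros(len(windows), dtype=int)
        for i in range(len(fr.pos)):
            for j, w in enumerate(windows):
                if w.chrom == fr.chrom[i] and w.start <= fr.pos[i] - 1 < w.end:
                    exp_abba[j] += abba[i]
                    exp_sites[j] += 1
                    break
        np.testing.assert_allclose([c.n_abba for c in counts], exp_abba)
        np.testing.assert_array_equal([c.n_sites for c in counts], exp_sites)


class TestPattersonD:
    def test_equal_counts_give_zero(self):
        counts = [
            hf.WindowCounts(hf.GenomicWindow("chr1L", 0, 10, "L"), 50, 50, 100),
            hf.WindowCounts(hf.GenomicWindow("chr1L", 10, 20, "L"), 30, 30, 60),
        ]
        assert hf.patterson_d(counts).d == 0.0

    def test_zero_denominator_raises(self):
        counts = [hf.WindowCounts(hf.GenomicWindow("chr1L", 0, 10, "L"), 0, 0, 0)]
        with pytest.raises(ValueError, match="no informative sites"):
            hf.patterson_d(counts)

    def test_d_bounded(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            counts = random_window_counts(rng)
            res = hf.patterson_d(counts)
            assert -1.0 <= res.d <= 1.0
            assert res.ci_low <= res.d <= res.ci_high

    def test_antisymmetric_under_p1_p2_swap(self):
        rng = np.random.default_rng(21)
        p = rng.uniform(size=(4, 200))
        fr = freqs_from_arrays(*p)
        fr_swapped = freqs_from_arrays(p[1], p[0], p[2], p[3])
        w = [hf.GenomicWindow("chr1L", 0, 1000, "L")]
        for f in (fr, fr_swapped):
            f.pos = np.arange(1, 201)
        d = []
        for f in (fr, fr_swapped):
            abba, baba = hf.pattern_weights(f)
            d.append(hf.patterson_d(hf.aggregate_windows(f, abba, baba, w), ci_z=0).d)
        assert abs(d[0] + d[1]) < 1e-12

    def test_global_d_is_weighted_window_mean(self):
        rng = np.random.default_rng(33)
        counts = random_window_counts(rng, n_l=10, n_s=0)
        res = hf.patterson_d(counts)
        weights = np.array([c.weight for c in counts])
        per_window_d = np.array([c.d for c in counts])
        assert abs(res.d - np.average(per_window_d, weights=weights)) < 1e-12
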