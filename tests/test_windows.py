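"""Window construction, variance shares q_w, WPPA and threshold schemes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from windowgwas import data_io, windows
from windowgwas.bayescpi import ChainConfig, PosteriorDraws, PriorSpec

from conftest import toy_genotypes


def make_map(chroms, positions):
    n = len(positions)
    return data_io.MarkerMap(
        np.array([f"m{i}" for i in range(n)], dtype=object),
        np.array(chroms, dtype=object),
        np.array(positions),
    )


def fake_draws(alpha):
    """Wrap an (S, p) effect array as PosteriorDraws for window algebra."""
    alpha = np.asarray(alpha, dtype=float)
    S, p = alpha.shape
    return PosteriorDraws(
        mu=np.zeros(S), alpha=alpha, include=alpha != 0,
        pi=np.full(S, 0.5), sigma2_alpha=np.ones(S), sigma2_e=np.ones(S),
        chain=ChainConfig(n_iter=S, burn_in=0, thin=1, seed=0),
        prior=PriorSpec(scale_alpha=1.0, scale_e=1.0), n_samples=0,
    )


class TestBuildWindowsBp:
    def test_direct_bucketing(self):
        mm = make_map(["1", "1"], [500_000, 1_500_000])
        ws = windows.build_windows_bp(mm, 1_000_000)
        assert ws.n_windows == 2
        assert list(ws.counts) == [1, 1]
        assert ws.windows[0].start == 1 and ws.windows[0].end == 1_000_000

    def test_single_window_when_all_markers_fit(self):
        mm = make_map(["1"] * 5, [10, 20, 30, 40, 50])
        ws = windows.build_windows_bp(mm, 1_000_000)
        assert ws.n_windows == 1 and ws.windows[0].size == 5

    def test_boundary_marker_belongs_to_lower_window(self):
        mm = make_map(["1", "1"], [1_000_000, 1_000_001])
        ws = windows.build_windows_bp(mm, 1_000_000)
        assert list(ws.counts) == [1, 1]
        assert ws.windows[0].end == 1_000_000

    def test_matches_per_marker_bucketing_oracle(self):
        rng = np.random.default_rng(12)
        pos = [np.sort(rng.choice(np.arange(1, 5_000_001), 250, replace=False))
               for _ in range(2)]
        mm = make_map(["1"] * 250 + ["2"] * 250, np.concatenate(pos))
        size = 700_000
        ws = windows.build_windows_bp(mm, size)
        oracle = {}  # exhaustive per-marker bucketing
        for j in range(len(mm)):
            key = (mm.chromosome[j], (mm.position[j] - 1) // size)
            oracle.setdefault(key, []).append(j)
        got = {(w.chromosome, (w.start - 1) // size): list(w.indices)
               for w in ws.windows}
        assert got == oracle

    def test_size_must_be_positive(self):
        mm = make_map(["1"], [5])
        with pytest.raises(ValueError):
            windows.build_windows_bp(mm, 0)


class TestBuildWindowsCount:
    def test_direct_chunking(self):
        mm = make_map(["1"] * 250, np.arange(1, 251))
        ws = windows.build_windows_count(mm, 100)
        assert list(ws.counts) == [100, 100, 50]
        assert [w.partial for w in ws.windows] == [False, False, True]

    def test_windows_never_span_chromosomes(self):
        mm = make_map(["1"] * 150 + ["2"] * 120,
                      list(range(1, 151)) + list(range(1, 121)))
        ws = windows.build_windows_count(mm, 100)
        assert list(ws.counts) == [100, 50, 100, 20]
        assert [w.chromosome for w in ws.windows] == ["1", "1", "2", "2"]

    def test_degenerate_chunk_is_one_window_per_chromosome(self):
        mm = make_map(["1"] * 30 + ["2"] * 40,
                      list(range(1, 31)) + list(range(1, 41)))
        ws = windows.build_windows_count(mm, 1000)
        assert list(ws.counts) == [30, 40]


def test_partition_covers_every_marker_once(het_panel):
    for ws in (windows.build_windows_bp(het_panel.map, 1_000_000),
               windows.build_windows_count(het_panel.map, 100)):
        assert ws.counts.sum() == ws.p == het_panel.n_markers
        assert len(np.unique(np.concatenate([w.indices for w in ws.windows]))) == ws.p


@pytest.mark.parametrize(
    "g, expected",
    [([0.0, 2.0], 1.0), ([3.0, 3.0, 3.0], 0.0), ([1.0, 2.0, 3.0, 4.0], 1.25)],
)
def test_genetic_variance_printed_formula(g, expected):
    assert windows.genetic_variance(g) == pytest.approx(expected)


def test_genetic_variance_rejects_empty():
    with pytest.raises(ValueError):
        windows.genetic_variance([])


class TestWindowQSamples:
    def test_whole_genome_window_explains_everything(self):
        rng = np.random.default_rng(3)
        G = toy_genotypes(rng, 20, 6)
        ws = windows.build_windows_bp(G.map, 10_000_000)
        draws = fake_draws(rng.standard_normal((15, 6)))
        wp = windows.window_q_samples(G, draws, ws)
        np.testing.assert_allclose(wp.q_samples, 1.0)
        assert windows.compute_wppa(wp.q_samples[0], 0.999) == 1.0

    def test_zero_effect_draw_gets_zero_share(self):
        rng = np.random.default_rng(4)
        G = toy_genotypes(rng, 10, 4)
        ws = windows.build_windows_count(G.map, 2)
        alpha = rng.standard_normal((5, 4))
        alpha[2] = 0.0
        wp = windows.window_q_samples(G, fake_draws(alpha), ws)
        np.testing.assert_array_equal(wp.q_samples[:, 2], 0.0)

    def test_orthogonal_blocks_sum_to_one_and_match_oracle(self):
        # two single-SNP windows whose centered columns are orthogonal
        mm = make_map(["1", "1"], [100, 1_000_100])
        dosages = np.array([[0, 0], [2, 0], [0, 2], [2, 2]], dtype=float)
        G = data_io.GenotypeMatrix(
            dosages, np.array(list("abcd"), dtype=object), mm
        )
        ws = windows.build_windows_bp(mm, 1_000_000)
        alpha = np.random.default_rng(5).standard_normal((12, 2))
        wp = windows.window_q_samples(G, fake_draws(alpha), ws)
        np.testing.assert_allclose(wp.q_samples.sum(axis=0), 1.0)
        # brute-force recomputation straight from the defining formulas
        for s in range(12):
            g = dosages @ alpha[s]
            s2g = np.mean(g**2) - np.mean(g) ** 2
            for k, w in enumerate(ws.windows):
                gw = dosages[:, w.indices] @ alpha[s, w.indices]
                s2gw = np.mean(gw**2) - np.mean(gw) ** 2
                assert wp.q_samples[k, s] == pytest.approx(s2gw / s2g)

    def test_threshold_scheme_never_changes_q(self):
        rng = np.random.default_rng(6)
        G = toy_genotypes(rng, 15, 8)
        ws = windows.build_windows_count(G.map, 3)
        wp = windows.window_q_samples(G, fake_draws(rng.standard_normal((9, 8))), ws)
        before = wp.q_samples.copy()
        for kind in ("one_over_N", "per_window"):
            windows.wppa_per_window(wp, windows.resolve_thresholds(kind, ws))
        np.testing.assert_array_equal(wp.q_samples, before)


class TestThresholds:
    def test_constant_scheme(self):
        ws = windows.build_windows_count(make_map(["1"] * 6, range(1, 7)), 2)
        sch = windows.resolve_thresholds("constant", ws, 0.001)
        np.testing.assert_array_equal(sch.values, 0.001)

    def test_one_over_n_matches_reported_window_count(self):
        # 378 physical windows -> T = 1/378 for every window
        mm = make_map(["1"] * 378, np.arange(378) * 1_000_000 + 5)
        ws = windows.build_windows_bp(mm, 1_000_000)
        assert ws.n_windows == 378
        sch = windows.resolve_thresholds("one_over_N", ws)
        np.testing.assert_allclose(sch.values, 1.0 / 378)
        assert sch.values[0] == pytest.approx(0.0026455, abs=1e-7)

    def test_per_window_uses_snp_share(self):
        # window sizes echoing a dense chip: 733 SNPs of 33701 total
        sizes = [733, 594, 545, 33701 - 733 - 594 - 545]
        idx = np.split(np.arange(33701), np.cumsum(sizes)[:-1])
        ws = windows.WindowSet(
            [windows.Window(f"w{k}", "1", 1, 2, ix) for k, ix in enumerate(idx)],
            "count", 33701,
        )
        sch = windows.resolve_thresholds("per_window", ws)
        assert sch.values[0] == pytest.approx(733 / 33701)
        assert sch.values[0] == pytest.approx(0.021750, abs=1e-6)
        assert sch.values.sum() == pytest.approx(1.0)

    def test_constant_out_of_range(self):
        ws = windows.build_windows_count(make_map(["1"] * 4, range(1, 5)), 2)
        with pytest.raises(ValueError):
            windows.resolve_thresholds("constant", ws, 1.5)


class TestWppa:
    def test_strict_exceedance_count(self):
        assert windows.compute_wppa([0.001, 0.002, 0.003, 0.004], 0.0025) == 0.5

    def test_boundaries(self):
        assert windows.compute_wppa([0.1, 0.2], 0.0) == 1.0
        assert windows.compute_wppa([0.1, 0.2], 0.2) == 0.0

    def test_ties_do_not_count(self):
        assert windows.compute_wppa([0.5, 0.5, 0.6], 0.5) == pytest.approx(1 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            windows.compute_wppa([], 0.1)

    @settings(derandomize=True, max_examples=50)
    @given(
        q=st.lists(st.floats(0, 1), min_size=1, max_size=30),
        t1=st.floats(0, 1),
        t2=st.floats(0, 1),
    )
    def test_monotone_nonincreasing_in_threshold(self, q, t1, t2):
        lo, hi = sorted((t1, t2))
        assert windows.compute_wppa(q, lo) >= windows.compute_wppa(q, hi)


class TestDenseWindows:
    def test_quartile_fence_matches_reported_cutoff(self):
        # quartiles 60 and 106 -> fence at 106 + 1.5 * 46 = 175
        counts = np.array([60, 60, 82, 106, 106])
        assert windows.dense_cutoff(counts) == pytest.approx(175.0)

    def test_equal_counts_flag_nothing(self):
        mm = make_map(["1"] * 8, range(1, 9))
        ws = windows.build_windows_count(mm, 2)
        assert windows.detect_dense_windows(ws) == set()

    def test_matches_quantile_threshold_oracle(self):
        rng = np.random.default_rng(8)
        sizes = rng.integers(2, 40, size=50)
        idx = np.split(np.arange(sizes.sum()), np.cumsum(sizes)[:-1])
        ws = windows.WindowSet(
            [windows.Window(f"w{k}", "1", 1, 2, ix) for k, ix in enumerate(idx)],
            "count", int(sizes.sum()),
        )
        got = windows.detect_dense_windows(ws)
        q1, q3 = np.quantile(sizes.astype(float), [0.25, 0.75])
        expected = {f"w{k}" for k, s in enumerate(sizes)
                    if s > q3 + 1.5 * (q3 - q1)}
        assert got == expected

    def test_needs_four_windows(self):
        mm = make_map(["1"] * 3, [1, 2, 3])
        ws = windows.build_windows_count(mm, 1)
        with pytest.raises(ValueError):
            windows.detect_dense_windows(ws)
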