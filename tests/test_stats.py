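"""GC profiles, abundance matrix, intron stats, correlation, length modes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trnadup.model import ANTICODONS, anticodon_to_amino_acid
from trnadup.simulate import ArraySpec, default_spec, generate_fixture
from trnadup.stats import (
    abundance_matrix,
    aggregate_gc,
    gc_profile,
    genome_size_correlation,
    intron_stats,
    length_distribution,
    _tricube_local_linear,
)
from conftest import make_gene

dna = st.text(alphabet="ACGT", min_size=10, max_size=120)


def brute_force_gc(seq, window, step):
    """Naive recount oracle: slice every window, count G/C directly."""
    out = []
    i = 1
    while i + window - 1 <= len(seq):
        win = seq[i - 1 : i - 1 + window]
        gc = sum(c in "GC" for c in win) / window
        center = i + (window - 1) / 2
        out.append((center / len(seq), gc))
        i += step
    return out


class TestGCProfile:
    def test_all_gc_single_window(self):
        p = gc_profile("GGGGG", window=5)
        assert len(p) == 1 and p.gc[0] == 1.0

    def test_no_gc_two_windows(self):
        p = gc_profile("ATATAT", window=5, step=1)
        assert len(p) == 2 and np.all(p.gc == 0.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            gc_profile("ACG", window=5)

    @given(dna, st.integers(2, 8), st.integers(1, 3))
    @settings(max_examples=150, deadline=None)
    def test_matches_brute_force_recount(self, seq, window, step):
        if len(seq) < window:
            return
        p = gc_profile(seq, window=window, step=step)
        expected = brute_force_gc(seq, window, step)
        assert len(p) == len(expected)
        for (pos, gc), ppos, pgc in zip(expected, p.position, p.gc):
            assert ppos == pytest.approx(pos, abs=1e-12)
            assert pgc == pytest.approx(gc, abs=1e-12)


class TestAggregateGC:
    def test_constant_profiles_give_flat_aggregate(self):
        profiles = [gc_profile("GCGCA" * 10), gc_profile("GCGCA" * 10)]
        # force exactly 0.5 everywhere for the analytic case
        for p in profiles:
            p.gc[:] = 0.5
        agg = aggregate_gc(profiles, n_bins=20)
        assert np.allclose(agg.mean_gc, 0.5)
        assert np.allclose(agg.smooth_gc, 0.5)
        assert np.allclose(agg.band_hi - agg.band_lo, 0.0)

    def test_two_constant_profiles_average(self):
        p1, p2 = gc_profile("ACGTA" * 12), gc_profile("ACGTA" * 12)
        p1.gc[:] = 0.4
        p2.gc[:] = 0.6
        agg = aggregate_gc([p1, p2], n_bins=10)
        assert np.allclose(agg.mean_gc, 0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_gc([])

    def test_smoother_equals_direct_weighted_least_squares(self):
        # closed-form local-fit oracle: solve the 2x2 normal equations with
        # numpy at probe points and compare to the smoother
        rng = np.random.default_rng(3)
        x = np.sort(rng.random(40))
        y = np.sin(2 * np.pi * x) + 0.1 * rng.standard_normal(40)
        span = 0.75
        probes = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        got = _tricube_local_linear(x, y, probes, span=span)
        k = int(np.ceil(span * len(x)))
        for x0, g in zip(probes, got):
            d = np.abs(x - x0)
            idx = np.argsort(d, kind="stable")[:k]
            h = d[idx].max()
            w = (1 - (d[idx] / h) ** 3) ** 3
            W = np.diag(w)
            X = np.column_stack([np.ones(k), x[idx] - x0])
            beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y[idx])
            assert g == pytest.approx(beta[0], abs=1e-9)


class TestAbundanceMatrix:
    def test_empty_input_all_absent(self):
        m = abundance_matrix([])
        assert len(m.absent) == 64

    def test_49_present_leaves_15_absent(self):
        present = [ac for ac in ANTICODONS
                   if anticodon_to_amino_acid(ac, selenocysteine=True)
                   != "stop-pairing"][:49]
        genes = [
            make_gene(f"g{i}", 1 + i * 5000, seq="", anticodon=ac,
                      isotype=anticodon_to_amino_acid(ac, selenocysteine=True))
            for i, ac in enumerate(present)
        ]
        m = abundance_matrix(genes)
        assert len(m.present) == 49
        assert len(m.absent) == 15

    def test_fixture_counts_match_generator_truth(self):
        fix = generate_fixture(default_spec(seed=11))
        m = abundance_matrix(fix.annotation.genes, include_und=True)
        truth = fix.truth["anticodon_counts"]
        for species, counts in truth.items():
            for ac, n in counts.items():
                planted_in_arrays = sum(
                    sum(1 for iso, a in
                        (tuple(u) for u in arr["unit"] * arr["copies"]) if a == ac)
                    for arr in fix.truth["arrays"] if arr["species"] == species
                )
                got = int(m.counts.loc[species, ac])
                # background counts plus planted array genes plus iMet (CAT)
                expected = n + planted_in_arrays
                if ac == "CAT":
                    sp_spec = [s for s in default_spec(seed=11).species_specs
                               if s.species == species][0]
                    expected += sp_spec.imet_count
                assert got == expected

    def test_row_sums_equal_species_totals(self):
        fix = generate_fixture(default_spec(seed=13))
        m = abundance_matrix(fix.annotation.genes, include_und=True)
        from collections import Counter

        by_species = Counter(g.species for g in fix.annotation.genes
                             if g.anticodon != "NNN")
        for sp, n in by_species.items():
            assert int(m.species_totals[sp]) == n

    def test_imet_merged_into_cat_in_64_view(self):
        genes = [
            make_gene("g1", 1000, seq="", anticodon="CAT", isotype="Met"),
            make_gene("g2", 9000, seq="", anticodon="CAT", isotype="iMet"),
        ]
        m = abundance_matrix(genes)
        assert int(m.counts.loc["Tst", "CAT"]) == 2
        assert int(m.counts_imet.loc["Tst", "CAT"]) == 1
        assert int(m.counts_imet.loc["Tst", "iMet"]) == 1


class TestIntronStats:
    def test_it_ratio_simple(self):
        genes = [make_gene(f"g{i}", 1 + i * 5000, seq="") for i in range(9)]
        genes.append(make_gene("g9", 90_000, seq="A" * 72, introns=[(40, 51)]))
        s = intron_stats(genes)
        row = s.per_species.iloc[0]
        assert row["n_intron_genes"] == 1 and row["n_genes"] == 10
        assert row["it_ratio_pct"] == pytest.approx(10.0)

    def test_no_introns_anywhere(self):
        genes = [make_gene(f"g{i}", 1 + i * 5000, seq="") for i in range(4)]
        s = intron_stats(genes)
        assert s.per_species["it_ratio_pct"].iloc[0] == 0.0
        assert s.length_hist == {}
        assert s.mean_length is None and s.mode_length is None

    def test_planted_lengths_mode_and_mean(self):
        # introns of length 12 (x5) and 11 (x2): mode 12, mean 82/7
        genes = []
        lengths = [12] * 5 + [11] * 2
        for i, L in enumerate(lengths):
            genes.append(
                make_gene(f"g{i}", 1 + i * 5000, seq="A" * (72 + L),
                          introns=[(40, 39 + L)])
            )
        s = intron_stats(genes)
        assert s.mode_length == 12
        assert s.mean_length == pytest.approx(82 / 7)
        assert s.n_introns == 7

    def test_fixture_intron_lengths_match_truth(self):
        fix = generate_fixture(default_spec(seed=17))
        s = intron_stats(fix.annotation.genes, include_und=True)
        truth_lengths = sorted(
            l for g in fix.truth["background_genes"] for l in g["intron_lengths"]
        )
        got = sorted(l for l, c in s.length_hist.items() for _ in range(c))
        assert got == truth_lengths
        if truth_lengths:
            assert min(truth_lengths) >= 3 and max(truth_lengths) <= 261


class TestGenomeSizeCorrelation:
    def test_exact_line(self):
        counts = {f"s{i}": 2 * i for i in range(1, 6)}
        sizes = {f"s{i}": i for i in range(1, 6)}
        r = genome_size_correlation(counts, sizes)
        assert r.r == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)
        assert r.slope == pytest.approx(2.0)

    def test_zero_variance_is_missing(self):
        counts = {f"s{i}": 7 for i in range(5)}
        sizes = {f"s{i}": i + 1 for i in range(5)}
        assert genome_size_correlation(counts, sizes) is None

    def test_textbook_formula_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0, 11.0])
        y = np.array([3.0, 5.0, 4.0, 9.0, 10.0, 14.0])
        counts = {f"s{i}": y[i] for i in range(6)}
        sizes = {f"s{i}": x[i] for i in range(6)}
        res = genome_size_correlation(counts, sizes)
        # hand formulae
        mx, my = x.mean(), y.mean()
        sxy = ((x - mx) * (y - my)).sum()
        sxx = ((x - mx) ** 2).sum()
        syy = ((y - my) ** 2).sum()
        r_hand = sxy / np.sqrt(sxx * syy)
        slope_hand = sxy / sxx
        assert res.r == pytest.approx(r_hand, abs=1e-12)
        assert res.slope == pytest.approx(slope_hand, abs=1e-12)
        assert res.r_squared == pytest.approx(r_hand**2, abs=1e-12)
        # two-sided p from the t transform
        from scipy import stats as sps

        t = r_hand * np.sqrt((6 - 2) / (1 - r_hand**2))
        p_hand = 2 * sps.t.sf(abs(t), df=4)
        assert res.p_value == pytest.approx(p_hand, abs=1e-12)

    def test_symmetric_in_x_and_y(self):
        counts = {f"s{i}": v for i, v in enumerate([3, 1, 4, 1, 5, 9])}
        sizes = {f"s{i}": v for i, v in enumerate([2, 7, 1, 8, 2, 8])}
        assert genome_size_correlation(counts, sizes).r == pytest.approx(
            genome_size_correlation(sizes, counts).r
        )

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            genome_size_correlation({"a": 1, "b": 2}, {"a": 1, "b": 2})


class TestLengthDistribution:
    def test_tied_modes_all_reported(self):
        lengths = [72, 72, 82, 82, 75]
        genes = [make_gene(f"g{i}", 1 + i * 5000, seq="A" * L)
                 for i, L in enumerate(lengths)]
        ld = length_distribution(genes)
        assert ld.modes == (72, 82)

    def test_single_gene(self):
        ld = length_distribution([make_gene("g", 1, seq="A" * 75)])
        assert ld.min_length == ld.max_length == 75
        assert ld.modes == (75,)

    def test_fixture_matches_generator_truth(self):
        fix = generate_fixture(default_spec(seed=19))
        from collections import Counter

        truth = Counter(g["mature_length"] for g in fix.truth["background_genes"])
        bg_ids = {g["gene_id"] for g in fix.truth["background_genes"]}
        bg_genes = [g for g in fix.annotation.genes if g.gene_id in bg_ids]
        ld = length_distribution(bg_genes, spliced=True, include_und=True)
        assert ld.hist == truth


class TestStemLoopGCStructure:
    def test_gene_starts_more_gc_rich_than_anticodon_region(self):
        # aggregate profile of a generated fixture: acceptor-stem region
        # (first 5% of positions) must beat the anticodon-region bins
        fix = generate_fixture(default_spec(seed=23))
        profiles = [gc_profile(g.genomic_seq) for g in fix.annotation.genes
                    if not g.has_intron]
        agg = aggregate_gc(profiles, n_bins=100)
        start = agg.mean_gc[agg.position <= 0.05].mean()
        anticodon_region = agg.mean_gc[
            (agg.position >= 0.42) & (agg.position <= 0.50)
        ].mean()
        assert start > anticodon_region
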