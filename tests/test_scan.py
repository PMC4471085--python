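"""LSBL / d_i scoring, windowing, outlier calling and agreement."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fstscan import (
    ScanConfig,
    SelectionScan,
    StandardizationStats,
    build_windows,
    compute_breed_scores,
    cross_breed_overlap,
    d_stat,
    fst_components,
    lsbl,
    merge_candidates,
    select_outlier_windows,
    stat_correlation,
    sweep_detection_rates,
)
from fstscan.scan import BreedScores, WindowTable


# ----------------------------------------------------------------------
# LSBL


def test_lsbl_reported_divergence_triple():
    # theta(G,A) = 0.19, theta(G,C) = 0.13, theta(A,C) = 0.14
    l_g, l_a, l_c = lsbl(0.19, 0.13, 0.14)
    assert (l_g, l_a, l_c) == pytest.approx((0.09, 0.10, 0.04), abs=1e-12)


def test_lsbl_symmetric_input():
    assert lsbl(0.2, 0.2, 0.2) == pytest.approx((0.1, 0.1, 0.1))


@settings(deadline=None, max_examples=200)
@given(st.tuples(*[st.floats(-0.2, 1.0, allow_nan=False)] * 3))
def test_lsbl_sum_identity(thetas):
    branches = lsbl(*thetas)
    assert sum(branches) == pytest.approx(sum(thetas) / 2, abs=1e-12)


# ----------------------------------------------------------------------
# d statistic


def _std_stats(e_ab, sd_ab, e_ac, sd_ac, e_bc, sd_bc):
    return StandardizationStats(
        e_fst={("A", "B"): e_ab, ("A", "C"): e_ac, ("B", "C"): e_bc},
        sd_fst={("A", "B"): sd_ab, ("A", "C"): sd_ac, ("B", "C"): sd_bc},
        n_loci=1,
    )


def test_d_is_zero_when_theta_equals_pair_means():
    stats = _std_stats(0.1, 0.05, 0.2, 0.07, 0.15, 0.02)
    d = d_stat({("A", "B"): 0.1, ("A", "C"): 0.2, ("B", "C"): 0.15}, stats)
    for breed in ("A", "B", "C"):
        assert d[breed] == pytest.approx(0.0, abs=1e-12)


def test_d_zero_sd_raises_naming_pair():
    stats = _std_stats(0.1, 0.0, 0.2, 0.07, 0.15, 0.02)
    with pytest.raises(ValueError, match="A.*B"):
        d_stat({("A", "B"): 0.1, ("A", "C"): 0.2, ("B", "C"): 0.15}, stats)


def test_d_five_locus_fixture_matches_two_pass_hand_computation():
    theta = {
        ("A", "B"): np.array([0.05, 0.10, 0.20, 0.40, 0.25]),
        ("A", "C"): np.array([0.02, 0.12, 0.08, 0.30, 0.18]),
        ("B", "C"): np.array([0.07, 0.03, 0.22, 0.10, 0.28]),
    }
    mask = np.ones(5, dtype=bool)
    stats = StandardizationStats.from_thetas(theta, mask)
    d = d_stat(theta, stats)
    # independent two-pass computation: means, (n-1) sds, standardized sums
    for breed in ("A", "B", "C"):
        expected = np.zeros(5)
        for pair, th in theta.items():
            if breed not in pair:
                continue
            e = th.mean()
            sd = th.std(ddof=1)
            expected += (th - e) / sd
        np.testing.assert_allclose(d[breed], expected, atol=1e-12)


def test_mean_d_over_standardization_set_is_zero(small_sim):
    _, gm, _ = small_sim
    pops = gm.populations
    comps = {
        (pops[i], pops[j]): fst_components(gm, pops[i], pops[j])
        for i in range(3) for j in range(i + 1, 3)
    }
    scores = compute_breed_scores(comps)
    for p in pops:
        d = scores.table[f"d_{p}"].to_numpy()[scores.defined]
        assert abs(d.mean()) < 1e-8


def test_lsbl_sum_identity_holds_at_every_defined_locus(small_sim):
    _, gm, _ = small_sim
    pops = gm.populations
    comps = {
        (pops[i], pops[j]): fst_components(gm, pops[i], pops[j])
        for i in range(3) for j in range(i + 1, 3)
    }
    scores = compute_breed_scores(comps)
    d = scores.defined
    total = sum(scores.table[f"lsbl_{p}"].to_numpy()[d] for p in pops)
    theta_sum = sum(c.theta[d] for c in comps.values())
    np.testing.assert_allclose(total, theta_sum / 2, atol=1e-12)


# ----------------------------------------------------------------------
# windows


def _toy_scores(lsbl_vals, d_vals=None, pops=("A", "B", "C")):
    n = len(lsbl_vals)
    d_vals = d_vals if d_vals is not None else lsbl_vals
    cols = {}
    for p in pops:
        cols[f"lsbl_{p}"] = np.asarray(lsbl_vals, dtype=float)
        cols[f"d_{p}"] = np.asarray(d_vals, dtype=float)
    cols["defined"] = np.ones(n, dtype=bool)
    stats = StandardizationStats(e_fst={}, sd_fst={}, n_loci=n)
    return BreedScores(pops=list(pops), table=pd.DataFrame(cols), standardization=stats)


def _toy_loci(pos, chrom=None):
    chrom = chrom if chrom is not None else [1] * len(pos)
    return pd.DataFrame(
        {"chrom": chrom, "pos": pos, "id": [f"s{i}" for i in range(len(pos))],
         "ref": "A", "alt": "B"}
    )


def test_underpopulated_windows_are_dropped():
    loci = _toy_loci([10_000, 20_000, 310_000])
    wt = build_windows(_toy_scores([1.0, 1.0, 1.0]), loci)
    assert len(wt) == 0
    assert (wt.locus_window == 0).all()


def test_single_window_mean_of_constant_scores():
    loci = _toy_loci([10_000, 50_000, 100_000, 150_000, 200_000, 299_999])
    wt = build_windows(_toy_scores([0.4] * 6), loci)
    assert len(wt) == 1
    row = wt.table.iloc[0]
    assert row["n_snps"] == 6
    assert row["lsbl_A"] == pytest.approx(0.4)
    assert row["start"] == 0 and row["end"] == 300_000
    assert (wt.locus_window == 1).all()


def test_window_boundaries_are_half_open():
    # 1-based position 300000 is the last bp of the first window;
    # 300001 opens the second
    loci = _toy_loci([299_998, 299_999, 300_000, 300_001, 300_002, 600_000])
    wt = build_windows(_toy_scores([1, 2, 3, 4, 5, 6]), loci)
    assert wt.table["n_snps"].tolist() == [3, 3]
    assert wt.table.iloc[0]["lsbl_A"] == pytest.approx(2.0)
    assert wt.table.iloc[1]["lsbl_A"] == pytest.approx(5.0)


def test_window_means_match_brute_force(small_sim):
    _, gm, _ = small_sim
    res = SelectionScan(gm).fit()
    wt = res.windows
    cfg = ScanConfig()
    pos = gm.loci["pos"].to_numpy()
    chrom = gm.loci["chrom"].to_numpy()
    scores = res.scores
    for row in wt.table.itertuples(index=False):
        in_win = (
            (chrom == row.chrom)
            & (pos > row.start)
            & (pos <= row.end)
            & scores.defined
        )
        assert in_win.sum() == row.n_snps
        for p in res.pops:
            vals = scores.table[f"lsbl_{p}"].to_numpy()[in_win]
            assert getattr(row, f"lsbl_{p}") == pytest.approx(vals.mean(), abs=1e-12)


def test_window_numbering_consecutive_in_genome_order(small_sim):
    _, gm, _ = small_sim
    wt = SelectionScan(gm).fit().windows
    t = wt.table
    assert t["window"].tolist() == list(range(1, len(t) + 1))
    key = list(zip(t["chrom"], t["start"]))
    assert key == sorted(key)


def test_peak_snp_is_argmax_lsbl_with_position_tiebreak():
    loci = _toy_loci([10_000, 20_000, 30_000, 40_000])
    scores = _toy_scores([0.1, 0.9, 0.9, 0.3])
    wt = build_windows(scores, loci)
    assert wt.table.iloc[0]["peak_A"] == "s1"  # tie at 0.9 -> lower position


# ----------------------------------------------------------------------
# outlier selection, merging, overlap


def _windows_from_values(values):
    n = len(values)
    table = pd.DataFrame(
        {
            "window": np.arange(1, n + 1),
            "chrom": 1,
            "start": np.arange(n) * 300_000,
            "end": (np.arange(n) + 1) * 300_000,
            "n_snps": 3,
            "lsbl_A": np.asarray(values, dtype=float),
            "d_A": np.asarray(values, dtype=float),
        }
    )
    return WindowTable(pops=["A"], window_bp=300_000, table=table,
                       locus_window=np.array([], dtype=int))


def test_percentile_rule_on_reported_window_count():
    rng = np.random.default_rng(0)
    wt = _windows_from_values(rng.permutation(7734).astype(float))
    sel = select_outlier_windows(wt, "lsbl", "A")
    assert len(sel) == 78
    # and they are precisely the 78 largest values
    top = set(wt.table.nlargest(78, "lsbl_A")["window"])
    assert sel == top


def test_percentile_rule_small_n_ceil():
    wt = _windows_from_values(np.arange(100, dtype=float))
    sel = select_outlier_windows(wt, "lsbl", "A")
    assert sel == {100}


def test_percentile_rule_all_ties_prefers_lowest_indices():
    wt = _windows_from_values(np.ones(200))
    sel = select_outlier_windows(wt, "d", "A")
    assert sel == {1, 2}


def test_merge_is_set_intersection():
    assert merge_candidates({1, 2, 3}, {4, 5}) == set()
    assert merge_candidates({1, 2}, {1, 2}) == {1, 2}
    assert merge_candidates({1, 2, 3}, {2, 3, 4}) == {2, 3}


def test_cross_breed_overlap_counts():
    merged = {"A": {1, 2, 3}, "B": {3, 4}, "C": {9}}
    pairwise, shared = cross_breed_overlap(merged)
    counts = {(r.breed_i, r.breed_j): r.n_shared for r in pairwise.itertuples()}
    assert counts == {("A", "B"): 1, ("A", "C"): 0, ("B", "C"): 0}
    assert shared["window"].tolist() == [3]
    assert shared["breeds"].tolist() == ["A,B"]


def test_cross_breed_overlap_matches_brute_force_on_random_sets():
    rng = np.random.default_rng(5)
    for _ in range(20):
        merged = {
            b: set(rng.choice(50, size=rng.integers(0, 15), replace=False).tolist())
            for b in ("A", "B", "C")
        }
        pairwise, shared = cross_breed_overlap(merged)
        for r in pairwise.itertuples():
            assert r.n_shared == len(merged[r.breed_i] & merged[r.breed_j])
        expect_shared = {
            w for b1 in merged for b2 in merged if b1 < b2
            for w in merged[b1] & merged[b2]
        }
        assert set(shared["window"]) == expect_shared


# ----------------------------------------------------------------------
# correlation of the two statistics


def test_affine_d_gives_perfect_correlation():
    rng = np.random.default_rng(6)
    l = rng.normal(size=500)
    scores = _toy_scores(l, d_vals=3.0 * l + 1.0, pops=("A", "B", "C"))
    r, bins = stat_correlation(scores, "A", ScanConfig(bin_size=100))
    assert r == pytest.approx(1.0, abs=1e-12)
    assert bins["r"].dropna().apply(lambda v: v == pytest.approx(1.0)).all()


def test_independent_scores_give_near_zero_correlation():
    rng = np.random.default_rng(7)
    scores = _toy_scores(rng.normal(size=10_000), d_vals=rng.normal(size=10_000))
    r, _ = stat_correlation(scores, "A")
    assert abs(r) < 0.05


def test_correlation_matches_two_pass_formula():
    rng = np.random.default_rng(8)
    l = rng.normal(size=57)
    d = 0.4 * l + rng.normal(size=57)
    scores = _toy_scores(l, d_vals=d)
    r, _ = stat_correlation(scores, "A")
    lm, dm = l.mean(), d.mean()
    expected = ((l - lm) * (d - dm)).sum() / math.sqrt(
        ((l - lm) ** 2).sum() * ((d - dm) ** 2).sum()
    )
    assert r == pytest.approx(expected, abs=1e-12)


def test_correlation_bins_partition_sorted_loci():
    rng = np.random.default_rng(9)
    scores = _toy_scores(rng.normal(size=12_503), d_vals=rng.normal(size=12_503))
    _, bins = stat_correlation(scores, "A")
    assert bins["n_loci"].tolist() == [5000, 5000, 2503]


def test_constant_bin_flagged_undefined():
    l = np.concatenate([np.full(5, 9.0), np.arange(5, dtype=float)])
    d = np.arange(10, dtype=float)
    scores = _toy_scores(l, d_vals=d)
    _, bins = stat_correlation(scores, "A", ScanConfig(bin_size=5))
    assert not bins.iloc[0]["defined"]
    assert np.isnan(bins.iloc[0]["r"])


# ----------------------------------------------------------------------
# end-to-end model behaviour


def test_scan_invariant_to_chromosome_relabelling(small_sim):
    """Relabelling chromosomes (and re-sorting) permutes windows coherently."""
    _, gm, _ = small_sim
    res1 = SelectionScan(gm).fit()

    flipped = gm.loci.copy()
    n_chrom = flipped["chrom"].max()
    flipped["chrom"] = n_chrom + 1 - flipped["chrom"]
    order = np.lexsort((flipped["pos"].to_numpy(), flipped["chrom"].to_numpy()))
    from fstscan import GenotypeMatrix

    gm2 = GenotypeMatrix(
        dosages=gm.dosages[:, order],
        loci=flipped.iloc[order],
        samples=gm.samples,
    )
    res2 = SelectionScan(gm2).fit()

    # map windows by (original chrom, start): flags must coincide
    def window_keys(res, unflip=False):
        keys = {}
        for row in res.windows.table.itertuples(index=False):
            c = n_chrom + 1 - row.chrom if unflip else row.chrom
            keys[row.window] = (c, row.start)
        return keys

    k1 = window_keys(res1)
    k2 = window_keys(res2, unflip=True)
    for p in res1.pops:
        sel1 = {k1[w] for w in res1.merged[p]}
        sel2 = {k2[w] for w in res2.merged[p]}
        assert sel1 == sel2


def test_scan_requires_three_populations(small_sim):
    _, gm, _ = small_sim
    two = gm.subset_samples((gm.samples["population"] != "AWD").to_numpy())
    with pytest.raises(ValueError):
        SelectionScan(two)


def test_planted_sweeps_are_recovered_and_specific(sweep_sim):
    _, gm, truth = sweep_sim
    res = SelectionScan(gm).fit()
    rates = sweep_detection_rates(truth.table, res.windows, res.merged)
    assert rates["detected"].all()
    assert not rates["cross_detected"].any()


def test_results_summary_mentions_key_quantities(small_sim):
    _, gm, _ = small_sim
    res = SelectionScan(gm).fit()
    text = res.summary()
    assert "F_ST" in text and "merged" in text
    for p in res.pops:
        assert p in text
    assert res.candidate_windows(res.pops[0])["window"].tolist() == sorted(
        res.merged[res.pops[0]]
    )
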