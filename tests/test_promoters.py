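"""Promoter construction, Fisher phase enrichment, specificity, occupancy."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chronocycle.promoters import (
    build_promoters,
    h3k9me3_occupancy,
    phase_enrichment,
    select_promoter_per_gene,
    specificity_scores,
)
from chronocycle.simdata import gen_regulome


def tss_frame(positions, gene="g1", chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "start": positions, "name": gene})


# ---------------------------------------------------------------------------
# promoter construction


def test_single_tss_promoter_span():
    out = build_promoters(tss_frame([1000]))
    assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (500, 1501)


def test_cluster_gap_threshold_semantics():
    """TSS <1 kb apart merge; >=1 kb apart split."""
    joined = build_promoters(tss_frame([1000, 1999]))
    assert len(joined) == 1
    split = build_promoters(tss_frame([1000, 2001]))
    assert len(split) == 2
    boundary = build_promoters(tss_frame([1000, 2000]))
    assert len(boundary) == 2


def test_clip_at_zero():
    out = build_promoters(tss_frame([100]))
    assert out.iloc[0]["start"] == 0


def test_missing_gene_assignment_rejected():
    bad = pd.DataFrame({"chrom": ["chr1"], "start": [5], "name": [""]})
    with pytest.raises(ValueError):
        build_promoters(bad)


def brute_force_single_linkage(positions, gap):
    """All-pairs single-linkage clustering oracle."""
    clusters = [[p] for p in positions]
    merged = True
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = min(abs(a - b) for a in clusters[i] for b in clusters[j])
                if d < gap:
                    clusters[i] += clusters.pop(j)
                    merged = True
                    break
            if merged:
                break
    return sorted((min(c), max(c)) for c in clusters)


def test_clustering_matches_brute_force_oracle():
    rng = np.random.default_rng(3)
    for _ in range(10):
        pos = sorted(rng.integers(600, 20_000, size=rng.integers(2, 50)).tolist())
        pos = list(dict.fromkeys(pos))
        out = build_promoters(tss_frame(pos))
        got = sorted(
            (row["start"] + 500, row["end"] - 501) for _, row in out.iterrows()
        )
        expected = brute_force_single_linkage(pos, 1000)
        assert got == expected


def test_promoter_construction_idempotent():
    """Rebuilding from emitted spans (compact clusters) returns the same
    intervals."""
    pos = [1000, 1500, 8000, 20_000, 20_400]
    out = build_promoters(tss_frame(pos))
    rebuilt_tss = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.concatenate(
                [[r["start"] + 500, r["end"] - 501] for _, r in out.iterrows()]
            ),
            "name": "g1",
        }
    )
    again = build_promoters(rebuilt_tss)
    pd.testing.assert_frame_equal(
        out[["chrom", "start", "end"]].sort_values("start").reset_index(drop=True),
        again[["chrom", "start", "end"]].sort_values("start").reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# promoter selection


def test_promoter_selection_keys():
    proms = pd.DataFrame(
        {"chrom": "chr1", "start": [0, 100, 200], "end": [50, 150, 250],
         "name": ["g1", "g1", "g2"], "cluster": [0, 1, 0]}
    )
    k4 = pd.Series([10.0, 5.0, 1.0], index=proms.index)
    k27 = pd.Series([0.0, 0.0, 0.0], index=proms.index)
    best = select_promoter_per_gene(proms, k4, k27)
    assert best.set_index("name").loc["g1", "start"] == 0  # higher H3K4me3 wins
    assert len(best) == 2  # singleton keeps itself

    k4_tie = pd.Series([5.0, 5.0, 1.0], index=proms.index)
    k27_tb = pd.Series([3.0, 7.0, 0.0], index=proms.index)
    best2 = select_promoter_per_gene(proms, k4_tie, k27_tb)
    assert best2.set_index("name").loc["g1", "start"] == 100  # H3K27ac breaks tie


def test_missing_signal_warns_and_zeroes():
    proms = pd.DataFrame(
        {"chrom": "chr1", "start": [0, 100], "end": [50, 150],
         "name": ["g1", "g1"], "cluster": [0, 1]}
    )
    k4 = pd.Series([np.nan, 2.0], index=proms.index)
    with pytest.warns(UserWarning):
        best = select_promoter_per_gene(proms, k4, pd.Series(0.0, index=proms.index))
    assert best.iloc[0]["start"] == 100


# ---------------------------------------------------------------------------
# Fisher enrichment


def test_balanced_table_is_null():
    from chronocycle._util import fisher_test

    odds, p = fisher_test(5, 5, 50, 50)
    assert odds == 1.0
    assert p == pytest.approx(1.0)


def test_fisher_against_hypergeometric_enumeration():
    """p equals the two-sided probability-mass enumeration for a fixture."""
    from chronocycle._util import fisher_test

    a, b, c, d = 8, 2, 2, 8
    _, p = fisher_test(a, b, c, d)
    N, r1, c1 = a + b + c + d, a + b, a + c
    support = np.arange(max(0, r1 + c1 - N), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, N, r1, c1)
    p_obs = stats.hypergeom.pmf(a, N, r1, c1)
    expected = pmf[pmf <= p_obs * (1 + 1e-7)].sum()
    assert p == pytest.approx(expected, rel=1e-9)


def test_planted_enrichment_detected_only_for_planted_pair():
    sim = gen_regulome(2000, 3, [("dbpA", "S1")], seed=4)
    tab = phase_enrichment(sim.promoters, sim.fits, sim.peak_sets, sim.fits.index)
    sig = tab[tab["p_adj"] < 0.05]
    assert set(zip(sig["dbp"], sig["phase"])) == {("dbpA", "S1")}
    rec = sig.iloc[0]
    assert rec["odds_ratio"] > 1
    # odds-ratio/table consistency on every record
    assert (
        (tab["odds_ratio"] > 1) == (tab["a"] * tab["d"] > tab["b"] * tab["c"])
    ).all()
    # 2x2 totals cover the universe
    assert (tab[["a", "b", "c", "d"]].sum(axis=1) == len(sim.fits)).all()


def test_zero_peak_dbp_yields_flat_records():
    sim = gen_regulome(200, 2, [], seed=1)
    empty = {"dbpA": sim.peak_sets["dbpA"].iloc[0:0]}
    tab = phase_enrichment(sim.promoters, sim.fits, empty, sim.fits.index)
    assert (tab["a"] == 0).all() and (tab["b"] == 0).all()
    assert (tab["p_raw"] == 1.0).all()


def test_empty_universe_rejected():
    sim = gen_regulome(50, 1, [], seed=0)
    with pytest.raises(ValueError):
        phase_enrichment(sim.promoters, sim.fits, sim.peak_sets, [])


# ---------------------------------------------------------------------------
# specificity


def enrichment_frame(pvals, dbp="d1"):
    from chronocycle.chronogram import DEFAULT_BIN_LABELS

    return pd.DataFrame(
        {"dbp": dbp, "phase": list(DEFAULT_BIN_LABELS), "p_adj": pvals}
    )


def test_specificity_distinct_and_tied():
    distinct = specificity_scores(
        enrichment_frame([0.001, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
    )
    assert distinct["specificity"].max() == pytest.approx(4.5)
    assert distinct.loc[distinct["p_adj"].idxmin(), "specificity"] == pytest.approx(4.5)

    tied = specificity_scores(enrichment_frame([0.5] * 8))
    np.testing.assert_allclose(tied["specificity"], 1.0)


def test_specificity_hand_ranked_ties():
    tab = specificity_scores(
        enrichment_frame([0.01, 0.01, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5])
    )
    best = tab[tab["p_adj"] == 0.01]["specificity"]
    np.testing.assert_allclose(best, 5.5 / 1.5)


def test_specificity_monotone_transform_invariance():
    p = np.array([0.01, 0.03, 0.2, 0.4, 0.5, 0.6, 0.9, 0.95])
    s1 = specificity_scores(enrichment_frame(p))["specificity"]
    s2 = specificity_scores(enrichment_frame(np.sqrt(p)))["specificity"]
    np.testing.assert_allclose(s1, s2)


def test_specificity_requires_eight_phases():
    with pytest.raises(ValueError):
        specificity_scores(enrichment_frame([0.1] * 8).iloc[:5])


# ---------------------------------------------------------------------------
# H3K9me3 occupancy


def signal_frame(mat):
    return pd.DataFrame(np.asarray(mat, dtype=float),
                        index=[f"g{i}" for i in range(len(mat))])


def test_occupancy_all_zero_signal():
    m = signal_frame(np.zeros((5, 300)))
    acr = pd.Series(np.arange(5.0), index=m.index)
    occ = h3k9me3_occupancy(m, acr)
    np.testing.assert_allclose(occ, 0.0)


def test_occupancy_high_plateau_promoter():
    m = np.ones((10, 300))
    m[0] = 10.0
    acr = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
    occ = h3k9me3_occupancy(signal_frame(m), acr)
    assert occ["g0"] == 1.0
    assert (occ.drop("g0") == 0.0).all()


def test_occupancy_scale_invariance():
    rng = np.random.default_rng(8)
    m = rng.uniform(0, 5, (12, 300))
    acr = pd.Series(rng.uniform(0, 2 * np.pi, 12), index=[f"g{i}" for i in range(12)])
    for mode in ("average-cutoff", "median-cutoff-gauss"):
        o1 = h3k9me3_occupancy(signal_frame(m), acr, mode=mode)
        o2 = h3k9me3_occupancy(signal_frame(4.2 * m), acr, mode=mode)
        np.testing.assert_allclose(o1, o2)
        assert ((o1 >= 0) & (o1 <= 1)).all()


def test_occupancy_step_signal_half_covered():
    m = np.zeros((6, 300))
    m[:, 78 : 78 + 66] = 2.0  # covers ~half of scored columns 85..215
    acr = pd.Series(np.arange(6.0), index=[f"g{i}" for i in range(6)])
    occ = h3k9me3_occupancy(signal_frame(m), acr)
    np.testing.assert_allclose(occ, 0.5, atol=0.05)


def test_occupancy_wrong_width_rejected():
    m = signal_frame(np.zeros((3, 200)))
    with pytest.raises(ValueError):
        h3k9me3_occupancy(m, pd.Series(np.arange(3.0), index=m.index))
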