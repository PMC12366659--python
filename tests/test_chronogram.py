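"""Cosinor fitting, rhythmicity testing, batch adjustment, circular stats."""

import numpy as np
import pandas as pd
import pytest

from chronocycle._util import bh_adjust
from chronocycle.chronogram import (
    ChronogramMatrix,
    CosinorModel,
    assign_peak,
    batch_adjust,
    circular_spearman,
    fit_cosinor,
)
from chronocycle.simdata import gen_chronogram


def make_chron(values, bins, batches=None):
    cols = [f"s{i}" for i in range(len(bins))]
    batches = batches or ["b1"] * len(bins)
    df = pd.DataFrame(np.atleast_2d(values), columns=cols)
    df.index = [f"g{i}" for i in range(df.shape[0])]
    return ChronogramMatrix(df, pd.Series(bins, index=cols),
                            pd.Series(batches, index=cols))


def grid_search_cosinor(y, t, period=8, resolution=1e-3):
    """Brute-force (M, A, phi) minimising the residual sum of squares.

    For fixed phi the optimal (M, A) solve a 2-parameter linear least
    squares, so only phi needs scanning.
    """
    best = None
    for phi in np.arange(0, 2 * np.pi, resolution):
        X = np.column_stack([np.ones_like(t), np.cos(2 * np.pi * t / period + phi)])
        coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = ((y - X @ coef) ** 2).sum()
        if best is None or rss < best[0]:
            best = (rss, coef[0], coef[1], phi)
    _, M, A, phi = best
    if A < 0:  # fold the sign into the phase
        A, phi = -A, (phi + np.pi) % (2 * np.pi)
    return M, A, phi


@pytest.mark.parametrize(
    "mesor,amp,phi",
    [(2.0, 1.0, 0.0), (3.0, 0.5, np.pi / 2), (5.5, 2.0, 4.0)],
)
def test_noiseless_fit_matches_grid_search_oracle(mesor, amp, phi):
    t = np.arange(8, dtype=float)
    y = mesor + amp * np.cos(2 * np.pi * t / 8 + phi)
    fits = fit_cosinor(make_chron(y, list(range(8))))
    row = fits.iloc[0]
    assert row["mesor"] == pytest.approx(mesor, abs=1e-10)
    assert row["amplitude"] == pytest.approx(amp, abs=1e-10)
    assert np.angle(np.exp(1j * (row["acrophase"] - phi))) == pytest.approx(0, abs=1e-10)
    M_o, A_o, phi_o = grid_search_cosinor(y, t)
    assert row["mesor"] == pytest.approx(M_o, abs=1e-2)
    assert row["amplitude"] == pytest.approx(A_o, abs=1e-2)
    assert abs(np.angle(np.exp(1j * (row["acrophase"] - phi_o)))) < 2e-3


def test_constant_gene_is_flat():
    fits = fit_cosinor(make_chron(np.full(8, 5.0), list(range(8))))
    assert fits.iloc[0]["mesor"] == pytest.approx(5.0)
    assert fits.iloc[0]["amplitude"] == pytest.approx(0.0, abs=1e-12)


def test_reconstruction_identity():
    """M + A*cos(wt + phi) must equal M + beta*cos(wt) + gamma*sin(wt)."""
    rng = np.random.default_rng(0)
    t = np.linspace(0, 8, 50)
    for _ in range(20):
        beta, gamma, M = rng.normal(size=3)
        A = np.hypot(beta, gamma)
        phi = np.mod(np.arctan2(-gamma, beta), 2 * np.pi)
        direct = M + beta * np.cos(2 * np.pi * t / 8) + gamma * np.sin(2 * np.pi * t / 8)
        polar = M + A * np.cos(2 * np.pi * t / 8 + phi)
        np.testing.assert_allclose(direct, polar, atol=1e-10)


def test_bh_step_up_hand_example():
    np.testing.assert_allclose(
        bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )


def test_bh_monotone_and_bounded():
    rng = np.random.default_rng(1)
    p = rng.uniform(size=200)
    adj = bh_adjust(p)
    assert np.all(adj <= 1) and np.all(adj >= p)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_null_f_statistic_mean():
    """Amplitude-0 genes with noise: E[F] = d2/(d2-2) for F(2, d2)."""
    chron, _ = gen_chronogram(500, 0, n_batches=1, reps_per_bin=5,
                              noise_sd=1.0, seed=11)
    res = CosinorModel(chron).fit()
    d2 = 8 * 5 - 3
    assert res.table["F_stat"].mean() == pytest.approx(d2 / (d2 - 2), abs=0.15)


def test_acrophase_and_peak_time_ranges():
    chron, _ = gen_chronogram(200, 100, n_batches=2, reps_per_bin=2,
                              noise_sd=0.3, seed=3)
    t = CosinorModel(chron).fit().table
    assert ((t["acrophase"] >= 0) & (t["acrophase"] < 2 * np.pi)).all()
    assert ((t["t_star"] >= 0) & (t["t_star"] < 8)).all()


def test_parameter_recovery_under_noise():
    """A=1, sd=0.2, 3 reps x 2 batches: acrophase within 0.2 rad,
    amplitude within 0.15, for >=95% of rhythmic genes."""
    chron, truth = gen_chronogram(300, 300, n_batches=2, reps_per_bin=3,
                                  noise_sd=0.2, seed=7, amplitude=1.0)
    t = CosinorModel(chron).fit().table
    dphi = np.abs(np.angle(np.exp(1j * (t["acrophase"] - truth["acrophase"]))))
    damp = np.abs(t["amplitude"] - truth["amplitude"])
    assert (dphi < 0.2).mean() >= 0.95
    assert (damp < 0.15).mean() >= 0.95


@pytest.mark.parametrize(
    "phi,expected_bin,expected_class",
    [(0.0, "eG1", "G1-c"),
     (-2 * np.pi * 3.5 / 8 % (2 * np.pi), "S1", "G1-c"),
     (-2 * np.pi * 5.5 / 8 % (2 * np.pi), "G2", "G2-c")],
)
def test_peak_bin_assignment(phi, expected_bin, expected_class):
    fits = pd.DataFrame(
        {"amplitude": [1.0], "acrophase": [phi],
         "t_star": [(-phi * 8 / (2 * np.pi)) % 8]}, index=["g0"]
    )
    out = assign_peak(fits)
    assert out.iloc[0]["peak_bin"] == expected_bin
    assert out.iloc[0]["cc_class"] == expected_class


def test_zero_amplitude_has_no_peak():
    fits = pd.DataFrame(
        {"amplitude": [0.0], "acrophase": [0.0], "t_star": [0.0]}, index=["g0"]
    )
    out = assign_peak(fits)
    assert out.iloc[0]["peak_bin"] is None and out.iloc[0]["cc_class"] is None


def test_missing_samples_fit_or_skip():
    chron, _ = gen_chronogram(5, 5, n_batches=1, reps_per_bin=2,
                              noise_sd=0.1, seed=2)
    vals = chron.values.copy()
    vals.iloc[0, :3] = np.nan          # partial: still fittable
    vals.iloc[1, :] = np.nan           # all missing: skipped
    chron2 = ChronogramMatrix(vals, chron.sample_bin, chron.sample_batch)
    with pytest.warns(UserWarning):
        fits = fit_cosinor(chron2)
    assert np.isfinite(fits.iloc[0]["amplitude"])
    assert fits.iloc[0]["n_obs"] == 13
    assert not np.isfinite(fits.iloc[1]["mesor"])


def test_rank_deficient_design_raises():
    with pytest.raises(ValueError):
        fit_cosinor(make_chron([1.0, 2.0], [0, 1]))


def test_batch_adjust_identity_and_alignment():
    chron, _ = gen_chronogram(20, 10, n_batches=1, reps_per_bin=2,
                              noise_sd=0.2, seed=5)
    adj = batch_adjust(chron)
    pd.testing.assert_frame_equal(adj.values, chron.values)  # single batch

    chron2, _ = gen_chronogram(20, 10, n_batches=2, reps_per_bin=2,
                               noise_sd=0.0, seed=5, batch_sd=1.0)
    adj2 = batch_adjust(chron2)
    b = chron2.sample_batch
    m1 = adj2.values.loc[:, (b == "b1").to_numpy()].mean(axis=1)
    m2 = adj2.values.loc[:, (b == "b2").to_numpy()].mean(axis=1)
    np.testing.assert_allclose(m1, m2, atol=1e-10)
    # grand mean preserved
    np.testing.assert_allclose(
        adj2.values.mean(axis=1), chron2.values.mean(axis=1), atol=1e-10
    )


def test_batch_adjust_removes_between_batch_variance():
    chron, _ = gen_chronogram(100, 0, n_batches=3, reps_per_bin=2,
                              noise_sd=0.05, seed=9, batch_sd=2.0)
    adj = batch_adjust(chron)
    b = chron.sample_batch
    def between_var(values):
        means = np.stack([
            values.loc[:, (b == lab).to_numpy()].mean(axis=1)
            for lab in sorted(b.unique())
        ])
        return means.var(axis=0).mean()
    assert between_var(adj.values) < 0.01 * between_var(chron.values)


def test_circular_spearman_identity_and_rotation():
    rng = np.random.default_rng(4)
    a = rng.uniform(0, 2 * np.pi, 100)
    assert circular_spearman(a, a) == pytest.approx(1.0)
    for c in (0.5, np.pi, 5.0):
        assert circular_spearman(a, np.mod(a + c, 2 * np.pi)) == pytest.approx(1.0)


def test_circular_spearman_null_bound():
    rng = np.random.default_rng(1)
    a = rng.uniform(0, 2 * np.pi, 200)
    b = rng.uniform(0, 2 * np.pi, 200)
    assert abs(circular_spearman(a, b)) < 0.15


def test_circular_spearman_balanced_phases_error():
    a = np.array([0, np.pi / 2, np.pi, 3 * np.pi / 2])
    with pytest.raises(ValueError, match="circular mean undefined"):
        circular_spearman(a, a)


def test_from_dataframes_constructor():
    chron, _ = gen_chronogram(10, 5, seed=0)
    meta = pd.DataFrame(
        {"sample": chron.values.columns,
         "bin": chron.sample_bin.to_numpy(),
         "batch": chron.sample_batch.to_numpy()}
    )
    res = CosinorModel.from_dataframes(chron.values, meta).fit()
    assert len(res.table) == 10
    g = res.gene("gene0001")
    assert g.rhythmic in (True, False)
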