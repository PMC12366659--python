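"""Repli-seq replication-timing indices and shift classification.

Repli-seq measures newly replicated DNA in FACS-sorted S-phase fractions,
giving per-50-kb-window read counts across f fractions ordered early to
late. The pipeline here:

1. per chromosome, Gaussian-smooth each fraction's window profile (edge
   padding, sd = 1 window) and row-normalize to percentages summing to 100;
2. summarize each window as the RT index
   RTi = log2((a.b)/(u.v)) with a the early half of the percentage row,
   b = (f/2, ..., 1), u the late half, v = (1, ..., f/2) — positive RTi
   means early replication, a uniform row gives exactly 0;
3. difference RTi between a knockout and wild type (RTdiff = KO - WT);
4. cluster RTdiff with a 3-component 1-D Gaussian mixture; windows in the
   near-zero-mean component that are late in WT (RTi_WT < 0) are
   "late-unchanged" (LU);
5. classify two-fraction early/late log-ratio changes: dlog2EL < -1 is
   late-to-later (LtLr), > +1 late-to-earlier (LtEr), the closed interval
   [-1, 1] unchanged; LU windows combine with these into LU_K9LtEr /
   LU_K9LtLr categories;
6. Fisher-test DNA-binding-protein peak enrichment within each category
   over all windows, flagging putative timing factors (enriched at
   LU_K9LtEr but not LU_K9LtLr).

The EM fit is written out explicitly so the log-likelihood ascent can be
asserted at every iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import bh_adjust, fisher_test, overlaps_any


# ---------------------------------------------------------------------------
# smoothing + normalization


@dataclass
class RepliseqMatrix:
    """Window x fraction Repli-seq signal for one or more chromosomes.

    ``windows`` carries BED-style ``chrom, start, end`` (fixed width,
    non-overlapping, sorted within chromosome); ``counts`` is the raw
    window x fraction matrix; ``percentages`` (set by
    :func:`smooth_normalize`) holds the smoothed row-percentage matrix.
    """

    windows: pd.DataFrame
    counts: np.ndarray
    percentages: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.dtype.kind not in "iuf":
            raise ValueError("counts must be numeric")
        if len(self.windows) != self.counts.shape[0]:
            raise ValueError("window table and count matrix row counts differ")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def f(self) -> int:
        return self.counts.shape[1]


def _gaussian_kernel(sd: float = 1.0, truncate: float = 4.0) -> np.ndarray:
    r = int(np.ceil(truncate * sd))
    k = np.exp(-0.5 * (np.arange(-r, r + 1) / sd) ** 2)
    return k / k.sum()


def smooth_windows(values: np.ndarray, sd: float = 1.0, edge_pad: bool = True) -> np.ndarray:
    """Gaussian smoothing along the window axis (axis 0) of one chromosome.

    The profile is edge-padded (replication of the terminal windows) out to
    the kernel radius and convolved with a Gaussian of the given sd in
    window units, truncated at 4 sd. With ``edge_pad=False`` zeros are used
    beyond the ends instead.
    """
    k = _gaussian_kernel(sd)
    r = (len(k) - 1) // 2
    mode = "edge" if edge_pad else "constant"
    padded = np.pad(values, ((r, r), (0, 0)), mode=mode)
    out = np.empty_like(values, dtype=float)
    for j in range(values.shape[1]):
        out[:, j] = np.convolve(padded[:, j], k, mode="valid")
    return out


def smooth_normalize(
    mat: RepliseqMatrix, sd: float = 1.0, edge_pad: bool = True
) -> RepliseqMatrix:
    """Smooth per chromosome and per fraction, then row-normalize to 100.

    Rows whose smoothed sum is zero have undefined percentages and are
    flagged missing (NaN row).
    """
    if mat.f < 2:
        raise ValueError("need at least 2 fractions")
    smoothed = np.empty_like(mat.counts, dtype=float)
    for chrom in pd.unique(mat.windows["chrom"]):
        sel = (mat.windows["chrom"] == chrom).to_numpy()
        smoothed[sel] = smooth_windows(mat.counts[sel], sd=sd, edge_pad=edge_pad)
    sums = smoothed.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * smoothed / sums
    pct[sums[:, 0] == 0] = np.nan
    return RepliseqMatrix(mat.windows, mat.counts, percentages=pct)


# ---------------------------------------------------------------------------
# RT index


def rt_index(percentages: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    """Ratio-of-dot-products replication-timing index per row.

    RTi = log2((a.b + eps)/(u.v + eps)) with a the first f/2 entries of the
    row, b = (f/2, ..., 1), u the last f/2 entries and v = (1, ..., f/2).
    Rows with zero mass in both halves (or NaN) are returned as NaN.
    """
    x = np.atleast_2d(np.asarray(percentages, dtype=float))
    f = x.shape[1]
    if f % 2 != 0:
        raise ValueError("RT index needs an even number of fractions")
    if np.any(x[np.isfinite(x)] < 0):
        raise ValueError("percentages must be nonnegative")
    h = f // 2
    b = np.arange(h, 0, -1, dtype=float)
    early = x[:, :h] @ b
    # u.v with v = rev(b): evaluate as rev(u).b so a uniform row yields
    # bit-identical dot products and an exact RTi of 0
    late = x[:, h:][:, ::-1] @ b
    out = np.log2((early + eps) / (late + eps))
    out[(early == 0) & (late == 0)] = np.nan
    return out if np.asarray(percentages).ndim > 1 else out[0]


def diff_rt(rt_ko: pd.Series, rt_wt: pd.Series) -> pd.Series:
    """Elementwise RTdiff = KO - WT over identical window sets.

    Missing (NaN) RT indices propagate to the difference.
    """
    if not rt_ko.index.equals(rt_wt.index):
        raise ValueError("KO and WT window sets differ")
    return rt_ko - rt_wt


# ---------------------------------------------------------------------------
# 1-D Gaussian mixture, explicit EM


class GMMDegenerateError(RuntimeError):
    pass


def _kmeanspp_centers(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    centers = [x[rng.integers(len(x))]]
    for _ in range(k - 1):
        d2 = np.min((x[:, None] - np.array(centers)[None, :]) ** 2, axis=1)
        total = d2.sum()
        if total == 0:
            centers.append(x[rng.integers(len(x))])
            continue
        centers.append(x[rng.choice(len(x), p=d2 / total)])
    return np.array(centers)


def _em_1d(x, means, variances, weights, tol, max_iter, var_floor=1e-10):
    """One EM run; raises GMMDegenerateError on component collapse.

    Asserts the log-likelihood never decreases between iterations (EM
    ascent property; a violation beyond rounding indicates a bug).
    """
    n = len(x)
    prev_ll = -np.inf
    for _ in range(max_iter):
        logpdf = (
            np.log(weights)[None, :]
            - 0.5 * np.log(2 * np.pi * variances)[None, :]
            - 0.5 * (x[:, None] - means[None, :]) ** 2 / variances[None, :]
        )
        m = logpdf.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logpdf - m).sum(axis=1))
        ll = lse.sum()
        if not np.isfinite(ll):
            raise GMMDegenerateError("non-finite likelihood")
        assert ll >= prev_ll - 1e-8 * max(1.0, abs(prev_ll)), "EM likelihood decreased"
        resp = np.exp(logpdf - lse[:, None])
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):
            raise GMMDegenerateError("empty component")
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        if np.any(variances < var_floor):
            raise GMMDegenerateError("component variance collapsed")
        weights = nk / n
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            break
        prev_ll = ll
    return means, variances, weights, ll


def fit_gmm1d(
    x,
    n_components: int = 3,
    seed: int = 0,
    n_restarts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> dict:
    """Fit a 1-D Gaussian mixture by EM with k-means++ restarts.

    Returns a dict with ``means, variances, weights, log_likelihood,
    labels`` (max-posterior component per point). Degenerate restarts
    (collapsing components) are discarded; if every restart degenerates a
    GMMDegenerateError is raised. Input with no spread is rejected.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 10 * n_components:
        raise ValueError(f"need at least {10 * n_components} finite values")
    if np.ptp(x) == 0:
        raise ValueError("all values identical: no mixture structure")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        means0 = _kmeanspp_centers(x, n_components, rng)
        var0 = np.full(n_components, max(np.var(x) / n_components, 1e-6))
        w0 = np.full(n_components, 1.0 / n_components)
        try:
            fitted = _em_1d(x, means0, var0, w0, tol, max_iter)
        except GMMDegenerateError:
            continue
        if best is None or fitted[3] > best[3]:
            best = fitted
    if best is None:
        raise GMMDegenerateError("all EM restarts degenerated")
    means, variances, weights, ll = best
    logpdf = (
        np.log(weights)[None, :]
        - 0.5 * np.log(2 * np.pi * variances)[None, :]
        - 0.5 * (x[:, None] - means[None, :]) ** 2 / variances[None, :]
    )
    return {
        "means": means,
        "variances": variances,
        "weights": weights,
        "log_likelihood": ll,
        "labels": logpdf.argmax(axis=1),
    }


def classify_lu(
    rt_diff: pd.Series, rti_wt: pd.Series, seed: int = 0, n_restarts: int = 10
) -> pd.DataFrame:
    """GMM-cluster RTdiff and flag late-unchanged (LU) windows.

    Windows assigned to the mixture component whose mean is closest to zero
    AND late in wild type (RTi_WT < 0) are LU. Windows with missing RTdiff
    get missing component/flags.
    """
    if not rt_diff.index.equals(rti_wt.index):
        raise ValueError("rt_diff and rti_wt window sets differ")
    finite = np.isfinite(rt_diff.to_numpy(dtype=float))
    fit = fit_gmm1d(rt_diff[finite], n_components=3, seed=seed, n_restarts=n_restarts)
    zero_comp = int(np.argmin(np.abs(fit["means"])))
    comp = pd.Series(pd.NA, index=rt_diff.index, dtype="Int64")
    comp[finite] = fit["labels"] + 1  # components reported 1..3
    lu = pd.Series(False, index=rt_diff.index)
    lu[finite] = (fit["labels"] == zero_comp) & (
        rti_wt[finite].to_numpy(dtype=float) < 0
    )
    return pd.DataFrame({"gmm_component": comp, "lu": lu}, index=rt_diff.index)


def classify_el_shift(delta_log2el: pd.Series) -> pd.Series:
    """Two-fraction early/late shift classes from dlog2EL values.

    < -1 -> LtLr (late-to-later); > +1 -> LtEr (late-to-earlier);
    [-1, 1] -> unchanged. NaN propagates.
    """
    d = delta_log2el.to_numpy(dtype=float)
    out = np.full(len(d), None, dtype=object)
    out[np.isfinite(d) & (d < -1)] = "LtLr"
    out[np.isfinite(d) & (d > 1)] = "LtEr"
    out[np.isfinite(d) & (d >= -1) & (d <= 1)] = "unchanged"
    return pd.Series(out, index=delta_log2el.index, name="el_class")


def combine_categories(lu: pd.Series, el_class: pd.Series) -> pd.Series:
    """LU flags x EL shift classes -> LU_K9LtEr / LU_K9LtLr / other."""
    cat = np.where(
        lu.to_numpy(dtype=bool) & (el_class == "LtEr").to_numpy(),
        "LU_K9LtEr",
        np.where(
            lu.to_numpy(dtype=bool) & (el_class == "LtLr").to_numpy(),
            "LU_K9LtLr",
            "other",
        ),
    )
    return pd.Series(cat, index=lu.index, name="category")


def rt_factor_enrichment(
    windows: pd.DataFrame,
    categories: pd.Series,
    peak_sets: dict[str, pd.DataFrame],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-DBP Fisher enrichment of peak-bearing windows in each category.

    For every DNA-binding protein and each of LU_K9LtEr / LU_K9LtLr, a 2x2
    of [window in category] x [window overlaps >=1 peak] over all windows;
    two-sided Fisher p, BH jointly across all (DBP, category) pairs.
    ``putative`` flags DBPs enriched (odds ratio > 1, adj p < alpha) at
    LU_K9LtEr but not at LU_K9LtLr.
    """
    cats = ("LU_K9LtEr", "LU_K9LtLr")
    rows = []
    for dbp, peaks in sorted(peak_sets.items()):
        bound = overlaps_any(windows, peaks)
        for cat in cats:
            in_cat = (categories == cat).to_numpy()
            if not in_cat.any():
                warnings.warn(f"category {cat} is empty")
            a = int((in_cat & bound).sum())
            b = int((~in_cat & bound).sum())
            c = int((in_cat & ~bound).sum())
            d = int((~in_cat & ~bound).sum())
            if in_cat.any():
                odds, p = fisher_test(a, b, c, d)
            else:
                odds, p = np.nan, 1.0
            rows.append(
                {"dbp": dbp, "category": cat, "a": a, "b": b, "c": c, "d": d,
                 "odds_ratio": odds, "p_raw": p}
            )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_raw"])
    enriched = (out["p_adj"] < alpha) & (out["odds_ratio"] > 1)
    flags = {}
    for dbp, grp in out.assign(enriched=enriched).groupby("dbp"):
        g = grp.set_index("category")["enriched"]
        flags[dbp] = bool(g.get("LU_K9LtEr", False)) and not bool(
            g.get("LU_K9LtLr", False)
        )
    out["putative"] = out["dbp"].map(flags)
    return out


# ---------------------------------------------------------------------------
# Model/Results facade


class RTShiftModel:
    """Replication-timing shift model for a WT/KO Repli-seq pair.

    Parameters
    ----------
    wt, ko
        Raw :class:`RepliseqMatrix` for wild type and knockout (identical
        window sets, fractions ordered early to late).
    delta_log2el
        Optional per-window two-fraction dlog2EL values (knockdown minus
        baseline) for the LtEr/LtLr classification.
    """

    def __init__(
        self,
        wt: RepliseqMatrix,
        ko: RepliseqMatrix,
        delta_log2el: pd.Series | None = None,
        smoothing_sd: float = 1.0,
    ):
        if not wt.windows.reset_index(drop=True).equals(
            ko.windows.reset_index(drop=True)
        ):
            raise ValueError("WT and KO window sets differ")
        self.wt = smooth_normalize(wt, sd=smoothing_sd)
        self.ko = smooth_normalize(ko, sd=smoothing_sd)
        self.delta_log2el = delta_log2el
        idx = pd.RangeIndex(len(wt.windows))
        self.rti_wt = pd.Series(rt_index(self.wt.percentages), index=idx, name="rti_wt")
        self.rti_ko = pd.Series(rt_index(self.ko.percentages), index=idx, name="rti_ko")
        self.rt_diff = diff_rt(self.rti_ko, self.rti_wt).rename("rt_diff")

    def fit(self, seed: int = 0) -> "RTShiftResults":
        flags = classify_lu(self.rt_diff, self.rti_wt, seed=seed)
        table = pd.concat(
            [self.wt.windows.reset_index(drop=True),
             self.rti_wt, self.rti_ko, self.rt_diff, flags],
            axis=1,
        )
        if self.delta_log2el is not None:
            el = classify_el_shift(
                pd.Series(np.asarray(self.delta_log2el, dtype=float), index=table.index)
            )
            table["el_class"] = el
            table["category"] = combine_categories(table["lu"], el)
        return RTShiftResults(self, table)


class RTShiftResults:
    """Per-window RT records: indices, GMM component, LU flag, categories."""

    def __init__(self, model: RTShiftModel, table: pd.DataFrame):
        self.model = model
        self.table = table

    def summary(self) -> pd.DataFrame:
        return self.table.copy()

    def factor_enrichment(
        self, peak_sets: dict[str, pd.DataFrame], alpha: float = 0.05
    ) -> pd.DataFrame:
        if "category" not in self.table:
            raise ValueError("no dlog2EL data: categories unavailable")
        return rt_factor_enrichment(
            self.table[["chrom", "start", "end"]],
            self.table["category"],
            peak_sets,
            alpha=alpha,
        )
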