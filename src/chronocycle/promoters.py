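"""Promoter construction and phase-resolved binding enrichment.

Promoters are defined from transcription start sites: per gene, TSS
positions closer than 1 kb are single-linkage clustered, the cluster span
is extended by 500 bp on both sides, and one promoter per gene is kept by
ranking on active-promoter histone signal (H3K4me3, then H3K27ac). For
every DNA-binding protein (DBP) with a peak set, a Fisher exact test asks
whether genes peaking in a given cell cycle phase are over-represented
among peak-bound promoters, over the universe of all rhythmicity-tested
genes; BH adjustment runs jointly over all (DBP, phase) pairs. A
phase-specificity score — median rank of the 8 adjusted p-values divided by
the rank in the phase at hand — highlights DBPs whose enrichment is
confined to one phase. A separate routine turns a binned heterochromatin
(H3K9me3) signal matrix over promoters into a per-promoter occupancy
fraction.

All coordinates are BED-style: 0-based, half-open.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from ._util import bh_adjust, fisher_test, overlaps_any


def build_promoters(
    tss: pd.DataFrame, cluster_gap: int = 1000, extension: int = 500
) -> pd.DataFrame:
    """Cluster TSS into promoters per gene.

    Parameters
    ----------
    tss
        DataFrame with ``chrom``, ``start`` (0-based TSS position) and
        ``name`` (gene id) columns; ``strand`` optional.
    cluster_gap
        TSS spaced by LESS than this many bp join one cluster.
    extension
        Symmetric extension of the cluster span, clipped at 0.

    Returns
    -------
    BED-like DataFrame (chrom, start, end, name, cluster) — one row per
    (gene, cluster); the span is [min_tss, max_tss + 1) +/- extension.
    """
    if cluster_gap < 0 or extension < 0:
        raise ValueError("cluster_gap and extension must be nonnegative")
    if tss["name"].isna().any() or (tss["name"].astype(str) == "").any():
        raise ValueError("every TSS needs a gene assignment")
    rows = []
    for (gene, chrom), grp in tss.groupby(["name", "chrom"], sort=True):
        pos = np.sort(grp["start"].to_numpy(dtype=int))
        breaks = np.flatnonzero(np.diff(pos) >= cluster_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for ci, (i, j) in enumerate(zip(starts, ends)):
            s = max(0, int(pos[i]) - extension)
            e = int(pos[j]) + 1 + extension
            rows.append({"chrom": chrom, "start": s, "end": e,
                         "name": gene, "cluster": ci})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "cluster"])


def select_promoter_per_gene(
    promoters: pd.DataFrame,
    h3k4me3_signal: pd.Series,
    h3k27ac_signal: pd.Series,
) -> pd.DataFrame:
    """Keep the single top-ranked promoter per gene.

    Ranking is by decreasing H3K4me3 then decreasing H3K27ac signal
    (values aligned to the promoter frame's index). Promoters missing a
    signal value are treated as 0 with a warning.
    """
    k4 = pd.Series(h3k4me3_signal).reindex(promoters.index)
    k27 = pd.Series(h3k27ac_signal).reindex(promoters.index)
    if k4.isna().any() or k27.isna().any():
        warnings.warn("missing promoter signal values treated as 0")
        k4, k27 = k4.fillna(0.0), k27.fillna(0.0)
    ranked = promoters.assign(_k4=k4, _k27=k27).sort_values(
        ["name", "_k4", "_k27"], ascending=[True, False, False], kind="stable"
    )
    best = ranked.groupby("name", sort=True).head(1)
    return best.drop(columns=["_k4", "_k27"]).reset_index(drop=True)


def phase_enrichment(
    promoters: pd.DataFrame,
    cosinor_fits: pd.DataFrame,
    peak_sets: dict[str, pd.DataFrame],
    universe_genes,
    phases=None,
    joint_bh: bool = True,
) -> pd.DataFrame:
    """Fisher enrichment of phase-peaking rhythmic genes among bound genes.

    Parameters
    ----------
    promoters
        One promoter per gene (``chrom, start, end, name``).
    cosinor_fits
        Per-gene table with ``rhythmic`` and ``peak_bin`` columns, indexed
        by gene.
    peak_sets
        Mapping DBP name -> peak interval frame (``chrom, start, end``). An
        empty frame yields a = b = 0 and p = 1 for that DBP.
    universe_genes
        All genes on which rhythmicity was tested.
    phases
        Ordered phase labels (defaults to the 8 chronogram bins).
    joint_bh
        BH jointly across all (DBP, phase) pairs (default) or within each
        DBP across its 8 phases.
    """
    from .chronogram import DEFAULT_BIN_LABELS

    phases = list(phases) if phases is not None else list(DEFAULT_BIN_LABELS)
    universe = pd.Index(universe_genes).unique()
    if len(universe) == 0:
        raise ValueError("empty gene universe")
    fits = cosinor_fits.reindex(universe)
    rhythmic = fits["rhythmic"].fillna(False).astype(bool)
    peak_bin = fits["peak_bin"]

    prom = promoters.set_index("name").reindex(universe)
    has_prom = prom["start"].notna().to_numpy()

    rows = []
    for dbp, peaks in sorted(peak_sets.items()):
        bound = np.zeros(len(universe), dtype=bool)
        if has_prom.any() and len(peaks):
            bound[has_prom] = overlaps_any(prom.loc[has_prom], peaks)
        for phase in phases:
            in_phase = (rhythmic & (peak_bin == phase)).to_numpy()
            a = int((in_phase & bound).sum())
            b = int((~in_phase & bound).sum())
            c = int((in_phase & ~bound).sum())
            d = int((~in_phase & ~bound).sum())
            odds, p = fisher_test(a, b, c, d)
            rows.append({"dbp": dbp, "phase": phase, "a": a, "b": b, "c": c,
                         "d": d, "odds_ratio": odds, "p_raw": p})
    out = pd.DataFrame(rows)
    if joint_bh:
        out["p_adj"] = bh_adjust(out["p_raw"])
    else:
        out["p_adj"] = np.nan
        for dbp, grp in out.groupby("dbp"):
            out.loc[grp.index, "p_adj"] = bh_adjust(grp["p_raw"])
    return specificity_scores(out)


def specificity_scores(enrichment: pd.DataFrame) -> pd.DataFrame:
    """Phase-specificity = median(rank of the DBP's 8 adj. p) / rank(phase).

    The smallest adjusted p-value gets rank 1; ties share the average rank.
    High scores mark DBPs enriched in one phase but not the others.
    """
    out = enrichment.copy()
    out["specificity"] = np.nan
    for dbp, grp in out.groupby("dbp"):
        if len(grp) != 8:
            raise ValueError(f"DBP {dbp!r} has {len(grp)} phase records, need 8")
        ranks = stats.rankdata(grp["p_adj"].to_numpy(), method="average")
        out.loc[grp.index, "specificity"] = np.median(ranks) / ranks
    return out


def scale_by_column_median(matrix: np.ndarray, axis: int = 0) -> np.ndarray:
    """Divide each column (axis=0) or row (axis=1) by its nonzero median.

    All-zero columns/rows are left untouched rather than producing NaN.
    """
    m = np.asarray(matrix, dtype=float).copy()
    med = np.median(m, axis=axis, keepdims=True)
    safe = np.where(med == 0, 1.0, med)
    return m / safe


def _median_filter_even4(padded: np.ndarray) -> np.ndarray:
    """Width-4 running median along rows, window offsets [-2, +1].

    Even-length median = mean of the two central order statistics. Edges
    are handled by replicating the terminal (already padded) columns.
    """
    ext = np.pad(padded, ((0, 0), (2, 1)), mode="edge")
    win = np.lib.stride_tricks.sliding_window_view(ext, 4, axis=1)
    return np.median(win, axis=2)


def h3k9me3_occupancy(
    signal_matrix: pd.DataFrame,
    acrophase: pd.Series,
    mode: str = "average-cutoff",
    scored_range: tuple[int, int] = (85, 215),
) -> pd.Series:
    """Fraction of each promoter covered by above-cutoff H3K9me3 signal.

    The 300-column binned promoter signal matrix is reordered by
    acrophase, padded by 7 columns (edge replication) on each side, and
    median-filtered (width 4). In ``average-cutoff`` mode the cutoff is the
    across-promoter mean of the smoothed signal over the scored columns
    (0-based inclusive positions of the padded matrix); in
    ``median-cutoff-gauss`` mode a Gaussian filter (sd 7 columns) is
    applied first and the across-promoter median is the cutoff. The
    returned fraction is the share of scored columns strictly exceeding
    the cutoff; ties count as non-covered.
    """
    if signal_matrix.shape[1] != 300:
        raise ValueError("signal matrix must have exactly 300 columns")
    order = acrophase.reindex(signal_matrix.index).sort_values(kind="stable").index
    M = signal_matrix.loc[order].to_numpy(dtype=float)
    padded = np.pad(M, ((0, 0), (7, 7)), mode="edge")
    smoothed = _median_filter_even4(padded)
    lo, hi = scored_range
    scored = smoothed[:, lo : hi + 1]
    if mode == "average-cutoff":
        cutoff = scored.mean()
    elif mode == "median-cutoff-gauss":
        smoothed = gaussian_filter1d(smoothed, sigma=7, axis=1, mode="nearest")
        scored = smoothed[:, lo : hi + 1]
        cutoff = np.median(scored)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    frac = (scored > cutoff).mean(axis=1)
    return pd.Series(frac, index=order, name="occupancy")
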