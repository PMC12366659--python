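"""Cosinor analysis of cell cycle expression chronograms.

Bulk RNA-seq from FACS-sorted cell cycle fractions yields, per gene, a
log-expression trace over eight ordered bins (eG1 .. M) spanning one cell
cycle. Rhythmicity is modelled with a single-harmonic cosinor regression

    Y(t) = M + A*cos(2*pi*t/T + phi) + delta_batch + e(t),   T = 8,

linearised as ``Y = M + beta*cos(2*pi*t/T) + gamma*sin(2*pi*t/T) + delta``
with ``beta = A*cos(phi)`` and ``gamma = -A*sin(phi)``. The model is fitted
per gene by ordinary least squares with batch treatment contrasts;
rhythmicity is called by an F-test of the harmonic pair against the
intercept+batch null, with Benjamini-Hochberg control across genes.

`CosinorModel` / `CosinorResults` follow the statsmodels pattern: the model
holds the data and design, ``fit()`` returns a results object carrying
per-gene estimates, the rhythmicity test and peak-bin assignments, plus a
``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import bh_adjust

#: Ordered cell cycle bin names for the 8-bin FACS design.
DEFAULT_BIN_LABELS = ("eG1", "lG1", "G1/S", "S1", "S2", "G2", "G2/M", "M")

#: Bins whose peaking genes are called G1-centered; the rest are G2-centered.
G1_CENTERED_BINS = frozenset({"M", "eG1", "lG1", "G1/S", "S1"})


@dataclass
class ChronogramMatrix:
    """Gene x sample log-normalized expression with per-sample bin and batch.

    Parameters
    ----------
    values
        DataFrame, rows = genes, columns = samples (log scale).
    sample_bin
        Integer cell cycle bin t in {0..T-1} per sample (aligned to columns).
    sample_batch
        Categorical batch label per sample.
    bin_labels
        Ordered names of the T bins.
    """

    values: pd.DataFrame
    sample_bin: pd.Series
    sample_batch: pd.Series
    bin_labels: tuple = DEFAULT_BIN_LABELS

    def __post_init__(self):
        self.sample_bin = pd.Series(self.sample_bin).reindex(self.values.columns)
        self.sample_batch = pd.Series(self.sample_batch).reindex(self.values.columns)
        if self.sample_bin.isna().any() or self.sample_batch.isna().any():
            raise ValueError("every sample needs a bin and a batch label")
        n_bins = len(self.bin_labels)
        present = set(self.sample_bin.astype(int))
        if not present <= set(range(n_bins)):
            raise ValueError(f"sample bins must lie in 0..{n_bins - 1}")


def _design(chron: ChronogramMatrix, period: float):
    """Full and reduced OLS design matrices with batch treatment coding."""
    t = chron.sample_bin.to_numpy(dtype=float)
    x = np.cos(2 * np.pi * t / period)
    z = np.sin(2 * np.pi * t / period)
    batches = sorted(chron.sample_batch.astype(str).unique())
    dummies = [
        (chron.sample_batch.astype(str) == b).to_numpy(dtype=float)
        for b in batches[1:]  # first (lexicographic) batch is the reference
    ]
    ones = np.ones_like(t)
    X_full = np.column_stack([ones, x, z, *dummies])
    X_red = np.column_stack([ones, *dummies])
    return X_full, X_red, batches


def _ols_rss(X: np.ndarray, Y: np.ndarray):
    """Coefficients and residual sums of squares for Y (samples x genes)."""
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            "rank-deficient design: fewer independent samples than model "
            "parameters (the bin/batch layout, not any one gene, is at fault)"
        )
    resid = Y - X @ coef
    return coef, (resid**2).sum(axis=0)


def fit_cosinor(chron: ChronogramMatrix, period: float = 8.0) -> pd.DataFrame:
    """Per-gene cosinor OLS fit (no p-values yet).

    Returns a DataFrame indexed by gene with columns
    ``mesor, beta, gamma, amplitude, acrophase, acr, t_star, rss_full,
    rss_reduced, n_obs``. Genes with missing samples are fitted on the
    available ones when the design still has full rank, otherwise skipped
    with a warning. ``acr = phi*T/(2*pi)`` is the acrophase in bin units as
    conventionally reported; ``t_star = (-acr) mod T`` is the time at which
    the fitted sinusoid actually peaks.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    X_full, X_red, _ = _design(chron, period)
    n, p_full = X_full.shape
    if n < p_full:
        raise ValueError(
            f"need at least {p_full} samples for {p_full} parameters, got {n}"
        )

    Y = chron.values.to_numpy(dtype=float).T  # samples x genes
    genes = chron.values.index
    complete = ~np.isnan(Y).any(axis=0)

    out = pd.DataFrame(
        index=genes,
        columns=[
            "mesor", "beta", "gamma", "amplitude", "acrophase", "acr",
            "t_star", "rss_full", "rss_reduced", "n_obs",
        ],
        dtype=float,
    )

    if complete.any():
        coef, rss_f = _ols_rss(X_full, Y[:, complete])
        _, rss_r = _ols_rss(X_red, Y[:, complete])
        out.loc[genes[complete], "mesor"] = coef[0]
        out.loc[genes[complete], "beta"] = coef[1]
        out.loc[genes[complete], "gamma"] = coef[2]
        out.loc[genes[complete], "rss_full"] = rss_f
        out.loc[genes[complete], "rss_reduced"] = rss_r
        out.loc[genes[complete], "n_obs"] = n

    for j in np.flatnonzero(~complete):
        keep = ~np.isnan(Y[:, j])
        if keep.sum() == 0:
            warnings.warn(f"gene {genes[j]!r} has no observed samples; skipped")
            continue
        try:
            coef, rss_f = _ols_rss(X_full[keep], Y[keep, j : j + 1])
            _, rss_r = _ols_rss(X_red[keep], Y[keep, j : j + 1])
        except np.linalg.LinAlgError:
            warnings.warn(
                f"gene {genes[j]!r}: too few observed samples for the design; skipped"
            )
            continue
        if keep.sum() <= p_full:
            warnings.warn(
                f"gene {genes[j]!r}: no residual degrees of freedom; skipped"
            )
            continue
        out.loc[genes[j], ["mesor", "beta", "gamma"]] = coef[:3, 0]
        out.loc[genes[j], "rss_full"] = rss_f[0]
        out.loc[genes[j], "rss_reduced"] = rss_r[0]
        out.loc[genes[j], "n_obs"] = keep.sum()

    beta = out["beta"].to_numpy(dtype=float)
    gamma = out["gamma"].to_numpy(dtype=float)
    out["amplitude"] = np.hypot(beta, gamma)
    phi = np.mod(np.arctan2(-gamma, beta), 2 * np.pi)
    out["acrophase"] = phi
    out["acr"] = phi * period / (2 * np.pi)
    out["t_star"] = np.mod(-phi * period / (2 * np.pi), period)
    return out


def test_rhythmicity(
    fits: pd.DataFrame, chron: ChronogramMatrix, alpha: float = 0.05
) -> pd.DataFrame:
    """F-test of the harmonic terms against the intercept+batch null.

    F = ((RSS_reduced - RSS_full)/2) / (RSS_full/(n - p_full)) on
    (2, n - p_full) degrees of freedom, BH-adjusted jointly over all
    tested genes. A gene with RSS_full = 0 (perfect fit) gets p_raw = 0
    and ``degenerate = True``.
    """
    X_full, _, _ = _design(chron, 8)  # p_full depends only on batch count
    p_full = X_full.shape[1]
    out = fits.copy()
    n = out["n_obs"].to_numpy(dtype=float)
    if np.any(n[np.isfinite(n)] <= p_full):
        raise ValueError("some fitted genes have n <= number of parameters")
    rss_f = out["rss_full"].to_numpy(dtype=float)
    rss_r = out["rss_reduced"].to_numpy(dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_r - rss_f) / 2.0) / (rss_f / (n - p_full))
    degenerate = np.isfinite(rss_f) & (rss_f == 0)
    p_raw = stats.f.sf(F, 2, n - p_full)
    p_raw[degenerate] = 0.0
    F[degenerate] = np.inf

    out["F_stat"] = F
    out["p_raw"] = p_raw
    out["degenerate"] = degenerate
    out["p_adj"] = bh_adjust(p_raw)
    out["rhythmic"] = out["p_adj"] < alpha
    return out


def assign_peak(
    fits: pd.DataFrame, bin_labels=DEFAULT_BIN_LABELS, period: float = 8.0
) -> pd.DataFrame:
    """Attach ``peak_bin`` and the G1-c/G2-c class from the peak time t*.

    The fitted sinusoid is maximal at t* = (-phi*T/(2*pi)) mod T; the peak
    bin is the half-open unit interval [k, k+1) containing t*. Genes with
    zero amplitude have no defined peak and get missing labels.
    """
    out = fits.copy()
    t_star = out["t_star"].to_numpy(dtype=float)
    idx = np.floor(t_star).astype(int) % len(bin_labels)
    labels = np.array(bin_labels, dtype=object)[idx]
    amp = out["amplitude"].to_numpy(dtype=float)
    undefined = ~np.isfinite(amp) | (amp == 0)
    labels = labels.astype(object)
    labels[undefined] = None
    out["peak_bin"] = labels
    out["cc_class"] = [
        None if lab is None else ("G1-c" if lab in G1_CENTERED_BINS else "G2-c")
        for lab in labels
    ]
    return out


def batch_adjust(chron: ChronogramMatrix) -> ChronogramMatrix:
    """Remove per-gene batch effects, preserving each gene's grand mean.

    Fits expression ~ batch per gene and subtracts the estimated batch
    offsets; intended for plotting/PCA, not for model fitting (the cosinor
    fit carries batch covariates itself).
    """
    batch = chron.sample_batch.astype(str)
    counts = batch.value_counts()
    if (counts == 0).any():
        raise ValueError("every batch label must have at least one sample")
    V = chron.values
    grand = V.mean(axis=1)
    adj = V.copy().astype(float)
    for b in counts.index:
        cols = V.columns[(batch == b).to_numpy()]
        adj[cols] = V[cols].sub(V[cols].mean(axis=1) - grand, axis=0)
    return ChronogramMatrix(adj, chron.sample_bin, chron.sample_batch, chron.bin_labels)


def circular_spearman(phases_a, phases_b) -> float:
    """Circularized Spearman rank correlation of two phase vectors.

    Each vector is centred on its own circular mean
    ``phi_bar = atan2(mean sin, mean cos)`` and the Spearman correlation of
    ``sin(phi - phi_bar)`` between the two vectors is returned. Invariant to
    rotating either vector by a constant. Raises if a vector's resultant
    length is (numerically) zero, leaving the circular mean undefined.
    """
    a = np.asarray(phases_a, dtype=float)
    b = np.asarray(phases_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("phase vectors must be 1-D and of equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 phases")

    def centred_sine(v):
        s, c = np.sin(v).mean(), np.cos(v).mean()
        if np.hypot(s, c) < 1e-12:
            raise ValueError(
                "circular mean undefined: phases are perfectly balanced"
            )
        return np.sin(v - np.arctan2(s, c))

    rho, _ = stats.spearmanr(centred_sine(a), centred_sine(b))
    return float(rho)


class CosinorModel:
    """Cosinor rhythmicity model for an 8-bin cell cycle chronogram.

    Parameters
    ----------
    chron
        The expression matrix with sample bin/batch annotations.
    period
        Cycle length in bin units (fixed by the experimental design).

    Examples
    --------
    >>> res = CosinorModel(chron).fit()
    >>> res.summary().head()
    """

    def __init__(self, chron: ChronogramMatrix, period: float = 8.0):
        self.chron = chron
        self.period = period

    @classmethod
    def from_dataframes(
        cls, values: pd.DataFrame, meta: pd.DataFrame, period: float = 8.0
    ) -> "CosinorModel":
        """Build from an expression frame and a sample-metadata frame.

        ``meta`` must be indexed by (or contain a ``sample`` column matching)
        the expression columns, with ``bin`` and ``batch`` columns.
        """
        if "sample" in meta.columns:
            meta = meta.set_index("sample")
        meta = meta.loc[values.columns]
        chron = ChronogramMatrix(values, meta["bin"].astype(int), meta["batch"])
        return cls(chron, period=period)

    def fit(self, alpha: float = 0.05) -> "CosinorResults":
        fits = fit_cosinor(self.chron, self.period)
        tested = test_rhythmicity(fits, self.chron, alpha=alpha)
        full = assign_peak(tested, self.chron.bin_labels, self.period)
        return CosinorResults(self, full, alpha)


@dataclass
class CosinorFit:
    """Per-gene cosinor estimate bundle (row view of the results table)."""

    gene_id: str
    mesor: float
    amplitude: float
    acrophase: float
    acr: float
    beta: float
    gamma: float
    F_stat: float
    p_raw: float
    p_adj: float
    rhythmic: bool
    peak_bin: str | None
    cc_class: str | None


class CosinorResults:
    """Fitted cosinor results; per-gene table plus convenience accessors."""

    def __init__(self, model: CosinorModel, table: pd.DataFrame, alpha: float):
        self.model = model
        self.table = table
        self.alpha = alpha

    @property
    def rhythmic_genes(self) -> pd.Index:
        return self.table.index[self.table["rhythmic"].fillna(False).astype(bool)]

    def predict(self, gene: str, t) -> np.ndarray:
        """Fitted mean trace M + A*cos(2*pi*t/T + phi) at times ``t``."""
        row = self.table.loc[gene]
        t = np.asarray(t, dtype=float)
        return row["mesor"] + row["amplitude"] * np.cos(
            2 * np.pi * t / self.model.period + row["acrophase"]
        )

    def gene(self, gene_id: str) -> CosinorFit:
        r = self.table.loc[gene_id]
        return CosinorFit(
            gene_id=gene_id,
            mesor=r["mesor"], amplitude=r["amplitude"],
            acrophase=r["acrophase"], acr=r["acr"],
            beta=r["beta"], gamma=r["gamma"], F_stat=r["F_stat"],
            p_raw=r["p_raw"], p_adj=r["p_adj"], rhythmic=bool(r["rhythmic"]),
            peak_bin=r["peak_bin"], cc_class=r["cc_class"],
        )

    def summary(self) -> pd.DataFrame:
        cols = [
            "mesor", "amplitude", "acrophase", "acr", "t_star",
            "F_stat", "p_raw", "p_adj", "rhythmic", "peak_bin", "cc_class",
        ]
        return self.table[cols].copy()
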