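"""Perturbation-induced cell cycle imbalance testing.

In a pooled CRISPRi screen with single-cell readout, each knockdown
condition yields a set of cells with inferred cell cycle phases on
[0, 2*pi). Phases are binned into five intervals (M/eG1, lG1, G1/S, S,
G2/M); the non-targeting control's bin proportions define a reference
multinomial. For each perturbed condition the reference is sampled many
times at that condition's cell count, and per-bin empirical tail
probabilities flag accumulations (excess cells) and attritions (missing
cells).

The tail convention: p_greater is the add-one-smoothed fraction of null
draws with simulated count >= observed, so a small p_greater means the
observed count is improbably HIGH under the reference — an accumulation.
p_smaller is the mirrored lower tail. Ties (simulated == observed) count
in both tails by default, hence p_greater + p_smaller >= 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import check_probabilities, derive_rng

logger = logging.getLogger(__name__)

#: Default five-bin partition of the cell cycle phase circle.
DEFAULT_BIN_LABELS = ("M/eG1", "lG1", "G1/S", "S", "G2/M")
DEFAULT_BREAKS = (
    0.0,
    3 * np.pi / 8,
    7 * np.pi / 8,
    7 * np.pi / 6,
    13 * np.pi / 8,
    2 * np.pi,
)


@dataclass(frozen=True)
class PhaseBins:
    """Phase-circle partition: k labels over k+1 strictly increasing breaks
    running from 0 to 2*pi. Intervals are half-open [lo, hi), the last one
    closed at 2*pi."""

    labels: tuple = DEFAULT_BIN_LABELS
    breaks: tuple = DEFAULT_BREAKS

    def __post_init__(self):
        b = np.asarray(self.breaks, dtype=float)
        if len(self.labels) != len(b) - 1:
            raise ValueError("need one label per interval")
        if b[0] != 0.0 or not np.isclose(b[-1], 2 * np.pi):
            raise ValueError("breaks must run from 0 to 2*pi")
        if np.any(np.diff(b) <= 0):
            raise ValueError("breaks must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.labels)


def bin_phases(
    phases: pd.DataFrame, bins: PhaseBins | None = None
) -> pd.DataFrame:
    """Per-condition phase-bin counts.

    Parameters
    ----------
    phases
        DataFrame with ``condition`` and ``phase`` columns (radians; reduced
        mod 2*pi before binning). Non-finite phases are dropped with a
        logged count.

    Returns
    -------
    DataFrame: rows = conditions, columns = bin labels, integer counts.
    """
    bins = bins or PhaseBins()
    phi = phases["phase"].to_numpy(dtype=float)
    ok = np.isfinite(phi)
    if not ok.all():
        logger.warning("dropping %d rows with non-finite phases", (~ok).sum())
    phi = np.mod(phi[ok], 2 * np.pi)
    idx = np.searchsorted(np.asarray(bins.breaks), phi, side="right") - 1
    idx = np.clip(idx, 0, bins.n_bins - 1)  # phase exactly 0 after mod
    cond = phases["condition"].to_numpy()[ok]
    counts = (
        pd.crosstab(pd.Series(cond, name="condition"), pd.Series(idx, name="bin"))
        .reindex(columns=range(bins.n_bins), fill_value=0)
    )
    counts.columns = list(bins.labels)
    return counts


def reference_probs(nt_counts) -> np.ndarray:
    """Reference multinomial event probabilities from control bin counts."""
    c = np.asarray(nt_counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("control condition has no cells")
    p = c / total
    if np.any(p == 0):
        warnings.warn(
            "reference has empty bins; attrition can never be called there"
        )
    return p


def imbalance_test(
    cond_counts,
    ref_probs,
    n_sims: int = 100_000,
    seed: int | np.random.Generator = 0,
    tie_both_tails: bool = True,
) -> pd.DataFrame:
    """Monte-Carlo per-bin tail probabilities for one condition.

    Samples ``n_sims`` multinomial draws of size n = sum(cond_counts) from
    ``ref_probs`` and reports, per bin, the add-one empirical tails

        p_greater = (#{sim >= obs} + 1) / (n_sims + 1)
        p_smaller = (#{sim <= obs} + 1) / (n_sims + 1)

    together with the expected count and the signed percentage deviation
    ``delta_pct = 100*(obs - expected)/n``. With ``tie_both_tails=False``
    ties count only in the >= tail (p_smaller uses strict <).
    """
    obs = np.asarray(cond_counts, dtype=int)
    n = int(obs.sum())
    if n <= 0:
        raise ValueError("condition has no cells")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    p = check_probabilities(ref_probs, "reference probabilities")
    if len(p) != len(obs):
        raise ValueError("count vector and probability vector lengths differ")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sims = rng.multinomial(n, p, size=int(n_sims))
    ge = (sims >= obs).sum(axis=0)
    le = (sims <= obs).sum(axis=0) if tie_both_tails else (sims < obs).sum(axis=0)
    expected = n * p
    return pd.DataFrame(
        {
            "observed": obs,
            "expected": expected,
            "delta_pct": 100.0 * (obs - expected) / n,
            "p_greater": (ge + 1) / (n_sims + 1),
            "p_smaller": (le + 1) / (n_sims + 1),
        }
    )


def classify_imbalance(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Attach accumulation/attrition calls at level ``alpha``.

    ``call`` is "accumulation" if p_greater <= alpha, "attrition" if
    p_smaller <= alpha, else "none" (both cannot fire: the observed count is
    in both tails, so p_greater + p_smaller > 1).
    """
    out = results.copy()
    call = np.where(
        out["p_greater"] <= alpha,
        "accumulation",
        np.where(out["p_smaller"] <= alpha, "attrition", "none"),
    )
    out["call"] = call
    return out


def summarize_condition(results: pd.DataFrame) -> dict:
    """Most severe imbalance of a condition: minimum p over all 2k tails."""
    tails = pd.concat(
        [
            results["p_greater"].rename("p").to_frame().assign(direction="accumulation"),
            results["p_smaller"].rename("p").to_frame().assign(direction="attrition"),
        ]
    )
    best = tails.sort_values("p", kind="stable").iloc[0]
    return {
        "min_p": float(best["p"]),
        "bin": best.name,
        "direction": best["direction"],
    }


class ImbalanceModel:
    """Cell cycle imbalance screen model.

    Parameters
    ----------
    phases
        Long table with ``cell``, ``condition``, ``phase`` columns.
    control
        Name of the non-targeting reference condition.
    bins
        Phase-circle partition (defaults to the five-bin scheme).
    """

    def __init__(
        self,
        phases: pd.DataFrame,
        control: str = "non-targeting",
        bins: PhaseBins | None = None,
    ):
        self.bins = bins or PhaseBins()
        self.counts = bin_phases(phases, self.bins)
        if control not in self.counts.index:
            raise ValueError(f"control condition {control!r} not present")
        self.control = control
        self.ref_probs = reference_probs(self.counts.loc[control])

    def fit(
        self,
        n_sims: int = 100_000,
        seed: int = 0,
        alpha: float = 0.05,
        tie_both_tails: bool = True,
    ) -> "ImbalanceResults":
        rows = []
        for cond in self.counts.index:
            if cond == self.control:
                continue
            rng = derive_rng(seed, cond)  # order-independent substream
            res = imbalance_test(
                self.counts.loc[cond].to_numpy(),
                self.ref_probs,
                n_sims=n_sims,
                seed=rng,
                tie_both_tails=tie_both_tails,
            )
            res.index = list(self.bins.labels)
            res = classify_imbalance(res, alpha=alpha)
            res.insert(0, "condition", cond)
            res.insert(1, "bin", res.index)
            rows.append(res.reset_index(drop=True))
        table = (
            pd.concat(rows, ignore_index=True)
            if rows
            else pd.DataFrame(
                columns=[
                    "condition", "bin", "observed", "expected",
                    "delta_pct", "p_greater", "p_smaller", "call",
                ]
            )
        )
        return ImbalanceResults(self, table, alpha)


class ImbalanceResults:
    """Per-(condition, bin) imbalance table plus per-condition summary."""

    def __init__(self, model: ImbalanceModel, table: pd.DataFrame, alpha: float):
        self.model = model
        self.table = table
        self.alpha = alpha

    def summary(self) -> pd.DataFrame:
        """One row per condition: its most severe imbalance."""
        rows = []
        for cond, grp in self.table.groupby("condition", sort=True):
            g = grp.set_index("bin")
            s = summarize_condition(g)
            s["condition"] = cond
            s["significant"] = s["min_p"] <= self.alpha
            rows.append(s)
        return pd.DataFrame(
            rows, columns=["condition", "bin", "direction", "min_p", "significant"]
        )

    def delta_matrix(self) -> pd.DataFrame:
        """Conditions x bins matrix of delta_pct, for external embedding."""
        return self.table.pivot(index="condition", columns="bin", values="delta_pct")[
            list(self.model.bins.labels)
        ]
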