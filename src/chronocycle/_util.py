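"""Shared helpers: BH adjustment, seeding, interval overlap."""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are passed through as NaN and do not count toward the
    family size.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def derive_rng(seed: int, *labels: str) -> np.random.Generator:
    """Generator for a substream keyed by (seed, labels).

    Hashing the labels makes per-condition results independent of the
    order in which conditions are processed.
    """
    key = [int(seed)]
    for lab in labels:
        digest = hashlib.sha256(str(lab).encode()).digest()
        key.append(int.from_bytes(digest[:4], "big"))
    return np.random.default_rng(np.random.SeedSequence(key))


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query interval: does it overlap >=1 subject interval?

    Both frames carry BED-style 0-based half-open ``chrom``, ``start``,
    ``end`` columns. A subject frame with zero rows yields all-False.
    """
    import pyranges as pr

    n = len(query)
    hit = np.zeros(n, dtype=bool)
    if len(subject) == 0 or n == 0:
        return hit
    q = pd.DataFrame(
        {
            "Chromosome": query["chrom"].to_numpy(),
            "Start": query["start"].to_numpy(),
            "End": query["end"].to_numpy(),
            "_qi": np.arange(n),
        }
    )
    s = pd.DataFrame(
        {
            "Chromosome": subject["chrom"].to_numpy(),
            "Start": subject["start"].to_numpy(),
            "End": subject["end"].to_numpy(),
        }
    )
    ov = pr.PyRanges(q).overlap(pr.PyRanges(s))
    if len(ov) > 0:
        hit[ov.df["_qi"].to_numpy()] = True
    return hit


def sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio (a*d)/(b*c) with degenerate tables resolved.

    Tables with a*d == b*c (including empty rows/columns) carry no
    association and return 1.0; a zero denominator with a nonzero
    numerator returns inf.
    """
    num, den = a * d, b * c
    if num == den:
        return 1.0
    if den == 0:
        return np.inf
    return num / den


def fisher_test(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test (probability-mass rule) on a 2x2 table.

    Returns (sample odds ratio, p). The p-value is scipy's exact
    conditional test; the odds ratio is the unconditional sample ratio
    (see :func:`sample_odds_ratio`).
    """
    from scipy import stats

    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return sample_odds_ratio(a, b, c, d), float(p)


def check_probabilities(p, name: str = "probabilities", tol: float = 1e-9) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError(f"{name} must lie in [0, 1]")
    if abs(p.sum() - 1.0) > tol:
        raise ValueError(f"{name} must sum to 1 (got {p.sum()!r})")
    return p
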