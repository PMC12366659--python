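"""Proliferation-signature scoring and KRAB-domain silencing PSSM.

Two auxiliary scores:

* A proliferation score per tumor sample: counts-per-million of a curated
  cell cycle marker gene set are log-transformed (log2(CPM+1)), z-scored
  per cancer subtype, and averaged over the signature genes. Spearman
  correlations between a gene's expression and the score, per cancer type,
  with BH adjustment, identify proliferation-associated regulators.

* A KRAB-domain loss-of-silencing score: a deep mutational scan of a
  reference KRAB domain (every single amino-acid substitution assayed for
  silencing) is normalized to the wild-type construct to form a
  position x residue matrix (PSSM; WT residues = 1, values < 1 mean loss of
  silencing). Any KRAB domain aligned to the reference is scored position
  by position; the minimum over positions predicts the silencing deficit of
  the domain's worst-matching residue, and domains of multi-KRAB proteins
  are averaged.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._util import bh_adjust

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


def proliferation_score(
    expr_cpm: pd.DataFrame,
    signature_genes,
    subtype_labels: pd.Series,
) -> pd.DataFrame:
    """Per-sample proliferation score from a marker gene signature.

    Parameters
    ----------
    expr_cpm
        Genes x samples CPM matrix (linear scale).
    signature_genes
        Iterable of marker gene ids; absent ones are logged and skipped.
    subtype_labels
        Per-sample cancer subtype (aligned to columns); z-scoring runs
        within subtype.

    Returns
    -------
    DataFrame (sample, subtype, score); the score is the mean across
    signature genes of log2(CPM+1) z-scored within the sample's subtype.
    Genes with zero variance within a subtype are skipped there.
    """
    sig = [g for g in signature_genes if g in expr_cpm.index]
    missing = set(signature_genes) - set(sig)
    if missing:
        warnings.warn(f"{len(missing)} signature genes absent from the matrix; skipped")
    if not sig:
        raise ValueError("no signature genes present in the expression matrix")
    subtypes = pd.Series(subtype_labels).reindex(expr_cpm.columns)
    counts = subtypes.value_counts()
    if (counts < 3).any():
        raise ValueError("every subtype needs at least 3 samples")

    logged = np.log2(expr_cpm.loc[sig].astype(float) + 1.0)
    z = pd.DataFrame(np.nan, index=logged.index, columns=logged.columns)
    for st in counts.index:
        cols = logged.columns[(subtypes == st).to_numpy()]
        block = logged[cols]
        sd = block.std(axis=1, ddof=0)
        flat = sd == 0
        if flat.any():
            warnings.warn(
                f"{int(flat.sum())} zero-variance signature genes skipped in subtype {st!r}"
            )
        keep = block.loc[~flat]
        z.loc[~flat, cols] = keep.sub(keep.mean(axis=1), axis=0).div(
            sd[~flat], axis=0
        )
    return pd.DataFrame(
        {"sample": expr_cpm.columns, "subtype": subtypes.to_numpy(),
         "score": z.mean(axis=0, skipna=True).to_numpy()}
    )


def correlate_proliferation(
    kzfp_expr: pd.DataFrame,
    scores: pd.DataFrame,
    cancer_type_labels: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of each gene with the proliferation score.

    Computed per cancer type (>=5 samples each), BH-adjusted jointly over
    all (gene, type) pairs. Genes constant within a type get a missing
    correlation.
    """
    score = scores.set_index("sample")["score"].reindex(kzfp_expr.columns)
    types = pd.Series(cancer_type_labels).reindex(kzfp_expr.columns)
    rows = []
    for ct in sorted(types.dropna().unique()):
        cols = kzfp_expr.columns[(types == ct).to_numpy()]
        if len(cols) < 5:
            raise ValueError(f"cancer type {ct!r} has fewer than 5 samples")
        s = score[cols].to_numpy(dtype=float)
        for gene in kzfp_expr.index:
            x = kzfp_expr.loc[gene, cols].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(s) == 0:
                rho, p = np.nan, np.nan
            else:
                rho, p = stats.spearmanr(x, s)
            rows.append({"gene": gene, "cancer_type": ct, "rho": rho, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_raw"])
    out["significant"] = out["p_adj"] < alpha
    return out


def build_krab_pssm(
    dms_table: pd.DataFrame, wt_sequence: str | None = None, mode: str = "ratio"
) -> pd.DataFrame:
    """Loss-of-silencing PSSM from a single-mutant deep mutational scan.

    Parameters
    ----------
    dms_table
        Columns ``position`` (1-based), ``residue`` (substituted amino
        acid, or the literal "WT" for the wild-type construct row) and
        ``value`` (positive silencing measurement).
    wt_sequence
        Wild-type residue per position. If omitted it is inferred as the
        one amino acid absent from each position's mutant set.
    mode
        "ratio": entry = mutant/WT (default); "difference": mutant - WT.

    Returns
    -------
    Positions x 20-residue DataFrame; wild-type (consensus) entries are
    exactly 1 (ratio mode) or 0 (difference mode); unassayed entries are
    NaN. ``df.attrs['consensus']`` holds the consensus sequence.
    """
    wt_rows = dms_table[dms_table["residue"] == "WT"]
    if len(wt_rows) != 1:
        raise ValueError("need exactly one WT row")
    wt_value = float(wt_rows["value"].iloc[0])
    mut = dms_table[dms_table["residue"] != "WT"]
    positions = sorted(mut["position"].astype(int).unique())
    pssm = pd.DataFrame(np.nan, index=positions, columns=list(AMINO_ACIDS))
    for _, r in mut.iterrows():
        if mode == "ratio":
            pssm.loc[int(r["position"]), r["residue"]] = float(r["value"]) / wt_value
        else:
            pssm.loc[int(r["position"]), r["residue"]] = float(r["value"]) - wt_value

    consensus = []
    for i, pos in enumerate(positions):
        if wt_sequence is not None:
            aa = wt_sequence[i]
        else:
            assayed = set(mut.loc[mut["position"] == pos, "residue"])
            leftover = set(AMINO_ACIDS) - assayed
            if len(leftover) != 1:
                raise ValueError(
                    f"cannot infer the wild-type residue at position {pos}"
                )
            aa = leftover.pop()
        consensus.append(aa)
        pssm.loc[pos, aa] = 1.0 if mode == "ratio" else 0.0
    missing = pssm.isna().sum().sum()
    if missing:
        warnings.warn(f"{int(missing)} unassayed (position, residue) pairs left missing")
    pssm.attrs["consensus"] = "".join(consensus)
    return pssm


def score_krab(
    aligned_domain: str, pssm: pd.DataFrame, aggregate: str = "min"
) -> dict:
    """Score one KRAB domain aligned to the PSSM's reference positions.

    ``aligned_domain`` must have one character per PSSM position ("-" for
    gaps, which are skipped). Returns per-position scores plus ``min`` and
    ``mean`` summaries; ``score`` repeats the requested aggregate. Unassayed
    (NaN) lookups are skipped with a warning.
    """
    if aggregate not in ("min", "mean"):
        raise ValueError("aggregate must be 'min' or 'mean'")
    if len(aligned_domain) != len(pssm.index):
        raise ValueError(
            f"aligned domain length {len(aligned_domain)} != {len(pssm.index)} PSSM positions"
        )
    per_position = {}
    for pos, aa in zip(pssm.index, aligned_domain):
        if aa == "-":
            continue
        if aa not in pssm.columns:
            raise ValueError(f"residue {aa!r} at position {pos} not in the amino-acid alphabet")
        val = pssm.loc[pos, aa]
        if np.isnan(val):
            warnings.warn(f"unassayed residue {aa} at position {pos}; skipped")
            continue
        per_position[pos] = float(val)
    if not per_position:
        raise ValueError("no scorable positions in the aligned domain")
    vals = np.array(list(per_position.values()))
    out = {
        "per_position": per_position,
        "min": float(vals.min()),
        "mean": float(vals.mean()),
    }
    out["score"] = out[aggregate]
    return out


def score_protein(
    aligned_domains: list[str], pssm: pd.DataFrame, aggregate: str = "min"
) -> dict:
    """Average the domain summaries of a multi-KRAB protein."""
    if not aligned_domains:
        raise ValueError("need at least one domain")
    scores = [score_krab(d, pssm, aggregate) for d in aligned_domains]
    return {
        "min": float(np.mean([s["min"] for s in scores])),
        "mean": float(np.mean([s["mean"] for s in scores])),
        "score": float(np.mean([s["score"] for s in scores])),
        "n_domains": len(scores),
    }
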