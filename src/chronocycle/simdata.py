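"""Synthetic data generators with ground truth for every pipeline stage.

Each generator is a pure function of its parameters and a seed
(bit-identical reruns) and returns, alongside the simulated input tables,
a truth table sufficient to measure downstream parameter recovery without
re-deriving anything. Identifiers are deterministic ("gene0001", "dbpA",
"chrS") so fixtures are diffable.

What is emulated (and what is not) per generator:

* ``gen_chronogram`` — sinusoidal log-expression over the 8 FACS-sorted
  cell cycle bins with per-gene batch offsets and Gaussian noise on the
  log scale (the cosinor model lives on logged normalized counts; raw
  counts are not simulated).
* ``gen_phase_assignments`` — control and perturbed cell populations with
  multinomial bin membership and phases uniform within each bin (the
  binned imbalance test is blind to the within-bin density).
* ``gen_repliseq`` — piecewise early/late replication domains over 50-kb
  windows, Poisson read counts across S-phase fractions, with planted
  knockout-shifted domains and matched two-fraction early/late tables.
* ``gen_regulome`` — TSS/promoter/peak interval sets with planted
  phase-specific binding enrichment, plus a binned heterochromatin signal
  matrix with planted high-occupancy promoters.
* ``gen_expression_cohort`` — a tumor cohort whose marker genes share a
  latent proliferation axis, with designated genes correlated to it at a
  planted Spearman strength.
* ``gen_dms_table`` — a single-mutant deep-mutational-scan table (one
  wild-type row plus every position x substitution) for PSSM building.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import check_probabilities
from .chronogram import DEFAULT_BIN_LABELS, ChronogramMatrix
from .imbalance import PhaseBins
from .repliseq import RepliseqMatrix
from .signatures import AMINO_ACIDS

# ---------------------------------------------------------------------------
# chronogram


def gen_chronogram(
    n_genes: int,
    n_rhythmic: int,
    n_batches: int = 1,
    reps_per_bin: int = 1,
    noise_sd: float = 0.2,
    seed: int = 0,
    amplitude: float = 1.0,
    batch_sd: float = 0.5,
    period: int = 8,
):
    """Simulate an 8-bin cell cycle expression chronogram.

    Rhythmic genes follow y = M + A*cos(2*pi*t/T + phi) + batch_offset +
    N(0, noise_sd^2); the rest are flat at their mesor plus the same batch
    and noise terms. Mesors are uniform on [2, 10], acrophases uniform on
    [0, 2*pi); per-gene batch offsets are N(0, batch_sd^2) with the first
    (reference) batch at 0.

    Returns
    -------
    (ChronogramMatrix, truth DataFrame) — truth carries gene_id,
    is_rhythmic, mesor, amplitude, acrophase, noise_sd and one
    batch_offset_<batch> column per non-reference batch.
    """
    if n_genes < 1 or n_batches < 1 or reps_per_bin < 1:
        raise ValueError("n_genes, n_batches and reps_per_bin must be positive")
    if not 0 <= n_rhythmic <= n_genes:
        raise ValueError("need 0 <= n_rhythmic <= n_genes")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)

    genes = [f"gene{i + 1:04d}" for i in range(n_genes)]
    batches = [f"b{i + 1}" for i in range(n_batches)]
    rhythmic = np.zeros(n_genes, dtype=bool)
    rhythmic[:n_rhythmic] = True
    mesor = rng.uniform(2, 10, n_genes)
    amp = np.where(rhythmic, amplitude, 0.0)
    phi = np.where(rhythmic, rng.uniform(0, 2 * np.pi, n_genes), np.nan)

    offsets = np.zeros((n_genes, n_batches))
    if n_batches > 1:
        offsets[:, 1:] = rng.normal(0, batch_sd, (n_genes, n_batches - 1))

    samples, sample_bin, sample_batch = [], [], []
    for b in range(n_batches):
        for t in range(period):
            for r in range(reps_per_bin):
                samples.append(f"{batches[b]}_t{t}_r{r + 1}")
                sample_bin.append(t)
                sample_batch.append(batches[b])
    t_arr = np.array(sample_bin, dtype=float)
    b_arr = np.array([batches.index(b) for b in sample_batch])

    cosine = np.cos(2 * np.pi * t_arr[None, :] / period + np.nan_to_num(phi)[:, None])
    Y = (
        mesor[:, None]
        + amp[:, None] * cosine
        + offsets[:, b_arr]
        + rng.normal(0, noise_sd, (n_genes, len(samples)))
    )
    values = pd.DataFrame(Y, index=genes, columns=samples)
    chron = ChronogramMatrix(
        values,
        pd.Series(sample_bin, index=samples),
        pd.Series(sample_batch, index=samples),
    )
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "is_rhythmic": rhythmic,
            "mesor": mesor,
            "amplitude": amp,
            "acrophase": phi,
            "noise_sd": noise_sd,
        }
    ).set_index("gene_id")
    for j, b in enumerate(batches[1:], start=1):
        truth[f"batch_offset_{b}"] = offsets[:, j]
    return chron, truth


# ---------------------------------------------------------------------------
# phase assignments


def gen_phase_assignments(
    control_probs,
    perturbations: pd.DataFrame,
    seed: int = 0,
    n_control: int = 5000,
    control_label: str = "non-targeting",
    bins: PhaseBins | None = None,
) -> pd.DataFrame:
    """Simulate per-cell phases for a control and perturbed conditions.

    ``perturbations`` has columns ``condition``, ``n_cells`` and
    ``bin_deltas`` (length-5 signed shifts summing to 0). Bin membership is
    multinomial with (control_probs + bin_deltas); phases are uniform
    within the assigned bin.

    Returns a long DataFrame (cell, condition, phase).
    """
    bins = bins or PhaseBins()
    p0 = check_probabilities(control_probs, "control_probs")
    if len(p0) != bins.n_bins:
        raise ValueError(f"control_probs must have length {bins.n_bins}")
    rng = np.random.default_rng(seed)
    breaks = np.asarray(bins.breaks)

    def draw(condition, n, probs):
        if n <= 0:
            raise ValueError(f"condition {condition!r} has no cells")
        counts = rng.multinomial(n, probs)
        phases = np.concatenate(
            [
                rng.uniform(breaks[i], breaks[i + 1], c)
                for i, c in enumerate(counts)
            ]
        )
        rng.shuffle(phases)
        return pd.DataFrame(
            {
                "cell": [f"{condition}_c{i + 1:05d}" for i in range(n)],
                "condition": condition,
                "phase": phases,
            }
        )

    frames = [draw(control_label, n_control, p0)]
    for _, row in perturbations.iterrows():
        deltas = np.asarray(row["bin_deltas"], dtype=float)
        if len(deltas) != bins.n_bins:
            raise ValueError("bin_deltas must have one entry per bin")
        if abs(deltas.sum()) > 1e-9:
            raise ValueError("bin_deltas must sum to 0")
        probs = p0 + deltas
        if np.any(probs < -1e-12) or np.any(probs > 1 + 1e-12):
            raise ValueError(
                f"condition {row['condition']!r}: shifted probabilities leave [0, 1]"
            )
        frames.append(draw(row["condition"], int(row["n_cells"]), np.clip(probs, 0, 1)))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# repli-seq


@dataclass
class RepliseqSim:
    """Simulated Repli-seq bundle: WT/KO matrices, two-fraction EL tables
    (baseline vs knockdown), and the per-window truth."""

    wt: RepliseqMatrix
    ko: RepliseqMatrix
    el_baseline: pd.DataFrame
    el_kd: pd.DataFrame
    truth: pd.DataFrame

    @property
    def delta_log2el(self) -> pd.Series:
        """Knockdown minus baseline two-fraction log2(E/L) per window."""
        base = np.log2(self.el_baseline["E"] / self.el_baseline["L"])
        kd = np.log2(self.el_kd["E"] / self.el_kd["L"])
        return (kd - base).rename("delta_log2el")


def _profile(f: int, mu: float, sd: float | None = None) -> np.ndarray:
    """Unimodal fraction-weight profile centred at fraction index mu."""
    sd = sd if sd is not None else f / 5.0
    w = np.exp(-0.5 * ((np.arange(f) - mu) / sd) ** 2)
    return w / w.sum()


def _in_blocks(n: int, blocks) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for lo, hi in blocks:
        mask[lo:hi] = True
    return mask


def gen_repliseq(
    n_windows: int,
    f_fractions: int,
    shifted_blocks,
    seed: int = 0,
    later_blocks=(),
    k9_blocks=(),
    depth: float = 100.0,
    bin_size: int = 50_000,
    domain_block: int = 20,
    chrom: str = "chrS",
) -> RepliseqSim:
    """Simulate WT/KO Repli-seq counts plus matched two-fraction EL data.

    The chromosome alternates early/late replication domains in blocks of
    ``domain_block`` windows. Block index ranges (half-open window-index
    pairs) plant perturbation effects:

    * ``shifted_blocks`` — late in WT, early in KO (RTdiff > 0);
    * ``later_blocks`` — late in WT, even later in KO (RTdiff < 0);
    * ``k9_blocks`` — late in both WT and KO (late-unchanged), but
      early-skewed in the knockdown two-fraction table, so the planted
      dlog2EL exceeds +1.

    Counts are Poisson(depth x fraction weight) per window and fraction.
    """
    if f_fractions < 2 or f_fractions % 2 != 0:
        raise ValueError("f_fractions must be even and >= 2")
    if n_windows < 1 or depth <= 0:
        raise ValueError("n_windows and depth must be positive")
    rng = np.random.default_rng(seed)
    f = f_fractions

    early_w = _profile(f, 0.15 * (f - 1))
    late_w = _profile(f, 0.85 * (f - 1))
    very_late_w = _profile(f, f - 1 + 0.4 * f, sd=f / 5.0)

    block_idx = np.arange(n_windows) // domain_block
    base_early = block_idx % 2 == 0
    shifted = _in_blocks(n_windows, shifted_blocks)
    later = _in_blocks(n_windows, later_blocks)
    k9 = _in_blocks(n_windows, k9_blocks)
    if (shifted & later).any() or (shifted & k9).any() or (later & k9).any():
        raise ValueError("planted block sets must not overlap")

    w_wt = np.where(base_early[:, None], early_w[None, :], late_w[None, :])
    w_wt[shifted | later | k9] = late_w  # planted blocks are late in WT
    w_ko = w_wt.copy()
    w_ko[shifted] = early_w
    w_ko[later] = very_late_w

    counts_wt = rng.poisson(depth * w_wt * f)
    counts_ko = rng.poisson(depth * w_ko * f)

    windows = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n_windows) * bin_size,
            "end": (np.arange(n_windows) + 1) * bin_size,
        }
    )
    wt = RepliseqMatrix(windows, counts_wt)
    ko = RepliseqMatrix(windows, counts_ko)

    # two-fraction E/L tables: baseline reflects the KO timing; the
    # knockdown flips planted k9 blocks to early.
    e_frac_base = np.where(
        base_early & ~(shifted | later | k9), 0.8, 0.2
    )
    e_frac_base[shifted] = 0.8
    e_frac_kd = e_frac_base.copy()
    e_frac_kd[k9] = 0.8
    el_depth = 2 * depth

    def el_table(e_frac):
        E = rng.poisson(el_depth * e_frac)
        L = rng.poisson(el_depth * (1 - e_frac))
        return pd.DataFrame({"E": np.maximum(E, 1), "L": np.maximum(L, 1)})

    el_baseline = el_table(e_frac_base)
    el_kd = el_table(e_frac_kd)

    domain_class = np.where(base_early, "early", "late").astype(object)
    domain_class[shifted] = "shifted-late-to-early"
    domain_class[later] = "shifted-late-to-later"
    domain_class[k9] = "k9-late-to-early"
    truth = windows.assign(
        domain_class=domain_class,
        is_shifted=shifted,
        is_later=later,
        is_k9=k9,
    )
    truth["weights_wt"] = list(w_wt)
    truth["weights_ko"] = list(w_ko)
    return RepliseqSim(wt, ko, el_baseline, el_kd, truth)


# ---------------------------------------------------------------------------
# regulome


@dataclass
class RegulomeSim:
    """Simulated regulatory landscape: TSS, promoters with histone-signal
    ranks, per-DBP peak sets, a 300-bin promoter signal matrix, and truth."""

    tss: pd.DataFrame
    fits: pd.DataFrame
    promoters: pd.DataFrame
    h3k4me3: pd.Series
    h3k27ac: pd.Series
    peak_sets: dict
    signal_matrix: pd.DataFrame
    truth: dict


def gen_regulome(
    n_genes: int,
    n_dbps: int,
    enriched_pairs,
    seed: int = 0,
    baseline_prob: float = 0.1,
    enrichment_fold: float = 5.0,
    rhythmic_fraction: float = 0.5,
    high_signal_fraction: float = 0.1,
    gene_ids=None,
    chrom: str = "chrS",
) -> RegulomeSim:
    """Simulate TSS, peak sets and promoter signal with planted enrichment.

    Each gene gets 1-3 TSS 10 kb apart from its neighbours; a promoter per
    gene is derived by the package's own clustering/selection. Each DBP
    binds any promoter with ``baseline_prob``; for planted (dbp, phase)
    pairs, rhythmic genes peaking in that phase are bound at
    ``enrichment_fold x baseline_prob`` (capped at 1). The signal matrix
    covers rhythmic-gene promoters (300 bins) with a fraction of planted
    high-occupancy rows.
    """
    from .promoters import build_promoters, select_promoter_per_gene

    if n_genes < 1 or n_dbps < 1:
        raise ValueError("n_genes and n_dbps must be positive")
    dbp_names = [f"dbp{chr(ord('A') + i % 26)}{i // 26 or ''}" for i in range(n_dbps)]
    for dbp, phase in enriched_pairs:
        if dbp not in dbp_names or phase not in DEFAULT_BIN_LABELS:
            raise ValueError(f"invalid planted pair ({dbp!r}, {phase!r})")
    if gene_ids is None:
        genes = [f"gene{i + 1:04d}" for i in range(n_genes)]
    else:
        genes = list(gene_ids)
        if len(set(genes)) != len(genes):
            raise ValueError("overlapping (duplicate) gene identifiers")
        if len(genes) != n_genes:
            raise ValueError("gene_ids length must equal n_genes")
    rng = np.random.default_rng(seed)

    # TSS: 1-3 starts per gene within a 2 kb neighbourhood
    rows = []
    for i, g in enumerate(genes):
        base = 5000 + i * 10_000
        for t in range(rng.integers(1, 4)):
            rows.append({"chrom": chrom, "start": base + int(rng.integers(0, 2000)),
                         "name": g, "tss": t})
    tss = pd.DataFrame(rows)

    rhythmic = rng.random(n_genes) < rhythmic_fraction
    peak_bin = np.where(
        rhythmic, rng.choice(DEFAULT_BIN_LABELS, n_genes), None
    ).astype(object)
    fits = pd.DataFrame(
        {"rhythmic": rhythmic, "peak_bin": peak_bin}, index=pd.Index(genes, name="gene")
    )

    clusters = build_promoters(tss)
    h3k4 = pd.Series(rng.gamma(2.0, 5.0, len(clusters)), index=clusters.index)
    h3k27 = pd.Series(rng.gamma(2.0, 5.0, len(clusters)), index=clusters.index)
    promoters = select_promoter_per_gene(clusters, h3k4, h3k27)

    planted = set(enriched_pairs)
    prom_by_gene = promoters.set_index("name")
    peak_sets = {}
    for dbp in dbp_names:
        prows = []
        for g in genes:
            if g not in prom_by_gene.index:
                continue
            phase = fits.loc[g, "peak_bin"]
            p = baseline_prob
            if fits.loc[g, "rhythmic"] and (dbp, phase) in planted:
                p = min(1.0, enrichment_fold * baseline_prob)
            if rng.random() < p:
                s, e = int(prom_by_gene.loc[g, "start"]), int(prom_by_gene.loc[g, "end"])
                ps = int(rng.integers(s, e - 50)) if e - s > 50 else s
                prows.append({"chrom": chrom, "start": ps,
                              "end": min(e, ps + 200), "name": dbp})
        peak_sets[dbp] = pd.DataFrame(
            prows, columns=["chrom", "start", "end", "name"]
        )

    rgenes = [g for g in genes if fits.loc[g, "rhythmic"]]
    sig = np.abs(rng.normal(0, 0.1, (len(rgenes), 300)))
    n_high = int(round(high_signal_fraction * len(rgenes)))
    high_idx = rng.choice(len(rgenes), n_high, replace=False) if n_high else []
    sig[list(high_idx), 40:260] += 1.0
    signal_matrix = pd.DataFrame(sig, index=pd.Index(rgenes, name="gene"))

    return RegulomeSim(
        tss=tss,
        fits=fits,
        promoters=promoters,
        h3k4me3=h3k4,
        h3k27ac=h3k27,
        peak_sets=peak_sets,
        signal_matrix=signal_matrix,
        truth={
            "enriched_pairs": sorted(planted),
            "high_promoters": [rgenes[i] for i in sorted(high_idx)],
        },
    )


# ---------------------------------------------------------------------------
# expression cohort


def gen_expression_cohort(
    n_samples: int,
    n_signature_genes: int,
    n_kzfps: int,
    planted_rho: float,
    seed: int = 0,
    n_subtypes: int = 2,
    noise_sd: float = 1.0,
    cancer_type: str = "typeA",
):
    """Simulate a tumor cohort with a latent proliferation axis.

    Signature genes load on a standard-normal latent axis with unit
    loading plus N(0, noise_sd^2) noise on the log2 scale; the first
    designated KZFP correlates with the axis at the planted Spearman
    strength (via the Gaussian-copula conversion r = 2*sin(pi*rho/6)),
    the remaining KZFPs are independent noise. Subtype labels add a mean
    shift to signature genes that per-subtype z-scoring must remove.

    Returns (expr_cpm DataFrame, meta DataFrame, truth dict).
    """
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    if abs(planted_rho) > 1:
        raise ValueError("|planted_rho| must be <= 1")
    rng = np.random.default_rng(seed)
    samples = [f"sample{i + 1:04d}" for i in range(n_samples)]
    subtypes = [f"subtype{(i % n_subtypes) + 1}" for i in range(n_samples)]
    z = rng.normal(0, 1, n_samples)
    shift = np.array([int(s[-1]) for s in subtypes], dtype=float)

    sig_genes = [f"ccg{i + 1:03d}" for i in range(n_signature_genes)]
    logx = (
        6.0
        + z[None, :]
        + shift[None, :]
        + rng.normal(0, noise_sd, (n_signature_genes, n_samples))
    )

    kzfps = [f"kzfp{i + 1:03d}" for i in range(n_kzfps)]
    r = 2 * np.sin(np.pi * planted_rho / 6)  # Pearson giving the target Spearman
    logk = 6.0 + rng.normal(0, 1, (n_kzfps, n_samples))
    if n_kzfps:
        logk[0] = 6.0 + r * z + np.sqrt(max(0.0, 1 - r**2)) * rng.normal(
            0, 1, n_samples
        )

    expr = pd.DataFrame(
        np.vstack([logx, logk]),
        index=sig_genes + kzfps,
        columns=samples,
    )
    cpm = np.maximum(2.0**expr - 1.0, 0.0)
    meta = pd.DataFrame(
        {"sample": samples, "subtype": subtypes, "cancer_type": cancer_type}
    )
    truth = {
        "latent_axis": pd.Series(z, index=samples),
        "signature_genes": sig_genes,
        "kzfps": kzfps,
        "planted": {kzfps[0]: planted_rho} if n_kzfps else {},
    }
    return cpm, meta, truth


# ---------------------------------------------------------------------------
# deep mutational scan


def gen_dms_table(domain_length: int, seed: int = 0, wt_value: float = 100.0):
    """Simulate a single-mutant silencing DMS of a KRAB-like domain.

    One wild-type row (residue "WT", position 0) plus one row per
    (position, substitute residue): domain_length x 19 mutant rows. A
    random third of positions are critical — substitutions there lose most
    silencing (ratios ~0.1-0.4); elsewhere ratios sit near 1. All values
    are positive.

    Returns (DataFrame[position, residue, value], wt_sequence).
    """
    if domain_length < 1:
        raise ValueError("domain_length must be >= 1")
    rng = np.random.default_rng(seed)
    wt_seq = "".join(rng.choice(list(AMINO_ACIDS), domain_length))
    critical = rng.random(domain_length) < 1 / 3
    rows = [{"position": 0, "residue": "WT", "value": wt_value}]
    for pos in range(1, domain_length + 1):
        wt_aa = wt_seq[pos - 1]
        for aa in AMINO_ACIDS:
            if aa == wt_aa:
                continue
            if critical[pos - 1]:
                ratio = rng.uniform(0.1, 0.4)
            else:
                ratio = np.exp(rng.normal(0, 0.1))
            rows.append(
                {"position": pos, "residue": aa, "value": wt_value * ratio}
            )
    return pd.DataFrame(rows), wt_seq
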