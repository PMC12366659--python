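# chronocycle

Statistical machinery for mapping transcription factors onto human cell
cycle regulation: cosinor chronograms of cell cycle expression,
phase-resolved promoter-binding enrichment, Monte-Carlo detection of
perturbation-induced cell cycle imbalances, and Repli-seq
replication-timing indices with Gaussian-mixture shift classification.
Every stage ships with a synthetic-data generator with known ground truth,
so the whole pipeline is testable without external datasets.

## Who it is for

Computational biologists analysing (a) bulk RNA-seq of FACS-sorted cell
cycle fractions, (b) Perturb-seq style screens with per-cell cell cycle
phase estimates, (c) multi-fraction or two-fraction Repli-seq, and
(d) promoter-level ChIP-seq peak and signal data.

## The models

**Cosinor chronogram.** For each gene, log-normalized expression over the
eight cell cycle bins (eG1, lG1, G1/S, S1, S2, G2, G2/M, M) is fitted with

    Y(t) = M + A·cos(2πt/T + φ) + δ_batch + ε,  T = 8,

linearised as `Y = M + β·cos(2πt/T) + γ·sin(2πt/T) + δ` with
`β = A·cos φ`, `γ = −A·sin φ`. Rhythmicity is an F-test of the harmonic
pair against the intercept+batch null, BH-adjusted across genes
(adj. p < 0.05). Genes peaking in M-to-S1 are G1-centered (G1-c), the rest
G2-centered (G2-c).

**Imbalance test.** Per-cell phases on [0, 2π) are binned into five
intervals (M/eG1, lG1, G1/S, S, G2/M with breaks 0, 3π/8, 7π/8, 7π/6,
13π/8, 2π). The non-targeting control's proportions parameterise a
reference multinomial; sampling it 1e5 times at each condition's cell
count gives per-bin empirical tails `p_greater` (accumulation when ≤ 0.05)
and `p_smaller` (attrition).

**RT index.** Smoothed, row-normalized Repli-seq percentages
`x = (x1..xf)` over f S-phase fractions are summarised as
`RTi = log2((a·b)/(u·v))` with `a` the early half, `b = (f/2,…,1)`,
`u` the late half, `v = (1,…,f/2)`; positive = early replicating, a
uniform profile gives exactly 0. Knockout-minus-wild-type RTdiff values
are clustered with a 3-component Gaussian mixture; near-zero-component
windows that are late in wild type are late-unchanged (LU), and
two-fraction Δlog2(E/L) values beyond ±1 call late-to-earlier /
late-to-later shifts.

**Promoter enrichment.** TSS clusters (<1 kb gaps, ±500 bp extension)
define promoters; Fisher exact tests ask whether genes peaking in a phase
are over-represented among peak-bound promoters, with a rank-based
phase-specificity score (median rank of the 8 adjusted p-values divided by
the rank in the phase at hand).

## Worked example

```python
import numpy as np
from chronocycle import CosinorModel
from chronocycle.simdata import gen_chronogram

chron, truth = gen_chronogram(n_genes=300, n_rhythmic=150, n_batches=2,
                              reps_per_bin=3, noise_sd=0.2, seed=7)
res = CosinorModel(chron).fit()
print(res.summary().loc["gene0001"])
print(f"{len(res.rhythmic_genes)} of {len(res.table)} genes rhythmic")
```

prints

```
mesor          7.049026
amplitude      0.991261
acrophase      3.988674
acr            5.078537
t_star         2.921463
F_stat       316.089544
p_raw               0.0
p_adj               0.0
rhythmic           True
peak_bin           G1/S
cc_class           G1-c
Name: gene0001, dtype: object
151 of 300 genes rhythmic
```

`gene0001` was simulated with mesor 7.00, amplitude 1 and acrophase 4.03
rad: the fit recovers all three to within the noise (M̂ = 7.05,
Â = 0.99, φ̂ = 3.99), places the expression peak at t\* ≈ 2.92 (bin
G1/S, hence a G1-centered gene), and the F-test calls it rhythmic; 151
genes are called rhythmic against 150 planted at this noise level. The same pattern — simulate with truth, fit, compare — works
for the imbalance screen (`ImbalanceModel`), replication timing
(`RTShiftModel`) and the promoter/signature scores.

A CLI mirrors the library:

```
chronocycle simulate chronogram --n-genes 1000 --seed 1 --out-dir sim/
chronocycle chronogram fit --expr sim/expression.tsv --meta sim/samples.tsv --out fits.tsv
chronocycle imbalance run --phases phases.tsv --control non-targeting --out imb.tsv
```

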