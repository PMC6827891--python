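# drynet

Differential regulatory-network modeling and characterization from short
time-course expression data.

When a drug works in one cancer cell line and fails in another, the
difference is often not a single gene but a rewired regulatory program:
resistant cells mount an *adaptive* response — expression transiently
changes and then returns toward baseline — where sensitive cells change
monotonically and stay changed. `drynet` reconstructs a gene regulatory
network (GRN) for each condition from a handful of timepoints (e.g.
0/6/12/24/48 h after treatment), extracts the **differential network** of
regulatory edges present only in the resistant state, and ranks its genes
as candidate resistance drivers. It is aimed at computational biologists
analyzing paired sensitive/resistant time-course RNA-seq experiments.

## The model

Expression dynamics are modeled as a sparse linear ODE per gene,

```
dx_i/dt = Σ_j e_ij · a_ij · x_j + b_i
```

where `a_ij` is the signed strength of regulator *j* on target *i*, `b_i`
absorbs degradation/basal effects, and `E = (e_ij)` is a binary prior mask
from an initial correlation network. The pipeline:

1. **TCG selection** — keep temporally changing genes: `max_k u_k ≥ ζ` and a
   pairwise fold change `≥ δ` (defaults ζ = 10, δ = 5, pseudocounted).
2. **Interpolation** — shape-preserving piecewise-cubic Hermite (PCHIP) onto
   `n = 100` uniform points; forward differences give the response
   `y_i(t_k)`.
3. **Inference** — per-gene L1-penalized regression of `y_i` on the masked
   regulator trajectories; penalty `λ_i` by 10-fold CV (minimum mean CV
   error); edges pruned by sweeping a strength threshold θ and minimizing
   `BIC = N log(RSS/N) + p log N`.
4. **Differential network** — edges present in the resistant GRN and absent
   from the sensitive one, `D = G(V*, E_R \ E_S)`.
5. **Prioritization** — per gene: hub score (principal eigenvector of
   `A·Aᵀ` of the differential adjacency), local network entropy change
   `ΔS_i = S_i^R − S_i^S` with `S_i = −Σ_j p_ij log2 p_ij`,
   `p_ij = |a_ij|/Σ|a_ij|`, and the adaptation score
   `D_i = R_i^R / R_i^S` from relative responses
   `R_i = (x_i(T) − x_i(0))/x_i(0)` at `T = 48 h`. The importance
   `I_i` is the normalized rank sum of the three ranks (`Σ I_i = 1`).
6. **Prediction** — a test cell line is classified sensitive/resistant by
   dynamic-time-warping (DTW) similarity of marker-gene temporal patterns,
   with an exact one-tailed Wilcoxon signed-rank test on the paired
   per-gene distance differences, plus a 1000-draw bootstrap test for
   marker-panel significance and an importance-weighted L1 logistic
   model (`drynb`) for cohort-level sensitivity scores.

A linear-ODE simulator with benchmark generators (five-node
feedback/crosstalk network, 100-network ensembles, a paired
sensitive/resistant scenario with planted feedback loops) provides ground
truth for validation, together with an absolute-Pearson-correlation
baseline and ROC edge-recovery scoring.

## Worked example

```python
from dataclasses import replace
from drynet import analyze_pair, classify_cell_line, RunConfig
from drynet.synthetic import make_resistance_scenario, simulate_timecourse

scen = make_resistance_scenario(seed=0)          # 8-gene ground truth pair
sens = simulate_timecourse(scen.sensitive)       # sensitive arm, 0-48 h
res = simulate_timecourse(scen.resistant)        # resistant arm (added loops)

result = analyze_pair(sens, res, RunConfig(seed=0, rho0=0.0))
print("differential edges:", result.diff.n_edges, "over", result.diff.n_genes, "genes")
cols = ["hub", "delta_entropy", "abs_adaptation", "importance", "final_rank"]
print(result.importance[cols].round(3).to_string())

test = simulate_timecourse(replace(scen.sensitive, seed=99))
report = classify_cell_line(test, result.sens_expr, result.res_expr,
                            scen.planted_genes[:5])
print(f"label={report.label}  D_S={report.D_S:.3f}  D_R={report.D_R:.3f}  "
      f"p={report.p_value:.5f}")
```

Output:

```
differential edges: 13 over 6 genes
        hub  delta_entropy  abs_adaptation  importance  final_rank
gene
G4    0.997          0.955           0.179       0.238           1
G2    0.069          1.414           0.639       0.206           2
G3    0.023          1.493           0.761       0.190           3
G1    0.001          1.088           0.198       0.175           4
G5    0.000          0.562           0.238       0.111           5
G6    0.001          0.207           0.812       0.079           6
label=sensitive  D_S=0.220  D_R=5.308  p=0.03125
```

The scenario plants negative-feedback loops on G1–G5 in the resistant arm
only; four of the five planted genes top the importance ranking (high hub
weight and entropy gain from the acquired regulators, low |adaptation|
because their resistant-arm expression returns toward baseline). The DTW
classifier compares a freshly simulated sensitive-like test line against
both references over the five planted marker genes: all five per-gene
distances favor the sensitive reference, the exact one-tailed signed-rank
test gives its minimal p-value 1/32 = 0.03125, and the line is called
sensitive.

## Command line

Each stage is exposed as a subcommand composing via the filesystem:

```sh
drynet simulate --kind scenario --seed 0 --outdir data/
drynet tcg data/scenario_sensitive.tsv -o tcg_sens.tsv
drynet rank --sensitive data/scenario_sensitive.tsv \
            --resistant data/scenario_resistant.tsv --outdir out/
drynet predict --test data/scenario_sensitive.tsv \
               --sensitive out/tcg_sensitive.tsv \
               --resistant out/tcg_resistant.tsv --markers G1,G2,G3,G4,G5
drynet benchmark --mode five-node --n 20
```

Expression matrices are TSV/CSV with a gene-id first column and timepoint
headers (`0h, 6h, 12h, 24h, 48h` or bare numbers); networks export as edge
lists, GraphML (Cytoscape) or SIF.

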