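# psgsurv

Sex-stratified survival analysis of **pregnancy-specific glycoprotein
(PSG)** gene-panel expression in lung adenocarcinoma-like cohorts.

The ten human PSG genes (PSG1–PSG9, PSG11) are essentially silent in
normal tissue but sporadically re-expressed in tumors, where bulk RNA-seq
reads exactly 0 for most samples and a positive value for a minority.
This package implements, and makes testable end-to-end on synthetic
cohorts, the analysis chain built around the binarized **PSG+/− status**:
a sample is *panel-negative* when every gene of a panel has expression
value exactly 0, and *panel-positive* otherwise. The scientific question
is whether panel positivity carries *sex-specific* prognostic
information — a hazard increase in women but not in men.

## What is implemented

| Stage | Module | Method |
|---|---|---|
| Synthetic cohorts | `psgsurv.simulate` | one-factor Gaussian copula with per-gene zero-inflation; exponential survival with sex-specific hazard; Dirichlet immune scores; PPI fixture graph |
| I/O + alignment | `psgsurv.io` | TSV expression/clinical/immune tables, GMT gene sets, edge lists |
| Panel binarization | `psgsurv.status` | all-zero rule, OR-decomposable, monotone in panel size |
| Core statistics | `psgsurv.stats` | KM/log-rank, BH-FDR, Pearson χ² (no continuity correction), Wilcoxon rank-sum, Spearman, Cox PH (Efron ties), Harrell's C |
| Combination search | `psgsurv.combos` | all C(10,2)=45 and C(10,3)=120 panels, log-rank per sex, BH within each size family, external validation |
| Immune association | `psgsurv.immune` | gene × cell-type Spearman grid; per-type rank-sum between status groups |
| DE + enrichment | `psgsurv.dge` | per-gene rank-sum DE with log₂ fold-change rule; hypergeometric over-representation; weighted-KS GSEA with gene-set-permutation NES |
| Graph transport | `psgsurv.transport` | W1 (Earth Mover's) distance on a PPI network via the Beckmann flux LP; survival-status pair-class analysis |
| Prediction | `psgsurv.predict` | elastic-net Cox (L1 ratio 0.5, penalty by 10-fold CV concordance), PCA feature blocks, stratified splits |
| Orchestration | `psgsurv.pipeline` | `run_all` — every stage from one master seed |

The graph distance is the network Earth Mover's distance in its
minimum-total-flux (Beckmann) form,

```
W1(μ, ν) = min_u { Σᵢ |uᵢ|  :  μ − ν − D u = 0 }
```

with `D` the signed node×edge incidence matrix and `uᵢ` a flux on edge
`i` (unit edge lengths). On a connected graph this equals the
Kantorovich optimal-transport cost under the shortest-path ground
metric, which the test suite verifies by an independent LP.

## Worked example

The `analysis/` scripts run the whole study on a synthetic cohort that
emulates the motivating LUAD data (506 samples, 271 female, per-gene
zero fractions and correlation structure matched to the published
cohort, hazard ratio 2.45 for panel-positive females only):

```bash
python analysis/01_simulate_cohort.py   --seed 1 --outdir results
python analysis/02_cohort_summary.py    --outdir results
python analysis/03_signature_search.py  --outdir results
python analysis/04_cox_models.py        --outdir results
python analysis/05_immune_association.py --outdir results
python analysis/06_dge_enrichment.py    --seed 1 --outdir results
python analysis/07_graph_wasserstein.py --seed 1 --outdir results
python analysis/08_predictive_models.py --seed 1 --outdir results
```

With `--seed 1` this prints, among other lines:

```
discovery cohort: 506 samples (271 female), panel-positive fraction 0.320
per-gene log-rank significant at .05: {'female': 4, 'male': 0}
female: best panel PSG3+PSG7 (log-rank p = 3.89e-11, FDR = 1.75e-09)
male: best panel PSG2+PSG9 (log-rank p = 0.0762, FDR = 0.902)
univariate bPSG3+PSG7: HR = 3.36 (p = 4.1e-10)
8 of 22 cell types differ at FDR < 0.05 between panel status groups
top over-represented set: PANEL_RESPONSE_UP (p = 5.87e-65, FDR = 2.93e-63)
GSEA: ES = 1.000, NES = 1.371, p = 0.0010
female: internal C = 0.638, external C = 0.503
```

Reading this: only the female stratum shows per-gene survival
separation (4 of 10 genes) and a strongly significant combination
signature; the male search finds nothing after FDR control. The immune
contrast recovers the seven injected cell-type shifts (plus one
borderline extra), the panel-coupled gene block dominates the
enrichment, and the internal female C-index (~0.64) sits near the value
reported for the real cohort while the tiny external cohort (36 women)
makes the external C-index noisy seed to seed. The best panel itself
varies across seeds among combinations that group nearly the same
samples — the generating panel is PSG3+PSG7+PSG8, and a 2-gene subset of
it wins here; see `docs/methods.md` for why that degeneracy is intrinsic.

## Layout

- `src/psgsurv/` — the library (all computation lives here)
- `analysis/` — numbered narrative drivers writing `results/`
- `tests/` — pytest suite, including brute-force oracles
  (`tests/oracles.py`) for the log-rank permutation null, exact rank-sum
  enumeration, O(n²) concordance, hand-rolled BH and the Kantorovich LP
- `docs/methods.md` — modelling assumptions, parameter choices, and
  known limitations
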