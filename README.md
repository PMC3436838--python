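# longreg

Multi-task sparse regression of SNP dosages on longitudinal imaging
phenotypes.

Given feature matrices for the same subjects at `T` visits (`X_t`, features
x subjects) and one subject x SNP dosage matrix `Y`, the package fits a
coefficient matrix per visit, jointly regularized by

* a **row-group penalty** — the l2,1 norm of the mode-1 unfolding
  `[B_1 | ... | B_T]` — that selects imaging features with a common effect
  across all SNPs and all visits, and
* a **trace-norm penalty** on the same unfolding, favouring a low-rank
  coefficient structure that couples correlated SNP columns.

The objective

```
sum_t ||X_t' B_t - Y||_F^2  +  gamma1 * l21(unfold(B))  +  gamma2 * tracenorm(unfold(B))
```

is convex and is minimized by an iteratively reweighted least-squares
scheme: each sweep rebuilds two weight matrices from the current solution
(a diagonal one from the unfolded row norms, a matrix inverse square root
from the unfolding's Gram matrix) and then solves one symmetric
positive-definite linear system per visit.  The recorded objective
decreases monotonically; safeguarded Anderson extrapolation accelerates
the slow tail of heavily penalized problems without breaking that
guarantee.

## Layout

| module               | contents                                                                 |
|----------------------|--------------------------------------------------------------------------|
| `longreg.core`       | data types, unfolding, the two norms, the loss and full objective         |
| `longreg.solver`     | reweighted solver, weight matrices, stationarity diagnostics              |
| `longreg.baselines`  | per-visit least squares / ridge / lasso and the trace-norm-only ablation  |
| `longreg.evaluation` | seeded k-fold CV, per-SNP correlation + pooled RMSE, visit-prefix ablation |
| `longreg.markers`    | global and per-SNP feature rankings, support-recovery scoring             |
| `longreg.simdata`    | synthetic problems with row-sparse, low-rank ground truth                 |
| `longreg.io` / `cli` | TSV readers/writers and the `longreg` command line                        |

## Command line

All interchange files are tab-separated tables with a header row;
phenotype files carry subjects in rows (first column `subject_id`) and
features in columns, one file per visit, and the genotype file carries
subjects x SNPs (a FID/IID-style dosage export is also accepted).
Subjects are matched by id; mismatches are hard errors.

```bash
# synthetic end-to-end example
longreg simulate --d 50 --n 60 --t 4 --c 10 --seed 1 --out sim/

longreg fit  --pheno sim/pheno_t0.tsv --pheno sim/pheno_t1.tsv \
             --pheno sim/pheno_t2.tsv --pheno sim/pheno_t3.tsv \
             --geno sim/geno.tsv --gamma1 10 --gamma2 1 --out fit/

longreg cv     ... --method full --method rr --method lasso --folds 5 --out cv/
longreg ablate ... --method full --folds 5 --out ablation/
longreg rank   --coef fit/coefficients_t0.tsv ... --out rank/          # global
longreg rank   --coef fit/coefficients_t0.tsv ... --snp snp3 --out rank/
```

`fit` writes per-visit coefficient tables, the objective history and a
run summary (all knobs, iterations, convergence flag, stationarity
residual); `cv` writes per-fold and summary scores; `ablate` evaluates
growing visit prefixes; `rank` writes marker-ranking tables.  A YAML file
mirroring the flags can be passed via `--config` (explicit flags win).

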