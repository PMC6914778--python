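# dualreporter

Partitioning cell-to-cell variation in gene expression with two-color
reporter pairs, for quantitative biologists studying expression
heterogeneity in intact tissue (the motivating system is the *C. elegans*
intestine, imaged cell-by-cell in rings 1–4 across replicate animals).

## The decomposition

Isogenic cells in a uniform environment still express a gene at very
different levels. Measuring *pairs* of fluorescent reporters in the same
cells splits that variation into three bins with distinct molecular causes:

- **η²(γ) — intrinsic noise.** Uncorrelated variation between two
  differently colored copies of the *same* gene at equivalent loci
  (a **Type I** pair): stochastic promoter/transcript binding events and
  unequal allele access.
- **η²(P) — pathway/signaling noise.** Cell-to-cell differences in
  activation of a specific signaling pathway. Measured from a **Type II**
  pair (two *different* genes) as uncorrelated variation minus the average
  Type I intrinsic noise of the two genes.
- **η²(G) — protein expression capacity.** Correlated variation of
  distinctly regulated genes: a cell's general ability to express and
  maintain proteins. Measured as the Type II correlated variation.

For paired, group-normalized intensities (x_i, y_i), the moment estimators
are

    uncorrelated = mean((x_i − y_i)²) / (2·mean(x)·mean(y))
    correlated   = (mean(x_i·y_i) − mean(x)·mean(y)) / (mean(x)·mean(y))

and on mean-1 data they satisfy `correlated + uncorrelated =
(CV²(x) + CV²(y))/2` exactly. Cells are grouped by cell fate
(experiment × intestine ring) before normalization because each ring has
its own ratiometric setpoint for a gene pair; pooling rings masquerades
those fixed ratios as signaling noise (`pooled_vs_grouped` quantifies the
artifact). A green→red **fluorescent timer** module separates
production-driven from turnover-driven brightness differences: the
steady-state new/old ratio d/k_m is independent of the production rate, so
only turnover variation shifts the ratio between bright and dim animals.

Because real per-cell microscopy tables are not publicly deposited, the
package ships a generative simulator (`synth`) with median-1 lognormal
factors for animal- and cell-level capacity, pathway activation, allele
noise and measurement error. Every bin then has an exact closed form
(e.g. η²(G) = e^{σ_G²} − 1), which the test suite uses to validate the
estimators end to end.

## Worked example

```python
import dualreporter as dr

# Type II pair at the study scale: 3 experiments x 10 animals x 8 cells
params = dr.default_params("paper_like", experiment_type="typeII",
                           promoter_a="hsp-16.2", promoter_b="vit-2", seed=11)
cells = dr.simulate_cells(params)

# intrinsic noise from a Type I experiment on one of the promoters
type1 = dr.decompose_type1(dr.simulate_cells(
    dr.type1_params(params, "hsp-16.2", seed=12)))
gamma = {"hsp-16.2": type1.aggregate["eta2_gamma"],
         "vit-2": type1.aggregate["eta2_gamma"]}

res = dr.decompose_type2(cells, ("hsp-16.2", "vit-2"), gamma)
print({k: round(res.aggregate[k], 4)
       for k in ("eta2_G", "eta2_P", "eta2_gamma")})
```

prints

```
{'eta2_G': 0.1491, 'eta2_P': 0.0107, 'eta2_gamma': 0.0017}
```

i.e. at this sample size general expression capacity (η²(G) ≈ 0.15)
dominates pathway noise (≈ 0.01) and intrinsic noise (≈ 0.002) — most of
the cell-to-cell variation reflects how much protein a cell can make at
all, not which allele or pathway fired.

The same workflow is available from the shell:

```bash
dualreporter simulate --type II --seed 11 --out cells.csv
dualreporter run --config run.yaml         # full pipeline + summary.txt
dualreporter timer simulate --mode turnover --out timer.csv
```

and as a narrated sequence of drivers under `analysis/`
(`01_simulate_cells.py` → `05_timer_turnover.py`), each writing its tables
to `results/`.

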