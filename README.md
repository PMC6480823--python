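# bifacet

Covariance-structure models for general and specific ability factors.

`bifacet` fits three families of confirmatory factor models to moment
matrices — the classical **bifactor** model, the **correlated first-order
factor** model, and the **bifactor(S-1)** model (one specific factor
omitted, its facet promoted to reference factor) — each optionally extended
with criterion variables, either *correlating* with the factors or
*regressed* on them in a latent multiple regression. On top of the fitting
machinery it provides:

- **Identification diagnostics**: a numerical local-identification check
  (SVD rank of the implied-moment Jacobian over random admissible points)
  plus the exact analytic non-identification family of the equal-loadings
  extended bifactor model, where shifting the general-factor/criterion
  covariance by δ and every specific-factor/criterion covariance by −δ
  leaves the implied moments unchanged.
- **Mixed correlation estimation**: Pearson covariances among continuous
  variables, two-step polychoric correlations among ordinal variables and
  two-step polyserial correlations for mixed pairs, assembled into one
  hybrid moment matrix.
- **Seeded Monte-Carlo studies**: parameter recovery through the full
  raw-data → mixed-matrix → fit pipeline, and a standard-error inflation
  study showing how factor–criterion SEs in the free-loading extended
  bifactor model blow up as the population loadings approach equality.
- A **bundled example**: the 8-variable moment summary of six intelligence
  test halves (number series, verbal analogies, unfolding; odd-even split)
  and two school grades on the latent-response metric (n = 219), together
  with catalog builders (`fig1a_equal` … `fig3c_refNS`) for every model
  variant studied on it.

## Quick start

```python
import bifacet as bf

moments = bf.ability_grades()                  # bundled 8x8 moment matrix
model = bf.make_model("fig2b")                 # correlated first-order + criteria
res = bf.fit(model, moments)                   # ULS fit
sol = bf.standardize(res)
print(res.df, sol.factor_corr.loc["AN", "Math"])

report = bf.local_identification_rank(bf.make_model("fig1b_equal"))
print(report.deficiency)                       # 2: one per criterion
```

## Command line

```bash
bifacet reproduce --out tables          # fit the whole catalog to the bundled
                                        # moments; emits table2..table8.tsv,
                                        # identification.json, fits.json
bifacet fit --model fig3b --ref AN --out out
bifacet identify --model fig1b_equal --out out
bifacet simulate --study recovery --config study.yaml --out sim
bifacet simulate --study se-inflation --config study.yaml --out sim
```

Exit codes: 0 success, 2 config error, 3 convergence failure,
4 identification gate. Every run writes a `manifest.json` with the config
echo, package versions, and seed; identical configs and seeds produce
byte-identical artifacts.

## Notes on estimation

The default estimator is ULS on the hybrid covariance/correlation matrix;
DWLS (user weights) and a normal-theory ML discrepancy are available.
Standard errors use a sandwich formula with a normal-theory moment
covariance. They approximate — but do not replicate — raw-data WLSMV
standard errors, so SE-based conclusions are about significance *patterns*,
not digit-level agreement. Degrees of freedom count nonredundant moments
(excluding the fixed unit diagonals of latent-response criteria) minus free
parameters after equality constraints. Heywood cases (negative variance
estimates) are reported as warnings, not errors, so that pathological
models remain fittable for demonstration purposes.
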