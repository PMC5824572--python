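# hic3d

Maximum-likelihood reconstruction of 3D chromosome structures from Hi-C
contact matrices.

Hi-C experiments count spatial contacts between pairs of genomic bins along a
chromosome, producing a square symmetric matrix of interaction frequencies
(IF). `hic3d` turns such a matrix into an ensemble of 3D bead models: contact
frequencies are converted to target spatial distances through the inverse
power law D = 1/IF^α, and bead coordinates are found by maximizing a Gaussian
log-likelihood of the observed distances by gradient ascent. The conversion
factor α is not assumed — it is estimated from the data by sweeping a grid and
keeping the value whose best model correlates most with the input.

## The model

For restrained bin pairs with targets D_1..D_n and model (Euclidean)
distances D_i^s, residuals are modeled as i.i.d. Gaussian with one global
standard deviation σ. Profiling σ at its MLE, σ = √(SSE/n) with
SSE = Σ (D_i^s − D_i)², gives the objective

    L(S) = −n/2 − n · ln σ

which is maximized over bead coordinates S by gradient ascent
S ← S + λ ∇L(S), with a step-decay learning-rate schedule
λ = initial_λ · 0.5^((1+epoch)/70) by default, or by AdaGrad per-coordinate
steps λ/√(G_t + ε) (the variant intended for noisy inputs, combined with a
low-IF pre-filter). Models are scored with distance-based correlation and
error metrics: dSCC (Spearman), dPCC (Pearson) and dRMSE after full
Procrustes superposition.

The package is organized as a scikit-learn-style estimator, `HiCStructure`
(fit a square contact matrix, read off `embedding_`, `alpha_`, `dscc_`), with
the underlying operations exposed as plain functions (`build_restraints`,
`optimize_gradient_ascent`, `ice_normalize`, `dscc`, ...) and a `hic3d`
command-line tool (`build`, `normalize`, `evaluate`, `simulate`). A synthetic
benchmark generator (`hic3d.simulate`) produces worm-like ground-truth
chains, graded structural-variability ensembles and noisy contact maps for
validation.

## Worked example

```python
import hic3d

# a self-contained benchmark: one 50-bead chain, exact (noise-free) map
truth = hic3d.generate_benchmark(
    n_beads=50, alpha_true=0.5, noise_level=0, sv_level=0, n_copies=1, seed=3
)

est = hic3d.HiCStructure(alphas=[0.1, 0.3, 0.5, 1.0, 1.5, 2.0], random_state=1)
est.fit(truth.contact_map)
print("selected alpha:", est.alpha_)
print("dSCC to input:", round(est.dscc_, 5))
print("dSCC vs truth:", round(
    hic3d.structure_dscc(est.structure_, truth.true_structures[0]), 5))
```

prints

```
selected alpha: 0.5
dSCC to input: 0.99995
dSCC vs truth: 0.99995
```

The sweep recovers the generating conversion factor (0.5) exactly, and the
representative model's pairwise distances are rank-identical to the true
chain's up to numerical residue — on noise-free input the likelihood optimum
reproduces the target distances, so dSCC approaches 1 and the
Procrustes-aligned distance error is ~0.

The same pipeline from the shell:

```sh
hic3d simulate --beads 50 --noise 0 --sv 0 --copies 1 --seed 3 -o sim/
hic3d build -i sim/contact_map.txt -o out/ --alphas 0.1,0.3,0.5,1.0,1.5,2.0 --seed 1
hic3d evaluate --model out/representative.xyz.tsv --truth sim/truth_000.xyz.tsv
```

`build` writes a per-entry `summary.tsv` (alpha, seed, iterations, final
log-likelihood, dSCC), one `.xyz.tsv` structure per optimization, the
representative structure (also as a PDB pseudo-atom model for molecular
viewers), and a `manifest.json` that makes the run reproducible
bit-for-bit.

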