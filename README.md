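# fcgraph

Graph-theoretical analysis of resting-state fMRI functional connectomes,
built for case-control studies of whole-brain network topology — the kind
of analysis used to characterise epileptic encephalopathies such as
infantile spasms, where patients' functional networks shift toward random
topology (lower normalised clustering γ, path length λ, small-worldness σ
and local efficiency E_loc; higher global efficiency E_glob) and lose
intra-modular connectivity in the default mode network (DMN).

The package takes extracted ROI time series (not image volumes) and runs
the complete chain:

1. **Signal cleaning** — linear detrend, ideal 0.01–0.08 Hz band-pass,
   OLS nuisance regression (24-parameter motion expansion plus
   global/WM/CSF columns), and scrubbing of frames with framewise
   displacement FD > 0.5 mm by linear interpolation.
2. **Network construction** — Pearson correlation between ROI pairs,
   Fisher r-to-z, then binarisation keeping the strongest positive-z edges
   at each sparsity level S ∈ [0.05, 0.40] (18 levels), so every subject's
   graph has the same edge count at a given S.
3. **Graph metrics** — clustering coefficient C_p, characteristic path
   length L_p (harmonic-mean convention), global/local efficiency, and
   normalisation against degree-preserving Maslov–Sneppen rewired nulls:
   γ = C_p/C_p^rand, λ = L_p/L_p^rand, σ = γ/λ. A network is small-world
   when γ > 1 and λ ≈ 1, i.e. σ > 1. Each metric's curve over the grid is
   summarised by its trapezoid-rule AUC.
4. **Modular analysis** — averaged Fisher-z strength within and between
   six a-priori functional systems (cingulo-opercular, fronto-parietal,
   default, sensorimotor, occipital, cerebellum), plus data-driven Newman
   spectral modularity Q per subject and threshold.
5. **Group inference** — covariate-adjusted comparisons
   (value ~ group + age + sex), Benjamini–Hochberg FDR, Hedges' g with
   Cohen-style magnitude labels, partial correlations of network measures
   with clinical variables, and a demographic χ² test.

Because patient fMRI data of this kind are generally not publicly
deposited, the package also ships a **synthetic-cohort generator** that
emulates the study conditions: 160-ROI, 130-frame (TR = 2 s) Gaussian
BOLD surrogates with block-modular covariance, motion traces with
FD spikes, a planted intra-DMN correlation reduction in patients, and
seizure frequencies negatively linked to each patient's realised intra-DMN
connectivity — a known ground truth the pipeline must recover.

## Worked example

```python
import fcgraph as fg

cohort = fg.generate_cohort(master_seed=7)
subj = cohort.subjects[0]  # a patient

cleaned, report = fg.clean_subject(subj.timeseries, subj.motion, subj.nuisance)
print(f"{subj.record.subject_id}: scrubbed {len(report.replaced_indices)} of "
      f"{cleaned.n_frames} frames")

cm = fg.pearson_matrix(cleaned)
stack = fg.sparsity_binarize(cm)
print(f"edges at S=0.05: {stack.edge_counts[0]}, at S=0.40: {stack.edge_counts[-1]}")

sw = fg.small_world_normalize(stack.adjacency[5], n_null=20, seed=1)
print(f"S={stack.grid.values[5]:.3f}: Cp={sw.cp:.3f} Lp={sw.lp:.3f} "
      f"gamma={sw.gamma:.2f} lambda={sw.lam:.2f} sigma={sw.sigma:.2f}")

dmn = fg.block_strength_curve(cm, stack, cohort.partition, ("default", "default"))
print(f"intra-DMN strength AUC: {dmn.auc:.4f}")

chi2, p = fg.chi_square_2x2([[5, 12], [13, 21]])
print(f"sex ratio chi2={chi2:.3f}, p={p:.3f}")
```

prints

```
sub-P01: scrubbed 5 of 130 frames
edges at S=0.05: 636, at S=0.40: 5088
S=0.153: Cp=0.433 Lp=1.864 gamma=2.29 lambda=1.06 sigma=2.17
intra-DMN strength AUC: 0.0518
sex ratio chi2=0.386, p=0.534
```

The subject's network at S ≈ 0.15 is strongly small-world (γ = 2.29 with
λ ≈ 1, so σ = 2.17 > 1): far more clustered than its degree-matched random
nulls at essentially the same path length. The edge counts are fixed by
the sparsity grid (round(S·N(N−1)/2) for N = 160), the intra-DMN AUC is
the threshold-free summary of that block's averaged z strength, and the χ²
is the demographic sex-ratio test for a 17-vs-34 cohort with 5 and 13
girls.

End-to-end runs go through `fg.run_analysis(config)` or the CLI:

```bash
fcgraph synth-cohort --out cohort/ --seed 1
fcgraph run-all --cohort-dir cohort/ --seed 1
```

which writes metric curves, AUC tables, block strengths, modularity,
group statistics, correlations and a reproducibility manifest as CSV/JSON.

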