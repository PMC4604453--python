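# e2dyn

Cross-variant essential-dynamics comparison of protein conformational
ensembles.

## The problem

Point mutations and phosphorylation at a single catalytic-cleft position can
switch an enzyme between active and inactive states without any visible change
in its fold. Ub/Ubl-conjugating (E2) enzymes are the motivating case: the
conserved catalytic-cleft Ser/Asp position (the **CES/D site**, hHR6A Ser120 /
Ube2I Asp127) holds an aspartate in constitutively active family members and a
phosphorylatable serine — almost always followed by a proline, so matching the
minimal Cdk phosphorylation consensus — in kinase-regulated ones. Whether such
a substitution perturbs the enzyme's *native dynamics*, and how it repositions
the substrate lysine relative to the catalytic cysteine, are questions asked of
multi-replicate conformational ensembles (typically molecular-dynamics
trajectories) of many sequence variants at once.

`e2dyn` packages the complete comparison workflow:

* **Essential dynamics.** Frames are least-squares fitted (Kabsch) to an
  iterated mean and the covariance matrix **C** of Cα positional fluctuations
  is diagonalised, `C = V Λ Vᵀ`. The leading eigenvectors (PCs) span the
  essential subspace of largest-amplitude concerted motions.
* **Cross-variant comparability.** Homologous systems are mapped onto a common
  Cα core through a multiple sequence alignment (only columns ungapped in all
  systems), so every system's PCA lives in the same 3M-dimensional space.
* **Eigenvalue crossing-over.** A motion at PC *i* in one system may surface at
  PC *j* ≠ *i* in another; comparing PCs index-by-index is then misleading. The
  crossing diagnostic reports the overlap profile `(v₁·wⱼ)²`, j = 1…k, and the
  best-matching index.
* **RMSIP.** Subspace similarity over the first D PCs (default D = 20):
  `RMSIP = sqrt( (1/D) Σᵢ Σⱼ (vᵢ·wⱼ)² )`, 1 for identical spans, 0 for
  orthogonal ones; class-wise distributions are summarised as Tukey boxplot
  statistics.
* **Cosine content** of PC projections, `cᵢ = (2/T) (∫ pᵢ(t) cos(iπt/T) dt)² /
  ∫ pᵢ²(t) dt` — values near 1 are the signature of random-diffusion-like,
  undersampled motion; converged sampling stays low (< 0.3).
* **Geometry.** Shrake–Rupley solvent accessible surface of the catalytic
  cysteine side chain, substrate-lysine distances (minimum heavy-atom or named
  atom pair), and contact/H-bond persistence (fraction of frames below the
  0.48 nm ion-pair cutoff).
* **Activity model.** An exponential relation `f(x) = b·e^(−c·x)` between
  Ub-conjugation activity and the mean Cys–Lys distance x, fitted by nonlinear
  least squares and scored by the Pearson correlation of observed vs fitted
  activities.
* **Motif classification.** Per-sequence CES/D-site calls (DP, SP, EP, SA, EA,
  E, other) and the Cdk consensus flag (S/T immediately followed by P in
  sequence space).

Because real multi-microsecond trajectory data cannot ship with a package, the
`synthetic` module generates Gaussian conformational ensembles with a
*prescribed* eigen-spectrum and *controlled* inter-variant subspace rotation —
every downstream statistic has an analytic ground truth (a variant rotated by
angle *a* has expected RMSIP |cos a| against the reference).

## Worked example

Generate a synthetic family (reference + three variants rotated by 0.3, 0.7,
1.2 rad; two replicates × 500 frames each) and compare the recovered class
medians against construction:

```sh
cd analysis
python 01_generate_ensembles.py
python 02_essential_dynamics.py
python 03_subspace_comparison.py
```

Output of the comparison step:

```
crossing-over of reference PC1:
  mild       best match PC1 (overlap 0.908)
  moderate   best match PC1 (overlap 0.580)
  strong     best match PC1 (overlap 0.129)
class medians vs construction:
  mild       median RMSIP 0.9553 (ground truth 0.9553)
  moderate   median RMSIP 0.7648 (ground truth 0.7648)
  strong     median RMSIP 0.3623 (ground truth 0.3624)
cosine content of replicate PCs: max 0.011 (all below the 0.30 sampling-quality threshold)
```

The measured medians reproduce the constructed |cos a| to four digits, the
reference PC1 overlap decays with perturbation strength, and the low cosine
content confirms the ensembles are well sampled. Drivers `04`–`06` add the
geometry measurements, the activity-fit recovery (`b = 136.28`, `c = 9.12`
recovered exactly from noiseless points, medians within 0.3% under 5% noise)
and the CES/D motif scan. All tables land in `results/`.

The same stages are scriptable through the `e2dyn` CLI (`run`,
`generate-synthetic`, `pca`, `compare`, `geometry`, `fit-activity`,
`ces-scan`) or the library API (`e2dyn.run_pipeline` on a YAML config).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the synthetic family from the given seed, runs the full pipeline
end to end (trim/concatenate → MSA mapping → per-system PCA → crossing +
RMSIP class statistics + cosine content → SASA → distances/persistence →
activity fit), prints the pairwise RMSIP values with their analytic ground
truths, and writes the results manifest to `--out`.

## Layout

```
src/e2dyn/        library: synthetic, structure_io, mapping, essential,
                  compare, geometry, activity, pipeline, cli
analysis/         numbered narrative drivers over the library
tests/            unit, property and acceptance suites
scripts/          acceptance entry point
docs/methods.md   models, parameters, numerical choices, limitations
```
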