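# Methods

This note records the models implemented in `e2dyn`, the parameters that
matter, what the synthetic generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Essential dynamics

An ensemble of F frames over M mapped Cα atoms is reduced to the covariance
matrix of positional fluctuations. Frames are superposed by weighted Kabsch
fits to an **iterated mean**: fit all frames to frame 1, average, refit all
frames to that average, re-average (two passes). The covariance

C = (1/F) Σₜ (xₜ − x̄)(xₜ − x̄)ᵀ,  C ∈ ℝ^{3M×3M}

is diagonalised with `eigh`; eigenvalues are sorted descending and clamped to
zero below a −10⁻¹⁰·λ₁ tolerance. Sign indeterminacy is fixed by making each
eigenvector's largest-magnitude component positive (first index on ties), so
repeated decompositions are bitwise identical. Degenerate eigenvalue blocks
remain rotationally ambiguous; all downstream comparisons (RMSIP) are
invariant to rotations within a retained block, so this ambiguity cannot leak
into reported numbers.

Mass weighting multiplies fluctuation components by √mᵢ. Over Cα atoms only
(the default analysis set) every mass is carbon's, so the weighting is a
uniform scale: eigenvectors and eigenvalue ratios are unchanged and the
default is unweighted. The flag exists for all-atom use.

**Cross-system comparability.** Systems are mapped to a common Cα core via
the alignment (columns ungapped in *all* selected systems; one Cα per
residue enforced). Each system's PCA is computed on its own macro-trajectory
over the mapped atoms — per-system decompositions on a common atom map rather
than one joint decomposition of the concatenated super-system. The per-system
route is required for the cross-variant questions the package answers (which
variant PC matches the reference PC1; RMSIP between variants); a joint
decomposition would yield a single shared basis and make those comparisons
vacuous. The macro-trajectory of a system is the concatenation of its
replicates after trimming the leading equilibration segment of each
(default: 10% of frames, or an explicit frame count — callers converting a
time-based trim, e.g. "the first 10 ns", divide by their frame spacing).

## Subspace comparison

* **Crossing-over**: for a reference PC v, the profile (v·wⱼ)², j = 1…k_max
  (default 10) over the other system's PCs, with the arg-max reported. A best
  match at j ≠ i is an eigenvalue interchange between systems.
* **RMSIP** over the first D PCs (default 20; reduced to the common rank when
  an ensemble supports fewer modes). For unrelated D-subspaces of an N-dim
  space E[RMSIP] ≈ √(D/N) — the floor against which observed values should be
  read (≈0.26 for D=20, N=300).
* **Cosine content** with trapezoidal quadrature on the unit-spaced frame
  index, clamped into [0,1]. Note the half-period probe cos(iπt/T) is *not*
  orthogonal to sin(2πt/T) (the overlap integral is 4T/3π, giving content
  64/9π² ≈ 0.72); orthogonal controls are sin(πt/T) or cos(2πt/T). Values
  near 1 flag random-diffusion-like sampling: the classic result applies to
  the first PC of a PCA over ≥2 diffusing degrees of freedom. A literal
  one-dimensional walk — where "the first PC projection" is the centred walk
  itself — averages content ≈0.4, because the walk is a random mixture of all
  cosine modes with coefficients ∼N(0, 1/k²).
* **Class statistics**: Tukey boxplots (linear-interpolation quantiles,
  whiskers at the most extreme datum within 1.5×IQR, the rest outliers).
  Pairing rule for variant classes: all reference-class-vs-reference-class
  pairs form the reference group; each other class collects its
  reference-vs-member pairs.

## Geometry

* **SASA**: sphere-point (Shrake–Rupley-style) algorithm with a deterministic
  golden-spiral point set (default 960 points, probe 0.14 nm). Radii (nm):
  C 0.170, N 0.155, O 0.152, S 0.180, H 0.120, P 0.180; an element outside
  the table is a configuration error. Every atom of the structure occludes,
  selected or not. The occlusion test is a closed ball with a 10⁻⁹ relative
  surface tolerance so exactly coincident identical atoms bury one another
  completely. Accuracy on an isolated sphere: exact by construction; partial
  occlusion agrees with an independent implementation (biotite) to <2% at
  3840 points. The in-package implementation exists because the library
  alternative treats on-surface points as accessible (open-ball test), which
  breaks the coincident-burial contract.
* **Distances**: per-frame minimum over heavy-atom pairs between two groups
  (`min-heavy`, the default for side-chain interactions) or a single named
  atom pair (`named-pair`, e.g. SG–NZ for the Cys–Lys axis). Both modes are
  provided because published distance analyses rarely state which convention
  was used; reports name the mode.
* **Persistence**: fraction of frames with distance below the cutoff
  (default 0.48 nm, the ion-pair threshold for charged-group heavy atoms).
  The optional hydrogen-bond criterion adds donor–acceptor < 0.35 nm and a
  donor–H–acceptor angle ≥ 120°, a standard geometric convention.

## Activity–distance model

Activity is modelled as f(x) = b·e^(−c·x) with x the per-variant mean
Cys–Lys distance (nm): b is the extrapolated activity at contact (activity
units), c the decay rate (nm⁻¹). The fit is unweighted nonlinear least
squares (`curve_fit`), initialised from the log-linear closed form when all
activities are positive; distance uncertainties (replicate sd) are carried
into the report but do not weight the fit. Goodness of fit is the Pearson
correlation between observed and fitted activities. Two degenerate regimes
are detected and flagged rather than reported as numbers: constant
activities, and near-constant distances (an unidentifiable ridge where b·e^(−c·x̄)
is fixed but b, c are not); both return the best constant model with
correlation 0 and `degenerate=True`. Because b extrapolates to x = 0 from
x ≈ 0.3–0.7 nm, its sampling error under multiplicative activity noise is
roughly 2.5× that of c; medians over repeated fits are unbiased to ~1%.

## Synthetic generator: what it emulates, what it does not

Frames are drawn as x = x̄ + Σᵢ √λᵢ zᵢ vᵢ with zᵢ ~ N(0,1): a stationary
Gaussian ensemble with prescribed spectrum {λᵢ} and modes {vᵢ}. This captures
exactly the properties the pipeline's statistics consume — second-order
structure (covariance, PCA, RMSIP, crossing) and per-frame geometry
(distances, SASA, persistence) — and nothing else. It does **not** emulate
anharmonicity, kinetic barriers, time correlation (frames are i.i.d., so
cosine content of well-sampled ensembles is near zero by construction),
solvent, or any force field. A green test therefore establishes that the
*analysis* is correct on ensembles of known truth, not that any physical
simulation was reproduced.

Design choices inside the generator:

* **Topology.** Toy structures trace a self-avoiding serpentine walk on a
  cubic lattice (Cα spacing 0.38 nm; 0.55 nm with pseudo side-chain atoms,
  guaranteeing > 0.2 nm self-avoidance with a constant diagonal CB offset).
  The compact 3-D shape mimics a globular domain and — decisively — keeps
  the Kabsch fit well conditioned: on a near-collinear chain the rotation
  about the chain axis is almost unconstrained and the superposition step
  scrambles prescribed spectra.
* **Internal modes.** Mode vectors are drawn randomly and orthogonalised
  against the six rigid-body modes (translations, linearised rotations) of
  the mean structure, then against each other (QR). Fluctuations are
  therefore pure internal motions — as equilibrated, fitted trajectory frames
  are — and prescribed spectra survive superposition to second order in
  (displacement/size).
* **Scale.** Default λ₁ = 0.004–0.005 nm² (≈0.07 nm rms along the top mode,
  a typical Cα fluctuation), decaying geometrically. Fixtures that compare
  *estimated* eigenvectors use ratio 0.6 between successive modes so that
  finite-sampling eigenvector mixing (∝ √(2/T)/gap) stays well below the
  effects under test; spectrum-recovery fixtures use flatter 0.9 to exercise
  close eigenvalues.
* **Variants.** A variant rotates every reference mode by a common angle a
  into a partner direction orthogonal to the whole reference essential
  subspace, then optionally permutes mode indices (the crossing fixture:
  content of reference PC1 placed at variant PC4). Ground truth emitted
  alongside: expected RMSIP vs reference (|cos a| for a pure rotation),
  computed by direct inner products over the constructed bases.
* **Determinism.** Every operation takes one integer seed; replicate and
  member seeds are derived arithmetically from it; there is no global state.

## Pipeline and I/O conventions

Coordinates are nm internally, Å in PDB files (3 decimals → round trips are
exact to 5·10⁻⁵ nm). Residue numbers are 1-based; atoms are addressed as
chain/residue/atom-name, with `sidechain` selecting non-backbone atoms of a
residue. PC indices are 1-based everywhere a person reads them. Alternate
locations: the first conformer is kept, others are counted and logged.
Report tables are TSV with six significant digits; identical configuration
and inputs give byte-identical bundles (no timestamps enter outputs). A
single-system run skips comparison stages with a warning but still performs
geometry. Stage failures surface as a `PipelineError` naming the stage and
system, and partially written outputs are removed.

## Known limitations

* Gaussian ensembles cannot probe time-dependent diagnostics beyond the
  trivial regime; the diffusive-sampling control for cosine content is built
  separately (independent random-walk coordinates).
* The SASA implementation is O(selection × occluders) per frame with a radial
  prefilter — fine for per-residue selections over thousands of frames, not
  intended for whole-proteome surface scans.
* The MSA mapper requires exactly one Cα per residue and treats the alignment
  as authoritative; it does not attempt structural re-alignment.
* The activity model is an empirical single-exponential; it encodes no
  mechanism and should not be extrapolated far outside the fitted distance
  range.
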