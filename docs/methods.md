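# Methods

## The geometric substrate criterion

CYP-mediated hydroxylation requires the target atom to approach the
ferryl oxygen formed at the heme iron. The package's central observable
is therefore the per-frame distance d(t), in nm, between a
user-designated reactive atom (e.g. the 1′-carbon of safrole) and the
heme Fe over an MD trajectory. The decision rule is deliberately simple
and qualitative: a complex is called a likely substrate ("Yes") when the
trajectory mean d̄ is at or below a threshold, 0.53 nm by default, and
"No" when d̄ is strictly wider. The boundary d̄ = threshold is "Yes"
because the rule defines non-substrates by *wider* distances. The call
uses the mean only; the SD, min/max and the fraction of frames below
threshold are reported as diagnostics but never enter the decision, and
the classifier makes no kinetic (Kcat/Km) claims.

The reactive atom is always user-designated via an atom selector
(`resname=SAF,name=C1` style); it is never inferred from topology,
because ligand atom naming conventions vary between preparation tools.

A descriptive "spread" metric complements the mean distance: after
Kabsch superposition of every frame onto frame 0 using a fit selection
(≥3 non-collinear atoms, typically the protein), the RMSF of the
reactive atom's position about its mean, and the maximum deviation
(cloud radius). Wider spread indicates a loosely held reactive moiety;
the metric is reported but, like the SD, never used by the classifier.

Units are nm throughout the library; PDB files (Å) are converted exactly
(×0.1) at the I/O boundary only. Distances honour an orthorhombic
minimum-image convention when requested (`pbc_mode="minimum_image"`,
requiring per-frame box vectors); the default is no wrapping, appropriate
for docking-derived complexes whose ligand and heme share one image.

## Group statistics

Across complexes, distance series are compared with a fixed-effects
one-way ANOVA computed from the standard sums of squares; the p-value is
the upper tail of F(k−1, N−k) obtained from the regularized incomplete
beta function, I_{d2/(d2+d1 f)}(d2/2, d1/2). Post-hoc pairwise
comparisons use pooled-variance t statistics whose pooled variance is
the ANOVA within-group mean square with df_within degrees of freedom
(the convention of classic ANOVA packages), with Bonferroni adjustment
p_adj = min(1, p·m) over the m = k(k−1)/2 pairs, α = 0.05 by default.
Summary SDs use the sample (n−1) denominator; at n = 5000 the choice is
numerically irrelevant but must be fixed for determinism.

**Caveat:** frames are treated as independent observations (n = 5000 per
complex in the reference setting). Successive MD frames are
autocorrelated, so these p-values are anti-conservative; no effective
sample-size correction is applied, matching common practice in the
field. Conclusions should rest on effect sizes (the means relative to
the threshold), not on the nominal p-values.

## Conformational clustering

Representative binding geometries are extracted with the gromos (Daura)
procedure on an all-vs-all RMSD matrix: iteratively, the frame with the
most neighbours within the cutoff (itself included; ties broken by
lowest frame index) becomes a cluster centre and is removed together
with its neighbours, until no frames remain. The default cutoff is
0.3 nm. Superposition is the Kabsch algorithm (SVD of the weighted
covariance, reflection corrected to a proper rotation); degenerate
(collinear) point sets are rejected. The RMSD may be measured on one
selection after fitting on another — the default pipeline fits on the
protein (`name=CA`) and measures on the ligand (`resname=SAF`), so the
clusters reflect ligand pose rather than global tumbling; both
selections are config keys since no single convention is universal.
The representative pose is the centre of the most populated cluster
(population ties → the cluster extracted first).

Because the RMSD matrix is O(n²) in frames, the pipeline clusters an
even-stride subset when a trajectory exceeds `max_cluster_frames`
(default 150, i.e. ≤ ~11k superpositions per complex); this is the usual
frame-skipping practice of trajectory clustering tools, and the stride
is recorded in the report.

## Interaction profile and affinity interface

On the representative pose, hydrogen bonds are detected geometrically:
donor/acceptor heavy atoms are N or O, donor–acceptor distance
≤ 0.35 nm, and D–H…A angle (at the hydrogen) ≥ 120°. Covalent bonds are
inferred by distance (<0.17 nm heavy–heavy, <0.125 nm X–H). Structures
without any explicit hydrogens fall back to the distance-only heavy-atom
criterion and such contacts are flagged; in protonated structures an
N/O without a hydrogen is simply not a donor. Hydrophobic contacts are
pairs of apolar carbons (carbons with no bonded N/O) across the
protein–ligand interface within 0.40 nm. These cutoffs are common
geometric practice and all are config keys; no attempt is made to
reproduce any specific profiler's rule set (π-stacking, salt bridges and
halogen bonds are out of scope). The predominant interaction kind is the
argmax of the per-kind counts ("mixed" on ties).

The binding-affinity estimate is a transparent linear model,
ΔG = intercept + Σ w_class·count_class (kcal/mol, negative =
favourable), over the contact classes above. Coefficients must be
supplied by the user; the package ships none, so any ΔG it prints is
explicitly model-dependent — the interface exists so a fitted
contact-count model can be plugged in without changing the pipeline.

## Homolog mining

The proximate homolog of a human CYP in another species is the candidate
with the highest percent identity to the reference. Identity is computed
from affine-gap global (Needleman–Wunsch) alignments — BLOSUM62, gap
open 10, gap extend 0.5, via Biopython's `PairwiseAligner`, taking the
first co-optimal alignment of its deterministic enumeration — as
100 × identical columns / columns where neither sequence is gapped. This
gap-robust convention matches the intuitive "identity between two
sequences"; it is a config option since identity definitions differ
between tools. All candidates tied (within 1e-9) at the maximal identity
are selected (so a species can legitimately carry two proximate
homologs, as rabbit does with CYP2A10/CYP2A11), and candidates below a
usability floor (50% by default) are excluded as too divergent to
preserve the function; if every candidate falls below the floor the
selection is empty and flagged, which is how chicken drops out of the
CYP2A6 analysis. Conservation profiles are reference-anchored: each
homolog is aligned pairwise to the reference and per-position matches
counted (gap = mismatch). A progressive MSA would give essentially the
same per-reference-position quantity at far greater implementation cost,
so it is not built; BLAST-style database search and accession retrieval
are likewise out of scope.

## Synthetic data: what it emulates and what it does not

Real inputs are 25 ns solvated MD trajectories sampled every 5 ps
(5000 frames). The generator emulates their *statistics*, not their
physics:

- **Distance series** are a discretised Ornstein–Uhlenbeck process,
  X_{t+1} = X_t + (μ−X_t)/τ + σ√(2/τ)·ξ_t with X_0 = μ — the simplest
  stationary mean-reverting Gaussian process with controllable mean μ,
  SD σ and correlation time τ (frames). Defaults mirror the reference
  regimes: substrate-like means 0.39–0.52 nm with SD 0.04–0.09 nm,
  non-substrate-like means 0.63–0.74 nm with SD 0.06–0.15 nm, τ = 50,
  n = 5000. Values are clipped at 0.05 nm (a physical lower bound);
  clip counts are surfaced so tests can demand clip-free regimes. The
  stationary SD of the discretisation is σ/√(1−1/(2τ)) ≈ 1.005σ at
  τ = 50. Note the sampling error this implies: the 5000-frame mean has
  standard deviation ≈ σ√(2τ/n) ≈ 0.14σ (≈ 0.006–0.013 nm for the
  regimes above), an order of magnitude wider than for independent
  frames — single-trajectory means recover μ to roughly ±0.01 nm, not
  better.
- **Toy complexes** place a rigid 5-atom ligand so its reactive atom
  realises a given distance series *exactly* against a fixed heme
  (Fe + 4 planar N) and a rigid 20-atom protein shell, with the approach
  direction performing a slow random walk on the sphere. They exercise
  selection, geometry and clustering code paths; they have no forces,
  water, flexibility or realistic packing.
- **Conformer mixtures** draw frames from K centre structures by weight
  plus isotropic Gaussian noise, returning ground-truth labels.
- **Mutated sequences** substitute round(n(1−t/100)) uniformly chosen
  positions with a different residue, so realised identity equals the
  target up to position-count rounding.
- **H-bond fixtures** solve for the acceptor position giving an exact
  requested donor–acceptor distance and D–H…A angle.

All generators are deterministic given their integer seed. Passing tests
on these inputs demonstrates that the *analysis layer* is correct and
calibrated; it says nothing about force fields, docking poses, sampling
convergence or any other upstream step of a real study.

## Numerical and design choices

- Deterministic tie-breaks everywhere: lowest frame index for gromos
  centres, first-extracted cluster for the representative pose, first
  co-optimal alignment for tracebacks, lexicographic ordering in
  reports. Rerunning the pipeline on identical inputs produces
  byte-identical output files (no timestamps enter reports).
- Degenerate inputs are explicit: zero within-group variance with
  unequal means reports p = 0 with a `degenerate_variance` flag;
  collinear point sets, empty selections, ambiguous selectors,
  inconsistent multi-model atom counts and duplicate manifest rows all
  raise with the offending item named. A failing complex is recorded
  and skipped by the pipeline, never silently dropped.
- Atom order, not serial number, matches frames across models of a
  trajectory; frame tables may have non-contiguous but monotone frame
  numbers and arbitrary row order.
- The frame-table trajectory dialect (TSV: `frame, atom_id, x, y, z` in
  nm plus an atom-metadata sidecar) exists so synthetic trajectories and
  tests need no binary formats; standard binary trajectories can be
  converted externally or adapted on top of `Trajectory`.
- The published distance table bundled in `cyptraj.datasets` carries the
  running-text variant of two cells (safrole/CYP1A2 0.63 ± 0.06 and the
  coumarin pair) only in the validation-stats helper; table and text
  values are kept side by side and neither is altered or averaged.

## Known limitations

- The 0.53 nm threshold is exposed as a parameter but its transfer to
  CYP families beyond those it was validated on is an assumption, not a
  result of this package.
- ANOVA on autocorrelated frames (above) inflates significance.
- Contact detection depends on protonation and on distance-based bond
  inference; unusual geometries (metal coordination, very short
  contacts) can misclassify carbon polarity.
- The affinity interface without coefficients produces no number at
  all — by design.
- Homology modelling, docking and MD simulation are consumed as inputs
  and are entirely out of scope.
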