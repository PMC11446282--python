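# Methods

## Interface detection

Contacts between the binder chain and the receptor binding site are found
in two stages. Stage 1 computes distances between representative
coordinates of all cross-chain residue pairs and keeps pairs within the
prefilter cutoff (default 8 Å, inclusive). The representative is the Cβ
atom; glycine uses Cα; residues lacking both fall back to their first
atom (configurable, on by default). Stage 2 keeps a surviving pair as a
contact if any atom–atom distance is at or below the atomic cutoff
(default 4 Å, inclusive), over all atoms present in the file —
hydrogens included when present, though predicted models rarely carry
them. Waters and HETATM residues are excluded from both stages. When a
binding-site definition is supplied, the receptor side is restricted to
site members *before* stage 1.

Both cutoffs are read inclusively (≤). "Within 8 Å" and "cutoff of 4 Å"
admit either reading; ≤ is the conventional one and the boundary is
exercised explicitly in the tests.

The prefilter is a speed optimisation and can, in principle, miss a
contact made by a long side chain whose atoms touch while the Cβ atoms
sit beyond 8 Å. `interface_residues_exhaustive` computes the same map
with no prefilter and `compare_maps` reports any difference. A
sufficient condition for exact agreement is that the residue "spreads"
r (the largest atom-to-representative distance) satisfy
r_binder + r_receptor ≤ prefilter − atomic: then any atomic contact at
≤ 4 Å forces a representative distance ≤ 8 Å by the triangle inequality.
`coverage_condition_holds` checks this with per-chain maxima. Arginine
and lysine side chains violate the condition (spread ≈ 5 Å), which is
exactly the adversarial case the test suite constructs.

Residues with pLDDT below 50 are removed from the resulting interface.
The removal applies to both chains' residues by default; whether the
receptor-side columns of the PAE submatrix should also shrink is
genuinely open, so `receptor_side_exclusion=False` disables that half.

## Confidence metrics and the screen

For a scored model, ipLDDT is the arithmetic mean pLDDT over the
*binder's* interface residues, and iPAE is the median over the PAE
submatrix indexed by binder residues as rows and receptor residues as
columns — that single orientation, not symmetrised (PAE is asymmetric; a
`symmetrize` flag pools the transposed block for sensitivity analyses).
Metrics are computed only when strictly more than `min_iface = 7` binder
interface residues remain after the pLDDT exclusion, i.e. at least 8;
otherwise the model receives the sentinel report (ipLDDT 0, iPAE 30),
which can never pass. The median of an even-sized set is the midpoint of
the two central values. The screen verdict is
`iPAE < 10 and ipLDDT > 70`, both strict, exactly as the thresholds are
printed.

The counting rule deliberately uses binder-side residues: the metrics are
defined over the binding partner's interface residues, so the size gate
is applied to the same set being averaged.

## Helix register

Helices are assigned from backbone dihedrals alone: a residue is helical
iff both φ and ψ exist (consecutive numbering, complete N/CA/C backbone
on the relevant neighbours) and fall in φ ∈ (−100°, −30°),
ψ ∈ (−80°, −5°); helices are maximal runs of ≥ 4 helical residues. The
window is a deterministic, backbone-only criterion — no hydrogen-bond
energy model — chosen wide enough to keep slightly distorted helical
residues and narrow enough to reject strand and PPII backbones; both
windows are arguments.

Binder residues are labelled with every patch whose member residues they
contact. The binding helix is the helix containing the most
patch-1-labelled residues (ties: more total interface residues, then most
N-terminal). The anchor *i* is the most N-terminal helix residue *r* such
that *r* and *r + 4* both carry patch 1; if no such pair exists, the
patch-1 residue with the most atom-level contacts to patch-1 receptor
atoms. Register offsets are limited to {0, 1, 2, 4, 5}; contacts at
other offsets, in loops, or in adjacent helices are reported under
`unassigned_contacts` rather than forced into the register — supplementary
electrostatic contacts from a preceding helix are a known real pattern
and must stay visible without polluting the register. Binders with no
patch-1 contact raise a distinct "non-canonical" error instead of a
silent empty result.

Default patch definitions (receptor author numbering): patch 1
{178, 197, 222, 225, 228}, patch 2 {284, 287}, patch 3 {340}, flank
{337, 343}. All are overridable through `BindingSiteDef` / the TOML
config, since conserved-site lists vary with the alignment used.

## Design QC

`superpose_rmsd` computes the optimal least-squares rigid superposition
(Kabsch, proper rotation enforced via the SVD sign correction — no
reflections) over atoms matched by (chain, author_seq_id, atom name),
requiring ≥ 3 matches; collinear references are computed but flagged.
`design_metrics` reports the mean binder pLDDT and a *pose-sensitive*
RMSD: the refolded model is superposed on the template using the
receptor chain, and the RMSD is then measured over binder Cα atoms with
no refit, so a perfectly refolded helix docked at the wrong site scores
poorly. Refold validation is about whether the design adopts the
structure *and pose* it was designed for, which fold-only RMSD cannot
see; `mode="fold"` (superpose on the binder itself) is available. The
default atom selection is Cα-only because refolded side chains are not
comparable. Designs pass at mean binder pLDDT strictly above 90; RMSD is
reported, not gated.

## Binding fits

The one-site specific binding equation Y = Bmax·X/(Kd + X) is fitted by
unweighted nonlinear least squares (trust-region reflective with positive
bounds), initialised at Kd₀ = the concentration whose response is nearest
half the maximum and Bmax₀ = the maximum response. Standard errors come
from the Jacobian-based covariance at the optimum. Concentrations are nM
throughout. There is no nonspecific linear term, matching the assay
model; steady-state SPR responses fit the same equation. Non-convergence
is reported as `converged=False` with NaN parameters, never silent
values. `OneSiteBindingModel` wraps the fit in a scikit-learn-style
estimator (`fit`/`predict`, `kd_`/`bmax_` attributes) so it composes with
generic model-selection tooling.

## Synthetic data

`make_helix_complex` builds the binder as an ideal peptide (φ = −57°,
ψ = −47°, ω = 180°, standard bond lengths/angles, Cβ at the standard
tetrahedral position; arbitrary φ/ψ segments allowed for
helix-loop-helix and strand controls). Each prescribed contact places a
single-residue receptor probe along the contacted residue's outward
radial direction (measured from the local helix axis, approximated by
the midpoint of the flanking Cα atoms) so that the probe's nearest atom
sits at exactly the prescribed closest-approach distance. The
construction is then verified numerically: prescribed pairs must realise
the approach distance to 1e-6 Å and every other cross-chain residue pair
must clear 6 Å, otherwise the spec is rejected as geometrically
infeasible rather than silently bent. On an ideal helix this clearance
is attainable for approach distances of about 3.4 Å and above at
non-terminal positions, which is why the random-spec sampler draws the
approach from [3.5, 3.9] Å and avoids the termini.

Confidence fixtures use constant pLDDT per chain with per-residue
overrides, and block-valued PAE: background everywhere, a prescribed
value on the binder-rows × receptor-columns interface block (optionally
mirrored). Binding-curve fixtures evaluate the one-site equation on a
three-fold dilution series from 1.8 nM (six points up to 437 nM,
spanning the 1.8–500 nM assay range) and add seeded Gaussian noise;
default simulation settings are Kd = 6 nM and Bmax = 150 with noise of
2% of Bmax, matching the affinity scale and noise level of a
fluorescence-polarization titration.

What the generator does *not* emulate: folded receptor domains (probes
are single residues — the screen's arithmetic depends only on distances,
confidence values and identities, which probes control exactly),
realistic AF-style error correlation in PAE (only block structure),
side-chain rotamers, or hydrogens. Passing tests therefore demonstrate
the correctness of the pipeline's arithmetic and decision rules on
inputs with known truth, not the accuracy of any structure predictor on
real complexes.

## Problem sizes and determinism

The test suite and the acceptance script run the pipeline at the scale
the statistics need and no more: 100 random complexes for the
prefilter/oracle comparison, 50 canonical fixtures for register
recovery, 20 rigid motions for superposition, 200 titrations for
parameter recovery. All randomness flows through explicit
`numpy.random.default_rng` seeds; generators are pure functions of
(spec, seed), and the CLI screen output is byte-identical across runs on
identical inputs.

## Known limitations

- Insertion codes, altlocs beyond the first, and multi-model files are
  rejected or truncated by design; prediction outputs do not use them.
- The PAE residue-index order must match the structure's residue order
  (or receptor-first, by flag); no automatic detection of other
  concatenation orders is attempted.
- Register assignment requires at least one patch-1 contact; binders
  engaging the site in non-canonical ways are flagged, not annotated.
- The two-stage interface detection inherits the prefilter's blind spot
  for very long side chains; use the exhaustive route when that matters.
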