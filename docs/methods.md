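# Methods

## Model

A protein conformation is coarse-grained to one bead per residue at the
Cα position.  Beads i, j interact through a harmonic spring of natural
length d_ij⁰ (their separation in the reference structure) and stiffness
κ_ij, giving the elastic energy

    U = ½ Σ_{i<j} κ_ij (d_ij − d_ij⁰)².

The energy is anharmonic in Cartesian coordinates; near equilibrium the
quadratic expansion dominates and the dynamics is governed by the
3N×3N Hessian H with 3×3 blocks

    H_ij = −κ_ij ê_ij ê_ijᵀ   (i ≠ j, ê_ij the equilibrium bond direction)
    H_ii = Σ_{j≠i} κ_ij ê_ij ê_ijᵀ.

With uniform bead mass m the eigenvalues of H are mω_k² and the
eigenvectors a^(k) are the vibrational modes.  A connected network in
generic position has exactly six vanishing eigenvalues (rigid
translations and rotations).  Equipartition over the remaining modes
gives the mean-square fluctuation of bead i,

    MSF_i = (k_BT/m) Σ_{k=7}^{3N} |a_i^(k)|² / ω_k²  =  k_BT Σ_k |a_i^(k)|²/λ_k,

(λ_k = mω_k², so the mass cancels), and the predicted B-factor is
B_i = (8π²/3)·MSF_i.

### Stiffness schemes

| scheme | κ_ij | cutoff | backbone pairs |
|---|---|---|---|
| `anm10/13/16` | uniform κ (default 1) | 10/13/16 Å | no special treatment |
| `sanm10/13` | pair table κ(s_ij) | 10/13 Å | fixed constant 10 |
| `sdanm` | distance-binned table κ(s_ij, d_ij⁰) | 16.5 Å hard radius | fixed constant 43.52 |

A pair interacts iff d_ij⁰ is *strictly* below the cutoff (the boundary
event has measure zero; Θ(0) is taken as 0).  Backbone pairs are
consecutive residues of the same chain with consecutive author numbering
(insertion-code successors included) and Cα–Cα distance ≤ 4.2 Å; larger
gaps are treated as chain breaks and receive no backbone override.  The
backbone constant applies to such pairs regardless of the cutoff.  A
residue pair missing from a table is an error, never a silent default.

The bundled sequence-specific tables are synthetic stand-ins (the
published tables are external supplementary data).  Each residue type a
gets a factor g(a) = exp(α + β·KD(a)) from its Kyte–Doolittle hydropathy,
with α, β solved so that the two published anchor pairs are exact:
κ(GLY,GLY) = g(GLY)² = 0.226 and κ(ILE,VAL) = g(ILE)·g(VAL) = 2.348; pair values are
g(a)·g(b) clipped to [0.226, 2.348].  This reproduces the published
order-of-magnitude heterogeneity and the physically motivated trend
(hydrophobic contacts stiffer), but individual entries beyond the
anchors are not the published constants.  The distance-binned dialect
multiplies the pairwise value by a decaying profile
(×3 below 5.5 Å, ×1 to 8 Å, ×0.3 to 11 Å, ×0.03 to 14 Å) and floors the
14–16.5 Å range at the published far-range softness 10⁻³.  Both tables
are replaceable TSV files.

### Parameters that matter

* `kBT`, `mass` (defaults 1, 1): the stiffness scale of an ENM is
  arbitrary, so these only set absolute units; the mean-matched
  rescaling (below) absorbs them.  They remain explicit parameters.
* `zero_tol` (default 1e-8, relative): eigenvalues below
  `zero_tol·max λ` count as vanishing.  Zero modes are detected by this
  threshold, *not* by discarding exactly six modes — degenerate toys
  (a two-bead dumbbell has five) and disconnected networks (more than
  six) are then handled consistently, and the survey's acceptance rule
  ("exactly six") is enforced separately by `reject_by_spectrum`.
* cutoff / interaction radius, per scheme as above.
* connectivity bin width (default 0.05) for stratified error summaries;
  the relative connectivity of a bead is its contact degree divided by
  the maximum degree in the same network, so the same structure yields
  different profiles under different interaction radii.

### Comparison to experiment

Predicted and experimental B-factor profiles are scored by the Pearson
product-moment correlation.  Because κ is defined up to one global
factor, predictions are rescaled per structure so that the mean
predicted B-factor equals the mean experimental one before per-residue
absolute MSF errors are computed; the correlation is invariant under
this rescaling.  Crystallographic input uses the deposited B-factors
(MSF = 3B/8π²).  Multi-model input uses the conformer scatter instead:
all models are least-squares superposed onto model 1 (uniform weights
over all Cα; the rotation from scipy's Kabsch solver), and
MSF_i = mean_m |R_i^(m) − ⟨R_i⟩|².  The network is built on model 1.

Residue chemistry is classified by a bundled, replaceable decision
table: hydrophobic {ALA VAL LEU ILE MET PHE TRP PRO GLY}, polar
{SER THR CYS TYR ASN GLN HIS}, charged {ASP GLU LYS ARG}.  Secondary
structure comes from deposited HELIX/SHEET records; for Cα-only input a
coarse geometric fallback based on i→i+2 / i→i+3 virtual distances can
be enabled (it recognises ideal helices and extended strands; it is not
a DSSP replacement).

### Entry screening for crystallographic surveys

An entry is accepted iff it is an X-ray structure at resolution ≤ 2.0 Å
("2 Å or better" read as inclusive), contains no nucleic-acid polymer,
has every sequence-record residue resolved and only the twenty standard
amino acids, and — after network construction — has exactly six
vanishing modes.  A missing sequence record makes the completeness
criterion unevaluable and is reported as `missing_residues` with a note.
Alternate locations keep the highest-occupancy Cα (ties: first
encountered); waters, ligands and other heteroatoms are ignored;
insertion codes stay part of the bead identity.

## Synthetic data

The generators emulate the geometric features the analysis depends on,
with one seedable random generator per call and no global state:

* `make_helix` — ideal α-helix Cα trace (rise 1.5 Å, radius 2.3 Å,
  100°/residue; consecutive spacing ≈ 3.8 Å).
* `make_globule` — compact self-avoiding cluster: beads placed
  sequentially in a sphere of radius 1.75·(n/0.25)^⅓ Å (protein-like
  packing at ~25 % volume fraction given the 3.5 Å exclusion diameter),
  rejected until the 10 Å contact graph is connected.
* `make_tip_structure` — globule plus a protruding tail attached at the
  most protruding surface bead.  The tail is a helical Cα trace rather
  than a straight line: a perfectly straight pair-spring chain can bend
  at zero energy cost to second order, which would add spurious zero
  modes; the helix is internally rigid while remaining sparsely
  connected, so the structure passes the six-zero-mode criterion yet
  shows the tip effect (tip/core MSF ratio ≈ 4–8 under a 10 Å network).
* `make_stiffness_table` — `uniform` (reproduces the homogeneous model
  exactly), `random_pairwise` (log-uniform in [0.2, 2.4], one order of
  magnitude of dispersion), and `soft_longrange`: κ = 1 inside the
  classic 10 Å contact shell, 10⁻³ from there to 16.5 Å.  The near/far
  boundary at 10 Å preserves the rigidity of a compact core the way the
  sequence+distance scheme's stiff short-range contacts do; pushing the
  boundary inward (e.g. 8 Å) instead melts the core's coordination
  shells and no longer mimics that profile.
* `make_synthetic_experiment` — mock B-factors
  b_i = B_i^pred(reference scheme)·exp(σ ε_i) with ε_i i.i.d. standard
  normal.  Multiplicative log-normal noise keeps B-factors positive
  without truncation artefacts.

What the synthetic data does *not* contain: real protein topology
(chain connectivity inside a globule is not geometrically realistic),
crystal packing and solvent damping, anisotropic displacement
information, and genuinely sequence-correlated stiffness.  Passing tests
therefore demonstrate correctness of the machinery and the generic
connectivity phenomenology (tip effect, cutoff sensitivity), not the
empirical performance of any scheme on real structures.

## Numerical choices

* Dense symmetric eigendecomposition (LAPACK via scipy) of the full
  Hessian, with a size guard at 3N = 15000; every non-trivial mode
  enters the MSF sum, so iterative partial solvers would not help.
  Assembly and accumulation are in float64 throughout — zero-mode
  detection depends on it.
* The Hessian path is validated against central finite differences of
  the exact (anharmonic) energy, and the spectrum against closed forms
  (dumbbell stretch mode mω² = 2κ, per-bead MSF k_BT/4κ) and null-space
  identities (translations and infinitesimal rotations).
* Superposition uses all Cα with uniform weights; a (nearly) collinear
  reference leaves the rotation undetermined and is an error.
* Survey outputs are sorted canonically before writing, so any
  processing order yields byte-identical tables; per-structure failures
  are tallied with reason codes instead of aborting the run.

## Analysis drivers and problem sizes

The numbered scripts under `analysis/` run the survey narrative on
synthetic fixtures: ten 40-residue globules with 13 Å-generated mock
experiments for the scheme comparison, three 40+8-residue tip structures
with damped-tip truth for the connectivity stratification, and one
12-model ensemble for the NMR-style comparison.  These sizes keep every
driver in the seconds range while leaving the qualitative effects
(cutoff recovery, ~18× error enhancement at low connectivity, soft-far
amplification of the tip ratio) far from marginal.

## Known limitations

* The bundled stiffness tables are labelled synthetic stand-ins; any
  quantitative conclusion about sequence specificity on real proteins
  requires the externally published tables (drop-in TSV replacement).
* Directional (anisotropic) fluctuations and mode covariances are out
  of scope, as are crystal-contact corrections and relaxational
  (overdamped) dynamics.
* The geometric secondary-structure fallback is deliberately coarse.
* Degenerate geometries (collinear chains, free beads) are rejected by
  the spectrum rule rather than special-cased; callers who want MSF for
  such toys must opt in (`allow_degenerate=True`).
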