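# enmfluct

Residue-fluctuation analysis with protein elastic networks whose spring
stiffnesses can be homogeneous, sequence-specific, or sequence- and
distance-dependent.

## The problem

Coarse-grained elastic network models (ENMs) represent a protein as one
bead per residue, placed at the Cα position, with harmonic springs
between spatially close pairs.  Despite their simplicity they reproduce
experimental flexibility patterns (crystallographic B-factors, NMR
conformer scatter) remarkably well, which makes them a standard tool for
probing slow conformational dynamics.  A long-standing question is
whether making the springs chemically aware — stiffness depending on the
amino-acid identities of the pair, and possibly on their separation —
improves the predictions, and where all such models fail.  This package
implements the full analysis chain needed to study that question:

1. **Network construction.** From the elastic energy
   U = ½ Σ_{i<j} κ_ij (d_ij − d_ij⁰)², with natural lengths d_ij⁰ taken
   from the reference structure.  Stiffness schemes:
   * `ANMlc` — anisotropic network model: κ_ij = κ·Θ(l_c − d_ij⁰) with a
     uniform κ and cutoff l_c (10, 13 or 16 Å);
   * `sANMlc` — sequence-specific: κ_ij = κ(s_ij)·Θ(l_c − d_ij⁰) from a
     symmetric 20×20 residue-pair table, with a strong backbone constant
     (10) for sequence-adjacent pairs;
   * `sdANM` — sequence + distance dependent: κ_ij = κ(s_ij, d_ij⁰) from
     distance-binned tables, very soft (10⁻³) at long range, zero beyond
     a 16.5 Å interaction radius, backbone constant 43.52.
2. **Normal-mode analysis.** The 3N×3N Hessian of U at equilibrium is
   diagonalised; a connected network in generic position has exactly six
   zero modes (rigid translations/rotations).  Mean-square fluctuations
   follow from MSF_i = (k_BT/m) Σ_{k=7}^{3N} |a_i^(k)|²/ω_k², and
   predicted B-factors from B_i = (8π²/3)·MSF_i.
3. **Scoring and stratification.** Predictions are rescaled so the mean
   predicted B-factor matches the experimental mean, scored by Pearson
   correlation, and per-residue absolute MSF errors are stratified by
   relative connectivity D_i/max{D}, chemical class
   (hydrophobic/polar/charged) and secondary structure
   (helix/sheet/unstructured).  For multi-model (NMR-style) input the
   experimental index is the per-residue positional spread across the
   superposed conformer ensemble.

The package also ships a synthetic-data module (compact globules,
helices, structures with protruding low-connectivity "tips", mock
experimental B-factors) so that every stage is testable without
downloading structures, and an entry-screening step for crystallographic
surveys (X-ray only, resolution ≤ 2 Å, protein-only, complete standard
sequence, exactly six vanishing modes).

**Note on bundled parameter tables.** The shipped sANM/sdANM tables are
*synthetic stand-ins* (see `src/enmfluct/data/`): full 20×20
parameterisations pinned to the published anchor constants
(glycine–glycine 0.226, isoleucine–valine 2.348, backbone 10 and 43.52,
16.5 Å radius, 10⁻³ far-range softness) but not the published values
pair-by-pair.  They are plain TSV files and can be replaced by real
tables without code changes (`--table` on the CLI, or
`load_stiffness_table`).

## Worked example

```
$ enmfluct synth --kind globule --n 25 --seed 7 \
      --experiment-scheme anm10 --noise-sigma 0.1 --out globule.pdb
wrote globule.pdb and globule.tsv (25 beads)

$ enmfluct predict globule.pdb --scheme anm10 --out profile.tsv
globule	anm10	PCC=0.9544
wrote profile.tsv
```

The fixture is a 25-residue compact random globule whose "experimental"
B-factors were generated from a 10 Å homogeneous network with 10 %
multiplicative noise; predicting with the same scheme recovers them with
correlation 0.95, and `profile.tsv` lists per-residue MSF (Å²) and
B-factors.  The same workflow scales to a survey.  The analysis drivers
under `analysis/` run it on a larger synthetic set; for example
`python analysis/01_make_fixtures.py` followed by
`python analysis/02_scheme_comparison.py` prints

```
scheme  mean_pcc  n_structures
 anm10  0.678188            10
 anm13  0.722535            10
 anm16  0.693082            10
sanm10  0.456511            10
sanm13  0.356766            10
 sdanm  0.467181            10
best mean correlation: anm13 (mock experiments were generated at 13 Å)
```

i.e. the scoring machinery correctly identifies the network architecture
that generated the data, and `analysis/03_connectivity_survey.py`
reproduces the tip effect on fixtures whose mock truth damps tip
mobility: the mean absolute MSF error in the lowest relative-connectivity
bin is ~18× the error in the highest bin, and softening far-range springs
to 10⁻³ at a fixed 16.5 Å radius raises the tip-to-core MSF ratio from
3.76 to 4.33.

See `docs/methods.md` for the model details, parameter defaults and the
limitations of the synthetic data.

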