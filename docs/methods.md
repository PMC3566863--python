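# Methods

`alphaturn` decides whether a small constrained scaffold mimics a protein
reverse turn. The pipeline is: build the molecular graph and assign scaffold
atoms to pseudo-residue positions 1–5; generate a conformer ensemble by
multi-start embedding and force-field minimization; remove duplicates and
keep a low-energy window; flag each conformer for the two diagnostic
intramolecular H-bonds and the dα probe; summarise the ensemble with
Boltzmann statistics and φ/ψ-region turn labels; and, independently,
quantify solution H-bond evidence from amide-NH NMR series.

## The turn model

A five-position pseudo-peptide chain is threaded through the scaffold. For
the THBC-DKP scaffold the chain runs from the Cbz group (position 1, with
the benzyl ether oxygen standing in for Cα1) through the carbamate NH–CH2
arm (position 2), the ring-fusion carbon and its flanking diketopiperazine
carbonyl (position 3), the glycine-derived CH2C(=O) arm (position 4), to the
terminal methylamide (position 5, the N-methyl carbon standing in for Cα5).
The role map is derived automatically by anchoring on the methylamide cap
and the Cbz carbamate substructures; it can also be supplied as YAML.

Two intramolecular H-bonds diagnose the turn type, named by the atom count
of the pseudo-cycle they close (counting both the amide hydrogen and the
acceptor oxygen along the shortest covalent path):

* **H-bond A** — N5H → position-3 carbonyl, a 7-membered pseudo-cycle (C7),
  the signature of a γ-turn;
* **H-bond B** — N5H → position-1 (Cbz) carbonyl, a 13-membered pseudo-cycle
  (C13), the signature of an α-turn (the i+4 → i bond of protein α-turns).

A generic reverse-turn probe is the distance dα between the Cα surrogates
of positions 1 and 5; dα < 7 Å (strict) marks a chain reversal. On an ideal
α-helical pentapeptide the same machinery reports a C13 bond and
dα ≈ 6.3 Å, which is the synthetic sanity check used in the tests.

## Conformer ensembles

The search driver takes a pluggable energy backend (random starts, local
minimizer, single-point energy). The default backend generates starts in
two stages: a handful of ETKDG distance-geometry embeddings fix the
geometry of the rigid fused-ring system while respecting the stereo
descriptors (so the (6S) and (6R) epimers stay distinct), and then every
rotatable-bond torsion is set to an independent uniform random angle for
each start — a torsional Monte Carlo move set — before MMFF94
minimization. Uniform torsional starts matter: plain distance-geometry
embedding draws torsions from knowledge-based priors that strongly
under-sample folded, intramolecularly H-bonded arrangements, and the
turn-defining basins are exactly such folds. The
original study used a proprietary Monte Carlo/molecular-mechanics engine
whose force field and duplicate criterion are unpublished; absolute
conformer counts are therefore backend-specific and only the qualitative
ensemble picture is comparable. Default search size is 972 starts with a
6 kcal/mol retention window (boundary inclusive, since a diagnostic
conformer is reported at exactly 5.9 kcal/mol in the reference analysis).

Duplicates are removed greedily, lowest energy first; a candidate is a
duplicate if every rotatable-bond torsion agrees within 20° (circular) or
the heavy-atom best-fit (Kabsch) RMSD is below 0.5 Å. These tolerances are
not from the reference study; they merge vibrational noise without merging
distinct torsional wells, and both are configurable. On very small test
molecules the RMSD criterion is the binding one, so distinct wells must
differ by large torsions to survive — a property of the criterion, not a
bug.

The driver is validated against an analytic one-torsion potential,
E(θ) = 2.0(1+cos θ) + 0.6(1−cos 3θ) kcal/mol, whose minima a dense 1° grid
scan locates at θ = 0° (E = 4.0) and ±136.6° (E = 0.76); with ≥ 30 random
starts the driver recovers exactly these wells.

H-bond geometric criteria are not standardised in the reference analysis;
the defaults follow common practice: H···O ≤ 2.5 Å and ∠N–H···O ≥ 120°,
with an alternative heavy-atom-only mode (N···O ≤ 3.5 Å) for ensembles
lacking hydrogen coordinates. Donor–acceptor pairs whose covalent
H→acceptor path is 3 bonds or shorter are excluded, which removes the
trivial contact of an amide H with its own carbonyl (a 4-atom
pseudo-cycle).

## Ensemble statistics

Boltzmann weights are w_i ∝ exp(−ΔE_i/RT), R = 0.0019872 kcal mol⁻¹ K⁻¹,
default T = 298.15 K (the solution-NMR comparison temperature; the
reference analysis does not state its temperature). Class populations (the
α-turn class = conformers with H-bond B, the γ class = H-bond A) are summed
weights; they are reported against two denominators — the windowed set and
the full deduplicated set — because "fraction of all conformers" is
ambiguous between the two.

Torsion averages are circular means. The reported per-residue averages are
Boltzmann-weighted, because the reference averages are explicitly taken
over the conformers dominating the population; unweighted variants are in
the report as well. Mean dα over the α-turn class is unweighted (a
weighted variant is reported alongside). The turn designation joins the
φ/ψ-region labels of pseudo-residues 2–4 computed from the α-class torsion
means; the γ type (inverse vs classic) is classified from the γ-class
central residue (position 4, the residue bracketed by the C7 bond).

The φ/ψ region rectangles (A, B, αL, fallback X) live in a YAML config, not
in code. They are calibrated stand-ins chosen so that canonical helical and
left-handed regions carry their conventional names; they are *not* the
nine-type α-turn classification of the protein-structure literature, and
users wanting that classification should substitute their own region file.
Rectangles are closed at the lower bound, open at the upper, with 180°
treated closed (it equals −180° on the circle); first match wins. γ-turn
windows are symmetric about the canonical (∓75°, ±65°) ideals: inverse for
φ ∈ [−110, −50), ψ ∈ [40, 110), classic for the mirror image.

## NMR evidence

The temperature coefficient Δδ/ΔT of an amide NH (ppb/K) is the
least-squares slope over the full series (not a two-point difference),
reported signed and classified on magnitude: in CDCl₃, |Δδ/ΔT| ≥ 4 ppb/K is
read as an equilibrium between H-bonded and free states, ≤ 3 ppb/K as fully
non-H-bonded, between as indeterminate. The DMSO-titration excursion
δ(30%) − δ(0%) classifies a proton as shielded (intramolecularly bonded,
|Δδ| < 0.5 ppm) or exposed (≥ 0.5 ppm). All thresholds are arguments with
these defaults; they follow the usual CDCl₃-mode reading of such data (the
DMSO-solvent convention is different and deliberately unsupported).

## Synthetic data

The generator builds ideal peptide backbones (N, H, Cα, C′, O per residue)
by sequential internal-coordinate (NeRF) placement with standard bond
lengths and angles (N–Cα 1.458 Å, Cα–C′ 1.525 Å, C′–N 1.329 Å, C′=O
1.231 Å, N–H 1.010 Å; angles 111.0°/116.2°/121.7°), trans amides (ω =
180°), and carbonyl O / amide H placed trans across the amide plane.
Rebuilding φ/ψ from the coordinates reproduces the input torsions to well
within 0.5°. These backbones are peptidic, whereas the scaffold is not:
they exercise the detection geometry (ring sizes, dα, torsions), not
force-field energetics, scaffold strain, or solvent effects — so passing
synthetic tests demonstrates the measurement machinery, not chemistry.
Decoy sets draw φ/ψ uniformly; energy sets and NMR series are generated
with assigned labels/known slopes for closed-form checks. All generators
are seed-deterministic.

## Problem sizes and numerical choices

The ensemble-level checks regenerate both epimer ensembles at the full
search size (972 starts each) with the MMFF backend; one compound takes a
few minutes on one CPU. Weights are computed with the minimum energy
shifted to zero for overflow safety. Circular means use atan2 of weighted
sine/cosine sums. Dihedrals follow the IUPAC sign convention, wrapped to
(−180°, 180°], and agree with an independent implementation to 1e−6°.
Degenerate inputs (empty ensembles, absent classes, too-few NMR points,
non-monotone temperatures) raise typed errors rather than returning
sentinel values; an absent class is reported as null in the JSON report.

## Known limitations

* MMFF94 gas-phase energetics differ from the original engine's; absolute
  energies, exact windowed counts, and class energy gaps are not
  comparable across backends — only flags, geometry, and dominance
  patterns are.
* The region map is a calibrated stand-in (see above).
* No entropy/solvation corrections; populations are raw Boltzmann over
  minimized energies.
* Aromaticity/tautomer perception is whatever RDKit provides; pKa and
  charge states are out of scope.
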