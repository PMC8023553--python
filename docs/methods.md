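# Methods

This note documents the models and numerical choices behind `dimerfeat`,
what the synthetic structure generator does and does not emulate, and the
limitations a user should know before trusting numbers on real data.

## Surface areas and residue classes

The accessible surface area engine is a rolling-probe numerical surface.
Each atom's sphere of radius r_vdw + r_probe is sampled on a Fibonacci
(golden-angle) lattice; a sample point is accessible when it lies outside
every neighbouring atom's expanded sphere, and the atom's area is the
accessible fraction times 4π(r_vdw + r_probe)².  Defaults: probe 1.4 Å
(water), 960 points per atom, heavy atoms only (hydrogen placement varies
wildly between deposited structures, so including it would make areas
incomparable across inputs).  Van der Waals radii are Bondi-like — C 1.70,
N 1.55, O 1.52, S 1.80 Å, 1.80 Å for anything unlisted — and configurable.
The lattice is deterministic, so areas are bit-reproducible; for an isolated
atom the engine recovers the closed form 4π(r + r_probe)² to machine
precision (every lattice point is free), and against a dense 20 000-point
surface the 960-point default agrees to about 1–2 % per residue on
random-coil test structures.  Exactly coincident atoms are a degenerate
input: boundary sample points are owned by the lower-index atom, so the
union area is counted once rather than twice or zero times.

Relative solvent accessibility divides a residue's ASA by its Sander–Rost
extended Gly-X-Gly reference area.  RSA can exceed 1 for distorted
conformations; it is logged, not clamped.  Classification uses the
**monomer-form** RSA — each chain's surface computed with the partner
removed — because interface residues are, by definition, surface residues
that the partner buries; classifying on complex-form RSA would mislabel the
most deeply buried interface residues as core.  The 0.20 cutoff is strict
(RSA = 0.20 exactly is core), and the 5 Å interface rule is strict-less
(distance exactly 5 Å is non-interfacial); both cutoffs and the
heavy-atom-only distance rule are configuration keys.

ΔASA = compASA − monASA is ≤ 0 wherever complexation buries area.  The
literal relASA = ΔASA/monASA is the default output; a buried-fraction
convention (−ΔASA/monASA, optionally ×100) is provided because large
positive per-cent values of "relative area lost" are common in interface
tables and the sign/scale convention differs between sources.  monASA = 0
with ΔASA ≠ 0 has no defined ratio and is emitted as missing with a
warning; 0/0 is defined as 0.

## Conservation

A PSSM's weighted-observed-percentage block, divided by 100 and renormalized
per position, gives the position distribution p; conservation is the
Jensen–Shannon divergence against a background f, in bits, so scores lie in
[0, 1] with higher = more conserved.  0·log 0 is handled exactly (masked
before the log) and a 1e-10 floor guards the remaining log arguments.
All-zero PSSM rows are replaced by the background with a warning.  No
sequence-window smoothing or gap weighting is applied — the score is the
bare divergence.

Three named backgrounds ship with the package.  `blosum62` holds the
standard BLOSUM62 amino-acid marginal frequencies.  The TM-helical (`slim`)
and β-barrel-TM (`bbtm_tm`) vectors are **synthetic stand-ins** (their
files are marked `.synthetic.txt`): the published membrane-specific
matrices' frequency vectors are not redistributable here, so these are
constructed by tilting the BLOSUM62 background toward hydrophobic (and,
for the barrel variant, aromatic) residues via the Kyte–Doolittle index and
renormalizing.  They have the right qualitative composition for exercising
the fold-dependent "appropriate background" logic, but results on real
membrane proteins should use genuine vectors, which can be supplied as a
20-line name/value file through the configuration.

## Interaction detectors

All detectors are purely geometric, operate only between the two chains,
and are invariant under rigid motion and chain exchange.  Thresholds
default to values conventional in binding-analysis tools: close contacts
2.5/4.0 Å; hydrophobic C–C 4.0 Å; hydrogen bond donor–acceptor 4.0 Å with
D–H–A within 40° of linear; salt bridge 5.5 Å closest inter-group atoms;
π–π centroid 7.5 Å with normals ≤ 30° apart and projected offset within
ring radius + 0.75 Å; T-stack centroid 5.0 Å with normals 90° ± 30°;
cation–π 6.0 Å with the cation's in-plane projection inside the padded
ring.  Every number is a config key.

Design points worth knowing:

- *Hydrogens.*  Detectors use hydrogens when present (the H-bond angle
  test) but never add them; without a donor hydrogen the H-bond criterion
  degrades to distance-only and the record is flagged `no_hydrogen`.
- *Histidine charge.*  HIS joins the cationic groups only when both ring
  nitrogens carry explicit hydrogens, or when `his_charged` is set —
  protonation is unknowable from heavy atoms.
- *Termini.*  The N-terminal backbone nitrogen and a C-terminal OXT count
  as charged groups for salt bridges.
- *Multiplicity.*  A residue pair may contribute to several kinds (a salt
  bridge is usually also a 4.0 Å close contact), except within the π
  classes, where each ring pair gets at most one label with π–π taking
  precedence over T-stack.
- *Counting unit.*  Close and hydrophobic contacts count atom pairs;
  H-bonds count donor/acceptor-atom pairs; salt bridges count residue
  pairs (closest-atom geometry retained on the record).
- Ring planes are least-squares fits (SVD); rings with missing atoms are
  skipped with a warning rather than guessed.
- The spatial index (k-d tree) is required by tests to agree exactly with
  exhaustive enumeration; both code paths are callable.

## Propensities and statistics

C_factor(class, residue) = f_class/f_total.  The algebraic identity
Σ_residues f_total·C_factor = 1 holds exactly per class and is asserted to
1e-12.  Correction multiplies selected feature columns by each row's
(class, residue) factor; relASA is exempt by default, residue types with no
occurrences anywhere get a missing factor (never 0), and rows lacking a
factor pass through flagged.  Quartiles use linear interpolation between
order statistics (the default of mainstream dataframe stacks — stated
because quartile conventions differ); SD is the n−1 sample estimate.
Class comparisons use the classic equal-variance independent t-test (an
unequal-variance switch exists) and one-way ANOVA; p-values are raw, with
Benjamini–Hochberg available but off by default.  Summary rows are ordered
by increasing Kyte–Doolittle hydropathy — ARG (−4.5) first, ILE (+4.5)
last.  Raw, corrected, and min–max-scaled variants of a column can all be
produced, since published "normalized" interface statistics rarely state
their scaling pipeline.

## Synthetic structures

The fixture generator produces two families.  *Motifs* realize one
interaction geometry exactly (to 1e-6 Å/°): ideal 1.39 Å aromatic hexagons
for stacking, a real guanidinium/carboxylate atom layout for salt bridges,
backbone N–H against a serine OG for hydrogen bonds, and so on — real atom
names so the typing tables are exercised, not bypassed.  *Random-coil
dimers* are self-avoiding CA walks (3.8 Å steps) dressed with N/C/O/CB at
plausible bond lengths, with seeded residue identities and B-factors.

These structures validate geometry, not biology.  They contain no secondary
structure, no membrane, no realistic packing density, no alternate
conformations and no missing atoms; their residues are almost all solvent
exposed, so class balances on them are nothing like a real membrane-protein
dataset.  Passing tests therefore demonstrate that each computation is
*correct on known geometry* — not that feature distributions on real
structures will match any published dataset.  Pre-processing a real
dataset additionally involves curation the package deliberately does not
automate (see Limitations).

## Problem sizes

The test suite and `scripts/acceptance.py` run on structures of 5–15
residues per chain, batches of 3–12 dimers, a 20 000-point dense reference
surface, 50 000-point antithetic Monte Carlo oracles in the tests, and
10 000 random distribution pairs for the divergence properties — sizes at
which every oracle comparison is exhaustive and the whole suite completes
in well under a minute on one core.

## Limitations

- PDB input only (fixed-column, via gemmi); no mmCIF, no symmetry-generated
  assemblies, no repair of missing atoms.  Residues with incomplete side
  chains are used as-is for areas and flagged by skipped-ring warnings for
  π detection.
- Model 1 only for multi-model files; alternate locations resolved by
  highest occupancy with alphabetical tie-break.
- TM trimming consumes a plain per-chain range file; deciding those ranges
  (annotation databases plus visual inspection) is outside the tool.
- The tool consumes PSSMs; it does not run the sequence search that builds
  them.
- ASA here is a rolling-probe surface, not the DSSP algorithm; RSA values
  for residues near the 0.20 boundary can differ slightly from
  DSSP-derived pipelines.
- Hydrogen-bond detection without explicit hydrogens is distance-only and
  correspondingly permissive.
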