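# Methods

`sahelix` implements the computational half of a single-α-helix (SAH)
design-and-analysis workflow: repeat-based sequence design, geometric
salt-bridge assignment in helices, a pair census over helix structure sets,
and salt-bridge kinetics from trajectories.  This note records the models,
the parameters that matter, and the design choices made where more than one
reasonable convention exists.

## Sequence model

De novo SAH designs are tiled 7-residue repeats (`AEEEXXX`, X ∈ {K, R})
flanked by an N-terminal Ser and a C-terminal Trp, the caps carried by the
expression constructs this design style targets.  A core of 96 residues is
13 full repeats plus a 5-residue partial repeat; **truncation keeps the
repeat prefix**, which is the only arrangement consistent with the
constructs' 98-residue length and their predicted monomer masses
(EK3 11.8 kDa, EK2R1 12.2 kDa).

Charge pairings are oriented: `X->Y(+n)` puts residue type X at position i
and Y at i + n, n ∈ {3, 4} (one helical turn).  Sequences are linear — no
pairing crosses the termini.  Each interior `AEEEXXX` repeat contributes
3 `E->X(+3)` pairs within the repeat, 3 `X->E(+4)` pairs to the next
repeat, and 2 of each alternate (`E->X(+4)`, `X->E(+3)`).

Masses are **average** (not monoisotopic) residue masses plus one water,
reported to 0.1 kDa, matching the precision at which predicted monomer
masses are quoted.  Helical-net coordinates use 100°/residue
(3.6 residues/turn); the axial unit is one residue of rise.

### The myosin-6 fixtures are synthetic stand-ins

`M6WT`, `M6K` and `M6R` in `data/myosin6_synthetic.fasta` are **synthetic**
sequences, not the natural myosin-6 SAH segment.  They are constructed to
match every published constraint on the real constructs — a 97-residue core
with S/W caps (99 aa), M6WT composition %R = 19, %K = 11, %E = 30, and
monomer masses 12.5 / 12.0 / 12.8 kDa — with M6K and M6R derived from the
stand-in by the same all-R→K / all-K→R substitution rule as the real
re-engineered constructs.  Composition and mass arithmetic on them is
therefore exact; anything depending on the natural residue order is not
represented.

## Helix geometry

Ideal helices are built residue-by-residue (NeRF internal-coordinate
placement) with φ = −57°, ψ = −47°, trans peptide bonds, and
Engh–Huber-style backbone covalent geometry.  Side chains are transplanted
from Chemical Component Dictionary ideal-geometry templates superimposed on
each backbone triad, then posed by explicit rotations about the χ bonds.
All defined χ torsions default to trans (180°).  Hydrogens are ignored
throughout; every criterion below is defined on heavy atoms.

Salt-bridge rule (used identically in the survey and trajectory analyses):
the centroid of the Glu OE1/OE2 carboxylate oxygens must lie **strictly
within 4 Å** of the Lys NZ, or of the nearest of the Arg NE/NH1/NH2
nitrogens.  Exactly 4 Å is not a bridge.  Steric clash: any inter-residue
heavy-atom contact strictly below 2.5 Å.

Rotamer bins partition (−180°, 180°]: t (χ ≥ 120° or χ ≤ −120°),
g+ (0° ≤ χ < 120°), g− (−120° < χ < 0°); the boundary values ±120° are t
and 0° is g+.  Representative angles t = 180°, g+ = 60°, g− = −60° are
used whenever a bin, rather than an angle, is requested.

### Rotamer-combination scan

For each pairing mode the pair is embedded centrally in a 12-residue
poly-Ala ideal helix and all 81 (χ1, χ2)-bin combinations are evaluated.
Torsions beyond χ2 (Glu χ3; Lys/Arg χ3, χ4) are not part of the binned
analysis, and pinning them trans turns out to leave the (+3) modes with no
capable combination at all under the strict 4 Å / 2.5 Å rules — an
artefact of the rigid representative-angle grid, not of helical geometry.
The scan therefore tries every arrangement of the distal torsions over the
three representative angles and reports the most favourable one per
combination; a combination is **capable** iff some arrangement is both
bridge-forming and clash-free.  With this choice the capable sets contain
the combinations that dominate real helix surveys (g−g−/g−t for
`E->K(+3)`, g−g−/tt among those for `E->R(+3)`), and Arg modes offer more
capable combinations than the corresponding Lys modes.  Pass
`distal_angles=(180.0,)` to recover the pinned-trans behaviour.

## Survey

Helices are extracted as maximal runs of DSSP-helical residues (H/G/I) of
≥ 12 residues.  Pair positions are classed **N-terminal** (any residue in
the first four of the helix), **C-terminal** (any in the last four) or
**central** (all residues ≥ 4 positions from both ends); a pair touching
both terminal windows of a short helix is classed N-terminal (the
convention had to pick one; it is documented here and affects only helices
shorter than ~12 residues plus the offset).

Expected pair counts use a single-residue composition model: for every
eligible start slot of a (mode, class) the product of the two residue-type
frequencies, frequencies computed over the whole dataset by default
(per-segment frequencies are available via `frequencies="segment"`).
Nothing is conditioned on the helix length distribution beyond the slot
count itself.  Salt-bridge fractions are computed over pairs whose
side-chain atoms are present; pairs with missing atoms stay in the
observed count and are logged.  Rotamer tables are collected for central
pairs only, split by bridged/non-bridged.

Resolution and redundancy culling of the input structure list is the
caller's responsibility, and no attempt is made to reproduce any particular
published cull; the survey's correctness is instead demonstrated by exact
recovery of planted fractions on synthetic ensembles (below).

## Trajectory statistics

Distances follow the same centroid-to-nitrogen rule per frame; a bridge is
formed at a frame iff its distance is strictly below 4 Å.  Distance
histograms use 0.1 Å bins with edges at bin multiples.  Occupancy of a
mode is 100 × formed frames / total frames pooled over all pairings of the
mode.

A **formation event** is a maximal run of consecutive formed frames;
lifetime = run length × frame interval (default 1 ps/frame, i.e. a 2 fs
integration step with frames recorded every 500 steps).  Events are *not*
bridged across gaps — a single broken frame ends the event — because any
smoothing rule would be arbitrary and the literal definition is exactly
reproducible.  Runs touching either trajectory end are flagged censored
and included in means by default (`drop_censored` gives the alternative).
Pooled-event means are the default; a per-pair averaging
(`mean_lifetime_per_pair`) is also provided since "the average lifetime
over all pairings" admits both readings.  Lifetime histograms use 5 ps
bins.

Simultaneous (network) occupancy: every residue participating in ≥ 2
potential bridges is a centre; for each pair of its bridges the fraction
of frames with both formed is averaged over all centres sharing the same
(centre letter, partner letters, signed offsets) label — e.g.
`R->E(-4)&E(+3)` is an E–R–E network.

Helicity is the per-frame fraction of residues assigned H/G/I by DSSP
(computed through mdtraj).  This is a plain-DSSP stand-in for
continuous-assignment variants; the assigner is pluggable (`psea` gives a
CA-only alternative).  Note DSSP never assigns the first/last residue of
even a perfect helix, so a rigid 98-residue ideal helix scores ≈ 0.98,
not 1.0.

## Synthetic generators

The generators emulate the *statistics* the analyses consume, not physics.

* Two-state dwell processes are discrete-time memoryless: geometric on/off
  dwell lengths with configurable means (frames), initial state drawn from
  the stationary distribution p_on = mean_on/(mean_on + mean_off).
* Distance emissions: formed frames draw from a 0.6/0.4 mixture of
  Gaussians at 2.8 and 3.7 Å (σ = 0.15 Å), the two direct-bridge
  geometries, clipped strictly below 4 Å so that thresholding reproduces
  the state series exactly; broken frames draw above 4.5 Å, with an
  optional narrow "indirect" (water-separated) component at 5.6–6.0 Å that
  is never counted as a bridge.
* Planted ensembles pose a chosen, exact number (`round(rate × n_pairs)`)
  of each mode's pairings at capable rotamer combinations and the rest at
  combinations whose charges stay beyond 4.5 Å under every distal
  arrangement.  The default planting sequence isolates pairs
  (`AAEAAKAA`/`AAEAARAA` blocks, four pairs per mode) so no two pairings
  share a residue; sequences with overlapping pairings are rejected rather
  than silently resolved.  Optional isotropic Gaussian jitter models
  coordinate noise.
* Dynamic trajectories keep a rigid ideal-helix backbone and switch each
  pair's side chains between one capable and one non-capable combination
  according to its dwell process.

All generators are pure functions of (parameters, seed).  What passing
tests show: the analysis pipeline recovers planted fractions exactly
(deterministic geometry), and occupancies/lifetimes within sampling error.
What they do not show: behaviour on real data with backbone flexibility,
correlated pair kinetics, water-mediated interactions, or non-ideal
side-chain geometry.

## Problem sizes and numerical choices

The shipped checks use ensembles of 5–8 structures (64-residue helices,
4 pairs per mode), dynamic trajectories of a few hundred frames, 10⁵-frame
dwell series for parameter-recovery grids (4 × 10⁵ for single-point
occupancy/lifetime recovery), and pooled series of 2 × 10⁶
pair-frames for the Lys/Arg lifetime contrast (the analysed constructs
pool ~40 pairings per mode over 2 × 10⁵ frames, so this is a same-order,
scaled-down pooling).  Coordinates are float32 (structure-container
native); all distance comparisons are strict inequalities, and tests avoid
poising values exactly on binary-representable boundaries.

## Known limitations

* The theoretical scan explores representative bin angles only; real
  rotamer distributions are continuous, so capable/non-capable is a
  statement about the grid, not an energy.
* No electrostatics, no solvent, no force field anywhere: every rule is
  geometric.
* The expected-count model ignores residue-pair correlations within
  helices; enrichment ratios inherit that assumption.
* The myosin-6 fixtures are composition/mass stand-ins (see above).
* DSSPcont-style continuous weighting is approximated by plain DSSP.
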