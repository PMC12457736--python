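# Methods

This note records how `lipscan` computes what it computes, which knobs exist,
and which design points were genuinely open.

## Structure model

PDB files are parsed with gemmi; model 1 only. Hydrogens are discarded
(heavy-atom SASA convention; crystal structures rarely resolve them), waters
always removed, and alternate locations resolved to the highest-occupancy
copy with ties broken by altloc letter. Other HETATM groups (ligands,
modified residues) are kept aside for SITE bookkeeping but never enter the
surface, volume or profile computations. Selenomethionine and similar
modified polymer residues are mapped to their parent residue and flagged
non-canonical; non-canonical residues are excluded from relative-exposure
tallies (their maxima are undefined) but participate in everything else.
SITE records are read directly from the PDB text with continuation records
merged per site identifier; members that do not resolve to a protein residue
are flagged, not dropped.

Residues are identified by (chain, author seq-number, insertion code)
throughout, and spans are inclusive. Two residues are *consecutively solved*
when their peptide bond is geometrically present (C–N distance ≤ 2.5 Å).
Author-numbering jumps without a broken bond are renumbering artifacts: they
do not split scan windows but are reported in the run summary, as are true
structural gaps.

Atom polarity is element-based — N, O polar; C, S apolar — matching the
NACCESS polar/non-polar partition. Whether sulfur should count as polar is a
convention choice; it is a one-line edit in `data/polarity.txt`. Radii are
the NACCESS-style Chothia set (aliphatic C 1.87 Å, trigonal/aromatic C
1.76 Å, N 1.65 Å, O 1.40 Å, S 1.85 Å), also an editable table.

## SASA

Shrake–Rupley with a deterministic golden-spiral (Fibonacci) lattice —
no random sphere points, so runs are reproducible without seeds. Defaults:
probe 1.4 Å, 960 points/atom. Isolated-atom areas are exact to well under
1 %; the binary point count quantizes per-atom area in ~0.14 Å² steps at 960
points, so individual atoms can differ from a densely converged answer by up
to ~0.7 Å² (mean ~0.15 Å²). Raise `n_points` where per-atom precision
matters more than speed.

Because a point lattice is orientation-dependent, all profile and ΔSASA
computations first move the analysis context into a canonical principal-axes
frame (centroid-centred, eigenvectors of the coordinate second-moment
matrix, signs fixed by the largest-magnitude projection, right-handed).
Results therefore do not depend on how the input file happens to be
oriented, and rigid copies of a subunit — the two chains of a symmetric
homodimer — produce identical profiles. A structure and its cropped version
always share one frame, which keeps the per-atom quadrature strictly
comparable: a retained residue's SASA can only grow on cropping, exactly.

ΔSASA is defined as SASA(cropped) − SASA(full), i.e. the exposure a residue
*gains* when a segment is cropped out; the cLIP rule selects residues with
ΔSASA strictly greater than 1.0 Å². The threshold is applied to all-atom
per-residue ΔSASA (side-chain-only is a conceivable alternative; all-atom is
the default and the implemented choice).

Relative exposure divides a canonical residue's SASA by its type's
theoretical maximum (Tien-style values, editable table). Classes: buried
< 10 %, intermediate 10–40 % inclusive, exposed > 40 %. Values above 1 are
possible for distorted geometry and are reported unclamped.

## Voronoi volumes and ρ

Plain bisector-plane (unweighted) Voronoi tessellation of atom centres via
Qhull; each bounded cell's volume is its convex-polyhedron volume. Cells
touching the unbounded region have no finite volume; they are excluded
*pairwise* from ρ — an atom contributes its standard volume V° only if it
also contributes an actual volume V. Interfaces that carry an mLIP are
buried, so this drops few atoms in practice; profiles flag windows where no
interface atom has a bounded cell (ρ undefined). Radical-plane weighting is
a recorded alternative, not implemented; standard and actual volumes must
come from the same partitioning rule for ρ ≈ 1 to mean "normally packed".

Standard volumes ship as a (residue, atom) → Å³ table assembled from
ProtOr-style chemical-class mean volumes (united heavy atoms: CH₃ 36.7,
CH₂ 23.2, CH 14.4, aromatic CH 20.4, bare sp² C 9.7, amide N 15.7, carbonyl
O 15.9, hydroxyl O 18.0, thiol S 36.7, thioether S 29.2 Å³, etc.). Unmatched
atom names fall back to an element-level median with a warning. Since the
detection rule compares ρ to its own profile mean − SD, the absolute scale
of the table largely cancels; the table dialect matters only if absolute ρ
values are interpreted.

## Profiles and detection

Window length 8, value assigned to the 4th residue, so the first 3 and last
4 positions of every continuously solved segment are undefined; windows
never span structural gaps. In intra mode the environment is the probe's own
chain minus the probe; in inter mode it is the whole partner chain, and both
orderings of a chain pair are scanned. For oligomers beyond dimers the user
picks the pair.

Interface membership needs more than 0.1 Å² of buried area per atom — a
small positive cut that suppresses quadrature noise (configurable). PR uses
buried area rather than the residual exposure of contact atoms: buried area
is the standard interface measure and keeps PR independent of how exposed
the non-interface face is. An interface with buried polar area but zero
buried apolar area yields a +∞ PR, stored as a 10⁶ cap for plotting and
treated as above any threshold.

Detection: (1) local PR maxima > 0.8 (plateaus allowed); (2) extension in
both directions over contiguous defined points while PR > 0.5; (3) merge of
overlapping candidate regions; (4) a region survives only if at least one of
its residues has ρ below the profile mean minus one SD, the moments being
computed from that profile alone (per chain, per mode — never pooled).
The ρ test reads the profile values at the region's own residues. mLIP
residues can still appear in another mLIP's cLIP; full-LIP tallies count
each residue once.

ρ statistics and thresholds (0.8 / 0.5 / mean − 1·SD / 1.0 Å² / window 8 /
probe 1.4 Å) are the published operating point and are the package defaults;
every one of them is a `DetectionParams` field or CLI flag.

## Statistics

* Enrichment: EF = ν(in)/ν(out) per amino acid and per polarity group
  (non-polar AGVLIPMCFW, polar-uncharged YSTNQ, negative DE, positive KRH —
  the only partition-consistent grouping). Group EF uses summed member
  frequencies; standard errors by binomial propagation on both frequencies;
  EF with ν(out) = 0 is flagged undefined rather than infinite.
* Two-proportion Z-test: pooled estimate, two-tailed normal p. No
  multiple-testing correction anywhere, by design.
* Mean differences over user-supplied score tables (conservation, stability;
  the scores' sign convention is carried as metadata, never interpreted):
  pooled-variance Student t by default (Welch available), point-biserial r
  derived from t (so r² = t²/(t² + df) holds identically), Cohen's d with
  the pooled SD.
* Secondary-structure masks come from user-supplied DSSP output files,
  parsed with biopython: alpha = 'H' only, beta = 'B'/'E', coil = blank;
  3₁₀/π helices, turns and bends are deliberately excluded as low-abundance
  noise sources.

## Synthetic structures

The generator builds ideal-geometry backbones (NeRF internal coordinates;
helix φ/ψ = −57°/−47°, extended −139°/135°, ω trans, standard bond lengths
and angles, L-chirality checked against reference amino-acid geometry) with
side chains to the γ atom at χ₁ = −65°. Asn and Asp additionally get their δ
oxygens/nitrogen: without them a carboxamide or carboxylate would present no
polar surface, and polar contact faces could not be designed. Geometries:
single helix, extended strand, a one-chain two-helix antiparallel bundle
(with a numbering jump and an unbonded gap between the helices), and a C2
symmetric dimer. Selected residue positions can be rotated to face the
partner helix.

The canonical control pair fixes the study conditions for all end-to-end
tests: a *polar bundle* — 18-residue helices, Ser/Asn at heptad a/d-like
face positions, axis separation 10.5 Å (loose) — and an all-leucine bundle
at 9.5 Å (tight, leucine-zipper-like). The polar bundle yields two
intra-chain mLIPs (one per helix, peak PR ≈ 1.3) under default thresholds;
the leucine control yields none (peak PR ≈ 0.6). These lengths and spacings
were chosen once for physical plausibility and detection-margin robustness.

What the generator does *not* emulate: real rotamer distributions, loop
irregularity, crystallographic noise, buried water, or the size and fold
diversity of real domains. Passing tests on these fixtures demonstrate that
the definitions, thresholds and bookkeeping behave as specified — not that
detection sensitivity/specificity on real proteome-scale data matches any
particular figure. Dataset-scale composition claims require the original
domain structure files, which are an external download; `lipscan.batch`
implements that pipeline and is exercised on synthetic domains.

## Numerical choices and degenerate inputs

* Fewer than 8 consecutively solved residues: empty profile with a warning.
* Empty interface window: PR and ρ undefined at that point; undefined points
  never break determinism and are serialized as `NA`.
* Degenerate geometry (collinear/coplanar atom sets) is rejected by the
  Voronoi engine with a clear error.
* Profile TSVs print 12 significant digits so re-parsed values round-trip.
* Identical input and parameters give bit-identical outputs; there is no
  randomness anywhere in the analysis path.

## Known limitations

* The SASA engine is a point-quadrature Shrake–Rupley, not a z-slice
  integrator; per-atom areas carry ~0.1–0.7 Å² quantization at the default
  960 points. The 1.0 Å² cLIP threshold sits comfortably above this noise,
  and the 0.1 Å² interface cut filters it, but single-atom areas should not
  be over-interpreted.
* Surface Voronoi cells are excluded rather than capped by a solvent
  pseudo-layer; ρ over a mostly-exposed atom set is reported as undefined
  rather than extrapolated.
* mmCIF input, NMR ensembles, automatic biological-unit assembly and 3D
  visualization are out of scope.
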