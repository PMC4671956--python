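# Methods

## Scope and model

`pocketstates` analyzes the conformational states of the Y220C
mutation-induced crevice on the p53 DNA-binding domain. The central model is
deliberately minimal: the open/closed state of the cryptic subsite III is a
deterministic function of the Cys220 χ1 rotamer, and pocket plasticity is
summarized by two named inter-atomic distances. No energetics, no surface
areas, no simulation physics — the package measures geometry and counts
states.

## χ1 and rotamer binning

χ1 is the N–Cα–Cβ–Sγ torsion under the IUPAC convention (right-handed about
Cβ looking from Cα; cis = 0°), range (−180°, 180°]. The three staggered
wells sit at −60° (g−), ±180° (t) and +60° (g+). Only well centers are
physically meaningful; the bin edges are a package choice placed at the
midpoints between wells (±120° and 0°), half-open on the left so every
angle maps to exactly one state. The state map g− → open, t → closed
follows the crystallographic observation that only those two rotamers occur
in structures; g+ appears in simulation but never in a crystal, so it maps
to "unassigned" rather than being forced into either pocket state.

Degenerate geometry (colinear triples, sin θ < 1e-8) raises instead of
returning a garbage angle. Superposition uses the Kabsch least-squares
proper rotation (via `scipy`'s `align_vectors`); reflections are never
admitted.

## Pocket metrics

- `pocket_width` = d(Thr150 Cα, Pro222 Cα): the rim separation between the
  rigid S3/S4 loop and the mobile S7/S8 loop. Crystal structures of
  ligand complexes span roughly 7.1–8.8 Å; the wild type is narrower
  (6.7/6.9 Å per chain).
- `proline_gate` = d(Pro151 Cδ, Pro223 Cδ): small values indicate the
  hydrophobic collapse of Pro151 onto Pro223 that blocks the central cavity.

Each (model, chain) pair counts as one observation in ensemble summaries,
because the deposited structures show per-chain differences. Values are
computed at full precision and rounded to 1 decimal only in reports.
Unresolvable (model, chain) pairs are listed in the summary's `failures`,
never silently dropped.

The displacement profile superposes on Cα atoms of a caller-chosen rigid
selection and reports the per-residue maximum over backbone atoms
(N, CA, C, O). For the Y220C loop analysis the recommended fit selection is
the domain core (residues 94–312 excluding 219–224): the source superposition
convention is unstated, so any displacement magnitude quoted through this
package is conditional on that documented assumption — fitting on the
flexible loop itself would mask its displacement.

## Interaction detection

Halogen bonds: halogen X ∈ {Cl, Br, I} on a hetero (ligand) residue, bonded
carbon = nearest same-residue carbon within 2.3 Å, acceptors are O/N/S
heavy atoms of other residues. The distance cutoff defaults to the Bondi
van der Waals radius sum (O 1.52, N 1.55, S 1.80, Cl 1.75, Br 1.85, I
1.98 Å; Bondi, J. Phys. Chem. 68:441, 1964) — a 3.0 Å Br···O contact
passes its 3.37 Å sum — with a fixed-cutoff mode as an alternative. The
σ-hole angle threshold defaults to a permissive 140°, exposed as a flag,
because near-ideal observed geometry (~174°) is a property of good
interactions, not a detection boundary.

Hydrogen bonds use a heavy-atom-only criterion (N/O/S pairs within 3.5 Å,
excluding intra-residue and covalent (< 1.8 Å) pairs, each unordered pair
once). No angular term is applied: the crystal structures this targets are
1.3–1.8 Å resolution and carry no hydrogens, so any donor-hydrogen angle
would be modeled, not measured. The 3.5 Å cutoff is an assumption and is
flagged in reports. Water-mediated contacts appear as chained records
(protein–water, water–ligand), not as a dedicated record type.

Structural waters: W1 must be within hydrogen-bond distance of both the
Val147 and Asp228 backbone oxygens; W2 of the Leu145 backbone oxygen and of
Thr230 through either OG1 or the main-chain N (the chain-dependent
alternative seen in the deposited structures). When several waters qualify,
the smallest summed distance wins; exact ties go to the lower residue
number, which makes tagging stable under file reordering. Partial
occupancies are not filtered — every water of the chain enters the B-factor
statistics, since the quoted ranges give no occupancy criterion.

## Affinity arithmetic

ΔG = RT ln K_D with R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹ and standard state 1 M.
LE = |ΔG|/N_heavy with N_heavy parsed from a molecular formula (no
structure perception needed for counting). The default temperature is
298 K: the LE figures quoted for the diiodosalicylate pair (0.35 at 820 μM
/ 12 heavy atoms; 0.38 at 21 μM / 17) reproduce at 298 K after 2-decimal
rounding and do not at 310 K, so 298 K is the implied convention and the
package adopts it. LE is reported as a positive magnitude. Fold changes are
K_D ratios, with a 1-significant-figure label (39.05 → "40-fold") for
reporting.

## Synthetic data: what it emulates and what it does not

The generator produces valid fixed-column PDB content for every pipeline
stage:

- **Cysteine fragments** are built by internal-to-Cartesian (NeRF)
  placement from ideal internals (N–Cα 1.458 Å, Cα–Cβ 1.530 Å, Cβ–Sγ
  1.810 Å; N-Cα-Cβ 110.5°, Cα-Cβ-Sγ 114.4°). Correctness is defined by
  round-trip — the measured χ1 equals the commanded value to 1e-6 — not by
  force-field fidelity.
- **Pocket fixtures** carry only the anchor pseudo-atoms the metrics and
  detectors read (Thr150 Cα, Pro151 Cδ, Leu145/Val147/Asp228 O, Pro222 Cα,
  Pro223 Cδ, Thr230 OG1/N, a Cys220 fragment, bridge waters, an optional
  C–X probe). Bridge waters are placed on the perpendicular bisector plane
  of their two partners, so a commanded equal distance to both is exact;
  geometrically unsatisfiable commands (distance < half the partner
  separation) raise a construction error. The fixtures are not physically
  complete proteins: no sterics, no full chains, no symmetry.
- **χ1 trajectories** come from a three-state Markov chain with
  T(i→j) = s·[i=j] + (1−s)·π_j. This rule was chosen because π·T = π holds
  algebraically for every stay probability s, so commanded populations are
  testable without burn-in; s controls dwell times (mean dwell in state i
  is 1/((1−s)(1−π_i))) without touching the stationary distribution. The
  emitted angle is the well center plus wrapped-normal noise (sd default
  15°; must stay < 60° so wells cannot leak across bin edges in bulk).
  This emulates the *state-frequency statistics* of a molecular-dynamics
  trajectory, not its kinetics, correlations within a well, or backbone
  coupling — a green population-recovery test certifies the
  classifier/generator loop, not any simulation physics.
- Default stationary distribution (0.38, 0.48, 0.14) over (g−, t, g+): the
  rotamer-cluster populations observed over 900 ns of simulation of the
  ligand-free pocket. Default trajectory length for acceptance runs is
  90,000 frames (one frame per 10 ps of 900 ns).

Seed handling: one `numpy` `default_rng(seed)` per generator call; identical
configs give byte-identical PDB output.

## Clustering

Trajectory frames are clustered on (cos χ1, sin χ1, pocket width, proline
gate) — χ1 enters as a point on the circle so that ±180° coincide — with
per-feature standardization and seeded k-means (k-means++ initialization,
one start, ≤ 500 iterations, tolerance 1e-8), default k = 3.
Zero-variance features are dropped with a warning. The algorithm choice is
a package decision: the clustering inputs are known but the original
algorithm is not, so cluster *identities* are reproducible only under this
package's seed and are treated as qualitative elsewhere. Representatives
are medoids (member frame nearest its center), so a representative is
always a real frame.

## Numerical and I/O choices

- PDB v3.3 fixed columns are the only dialect; coordinates round-trip at 3
  decimals, B factors at 2. Alternate locations resolve at parse time
  (highest occupancy, ties alphabetical by alt-loc id; or first-seen).
  Waters are HOH/WAT. Residue numbering is taken verbatim (p53 canonical
  numbering in the deposited structures).
- Angles cross module boundaries in degrees only.
- All cutoffs the source leaves unstated (hydrogen-bond distance, σ-hole
  angle) live in `AnalysisConfig` with the defaults above.
- Reports are plain dicts validated against a shipped structural schema
  (`data/report_schema.json`); analyses are deterministic for fixed input,
  config and seed.

## Known limitations

- Open/closed calls are purely rotamer-based; a gauche(−) cysteine with a
  ligand filling subsite III and a gauche(−) apo structure are both "open".
- Hydrogen-bond detection without an angular term over-reports at the
  cutoff margin; it is a candidate enumerator, not an energy filter.
- The benchmark command requires user-supplied local copies of the
  deposited structures; nothing is downloaded, and accession-dependent
  numbers cannot be produced hermetically.
- CH–π/stacking interactions, pocket volumes, occupancy refinement and
  mmCIF input are out of scope.
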