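# pocketstates

Conformational-state analysis of the transient binding pocket created by the
p53 cancer mutation Y220C.

The Y220C mutation replaces a buried tyrosine with cysteine and opens a
narrow, druggable surface crevice on the p53 DNA-binding domain. At the
bottom of that crevice sits a *cryptic* hydrophobic subpocket (subsite III)
gated by the Cys220 side chain: in the trans rotamer (χ1 ≈ ±180°) the
sulfur blocks the subpocket ("closed"), and a switch to gauche(−)
(χ1 ≈ −60°) opens it. `pocketstates` is for structural biologists and
medicinal chemists analyzing this kind of pocket plasticity: it classifies
the gate state from crystal structures or trajectory frames, measures
pocket-width metrics across ensembles, detects halogen-bond/hydrogen-bond
and structural-water geometry, and does the ligand-efficiency arithmetic
used when growing fragments into the transient state.

## The core quantities

- **χ1 rotamer classification.** χ1 = dihedral(N, Cα, Cβ, Sγ), IUPAC signs,
  in (−180°, 180°]. Bins are half-open with edges at the midpoints between
  the staggered wells: g− = [−120°, 0°), g+ = [0°, 120°),
  t = [120°, 180°] ∪ (−180°, −120°). State map: g− → open, t → closed,
  g+ → unassigned (never observed crystallographically).
- **Pocket metrics.** Width = d(Thr150 Cα, Pro222 Cα); proline gate =
  d(Pro151 Cδ, Pro223 Cδ); per-chain, summarized min/max/mean over
  ensembles, per-frame over trajectories with crystal-range reference
  bounds.
- **Halogen bonds.** For halogen X bonded to carbon C and acceptor A
  (O/N/S): report when d(X···A) ≤ cutoff (Bondi vdW-radius sum by default)
  and the σ-hole angle ∠(C–X···A) ≥ 140° (configurable).
- **Structural waters.** W1 bridges the Val147 and Asp228 backbone
  carbonyls; W2 binds the Leu145 carbonyl plus Thr230 (OG1 or N). Water
  B-factor statistics are reported per chain.
- **Ligand efficiency.** ΔG = RT·ln K_D (R = 1.987×10⁻³ kcal/mol/K,
  T = 298 K default); LE = |ΔG| / N_heavy, kcal/mol per non-hydrogen atom.
- **Synthetic trajectories.** A three-state Markov chain with transition
  rule T(i→j) = s·[i=j] + (1−s)·π_j has stationary distribution exactly π
  for any stay probability s; emitted χ1 = well center + wrapped-normal
  noise. Default π = (0.38, 0.48, 0.14) over (g−, t, g+).

## Worked example

Generate a synthetic open-state pocket with a bromine probe at near-ideal
halogen-bond geometry and analyze it:

```bash
pocketstates synth pocket --width 7.5 --gate 5.0 --chi1 -60 \
    --xb Br:3.0:174 --water W1:2.8:12 -o pocket.pdb
pocketstates analyze-structure pocket.pdb
```

The chain report prints

```json
{
  "chain": "A",
  "chi1_deg": -60.008910259327315,
  "rotamer": "g_minus",
  "subsite3": "open",
  "pocket_width": 7.5,
  "proline_gate": 5.0,
  "water_tags": {"W1": ["A", 501]}
}
```

— the Cys220 gate is in gauche(−), so subsite III is called open; the rim
width and proline-gate distances are recovered exactly as commanded; the
water bridging Val147 O and Asp228 O is tagged W1. (The χ1 differs from
−60° by ~0.009° only because PDB coordinates carry 3 decimals.) The one
detected halogen bond reads

```json
{"kind": "halogen_bond", "donor_atom": ["A", 901, "LIG", "BR"],
 "acceptor_atom": ["A", 145, "LEU", "O"], "distance": 3.0, "angle": 173.99}
```

i.e. a 3.0 Å Br···O contact to the Leu145 backbone carbonyl with a σ-hole
angle of ~174°, the textbook near-linear geometry. Ligand-efficiency
arithmetic:

```bash
pocketstates le --kd 820e-6 --formula C7H4I2O3
# -> "delta_g": -4.2078 kcal/mol, "n_heavy": 12, "ligand_efficiency_2dp": 0.35
```

A 820 μM diiodosalicylate scaffold with 12 heavy atoms has LE 0.35 kcal/mol
per heavy atom; replacing it by the 21 μM pyrrole hybrid (17 heavy atoms)
gives LE 0.38 and a 40-fold affinity gain — high efficiency is maintained
while potency grows.

Trajectory analysis (`pocketstates analyze-trajectory traj.pdb` or
`pocketstates synth traj --n 90000 --seed 1`) reports per-frame χ1 records,
rotamer populations and a seeded k-means clustering of the pocket features.

Checks against the deposited Y220C crystal structures run through
`pocketstates benchmarks <dir>`, where `<dir>` holds locally downloaded
PDB files (e.g. `2XWR.pdb`); the tool itself never touches the network.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the trans-rotamer population obtained by
classifying a freshly sampled 90,000-frame synthetic χ1 trajectory at the
package's default stationary distribution (noise sd 15°, no stickiness) and
writes it as JSON.
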