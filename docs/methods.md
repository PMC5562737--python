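# Methods

This note records the models, conventions and defaults the package
implements, the design choices made where several conventions exist, and
what the synthetic systems do and do not establish about real data.

## Energetics

**Binding free energy.** The end-point estimate is
ΔG_bind = ⟨G(complex) − G(receptor) − G(ligand)⟩ over snapshots, with
G = E_ele + E_vdw + E_int + G_sol_polar + G_sol_np. The protocol is
strictly single-trajectory: receptor and ligand coordinates are taken
from the complex snapshot itself. Every intramolecular gas-phase term
then cancels *identically* in the difference, so the implementation
evaluates ΔE_ele and ΔE_vdw directly as sums over receptor×ligand cross
pairs rather than as a difference of three large sums — the two forms are
mathematically equal, but the direct form avoids float cancellation
against intramolecular LJ terms that can reach 10⁶ kcal/mol on coarse
geometries, and it is what makes the per-residue decomposition conserve
to machine precision. ΔE_int is reported as exactly 0. The solvation
terms are not pairwise additive and are computed complex-minus-parts.

No nonbonded cutoffs are applied anywhere (systems are small), and no
1-2/1-3/1-4 exclusions exist because the synthetic topologies carry no
bonded terms; receptor–ligand cross pairs, the quantity of interest,
never involve bonded pairs in any case.

**Electrostatics.** Vacuum Coulomb with k = 332.0637 kcal·Å/(mol·e²).
Pairs closer than 0.1 Å are treated as geometry errors rather than
evaluated.

**Generalized Born.** Still's pairwise form,
G_pol = −½ (1/ε_in − 1/ε_out) k Σ_ij q_i q_j / f_GB with
f_GB = sqrt(r² + R_iR_j exp(−r²/4R_iR_j)), double sum including i = j, so
a single ion reduces exactly to the Born formula. Defaults ε_in = 1,
ε_out = 80. Effective Born radii are *inputs*, supplied per atom by the
topology sidecar; a Coulomb-field-approximation estimator from intrinsic
radii is provided as a convenience but nothing depends on it. No claim of
numeric parity with any particular MD package's GB flavor (which differ
in their descreening integrals) is made.

**SASA.** Shrake–Rupley with a deterministic golden-angle (Fibonacci)
sphere sample, default 960 points per atom, probe 1.4 Å; a sample point
is buried iff strictly inside another atom's expanded sphere. An isolated
atom's area is exact by construction (all points accessible), which is
what makes the probe-radius recovery in `scripts/acceptance.py` exact.
Nonpolar solvation is γ·SASA with γ = 0.0072 kcal/(mol·Å²) and no offset
term.

**Report.** Means ± standard error of the mean over snapshots. The
additivity identities (ΔE_gas = ΔE_ele+ΔE_vdw+ΔE_int,
ΔG_sol = ΔG_sol_np+ΔG_sol_polar, ΔH = ΔE_gas+ΔG_sol) hold by construction
on the per-snapshot series. No entropy term is computed; ΔG is reported
equal to ΔH and should be read as an enthalpic estimate only.

**Per-residue decomposition.** A receptor residue collects the full
Coulomb, LJ and GB-screening terms of its atom pairs with the ligand,
plus γ·ΔSASA where ΔSASA = SASA(in complex) − SASA(isolated molecule) for
its atoms — *negative* upon burial, keeping the sign convention
(favorable = negative) consistent with the totals. The ligand residue
carries only its own ΔSASA term. With this convention the residue sum
equals the snapshot's complete cross-interaction energy (checked to 1e-6
in the tests). Residues with |contribution| > 0.4 kcal/mol are labeled;
the threshold is configurable.

## Trajectory observables

* **Superposition** is Kabsch (SVD, proper rotation enforced; fit sets
  must contain ≥ 3 non-collinear atoms).
* **RMSD series** fit each frame on a selection (default Cα) and measure
  over a second selection, against the starting structure.
* **RMSF** superposes frames onto their time-average (two passes starting
  from the first frame), then reports per-residue fluctuations via the
  Cα atom. Superposition absorbs six rigid degrees of freedom, so on
  uniform noise the expectation is σ√3·sqrt(1 − 2/N) for N residues — the
  tests use this corrected expectation.
* **Active site**: residues with any atom within 5 Å of the ligand in the
  reference structure (configurable). The literature often leaves this
  definition implicit; it is an explicit, configurable choice here.
* **Hydrophobic contacts**: count of selected receptor atoms (default:
  Cα of ALA/VAL/LEU/ILE/PRO/PHE/MET/TRP, flag stored in the topology)
  with at least one ligand heavy atom strictly within 6.0 Å
  (configurable).
* **Hydrogen bonds**: donor–acceptor distance ≤ 3.5 Å AND
  donor–H···acceptor angle ≥ 135°, both configurable. A donor's hydrogens
  are the element-H atoms of its own residue within 1.25 Å; donors
  without one are skipped with a warning.
* **Ring geometry**: plane normals by total least squares (smallest
  singular vector), *directed* by the right-hand rule over the ring's
  atom ordering; the inter-plane angle therefore lives in [0°, 180°] and
  distinguishes 40° from 140° — reversing one ring's ordering complements
  the angle. Centroid distance is unweighted.
* **Snapshot extraction** takes frames at window_start + k·interval,
  half-open at the start and closed at the end, matched to the nearest
  frame within interval/2. A 200 ns window at 200 ps thus yields exactly
  1000 snapshots.

## Residue networks

Nodes are residues (their Cα); an edge joins pairs with Cα–Cα distance
strictly below the cutoff (default 7 Å). Edges store the distance, but
path semantics are *unweighted*: shortest path length is the hop count
(residues traversed), computed by Floyd–Warshall; a distance-weighted
mode exists behind a flag. Among co-optimal paths the canonical one is
the lexicographically smallest residue-id sequence (deterministic across
runs), and all co-optimal paths are enumerated when there are ≤ 10⁴.
Betweenness is the raw count of shortest paths through a node summed over
unordered endpoint pairs excluding it — deliberately *not* Brandes'
fractional convention (available via `normalized=True`); raw counts
always dominate the fractional values, which the tests check. Networks
are built on the clustering stage's representative structure, not on
frame-averaged coordinates.

## Conformational clustering

Greedy neighbor-count (Daura-style) clustering on the all-pairs RMSD
matrix, each pair superposed on the clustering selection (default Cα plus
ligand heavy atoms), default cutoff 2.0 Å. Ties in neighbor count break
toward the lowest frame index; clusters are ordered by decreasing size,
and the representative conformation is the center of the largest cluster.
Other algorithms (hierarchical, k-means, DBSCAN) are out of scope; no
numeric parity with any MD suite's clustering is claimed.

## Synthetic systems

The generator produces the statistical situations the analyses assume,
not physical realism:

* **Receptor**: a coarse two-atoms-per-residue chain (Cα plus a
  pseudo-sidechain 1.5 Å outward) traced along an area-uniform spherical
  spiral with open polar caps; the top cap is the concave ligand pocket
  mouth. Consecutive Cα are ~3.8 Å apart, adjacent turns ~4.6 Å, so a
  7 Å cutoff yields a chemically sensible contact graph.
* **Ligand**: two regular hexagons (1.4 Å bonds) at a construction angle
  of 40° and centroid distance 3.8 Å, plus linker atoms; seated on the
  pocket axis at the snuggest position with ≥ 4.2 Å wall clearance — just
  outside the LJ minimum, so bound complexes are attractive by
  construction (ΔH < 0 across seeds, which the tests verify). Unbound
  twins are displaced along the axis to ≥ 100 Å separation (the contract
  is ≥ 50 Å; the larger distance makes residual multipole electrostatics
  negligible in the non-interacting limit).
* **Parameters**: charges uniform in ±0.2 e with each molecule's net
  charge forced to the nearest integer via its last atom; σ in
  [3.2, 3.6] Å, ε in [0.05, 0.15] kcal/mol, Born radii in [1.4, 2.2] Å,
  intrinsic radii in [1.5, 1.9] Å. Known, not realistic — every
  energetics test needs ground truth, not chemistry.
* **Dynamics**: frames are the base structure plus i.i.d. isotropic
  Gaussian noise, per-coordinate σ given by the per-residue fluctuation
  profile (ligand atoms move with the nearest receptor residue's scale —
  a pocket residue when bound, trivially the nearest residue otherwise).
  Default profile: 0.30 Å everywhere, with the two pocket-flanking loop
  segments at 1.00 Å when apo and 0.40 Å when holo, emulating
  ligand-bound loop rigidification. Loop spans default to ~4–18% and
  ~22–36% of the chain.
* **Randomness**: numpy's PCG64 seeded from the spec; the seed and all
  ground truth (atom counts, net charges, fluctuation profile, ring
  geometry, pocket residues) are recorded in a JSON manifest. Bitwise
  determinism is promised within one implementation; across platforms
  only statistical agreement.

Because the noise has no autocorrelation, no solvent and no force-field
realism, passing tests establish the *estimators* (RMSF recovers imposed
amplitudes, energies match independent summation, networks match graph
oracles) — they do not establish that any particular real system's
energies or paths would be reproduced. In particular, published
binding-energy tables from microsecond explicit-solvent MD of real
bromodomain–inhibitor systems are not reproducible at this scale, and the
package does not attempt it; the qualitative exercise of building contact
networks on downloaded crystal structures (e.g. RCSB 4MR4/4MR6) works
through the ordinary `gbnet network` command but carries no parity claim.

## Numerical choices and degenerate inputs

* Kabsch and ring-plane fits reject < 3 points or collinear sets.
* Pair energies reject distances < 0.1 Å (near-singular geometry).
* Floyd–Warshall is run in vectorized min-plus form; disconnected pairs
  report a no-path result, not an error.
* Snapshot extraction errors on empty windows and on intervals finer than
  the frame spacing.
* The PDB writer refuses coordinates that do not fit the fixed 8.3
  column (≥ 10000 or ≤ −1000 Å); coordinates round-trip to 3 decimals.
* Pipeline problem sizes default to a 100-residue receptor and a
  300-frame trajectory; the test suite uses 2000-frame trajectories for
  statistical recovery checks and 20–60-residue systems where an O(n²)
  pure-python oracle is the reference.

## Known limitations

* No Poisson–Boltzmann polar solvation; GB only.
* No entropy estimate (ΔG ≡ ΔH).
* Born radii are inputs, not self-consistently derived.
* Multi-model PDB is the only trajectory format; no DCD/XTC/NetCDF,
  mmCIF, altlocs or insertion codes.
* The synthetic dynamics are time-uncorrelated; autocorrelation-sensitive
  analyses are out of scope.
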