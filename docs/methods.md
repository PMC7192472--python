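# Methods

## The end-point effective binding free energy

`stapletherm` analyses the thermodynamics of a peptide–protein complex
from snapshots of its bound ensemble only (an *end-point* analysis; no
alchemical intermediates, no free-state simulation). The central
per-frame score is the effective binding free energy

    Δf = ΔE_u + ΔG_solv

where ΔE_u is the direct peptide–protein interaction energy and
ΔG_solv the solvation free-energy change of complexation (the
dehydration penalty). It connects to the binding free energy through

    ΔG_bind = Δf − T(ΔS_config + ΔS_ext),

and since the configurational and external entropy terms are typically
negative, Δf carries the favourable part of the affinity. Those entropy
terms are user-supplied inputs here; the package deliberately ships no
entropy estimator.

The analytical value of Δf over ΔE_u alone is that contact formation is
always a trade: favourable direct interactions (ΔE_u < 0) are paid for
by desolvating the surfaces they bury (ΔG_solv > 0). Only the sum
identifies which residues genuinely drive binding. Every energy in the
package is therefore computed with an **exact atomic decomposition**:
the per-atom contributions are constructed so they sum to the total to
machine precision, at every level (atom → residue/linker group → total
→ replica mean). This is an identity of the bookkeeping, not an
approximation, and the test suite asserts it exhaustively.

### Direct interaction energy (ΔE_u)

Nonbonded inter-molecular sum over all peptide-atom × receptor-atom
pairs: Coulomb (constant 332.0636 kcal·Å/(mol·e²)) plus Lennard-Jones
12-6 with Lorentz–Berthelot mixing. No distance cutoff and no periodic
boundaries by default — frames are isolated complexes and the
exactness of the decomposition is the point; a cutoff flag exists for
speed and is off in all tests. Intra-molecular terms are never
computed (single-trajectory convention: bound-state frames are the
only input, so internal energies cancel in the comparison the method
supports).

**Pair-splitting convention.** Each pair energy is shared half/half
between its two atoms. This symmetric convention sums exactly, treats
the two molecules identically, and is the standard choice in
per-residue end-point analyses. Other exact decompositions of the
*solvation* cross-terms exist in the literature; only the additivity
property, not any particular cross-term assignment, is relied on here.

### Solvation (ΔG_solv) — pluggable backend

The physical reference for this term in the end-point literature is an
integral-equation solvent model. This package substitutes a
**generalized-Born + SASA backend** whose per-atom decomposition is
exact by construction, behind a backend interface (`backend:
"gb_obc"`) so a different solvent engine can be slotted in without
touching the analysis layer. The substitution preserves every property
the analysis uses: additive atomic partition of G_solv, the positive
sign structure of the dehydration penalty, and the separated-complex
zero limit.

Polar term: GB double sum with the canonical smooth interpolation
f_GB(r, R_i, R_j) = sqrt(r² + R_i R_j exp(−r²/4R_iR_j)). Effective
Born radii come from pairwise descreening: the shell-by-shell
spherical-cap integral of the r⁻⁴ kernel over each neighbour sphere
has a closed form (validated against direct numerical quadrature to
better than 1e-10), and the summed integral is rescaled through the
standard tanh map with coefficients (1.0, 0.8, 4.85). The radius
offset is zero, so an isolated atom's effective radius equals its
intrinsic radius exactly; radii are floored at half the intrinsic
radius as a guard (with offset zero the floor cannot trigger — the
tanh map only grows radii). Per-atom polar share: full self term plus
half of each cross term.

Nonpolar term: γ·SASA with γ = 0.0054 kcal/(mol·Å²) and probe radius
1.4 Å (conventional implicit-solvent values, both configurable). SASA
uses Shrake–Rupley sphere sampling with a deterministic spiral
(Fibonacci) lattice, default 960 points/atom, so results are
bit-reproducible; the point count is configurable and the suite checks
self-convergence against a 10⁴-point reference within 2 %.

Dehydration penalty: ΔG_solv = G_solv(complex) − G_solv(peptide) −
G_solv(receptor), all three evaluated on the same complex-frame
coordinates (single-trajectory convention — no separate free-state
ensemble). Per-atom share: complex-state contribution minus the
owning monomer's contribution, so additivity is exact. A `"null"`
backend (identically zero) exists to isolate the direct component in
interface-contract tests.

### Replica statistics

Replica = one trajectory. Frames are averaged within a replica first;
the ensemble mean and the standard error (sample SD with n−1
denominator over replica means, divided by √n) are then taken across
replicas. Frame populations are never pooled across replicas for the
SE. A single replica reports SE = 0 with a warning. Group rankings
("hotspots") sort by most-negative mean contribution, ties broken by
group key; peptide-side hotspot reports restrict the ranking to
peptide groups, since the design question the ranking answers is which
peptide residues (or the staple) to engineer.

## Conformational analyses

**Superposition/RMSD.** Kabsch least-squares rigid alignment
(reflections excluded); RMSD is always reported after fitting. The
suite cross-checks against an independent quaternion (QCP) oracle to
1e-8 Å.

**Clustering.** "Clustering with a radius" is interpreted as
radius-capped leader clustering in pairwise-fitted RMSD space with one
centroid-refinement pass: frames are visited in file order, join the
nearest centroid within the radius or open a new cluster; one
reassignment pass against mean centroids follows, and any member
pushed beyond the radius by centroid drift is split out, so the radius
bound holds for every member on output. This reproduces the intent —
conformational families within a fixed RMSD radius — without
inventing a cluster count, and is deterministic. The fitted selection
defaults to Cα atoms and is a required, configurable parameter (which
atom set the original analyses used is not documented). The
representative conformation is the medoid of the most populated
cluster, ties to the lowest frame index.

**Secondary structure.** Four classes (helix/turn/bend/coil) from the
classic backbone hydrogen-bond energy criterion E = 332·0.42·0.20 ·
(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with bond threshold
−0.5 kcal/mol. Amide hydrogens are built geometrically (N–H 1.01 Å
along the bisector of C(prev)→N and CA→N) since heavy-atom inputs
carry no hydrogens. H requires i→i+4 bonds on two consecutive
residues (α only — 3-10-like i→i+3 patterns count as turn, a
deliberate conservative reading of "helix"; see `helix` vs `turn`
precedence H > T > B > C). Bend is a Cα(i−2)–Cα(i)–Cα(i+2) direction
change above 70°. Helical content is the mean over frames of the
helical residue fraction. Residues with missing backbone atoms are
labelled coil with a warning.

**Contacts.** A peptide residue and a receptor residue are in contact
when their minimum heavy-atom distance is at or below the cutoff
(default 4.5 Å, the common hydrophobic-contact convention; no cutoff
is canonical, so it is configurable). A k-d tree accelerates the
search; equality with the brute-force all-pairs scan is asserted in
the suite.

## The synthetic-data generator

The generator emulates the *statistical shape* of a stapled
α-helical peptide bound in a hydrophobic surface pocket, with planted,
machine-checkable ground truth. It makes no claim of structural
realism beyond what the analysis layer needs; the sampler is not the
artifact.

- **Peptide** (default 11 residues, sequence modelled on a stapled
  p53-mimetic with staple positions 4 and 11 and epitope residues 3, 7
  and 10): ideal α-helix backbone built by internal-coordinate chaining
  at φ = −57°, ψ = −47° (≈1.5 Å rise, ≈100° twist), four backbone atoms
  plus one side-chain pseudo-atom per residue. Epitope side chains
  extend 3.8 Å toward the pocket; others 1.8 Å along their own helix
  radial.
- **Staple** ("LINKER" group): 8 hydrocarbon-like pseudo-atoms on an
  arc bridging the two staple positions, on a helix face rotated 65°
  from the pocket direction (configurable — the real staple–surface
  geometry is not derivable from cartoon figures, so the placement
  angle is a parameter rather than a constant). The adjacent face
  choice makes the staple receptor-contact-capable, which is the
  scientific scenario of interest.
- **Receptor**: a concave shell of uncharged Lennard-Jones spheres
  (up to three spherical-cap shells at pocket_depth + 3k Å so the
  requested atom count fits at packing distance), one charged probe
  (−0.20 e) facing each epitope tip with a compensating counter-charge
  behind the shell (both molecules are net-neutral, so the
  inter-molecular Coulomb energy decays as a dipole term and the
  separated-complex limit vanishes numerically), and a hydrophobic
  patch of four atoms facing the staple arc.
- **Planted strengths**: epitope side chains and probes carry deep LJ
  wells (ε = 4.3) and small charges; staple/patch atoms ε = 2.7;
  everything else is weak (ε ≤ 0.25, small backbone dipoles, zero net
  residue charges). The balance is deliberate: the attraction is
  carried mostly by LJ terms, which scale linearly under attenuation,
  while the q²-scaling dehydration self-terms stay small — this keeps
  mean Δf strictly monotone in the attenuation factor. Planted
  partners sit at ~1.3 σ — inside the attractive well but with a wide
  buffer before the r⁻¹² wall (frame noise essentially never flips a
  planted contact's sign) and still within the 4.5 Å contact
  convention, so the planted interface is visible to the contact
  analysis. The resulting per-group Δf margins are several kcal/mol
  (hotspots ≈ −3 to −9, bystanders within ±0.5), which is what makes
  rank recovery a sharp test.
- **Trajectories**: base coordinates + isotropic Gaussian noise
  (default σ = 0.3 Å), 100 frames per replica at a nominal 1 ns
  interval, 10 replicas, all deterministic under (spec seed, replica
  seed). An excluded-volume guard redraws any frame in which noise
  would compress an atom pair below 0.25 Å: unbounded Gaussian noise
  occasionally produces overlaps no physical ensemble contains, and
  the energy models are (by contract) invalid there. The redraw is
  part of the seeded path, so determinism is preserved.
- **Attenuation variants** emulate staple-shift mutants of decreasing
  affinity: receptor probe charges scale linearly and planted pair LJ
  depths scale linearly with the attenuation factor, geometry
  unchanged — so a purely Coulombic reduction scales ΔE_u exactly
  linearly, and mean Δf is strictly monotone in the attenuation.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: no physical sampling (no correlations
between frames, no conformational transitions in the bound state), no
explicit or granular solvent, no protonation states, no real rotamers,
and fluctuation amplitudes far below real side-chain dynamics. The
tests demonstrate that the *analysis* is exact, consistent and able to
recover planted signal at realistic margins — not that the GB/SASA
backend reproduces integral-equation solvation for real complexes.

## Problem sizes used in tests and the acceptance script

The default synthetic complex has ~120 atoms (63 peptide including the
staple, ~55 receptor). Ensemble evaluations in the acceptance layer use
scaled-down frame counts chosen so that the quantities they estimate
are statistically equivalent to the full default ensemble: hotspot
recovery uses 2 replicas × 15 frames per seed (the planted per-group
margins are ~5× the frame-mean noise at 30 frames), attenuation
ordering uses 10 replicas × 6 frames, and the headline ensemble uses
10 replicas × 10 frames. Decomposition exactness is checked on 100
noisy frames; it is an identity and holds on every frame.

## Numerical choices and degenerate inputs

- Totals are defined as compensated sums (`math.fsum`) of the atomic
  shares, making additivity an identity rather than a tolerance.
- Superposition requires ≥3 non-collinear points; collinearity is
  detected via the second singular value (< 1e-10).
- Clustering tie-breaks: frame visiting order is file order;
  representative ties go to the lowest frame index.
- An inter-molecular pair closer than 0.1 Å raises a "clash" error in
  ΔE_u; the descreening machinery likewise rejects sub-0.1 Å overlaps.
- CSV reports serialize at 6 decimals; the `verify` integrity check
  uses a tolerance matching that precision (identities hold to machine
  precision in memory).
- PDB I/O: one MODEL block per frame (none for single frames),
  %8.3f coordinate columns (round-trips to 1e-3 Å), HETATM parsed like
  ATOM so non-standard staple residues load, highest-occupancy altloc
  kept, residues renumbered 1-based sequentially per chain.

## Known limitations

- The GB/SASA backend is a stand-in for integral-equation solvation:
  absolute ΔG_solv values are model-dependent, and cross-term
  assignment conventions differ between exact decomposition schemes;
  only additivity and sign structure are invariant claims.
- Entropy terms are bookkeeping inputs; ΔG_bind is only as good as
  the numbers supplied.
- No periodic boundaries, salt dependence, or temperature dependence
  of G_solv.
- The secondary-structure module assigns no β classes (the target
  peptides show none); `helix_includes_310`-style reclassification is
  out of scope — 3-10 patterns are reported as turn.
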