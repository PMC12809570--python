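# Methods

This note documents the models and conventions behind `memiso`: what each
metric computes, what the synthetic generator does and does not emulate,
the numerical choices, and the limitations a user should know before
trusting a number.

## System and annotation

The package targets two-leaflet phospholipid patches. Atom roles are never
inferred from chemistry; they come from a shipped, editable YAML table
(`memiso/data/lipids.yaml`) mapping residue names to phosphate atoms, tail
carbon chains, double-bond dihedral quadruples, and explicit C–H pairs,
using CHARMM36-style names (sn-1 = chain 3, sn-2 = chain 2; cardiolipin
chains A–D). The default composition is a bacterial inner-membrane model
with, per leaflet: 10 PYPE, 7 POPE, 14 YOPE, 11 PYPG, 6 POPG and 2
cardiolipin (PVCL2) — 50 lipids per leaflet, 100 in the bilayer. All
unsaturations are Δ9. Cardiolipin contributes the atoms of **both** of its
phosphate groups to the phosphate set and is treated as a single residue
(one diffusion track) despite its four tails.

Units: Å for coordinates, ns for time, Å²/ns and cm²/s for diffusion
(1 Å²/ns = 10⁻⁷ cm²/s). Boxes are orthorhombic; x/y are periodic
(minimum image), z is not (the bilayer is centred and never crosses the z
face). Coordinates are not unwrapped at read time; unwrapping is an
explicit geometry operation because metrics disagree about wrapped vs
unwrapped input.

## Cis/trans classification and the isomerization operator

The state of a double bond is the torsion of C(i−1)–C(i)–C(i+1)–C(i+2):
cis iff |φ| < 90°, trans otherwise, with the 90° boundary assigned to
trans (90° is the symmetry point between the two wells; real simulations
essentially never sit there). The isomerization operator rotates every
atom distal to the bond — found by walking the intra-residue bond graph
from C(i+1) away from C(i) — by 180° about the axis through the two bond
carbons, using the exact involution `R = 2uuᵀ − I`. This preserves all
internal geometry of the rotated set to machine precision, keeps the
glycerol-proximal part fixed (minimal headgroup perturbation), and applied
twice restores the input to < 10⁻⁶ Å. Multiple unsaturations on one tail
are processed from the chain end inward so distal sets nest. The operator
is purely geometric; no relaxation of the flipped structure is attempted.

## Metrics

**Leaflets.** Per-residue assignment by the sign of the phosphate-centroid
z against the global phosphate mean; residues within 5 Å of the midplane
fall back to tail direction (phosphate above its tail carbons ⇒ upper).
Invariant under rigid translation.

**Thickness / volume.** Thickness is the difference of mean z of the
phosphate-group atoms (P and its oxygens) of the two leaflets; volume is
`Lx·Ly·thickness` per frame.

**Area per lipid.** The xy plane is divided into ⌈L/s⌉ cells per axis
(s ≤ 1 Å, so the realized spacing is at most 1 Å); grids sit at z =
midplane ± 18 Å (defaults, configurable), where the midplane is the
midpoint of the two phosphate planes. Each cell centre is assigned to the
lipid residue of that side's leaflet with the nearest heavy atom — 3D
distance with xy minimum image, implemented with a KD-tree over a 3×3
tiling and verified cell-for-cell against a brute-force all-pairs scan in
the tests. Restricting candidates to one leaflet prevents the opposing
leaflet from capturing cells. Per-type area = cells × cell area / count of
that type in the leaflet; every cell is assigned exactly once, so the
partition conserves `Lx·Ly` exactly. A type absent from a leaflet is
reported absent, not zero. An xy-only (2D) distance mode is available.

**Chain order.** `S_CH = ⟨(3cos²θ − 1)/2⟩` with θ against the fixed +z
normal (not a fitted director), averaged over each carbon's hydrogens,
residues and frames. Explicit hydrogens are required; nothing is
reconstructed from heavy atoms. The sign convention is kept (−0.5 …
1.0); absolute-value presentation is left to plotting. A windowed
tail-mean time series exposes order drift such as a phase change.

**Depth distribution and surface accessibility.** The reference plane is
the per-leaflet, per-frame mean z of the phosphorus atoms **only**; the
measured phosphate distribution includes P and the phosphate oxygens.
Signed depth d > 0 points toward the midplane, d < 0 past the plane into
water; leaflets contribute independently and are pooled. Histograms use
0.5 Å bins over [−10, 30] Å by default (fine enough to resolve sub-2 Å
shifts). The surface population counts samples with **d ≤ cutoff**
(default 5 Å) — i.e. the water side counts too, since excursions past the
plane are the phenomenon of interest; a |d| ≤ cutoff mode is a switch.
Samples are per double-bond carbon atom (two per bond), also switchable.
The cis/trans accessibility ratio is computed on pooled samples.

**Kink angle.** Interior angle at the chain-proximal carbon of a tail's
first double bond, between vectors to the tail's carbonyl and terminal
carbons; 180° is straight. Each cardiolipin tail is measured
independently. Saturated tails raise (no kink defined).

**Lateral diffusion.** Residue positions are heavy-atom xy centroids
(computed minimum-image-robustly), unwrapped, then per-leaflet collective
drift is removed by subtracting each frame's centroid of centroids.
Trajectories are cut into non-overlapping chunks (200 ns at production
scale; duration/5 by default here), each restarting its reference
position; `MSD(t) = ⟨|r(t) − r(0)|²⟩` uses a single origin per chunk (a
multi-origin mode exists). `D = MSD(T)/(2nT)` with n = 2 — the literal
endpoint estimator — is the default, with a least-squares-through-origin
fit as the alternative; the two agree exactly on linear MSD. The estimate
is the unweighted mean over chunk × replicate samples (5 × 5 = 25 at
defaults) and SE = sd/√n. Note that subtracting the drift of R lipids
shrinks each lipid's expected MSD by exactly (1 − 1/R) (2% at R = 50);
recovery tests account for this.

## The synthetic generator

The generator emulates the *statistical structure* of a bilayer
trajectory, not its physics: lipids are rigid bead templates (headgroup
beads including named phosphate atoms; ideal-geometry chains built by
internal coordinates with C–C 1.53 Å, C=C 1.33 Å, angles 111°, all-trans
torsions except the unsaturation torsion at 0°/180°), placed on jittered
lattices at ±thickness/2 with random azimuths. Each observable is driven
by its own law so its expectation is known exactly:

* **Lateral motion** — rigid per-residue 2D Brownian steps, per-type D
  (defaults: cis 0.65 Å²/ns ≈ 6.5 × 10⁻⁸ cm²/s, trans 0.525 for
  phospholipids; cardiolipin 0.30/0.24), so the MSD slope is 4D.
* **Thickness** — phosphate planes at ±μ/2 with fresh per-frame Gaussian
  z jitter (σ = 1 Å); expectation μ (cis 38 Å, trans 40 Å). σ = 0 gives
  the exact value.
* **Chain order** — C–H unit vectors redrawn each frame from a tilt law
  (fixed polar angle θ₀ or a weighted mixture; azimuth uniform, z-sign
  random), so `S_CH = Σ wᵢ P₂(cos θᵢ)` exactly (cis θ₀ = 65° ⇒ −0.232,
  trans 75° ⇒ −0.400).
* **Double-bond depth** — a two-state Markov chain per site (mean surface
  dwell 5 frames) whose stationary excursion probability is exactly p_s
  (cis 0.008, trans 0.0015); excursions are uniform in the (0, 5] Å band
  below the phosphate plane, bulk depths Gaussian (σ = 2 Å) centred by
  default on the site's as-built depth (a global mean is available — the
  per-site centring avoids displacing the kink carbons systematically).
  The expected surface fraction is the closed-form mixture of the band
  fraction and the Gaussian CDF term. The four dihedral carbons and their
  hydrogens translate rigidly in z, so the cis/trans torsion is invariant
  under the depth dynamics.
* **Kink angle** — fixed by the template chains (cis ≈ 115–116°, trans ≈
  175°, type-dependent); exact on the built frame, fluctuating a few
  degrees along trajectories through the depth jitter.

All randomness flows from one mandatory seed through spawned independent
streams (one per residue, per site, per purpose); a spec is
bit-reproducible. Residues are wrapped into the box as whole units so the
unwrap operation recovers continuous tracks. Paired condition sets derive
per-replicate seeds from each condition's base seed and refuse duplicates.

What the generator does **not** emulate: sterics and packing (lipids can
overlap), water, force-field energetics, headgroup conformational
dynamics, area-per-lipid differences between conditions (both conditions
share the lattice, so APL ≈ box area / 50 regardless of state), and phase
transitions. Passing tests therefore demonstrate that the *analysis*
recovers known statistical structure — not that real membranes behave this
way, nor that the generator's defaults are thermodynamically consistent.

## Scales, defaults and numerical choices

Desk-scale study conditions: 5 + 5 replicates × 500 frames at dt = 0.2 ns
(100 ns per replicate), diffusion chunks of 20 ns (5 per replicate, 25
samples per condition) — the production-scale protocol (1 μs, 200 ns
chunks) at one-tenth length. The 55 × 55 × 80 Å box holds 50 lipids per
leaflet at ~60 Å² each; building refuses boxes below 55 Å²/lipid.
Replicate aggregation is an unweighted mean over replicate means; percent
differences are reported against both denominators. Degenerate inputs
raise rather than warn: empty leaflets, saturated tails asked for a kink,
zero chunk durations, zero depth samples, dihedrals with collinear atoms.
Grid ties in the area partition are broken by the KD-tree's nearest-hit
order; ties have measure zero for real coordinates. DCD time handling is
dialect-dependent, so stored-file times are synthesized as
`frame_index × dt` with dt from the caller (10 ps default).

## Limitations

* The bilayer normal is fixed to +z; tilted or curved membranes are out of
  scope, as are triclinic boxes and 3D voxel densities.
* The endpoint D estimator reproduces the conventional arithmetic; for
  real data the fit mode with multiple origins has lower variance.
* The drift-correction MSD shrinkage (1 − 1/R) is documented, not
  corrected, to keep the estimator literal.
* Explicit hydrogens are required for S_CH; united-atom trajectories
  need a definition table without C–H pairs and cannot produce order
  parameters.
* The synthetic generator's realism caveats above: it validates analysis
  code, it is not a membrane model.
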