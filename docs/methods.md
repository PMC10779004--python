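# Methods

`nmmdfit` extracts continuous conformational landscapes from cryo-EM
particle data by fitting an atomic model independently to every single
particle image (or subtomogram) with a biased, normal-mode-accelerated
molecular dynamics simulation, then embedding the resulting per-particle
models in a low-dimensional space. This note records the model, the
numerical choices, and what the synthetic benchmarks do and do not show.

## Coarse-grained force field

The structure is reduced to one Cα bead per residue and simulated with a
structure-based (Gō-type) potential whose global minimum is the input
(native) conformation:

    E = Σ_bonds     k_b (r − r0)²                       k_b = 100 ε/Å²
      + Σ_angles    k_a (θ − θ0)²                       k_a = 20 ε/rad²
      + Σ_dihedrals k_1 [1 − cos(φ − φ0)]               k_1 = 1 ε
                  + k_3 [1 − cos 3(φ − φ0)]             k_3 = 0.5 ε
      + Σ_contacts  ε_c [5 (σij/r)¹² − 6 (σij/r)¹⁰]     ε_c = 1 ε
      + Σ_other     ε_x [(r_x/r)⁶ − 1]²  (r < r_x)      ε_x = 1 ε, r_x = 4 Å

Bonded terms connect consecutive residues within a chain (no bond across
gaps larger than 4.5 Å). Native contacts are pairs at least 4 residues
apart in sequence within an 8 Å cutoff; σij equals the native distance,
so each contact contributes −ε_c at the native geometry. All constants
are config-overridable; they are the conventional defaults for this model
class, expressed in reduced units (length Å, energy ε, bead mass 1).
Temperatures in kelvin are mapped through k_B = 0.0019872 ε/K, i.e. 1 ε ≡
1 kcal/mol.

Two deliberate choices differ from the most common textbook form:

- **Excluded volume is truncated and shifted.** Non-contact pairs with
  sequence separation ≥ 3 repel through ε_x((r_x/r)⁶ − 1)² for r < r_x
  and are inert beyond r_x. A bare r⁻¹² repulsion never vanishes, which
  would make the native structure *not* an exact stationary point (the
  nearest non-contact pairs sit at ~5 Å in helices). The truncated form
  keeps the native state an exact minimum — forces are identically zero
  there — which makes minimization, normal-mode analysis about the
  minimum, and the energy-conservation benchmarks clean. The repulsion
  still prevents core collapse during biased fitting.
- **No neighbor list.** At the intended scale (tens to a few hundred
  beads) a fully vectorized evaluation over the precomputed pair list is
  faster than maintaining a Verlet list, and the force is exactly smooth.

Forces are the exact analytic negative gradient of every term (the
torsion gradient uses the standard four-point formulation); unit tests
verify them against central finite differences to < 1e-4 absolute and
confirm zero net force and net torque for arbitrary configurations.

## Elastic-network normal modes

Modes are computed from a plain anisotropic elastic network on the
energy-minimized bead coordinates: uniform springs (k = 1) between all
pairs within 8 Å, mass-weighted Hessian diagonalized densely (the
systems are small). Eigenvalues below 1e-6 × λ_max are treated as the
rigid-body subspace; for well-connected, non-collinear structures there
are exactly six such modes. Eigenvector signs follow a first-significant-
component-positive convention so results are reproducible across
eigensolvers.

The degree of collectivity κ = (1/N) exp(−Σ αd²_i ln αd²_i) discriminates
global (hinge, breathing) from local motions; the packaged two-domain
fixture has κ ≈ 0.7 for its lowest internal mode.

Two caveats, both real properties of central-force networks rather than
implementation artifacts:

- Collinear (or locally straight/planar) geometries have zero-energy
  transverse displacements; a perfectly straight N-bead chain has a
  2N + 1-dimensional null space, not 6. The toy-structure generator
  therefore builds genuinely three-dimensional geometries.
- Thin two-strand folds (the hairpin fixture) can retain one or two
  near-mechanisms at larger sizes. The hinged two-domain and helix
  fixtures, used for all dynamics benchmarks, are fully rigid beyond the
  six rigid-body modes.

## NMMD integration

NMMD adds the amplitudes q_m of selected (non-rigid-body) normal modes to
the dynamical state. Modes 7–16 are the default selection. Each
amplitude carries an inertia `nm_mass` (default 5 for images, 10 for
subtomograms) and evolves under the generalized force f_m = u_mᵀF, the
projection of the instantaneous Cartesian forces onto mode m; the mode
displacement increment Σ_m Δq_m u_m is added to the coordinates every
step. Because the effective inverse inertia along the mode directions
becomes 1/m + 1/nm_mass, motion along the most collective directions is
amplified at negligible extra cost.

The coupled system is integrated with a single Velocity Verlet scheme
(kick–drift–kick, with the mode kicks and drifts interleaved at the same
stages); with a positive target temperature the BAOAB Langevin splitting
(friction 1 ps⁻¹) thermostats Cartesian and mode velocities in a fixed
draw order, so a fixed seed gives bit-identical trajectories. The total
energy U + ½Σmv² + ½Σ nm_mass q̇² is conserved by the unthermostatted
integrator to < 0.1% over 10,000 steps at dt = 0.002 on the packaged
fixture. Two contracts pin the scheme down:

- an empty mode selection reduces to plain MD *bit-for-bit*;
- a constant generalized force produces exactly quadratic amplitude
  growth q(t) = f t²/(2·nm_mass).

`nm_dt` defaults to dt; values that are integer multiples of dt are
applied by sub-cycling (mode updates fire every nm_dt/dt-th step), and
anything else is rejected. Whether the mode displacement should also
feed back into the Cartesian velocities is a genuinely open design
point; this implementation applies it to coordinates only, which keeps
the empty-set reduction exact and conserves the extended energy.

The mode displacement is *not* removed from the Cartesian forces, so the
same physical motion can be represented redundantly by both coordinate
sets; this redundancy is intentional (it is what accelerates the
collective motions) and harmless to the recorded observables.

## Biasing potential

The fitting objective is U_bias = −k_bias · CC, where CC is the zero-mean
normalized cross-correlation between the data and a density simulated
from the current coordinates: a sum of isotropic Gaussians (σ = 2 Å by
default) placed at the bead positions — rendered as an analytic 2-D
projection after rotating the model by the particle's imported pose
(intrinsic ZYZ Euler angles, in-plane shifts in pixels) for images, or
as a 3-D volume for subtomograms. Gaussians are truncated at 4σ per
axis. The bias force is the exact analytic gradient through the
rendering and the pose rotation; CC is invariant to affine intensity
changes of the data, so data normalization (zero mean, unit variance at
load) affects conditioning only.

Force constants follow the workflow presets: 3000 ε per CC unit for
images, 1000 for subtomograms (noisier data, gentler pull). Poses are
inputs and held fixed; CTF and missing-wedge effects are assumed handled
upstream and are not modelled. Correlation is computed over the full
box; masked comparison would be a straightforward extension.

## Fitting pipeline and refinement

Each particle is fitted independently, starting from the energy-minimized
input model, under Gō + bias forces, with per-particle seed =
global seed + particle index — results are identical for any worker
count. A diverged simulation marks that particle failed and the batch
continues.

For image sets, the conformational space can be refined iteratively:
after each pass the fitted models are rigid-body aligned (Kabsch) to the
minimized model, a PCA is computed, and the top n_pcs unit-normalized
component vectors replace the mode basis for the next pass, every
particle restarting from the minimized model. The PCA vectors reuse
`nm_mass` as their inertia; since both basis types are unit-normalized
3N-vectors this keeps the amplitude dynamics commensurate. Subtomogram
sets use a single pass (the out-of-plane ambiguity that refinement
addresses does not arise in 3-D data).

## Landscape analysis

Aligned fitted models are embedded by PCA of the flattened coordinates
(reference implementation: scikit-learn, full SVD) or by UMAP when the
optional dependency is installed. Free-energy surfaces are −ln(ρ/ρ_max)
over 1–3 chosen axes (64 bins per axis by default), reported in k_BT
units — no absolute calibration is claimed; empty bins are masked.
Clustering is either equal-width binning along a chosen direction or
seeded K-means (10 restarts). Cluster representatives are the arithmetic
mean of aligned member models plus an average density: re-oriented
member averages for subtomograms, and a direct real-space backprojection
for images. The backprojection omits ramp weighting deliberately — its
purpose here is cluster-average visualization and peak-location checks,
not high-fidelity reconstruction.

## Synthetic benchmarks — what they show

The generator displaces a toy Cα structure (helix, hairpin, or hinged
two-domain) along chosen ENM modes with known amplitudes, renders
projections or volumes at known poses with the same Gaussian model used
for fitting, and adds white Gaussian noise last (the clean signal is
independent of the noise level; everything is bit-reproducible from the
seed). Amplitude samplers cover a uniform range (continuous landscapes)
and a two-component Gaussian mixture (clusterable landscapes); poses are
uniform over SO(3) via quaternion sampling, or identity-biased for
subtomogram-like data.

Benchmark problem sizes are chosen to make the full workflow cheap
enough to run routinely: 20-residue structures, 32² images at 2 Å/pixel,
2,000-step fits, 20–50 particles. At these conditions a single fitting
pass recovers the ground-truth heterogeneity coordinate with
|Pearson r| ≈ 0.98 between the first landscape coordinate and the true
mode amplitude, and ≥ 90% of particles move closer to their target
conformation. A single projection image constrains the out-of-plane
component of the motion only weakly, so per-particle RMSD to target
improves but does not vanish even at CC ≈ 0.996 — the ensemble-level
landscape, not any single fit, is the meaningful result, which is
exactly the method's premise.

Because the generator uses the same Gaussian rendering as the bias (an
"inverse-crime" setup) and white noise without CTF, missing wedge, or
model mismatch, passing benchmarks demonstrate the correctness of the
machinery — force gradients, integrator, geometry conventions, landscape
recovery — not performance on real micrographs.

## Degenerate inputs and tie-breaks

- Residues without a CA atom are dropped with a logged warning.
- Chain breaks (consecutive Cα > 4.5 Å) get no bond and a warning.
- Atom pairs closer than 1e-6 Å raise immediately.
- Angle terms guard sin θ ≥ 1e-6; the toy geometries avoid near-straight
  triples, whose Cartesian curvature would be unbounded.
- Degenerate ENM eigenvalues (symmetric structures) are reported as-is.
- K-means and UMAP take explicit seeds; all stochastic tests are seeded.
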