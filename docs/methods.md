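# Methods

`allodyn` analyses how effector binding reshapes a protein's mechanics and
dynamics: which inter-residue interactions change (force-distribution
analysis), how much configurational entropy the binding event costs
(quasi-harmonic and force-covariance estimators), how local flexibility
shifts (methyl-axis and dihedral order parameters), and how collective
motions compare across liganded states (PCA, motion matrices, projections).
Because public trajectory data for the systems these methods were developed
on is generally unavailable, the package carries a first-class synthetic
generator whose ground truth is analytic; every estimator is validated
against closed forms before it is pointed at real data.

## The synthetic dimer

The generator builds a C2-symmetric homodimer as an elastic network model
(ENM): one pseudo-atom per residue (mass 110 amu) on a jittered compact
lattice, optionally four sites per residue (N, CA, C and a side-chain
centroid; masses 15/13/28/54 amu) when backbone dihedrals or atom-resolved
minimal distances are needed. Hookean springs of stiffness `k_default`
(500 kJ·mol⁻¹·nm⁻² by default) join all node pairs within a contact cutoff
(1.2 nm). Protomer B is the image of protomer A under a two-fold rotation,
so the dimer is exactly C2-symmetric and protomer-stress symmetry is an
exact null hypothesis for convergence diagnostics.

Two perturbations emulate effector binding:

* **Ligand node** — a 329 amu pseudo-atom at the pocket centroid, attached
  by springs to each pocket residue. A pocket needs **at least four**
  anchors: a node held by three springs has three degrees of freedom and can
  relax all three constraints, so it adds exactly zero effective stiffness
  to the protein (the Schur complement of the added quadratic form
  vanishes).
* **Planted pathway** — a designated chain of residue contacts (typically
  the shortest inter-protomer path between two residues) whose spring
  stiffnesses differ by `delta_k` between the two states. The chain is
  recorded on the model as ground truth, so pathway-recovery by the force
  network machinery can be scored exactly.

Equilibrium lengths equal the build geometry's distances (a relaxed
network), so the Hessian is the sum of `k·d̂d̂ᵀ` bond blocks and has exactly
six zero modes for a connected 3-D model.

**Sampling.** Frames are drawn i.i.d. from the exact Gaussian of the
harmonic model: covariance `kB·T·H⁺` (pseudo-inverse over internal modes) at
T = 300 K by default. This makes the entropy and per-bond force statistics
of the ensemble exact, decoupling estimator validation from integrator
error. A Langevin option replaces i.i.d. modal amplitudes with per-mode
Ornstein–Uhlenbeck series (correlation time 1/ω) for analyses that need
time correlation, such as windowed order parameters. All randomness flows
from one integer seed through counter-based (Philox) streams keyed per
replica, so replica r is bitwise identical regardless of how many replicas
are drawn.

**Forces.** Pairwise spring forces are exact by default,
`F_ij = −k(r−r₀)d̂`. Exact forces on Gaussian-sampled frames carry the
geometric anharmonicity of finite-length springs (transverse second-order
terms), which at `k = 500`, T = 300 K biases force-covariance entropies by
several percent relative to the harmonic oracle. A `linearize` option
returns the first-order force `−k(d̂₀·(d−d₀))d̂₀` — exactly the force field
of the harmonic model the sampler draws from — and is the right input when
an estimator is compared against the analytic entropy. Force-distribution
analysis uses the exact forces.

**What the generator does not emulate.** No solvent or friction, no
anharmonic force field (beyond the geometric term above), no conformational
transitions, no side-chain rotamers, and its binding mechanism (added
springs) is a stand-in, not a physical model of ligand chemistry. Passing
tests therefore demonstrate that the estimators are implemented correctly
and converge at known rates on harmonic ensembles — not that any particular
biological system behaves harmonically.

## Force distribution analysis

The residue-pair force at one frame is `F_uv = ‖Σ F_ij‖` over atom pairs
(i ∈ u, j ∈ v): vectors are summed *before* the norm, so opposing atomic
forces cancel, and intra-residue pairs are excluded. The magnitude is taken
per frame and then averaged over time and (unweighted) over replicas — note
that these magnitudes do not average to zero at equilibrium, unlike the
atomic force vectors themselves. The alternative convention (average the
vector, then take the norm) is available but not the default. Forces are
reported in pN (1 kJ·mol⁻¹·nm⁻¹ = 1.661 pN).

State differences ΔF_uv are thresholded by |ΔF| ≥ cutoff (undirected edges;
40 and 50 pN are the bundled presets) and the connected components ordered
by residue count, with ties broken by summed |ΔF| and then by
lexicographically smallest member, making component identity deterministic.
Punctual stress `S_u = Σ_v ⟨F_uv⟩` supports a convergence diagnostic on
homodimers: for every subset of k replicas (capped at 2,000 random subsets
per k, seeded), the mean absolute stress difference between C2-mirrored
residues is averaged; on a symmetric system the curve must decay toward
zero as k grows.

## Configurational entropy

Both estimators assume harmonic dynamics and infer mode frequencies from an
observed covariance, then sum the quantum harmonic-oscillator entropy

    s(ω) = kB [ x/(eˣ−1) − ln(1−e⁻ˣ) ],  x = ħω/(kB·T),

over retained modes (the quantum form matches the estimator literature the
approach derives from; at the toy's frequencies and 300 K it is within a
fraction of a percent of the classical limit).

* **QH** diagonalises the covariance of mass-weighted coordinates after
  superposing all frames onto the selection's iterated mean;
  `ω = √(kB·T/λ)`. Superposition removes rigid-body variance, so the
  rigid modes appear as a near-null subspace of the covariance; eigenvalues
  below 10⁻¹⁰ of the spectral maximum are dropped. (They are the
  *highest*-frequency modes under this mapping and carry no entropy, so the
  floor is a numerical convenience, not a physical truncation.)
* **FC** diagonalises the covariance of mass-weighted atomic forces
  `f/√m`; `ω = √(μ/(kB·T))`, consistent with `⟨f²⟩ = m·ω²·kB·T` for a
  harmonic oscillator. No superposition is needed — a rigid rotation of all
  frames rotates the covariance without changing its spectrum. Rigid-body
  *force* components (net force; net torque when a reference structure is
  available) are projected out first: for a full system they vanish
  identically by Newton's third law, but a sub-selection of a liganded
  complex retains weak restoring forces along its own rigid directions,
  and those ultra-soft pseudo-modes would make entropy differences across
  binding states incomparable.

On exactly harmonic ensembles the two estimators agree and converge to the
analytic mode-sum entropy (the package computes per-selection analytic
limits too: the QH limit sees the marginal coordinate covariance
`kB·T·(H⁺)_sel`, the FC limit the stiffness block `kB·T·H_sel`; the two
differ on sub-selections, which is why estimator and selection must match
before a −TΔS is formed). On anharmonic landscapes they split: for a
*single-well* quartic perturbation the coordinate-based estimate is in fact
slightly closer to the exact entropy (both frequency estimates shift
identically to first order in the anharmonicity), but on multimodal
landscapes — the regime that matters for side-chain and loop dynamics — the
coordinate variance inflates with the basin spread and QH overestimates
entropy grossly, while forces track local curvature. The anharmonic
benchmark is therefore a quartic double-well, where the FC bias is several
times smaller than the QH bias against a quadrature-exact reference.

Binding entropy changes are reported as −TΔS in kcal·mol⁻¹ at the
simulation temperature (300 K), positive = penalty, with a replica-bootstrap
percentile band available.

## Order parameters

Methyl-axis S² uses the standard second-moment form with factor 2 on all
three cross terms,

    S² = 3/2 [⟨x²⟩² + ⟨y²⟩² + ⟨z²⟩² + 2⟨xy⟩² + 2⟨xz⟩² + 2⟨yz⟩²] − 1/2,

computed per non-overlapping window (3 ns default) on superposed frames and
averaged over windows and replicas; windowing matters because slow exchange
between orientations lowers the whole-trajectory S² below the window mean
(motional narrowing). The validation generator samples wobble-in-a-cone
vectors whose cone angle is solved from `S = cosθ₀(1+cosθ₀)/2`, `S² = S²`,
so the target is recovered by construction. Dihedral order parameters use
circular moments, `S = ⟨cos χ⟩² + ⟨sin χ⟩²`, over the concatenated ensemble,
averaged per residue over φ, ψ and the side-chain stand-in χ; the von Mises
closed form `(I₁(κ)/I₀(κ))²` is the test oracle. Differences follow the
convention Δ = S_before − S_after: positive means flexibility gained after
the perturbation.

## Collective motions

PCA superposes frames to the selection's iterated mean (main-chain atoms by
default) and diagonalises the plain (not mass-weighted) coordinate
covariance; eigenvector signs are fixed so the largest-magnitude component
is positive. Motion matrices — differences of two Cα–Cα distance matrices —
compare motions in internal coordinates with no fitting at all; their
similarity is the Pearson correlation over unique off-diagonal entries.
Mode-derived motion matrices displace the mean by ±1 standard deviation
(√eigenvalue) along the mode by default. Structure sets (e.g. crystal
ensembles) are analysed with equal weights; the first five modes are the
default scope for cross-comparisons. RMSF converts to B-factors as
`B = (8π²/3)·RMSF²`; locally-fitted RMSD fits each frame on the atoms within
6 Å of a target residue (in a reference averaged over all states) before
measuring that residue's deviation, isolating local rearrangement from
global motion. A domain rotation angle is read from the least-squares
rotation of the domain after fitting on the stationary core.

## Distance metrics and classification

Minimal inter-residue distances default to side-chain heavy atoms
(configurable). State classification smooths the reference state's distance
samples with a Gaussian KDE and takes the two inflection points flanking
the dominant basin as integration limits; each state's density is then
integrated over the three intervals (activated / intermediate /
deactivated), summing to 1 within 10⁻⁶. Inflection detection uses the
normal-scale bandwidth for *second-derivative* estimation (1.06·n^(−1/9)) —
Silverman's density-optimal rule leaves curvature-scale sampling wiggles
that generate spurious inflections — plus a sign-persistence filter; the
integration densities themselves use Silverman's rule. Explicit limits can
be supplied instead. Hydrogen-bond occurrence uses donor–acceptor ≤ 3.5 Å
and, when hydrogens exist, D–H···A ≥ 150° (common practice defaults;
configurable); topologies without hydrogens fall back to the distance
criterion and the output flags `distance-only`. Pair non-bonded energies
sum `4ε[(σ/r)¹² − (σ/r)⁶] + q_i q_j/(4πε₀ ε_r r)` over inter-residue atom
pairs with Lorentz–Berthelot mixing, ε_r = 1 by default, no cutoff.

## Numerical choices and problem sizes

Internal units are nm, amu, kJ·mol⁻¹, ps (so ω = √(k/m) is rad·ps⁻¹
directly); kB = 8.3145×10⁻³ kJ·mol⁻¹·K⁻¹, ħ = 6.3508×10⁻² kJ·mol⁻¹·ps.
Spectral floors are relative (10⁻¹⁰ of the maximum eigenvalue). Atom serials
are 1-based on disk and 0-based in memory, with the parsers as the only
boundary. The test suite and the acceptance script run on dimers of 10–12
residues per protomer with ensembles up to 10⁵ frames, sizes at which the
closed-form checks resolve sub-percent biases while the whole suite runs in
well under a minute of compute-heavy steps.

## Known limitations

Entropy estimators are selection-dependent and the QH and FC selection
entropies are *different functionals* on sub-selections; only matching
estimator/selection pairs may be differenced. The FC estimator inherits the
harmonic approximation's blindness to basin multiplicity — it degrades more
gracefully than QH on multimodal landscapes but is still biased there. The
pipeline's synthetic states share equilibrium geometry across binding
states (binding changes stiffness, not structure), so mean-structure
read-outs (distance shifts between states) require the structure-series
utilities rather than the ENM sampler. PDB reading assigns element-based
masses and does not parse mmCIF.
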