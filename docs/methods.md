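# Methods

`afmfit` recapitulates coarse-grained 3D topological structures of single
RNA molecules from AFM topographs.  A structure model is driven by Langevin
dynamics under a pseudo-potential that rewards agreement between the
experimental height map and a pseudo-AFM image back-calculated from the
model, while a native-centric structure potential preserves the covalent
and secondary structure.  The resulting trajectory is mined for candidate
structures by an unsupervised energy/PCA/clustering pipeline, and a small
feed-forward network estimates each candidate's accuracy (RMSD to the
unknown reference) from its energy and topography features alone.

## Image model and scoring

An AFM topograph is a rectangular grid of heights Z(x, y) (Å), row-major
with the origin at the lower-left pixel centre and a fixed pixel size
(default 5 Å/px).  Agreement between the experimental image I_exp and a
simulated image I_sim is the **non-centred cosine similarity**

    CC = Σ_i I_exp,i I_sim,i / sqrt(Σ_i I_exp,i² · Σ_i I_sim,i²) ,

which lies in [0, 1] for non-negative height maps.  This is deliberately
not a Pearson correlation: background pixels carry signal (absence of
material) and mean-centring would discard it.  The mean-centred form is
used only by the resolution analysis (ACV below).  The fitting bias is

    V_AFM = θ_AFM · N · k_B T · (1 − CC) ,

with N the total bead count and k_B T = 1 in reduced units; it vanishes
exactly at CC = 1.  θ_AFM is the only weight a user routinely changes; it
is scanned (typically 2–50) because its optimum depends on the particle
topography, the image noise and the distance of the start model from the
truth.

A **stage potential** keeps the molecule's backside on the support plane:
per bead of height z above the stage, a 12-6 Lennard-Jones term
4ε[(d/z)¹² − (d/z)⁶] with ε = 1 (reduced) and contact distance d equal to
the bead radius (4 Å).  Its per-bead minimum is exactly −ε at z = 2^{1/6}d.
Heights below 0.25·d are clamped (the wall is already astronomically
steep there); in the integrator the clamped region applies the floor
force so penetrating beads are always pushed back out.

## Pseudo-AFM synthesis (tip dilation)

The probe is a sphere of radius r_t (default 10 Å) and each bead a sphere
of radius r_b (default 4 Å).  The recorded height at a pixel is the lowest
apex position at which the tip touches any bead: for a bead at height z
and lateral distance ρ,

    h(ρ) = z − r_t + sqrt(R² − ρ²) ,   R = r_t + r_b ,  ρ ≤ R ,

max-composited over beads and clipped at zero (grayscale dilation).  The
molecule is first dropped so its lowest bead *surface* rests at z = 0.
The sphere-tip model and its two radii are deliberately simple and fully
reproducible; both radii are configurable.

**Differentiable surrogate.**  The dilation max and the sphere-cap edge
are not differentiable, so the force routine uses a C∞ surrogate: with
q = R² − ρ² and the hyperbolic rectifier t = sqrt(q² + β²),
spos = (t+q)/2, sneg = (t−q)/2 (smoothing scale β = 2Rτ),

    c_i = z_i − r_t + sqrt(spos) − sneg / λ ,   λ = R/2 ,

and per pixel the bead contributions combine with the bare stage (height
0) through a log-sum-exp of temperature τ (default 1 Å).  The − sneg/λ
term sends far-away contributions to −∞ so distant beads never raise the
background.  The AFM force is the exact analytic gradient of V_AFM through
this surrogate; tests verify agreement with central finite differences to
10⁻³ relative on random configurations.  The hard dilation is used for
imaging and registration; the soft one for dynamics and the CC values
recorded along a trajectory (the two agree closely once τ ≪ feature
height).

**Initial registration** is a deterministic grid search over in-plane
rotations (15° steps) about the molecule centroid and integer-pixel
translations, maximizing hard-image CC.

## Structure potential and dynamics

The engine is deliberately **not** a full biomolecular force field; its
purpose is the topographic bias and the ten per-frame energy features.
Each nucleotide is three beads (phosphate at P, sugar at C4', base at the
base-ring centroid).  From a native (reference) model we measure:

- harmonic bonds, angles and dihedrals along the backbone chain
  (P,S,P,S,…) plus sugar–base branches (k_bond 20, k_angle 10, k_dih 1;
  reduced units, lengths in Å) — these form E_local;
- 12-10 Go wells ε_go[5(r0/r)¹² − 6(r0/r)¹⁰] for native bead pairs within
  12 Å (ε_go 0.4), excluding bonded/angle pairs — E_go, the "does this
  model still fold like the native" term;
- harmonic wells between base beads of listed base pairs and stacks
  (k 2.0) — E_pairing, E_stacking;
- soft-core excluded volume ε_ev[(σ/r)¹² − 1] for r < σ = 4 Å — E_repulsive;
- Debye-screened phosphate–phosphate repulsion k_e·exp(−r/λ_D)/r
  (k_e 0.5, λ_D 10 Å) — E_electrostatic.

The weighted total energy is

    E_total = V_AFM + θ_c E_local + θ_stacking E_stacking
            + θ_pairing E_pairing + θ_contact E_go
            + E_repulsive + E_electrostatic + B_stage ,

with the empirically optimal weights θ_c = 5, θ_stacking = 9,
θ_pairing = 9 and θ_contact = 1 (unity to avoid biasing toward the start
structure).  Trajectory energy records store the weighted components.

Integration is BAOAB Langevin splitting (unit masses, timestep 0.02,
friction 0.5, temperature 0.3 reduced).  These desk-scale defaults were
chosen once for stability of the bonded terms (ω_max·dt ≈ 0.1) and kept;
production-scale parameters belong to the user.  The AFM force is
recomputed every step by default (configurable cadence).  Runs are
bitwise reproducible per seed; frames and full energy records are saved
every `save_every` steps (default n_steps/1000).  Hot loops (structure
force, soft synthesis + CC gradient) are numba-compiled; the vectorized
numpy implementations remain as references and the test suite enforces
equivalence to ~1e-10.

## Unsupervised model selection

1. **Energy filtering**, two stages, z-scores with the population σ.
   Stage 1 bounds each of E_repulsive, E_local, E_stacking, E_pairing,
   B_stage from above (default +3σ); stage 2, recomputed on the
   survivors, keeps CC ≥ −1σ and E_total ≤ +1σ.  Seven components in
   total.  No single set of cutoffs is canonical across instruments and
   trajectories, so every cutoff is a config key; the defaults are
   deliberately permissive.
2. **PCA** of the standardized 10-feature matrix (the nine energies/CC
   plus V_AFM) via full SVD.  Eigenvalues follow the population-covariance
   convention.  The component count is the smallest n whose next
   component adds less than 5% explained variance, floored at 3 (the
   dimensionality used for visual inspection).
3. **k-means** (k-means++, 10 restarts, fixed seed) on the selected
   scores for k = 1..k_max; k is chosen from the WCSS curve: the smallest
   k whose next WCSS drop falls below 10% of the initial drop.  If even
   the best split removes less than half the WCSS there is no cluster
   structure and k = 1 (a single Gaussian blob loses only ~35–40% on its
   first split — the first-difference rule alone cannot flag it).
4. **Representative cluster**: lowest sum of standardized means of
   E_local, E_total, E_go; ties resolve to the lowest cluster id.
5. **Cohort**: within that cluster, frames with CC above its 0.90
   quantile and each of E_total, E_local, E_go below its 0.25 quantile.
   An empty intersection relaxes the quantiles in 0.05 steps with a
   warning (guaranteeing a non-empty cohort) — anti-correlated
   energy/CC structure is a signal worth surfacing, not an error.

## Neural RMSD estimation

Ten features per frame: E_total, E_local, E_go, E_repulsive, E_stacking,
E_pairing, E_electrostatic, V_AFM, CC and the engineered feature
CC⁷·E_total (the 7th power concentrates weight on frames with
near-perfect image agreement).  Size extensivity: E_total, E_local, E_go,
E_repulsive, E_electrostatic and V_AFM are divided by the nucleotide
count, E_stacking/E_pairing by their interaction counts; V_AFM is further
divided by θ_AFM, E_stacking/E_pairing by θ = 9 and E_local by θ_c = 5, so
one trained network transfers across RNAs and θ choices.  Features are
standard-scaled with statistics frozen from the training set; every later
evaluation reuses those statistics.

The network is 10→128→64→16→1 (10,721 parameters), ELU activations, 20%
dropout on hidden layers, He-normal initialization, Adam (lr 0.001,
mini-batch 128), Huber loss (δ = 1, configurable; mean-reduced so the
learning rate is batch-size portable; MSE available).  Early stopping
monitors the validation loss restricted to examples with true RMSD ≤ 10 Å
— accuracy matters most where models are good — with patience 20
(an explicit value is required for early stopping to terminate); the
best-epoch weights are restored.  Batch normalization is omitted (useful
only for much deeper variants of this architecture).  The network and its
training loop are implemented directly on numpy arrays.

## Synthetic data

The generators define the study conditions for every test:

- **Toy RNAs** on idealized A-form tracks: rise 2.8 Å/residue, twist
  32.7°/residue, phosphate track radius 10.5 Å — chosen so duplex width
  (~21 Å phosphate-track separation) and pitch (~31 Å) land in the ~25/30 Å
  A-form envelope.  Topologies: hairpin (default 20 residues, 59 beads),
  two-helix junction, three-way junction; helix axes lie in the stage
  plane.  These are geometric scaffolds, not folded RNA: they carry no
  sequence-dependent energetics, groove asymmetry or tertiary contacts,
  so passing tests demonstrate the machinery, not force-field realism.
- **Perturbations with known RMSD**: a chain-smoothed random displacement
  field ("jitter") or a rigid hinge rotation of the second half of the
  beads, closed-loop scaled until the Kabsch RMSD hits the target within
  0.5% (tests require 2%).
- **Benchmark surfaces**: noiseless ground-truth image plus Gaussian
  noise at 5, 10, 15, 20, 30, 40 and 50% of the maximum height, clipped
  at zero (post-levelled AFM heights are non-negative).  Clipping makes
  the background a folded normal; recovery tests compare against
  σ·sqrt(1 − 2/π).
- **Planted trajectories**: RMSD labels uniform in [2, 25] Å; each energy
  component intercept + slope·RMSD + Gaussian noise, CC a monotone
  decreasing map 0.97 − 0.018·RMSD with σ = 0.02 noise, clipped to [0, 1].
  Slopes and noise (e.g. E_total: 40/Å slope, σ = 60) give a clearly
  learnable but noisy relation — the assumption under test is exactly the
  selection hypothesis: good models are simultaneously low-energy and
  high-correlation.  Real trajectories are noisier and non-linear; the
  planted generator shows the pipelines select and score correctly when
  the assumption holds, not that the assumption holds for any particular
  experiment.

All generators are bitwise reproducible per seed.

## Resolution and noise analysis

Background noise is the mean/SD of particle-free pixels (mask or
auto-threshold at 5% of the maximum height).  Resolution uses the
auto-correlation value (ACV): the image is low-pass filtered by zeroing
all Fourier components with radial frequency above a cutoff (a circular
"ring" in frequency space), and the mean-centred correlation between
original and reconstruction is traced from low to high cutoff.  The ACV
is non-decreasing in the cutoff (nested projections) and reaches 1 at the
grid's corner frequency √2·f_Nyquist (with circular rings, components
between f_Nyquist and the corner exist along the diagonals; the profile
therefore ends at the corner frequency, where reconstruction is exact).
Kinks in the first derivative mark the spatial frequencies of real image
features; they are reported (with a documented local-maximum heuristic)
but intended for visual inspection, as in practice.

## Numerical choices and degenerate inputs

- All-zero images make CC undefined → error, as does a zero-variance
  image in the ACV.
- Zero-variance features cannot be standardized → error naming the
  feature/component; in the energy filter a constant component simply
  filters nothing.
- DCCM uses the sugar bead as the residue representative (always present,
  exactly one per residue); zero-variance residues give 0 entries with a
  warning.
- RMSD defaults to all beads (models are coarse-grained); a bead-kind
  selection and a residue mask are available (e.g. to exclude residues
  unresolved in a reference structure).
- Trajectory blow-up (|coordinate| > 10⁶ Å) aborts with the step index.

## Desk-scale problem sizes

The package's experiments are sized for a single CPU: 20-residue toys,
~20×20-pixel images at 5 Å/px, 50k-step fitting runs (the 10-seed CC-gain
experiment), and 6000-frame planted trajectories (5000 train / 1000
held-out for the network).  Full-scale runs (tens of millions of steps,
millions of frames, multi-RNA training databases) use the same code paths
with larger numbers.

## Known limitations

- The structure potential is a documented stand-in; energies are in
  reduced units and not comparable to any physical force field's output.
- The tip-dilation parameters are generic; real probes are neither
  spherical nor constant.
- The engine simulates one molecule on an ideal stage: no drift, no
  scan-line artefacts, no probe wear, no molecule–molecule contacts.
- The WCSS elbow and PCA component rules are heuristics with documented
  thresholds; pathological score geometries can defeat them.
- The RMSD estimator is only as good as the energy–accuracy correlation
  in its training distribution; predictions degrade for models far worse
  than anything seen in training.
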