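# Methods

This note records the models, numerical choices and known limitations
behind `mreitep`.  Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`; nothing is quoted from
elsewhere.

## Electrostatic forward model

During a pulse the tissue is treated as an ohmic conductor at
quasi-static conditions: ∇·(σ∇u) = 0 on the sample body Ω, u = U_el on
the anode surface, u = 0 on the cathode, and σ ∂u/∂n = 0 on the rest of
∂Ω.  Capacitive and thermal effects, electrode–tissue contact impedance
and the time course of σ within a pulse are all outside the model; σ is
the (possibly field-dependent, see below) effective conductivity over the
pulse train.

**Discretization.**  Cell-centered finite volume on the imaging raster
(the natural grid for MREIT, whose data arrive as images).  Face
conductances use the harmonic mean of the two adjacent cell
conductivities, which keeps fluxes exact across the sharp tumor–liver
contrast.  Faces from an unknown cell to an electrode cell use the
distance from the cell center to the *analytic* electrode circle along
the face axis instead of the full cell spacing (a Shortley–Weller-type
correction); without it the staircased circular electrodes limit the
convergence order to ≈1.  With it, the coaxial (annulus) oracle
u(r) = U ln(b/r)/ln(b/a) is reproduced to 0.02 % relative L2 at 128² and
the fitted convergence order over 64²–256² is ≈2.1 (acceptance suite).
Sparse direct factorization up to 256² unknowns, diagonally
preconditioned CG beyond; default relative residual 1e-10.

Derived fields stay flux-consistent with the solve: J is the average of
the face fluxes the solver balanced (so the discrete divergence of J is
at rounding level on interior cells and electrode currents balance to
1e-14), and E uses the same face differences, so E = J/σ holds exactly
on homogeneous regions.

**Inactive electrodes** are non-conductive markers (holes), not floating
conductors.  A floating metal needle would in reality perturb the field
in its vicinity; this model choice is one reason reconstruction artifacts
near inactive needles must be expected, and error metrics exclude a 2 mm
zone around every needle.

## Measurement channel

**What B_z can and cannot see.**  For a z-invariant planar current in a
slab, the induced B_z at the mid-plane is a convolution of the *vorticity*
of the in-plane current with a radial kernel — for any slab thickness.
Consequently the irrotational part of the current is invisible: needle
electrodes feed the plane through monopole sources whose radial flow
induces no B_z at all.  The synthesis therefore splits the current as
J = J_div-free + J_source, where J_source is the analytically known
disk-spread monopole field of the two needles carrying the
generator-measured current ±I:

* forward: B_z = µ₀ψ with ∇²ψ = ∂J_x/∂y − ∂J_y/∂x computed for
  J − J_source (divergence-free, compactly supported, so ψ ≡ 0 outside
  the sample and a homogeneous-Dirichlet fast sine-transform Poisson
  solve is exact up to discretization; the window is padded 4× to keep
  the artificial boundary away from any residual stream tail);
* recovery: J_CDI = (∂B_z/∂y, −∂B_z/∂x)/µ₀ + J_source.

Both steps use second-order differences (central interior, one-sided at
boundaries); the round trip on a smooth divergence-free current is
second order (slope 2.0, 0.3 % relative L2 at 128²).  An O(N²) direct
Biot–Savart summation over a finite-thickness slab provides an
independent cross-check: on a loop-current phantom it agrees with the
planar synthesis to ≈4 % away from the current sheet at 32², with the
discrepancy shrinking as the slab thickens (the planar model is the
infinite-slab limit).

**Phase encoding.**  φ = γ B_z t_c with γ = 2.6752218744×10⁸ rad s⁻¹ T⁻¹
(CODATA proton value) and t_c = n_pulses × pulse_duration (default
4 × 100 µs = 400 µs).  Wrapping is off by default; a quality-guided
unwrap (scikit-image) is provided for wrapped tests.  Phase noise is
zero-mean Gaussian with standard deviation 1/SNR rad, reproducible under
a fixed seed — a deliberately simple stand-in for the CDI sensitivity
floor, white rather than structured.

## J-substitution reconstruction

Iterate: solve the forward problem under σ_k, form |J_k|, update
σ_{k+1} = σ_k·|J_CDI|/|J_k| on the sample (clamped to [1e-4, 10] S/m;
cells with |J_k| below 1e-6 of its maximum carry no information and are
skipped), stop when the change between successive conductivities falls
below 0.01.  Because the electrode voltages enter as absolute Dirichlet
data, the reconstructed σ is absolute: scaling the true σ by c scales
|J_CDI| by c and the reconstruction returns c·σ (tested).  The electric
field is then E = J_CDI/σ_MREIT (vector Ohm's law).

**Stopping rule.**  "Change below 0.01" is read as the relative max-norm
|Δσ|/σ over the region of interest for idealized data; for
channel-recovered data the presets use the relative L2 norm instead,
because a handful of rim cells flicker indefinitely at the artifact
level and the max-norm never fires.  Both readings (and absolute
variants) are configurable (`ReconstructionConfig.change_norm`).  The
divergence guard triggers on *sustained* growth (>5 % per step, five
consecutive steps).

**Semi-convergence and the interior update region.**  On idealized
(inverse-crime) data the iteration converges cleanly: the homogeneous
disc is recovered exactly in 2 iterations, the two-tissue phantom to
<0.5 % per-region median in 14.  Channel-recovered data contain
systematic errors where differentiation crosses the sample rim and near
the needles; iterating on those cells drags an initially excellent
reconstruction away (bulk recovered in ~1–5 sweeps, artifacts fitted
thereafter).  The pipeline therefore (i) updates σ only on the interior
(mask eroded by 2 cells, 1 mm needle zone excluded) and extends the
result into the rim by nearest neighbor, and (ii) retains the iterate
with the smallest inter-iteration change (`keep_best`), reporting
`converged: false` when the 0.01 rule itself never fired.  Both
safeguards are plain `ReconstructionConfig` options and off outside the
pipeline defaults.

**Initialization** is uniform 0.1 S/m (configurable); no value is
assumed known beyond the applied voltage and electrode geometry.

## Phantoms and presets

The synthetic phantoms define the study conditions:

* `exvivo_liver_4electrode` — 20 mm tissue disc (baseline 0.1 S/m, a
  typical ex vivo liver value), four 1 mm needles on an 8 mm square,
  pulse pairs 1–2 (adjacent) or 1–3 (diagonal) at 1000 or 1500 V;
  64×64 over 30 mm.  The ex vivo presets enable the field-dependent
  conductivity option (below).
* `tumor_region` — homogeneous tumor section, σ_T = 0.4 S/m, needle pair
  20 mm apart at 1700 V; 128×128 over 60 mm, needle radius 0.9 mm
  (clinical long-needle scale; the source geometry for the patient model
  is not published, so spacing and window are package assumptions).
* `tumor_liver_region` — tumor (0.4 S/m) and liver (0.05 S/m) joined by
  a sigmoid transition, needle pair at 2100 V.  The logistic form
  1/(1+exp(−4d/w)) with w the 12–88 % width (default 1 mm) is a package
  choice; only "sigmoid" is specified by the underlying protocol.
* `annulus` — coaxial oracle with a closed-form solution.

**Pulse-pair orientation and non-uniqueness.**  A single pulse direction
yields one |J_CDI| map, and distinct conductivity distributions can share
it exactly — the test suite constructs two layered conductivities with
equal series resistance whose current fields coincide to 1e-6.  The
degeneracy lies *along* the current: conductivity contrast transverse to
the flow is recovered to fractions of a percent, contrast in series with
it is essentially undetermined (verified: a flow-crossing two-tissue
split converges to a wrong σ while matching |J_CDI| to 0.4 %).  More
pulse directions would resolve this but are not available during a
treatment, where every pulse train alters the tissue.  The
`tumor_liver_region` preset therefore places the needle pair along the
tumor margin — the arrangement used to secure field coverage of the
margin, and the orientation in which the data determine both plateaus;
the flow-crossing arrangement remains available as
`orientation="crossing"` to demonstrate the limitation.

**Field-dependent conductivity.**  Electroporation raises tissue
conductivity nonlinearly with the local field.  As no functional form is
established, the package uses a smooth logistic multiplier rising from 1
below E_rev = 400 V/cm toward `factor` = 2 above E_irrev = 800 V/cm
(threshold scale typical for liver), applied as a fixed point with the
forward solve (under-relaxed by 0.5; the bare map flip-flops across the
threshold).  With it, raising the ex vivo pulse amplitude from 1000 V to
1500 V increases the delivered current super-proportionally (ratio ≈1.6
vs the linear 1.5; tested), the qualitative signature of tissue
permeabilization.  This mechanism is a
qualitative emulation — it reproduces a conductivity rise between the
active needles and a super-proportional current increase, not any
measured dynamics.

## What the synthetic data do and do not show

The generator reproduces: the imaging raster and pulse timing, the
planar-current geometry, the single-component measurement with its
blindness to source flow, boundary-differentiation artifacts, Gaussian
phase noise, and tissue-like conductivity contrasts.  It does not
reproduce: 3D current spreading near needle tips, RF-chain and sequence
artifacts, wrap in the presence of noise, structured (non-white) noise,
susceptibility distortions near metal, or real electroporation dynamics.
Passing tests therefore demonstrate the correctness and stability of the
reconstruction chain under its stated model, not clinical performance.

## Numerical details and defaults

| parameter | default | meaning |
|---|---|---|
| solver tol | 1e-10 | relative algebraic residual of the forward solve |
| σ floor/cap | 1e-4 / 10 S/m | positivity clamps of the update |
| stopping tol | 0.01 | change between successive conductivities |
| max iterations | 50 | J-substitution cap |
| γ | 2.6752218744e8 rad/(s·T) | proton gyromagnetic ratio |
| t_c | 400 µs | 4 pulses × 100 µs |
| exclusion zone | 2 mm | electrode-adjacent cells excluded from metrics |
| update region | mask − 2 cells − 1 mm needle zone | pipeline update support |
| Poisson pad | 4× | window padding of the stream-function solve |
| Biot–Savart guard | 64² cells | O(N²) size guard (overridable) |

Degenerate inputs raise typed errors: electrodes outside the sample or
unresolved by the grid, missing anode/cathode, wrapped phase fed to the
decoder, empty ROIs, σ below floor inside the mask.

Benchmark problem sizes (64²–256² grids, 32² for the O(N²) summation,
five SNR levels for the robustness trend) were chosen so the whole
acceptance computation completes in well under a minute; all quantities
are grid-converged at those sizes as the refinement checks show.

## Known limitations

* Single-direction data: series conductivity structure is undetermined
  (see above); reconstructions in the flow-crossing orientation are
  qualitative at best.
* The B_z model is strictly planar; the slab oracle quantifies but does
  not remove the idealization.
* The source-flow restoration assumes the needle positions and total
  current are known exactly; errors in either translate directly into
  J_CDI.
* `converged: false` with `keep_best` means "stopped at the most
  self-consistent iterate", not failure — but also not a certificate.
* The field-dependent σ mechanism is synthetic; its parameters are
  plausibility choices, not fits to data.
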