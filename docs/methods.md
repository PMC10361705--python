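# Methods

This note documents the model, the estimators, the synthetic fixtures and
the numerical choices behind them, in the spirit of a package reference
rather than a tutorial.

## Units

Lengths are nm (PDB Å are divided by 10 on read), energies are reduced units
(r.u.) with 1 r.u. = 2 k_BT at the reference simulated temperature, and time
is the reduced time unit τ_ru. The reference temperature in reduced energy
units is k_BT = 0.49887. Free-energy profiles store F in units of k_BT
(`F = −ln P` plus an offset), with the temperature carried as metadata.

## The multi-basin structure-based model

### Term construction

Bonds, angles and improper dihedrals are harmonic about equilibrium values;
planar ring dihedrals use a periodicity-2 cosine; proper dihedrals use
`F_D(φ) = [1−cos φ] + ½[1−cos 3φ]` about minima `φ₀`; native contacts are
12-6 wells `ε[(σ/r)¹² − 2(σ/r)⁶]`; all remaining pairs feel a repulsive
`ε_nc (σ_nc/r)¹²` (defaults ε_nc = 0.01 r.u., σ_nc = 0.25 nm; conventional
values, not normalization targets). Exclusions cover pairs within three
covalent bonds plus all contact pairs.

For desk-scale systems the bonded equilibrium geometry is measured from the
input structure. A transferable bonded-parameter database would serve the
same role for biomolecular structures; it does not affect any quantitative
identity the package enforces.

### Contact map

The default contact definition is a cutoff map: atom pairs within 0.6 nm,
at least 3 residues apart when on the same chain, and not covalent
neighbors. An optional line-of-sight ("shadowing") filter removes pairs
whose connecting segment passes within 0.1 nm of a third atom. The cutoff
map with these defaults is a faithful stand-in for screened contact maps on
the dense toy systems used here; the filter is exercised by tests but off by
default.

### Dihedral weights

Proper dihedrals are grouped by their middle bond; members of a group split
the group weight equally. Backbone groups (both middle-bond atoms in the
backbone name set) share one group weight across polymer types; sidechain
group weights are set per polymer type so that the *summed*
backbone/sidechain ratio is R_bb/sc = 2 for proteins and 1 for nucleic
acids. The ratio is enforced on the sums because group counts of the two
kinds are generally unequal; with equal counts this reduces to the
per-group-weight reading.

### Normalization

Two scalar rescalings impose, exactly,

- `Σε_C / (Σε_bb + Σε_sc) = R_C/D = 2`
- `Σε_C + Σε_bb + Σε_sc = N ε` (N = atom count).

Unique contacts keep their fixed weights (0.21 rotated / 0.19 unrotated, in
r.u.); the common contacts and the dihedrals absorb the rescaling, so both
identities hold after a multi-basin merge as well. The weights 0.21/0.19 are
treated as given constants of the model.

### Multi-basin merge

Given endpoint topologies built on identical atom tables:

- proper-dihedral minima move to the circular mean of the two endpoint
  values (vector averaging; exactly antipodal endpoint values raise an
  error rather than guessing a branch). `F_D` is even about its minimum, so
  the two endpoints are exactly isoenergetic for every dihedral.
- inter-subunit pairs present in both endpoint contact maps get the
  isoenergetic well position, the closed form
  `σ′⁶ = 2(r_A⁻⁶ − r_B⁻⁶)/(r_A⁻¹² − r_B⁻¹²)` (limit `σ′ = r_A` when the
  distances coincide), and the shared depth fraction
  `ε_iso/ε_C = −V(r_A)/ε_C ∈ (0,1]`. Fractions above ½ classify the pair
  "common"; intra-subunit pairs are always common.
- pairs in a single endpoint map are unique to that endpoint with its own
  native distance. A pair present in both maps but failing the ½ criterion
  is assigned to the endpoint where it is shorter — the choice is symmetric
  under swapping the endpoint labels, which the tests assert.
- intra-subunit pairs appearing in only one endpoint map are kept common
  with that endpoint's distance (for near-rigid endpoint pairs this is a
  boundary effect of the cutoff).

The 0.96 well-position scaling (`σ = 0.96 σ′`), which counteracts entropic
expansion of large assemblies, is applied *after* the isoenergetic solve,
to all contacts; classification uses the unscaled geometry. The alternative
ordering (scale native distances first) and exempting unique contacts are
available behind `sigma_scale_stage` / `scale_unique`. Isoenergeticity is an
exact property of the unscaled well `σ′` and is tested there; the scaled
wells shift both endpoints almost identically.

## Dynamics

A BAOAB-splitting Langevin integrator with uniform unit masses, default
friction 1/τ_ru and time step 0.002 τ_ru; with friction 0 it reduces to
velocity Verlet. Trajectories are bit-reproducible for a given seed and
record the total potential energy of every saved frame (the U used for
temperature reweighting). Forces for every term are analytic and verified
against central differences in the tests. The integrator targets desk-scale
systems (10²–10³ atoms); assemblies of ribosome size are the domain of the
emitted GROMACS-dialect files, not of this integrator.

## Rotation coordinates

`superpose` is Kabsch superposition via SVD with the determinant correction
(proper rotations only). Core residues are the fixed point of: fit on the
included set; re-include every mapped proxy atom (P for rRNA, configurable
for toys) within 1 Å of its fitted position, exclude the rest; repeat.
Oscillating sets and sets below three residues are errors.

Per frame: the reference structure is fitted to the frame's LSU core (this
defines the lab frame), the LSU-aligned reference body is fitted to the
frame's SSU-body core, and the residual body rotation is decomposed in z–x–z
Euler angles in a basis whose z axis is the pure-rotation axis. The basis is
constructed *once* in reference coordinates and carried through the LSU
alignment, which makes all three reported angles invariant under rigid
motion of the whole complex (asserted to 1e-8 degrees). Reported
coordinates: φ_body = φ+ψ, θ_body = θ, ψ_body = φ+C with C a configurable
offset (0 by default; anchoring ψ_body to a structural feature such as
helix 44 requires the corresponding reference structure). Below θ = 0.1°
the tilt direction is geometrically undefined: frames are flagged, φ_body
carries the full in-plane angle and ψ is reported as 0.

## Landscape analysis

**Free energy.** Histogram estimate `F = −ln P` in k_BT, empty bins NaN
(never zero-filled), minimum offset to zero.

**Transition paths.** A frame is on a transition path iff it lies strictly
between the last exit from one state window and the next entry into the
other window; excursions that return to their origin state are not paths.
P(TP|q) is the per-bin fraction of such frames. The peak is reported over
bins holding at least 50 frames (configurable) to keep it out of
noise-dominated bins. For diffusive dynamics on a coordinate that resolves
the barrier the peak approaches 0.5; mixing orthogonal noise into the
coordinate lowers it, which a test asserts as a direction of change.

**Diffusion.** The coordinate is discretized on the profile's bins and
modeled as a nearest-neighbor jump process consistent with the supplied F
(discretized Smoluchowski generator, rates
`k(i→i±1) = D/Δx² · exp(−(F_dest−F_src)/2)`); the observed bin-to-bin
transition counts at a chosen lag enter a likelihood maximized over a single
log D (matrix exponential propagator, bounded scalar optimization). A
uniform D is the model; lag-robustness is checked by re-inference at a
doubled lag. Too few inter-bin transitions at the chosen lag is an error
suggesting a larger lag.

**MFPT.** The nested quadrature
`⟨τ⟩ = ∫_{ρi}^{ρf} dρ ∫_{ρmin}^{ρ} dρ′ exp[F(ρ)−F(ρ′)] / D` is evaluated by
cumulative trapezoid on a 2000-point grid with F linearly interpolated from
occupied bin centers. The printed form divides the outer integrand by D(ρ);
`variant="inner"` offers the textbook placement of D(ρ′) inside the inner
integral (identical for uniform D, which is the supported model). Empty
bins inside the integration range are an error demanding re-binning.

**Rates.** `τ = exp(ΔF/k_BT)/C` with the attempt frequency C always a
required user parameter — the package never defaults it, since it is
system-specific.

**Temperature reweighting (FEP).** Per-frame weights
`W = exp[−(1/k_BT′ − 1/k_BT₀) U]` with the maximum exponent subtracted
before exponentiation; the effective sample size `(ΣW)²/ΣW²` is reported
and flagged below 10% of the frame count. Temperature shifts beyond ±2% are
refused unless forced, because reweighting is only trustworthy where the
reference ensemble already covers the perturbed one. Ensemble free-energy
gaps `ΔF = k_BT ln(P_unrot/P_rot)` carry block-bootstrap error bars
(contiguous blocks resampled with replacement, respecting correlation).
The default ensemble windows are the rotation-angle windows
(−1.12°, 0.82°) and (5.4°, 7.86°); a variant upper bound of 7.83° appears
in some figure annotations of the source literature — the main-text value
7.86° is the default here.

**Endpoint-stabilization arithmetic.** The helper
`contact_strength_perturbation(n, w, f, kbt_per_ru)` evaluates
`n·w·f·kbt_per_ru`: e.g. increasing ~500 unique contacts of ~0.2 r.u. by 2%
stabilizes the endpoints by 4 k_BT.

## Interface analysis

A contact is "formed" iff `r < 1.2 σ` (strict; 1.2 is the common
native-contact convention — the cutoff is configurable since conventions
vary). Contact-formation probabilities are per-(coordinate bin, contact)
frequencies; per-atom values are exact averages over that atom's contacts,
so `P_N(i)·N_i = Σ_j P_N(ij)` holds bin by bin. TSE contact atoms are those
with at least one contact formed above 0.8 probability inside the
transition-state window (default φ_body ∈ [3.0°, 4.0°], around the 3.5°
barrier top). rmsf is computed per ensemble after aligning frames on a core
(LSU core by default, so SSU mobility is measured in the LSU frame; the
alignment set is configurable) — first onto the initial frame, then onto
the resulting mean structure.

## Synthetic fixtures

**Two-state structure pair.** Two helical domains of four-atom residues
(backbone B1–B2, sidechain S1–S2) face each other across an interface;
domain 2 of the "rotated" endpoint is rigidly rotated about the
inter-domain axis through its centroid, with an optional orthogonal tilt.
Residue jitter is 0.004 nm — small enough that covalent distances
(≲0.17 nm) and the nearest non-bonded distances (≳0.19 nm) stay separable
for distance-based bond inference. Atoms far from the rotation axis move
enough to break/form interface contacts (unique classes), atoms near the
axis do not (common class), so a 12° default rotation populates all three
contact classes. What this toy does *not* emulate: realistic rRNA/protein
geometry, the size-scale separation of a real ribosome, and HETATM content;
passing tests demonstrate the correctness of the bookkeeping and geometry,
not biological realism.

**Brownian landscapes.** Overdamped Euler–Maruyama dynamics (numba-compiled)
on `V(x) = B(x²−1)² + Δ·s(x)` with a logistic switch s of width 0.2, plus
optional orthogonal harmonic dimensions whose stiffness interpolates
between basin-specific values — mobility D/k_BT, noise √(2D dt), so the
stationary law is Boltzmann at the requested temperature. Optional
reflecting walls make the zero-barrier variant genuinely flat at
stationarity (used for diffusion-inference checks). A stability guard
rejects `dt·D·max|V″|/k_BT > 0.1`.

The temperature-dependence fixture deliberately uses *energy–entropy
compensation*: with purely harmonic orthogonal dimensions, the entropic
free-energy difference between basins is `(n/2) ln(k_L/k_R)` in k_BT units
— temperature-independent — so a stiffness asymmetry alone produces no
population shift with temperature. Adding a basin energy offset Δ that
cancels the entropy at the reference temperature (default test fixture:
Δ = 6 k_BT against (4/2)·ln 20 ≈ 6 k_BT) yields
`d(ΔF/k_BT)/d ln T = −ΔU/k_BT`, i.e. the wide, high-energy basin gains
stability as temperature rises — the same mechanism as an interface segment
that becomes mobile upon rotation.

## Problem sizes used by the test suite and acceptance script

- builder identities: 120-atom toy pairs (seconds);
- transition-path/MFPT checks: 6×10⁷ Euler–Maruyama steps (3×10⁶ saved
  frames, ~350 barrier crossings), a few seconds with numba;
- FEP checks: three runs of 4×10⁷ steps (reference plus ±2% direct
  simulations), roughly a minute in total;
- Euler-angle grids: 12 toy builds across rotation × tilt combinations.

These sizes were chosen so each statistic is comfortably inside its
tolerance band (e.g. ≥200 transitions where the transition-path peak is
asserted at ±0.05) while the full suite remains a coffee-break run.

## Known limitations

- The integrator is serial numpy; it is not intended for 10⁵-atom systems.
  The topology writer emits the GROMACS-dialect files for that regime.
- Diffusion inference supports a uniform D only; per-bin D profiles and 2D
  diffusion tensors are out of scope.
- The ψ_body offset C is a configuration constant; reproducing a
  literature-anchored tilt-direction zero requires the corresponding
  reference structure.
- mmCIF input, structure repair of unresolved residues, and
  sequence/structure alignment are out of scope; residue correspondences
  are consumed as a table.
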