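# Methods

## Physical model

The simulator treats every atom of a crystal snapshot as a source of a
secondary wavelet and computes each detector pixel as the coherent sum of
those wavelets.  The conventions are fixed package-wide: incident beam
along +z with |**k**| = 1/λ (cycles per Å), flat detector perpendicular to
the beam with its fast axis along lab x, crystal rotation about lab x,
momentum transfer **q** = **k** − **k**′, and s = |**q**|/2 = sinθ/λ as the
scattering-factor argument.  With these choices the wavelet phase
δ = 2π **r**·(**k**−**k**′) is in radians with no hidden 2π factors, and
the same s feeds the form-factor Gaussians and the Debye–Waller
exponential.

Assumptions and deliberate omissions:

* **Far field.**  Wavelets are plane waves; no 1/R amplitude decay, no
  solid-angle, Lorentz, polarization or air-absorption corrections.  These
  belong to instrument modeling, which is out of scope here, and leaving
  them out keeps closed-form test oracles exact.  (A relative 1/R² option
  was considered and rejected: none of the package's own statistics needs
  it, and it would break the two-engine equivalence tests.)
* **Real scattering factors.**  Anomalous dispersion (f′, f″) is omitted,
  which makes Friedel symmetry I(q) = I(−q) an exact invariant that the
  test suite checks to 1e-10.
* **B = 0 by default.**  When the input is an ensemble of snapshots, the
  ensemble itself carries the atomic motion, so per-atom B factors would
  double-count it; every atom scatters with B = 0 unless `honor_b=True`
  (intended for single static structures read from PDB).
* **Accumulation by intensity.**  Within a snapshot, amplitudes add as
  complex numbers.  Across rotation substeps and across snapshots,
  intensities add — the detector integrates exposure and never sees
  phases.  Snapshot additivity is therefore exact and is asserted
  bit-tight in the tests.
* **Occupancy** multiplies the atomic amplitude, so partially occupied
  sites in real PDB files behave conventionally.

## Scattering factors

The four-Gaussian-plus-constant parameterization
f(s) = Σ₄ aₘ exp(−bₘ s²) + c is shipped as a CSV asset for H, C, N, O, Na,
Mg, P, S, Cl, K, Ca, Fe plus the ionic entries Cl1− and Na1+.  The
normalization check f(0) ≈ Z (within 0.1 e) is enforced by tests for every
neutral entry, and f is verified to be positive and non-increasing on
s ∈ [0, 1.5 Å⁻¹].  A user table can be substituted by path.

## Geometry and the rotation series

Pixel (fast, slow) maps to **k**′ through the pixel center in lab
coordinates; elasticity | |**k**′| − 1/λ | < 1e-12 is an invariant.  An
oscillation frame of width Δφ is assembled from substeps Δ_Ω placed at
substep midpoints — midpoint placement gives unbiased angular coverage and
makes the one-substep-per-frame degenerate case exactly a single rotated
snapshot.  Frame width must be an integer multiple of Δ_Ω, and the total
range an integer multiple of the frame width; the standard protocol
(1° frames from ten 0.1° substeps, 180 frames over 180°) is pure
configuration arithmetic on this type.  The crystal orientation is a
user-supplied proper rotation applied to all snapshots before the series
begins; the package deliberately does not guess orientations from data.

## The two engines

**Direct summation.**  A_total(p) is evaluated per pixel as a
(pixels × atoms) phase product, grouped by element so each element's
s-dependent form factor is applied once, and blocked so no intermediate
exceeds a configurable memory budget (4·10⁶ phase-matrix elements by
default).  When a photograph mask is supplied, only unmasked pixels are
evaluated — masked regions are zeroed and flagged invalid in the output.

**Gridded FFT.**  Each snapshot is spread onto a real-space grid with a
narrow Gaussian kernel (per-element grids, occupancy-weighted), FFT'd
once, and evaluated at the off-grid Ewald-sphere points of every substep
by Gaussian-kernel interpolation in reciprocal space; both kernels are
deconvolved analytically.  Numerical choices: grid spacing
h ≤ min(0.75·spacing, 1/(4 q_max)) (two-fold oversampling at the band
limit), kernel half-width 5 cells in both domains, kernel widths s_x = h
and s_q = Δq chosen to balance truncation against periodic-image aliasing,
and a box 3× the crystal extent so the aliasing floor (~1e-6 relative) is
independent of grid spacing.  Pixels at resolution better than
d = 3 × spacing are masked invalid, and a coarser grid than a requested
d_min raises an error stating the implied resolution.  The per-atom-B
variant is refused by this engine (B would have to be uniform per element);
the direct engine handles it.

The engines agree to ~1e-6 relative RMS on toy crystals — far inside the
2% acceptance bound, which also covers coarse-grid settings.  A
`snapshot_average="amplitude"` option averages complex amplitudes (i.e.
densities) over snapshots before squaring instead of adding intensities;
for dynamic ensembles this suppresses the diffuse component and is
provided for comparison only, with the intensity convention as the
default in both engines.

## Image export

Quantization is round(scale·I) clamped to 16 bits with masked pixels
written as a sentinel (0 by default).  The scale scanner applies each
candidate constant in [0.1, 10] uniformly to the whole series and chooses
the largest one keeping the saturated fraction below 10⁻⁴ — a
self-contained criterion standing in for tuning against an external
integration program's log output, and reported alongside a full per-scale
table so a user can apply any other criterion.  The SMV writer emits the
conventional 512-byte brace-delimited ASCII header plus little-endian
unsigned-short data and round-trips bit-exactly through the paired reader.
Template grafting treats an existing detector file as opaque bytes plus a
data-array descriptor (offset, length, element type): only the declared
byte range changes, and a preserve-mask keeps chosen pixels (beamstop,
screen spacer) at their template values.  No attempt is made to parse the
proprietary container formats themselves.

## Bragg prediction, integration, merging

Reflections are predicted by solving the Ewald-crossing condition in
closed form for rotation about x: with **G**(ω) the rotated reciprocal
lattice vector, G_z(ω) = λ|G|²/2 reduces to ρ sin(ω+φ) = e.  Crossings
inside the series range are mapped through the scattered beam to a
detector pixel and assigned to the frame containing the crossing angle; a
crossing within a configurable tolerance (0.1° default) of a frame
boundary is flagged partial rather than split across frames.  Integration
is plain summation in a square box minus the median of a surrounding
annulus — deterministic and exactly reproducible by a brute-force oracle,
at the cost of the robustness a profile-fitting integrator would add.
Negative integrated intensities are kept so the merging statistic reflects
integration noise honestly; merge groups (keyed by the lexicographically
largest point-group orbit member, Friedel mates optional) whose intensity
sum is non-positive are dropped with a logged count.

## The rotation-substep study

The `delta_omega_rmerge_ladder` experiment reproduces, at desk scale, the
dependence of R_merge on the angular substep: a static, exactly symmetric
point-scatterer supercell is photographed with substeps equal to the frame
width, a tenth and a hundredth of it, integrated identically, and merged.
Design constraints that make the trend observable:

* the rocking-curve width ≈ (1/L_yz)/|q_yz| must lie between the finest
  and coarsest substeps — the default 2×24×24-cell block (240 Å in the
  rotating plane) with q up to ~0.74 Å⁻¹ gives widths of ~0.2–1°, bracketed
  by the 0.08° and 8° rungs;
* equivalents must be co-observed within the wedge: merging uses the
  orthorhombic sign-flip orbit (P222 + Friedel), whose in-wedge pairs have
  mirror-related Ewald crossings and hence identical converged rocking
  integrals even without a Lorentz correction;  mirror mates cross up to
  ~2·asin(λq²/2|q_yz|) apart, so the wedge spans 64°;
* the crystal is thin (2 cells) along the rotation axis, which does not
  affect rocking widths but keeps the atom count at 1152.

The experiment is deterministic; with the defaults it yields
R_merge ≈ 0.41 → 0.10 → 0.056, a strictly decreasing ladder.  Only the
trend is meaningful: the absolute values depend on this integrator and
this toy crystal and are not comparable to full-scale numbers produced by
profile-fitting pipelines on solvated 125-cell supercells.

## Ensemble metrics

Two alignment conventions: *best fit* (per-copy Kabsch superposition onto
a reference molecule — only internal deformation remains) and *lattice*
(center-of-mass-only alignment of the whole supercell — rigid-body motion
within the lattice is retained).  Lattice r.m.s.d. ≥ best-fit r.m.s.d.
frame by frame, by optimality of the superposition.  Periodic jumps are
removed before lattice metrics by applying, per molecule, the integer box
shift that minimizes the center displacement between consecutive frames,
from the first jump frame onward.  R.m.s.f. is computed about the per-copy
time mean and pooled over copies; B = (8π²/3)·r.m.s.f.² converts to the
crystallographic displacement parameter, and the same constant is verified
independently against the diffraction engine (the Bragg-attenuation
regression recovers 8π²σ² within 10% for a σ = 0.3 Å Gaussian ensemble of
256 frames).  B-factor profiles are taken per residue for Cα or as the
mean over side-chain heavy atoms, and compared by Pearson correlation.

Ordered waters in two structures are considered identical when they form a
hydrogen bond to the same protein atom in the same capacity (water as
donor or as acceptor), with the geometric criteria |D−A| < 3.5 Å and
∠(D—H⋯A) > 150°; matching is greedy one-to-one by partner overlap with
O–O distance as tie-break.  When a structure lacks explicit hydrogens, an
H is placed 1.0 Å along the donor→acceptor direction, which reduces the
angle criterion to the distance criterion for those bonds; the result
flags when this stand-in was used.  A water matching any one shared
(partner, capacity) pair counts — requiring all pairs to coincide would be
the stricter alternative reading, and is not what the definition above
says.

## Synthetic data

The fixture generators produce every input the tests need, deterministic
per seed: point-scatterer lattices (closed-form interference oracles), a
~20-atom random compact "pseudo-peptide" asymmetric unit expanded into
symmetric crystals, Gaussian-displacement ensembles (independent isotropic
per-axis displacements of std σ — exactly the harmonic model under which
B = 8π²σ² holds), and synthetic binary detector templates for grafting
tests.  What they emulate: the geometry and statistics that the engine and
metrics operate on.  What they do not emulate: real protein chemistry,
correlated (phonon-like or rotameric) motion, solvent structure, detector
noise and backgrounds.  Passing tests therefore demonstrate the
correctness of the optics, bookkeeping and statistics, not force-field
realism; conclusions about real crystals require real ensembles as input.

Charge bookkeeping for ion addition is a per-residue formal-charge table
(Arg/Lys +1, Asp/Glu −1, neutral His and protonated variants by default)
rather than a pKa prediction; the per-chain charge is thus configuration,
not chemistry, and the 3-site rigid water used for synthetic solvation
(O–H 1.0 Å, 109.47°) is geometric only.

## Problem sizes and limitations

Default experiment sizes (a 1152-atom ladder supercell over a 64° wedge,
640-atom cross-engine crystals, 256-frame ensembles) were chosen so the
full suite and the reproduction script each run in minutes on a single
core; all scale linearly (atoms × pixels × substeps) if larger studies are
wanted.  Known limitations: no mosaicity, beam divergence, spectral
dispersion, detector point-spread or background model; no profile-fitting
integrator or inter-frame scaling; space groups are handled as explicit
operator lists (arbitrary groups accepted by Hermann–Mauguin symbol or
operator strings, with P1, P222 and P4₃2₁2 shipped as data); the PDB
writer uses fixed-width records and wraps serial numbers above 99999.
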