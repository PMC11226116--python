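# Methods

## Vascular phantom

The phantom is a cube of side `cube_side` (desk default 100 µm, voxel size
500 nm) containing a random vessel tree grown by a rapidly-exploring random
tree: starting from an arterial entry point on the cube surface, each
iteration samples a uniform point in the cube, finds the nearest existing
vertex (Euclidean), and extends toward the sample by `step_length` (default
20 µm), clipping at the faces. Each edge is a pair of concentric finite
cylinders with rounded (point-to-segment distance) end caps: the lumen of
radius *r* and a wall extending a fixed `wall_thickness` = 2 µm beyond it.
The child radius tapers as `max(min_radius, r_parent − taper_rate·length)`.

Two taper conventions are supported. The literal rule — 0.5 µm of radius per
µm of added vessel — exhausts a 20 µm root in 36 µm of growth and cannot
coexist with a space-filling tree, so the default `taper_rate` is 0.04 µm/µm,
chosen so radii span root-to-minimum over a few generations; `taper_rate=0.5`
reproduces the literal reading. Similarly, a 20 µm root radius is geometrically
inconsistent with a (100 µm)³ desk cube (one root segment already exceeds the
3% volume target, so termination tolerance would be vacuous); the desk default
is `root_radius` = 6 µm, and the full 2–20 µm span belongs to millimeter-scale
cubes (`root_radius=20`).

Growth terminates once the vascular volume (lumen + wall) reaches
`target_vascular_fraction` (default 3%) of the cube. The volume is tracked by
incrementally rasterizing each new segment onto a tracking grid at the output
voxel resolution, so junction overlaps are counted once and the terminated
fraction equals the voxelized fraction by construction; the generated fraction
therefore lands in [target, target + one segment's volume]. After termination
the vertex nearest the venous exit point is connected to it by one
minimum-radius segment. Unreachable targets (packing limits, stalled growth)
raise an explicit error rather than looping.

Voxelization labels a voxel BLOOD if its center is within the inner radius of
any segment axis, WALL if within inner radius + wall thickness, else TISSUE,
with priority BLOOD > WALL > TISSUE at junctions. Voxels use 0-based indices
and half-open extents `[i·Δ, (i+1)·Δ)`. Grids beyond the in-memory budget are
produced by slab-streamed chunked rasterization.

Materials: ICRU-44 soft tissue (tissue and vessel wall) and ICRU-44 whole
blood, both 1.06 g/cm³; gold 19.3 g/cm³.

## Gold-nanoparticle loading

Internalized gold nanoparticles aggregate into clusters on the order of the
voxel size, so one cluster = one whole voxel of bulk gold. The cluster count
realizing a concentration *C* (mg Au per g of phantom, default 10) is
`N = round(C·M/m)`, with *M* the pre-placement phantom mass and
`m = 19.3 g/cm³ × (500 nm)³ = 2.4125 pg`; on the default desk phantom
N = 4394. The concentration denominator excludes the gold itself (a
second-order distinction at 1% mass). Clusters are drawn uniformly without
replacement from the eligible set — BLOOD voxels; BLOOD voxels face-adjacent
to a WALL voxel (wall-attached clusters sit on the lumen side of the
interface); or TISSUE voxels — and each relabeled voxel's original
compartment is recorded. Requests exceeding the eligible set fail loudly.

## Photon and electron physics

Interaction data are packaged plain-text tables generated once from compact
analytic models (`scripts/make_physics_tables.py`, synthetic tabulations):

* photoelectric: σ = 2 r_e λ f″ from Cromer–Liberman anomalous-scattering
  factors, which carry the full edge structure (gold K edge at 80.7249 keV
  with a tabulated jump ~4.9, L and M edges, Fe K edge);
* incoherent: Z × Klein–Nishina (free electrons; binding corrections
  neglected, a few-percent overestimate below ~30 keV);
* coherent: Thomson angular distribution with a Thomas–Fermi screened
  hydrogenic form factor;
* pair production: Born-approximation Bethe–Heitler, clamped near threshold;
* electron collision stopping power: relativistic Bethe without density
  effect (I = 75 eV tissue/blood, 790 eV gold), integrated to CSDA range.

Spot checks against widely published values: tissue µ/ρ at 100 keV 0.171
(reference ≈ 0.169), gold 5.21 (≈ 5.16) cm²/g; water-like CSDA range at
100 keV 14.5 mg/cm² (≈ 14.3). Mixtures use mass-fraction additivity with
log-log interpolation; duplicated edge knots make interpolation
right-continuous at an edge and never bridge the discontinuity.

Spectra: monoenergetic 100 keV (photoelectric-dominated regime, just above
the gold K edge); a representative heavily filtered 220 kVp tungsten-anode
spectrum (Kramers continuum through 2 mm Al + 0.3 mm Cu, W K lines, mean
~89 keV); a representative analytic 6 MV FFF histogram (mean ~1.3 MeV). The
kilovoltage/megavoltage spectra are synthetic stand-in shapes, not measured
beams; user CSVs substitute freely, and absolute enhancement figures inherit
the spectrum-shape uncertainty.

## Transport engine

Analog, history-based: a uniform parallel beam enters the padded phantom
along +z. The cube sits in a soft-tissue padding box whose default thickness
is the CSDA range of the most energetic secondary electron (electronic
equilibrium); photons are tracked analytically through the padding and by
Woodcock delta-tracking (majorant = densest material present) inside the
cube. Interactions: photoelectric (gold K events emit one 68.8 keV K x-ray
with probability 0.96×[K-shell fraction], the Auger remainder deposits
locally; photoelectron direction isotropic), Klein–Nishina incoherent
scattering with recoil-electron kinematics, Thomson-angle coherent
scattering, and pair production with positron annihilation into two 511 keV
photons. Cutoffs default to 1 keV (CSDA range ≈ 50 nm ≪ voxel, so sub-cutoff
energy deposits locally with spatial error far below the voxel size).

Electrons slow down continuously along straight lines (optional isotropic
per-step direction resampling) with steps of min(tally cell, 10% of residual
range), depositing Bethe stopping-power energy along the path. This
deliberately replaces step-by-step knock-on/elastic transport; it preserves
energy exactly and places dose within an electron range, but does not
reproduce sub-voxel track structure or Auger microdosimetry.

Dose is tallied per (tally cell, compartment label): labels keep the full
500 nm resolution while energy is accumulated in cells of `tally_downsample`
voxels per axis (desk default 4–10, i.e. 2–5 µm cells). This keeps
blood/wall/tissue/gold distinctions exact at the material interface scale
while reaching usable counting statistics at 10⁶–10⁷ histories — an analog
per-voxel tally at 500 nm would need ~10¹¹ histories. The per-voxel dose
grid expands each (cell, label) average onto its voxels. Uncertainty is the
batch-to-batch standard error (default 10 batches). Every batch closes its
energy balance (emitted = cube + padding + escaped) to better than 10⁻⁶
relative.

Two efficiency choices trade strict equilibrium for desk-scale statistics,
and both are shared identically by the reference and GNP runs so they cancel
to first order in any DER: the beam's lateral margin may be set below the
padding thickness (default profiles use ~20 µm), and 6 MV runs cap the
padding below the ~3 cm CSDA range of a 6 MeV electron. Reference and loaded
runs also share the transport seed and the Woodcock majorant, so their
random streams are identical until a history touches a gold voxel
(common-random-number pairing); this stabilizes DERs strongly.

## Dosimetry

The reference (no-GNP) grid is scaled so its minimum dose equals the
prescription (default 10 Gy, a typical hypofractionated fraction); the same
factor then scales the GNP grid. The minimum is taken over the mass-weighted
tally-cell dose — the dose matrix at the engine's statistical resolution —
because per-(cell,label) slivers containing a handful of voxels would pin a
per-voxel minimum to counting noise. At desk history counts the cell-level
minimum is itself noise-broadened, so absolute renormalized doses are upper
estimates; DERs are unaffected (the factor cancels).

Cumulative DVHs are exact sort/count curves on a shared dose axis (1024 bins
by default). D_V uses the standard convention — the largest dose received by
at least a fraction V of the structure — computed exactly from the sorted
voxel doses inside `der_report` (the curve-based accessor interpolates
linearly between bin edges). Gold voxels are excluded from all three
compartment masks by default ("dose to blood" means dose to blood material);
`include_gold_hosts=True` switches to the inclusive convention using the
recorded host labels. DER(V) is the with/without ratio at V = 25, 50, 75%,
and the average DER is their mean; the report also carries per-compartment
mean doses.

## Analytic confinement model

For fluence Φ crossing a volume V = A·L holding N particles of volume V_GNP
and diameter D, the expected interacting-photon count is modeled as
Φ·A·(N·V_GNP/V)·e^(−µD): available photons × geometric probability (the
volume ratio) × a radiological factor with µ the linear attenuation of gold.
The exponential is retained in this transmission form deliberately even
though 1−e^(−µD) is the conventional single-particle interaction
probability; the confinement ratio P₂/P₁ = L₁/L₂ is insensitive to the
choice. The model is validated against a ray-tracing oracle in the dilute
regime, where the mean in-gold chord fraction of straight photon lines
estimates the geometric term exactly in expectation.

## What the desk-scale experiments show — and what they do not

At reduced scale ((50 µm)³, ~10⁷ histories, 5 µm tally cells) the package
reproduces, deterministically per seed:

* strong kilovoltage enhancement inside the vasculature when the clusters
  are confined there (blood-compartment average DER ≈ 9 at 100 keV, ≈ 6.5 at
  220 kVp for blood-borne clusters; wall-attached clusters push the wall
  DER above the blood-borne case), with 100 keV > 220 kVp throughout;
* marginal megavoltage enhancement (6 MV FFF DERs 1.0–1.1 in every
  compartment);
* near-identical dose distributions across all three compartments when the
  clusters are uniformly extravasated.

One published finding is *not* reproduced: that the tissue-compartment
enhancement is several-fold larger with the clusters confined to the
vasculature than uniformly spread in the tissue. In this engine the ordering
is reversed (tissue DER ≈ 1.1 confined vs ≈ 1.3 uniform), and an energy-budget
argument suggests the engine's side of the disagreement: at 10 mg-Au/g and
100 keV, gold raises the phantom's interaction density by ~30%
(0.01×5.2 vs 0.99×0.17 cm²/g), and a gold photoelectric event can leave at
most ~31 keV near the site (19 keV photoelectron plus sub-K relaxation; the
68.8 keV K x-ray almost always escapes a millimeter-scale phantom), so the
whole-phantom mean enhancement is bounded near 1.6× — well short of a
several-fold tissue-wide increase. Resolving this would require the original
condensed-history runs; the corresponding acceptance test asserts the
published ordering and is expected to fail, by design rather than by
accident.

## Numerical choices and limitations

* Desk problem sizes: (100 µm)³ / 200³ voxels for generator and placement
  checks; (50 µm)³ / 100³ voxels, 10⁶–1.2×10⁷ histories, 4 batches for
  transport experiments — seconds to a minute each on one CPU.
* Tie-breaks and degenerate inputs: zero vascular target returns a rootless
  tree; zero concentration places nothing and leaves the phantom unchanged;
  empty DVH masks, non-surface entry/exit points, over-packed placements and
  zero-dose renormalization all raise typed errors.
* The photoelectron is emitted isotropically (no Sauter forward peaking);
  coherent scattering uses the Thomson angle (over-broad at high energy, but
  coherent is a small fraction of the total); bremsstrahlung, Doppler
  broadening and sub-K fluorescence are omitted; the Compton electron is
  free-electron kinematic. These mainly blur sub-micrometer hotspots and
  bias megavoltage dose by a declared small amount.
* The generator emulates vascular topology only through the stated fraction,
  radius and wall constraints — no hemodynamics, no physiological branching
  statistics, no concentration gradients — so passing tests certify the
  stated geometric properties, not anatomical realism.
* Fixture tables are pinned by checksum; regeneration is deterministic.
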