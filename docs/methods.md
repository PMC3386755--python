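# Methods

## Adsorption energetics

The free energy of the non-covalent P450–nanotube complex is decomposed as

    dG = dH_phi + dH_el − T·(dS_cf + dS_tr + dS_id)

with a hydrophobic enthalpy proportional to the buried contact area,
dH_phi = α·A_contact. The coefficient is the empirical buried-surface value
from antigen–antibody crystallography, α = −104.5 J/(mol·Å²) (equivalently
−10.45 kJ/(mol·nm²)). Sources sometimes quote this constant with a nm²
unit attached to the per-Å² magnitude; the worked values (272 Å² → −28
kJ/mol) fix the per-Å² reading, which is what the package uses. Only the
hydrophobic term is quantified by default; the Van der Waals and entropic
terms are configurable fields of `EnergyTerms` (default 0) so the full
decomposition is representable. At 690 Å², the largest typical
antigen–antibody contact, the model gives −72.1 kJ/mol.

Orientation sampling follows the adsorption rule that attachment probability
is directly proportional to contact area (`weighting="area"`, the default).
A Boltzmann alternative, p ∝ exp(−dG/RT) on the hydrophobic free energy, is
exposed (`weighting="boltzmann"`) but not used by default: with |dG| ≈ 30
kJ/mol ≫ RT it collapses onto the single largest face and suppresses the
orientational diversity the monolayer model is meant to capture.

## Geometry and the contact-strip construction

The protein is a triangular prism: base edge 4.5–5 nm (`edge_a`), long edge
5–6.5 nm (`edge_b`), thickness 3.5–4.5 nm. The tube is a cylinder of
diameter 10 nm unrolled into a flat rectangle of width π·d with a periodic
arc coordinate; at a footprint-to-circumference ratio of ≈5/31.4 the
unrolling distortion is small. Footprints are axis-aligned rectangles;
overlap testing folds the arc separation modulo the period.

A flat face tangent to the cylinder touches it over a strip: the gap at
transverse offset x is g(x) = r − √(r² − x²) ≈ x²/2r, so points with
g ≤ c form a strip of width w = 2·√(2rc) and the contact area is w times
the contacting face length. The gap cutoff c is the one calibrated constant
of the geometry: c = 0.008 nm puts the lateral-face contact area of the
midpoint prism (4.75 × 5.75 × 4.0 nm) at 325 Å², inside the 272–378 Å²
range estimated for the P450–CNT complex. (How that printed range follows
from the prism dimensions is not documented anywhere; the strip construction
is this package's reconstruction, calibrated rather than derived.)

Five attachment modes are parameterised (contacting length along the tube
axis → radial protrusion): lateral largest face (edge_b → thickness),
triangular end face (edge_a → edge_b), long edge (½·edge_b → edge_a), short
edge (½·edge_a → edge_b), corner (¼·thickness → edge_b). The ½ and ¼
factors encode that a wedge or vertex buries far less surface than a flat
face; they keep the lateral mode dominant (probability ≈ 0.34 at midpoint
dimensions) while letting upright modes contribute the thickness spread seen
in coated-tube images.

## Random sequential adsorption

Monolayer self-assembly is modelled as RSA: candidates arrive at uniform
(z, s) positions, draw an orientation in proportion to contact area, are
accepted iff their footprint overlaps no adsorbed molecule, and never move
or desorb. Jamming is operationalised as 10,000 consecutive rejections
(RSA has no natural termination; this stopping rule makes the residual
acceptance probability < 10⁻⁴ per trial). Candidates are processed in
batches of 256 with vectorised overlap checks; batching only discards
unexamined proposals after an acceptance, so the accepted sequence is a
faithful RSA draw and identical seeds give identical states.

In ensemble runs every arriving molecule samples its prism dimensions
uniformly within the crystallographic ranges. This per-molecule jitter is
what produces the ±1.6 nm spread of projected diameters; a single fixed
prism would give a nearly deterministic coated diameter. Tube i of an
ensemble uses generator seed `seed + i`.

Defaults: tube diameter 10 nm; ensemble tube length 300 nm with 100 axial
sample positions per tube and 50 tubes. Tube length is an intensive choice —
per-length statistics are unchanged apart from axial edge effects of order
footprint/length ≈ 2% — made so a 50-tube ensemble completes in ~30 s.
Axial boundaries are hard (molecules must fit entirely on the tube); the
arc coordinate wraps.

SEM emulation: a projected image shows the tube silhouette, so the measured
diameter at axial position z is the bare diameter plus, for each of the two
arc halves, the largest radial extent among molecules covering z there (zero
if bare). With jamming coverage ≈ 0.58 and mean radial extent ≈ 5 nm this
yields a mean coated diameter of ≈ 20.8 nm, i.e. a ≈ 10.8 nm increase over
the bare tube, and a mean layer thickness of ≈ 5.2 nm — one protein layer
per side.

## Synthetic voltammograms

The generator emulates the measurement protocol, not the electrochemistry:
a triangular potential sweep −600 → +300 → −600 mV at 20 mV/s, sampled
every 1 mV (the instrument's true sampling density is not documented).
The current is the sum of

* a capacitive background ±C·ν (C = 10 nA/(mV/s) by default, sign by
  branch), giving the hysteresis envelope;
* a resistive baseline 0.1 nA/mV;
* Gaussian faradaic peaks (σ = 15 mV by default). Gaussian shape keeps the
  amplitude analytically known for round-trip tests; no claim is made about
  true voltammetric peak shapes. CYP electrodes carry the monitored −330 mV
  reduction, a companion −450 mV reduction at 0.8× the monitored amplitude,
  and the constant −200 mV oxygen-moiety peak of the nanotubes; the bare-CNT
  etoposide electrode carries the monitored +220 mV oxidation, a +150 mV
  reduction at 0.4×, and the oxygen peak. (The +450/+350 mV pair reported
  for etoposide lies outside the sweep window and is omitted.)
* i.i.d. Gaussian sample noise, default σ = 5 nA — the simplest model
  consistent with a 3σ detection-limit definition. The absolute capacitive
  and noise magnitudes of the real electrodes are only shown graphically,
  so these are free parameters.

The monitored peak amplitude is `sign·(S·area·conc + blank)` with S the
per-area sensitivity preset of the drug/isoform pair (PBS or serum column)
and area = 12.56 mm². Serum is emulated solely as the preset's reduced
sensitivity; plasma-protein binding kinetics are not modelled.
Hetero-activation by a co-present drug multiplies the sensitivity by
(1 + γ·[modulator]): γ = 0 reproduces non-interacting (overlapping)
calibration curves, γ > 0 the monotone sensitivity increase seen when
etoposide activates CYP-mediated turnover of a second substrate. The linear
form is the minimal monotone model; no functional form is documented for
the real effect.

## Calibration analysis

Peak currents are read after subtracting a straight baseline least-squares
fitted through the two 25 mV flanking margins of a ±50 mV window around the
monitored potential; the peak current is the extremal signed deviation
inside the window. (The original peak-determination procedure is in an
inaccessible reference; this is a documented default, not a
reconstruction.) The window stays clear of the companion peak 120 mV away.
Blank (zero-concentration) signals are read at the monitored potential
itself rather than at the argmax: the extremum of pure noise is a biased
max-statistic whose spread misrepresents the per-sample noise, while the
fixed-potential reading has sd ≈ the noise sd, which is what the 3σ LOD
formula assumes.

Sensitivity is the OLS slope of |peak current| vs concentration (absolute
value so cathodic and anodic series share one convention), fitted over the
preset's pharmacological range, which stands in for the undocumented
"linear range". LOD = 3·sd(blanks)/slope with sd computed with one degree
of freedom removed. The drug-pair analysis fits one sensitivity per
modulator level, regresses sensitivity on modulator concentration, flags
`monotone_increase` when successive sensitivities strictly increase, and
flags `overlap` when the two-sided t-test of the activation slope against
zero is non-significant at 0.05 (undefined with fewer than three levels).
At the 0.05 level the overlap flag is correct for ~95% of non-interacting
families by construction.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analysis assumes —
linear response, Gaussian noise, stated peak potentials, preset
sensitivities — so passing tests demonstrate that the pipeline recovers
known generator parameters (slopes within 5% at 1% noise, LOD scaling
linear in noise sd, interaction flags calibrated). They do not validate the
presets against real electrodes: no raw voltammograms are publicly
deposited, so experimental sensitivities/LODs and multilayer deposition
currents are inputs (presets), not outputs. Likewise the RSA model adopts
one consistent reading of an under-specified Monte Carlo procedure (sample
sizes, stopping rule and orientation weighting were never documented); its
agreement with the coated-diameter statistics supports plausibility, not
uniqueness. Per-face hydrophobicity percentages are not numerically
available and are not modelled.

## Numerical notes

* Overlap tests use strict inequalities: touching footprints are legal.
* `contact_strip_area`'s small-gap approximation is within 0.1% of grid
  integration of the exact gap for cutoffs ≤ 0.02 nm.
* Degenerate inputs raise typed errors (`InvalidParameterError`,
  `InsufficientDataError`, `EmptyStateError`, `FormatError`,
  `ValidationError`) rather than returning sentinels.
* JSON/CSV writers emit 6-significant-digit floats with sorted keys, so
  fixed seeds give byte-identical artifacts.
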