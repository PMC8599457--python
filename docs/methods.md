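# Methods

`fiberindent` estimates the elastic constants of pulp fiber walls from
nanoindentation performed on fibers embedded in paper sheets.  This note
records the models, the conventions they hinge on, the synthetic-data design,
and the known limitations.

## Material model

The fiber wall (dominated by the S2 layer) is treated as transversely
isotropic with the symmetry axis 3 along the fiber's longitudinal direction,
i.e. the microfibril angle is taken as zero.  Five engineering constants
describe it: E_L, E_T, ν_LT, ν_TT, G_LT.  Voigt notation uses engineering
shear strains, so the compliance matrix is

    S11 = S22 = 1/E_T        S33 = 1/E_L
    S12 = −ν_TT/E_T          S13 = S23 = −ν_LT/E_L
    S44 = S55 = 1/G_LT       S66 = 2(1+ν_TT)/E_T

with ν_TL derived from the symmetry relation ν_TL/E_T = ν_LT/E_L.  The single
assumed Poisson value 0.25 is interpreted as the **axial** ratio ν_LT entering
S13; this is the only reading under which the identification's parameter list
is self-consistent, and the only one that reproduces the identified moduli of
kraft pulp (the alternative reading reproduces none of them).  Admissibility
(positive definiteness of S) is enforced on construction, and a
`rotate_stiffness` utility (Bond transformation about an in-plane axis) is
provided for microfibril-angle sensitivity studies; no indentation model for
tilted symmetry axes is included.

## Forward indentation model

For a frictionless rigid indenter on a transversely isotropic half-space,
closed-form conical-indenter approximations give the two axis-aligned
indentation moduli in terms of the Voigt stiffness components C11 = C1111,
C12 = C1122, C13 = C1133, C33 = C3333, C44 = C2323:

Longitudinal (indentation along the fiber axis):

    M_L = 2 √[ (C11·C33 − C13²)/C11 · ( 1/C44 + 2/(√(C11·C33)+C13) )⁻¹ ]

Transverse (indentation perpendicular to the axis): the contact is elliptical.
Two principal surface compliance amplitudes govern it,

    h_ax = (1/2π) √[ C33/(C33·C11 − C13²) · (1/C44 + 2/(√(C33·C11)+C13)) ]
    h_ip = (1/π) · C11/(C11² − C12²)

(h_ax for the stiff in-surface direction along the fiber axis, h_ip for the
compliant in-plane transverse direction; both reduce to 1/(πM) in the
isotropic limit).  With ellipticity e = √(1 − min(h)/max(h)) and E(e) the
complete elliptic integral of the second kind of modulus e (numerically:
`scipy.special.ellipe(m)` with parameter m = e²),

    M_T = 1 / ( 2 E(e) · h_ax^{1/4} · h_ip^{3/4} ).

**Convention note.**  Published statements of the transverse formula differ
in which amplitude carries the dominant 3/4 exponent.  We place it on the
in-plane (compliant) amplitude.  Three independent checks support this
choice: (i) the isotropic limit is exact either way, so it cannot
discriminate, but (ii) a zeroth-order surface-Green's-function estimate —
M ≈ 1/(π·h̄) with h̄ the angular average of the amplitude — lands within a few
percent of this weighting and ~40% away from the alternative, and (iii) only
this weighting is consistent with the transverse moduli identified for pulp
fiber walls (E_T ≈ 1.1 GPa for measured M_T ≈ 1.57 GPa with the Table of
fixed parameters below).

Both moduli equal E/(1−ν²) in the isotropic limit to 1e−9·E (property-tested),
M_L is strictly increasing in E_L and M_T in E_T over the admissible range,
and the indenter's own compliance is neglected (diamond on a ~GPa solid).

## Curve processing

One indent record (time s, force µN, depth nm) acquired under the trapezoidal
schedule — 1 s ramp to peak (20 µN hemisphere, 10 µN pyramid, 100 µN cube
corner), 10 s hold, force-controlled unload to 5% of peak, 30 s drift
window — is processed as:

1. **Segmentation** from the known schedule, with the ramp onset detected as
   the first force rise above 2% of peak.
2. **Drift correction**: a linear depth rate fitted on the drift window is
   subtracted from the whole record.  The drift window sits at near-zero load
   after the unload, where creep has essentially stopped.
3. **Machine-compliance compensation** z → z − C_m·F (signed, hence
   invertible).
4. **Depth baseline**: the mean approach-segment depth is subtracted, so the
   contact depth never sees absolute-offset artifacts.
5. **Hold creep fit** z(t) = D5 + D6·t^D7 (t from hold onset), bounded
   D7 ∈ (0.01, 0.99), initialized at D7 = 0.3.  The creep rate at the
   hold-to-unload transition is ż(τ_u) = D6·D7·τ_u^(D7−1).  z_max is taken
   from this fit at τ_u, which is robust to sample noise and boundary
   rounding.
6. **Unloading fit** z(F) = D1 + D2√F + D3·F^D4 on the 75% of the unload
   adjacent to peak force (samples with F ≥ 0.25·F_max; the window fraction
   is configurable and anchored at the peak, where fit quality matters for
   the stiffness).  The model is separable, so a variable-projection sweep
   over D4 (linear least squares per candidate exponent) provides the start
   for the bounded nonlinear polish; this is what keeps the fit stable when
   the √F and F^D4 terms become collinear near D4 = 1/2 (sharp tips).
7. **Observed stiffness** S_u = (dz/dF at F_max)⁻¹.
8. **Creep correction** 1/S = 1/S_u − ż(τ_u)/Ḟ with the signed unload rate
   Ḟ < 0, so forward creep yields S < S_u.  If 1/S ≤ 0 the indent is flagged
   unreliable (the regime where apparent unloading slopes can even turn
   negative) and excluded from summaries, with the exclusion counted.
9. **Contact depth** z_c = z_max − ε·F_max/S with ε = 0.75 for all tips
   (configurable).
10. **Contact area** from ideal tip geometry: a spherical cap for the
    hemisphere (R = 300 nm), and for the sharp tips a spherical cap joined
    C¹-continuously to the tangent equivalent cone reproducing the ideal
    far-field area law (pyramid: A → 4z², cap R = 100 nm; cube corner:
    A → 2.598z², default cap R = 40 nm, a typical nominal value — the
    instrument's actual radius was not published).  A calibrated polynomial
    area function can override the ideal geometry per tip.
11. **Indentation modulus** M = √π·S/(2β√A), with β = 1.0 (hemisphere) and
    1.05 (pyramid, cube corner).

## Inverse identification

With ν_LT = ν_TT = 0.25, G_LT = 2.51 GPa and θ = 0 held fixed (assumed /
literature values for the same pulp type), (E_L, E_T) minimize

    g(E_L, E_T) = (1/n) √[ Σ_r (M_r^model − M_r^exp)² / M_r^exp ],   n = 2.

The search runs in log-parameters (positivity plus scale balance between E_L
and E_T) with BFGS from 5 log-spaced starts across E_L ∈ [0.5, 100],
E_T ∈ [0.05, 20] GPa, followed by a Gauss–Newton polish on the residual
vector — the square root makes g non-smooth at a zero-residual optimum, where
quasi-Newton progress stalls near 1e−9.  Inadmissible trial constants return
a finite penalty (1e6) so line searches can retreat.  Diagnostics include the
multistart dispersion and an at-bound flag.  A grid scan
(`uniqueness_grid`, default 200×200 log-spaced over E_L ∈ [1, 40],
E_T ∈ [0.1, 5] GPa) counts strict 8-neighbor local minima; all measured
configurations show exactly one, so the identified pair is unique in the
realistic range.

Identification is ill-conditioned at high anisotropy: M_L saturates in E_L
once the response is limited by the transverse and shear compliances, so
beyond E_L/E_T ≈ 10 small changes in the measured M_L move E_L a lot while
E_T stays pinned by M_T.  This is why mean-based longitudinal summaries
(pulled up by the right-skewed scatter) yield much larger E_L than
median-based ones, and why E_T is stable (~1.1 GPa) throughout.

Two baselines: Cox shear-lag inversion E_L = 3·E_sheet·ρ_fiber/ρ_sheet for an
in-plane isotropic sheet of long pin-jointed fibers, and the elastic-truss
tensile estimate E_L = F·L/(δ·A).  Mean and median summaries are both carried
(mean paired with mean, median with median), since the per-indent scatter is
right-skewed.

## Synthetic data

The generator emulates the acquisition so the chain is testable without
instrument data.  Design choices:

- **Elastic contact law.**  Rather than a fixed textbook law, the loading
  curve is the one exactly consistent with the processing conventions:
  incremental stiffness S(z_c) = 2βM√(A(z_c)/π) with the same ideal area
  functions the analysis uses, and z = z_c + ε·F/S.  This yields the ODE
  dF/dz_c = (S − εF·S′/S)/(1 − ε), integrated from the apex.  For a parabolic
  area it reduces in closed form to Hertz, F = (4/3)βM√R·z^{3/2} (so Hertz
  oracles remain valid at shallow depth); for capped tips it removes the
  cap-versus-paraboloid bias, making noise-free recovery of M exact to fit
  precision (observed ≤ 0.03% for all three tips).  Recovery tests therefore
  isolate pipeline defects instead of generator/analyzer mismatch.
- **Creep** is injected additively on depth during the hold as D6·t^D7 —
  exactly the series spring-dashpot structure the correction assumes — and
  continues through the unload with a continuous rate; it is frozen during
  the near-zero-load drift window.  Defaults D6 = 0.5 nm, D7 = 0.3 give
  ~1 nm of hold creep at 15–30 nm depths, a few percent of the penetration,
  consistent with the visible-but-small hold creep of wet-stiff cellulose
  walls at 45% RH.
- **Drift** is linear in time; **noise** is independent Gaussian per sample
  on force and depth (defaults 0 in the config; tests typically use
  0.2–0.3 nm depth, 0.02–0.05 µN force).  The instruments' true noise levels
  are not published; these are nominal scales, fully config-exposed.
- **Populations**: per-fiber (E_L, E_T) are lognormal (default medians
  8.0/1.1 GPa, log-dispersions 0.45/0.15) with lognormal per-indent
  multiplicative scatter (σ_log = 0.25), 5 fibers, 10 longitudinal and 30
  transverse indents per fiber — mirroring the sampling plan and the
  right-skew of measured longitudinal moduli (mean > median).  Inadmissible
  draws are rejected, redrawn and counted.

What the generator does **not** emulate: surface roughness and imperfect
contact geometry, adhesion, multi-phase wall structure (cellulose versus
lignin/hemicellulose domains — the leading candidate for the real scatter at
small indent sizes), stochastic drift, or humidity dynamics.  Passing
recovery tests therefore demonstrate the correctness of the analysis chain,
not the absence of these physical confounders in real data.

## What creep correction can and cannot fix

The rate correction removes the creep contamination of the unloading slope
and demonstrably recovers the true elastic contact stiffness (on every
creeping synthetic curve, |S_corrected − S_true| < |S_u − S_true|).  It does
not address the *accumulated* hold creep Δ = D6·τ_u^D7, which deepens z_max
and inflates the contact area, biasing M low by ≈ Δ/(2·z_c) in both
corrected and uncorrected modes.  With a 10 s hold, the rate term
ż(τ_u)/|Ḟ| is of order 0.1–1% while the area term is of order 3%; the two
effects partially cancel in the uncorrected mode, so on additive-creep
synthetics the corrected modulus is *not* systematically closer to M_true
than the uncorrected one — the ratio of correction to shared bias is
~2·(unload duration)·D7/(hold duration), below 1 for any physical parameters
under this schedule.  The long hold is itself the mitigation: it shrinks the
rate term precisely so that the unloading analysis is valid.  The modulus
bias from contact deepening is bounded by keeping hold creep small relative
to depth; it is reported per indent (creep fit and rate) so outliers can be
screened.

## Defaults and tolerances

| parameter | default | meaning |
|---|---|---|
| ν_LT, ν_TT | 0.25, 0.25 | assumed / literature Poisson ratios |
| G_LT | 2.51 GPa | literature shear modulus, same pulp type |
| θ | 0° | microfibril angle assumed small |
| ε | 0.75 | contact-depth factor, all tips |
| β | 1.0 / 1.05 | BASh factor, hemisphere / sharp tips |
| unload fit window | 75% | fraction of unload adjacent to peak |
| D4 bounds / init | (0.05, 1] / 2/3 | unloading exponent |
| D7 bounds / init | (0.01, 0.99) / 0.3 | creep exponent |
| E_L, E_T search bounds | [0.5, 100], [0.05, 20] GPa | identification range |
| multistart | 5 log-spaced | uniqueness insurance |
| inadmissible penalty | 1e6 | finite, so line searches retreat |

Numerical tolerances: compliance↔stiffness round trips hold to <1e−10;
forward→inverse round trips recover constants to <1e−5 relative with final
cost at machine precision; the contact-law ODE is integrated at rtol 1e−10.
Degenerate inputs (non-positive corrected stiffness, negative contact depth)
raise or clip with warnings and are excluded from summaries with counts.

Problem sizes used in the shipped tests and examples: single curves at
200 Hz (≈8500 samples), recovery sweeps of 2–5 constant pairs with 1–5
curves per direction, populations of 5 fibers × (10 L + 30 T) indents, and
uniqueness grids of 200×200.  These are the sizes at which every reported
behavior is already fully resolved.

## Known limitations

- The transverse model is a conical-indenter approximation evaluated for
  sphere and pyramid contacts; comparisons in the literature suggest only
  marginal differences for spheres, but no general-anisotropy surface-Green's
  function model is included to quantify this here.
- Fixed ν and G values are literature/assumed inputs; errors in them
  propagate unquantified into (E_L, E_T).  Only multistart dispersion is
  reported, not parameter uncertainty.
- The microfibril angle is taken as zero; for MFA ≳ 20° the axis-aligned
  formulas are no longer adequate and the provided tensor rotation is only a
  sensitivity aid.
- Hardness, plasticity, pile-up/sink-in beyond ε, adhesion and humidity
  dependence are out of scope.
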