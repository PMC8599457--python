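"""Two classical baselines for the longitudinal fiber modulus.

The Cox shear-lag network model relates the tensile modulus of an in-plane
isotropic handsheet to the modulus of its fibers through the density ratio;
inverting it gives a network-level estimate of E_L.  Single-fiber tensile
testing gives a direct per-fiber estimate E_L = F L / (delta A).  Both are
independent of the indentation route and bracket the same property.
"""

from fiberindent import (
    FiberTensileRecord,
    SheetProperties,
    cox_invert,
    tensile_modulus,
)

# handsheet measurements: modulus 1.55 GPa, density 459 kg/m3; fiber wall
# density assumed 1500 kg/m3 (void-free cellulose wall)
sheet = SheetProperties(E_sheet_GPa=1.55, rho_sheet_kg_m3=459.0,
                        rho_fiber_kg_m3=1500.0)
E_cox = cox_invert(sheet)
print(f"Cox network inversion: E_L(fiber) = {E_cox:.1f} GPa")
print("  (an upper-range estimate: the model assumes long, straight,")
print("   pin-jointed fibers and a void-free wall density)")

# a representative single-fiber tensile record: 36.5 mN at 15 um displacement
# over a 0.85 mm span, average wall cross-section 249 um^2
record = FiberTensileRecord(F_N=36.5e-3, L_m=0.85e-3, delta_m=15e-6,
                            A_m2=249e-12)
E_tens = tensile_modulus(record)
print(f"single-fiber tensile:  E_L = {E_tens:.1f} GPa")
print("  (elastic-truss estimate; per-fiber values scatter widely because")
print("   wall area and fibril angle vary fiber to fiber)")
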