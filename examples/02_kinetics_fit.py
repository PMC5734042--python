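"""Fit Michaelis-Menten parameters to a simulated initial-rate assay.

Simulates a noisy saturation-kinetics dataset at the constants measured
for the resurrected ORF-fusion enzyme on phenylacetaldehyde (Km 296 uM,
Vmax 0.49 umol/min/mg), fits v = Vmax*S/(Km+S) by nonlinear least squares,
and prints the estimates with their asymptotic standard errors.
"""

from aadscan.kinetics import fit_mm, kcat_from_vmax
from aadscan.synthetic_data import MMDesign, generate_mm_dataset

design = MMDesign(km=296.0, vmax=0.49, cv=0.05, replicates=3, seed=11,
                  substrate="phenylacetaldehyde")
data = generate_mm_dataset(design)
fit = fit_mm(data)

print(f"substrate: {data.substrate}")
print(f"design:    8 concentrations from {design.concentrations_uM[0]:.1f} to "
      f"{design.concentrations_uM[-1]:.0f} uM, triplicate, 5% noise")
print(f"truth:     Vmax {design.vmax}  Km {design.km}")
print(f"fit:       Vmax {fit.vmax:.3f} +- {fit.vmax_se:.3f} umol/min/mg, "
      f"Km {fit.km:.1f} +- {fit.km_se:.1f} uM "
      f"(converged={fit.converged}, n={fit.n_points})")
print(f"kcat at a 34-kDa monomer: {kcat_from_vmax(fit.vmax, 34000):.1f} min^-1")
print("\nThe fitted curve passes Vmax/2 at S = Km; the standard errors come"
      "\nfrom the curvature of the least-squares surface at the optimum.")
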