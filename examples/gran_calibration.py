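"""Gran endpoint and electrode calibration from a strong-acid titration.

Simulates the daily calibration titration (3 mL of 4 mM strong acid with
0.1 M NaOH, electrode E0 = 400 mV, slope = 59.16 mV/decade, 0.1 mV noise),
then recovers the equivalence volume by the Gran linearization and the
electrode parameters by regression of emf on log10[H+].
"""

import numpy as np

from equispec import (
    ElectrodeParams,
    TitrationDataset,
    TitrationProtocol,
    calibrate_electrode,
    gran_endpoint,
    simulate_titration,
    strong_acid_model,
)

electrode = ElectrodeParams(E0_mV=400.0, slope_mV=59.16)
protocol = TitrationProtocol(
    initial_volume_mL=3.0,
    initial_totals={"H": 4e-3},
    titrant_concentration_M=0.1,
    volume_points_mL=np.linspace(0.0, 0.2, 101)[1:],
)
clean = simulate_titration(strong_acid_model(), protocol, electrode)
rng = np.random.default_rng(1)
noisy = TitrationDataset(
    clean.volumes_mL, clean.values + rng.normal(0.0, 0.1, len(clean)), "emf_mV"
)

gran = gran_endpoint(noisy, 3.0, electrode=electrode, branch="acid")
cal = calibrate_electrode(noisy, protocol)

print(f"analytic equivalence volume: 0.1200 mL (3 mL x 4 mM / 0.1 M)")
print(
    f"Gran endpoint: {gran.equivalence_volume_mL:.4f} +/- {gran.stderr_mL:.4f} mL "
    f"({gran.n_points} points in the linear window)"
)
print(
    f"calibrated electrode: E0 = {cal.E0_mV:.2f} +/- {cal.sigma_E0:.2f} mV, "
    f"slope = {cal.slope_mV:.2f} +/- {cal.sigma_slope:.2f} mV/decade"
)
print(
    "\nBoth generating parameters are recovered within their standard errors;"
    "\nthe Gran volume fixes the acid (and hence ligand) standardization."
)
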