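"""Passive membrane properties from the hyperpolarising step family.

Simulates the -25/-50/-75/-100 pA 1-s steps, then recovers input
resistance (OLS slope of steady-state deflection vs current), the
membrane time constant (exponential fit to the charging phase) and
capacitance (tau / R_in).
"""

import numpy as np

from strokephys import (
    PassiveModel,
    StepDescriptor,
    input_resistance,
    membrane_capacitance,
    membrane_time_constant,
    resting_membrane_potential,
    simulate_passive,
)

truth = PassiveModel(E_L=-70.0, R_in=150.0, tau_m=20.0, noise_sd=0.2)
family = [StepDescriptor(0.0, a, 0.1, 1.0) for a in (-25.0, -50.0, -75.0, -100.0)]
sweeps = simulate_passive(truth, family, seed=0)

rmp = np.mean([resting_membrane_potential(s) for s in sweeps])
r_in, diag = input_resistance(sweeps)
fits = [membrane_time_constant(s) for s in sweeps]
tau = np.mean([f.tau for f in fits if f.converged])
cap = membrane_capacitance(tau, r_in)

print(f"RMP              = {rmp:8.2f} mV    (truth -70.00)")
print(f"input resistance = {r_in:8.2f} MOhm  (truth 150.00)")
print(f"time constant    = {tau:8.2f} ms    (truth  20.00)")
print(f"capacitance      = {cap:8.1f} pF    (truth {1000*20/150:.1f})")
print("Capacitance is tau/R_in; with 0.2 mV of recording noise all four")
print("properties come back within a few percent of the truth (and exactly,")
print("to three significant figures, when the noise is switched off).")
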