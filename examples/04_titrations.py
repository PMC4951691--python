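"""Titration analytics: quenching linearity and unfolding cooperativity.

Simulates an acrylamide quenching series, a cooperative two-state urea
unfolding, and a non-cooperative linear one, and fits each.
"""

import numpy as np

import foldstate as fs
from foldstate.synthetic import (NoiseModel, SimulationSpec,
                                 make_quenching_series, make_spectral_series,
                                 make_unfolding_series)

noisy = SimulationSpec(seed=3, noise=NoiseModel("gaussian_relative", 0.02))

quench = make_quenching_series(5.0, np.linspace(0.0, 0.5, 10), noisy)
sv = fs.stern_volmer_fit(quench)
print(f"Stern-Volmer: KSV = {sv.ksv:.2f} M^-1, linear = {sv.linear}")

urea = np.linspace(0.05, 5.0, 20)
coop = fs.fit_unfolding(make_unfolding_series("two_state", urea, noisy,
                                              dg0=5.0, m=2.0))
print(f"two-state data : verdict = {coop.verdict}, "
      f"m = {coop.parameters['m_kcal_mol_M']:.2f} kcal/mol/M, "
      f"Cm = {coop.parameters['Cm_M']:.2f} M")

lin = fs.fit_unfolding(make_unfolding_series("linear", urea, noisy))
print(f"linear data    : verdict = {lin.verdict}")

shift = fs.lambda_max_series(
    make_spectral_series(np.linspace(0, 8, 12), np.linspace(344, 352, 12)))
print(f"lambda-max shifts {shift.y[0]:.0f} -> {shift.y[-1]:.0f} nm across urea")
print()
print("A linear Stern-Volmer plot means one uniformly accessible fluorophore")
print("population; a sigmoidal unfolding curve (two-state wins by AICc) marks")
print("cooperative unfolding, while a plain linear loss of signal is the")
print("low-cooperativity pattern typical of molten globules.")
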