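"""Memantine dose-response: NMDAR-level attenuation of the P212L phenotype.

Memantine is modeled as a dose-dependent reduction of the per-pulse
Ca2+ increment upstream of the kinase.  The example measures kinase and
Ca2+-indicator responses at 0/1/10/100 uM, runs Dunnett contrasts
against vehicle, and reports the descriptive Hill inhibition fit.
"""

import pandas as pd

from camfret.kinetics import analyze_recording
from camfret.protocol import StimulusProtocol
from camfret.simulate import get_preset, memantine_ca_factor, simulate_cohort
from camfret.tuning import dose_group_compare, fit_dose_inhibition

protocol = StimulusProtocol(n_pulses=30, frequency=20.0, onset_time=5.0)
params = get_preset("P212L")
rows = []
for di, dose in enumerate((0.0, 1.0, 10.0, 100.0)):
    factor = memantine_ca_factor(dose)
    for rec in simulate_cohort(params, protocol, 8, base_seed=30 + di, ca_scale=factor):
        res = analyze_recording(rec)
        rows.append({"dose_um": dose, "response": res.peak_dRR0, "ca": res.peak_dFF0})

df = pd.DataFrame(rows)
means = df.groupby("dose_um")[["response", "ca"]].mean()
print(means.rename(columns={"response": "hK2a peak dR/R0", "ca": "Ca2+ peak dF/F0"}))
stats = dose_group_compare(df[["dose_um", "response"]])
print(stats["contrasts"].to_string(index=False))
fit = fit_dose_inhibition(df[["dose_um", "response"]])
print(f"descriptive Hill fit: IC50 = {fit.ic50:.1f} uM, slope = {fit.hill_slope:.2f}")
# Both the Ca2+ and kinase responses fall with dose; 10 uM roughly
# halves the Ca2+ response and the kinase response collapses by 100 uM.
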