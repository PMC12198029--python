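"""Simulate PGT spots at four cavity thicknesses and show the range signal.

A thicker air cavity shortens the proton track, so prompt gammas are
emitted earlier on average and the detector subtends a slightly larger
solid angle: the time-projection mean falls and the detected counts rise
with the range shift ΔR.
"""

import numpy as np

from pgtrange import BinningSpec, SimConfig, SpotMeta, bin_events, project_time, simulate_spot
from pgtrange.simulate import solid_angle_factor

config = SimConfig(events_per_1e9_protons=5e4)
binning = BinningSpec()
centres = (np.arange(binning.n_time_bins) + 0.5) * binning.time_bin_width_ns

print(f"{'dR/mm':>6} {'events':>8} {'mean t/ns':>10} {'solid angle':>12}")
for cavity in (0.0, 5.0, 10.0, 20.0):
    meta = SpotMeta(
        spot_id=f"demo_{cavity:g}", beam_energy=162.0, mode="static",
        cavity_mm=cavity, seed=42,
    )
    events = simulate_spot(config, meta)
    spectrum, _ = bin_events(events, binning)
    mean_t = np.average(centres, weights=project_time(spectrum))
    omega = solid_angle_factor(config, 162.0, cavity)
    print(f"{cavity:6.0f} {len(events):8d} {mean_t:10.4f} {omega:12.4f}")

print()
print("The mean detection time drops by tens of ps per 5 mm of range shift —")
print("that is the signal the downstream models exploit.")
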