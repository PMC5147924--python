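#!/usr/bin/env python
"""Raw wrist-signal processing on synthetic 60 Hz bouts.

Demonstrates the raw-signal path on short bouts with known ground truth:

* auto-calibration recovers an injected per-axis offset/gain distortion
  from stationary periods;
* ENMO and HPFVM epoch means of a sinusoidal movement bout match their
  closed-form values (a/pi and 2a/pi for amplitude a, both in the filter
  passband).

Writes results/signal_demo.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from wristpaee.signals import (autocalibrate, apply_calibration,
                               process_raw_signal, vector_magnitude)
from wristpaee.synthetic import generate_raw_bout

out = Path(__file__).resolve().parent.parent / "results"
out.mkdir(exist_ok=True)
rows = []

# --- auto-calibration ----------------------------------------------------
offset, gain = (0.05, -0.03, 0.02), (1.03, 0.98, 1.01)
bout = generate_raw_bout("mixed", duration=900, sample_rate=60,
                         noise_sd=0.002, offset=offset, gain=gain, seed=1)
params = autocalibrate(bout)
vm_after = vector_magnitude(apply_calibration(bout, params).data)
for axis, o_true, o_est, g_true, g_est in zip(
        "xyz", offset, params.offset, gain, params.gain):
    rows.append({"quantity": f"offset_{axis}_g", "truth": o_true,
                 "estimate": o_est})
    rows.append({"quantity": f"gain_{axis}", "truth": g_true, "estimate": g_est})
rows.append({"quantity": "stationary_vm_after_calibration_g", "truth": 1.0,
             "estimate": float(np.median(vm_after))})

# --- metric derivation ---------------------------------------------------
amp = 0.1
move = generate_raw_bout("sinusoidal", duration=600, sample_rate=60,
                         amplitude=amp, frequency=1.0, noise_sd=0.0, seed=2)
epochs = process_raw_signal(move, calibrate=False)
rows.append({"quantity": "sinusoid_enmo_mg", "truth": 1000 * amp / np.pi,
             "estimate": float(epochs["enmo_mg"].iloc[0])})
rows.append({"quantity": "sinusoid_hpfvm_mg", "truth": 1000 * 2 * amp / np.pi,
             "estimate": float(epochs["hpfvm_mg"].iloc[0])})

table = pd.DataFrame(rows)
table["error"] = table["estimate"] - table["truth"]
table.to_csv(out / "signal_demo.csv", index=False)
print(table.round(4).to_string(index=False))
print("\nCalibration RMS error %.4f g over %d stationary windows"
      % (params.post_calibration_error, params.n_stationary_points))
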