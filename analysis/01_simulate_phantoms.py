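"""Generate a reference phantom and record the washout signal model.

Builds one default-condition synthetic atrium, prints the compartment
intensities at the three acquisition timepoints and the ground-truth scar
burden, writes the signal model table to results/, and exports a full
phantom fixture set (NIfTI volumes, PLY shells, tag CSV, truth JSON) under
scratch/ for visual inspection.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from atriascar import PhantomConfig, export_phantom, generate_phantom, signal_at_time

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main():
    config = PhantomConfig(seed=1)
    volumes, truth = generate_phantom(config)

    rows = []
    for t in np.arange(0.0, 41.0, 1.0):
        rows.append(
            {
                "t_min": t,
                "blood": signal_at_time(config.kinetics, "blood", t),
                "scar": signal_at_time(config.kinetics, "scar", t),
                "wall": signal_at_time(config.kinetics, "wall", t),
            }
        )
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "phantom_signal_model.csv", index=False)

    print("Washout model (noiseless compartment intensities):")
    for t in config.timepoints_min:
        b = signal_at_time(config.kinetics, "blood", t)
        s = signal_at_time(config.kinetics, "scar", t)
        print(
            f"  t={t:4.0f} min  blood={b:6.1f}  scar={s:6.1f}  "
            f"contrast={(s - b) / config.kinetics.noise_sigma:4.1f} sigma"
        )
    print(
        f"Ground truth: {truth.scar_faces_true.sum()} of {truth.mesh.n_faces} "
        f"shell faces scarred, %PAAS = {100 * truth.true_paas_fraction:.1f}%"
    )
    print(
        "Finding: scar-blood contrast grows monotonically with time post "
        "injection because the blood pool washes out faster than scar."
    )

    out = SCRATCH / "phantom_example"
    export_phantom(volumes, truth, out)
    print(f"Fixture set exported to {out}")


if __name__ == "__main__":
    main()
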