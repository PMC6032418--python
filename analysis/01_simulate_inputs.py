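"""Generate one synthetic copy of every raw input modality.

Writes an inversion-recovery series, a binding titration, and a Soret
spectrum (each with mild noise) plus their generating parameters to
results/synthetic/, in the same CSV formats the fitting stages read.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hemedist import gen_inversion_recovery, gen_isotherm, gen_soret_spectrum
from hemedist.io import write_ground_truth

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 20260926


def main() -> None:
    rng = np.random.default_rng(SEED)

    series, s_spec = gen_inversion_recovery(t1=1.54, noise_sd=1.0, seed=rng)
    pd.DataFrame({
        "proton_label": series.proton_label,
        "enzyme_state": series.enzyme_state,
        "temperature_K": series.temperature,
        "delay_s": series.delays,
        "peak_height": series.heights,
    }).to_csv(OUT / "inversion_recovery.csv", index=False)

    iso, i_spec = gen_isotherm(ks=17.1, bmax=0.05, noise_sd=0.001, seed=rng)
    pd.DataFrame({
        "substrate_uM": iso.substrate_conc,
        "delta_A": iso.delta_A,
    }).to_csv(OUT / "isotherm.csv", index=False)

    sp, p_spec = gen_soret_spectrum(f_high=0.27, noise_sd=0.01, seed=rng)
    pd.DataFrame({
        "wavelength_nm": sp.wavelengths,
        "absorbance": sp.absorbance,
    }).to_csv(OUT / "soret_spectrum.csv", index=False)

    write_ground_truth(
        {
            "seed": SEED,
            "inversion_recovery": s_spec.ground_truth,
            "isotherm": i_spec.ground_truth,
            "soret_spectrum": p_spec.ground_truth,
        },
        OUT / "ground_truth.json",
    )
    print(f"wrote synthetic inputs + ground truth to {OUT}")


if __name__ == "__main__":
    main()
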