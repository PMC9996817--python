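#!/usr/bin/env python
"""Calibrate the silicone-rubber samplers on synthetic lab fixtures.

Generates a cosolvent dilution series (known log Kpw 5.86 for AlteSil) and
a noise-free PRC dissipation series (known ke 0.5 d^-1), then recovers both
through the package's regression and pooling operations.  Writes the
calibration summary to results/calibration.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from deltarisk import pas, synth

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main(seed: int = 1) -> None:
    rows = []
    for polymer, truth in (("AlteSil", 5.86), ("SSP", 5.45)):
        pts = synth.gen_cosolvent_series(
            truth, -8.0, [0.05, 0.10, 0.15, 0.20, 0.25, 0.30], noise_sd=0.05, seed=seed
        )
        fit = pas.fit_cosolvent_regression(pts)
        rows.append(
            {
                "polymer": polymer, "quantity": "log_kpw_deltamethrin",
                "true": truth, "estimate": fit.intercept,
                "se": fit.se_intercept, "r_squared": fit.r_squared,
            }
        )
        print(f"{polymer}: log Kpw {fit.intercept:.3f} (se {fit.se_intercept:.3f}, "
              f"true {truth}); slope {fit.slope:.2f} per mole fraction methanol")

    ke_true = 0.5
    obs = synth.gen_prc_dissipation(ke_true, [1.0, 2.0, 3.5], noise_sd=0.05, seed=seed)
    sampler = pas.PolymerSampler()
    for o in obs:
        sampler = sampler.with_analyte(o.compound, sampler.log_kpw["deltamethrin"])
    kin = pas.pool_prc_kinetics(obs, sampler, "deltamethrin")
    rows.append(
        {
            "polymer": "AlteSil", "quantity": "ke_per_day",
            "true": ke_true, "estimate": kin.ke, "se": float("nan"),
            "r_squared": float("nan"),
        }
    )
    print(f"PRC kinetics: ke {kin.ke:.4f} d^-1 (true {ke_true}), "
          f"Rs {kin.rs:.3f} L d^-1, regime {kin.regime}")

    pd.DataFrame(rows).to_csv(OUT / "calibration.csv", index=False)
    print(f"wrote {OUT / 'calibration.csv'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
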