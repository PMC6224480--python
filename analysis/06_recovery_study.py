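#!/usr/bin/env python
"""Repeated simulate-and-refit study of the global ITC estimator.

Twenty repetitions of the four-isotherm experiment quantify how well
the sequential model's global parameters come back under realistic heat
noise and concentration errors.  The stage split (K1 vs K2, dH1 vs dH2)
is weakly identified per repetition — the parameters are strongly
correlated at these conditions — so the per-repetition scatter is wide
while the medians land close to the truth.  Writes
results/itc_recovery.csv.
"""

from pathlib import Path

import numpy as np

from tprbind.recovery import REFERENCE_PARAMS, itc_recovery_study

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ROOT.mkdir(parents=True, exist_ok=True)
    df = itc_recovery_study(n_repetitions=20, seed=0, n_starts=2)
    df.to_csv(ROOT / "itc_recovery.csv", index=False)
    truth = REFERENCE_PARAMS
    for col, want in (("k1", truth.k1), ("k2", truth.k2),
                      ("dh1", truth.dh1), ("dh2", truth.dh2)):
        med = float(np.median(df[col]))
        iqr = np.percentile(df[col], [25, 75])
        print(f"  {col:4s}: median {med:9.4f} (truth {want:9.4f}, "
              f"{100 * (med - want) / want:+.1f}%), IQR [{iqr[0]:.4f}, {iqr[1]:.4f}]")
    print(f"  median |rel err| K1 = {np.median(df.rel_err_k1):.2f}; "
          "the per-repetition spread reflects the K1/dH1 correlation of the "
          "sequential model at these concentrations, not optimiser failure")
    print(f"wrote {ROOT / 'itc_recovery.csv'}")


if __name__ == "__main__":
    main()
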