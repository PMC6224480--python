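#!/usr/bin/env python
"""Fit the anisotropy titrations: tracer affinity, competitor K_I, and
the non-binding control.

The direct titration gives the tracer dissociation constant K_d; that
value is then held fixed while fitting the competition closed form for
K_I.  The non-binding competitor should come back flagged with only a
lower bound.  Writes results/anisotropy_fits.json.
"""

import json
from pathlib import Path

from tprbind import io as tio
from tprbind.anisotropy import fit_direct, fit_ki

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data_dir = ROOT / "data"
    if not (data_dir / "anisotropy_direct.csv").exists():
        raise SystemExit("run 01_simulate_inputs.py first")

    direct = tio.read_anisotropy_csv(data_dir / "anisotropy_direct.csv")
    dres = fit_direct(direct)
    print(f"direct titration: K_d = {dres.k_d:.1f} +/- {dres.stderr['k_d']:.1f} uM "
          f"(truth 37 uM, {100 * (dres.k_d - 37) / 37:+.1f}%)")

    comp = tio.read_anisotropy_csv(data_dir / "anisotropy_competition.csv")
    cres = fit_ki(comp, k_lfp=dres.k_d, klc_conc=comp.klc_conc)
    print(f"competition (K_LFP fixed at fitted {dres.k_d:.1f} uM): "
          f"K_I = {cres.k_i:.1f} +/- {cres.stderr['k_i']:.1f} uM "
          f"(truth 11.3 uM, {100 * (cres.k_i - 11.3) / 11.3:+.1f}%)")

    null = tio.read_anisotropy_csv(data_dir / "anisotropy_null_competitor.csv")
    nres = fit_ki(null, k_lfp=dres.k_d, klc_conc=null.klc_conc)
    if nres.identifiable:
        print(f"null competitor: unexpectedly identifiable, K_I = {nres.k_i:.0f} uM")
    else:
        print(f"null competitor: flat curve, K_I unidentifiable "
              f"(lower bound {nres.k_i_lower_bound:.0f} uM) — the competitor "
              "does not displace the tracer")

    report = {
        "direct": {"k_d_uM": dres.k_d, "stderr": dres.stderr["k_d"],
                   "a_min": dres.a_min, "a_max": dres.a_max},
        "competition": {"k_i_uM": cres.k_i, "stderr": cres.stderr["k_i"],
                        "identifiable": cres.identifiable},
        "null_competitor": {"identifiable": nres.identifiable,
                            "k_i_lower_bound_uM": nres.k_i_lower_bound},
    }
    (ROOT / "anisotropy_fits.json").write_text(json.dumps(report, indent=2) + "\n")
    print(f"wrote {ROOT / 'anisotropy_fits.json'}")


if __name__ == "__main__":
    main()
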