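"""Render the regression table: IDRs, Wald CIs and the mixing proportion.

Reads the fitted mixture from 03 and the cohort for level ordering, builds
the coefficient table with "(ref)" rows, and narrates the key effects as
percent changes of the marginal visit rate.  Writes results/table2.csv.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from ancmix.estimation import FitResult
from ancmix.reporting import build_table2, render_percent_change
from ancmix.synthetic_data import default_covariate_specs


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fit", default="results/fit_mpoispois.json")
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()

    raw = json.loads(Path(args.fit).read_text())
    names = list(raw["estimates"])
    fit = FitResult(
        model_name=raw["model"],
        params=np.array([raw["estimates"][k] for k in names]),
        se=np.array([raw["se"][k] for k in names]),
        loglik=raw["loglik"],
        n_params=raw["n_params"],
        n_obs=raw["n_obs"],
        converged=raw["converged"],
        param_names=names,
    )
    levels = {s.name: list(s.levels) for s in default_covariate_specs()}
    tab = build_table2(fit, levels)

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tab.to_csv(out / "table2.csv", index=False)
    print(tab.to_string(index=False))

    print("\nkey adjusted effects on the marginal visit rate:")
    for _, row in tab.iterrows():
        if row["is_reference"] or row["variable"] in ("intercept", "mixing_proportion"):
            continue
        if row["p"] < 0.05:
            print(
                f"  {row['variable']}={row['level']}: "
                f"{render_percent_change(row['beta'])} (IDR {row['idr']:.3f})"
            )
    pi_row = tab[tab["variable"] == "mixing_proportion"].iloc[0]
    print(f"\nmixing proportion pi = {pi_row['beta']:.3f} (SE {pi_row['se']:.3f})")


if __name__ == "__main__":
    main()
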