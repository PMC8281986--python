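#!/usr/bin/env python
"""Compare beta mixed-effects models of TPV with AICc weights and LRTs.

Fits the nested ladder mb0 (intercept only) → mb1 (+condition) → mb2
(+StimulusRandomTime) → mb3 (condition × StimulusRandomTime), all with a
participant random intercept, on the retained correct trials from
``scratch/kinematics.csv``.  Writes the comparison table to
``results/model_comparison.csv`` (and JSON) and prints the winning model.
"""

import argparse
from pathlib import Path

import pandas as pd

from reachkin.betaglmm import fit_ladder, fit_model
from reachkin.compare import lrt_ladder, model_comparison
from reachkin.io import write_report

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--quad-order", type=int, default=15)
    args = ap.parse_args()

    kin_path = ROOT / "scratch" / "kinematics.csv"
    if not kin_path.exists():
        raise SystemExit("no kinematics table; run 02_extract_kinematics.py first")
    kin = pd.read_csv(kin_path)
    table = kin[(kin["validity"] == "valid_correct") & kin["retained"]].copy()
    table["tpv"] = table["tpv_pct"] / 100.0
    table = table[["participant", "condition", "srt_ms", "tpv"]]
    print(f"fitting on {len(table)} retained correct trials, "
          f"{table['participant'].nunique()} participants")

    fits = fit_ladder(table, order=args.quad_order)
    comparison = model_comparison(fits)
    lrt = lrt_ladder(fits)

    comparison.round(4).to_csv(ROOT / "results" / "model_comparison.csv", index=False)
    best = fits[int(comparison["aicc_weight"].idxmax())]
    best_cov = fit_model(best.spec, table, order=args.quad_order, compute_cov=True)
    wald = best_cov.wald_table()
    write_report(dict(
        comparison=comparison.to_dict(orient="records"),
        lrt=lrt.to_dict(orient="records"),
        best_model=dict(model=best.name, sigma_b=best.sigma_b, phi=best.phi,
                        beta={n: float(b) for n, b in zip(best.beta_names, best.beta)},
                        wald=wald.to_dict(orient="records")),
    ), ROOT / "results" / "model_comparison.json")

    print(comparison.round(3).to_string(index=False))
    print(f"best model by Akaike weight: {best.name} "
          f"(weight {comparison['aicc_weight'].max():.2f})")
    print(wald.round(4).to_string(index=False))
    print("  tables -> results/model_comparison.csv / .json")


if __name__ == "__main__":
    main()
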