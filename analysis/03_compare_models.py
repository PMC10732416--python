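"""Compare fitted models by LOOIC.

Reads the pointwise log-likelihood matrices written by ``02_fit_models.py``
and ranks the models by PSIS-LOO information criterion (lower is better),
reporting each model's LOOIC, its standard error, and the difference from
the best model.
"""

import argparse
import re
from pathlib import Path

import pandas as pd

from gngwm.comparison import looic
from gngwm.family import build_model_spec


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fits", type=Path, default=Path("results"),
                    help="directory holding fit_m*_pointwise.csv files")
    ap.add_argument("--out", type=Path, default=Path("results/model_comparison.csv"))
    args = ap.parse_args()

    rows = []
    for path in sorted(args.fits.glob("fit_m*_pointwise.csv")):
        mid = int(re.search(r"fit_m(\d+)_pointwise", path.name).group(1))
        res = looic(pd.read_csv(path).to_numpy())
        rows.append({
            "model_id": mid,
            "n_params": build_model_spec(mid).n_params,
            "looic": res.looic,
            "se": res.se,
            "unreliable": res.unreliable,
        })
    if not rows:
        raise SystemExit(f"no fit_m*_pointwise.csv files under {args.fits}")

    table = (pd.DataFrame(rows)
             .sort_values(["looic", "n_params", "model_id"], kind="stable")
             .reset_index(drop=True))
    table["delta_looic"] = table["looic"] - table["looic"].iloc[0]
    print(table.round(2).to_string(index=False))
    best = table.iloc[0]
    print(f"best model: {int(best.model_id)} "
          f"(LOOIC {best.looic:.1f} +/- {best.se:.1f})")
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
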