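"""Fit the binomial relative-productivity model.

Drops juvenile-only stations (no adults ever captured), standardizes
covariates, and samples the posterior of the juvenile-proportion model.
Productivity is modelled separately from the joint abundance/survival model.
"""

import argparse
import json
from pathlib import Path

from mapsdemog import data_io, inference


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--preset", choices=["test", "full"], default="test")
    ap.add_argument("--hf-scale", choices=["1km", "10km"], default="1km")
    args = ap.parse_args()

    stations = data_io.read_stations(args.data / "stations.csv")
    productivity = data_io.read_productivity(args.data / "productivity.csv")
    md = data_io.prepare_productivity_data(
        stations, productivity, hf_scale=args.hf_scale, first_year=1993
    )
    pdata = md.productivity
    print(f"after filters: {pdata.n_stations} stations, "
          f"{len(pdata.totals)} station-years, "
          f"{int(pdata.totals.sum())} captures")
    preset = (inference.FULL_PRESET if args.preset == "full"
              else inference.McmcConfig(n_chains=2, n_iterations=3000,
                                        burn_in=1500, thin=1))
    cfg = inference.McmcConfig(**{**preset.__dict__, "seed": args.seed})
    chains = inference.sample_posterior("productivity", md.productivity, cfg)

    args.out.mkdir(parents=True, exist_ok=True)
    chains.save_csv(args.out / "chains_productivity.csv")
    summary = chains.summary()
    summary.to_csv(args.out / "summary_productivity.csv", index=False)
    with open(args.out / "diagnostics_productivity.json", "w") as fh:
        json.dump({r.parameter: r.rhat for r in summary.itertuples(index=False)},
                  fh, indent=2, sort_keys=True)
    print(f"wrote {args.out}/chains_productivity.csv "
          f"({cfg.pooled_draws} pooled draws)")


if __name__ == "__main__":
    main()
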