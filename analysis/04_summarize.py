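"""Summarize the fitted posteriors.

Rebuilds the model-ready data (same filters as the fitting step, so station
random-effect indexing matches the chains), loads the serialized chains, and
writes the report: survival/residency by region and sex, footprint-effect
coefficients with the posterior mass below zero, and per-region annual
trends for breeding density, productivity, apparent survival and derived
recruitment (as percent per year), plus a trend figure.
"""

import argparse
from pathlib import Path

from mapsdemog import data_io, summaries
from mapsdemog.inference import PosteriorChains


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--chains", type=Path, default=Path("results"))
    ap.add_argument("--out", type=Path, default=Path("results/report"))
    ap.add_argument("--hf-scale", choices=["1km", "10km"], default="1km")
    args = ap.parse_args()

    stations = data_io.read_stations(args.data / "stations.csv")
    counts = data_io.read_counts(args.data / "counts.csv")
    histories = data_io.read_captures(args.data / "captures.csv")
    md = data_io.prepare_joint_data(
        stations, counts, histories, hf_scale=args.hf_scale, first_year=1993
    )
    n_years = md.survival.n_occasions
    t_values = summaries.centered_years(n_years)

    joint = prod = None
    joint_path = args.chains / "chains_joint.csv"
    prod_path = args.chains / "chains_productivity.csv"
    if joint_path.exists():
        joint = PosteriorChains.load_csv(joint_path)
    if prod_path.exists():
        prod = PosteriorChains.load_csv(prod_path)

    report = summaries.make_report(joint, prod, md, t_values)
    summaries.write_report(report, args.out)
    if "trends" in report:
        cols = ["rate", "region", "mean", "hpd_low", "hpd_high",
                "percent_per_year", "prob_decline"]
        print(report["trends"][cols].to_string(index=False,
                                               float_format="%.4f"))
        summaries.plot_trend_coefficients(report["trends"],
                                          args.out / "trends.png")
    if report["gaps"]:
        print("gaps:", "; ".join(report["gaps"]))
    print(f"wrote {args.out}/")


if __name__ == "__main__":
    main()
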