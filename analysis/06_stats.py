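"""The statistical battery on the synthetic session.

Stepwise regressions of binned median quality and ionic-current noise on
time / RMS vibration / g level; one-way ANOVA + Tukey HSD of read quality
by flight phase; ground-vs-flight KS on per-base dwell; MAD outliers in
the binned noise. Writes JSON reports to results/ and narrates what the
null/planted structure of the generator should (and does) produce.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import (BASES_FLIGHT, BASES_GROUND, BINS_TSV, PERIODS_TRUE,
                     READS_FLIGHT, RESULTS, ensure_dirs)

from gravseq.integration import assign_phases
from gravseq.segmentation import read_periods
from gravseq.stats import (anova_oneway, ks_two_sample, mad_outliers,
                           stepwise_lm, tukey_hsd)


def main() -> None:
    ensure_dirs()
    bins = pd.read_csv(BINS_TSV, sep="\t")
    cand = {c: bins[c].to_numpy(float) for c in ("elapsed_s", "rms_g", "mean_g")}

    for response in ("median_q_pbar", "median_norm_std"):
        res = stepwise_lm(bins[response], cand)
        report = {"response": response, "terms": res.terms,
                  "coefficients": res.coefficients, "p_values": res.p_values,
                  "adj_r2": res.adj_r2, "n_obs": res.n_obs}
        (RESULTS / f"regression_{response}.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        print(f"stepwise {response}: terms={res.terms} "
              f"adj_R2={res.adj_r2:.3f} (nothing planted: any selected "
              f"term is a type-I entry at the 0.05 threshold)")

    reads = pd.read_parquet(READS_FLIGHT)
    periods = read_periods(PERIODS_TRUE)
    run = reads[~reads["is_mux"]].copy()
    run["phase"] = assign_phases(run, periods)
    keep = ~run["phase"].isin(["spanning", "transition"])
    groups = {lbl: g["q_pbar"].to_numpy(float)
              for lbl, g in run[keep].groupby("phase") if len(g) >= 2}
    an = anova_oneway(groups)
    tk = tukey_hsd(groups)
    (RESULTS / "anova_quality.json").write_text(json.dumps(
        {"means": an.means, "ns": an.ns, "f": an.f, "p_value": an.p_value,
         "tukey": tk.comparisons.to_dict(orient="records")},
        indent=2, sort_keys=True) + "\n")
    print(f"ANOVA q_pbar by phase: F={an.f:.2f} p={an.p_value:.3g}; "
          f"means={ {k: round(v, 3) for k, v in an.means.items()} }")

    flight = pd.read_parquet(BASES_FLIGHT)["trans_ms"].to_numpy()
    ground = pd.read_parquet(BASES_GROUND)["trans_ms"].to_numpy()
    ks = ks_two_sample(ground, flight)
    (RESULTS / "ks_translocation.json").write_text(json.dumps(
        {"d": ks.d, "p_value": ks.p_value,
         "mean_ground_ms": float(ground.mean()),
         "mean_flight_ms": float(flight.mean()),
         "mean_diff_ms": float(flight.mean() - ground.mean())},
        indent=2) + "\n")
    print(f"KS dwell ground vs flight: D={ks.d:.4f} p={ks.p_value:.3g}; "
          f"mean diff {flight.mean() - ground.mean():.4f} ms "
          f"(planted 0.1249 ms)")

    noise = bins["median_norm_std"].dropna().to_numpy()
    flags = mad_outliers(noise, k=3)
    print(f"MAD outliers in binned noise: {int(flags.sum())} of {len(noise)} "
          f"bins flagged at k=3")


if __name__ == "__main__":
    main()
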