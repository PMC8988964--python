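#!/usr/bin/env python
"""Skin optical properties per phantom: weighted means and the
contaminated-phantom bias.

Reads the simulated skin fits, drops excluded records, aggregates the
repeated measurements of each calibration by their individual confidence
intervals (inverse-variance weighting), and compares the per-calibration
weighted means of a_800 and the power-law exponent b between the
contaminated phantom 8 and the fresh reference phantom 1.

Outputs (results/):
    skin_weighted_means.csv   one row per probe x phantom x calibration
    phantom8_effect.csv       phantom 8 vs phantom 1 location tests
"""

from pathlib import Path

import pandas as pd

from mdsfr import group_tests, weighted_mean

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    fits = pd.read_csv(RESULTS / "phantom_skin_fits.csv")
    n = len(fits)
    for crit, col in (("residual", "residual_exceeded"),
                      ("BVF", "bvf_exceeded"),
                      ("StO2 CI", "sto2_ci_outlier")):
        print(f"excluded by {crit:9s}: {100 * fits[col].mean():.1f}% of {n}")

    rows = []
    for (probe, phantom, cal), sub in fits.groupby(
        ["probe_id", "phantom_id", "calibration"]
    ):
        row = {"probe_id": probe, "phantom_id": phantom, "calibration": cal}
        for par in ("a_800", "b"):
            summary = weighted_mean(
                sub[par], sub[f"ci_{par}"], excluded=sub["excluded"], parameter=par
            )
            row[f"wmean_{par}"] = summary.weighted_mean
            row["n_used"] = summary.n_used
        rows.append(row)
    wm = pd.DataFrame(rows)
    wm.to_csv(RESULTS / "skin_weighted_means.csv", index=False)

    pair = wm[wm.phantom_id.isin(["ph01", "ph08"])].copy()
    tests = []
    for par in ("a_800", "b"):
        t = group_tests(
            pair.rename(columns={f"wmean_{par}": "snr"}).to_dict("records"),
            "phantom_id",
        )
        t.insert(0, "parameter", par)
        tests.append(t)
    effect = pd.concat(tests, ignore_index=True)
    effect.to_csv(RESULTS / "phantom8_effect.csv", index=False)

    m1 = wm[wm.phantom_id == "ph01"]
    m8 = wm[wm.phantom_id == "ph08"]
    print(f"a_800 weighted mean     : phantom 1 {m1.wmean_a_800.mean():.2f} mm^-1, "
          f"phantom 8 {m8.wmean_a_800.mean():.2f} mm^-1")
    print(f"exponent b weighted mean: phantom 1 {m1.wmean_b.mean():.2f}, "
          f"phantom 8 {m8.wmean_b.mean():.2f}")
    for r in effect[effect.test == "mann_whitney"].itertuples():
        print(f"phantom 8 vs 1, {r.parameter:6s}: Mann-Whitney p = {r.p_value:.2e}")


if __name__ == "__main__":
    main()
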