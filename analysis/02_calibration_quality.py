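#!/usr/bin/env python
"""Intra- and inter-phantom variability of the calibration-quality SNR.

Reads the simulated phantom-study SNR table and, per probe, computes the
coefficient of variation of SNR within each phantom (intra-phantom) and
compares every phantom against phantom 1, the freshest reference
(inter-phantom, unpaired t-test and Mann-Whitney side by side).  A
multi-group comparison across probes closes the analysis.

Outputs (results/):
    phantom_variability.csv   per probe x phantom CV% + reference p-values
    probe_comparison.csv      ANOVA / Kruskal-Wallis across probes
"""

from pathlib import Path

import pandas as pd

from mdsfr import group_tests, variability

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    snr = pd.read_csv(RESULTS / "phantom_snr_reports.csv")
    tables = []
    for probe_id, sub in snr.groupby("probe_id"):
        t = variability(sub.to_dict("records"), "phantom_id", reference="ph01")
        t.insert(0, "probe_id", probe_id)
        tables.append(t)
    var = pd.concat(tables, ignore_index=True)
    var.to_csv(RESULTS / "phantom_variability.csv", index=False)

    probes = group_tests(snr.to_dict("records"), "probe_id")
    probes.to_csv(RESULTS / "probe_comparison.csv", index=False)

    intra = var["cv_percent"]
    print(f"intra-phantom CV of SNR : {intra.min():.2f}% to {intra.max():.2f}% "
          f"(median {intra.median():.2f}%)")
    worst = var.loc[var["mean_snr"].idxmin()]
    print(f"lowest mean SNR         : {worst.mean_snr:.1f} "
          f"({worst.probe_id}, {worst.phantom_id})")
    ph8 = var[var.phantom_id == "ph08"]
    sig = (ph8["mannwhitney_p_vs_reference"] < 0.05).sum()
    print(f"phantom 8 vs phantom 1  : Mann-Whitney p < 0.05 for "
          f"{sig}/{len(ph8)} probes")
    print(f"across-probe comparison : "
          + ", ".join(f"{r.test} p={r.p_value:.3g}" for r in probes.itertuples()))


if __name__ == "__main__":
    main()
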