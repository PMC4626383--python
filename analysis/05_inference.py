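#!/usr/bin/env python
"""Statistical layer: factor effects, band contrasts, polynomial fits and
the individual-vs-cumulative comparison.

Each metric is tested for altitude and time effects (ANOVA when residuals
pass normality and homogeneity, Kruskal-Wallis otherwise), contrasted
between the low and high elevation bands (pooled-variance or Welch t,
routed by Levene), regressed on altitude (linear) and precipitation
(quadratic), and compared across individual and pooled network scales.
"""

from pathlib import Path

import pandas as pd

from mosaicweb.inference import (
    band_contrast,
    band_table,
    factor_effects,
    factor_table,
    individual_vs_cumulative,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = pd.read_csv(OUT / "metrics_units.tsv", sep="\t")
    frames = [factor_table(factor_effects(table, factor))
              for factor in ("altitude", "time")]
    factors = pd.concat(frames, ignore_index=True)
    factors.to_csv(OUT / "factor_effects.tsv", sep="\t", index=False)
    for factor in ("altitude", "time"):
        sub = factors[factors["factor"] == factor]
        sig = sub[sub["p"] < 0.05]["metric"].tolist()
        print(f"{factor}: significant at 0.05 for {sig or 'no metric'}")

    bands = band_table(band_contrast(table))
    bands.to_csv(OUT / "band_contrasts.tsv", sep="\t", index=False)
    welch = (bands["test"] == "welch_t").sum()
    print(f"band contrasts: {welch} of {len(bands)} metrics used Welch's t")

    cum_alt = pd.read_csv(OUT / "metrics_altitude.tsv", sep="\t")
    cum_month = pd.read_csv(OUT / "metrics_month.tsv", sep="\t")
    comparison = individual_vs_cumulative(table, cum_alt, cum_month)
    comparison.to_csv(OUT / "individual_vs_cumulative.tsv", sep="\t",
                      index=False)
    row = comparison.set_index("metric").loc["C"]
    print(f"connectance: individual {row['mean_individual']:.2f} vs "
          f"cumulative altitude {row['mean_cumulative_altitude']:.2f} / "
          f"time {row['mean_cumulative_time']:.2f} (chi2={row['chi2']:.1f})")


if __name__ == "__main__":
    main()
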