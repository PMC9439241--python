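#!/usr/bin/env python
"""Per-subject decay fits and their correlation with fitness indices.

Fits the HR decay model to each subject's own windows, then correlates
the fitted halving constant (tau) and intercept (b) with VO2max, maximal
aerobic power, ventilatory-threshold powers, peak HR and heart-rate
recovery — both as Pearson r and as rank correlation. Writes
results/crf_correlations.csv.
"""

import pandas as pd

import hrvdecay as hd
from hrvdecay.cohort import correlate_crf, crf_table, fit_cohort
from hrvdecay.io import load_cohort

IN = "results/cohort"
OUT = "results/crf_correlations.csv"


def main() -> None:
    cohort = load_cohort(IN)
    fits, _ = fit_cohort(cohort)
    crf = crf_table(cohort)
    table = pd.concat(
        [correlate_crf(fits, crf, m) for m in ("linear", "rank")],
        ignore_index=True,
    )
    table.to_csv(OUT, index=False)

    lin = table[(table.method == "linear") & (table.coefficient == "tau_hr")]
    print("tau (HRV halving constant) vs fitness, Pearson r (p):")
    for _, row in lin.iterrows():
        print(f"  {row['index']:>8s}: r = {row.r:+.2f} (p = {row.p_value:.3f})")
    taus = [f.tau for f in fits if f is not None]
    print(f"\nper-subject tau range: {min(taus):.1f} - {max(taus):.1f} beats/min "
          f"({len(taus)} converged fits)")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
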