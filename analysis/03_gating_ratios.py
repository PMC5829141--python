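"""Quantify paired-pulse inhibitory gating per session.

For every sound-pair epoch container from step 01, averages the 120
trials, finds the region's negative/positive deflections (AC: N25/P40;
HP/AMY/PFC: N35/P70), keeps only peaks that beat the pre-stimulus control
period at p < 0.01, and reports T-amp/C-amp per peak.  Writes
results/ig_results.tsv and prints mean T/C per region x condition, which
should deepen (decrease) from AC to PFC and be largely unchanged by
anesthesia.
"""

import sys
import warnings
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]

from audlfp import RunConfig, compute_ig, load_epochs
from audlfp.gating import ig_result_rows


def main() -> int:
    cohort = sorted((ROOT / "scratch" / "cohort").glob("*_pairs.h5"))
    if not cohort:
        print("no cohort found; run analysis/01_simulate_cohort.py first",
              file=sys.stderr)
        return 1
    config = RunConfig()
    rows, n_undefined = [], 0
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for path in cohort:
            rows.extend(ig_result_rows(compute_ig(load_epochs(path), config)))
        n_undefined = sum("undefined" in str(w.message) for w in caught)
    df = pd.DataFrame(rows)
    out = ROOT / "results" / "ig_results.tsv"
    df.to_csv(out, sep="\t", index=False, float_format="%.8g")
    print(f"wrote {len(df)} peak rows -> {out}")
    print(f"({n_undefined} peak ratios undefined: a constituent peak failed "
          f"the p < {config.alpha_peak} control-period test)\n")
    means = (df.assign(polarity=df["label"].str[0])
               .pivot_table(index=["condition", "region"], columns="polarity",
                            values="tc_ratio"))
    means.columns = ["tc_negative", "tc_positive"]
    print("mean T/C per region x condition:")
    print(means.round(3).to_string())
    return 0


if __name__ == "__main__":
    sys.exit(main())
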