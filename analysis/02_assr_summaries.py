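"""Quantify the 40-Hz auditory steady-state response per session.

For every click-train epoch container from step 01, runs the Morlet
wavelet decomposition (1-100 Hz, 7 cycles) and summarizes mean trial
power (MTP) and phase-locking factor (PLF) over the 35-45 Hz x 50-550 ms
box.  Writes results/assr_summaries.tsv and prints the regional means,
which should fall off AC > HP > AMY > PFC in the conscious state and be
suppressed by anesthesia.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]

from audlfp import RunConfig, load_epochs
from audlfp.pipeline import assr_summary


def main() -> int:
    cohort = sorted((ROOT / "scratch" / "cohort").glob("*_clicks.h5"))
    if not cohort:
        print("no cohort found; run analysis/01_simulate_cohort.py first",
              file=sys.stderr)
        return 1
    config = RunConfig()
    rows = []
    for path in cohort:
        es = load_epochs(path)
        mtp40, plf40 = assr_summary(es, config)
        rows.append({"session_id": es.session_id, "region": es.region,
                     "condition": es.condition, "mtp40": mtp40, "plf40": plf40})
    df = pd.DataFrame(rows)
    out = ROOT / "results" / "assr_summaries.tsv"
    df.to_csv(out, sep="\t", index=False, float_format="%.8g")
    print(f"wrote {len(df)} session summaries -> {out}\n")
    means = df.groupby(["condition", "region"])[["mtp40", "plf40"]].mean()
    print("regional means (MTP in uV^2, PLF dimensionless):")
    print(means.round(3).to_string())
    return 0


if __name__ == "__main__":
    sys.exit(main())
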