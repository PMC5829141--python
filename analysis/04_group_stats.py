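"""Group-level inference across regions and conditions.

Joins the per-session ASSR summaries (step 02) and gating ratios (step
03), then runs the study's statistics: one-way ANOVA across regions with
Tukey HSD on the conscious cohort, and paired t-tests between conscious
and anesthetized within each region.  Writes the group tables and the
text report under results/ and prints the three headline findings.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]

from audlfp.stats import group_stats


def main() -> int:
    resdir = ROOT / "results"
    try:
        assr = pd.read_csv(resdir / "assr_summaries.tsv", sep="\t")
        ig = pd.read_csv(resdir / "ig_results.tsv", sep="\t")
    except FileNotFoundError as exc:
        print(f"{exc}; run steps 02 and 03 first", file=sys.stderr)
        return 1
    tc = (ig.assign(polarity=ig["label"].str[0])
            .pivot_table(index=["session_id", "region", "condition"],
                         columns="polarity", values="tc_ratio")
            .rename(columns={"N": "tc_negative", "P": "tc_positive"})
            .reset_index())
    summaries = assr.merge(tc, on=["session_id", "region", "condition"])
    summaries.to_csv(resdir / "session_summaries.tsv", sep="\t", index=False,
                     float_format="%.8g")

    report = group_stats(summaries)
    report.anova_frame().to_csv(resdir / "group_anova.tsv", sep="\t", index=False,
                                float_format="%.8g")
    report.tukey_frame().to_csv(resdir / "group_tukey.tsv", sep="\t", index=False,
                                float_format="%.8g")
    report.paired_frame().to_csv(resdir / "group_paired.tsv", sep="\t", index=False,
                                 float_format="%.8g")
    (resdir / "report.txt").write_text(report.to_text())
    print(report.to_text())

    cons = summaries[summaries["condition"] == "conscious"]
    order = list(cons.groupby("region")["mtp40"].mean()
                 .sort_values(ascending=False).index)
    print(f"finding 1: conscious 40-Hz MTP ordered {' > '.join(order)}")
    assr_sig = all(report.paired[(r, m)].p_value < 0.05
                   for r in ("AC", "HP", "AMY") for m in ("mtp40", "plf40"))
    print(f"finding 2: anesthesia reduces MTP/PLF in AC, HP, AMY "
          f"(all paired p < 0.05: {assr_sig})")
    tc_ps = [report.paired[(r, m)].p_value for r in ("AC", "HP", "AMY", "PFC")
             for m in ("tc_negative", "tc_positive")]
    print(f"finding 3: no T/C ratio is altered by anesthesia "
          f"(min paired p = {np.min(tc_ps):.3f}; all > 0.05: {all(p > 0.05 for p in tc_ps)})")
    return 0


if __name__ == "__main__":
    sys.exit(main())
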