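"""Simulate the synthetic recording cohort.

Generates 10 sessions per region x condition cell (AC/HP/AMY/PFC x
conscious/anesthetized), each with 120 click-train trials and 120
sound-pair trials, using the region presets plus between-session
heterogeneity, and saves the epoch containers under scratch/cohort/.
Also writes the generative preset table (the ground truth the later
steps try to recover) to results/presets.tsv.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

from audlfp import CohortSpec, save_epochs
from audlfp.pipeline import iter_cohort_sessions
from audlfp.simulate import presets_table

SEED = 1
N_SESSIONS = 10


def main() -> None:
    outdir = ROOT / "scratch" / "cohort"
    outdir.mkdir(parents=True, exist_ok=True)
    resdir = ROOT / "results"
    resdir.mkdir(exist_ok=True)

    presets_table().to_csv(resdir / "presets.tsv", sep="\t", index=False)
    print(f"wrote generative preset table -> {resdir / 'presets.tsv'}")

    spec = CohortSpec(n_sessions=N_SESSIONS, seed=SEED)
    n = 0
    for clicks, pairs in iter_cohort_sessions(spec):
        stem = f"{clicks.session_id}_{clicks.condition}"
        save_epochs(clicks, outdir / f"{stem}_clicks.h5")
        save_epochs(pairs, outdir / f"{stem}_pairs.h5")
        n += 1
    print(f"simulated {n} session-conditions "
          f"({N_SESSIONS} sessions/cell, seed {SEED}) -> {outdir}")


if __name__ == "__main__":
    sys.exit(main())
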