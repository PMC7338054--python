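#!/usr/bin/env python
"""Generate and characterise the stimulus sets for every experiment.

Writes one trial table per experiment under results/stimuli/ and prints
the block compositions, transition-window statistics and the PATinRAN gap
distribution -- the geometry every later stage builds on.
"""

from pathlib import Path

import numpy as np

from seqmem.stimuli import (build_frequency_pool, schedule_session,
                            session_to_dataframe)

OUT = Path(__file__).resolve().parent.parent / "results" / "stimuli"
SEED = 20240


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    pool = build_frequency_pool()
    print(f"frequency pool: {pool.size} tones, "
          f"{pool.frequencies[0]:.0f}-{pool.frequencies[-1]:.0f} Hz, "
          f"step {100 * (pool.step_ratio - 1):.1f}%")
    for exp in ("1A", "1B", "2", "3", "4", "5"):
        session = schedule_session(exp, np.random.default_rng(SEED))
        df = session_to_dataframe(session)
        path = OUT / f"trials_exp{exp}.csv"
        df.to_csv(path, index=False)
        comp = df[df.block == 0]["condition"].value_counts().to_dict()
        print(f"Exp {exp}: {df.block.nunique()} blocks x "
              f"{len(df) // df.block.nunique()} trials; block composition "
              f"{comp}")
        tt = df["transition_time_s"].dropna()
        if len(tt):
            print(f"  transitions span {tt.min():.2f}-{tt.max():.2f} s")
    print(f"\nwrote trial tables to {OUT}")


if __name__ == "__main__":
    main()
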