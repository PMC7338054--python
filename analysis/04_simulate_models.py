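#!/usr/bin/env python
"""Paired unconstrained/constrained model simulations of the two key
experiments.

Reproduces the central model result: with perfect memory the RT advantage
for reoccurring patterns is immediate and large, while the memory-decay
kernel makes it start near zero and grow across blocks (base experiment),
and abolishes first-presentation memory for patterns that were only ever
heard non-adjacently (non-adjacency experiment's test block).  Writes
trial-level simulated RTs and the advantage summaries under results/.
"""

import time
from pathlib import Path

import pandas as pd

from seqmem.decay import DecayParams
from seqmem.harness import (HarnessConfig, calibrate_matched, run_replicates,
                            summarize_rt_advantage)

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20242
REPLICATES = {"unconstrained": 4, "constrained": 12}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    dets = {
        "unconstrained": calibrate_matched(10_000.0, 140, 30_000, seed=SEED),
        "constrained": calibrate_matched(10_000.0, 140, 20_000,
                                         decay=DecayParams(), seed=SEED),
    }
    for exp in ("1A", "2"):
        for mode, det in dets.items():
            t0 = time.time()
            cfg = HarnessConfig(model_mode=mode, decay=DecayParams(),
                                detector=det, seed=SEED)
            df = run_replicates(exp, cfg, REPLICATES[mode], seed=SEED + 7)
            df.to_csv(OUT / f"model_rts_exp{exp}_{mode}.csv", index=False)
            if exp == "1A":
                adv = summarize_rt_advantage(df, "per_block")
                novel = df[df.condition == "RANREG"]["model_rt"]
                print(f"\nExp 1A, {mode} ({time.time() - t0:.0f} s): novel "
                      f"RANREG latency {novel.mean():.3f} s; per-block "
                      f"advantage (s):")
            else:
                adv = pd.concat([
                    summarize_rt_advantage(df, "per_intra_block_presentation",
                                           reoccurring=c).assign(condition=c)
                    for c in ("RANREGr", "RANREGr*")])
                print(f"\nExp 2 test block, {mode} ({time.time() - t0:.0f} s): "
                      f"advantage per intra-block presentation (s):")
            print(adv.round(3).to_string(index=False))
            adv.to_csv(OUT / f"rt_advantage_exp{exp}_{mode}.csv", index=False)
    print(f"\nwrote model tables to {OUT}")


if __name__ == "__main__":
    main()
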