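#!/usr/bin/env python
"""One-parameter sensitivity sweeps around the printed scenarios.

Three sweeps: the bribe size K over the scenario-A base, and the
regulation cost Cr and credibility loss Pg over the scenario-C base.
Each writes per-value trajectory CSVs plus a summary JSON with limits,
corner attribution and qualitative shape labels.

Findings: raising K from 30 to 50 flips the system from the compliant
corner (0,0,0) to bribery under lax supervision (1,1,0), with the
low-quality share x dipping before it recovers to 1 (a single-trough
transient); the regulator's limit stays lax across the whole K sweep.
Raising Pg from 20 to 100 forces strict supervision (z: 0 -> 1). The
Cr=40 run under the scenario-C base is reported as computed: x collapses
to the high-quality face and (y, z) keep circulating without settling on
a corner within the horizon, even though E8 is the locally stable corner
there — the centre start is outside its numerically reachable basin.
"""

from pathlib import Path

from adrgame import printed_sets, sweep
from adrgame.io import write_sweep_json, write_trajectory_csv

RESULTS = Path(__file__).resolve().parents[1] / "results"

SWEEPS = (
    ("A", "K", (30.0, 50.0, 100.0)),
    ("C", "Cr", (40.0, 120.0, 200.0)),
    ("C", "Pg", (20.0, 100.0, 180.0)),
)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    sets = printed_sets()
    for scen, param, values in SWEEPS:
        result = sweep(sets[scen].params, param, values)
        out_dir = RESULTS / f"sweep_{param}_base{scen}"
        out_dir.mkdir(exist_ok=True)
        for e in result.entries:
            write_trajectory_csv(e.trajectory, out_dir / f"{param}_{e.value:g}.csv",
                                 max_rows=500)
        write_sweep_json(result, out_dir / f"sweep_{param}.json")
        print(f"base {scen}, sweep {param} over {list(values)}: "
              f"limits reach corners {result.corners}")


if __name__ == "__main__":
    main()
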