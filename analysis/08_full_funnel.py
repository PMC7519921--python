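#!/usr/bin/env python
"""Run the whole discovery funnel in one call and print the stage report.

Equivalent to scripts 01-06 composed through pygmyscan.run_pipeline: simulate
-> filter -> F_st scan -> tier -> sPLS -> cluster -> associate, with the
funnel report at results/funnel/funnel.json.
"""

from pathlib import Path

import pygmyscan as pg

OUT = Path(__file__).resolve().parents[1] / "results" / "funnel"


def main() -> None:
    cfg = pg.PipelineConfig(simulation=pg.SimulationConfig())
    report = pg.run_pipeline(cfg, OUT)
    print("funnel stage cardinalities:")
    for rec in report.stages:
        params = f"  {rec.parameters}" if rec.parameters else ""
        print(f"  {rec.stage:12s} {rec.n_in:6d} -> {rec.n_out:6d}{params}")
    print(f"artifacts under {OUT}")


if __name__ == "__main__":
    main()
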