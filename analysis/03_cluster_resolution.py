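#!/usr/bin/env python
"""Leiden resolution sweep (0.1..1.0) with the dual selection criterion:
modularity-Q plateau capped by marker-AUC validity (every cluster must keep
a marker with AUC > 0.6). Prints the sweep table and the choice rationale.
"""

import argparse
from pathlib import Path

from cotransmit.pipeline import PipelineConfig, run_pipeline

REPO = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--config", default=REPO / "configs" / "demo.toml")
    ap.add_argument("--out", default=REPO / "results" / "demo")
    args = ap.parse_args()

    cfg = PipelineConfig.from_toml(args.config)
    results = run_pipeline(cfg, args.out, upto="cluster")
    print(results["sweep"].to_frame().to_string(index=False))
    choice = results["choice"]
    print(f"\n{choice.rationale}")
    print(f"clusters at chosen resolution: {int(results['labels'].max() + 1)}")


if __name__ == "__main__":
    main()
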