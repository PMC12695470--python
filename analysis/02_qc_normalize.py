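#!/usr/bin/env python
"""Cell quality control, log-normalization and PCA of the demo experiment.

Cells with <300 detected genes, >6,000 genes, <500 total counts, >1%
mitochondrial counts, or a doublet flag are removed (boundary cells are
retained). Prints the QC report and the leading principal-component
variances.
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
    results = run_pipeline(cfg, args.out, upto="qc")
    report = results["qc_report"]
    print(report.to_frame().to_string(index=False))
    ev = results["embedding"].explained_variance
    print(f"\nPCA: {len(ev)} components; leading variances "
          + ", ".join(f"{v:.2f}" for v in ev[:5]))


if __name__ == "__main__":
    main()
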