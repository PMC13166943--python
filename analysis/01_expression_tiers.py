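#!/usr/bin/env python
"""Expression-tier study: quantify membrane MET/phospho-MET across synthetic
cell-line tiers spanning negligible to high, constitutively active expression.

Generates three fields per tier (negligible / moderate / high), runs the
full pipeline (isotype-derived thresholds, Otsu segmentation), and writes
the endpoint and group-summary tables.  The expected finding is a clean
ordering of %MAP and area-per-cell across tiers, with the negligible tier
near zero for every marker metric.
"""

import argparse

from mifquant.config import load_config
from mifquant.pipeline import make_fixtures, run_quantification


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=5)
    ap.add_argument("--scratch", default="scratch/expression_tiers")
    ap.add_argument("--results", default="results/expression_tiers")
    args = ap.parse_args()

    config_path = make_fixtures("expression-tiers", args.scratch, seed=args.seed)
    config = load_config(config_path)
    config.output_dir = args.results
    result = run_quantification(config)

    s = result.summary
    for metric in ("total_met_pct_map", "phospho_met_pct_map", "pct_map_dual"):
        m = s[s.metric == metric].set_index("group")["mean"]
        print(f"{metric}: negligible={m['negligible']:.2f}  "
              f"moderate={m['moderate']:.2f}  high={m['high']:.2f}")
    print(f"tables written to {args.results} (exit {result.exit_code})")


if __name__ == "__main__":
    main()
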