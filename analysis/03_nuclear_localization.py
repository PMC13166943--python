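#!/usr/bin/env python
"""Nuclear phospho-MET accumulation: wildtype-like vs ligand-driven tumours.

Simulates two groups of five fields whose painted nuclear phospho-MET
fraction is 30% vs 60% (the pattern of constitutive HGF exposure), runs the
pipeline, and compares %NAP between groups.  The expected finding is a
~30-point %NAP shift with a significant Mann-Whitney contrast.
"""

import argparse

from mifquant.config import load_config
from mifquant.pipeline import make_fixtures, run_quantification


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=2)
    ap.add_argument("--scratch", default="scratch/nuclear_shift")
    ap.add_argument("--results", default="results/nuclear_shift")
    args = ap.parse_args()

    config_path = make_fixtures("nuclear-shift", args.scratch, seed=args.seed)
    config = load_config(config_path)
    config.output_dir = args.results
    result = run_quantification(config)

    s = result.summary
    m = s[s.metric == "phospho_met_pct_nap"].set_index("group")
    for g in ("wildtype", "hgf_ki"):
        print(f"phospho %NAP {g}: mean={m.loc[g, 'mean']:.1f} sd={m.loc[g, 'sd']:.2f}")
    print(f"shift: {m.loc['hgf_ki', 'mean'] - m.loc['wildtype', 'mean']:.1f} points")
    c = result.comparisons
    row = c[(c.metric == "phospho_met_pct_nap")].iloc[0]
    print(f"{row.group_a} vs {row.group_b}: U={row.u_statistic:g} p={row.p_value:.4g}")
    print(f"tables written to {args.results} (exit {result.exit_code})")


if __name__ == "__main__":
    main()
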