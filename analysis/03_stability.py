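#!/usr/bin/env python
"""Bootstrap stability of the estimated network.

Case-dropping bootstrap of the centrality vectors (correlation-stability
coefficients; > 0.25 acceptable, > 0.5 good) and a nonparametric
bootstrap of the edge weights (95% percentile CIs).  Replication counts
are reduced relative to a production run of 500 to keep this driver
quick; pass --reps to change.

Outputs under results/stability/:
    correlations.csv, edge_bootstrap.csv, summary.json
"""

import argparse
import json
from pathlib import Path

from isingnet import ItemCodebook, load_responses
from isingnet.elasso import EstimationConfig
from isingnet.stability import case_drop_bootstrap, cs_coefficient, edge_bootstrap

ROOT = Path(__file__).resolve().parents[1]
FAST = EstimationConfig(n_lambda=30, lambda_min_ratio=0.05, tol=1e-5)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", type=Path, default=ROOT / "results" / "study")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "stability")
    ap.add_argument("--reps", type=int, default=50)
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cb = ItemCodebook.from_json(args.study / "codebook.json")
    X = load_responses(args.study / "responses.csv", cb)

    grid = (0.1, 0.25, 0.5, 0.75)
    res = case_drop_bootstrap(X, grid=grid, reps=args.reps, cfg=FAST, seed=args.seed)
    res.correlations.to_csv(args.out / "correlations.csv", index=False)
    cs = cs_coefficient(res)

    eb = edge_bootstrap(X, reps=args.reps, cfg=FAST, seed=args.seed + 1)
    eb.table.to_csv(args.out / "edge_bootstrap.csv", index=False)
    nonzero = eb.table[eb.table["observed"] != 0]
    frac_excl0 = float(((nonzero["ci_low"] > 0) | (nonzero["ci_high"] < 0)).mean())

    summary = {"cs_coefficient": cs, "reps": args.reps,
               "skipped": {str(k): v for k, v in res.n_skipped.items()},
               "frac_edges_ci_excluding_zero": frac_excl0}
    (args.out / "summary.json").write_text(json.dumps(summary, indent=1))

    print(f"case-dropping bootstrap ({args.reps} reps, grid {grid}):")
    for m, v in cs.items():
        verdict = "good" if v > 0.5 else ("acceptable" if v > 0.25 else "unstable")
        print(f"  CS[{m}] = {v:.2f} ({verdict})")
    print(f"{len(nonzero)} estimated edges; 95% CI excludes 0 for "
          f"{frac_excl0:.0%} of them")
    print(f"wrote {args.out}/correlations.csv, edge_bootstrap.csv, summary.json")


if __name__ == "__main__":
    main()
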