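#!/usr/bin/env python
"""Regenerate the shipped Gumbel calibration for per-hit P-values.

Aligns random fragment pairs from the tool's operating regime (9-14 aa
queries vs 50-300 aa targets, default scoring scheme) and fits the
score tail by censored maximum likelihood.  Writes the parameters, the
seed and the regime to src/spacerlink/data/gumbel_params.json.
"""

import argparse
import json
from pathlib import Path

from spacerlink.calibrate import calibrate


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n-pairs", type=int, default=100_000)
    ap.add_argument("--seed", type=int, default=20240801)
    ap.add_argument(
        "--out",
        default=Path(__file__).resolve().parents[1]
        / "src/spacerlink/data/gumbel_params.json",
    )
    args = ap.parse_args()
    record = calibrate(n_pairs=args.n_pairs, seed=args.seed)
    Path(args.out).write_text(json.dumps(record, indent=2) + "\n")
    print(json.dumps(record, indent=2))


if __name__ == "__main__":
    main()
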