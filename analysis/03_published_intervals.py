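#!/usr/bin/env python
"""Reproduce the published 95% confidence intervals from their printed
(r, n) pairs via the Fisher-z transform, and the printed two-sided p for the
histology-score panel. Writes results/published_intervals.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from sigstrat.association import correlation_p, fisher_ci

PANELS = [
    ("MYC vs MEIS1, microdissected cohort", -0.4321, 19),
    ("MYC vs HOXB13, full microdissected cohort", 0.6801, 69),
    ("MYC vs AR-activity score, full microdissected cohort", 0.7550, 69),
    ("MYC vs HOXB13, 499-sample cohort", 0.0894, 499),
    ("MYC vs AR-activity score, 499-sample cohort", 0.0567, 499),
    ("MEIS1 vs AR-activity score, 499-sample cohort", -0.3814, 499),
    ("MYC IHC vs Ki67 histology score", 0.4954, 20),
]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results/published_intervals.tsv"))
    args = parser.parse_args()

    rows = []
    for label, r, n in PANELS:
        lo, hi = fisher_ci(r, n, 0.95)
        rows.append(
            {
                "panel": label, "r": r, "n": n,
                "ci_low": round(lo, 4), "ci_high": round(hi, 4),
                "p_two_sided": round(correlation_p(r, n), 4),
            }
        )
    frame = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(args.out, sep="\t", index=False)
    print(frame.to_string(index=False))


if __name__ == "__main__":
    main()
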