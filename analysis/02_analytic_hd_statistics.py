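#!/usr/bin/env python
"""Chance-level Hamming-distance statistics for the three populations.

Computes the binomial HD theory (per-component difference probability
2p(1-p), mean, SD, expected overlap) for CA1 at its 0.14 operating
probability and for the CA3/EC input populations at their calibrated
activity levels, and quantifies how the exact fixed-count (hypergeometric)
law relates to the binomial approximation.  Writes results/analytic_hd.csv.
"""

from pathlib import Path

import pandas as pd

from ca1sep.hd_analysis import (
    binomial_hd_stats,
    exact_hd_moments,
    ks_normal_vs_exact,
    relative_sd_active,
)

OUT = Path(__file__).resolve().parents[1] / "results"

cases = [
    ("CA1", 23500, 0.14, "printed"),
    ("CA3", 28009, 1540 / 28009, "exact"),
    ("EC", 45073, 3086 / 45073, "exact"),
]
rows = []
for name, n, p, mode in cases:
    s = binomial_hd_stats(n, p, rounding=mode)
    rows.append({
        "population": name, "n": n, "p": round(p, 4), "pr_hd": round(s.pr_hd, 4),
        "mean_hd": s.mean_hd_int, "sd_hd": s.sd_hd_int,
        "expected_overlap": round(s.expected_overlap, 1), "n_active": s.n_active,
    })
df = pd.DataFrame(rows)
OUT.mkdir(exist_ok=True)
df.to_csv(OUT / "analytic_hd.csv", index=False)
print(df.to_string(index=False))

print(
    "\nPer-cell input variability (relative SD of the active-synapse count): "
    f"CA3 {relative_sd_active(0.055, 4407):.2f}% vs EC {relative_sd_active(0.0685, 1918):.2f}% "
    "- the EC pathway, with fewer synapses per cell, is the noisier one."
)
for name, n, k in [("CA3", 28009, 1540), ("EC", 45073, 3086)]:
    mean, sd = exact_hd_moments(n, k)
    binom = binomial_hd_stats(n, k / n)
    print(
        f"{name}: exact fixed-count law mean {mean:.1f} (binomial {binom.mean_hd:.1f}, "
        f"identical to O(1/n)); exact SD {sd:.1f} vs binomial {binom.sd_hd:.1f} - "
        "conditioning on the spike count shrinks the spread ~3x; "
        f"KS(normal approx, exact) = {ks_normal_vs_exact(n, k):.4f}"
    )
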