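"""Grouped sharing and isolation-by-distance summaries on a synthetic callset.

Builds a small synthetic callset in which within-group sharing dominates and
total shared segment length decays exponentially with geographic distance,
then runs the sharing-matrix, private-sharing and distance-regression
reports to show the expected signals are recovered.
"""

import numpy as np
import pandas as pd

import doubrcr.reporting as rp

rng = np.random.default_rng(3)

# 4 "countries" along the equator, 10 individuals each
groups, coords = [], []
for g in range(4):
    for _ in range(10):
        groups.append(f"country{g}")
        coords.append((0.0, 3.0 * g))
meta = pd.DataFrame(
    {
        "sample_id": [f"s{i}" for i in range(40)],
        "group": groups,
        "lat": [c[0] for c in coords],
        "lon": [c[1] for c in coords],
    }
)

rows = []
decay = 5e-4  # per-km decay of log shared length
for _ in range(3000):
    if rng.random() < 0.5:  # within-country pair
        g = rng.integers(4)
        a, b = rng.choice(np.arange(10 * g, 10 * g + 10), 2, replace=False)
    else:
        a, b = rng.choice(40, 2, replace=False)
    ga, gb = a // 10, b // 10
    dist = rp.haversine_km(0, 3.0 * ga, 0, 3.0 * gb)
    length = float(np.exp(9 - decay * dist + rng.normal(0, 0.1)))
    left = int(rng.integers(0, 1_000_000))
    rows.append(
        {"sample_a": f"s{a}", "sample_b": f"s{b}", "left_bound": left,
         "right_bound": left + int(length), "length": int(length)}
    )
callset = pd.DataFrame(rows)

raw, norm = rp.sharing_matrix(callset, meta)
print("row-normalized sharing matrix (within-country cells dominate):")
print(norm.round(2))

priv = rp.private_sharing(callset, meta)
print(f"\nwithin-country sharing: observed {priv['observed_private_fraction']:.2f} "
      f"vs random-pairing null {priv['null_private_fraction']:.2f}")

pl = rp.pair_total_lengths(callset)
res = rp.distance_regression(pl, meta, min_pairs=5)
fit = res["fit"]
print(f"\nln(shared length) vs distance: slope {fit['slope']:.2e} "
      f"+/- {fit['slope_se']:.1e} per km (true -{decay:.0e}), "
      f"R^2 {fit['r_squared']:.2f}, p {fit['p']:.2g}")
print("\nReading: relatedness signals — excess within-group sharing and the"
      "\ndecay of shared haplotype length with distance — survive the"
      "\ngrouped summaries, mirroring an isolation-by-distance analysis.")
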