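"""Grouped summaries over segment and callset tables.

Generic reimplementations of the downstream analyses that a called set of
single-origin doubletons supports: group-by-group sharing matrices,
binned/smoothed length-vs-position profiles, rank-sum comparisons of
length distributions with Holm correction, and isolation-by-distance
regressions of log haplotype length on great-circle distance.  All
operations are pure functions of their input tables (bit-identical reruns
given the same seed).
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km (haversine, Earth radius 6,371 km)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def load_metadata(path) -> pd.DataFrame:
    """Sample metadata TSV: sample_id, group, optional species/lat/lon."""
    md = pd.read_csv(path, sep="\t")
    if md["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    for col, lo, hi in (("lat", -90, 90), ("lon", -180, 180)):
        if col in md and ((md[col] < lo) | (md[col] > hi)).any():
            raise ValueError(f"{col} outside valid range")
    return md


def sharing_matrix(
    callset: pd.DataFrame,
    metadata: pd.DataFrame,
    downsample_to: int | None = None,
    seed: int | None = None,
) -> tuple:
    """Group × group shared-doubleton counts and a row-normalized copy.

    Each called doubleton contributes one count to the (group of carrier a,
    group of carrier b) cell; the raw matrix is symmetrized.  With
    ``downsample_to`` set, a seeded random subset of that many individuals
    is kept per group first (to remove unequal-sampling effects); a group
    smaller than the target is an error naming the group.  Rows of the
    normalized matrix sum to 1.
    """
    groups = metadata.set_index("sample_id")["group"]
    labels = sorted(groups.unique())
    keep = None
    if downsample_to is not None:
        rng = np.random.default_rng(seed)
        keep = set()
        for g in labels:
            members = metadata.loc[metadata["group"] == g, "sample_id"].tolist()
            if len(members) < downsample_to:
                raise ValueError(f"group {g!r} has {len(members)} < {downsample_to} members")
            keep.update(rng.choice(members, size=downsample_to, replace=False))
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for row in callset.itertuples(index=False):
        a, b = row.sample_a, row.sample_b
        if keep is not None and (a not in keep or b not in keep):
            continue
        ga, gb = groups[a], groups[b]
        mat.loc[ga, gb] += 1
        if ga != gb:
            mat.loc[gb, ga] += 1
    row_sums = mat.sum(axis=1)
    norm = mat.div(row_sums.replace(0, np.nan), axis=0)
    return mat, norm


def private_sharing(callset: pd.DataFrame, metadata: pd.DataFrame) -> dict:
    """Observed within-group sharing fraction vs. the random-pairing null.

    The null expectation is the chance two uniformly chosen distinct
    individuals fall in the same group: Σ_g C(n_g,2) / C(N,2).
    """
    groups = metadata.set_index("sample_id")["group"]
    same = np.array(
        [groups[r.sample_a] == groups[r.sample_b] for r in callset.itertuples(index=False)]
    )
    sizes = metadata.groupby("group").size()
    n = sizes.sum()
    null = float((sizes * (sizes - 1)).sum() / (n * (n - 1)))
    return {
        "observed_private_fraction": float(same.mean()),
        "null_private_fraction": null,
        "n_doubletons": int(len(same)),
    }


def length_by_position(
    segments: pd.DataFrame, bin_bp: int = 10_000, smooth_bins: int = 100
) -> pd.DataFrame:
    """Binned median segment length along the contig, per kind, smoothed.

    Segments are assigned to ``bin_bp`` bins by their midpoint; per-bin
    medians are taken for each kind ("doubleton" and "random"), then a
    centred rolling median over ``smooth_bins`` bins is applied.  Empty
    bins stay missing (NaN), never zero.  A ``difference`` column holds
    doubleton − random, bin-wise.
    """
    seg = segments.copy()
    seg["mid"] = (seg["left_bound"] + seg["right_bound"]) // 2
    seg["bin"] = (seg["mid"] // bin_bp) * bin_bp
    out = None
    for kind in ("doubleton", "random"):
        med = (
            seg[seg["kind"] == kind].groupby("bin")["length"].median().rename(kind)
        )
        out = med.to_frame() if out is None else out.join(med, how="outer")
    if out is None or out.empty:
        return pd.DataFrame(columns=["bin", "doubleton", "random", "difference"])
    out = out.sort_index()
    for kind in ("doubleton", "random"):
        if kind in out:
            out[f"{kind}_smoothed"] = (
                out[kind].rolling(smooth_bins, center=True, min_periods=1).median()
            )
    out["difference"] = out.get("doubleton") - out.get("random")
    return out.reset_index()


def _median_se(x: np.ndarray, method: str = "order_statistic", seed: int = 0) -> float:
    """SE of the median: binomial order-statistic CI width / (2·1.96), or a
    seeded bootstrap."""
    x = np.sort(np.asarray(x, float))
    n = len(x)
    if n < 2:
        return float("nan")
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        meds = np.median(x[rng.integers(0, n, size=(500, n))], axis=1)
        return float(np.std(meds, ddof=1))
    lo_k = stats.binom.ppf(0.025, n, 0.5)
    hi_k = stats.binom.ppf(0.975, n, 0.5)
    lo = x[int(max(lo_k - 1, 0))]
    hi = x[int(min(hi_k, n - 1))]
    return float((hi - lo) / (2 * 1.959963984540054))


def grouped_length_test(
    segments: pd.DataFrame,
    group_col: str = "group",
    length_col: str = "length",
    se_method: str = "order_statistic",
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests with Holm correction.

    Groups of size < 2 are excluded with a warning.  One row per group
    pair with the Mann–Whitney U statistic, raw and Holm-adjusted p, and
    each group's median ± SE.
    """
    from statsmodels.stats.multitest import multipletests

    sizes = segments.groupby(group_col).size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        logger.warning("groups excluded (size < 2): %s", small)
    groups = [g for g in sizes.index if g not in small]
    if len(groups) < 2:
        raise ValueError("need at least two groups of size >= 2")
    data = {g: segments.loc[segments[group_col] == g, length_col].to_numpy() for g in groups}
    rows = []
    for a, b in itertools.combinations(groups, 2):
        stat, p = stats.mannwhitneyu(data[a], data[b], alternative="two-sided")
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "statistic": float(stat),
                "p_raw": float(p),
                "median_a": float(np.median(data[a])),
                "median_a_se": _median_se(data[a], se_method),
                "median_b": float(np.median(data[b])),
                "median_b_se": _median_se(data[b], se_method),
            }
        )
    out = pd.DataFrame(rows)
    out["p_holm"] = multipletests(out["p_raw"], method="holm")[1]
    return out


def pair_total_lengths(callset: pd.DataFrame) -> pd.DataFrame:
    """Total unique shared segment length per individual pair.

    Unique segments (pair + bounds) are summed per pair, so a pair sharing
    several haplotypes contributes its combined length.
    """
    seg = callset.drop_duplicates(subset=["sample_a", "sample_b", "left_bound", "right_bound"])
    key = seg.apply(lambda r: tuple(sorted((r["sample_a"], r["sample_b"]))), axis=1)
    seg = seg.assign(pair=key)
    tot = seg.groupby("pair")["length"].sum().reset_index()
    tot[["sample_a", "sample_b"]] = pd.DataFrame(tot["pair"].tolist(), index=tot.index)
    return tot[["sample_a", "sample_b", "length"]]


def distance_regression(
    pair_lengths: pd.DataFrame,
    metadata: pd.DataFrame,
    min_pairs: int = 10,
    species_col: str | None = None,
) -> dict:
    """Isolation by distance: OLS of ln(mean total shared length) on km.

    Individual pairs are grouped by their (group_a, group_b) country pair;
    pairs of groups with fewer than ``min_pairs`` individual pairs are
    excluded.  Distances are haversine between per-group mean coordinates.
    With ``species_col`` given, one regression per species plus an
    interaction-term test for a slope difference.  Refuses to fit fewer
    than 3 group-pair points.
    """
    import statsmodels.formula.api as smf

    md = metadata.set_index("sample_id")
    coords = metadata.groupby("group")[["lat", "lon"]].mean()

    recs = []
    for r in pair_lengths.itertuples(index=False):
        ga, gb = md.loc[r.sample_a, "group"], md.loc[r.sample_b, "group"]
        if ga == gb:
            continue
        rec = {"pair": tuple(sorted((ga, gb))), "length": r.length}
        if species_col:
            sa, sb = md.loc[r.sample_a, species_col], md.loc[r.sample_b, species_col]
            if sa != sb:
                continue
            rec["species"] = sa
        recs.append(rec)
    df = pd.DataFrame(recs)
    if df.empty:
        raise ValueError("no between-group pairs to regress")
    by = ["species", "pair"] if species_col else ["pair"]
    agg = df.groupby(by).agg(mean_length=("length", "mean"), n=("length", "size")).reset_index()
    agg = agg[agg["n"] >= min_pairs]
    agg["distance_km"] = [
        haversine_km(
            coords.loc[p[0], "lat"], coords.loc[p[0], "lon"],
            coords.loc[p[1], "lat"], coords.loc[p[1], "lon"],
        )
        for p in agg["pair"]
    ]
    agg["ln_length"] = np.log(agg["mean_length"])

    def fit(sub):
        if len(sub) < 3:
            raise ValueError("fewer than 3 group-pair points; regression refused")
        res = smf.ols("ln_length ~ distance_km", data=sub).fit()
        return {
            "slope": float(res.params["distance_km"]),
            "slope_se": float(res.bse["distance_km"]),
            "r_squared": float(res.rsquared),
            "p": float(res.pvalues["distance_km"]),
            "n_points": int(len(sub)),
        }

    out: dict = {"points": agg}
    if species_col:
        out["per_species"] = {
            sp: fit(agg[agg["species"] == sp]) for sp in agg["species"].unique()
        }
        if agg["species"].nunique() > 1:
            inter = smf.ols("ln_length ~ distance_km * C(species)", data=agg).fit()
            pcols = [c for c in inter.pvalues.index if c.startswith("distance_km:")]
            out["slope_difference_p"] = float(inter.pvalues[pcols[0]])
    else:
        out["fit"] = fit(agg)
    return out


def plot_posterior_curve(curve_table: pd.DataFrame, path) -> None:
    """Posterior and LRV-proportion curves vs. allele-count threshold."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    ax1.plot(curve_table["n"], curve_table["p_lrv_d_cum"], "o-", label="doubleton pairs")
    ax1.plot(curve_table["n"], curve_table["p_lrv_nd_cum"], "s-", label="random pairs")
    ax1.set_xlabel("LRV allele-count threshold n")
    ax1.set_ylabel("P[shared LRV ≤ n]")
    ax1.legend(frameon=False)
    ax2.plot(curve_table["n"], curve_table["posterior_cum"], "o-", color="firebrick")
    ax2.set_xlabel("LRV allele-count threshold n")
    ax2.set_ylabel("posterior P[RCR | d, LRV]")
    ax2.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_length_profile(profile: pd.DataFrame, path) -> None:
    """Smoothed median segment length along the contig, per kind."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3.5))
    for kind, color in (("doubleton", "firebrick"), ("random", "steelblue")):
        col = f"{kind}_smoothed"
        if col in profile:
            ax.plot(profile["bin"] / 1e6, profile[col] / 1e3, color=color, label=kind)
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel("median segment length (kb)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
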