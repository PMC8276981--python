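"""DMC calling and merging of proximal DMCs into regions (DMRs).

A DMC is a single CpG with pooled coverage >= min_cov in both groups, a
group difference of at least min_diff percentage points and BH q below the
configured threshold.  Same-direction DMCs within ``gap`` bp of each other
(inclusive) merge transitively; clusters of two or more become DMRs,
clusters of one are reported as single CpGs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from methylkin.constants import DEFAULTS
from methylkin.io import SampleCallSet
from methylkin.stats import (bh_adjust, estimate_common_dispersion,
                             fisher_pooled_many, gtest_pooled)
from methylkin.tiling import _stack_callsets

DMC_COLUMNS = ("chrom", "pos", "strand", "meth_ctrl", "cov_ctrl",
               "meth_mut", "cov_mut", "pct_control", "pct_mutant",
               "diff", "p", "q", "direction")

DMR_COLUMNS = ("chrom", "start", "end", "n_dmcs", "mean_diff", "size")


def call_dmcs(control: list[SampleCallSet], mutant: list[SampleCallSet],
              min_cov: int = DEFAULTS["min_cov"],
              min_diff: float = DEFAULTS["min_diff"],
              q_threshold: float = DEFAULTS["q_threshold"],
              method: str = "logistic",
              overdispersion: str = "mn") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-CpG differential test on pooled group counts.

    A CpG is tested iff its pooled coverage reaches min_cov in **both**
    groups (pooled-per-group rule, unlike the per-sample tile rule).  BH is
    applied jointly across tested CpGs.  ``overdispersion='mn'`` applies the
    common variance-inflation correction estimated from replicate
    residuals.  Returns ``(tested_sites, dmcs)``.
    """
    if not control or not mutant:
        raise ValueError("both groups need at least one call set")
    if overdispersion not in ("mn", "none"):
        raise ValueError("overdispersion must be 'mn' or 'none'")
    sites, meth, cov, ids = _stack_callsets(list(control) + list(mutant))
    is_control = np.array([i < len(control) for i in range(len(ids))])
    out = sites.copy()
    out["meth_ctrl"] = meth[:, is_control].sum(axis=1)
    out["cov_ctrl"] = cov[:, is_control].sum(axis=1)
    out["meth_mut"] = meth[:, ~is_control].sum(axis=1)
    out["cov_mut"] = cov[:, ~is_control].sum(axis=1)
    testable = ((out["cov_ctrl"] >= min_cov) & (out["cov_mut"] >= min_cov)).to_numpy()
    out = out[testable].reset_index(drop=True)
    meth, cov = meth[testable], cov[testable]
    if len(out) == 0:
        empty = pd.DataFrame(columns=list(DMC_COLUMNS))
        return empty, empty.copy()
    m1 = out["meth_ctrl"].to_numpy(float)
    n1 = out["cov_ctrl"].to_numpy(float)
    m2 = out["meth_mut"].to_numpy(float)
    n2 = out["cov_mut"].to_numpy(float)
    out["pct_control"] = 100.0 * m1 / n1
    out["pct_mutant"] = 100.0 * m2 / n2
    out["diff"] = out["pct_mutant"] - out["pct_control"]
    if method == "logistic":
        stat, p = gtest_pooled(m1, n1, m2, n2)
        if overdispersion == "mn":
            dispersion = estimate_common_dispersion(meth, cov, is_control)
            if dispersion > 1.0:
                from scipy import stats as sps
                p = sps.chi2.sf(stat / dispersion, df=1)
    elif method == "fisher_pooled":
        p = fisher_pooled_many(m1, n1, m2, n2)
    else:
        raise ValueError(f"unknown test method {method!r}")
    out["p"] = p
    out["q"] = bh_adjust(out["p"].to_numpy())
    is_dmc = (out["q"] < q_threshold) & (out["diff"].abs() >= min_diff)
    dmcs = out[is_dmc].copy()
    dmcs["direction"] = np.where(dmcs["diff"] < 0, "hypo", "hyper")
    return out, dmcs.reset_index(drop=True)


def merge_dmcs(dmcs: pd.DataFrame, gap: int = DEFAULTS["gap"],
               direction: str = "hypo") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge proximal same-direction DMCs into DMRs.

    Consecutive DMCs whose positions differ by at most ``gap`` bp join one
    cluster (transitively).  Clusters with >= 2 members become DMRs spanning
    the first to the last member C (0-based half-open, so size counts both
    end CpGs); single-member clusters are returned separately.

    The input must be single-direction; pass ``direction`` matching the
    ``direction`` column (mixed input raises).
    """
    if "direction" in dmcs.columns and len(dmcs) > 0:
        present = set(dmcs["direction"].unique())
        if not present <= {direction}:
            raise ValueError(
                f"mixed or mismatched directions {sorted(present)}; split "
                f"the DMC set by direction before merging")
    if len(dmcs) == 0:
        return (pd.DataFrame(columns=list(DMR_COLUMNS)),
                dmcs.copy())
    df = dmcs.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    new_cluster = np.ones(len(df), dtype=bool)
    same_chrom = df["chrom"].to_numpy()[1:] == df["chrom"].to_numpy()[:-1]
    close = np.diff(df["pos"].to_numpy()) <= gap
    new_cluster[1:] = ~(same_chrom & close)
    cluster_id = np.cumsum(new_cluster) - 1
    df["_cluster"] = cluster_id
    agg = df.groupby("_cluster").agg(
        chrom=("chrom", "first"),
        first_pos=("pos", "min"),
        last_pos=("pos", "max"),
        n_dmcs=("pos", "size"),
        mean_diff=("diff", "mean"),
    )
    is_region = agg["n_dmcs"] >= 2
    dmrs = agg[is_region].copy()
    dmrs["start"] = dmrs["first_pos"] - 1     # 0-based first C
    dmrs["end"] = dmrs["last_pos"]            # half-open past last C
    dmrs["size"] = dmrs["end"] - dmrs["start"]
    dmrs = dmrs[list(DMR_COLUMNS)].reset_index(drop=True)
    single_clusters = agg.index[~is_region]
    singles = df[df["_cluster"].isin(single_clusters)].drop(columns="_cluster")
    return dmrs, singles.reset_index(drop=True)


def size_classes(dmrs: pd.DataFrame, cut: int = 100) -> dict:
    """Partition DMR sizes at ``cut`` (lower class includes the cut).

    Returns counts {'le_cut', 'gt_cut'}, the max size and the raw sizes.
    """
    if len(dmrs) == 0:
        return {"cut": cut, "le_cut": 0, "gt_cut": 0, "max_size": 0,
                "sizes": np.empty(0, dtype=int)}
    sizes = dmrs["size"].to_numpy(int)
    le = int((sizes <= cut).sum())
    return {"cut": cut, "le_cut": le, "gt_cut": int(len(sizes) - le),
            "max_size": int(sizes.max()), "sizes": sizes}


def compare_size_classes(a: dict, b: dict) -> tuple[float, float]:
    """Chi-square on the 2x2 of {<=cut, >cut} counts between two cohorts."""
    from methylkin.stats import chi2_2x2

    return chi2_2x2(a["le_cut"], a["gt_cut"], b["le_cut"], b["gt_cut"])
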