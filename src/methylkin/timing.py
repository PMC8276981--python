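"""Developmental methylation-timing analysis.

Quantifies mean methylation of region sets across ordered timepoints
against a random genome-bin background, classifies early vs late de novo
methylation, computes RPKM from histone read intervals and joins the two
signals per region.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from methylkin.constants import DEFAULTS, TIMEPOINTS
from methylkin.intervals import IntervalIndex
from methylkin.io import SampleCallSet


def bin_genome(chrom_sizes: dict[str, int],
               bin_size: int = DEFAULTS["genome_bin"]) -> pd.DataFrame:
    """Non-overlapping genome bins; a trailing partial bin is kept only when
    it is at least half a bin long."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    for chrom, length in chrom_sizes.items():
        full = length // bin_size
        for k in range(full):
            rows.append((chrom, k * bin_size, (k + 1) * bin_size))
        rest = length - full * bin_size
        if rest >= bin_size / 2:
            rows.append((chrom, full * bin_size, length))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def region_methylation(regions: pd.DataFrame, callset: SampleCallSet,
                       min_cov: int = DEFAULTS["track_min_cov"]) -> np.ndarray:
    """Coverage-weighted mean percent methylation per region.

    100 * sum(meth) / sum(cov) over CpGs with cov >= min_cov whose 0-based
    position falls in the region; NaN when no CpG is eligible.
    """
    out = np.full(len(regions), np.nan)
    sites = callset.sites
    sites = sites[sites["cov"] >= min_cov]
    if len(sites) == 0 or len(regions) == 0:
        return out
    for chrom, sub in sites.groupby("chrom", sort=False):
        sel = regions["chrom"] == chrom
        if not sel.any():
            continue
        pos0 = sub["pos"].to_numpy(np.int64) - 1
        order = np.argsort(pos0, kind="mergesort")
        pos0 = pos0[order]
        cmeth = np.concatenate([[0], np.cumsum(sub["meth"].to_numpy(np.int64)[order])])
        ccov = np.concatenate([[0], np.cumsum(sub["cov"].to_numpy(np.int64)[order])])
        idx = np.nonzero(sel.to_numpy())[0]
        lo = np.searchsorted(pos0, regions["start"].to_numpy(np.int64)[idx], "left")
        hi = np.searchsorted(pos0, regions["end"].to_numpy(np.int64)[idx], "left")
        meth = cmeth[hi] - cmeth[lo]
        cov = ccov[hi] - ccov[lo]
        with np.errstate(invalid="ignore"):
            vals = np.where(cov > 0, 100.0 * meth / np.maximum(cov, 1), np.nan)
        out[idx] = vals
    return out


def trajectory_matrix(regions: pd.DataFrame,
                      tracks: dict[str, SampleCallSet],
                      timepoints=TIMEPOINTS,
                      min_cov: int = DEFAULTS["track_min_cov"]) -> pd.DataFrame:
    """Region x timepoint mean-methylation matrix (NaN = no eligible CpG)."""
    cols = {}
    for tp in timepoints:
        if tp not in tracks:
            raise KeyError(f"missing track for timepoint {tp!r}")
        cols[tp] = region_methylation(regions, tracks[tp], min_cov=min_cov)
    return pd.DataFrame(cols, index=regions.index)


def sample_background(bins: pd.DataFrame, n: int = DEFAULTS["background_n"],
                      seed: int = 0) -> pd.DataFrame:
    """Uniform sample of genome bins without replacement, seed-reproducible."""
    if n > len(bins):
        raise ValueError(f"requested {n} bins but only {len(bins)} exist")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(bins), size=n, replace=False)
    idx.sort()
    return bins.iloc[idx].reset_index(drop=True)


def classify_timing(trajectory,
                    late_max_e16: float = DEFAULTS["late_max_e16"],
                    min_gain: float = DEFAULTS["min_gain"],
                    early_min_e16: float = DEFAULTS["early_min_e16"]) -> str:
    """'late', 'early' or 'ambiguous' from an ordered 4-point trajectory.

    The second value is the E16.5 analog and the last the sperm analog:
    late iff e16 <= late_max_e16 and final - e16 >= min_gain; early iff
    e16 >= early_min_e16; a missing E16.5 value is ambiguous.
    """
    vals = np.asarray(trajectory, dtype=float)
    if vals.size != 4:
        raise ValueError("trajectory must have exactly four timepoints")
    e16, final = vals[1], vals[3]
    if np.isnan(e16):
        return "ambiguous"
    if e16 <= late_max_e16 and not np.isnan(final) and final - e16 >= min_gain:
        return "late"
    if e16 >= early_min_e16:
        return "early"
    return "ambiguous"


def classify_timing_matrix(matrix: pd.DataFrame, **kw) -> pd.Series:
    return pd.Series([classify_timing(row, **kw) for row in matrix.to_numpy()],
                     index=matrix.index, name="timing")


def top_by_size(dmrs: pd.DataFrame, n: int = 200) -> pd.DataFrame:
    """Largest-n regions by bp size, ties broken by leftmost coordinate."""
    df = dmrs.copy()
    if "size" not in df.columns:
        df["size"] = df["end"] - df["start"]
    df = df.sort_values(["size", "chrom", "start"],
                        ascending=[False, True, True], kind="mergesort")
    return df.head(n).reset_index(drop=True)


def rpkm(regions: pd.DataFrame, reads: pd.DataFrame, library_size: int) -> np.ndarray:
    """Reads-per-kilobase-per-million over each region.

    ``reads`` are intervals (chrom, start, end); a read counts when it
    overlaps the region by at least 1 bp.
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    out = np.zeros(len(regions), dtype=float)
    if len(regions) == 0:
        return out
    if len(reads) > 0:
        index = IntervalIndex.from_frame(reads)
        counts = index.count_overlapping(regions)
    else:
        counts = np.zeros(len(regions), dtype=np.int64)
    lengths_kb = (regions["end"].to_numpy(float) - regions["start"].to_numpy(float)) / 1000.0
    return counts / (lengths_kb * library_size / 1e6)


def joint_profile(regions: pd.DataFrame, callset: SampleCallSet,
                  chip_reads: pd.DataFrame, library_size: int,
                  min_cov: int = DEFAULTS["track_min_cov"]) -> pd.DataFrame:
    """Row-aligned (percent methylation, RPKM) pairs for one timepoint."""
    meth = region_methylation(regions, callset, min_cov=min_cov)
    signal = rpkm(regions, chip_reads, library_size)
    return pd.DataFrame({"meth": meth, "rpkm": signal}, index=regions.index)


def ko_comparison(regions: pd.DataFrame, callset_wt: SampleCallSet,
                  callset_ko: SampleCallSet,
                  min_cov: int = DEFAULTS["track_min_cov"],
                  drop_threshold: float = DEFAULTS["drop_threshold"]) -> dict:
    """Per-region (WT%, KO%) pairs and the fraction dropped below diagonal.

    The dropped fraction counts pairs with WT - KO >= drop_threshold among
    regions where both tracks have eligible CpGs.
    """
    wt = region_methylation(regions, callset_wt, min_cov=min_cov)
    ko = region_methylation(regions, callset_ko, min_cov=min_cov)
    pairs = pd.DataFrame({"wt": wt, "ko": ko}, index=regions.index)
    valid = ~(np.isnan(wt) | np.isnan(ko))
    n_valid = int(valid.sum())
    dropped = int(((wt - ko) >= drop_threshold)[valid].sum())
    return {
        "pairs": pairs,
        "n_valid": n_valid,
        "n_dropped": dropped,
        "dropped_fraction": dropped / n_valid if n_valid else float("nan"),
    }
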