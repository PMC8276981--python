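"""Differentially methylated tile (DMT) calling.

Fixed, non-overlapping 100 bp windows; a window is testable when it holds at
least ``min_cpgs`` CpGs covered at ``min_cov`` or better in every sample of
both groups; group difference is tested per window, BH-corrected jointly
across all tested windows, and a window is a DMT when q < q_threshold and
the pooled difference is at least ``min_diff`` percentage points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from methylkin.constants import DEFAULTS, MAGNITUDE_BINS
from methylkin.io import SampleCallSet
from methylkin.stats import (bh_adjust, estimate_common_dispersion,
                             fisher_pooled, fisher_pooled_many, gtest_pooled)

TILE_COLUMNS = ("chrom", "start", "end", "n_cpgs",
                "meth_ctrl", "cov_ctrl", "meth_mut", "cov_mut")


@dataclass
class TileData:
    """Per-site count matrices joined across samples, with tile assignment.

    ``meth``/``cov`` are (n_sites, n_samples) arrays over the union of
    sites; absent sites carry zero coverage.
    """

    sites: pd.DataFrame            # chrom, pos, strand, tile_start
    meth: np.ndarray
    cov: np.ndarray
    samples: list[str]
    is_control: np.ndarray         # bool per sample column
    tile_size: int

    @property
    def n_tiles(self) -> int:
        if len(self.sites) == 0:
            return 0
        return len(self.sites.drop_duplicates(["chrom", "tile_start"]))


def _stack_callsets(callsets: list[SampleCallSet]) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, list[str]]:
    ids = [cs.sample_id for cs in callsets]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id across call sets")
    frames = []
    for cs in callsets:
        frames.append(cs.sites.assign(sample=cs.sample_id))
    big = pd.concat(frames, ignore_index=True)
    wide_cov = (big.set_index(["chrom", "pos", "strand", "sample"])["cov"]
                .unstack("sample", fill_value=0).reindex(columns=ids, fill_value=0))
    wide_meth = (big.set_index(["chrom", "pos", "strand", "sample"])["meth"]
                 .unstack("sample", fill_value=0).reindex(columns=ids, fill_value=0))
    sites = wide_cov.index.to_frame(index=False)
    return sites, wide_meth.to_numpy(np.int64), wide_cov.to_numpy(np.int64), ids


def build_tiles(control: list[SampleCallSet], mutant: list[SampleCallSet],
                tile_size: int = DEFAULTS["tile_size"],
                step: int = DEFAULTS["step"]) -> TileData:
    """Assign every CpG of every sample to its non-overlapping window.

    A CpG at 1-based position p belongs to the window starting at
    ``floor((p - 1) / tile_size) * tile_size`` (0-based half-open grid).
    Only ``step == tile_size`` is supported.
    """
    if step != tile_size:
        raise ValueError("stepwise tiling requires step == tile_size in v1")
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    if not control or not mutant:
        raise ValueError("both groups need at least one call set")
    sites, meth, cov, ids = _stack_callsets(list(control) + list(mutant))
    is_control = np.array([i < len(control) for i in range(len(ids))])
    sites = sites.copy()
    sites["tile_start"] = ((sites["pos"] - 1) // tile_size) * tile_size
    return TileData(sites=sites, meth=meth, cov=cov, samples=ids,
                    is_control=is_control, tile_size=tile_size)


def filter_tiles(data: TileData, min_cpgs: int = DEFAULTS["min_cpgs"],
                 min_cov: int = DEFAULTS["min_cov"]) -> pd.DataFrame:
    """Eligible tiles with pooled per-group counts.

    A CpG is eligible iff its coverage is >= min_cov in **every** sample of
    both groups; a tile is retained iff it has >= min_cpgs eligible CpGs.
    """
    if len(data.sites) == 0:
        return pd.DataFrame(columns=list(TILE_COLUMNS))
    eligible = (data.cov >= min_cov).all(axis=1)
    sub = data.sites.loc[eligible, ["chrom", "tile_start"]].copy()
    if len(sub) == 0:
        return pd.DataFrame(columns=list(TILE_COLUMNS))
    meth_c = data.meth[:, data.is_control][eligible].sum(axis=1)
    cov_c = data.cov[:, data.is_control][eligible].sum(axis=1)
    meth_m = data.meth[:, ~data.is_control][eligible].sum(axis=1)
    cov_m = data.cov[:, ~data.is_control][eligible].sum(axis=1)
    sub["meth_ctrl"] = meth_c
    sub["cov_ctrl"] = cov_c
    sub["meth_mut"] = meth_m
    sub["cov_mut"] = cov_m
    grouped = sub.groupby(["chrom", "tile_start"], sort=True)
    tiles = grouped.agg(
        n_cpgs=("meth_ctrl", "size"),
        meth_ctrl=("meth_ctrl", "sum"),
        cov_ctrl=("cov_ctrl", "sum"),
        meth_mut=("meth_mut", "sum"),
        cov_mut=("cov_mut", "sum"),
    ).reset_index()
    tiles = tiles[tiles["n_cpgs"] >= min_cpgs].reset_index(drop=True)
    tiles = tiles.rename(columns={"tile_start": "start"})
    tiles["end"] = tiles["start"] + data.tile_size
    return tiles[list(TILE_COLUMNS)]


def tile_sample_counts(data: TileData, tiles: pd.DataFrame,
                       min_cov: int = DEFAULTS["min_cov"]) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample (meth, cov) sums over eligible CpGs, row-aligned to tiles.

    Used to estimate the common overdispersion factor from within-group
    replicate variation.
    """
    eligible = (data.cov >= min_cov).all(axis=1)
    sub = data.sites.loc[eligible, ["chrom", "tile_start"]]
    key = pd.MultiIndex.from_frame(sub)
    want = pd.MultiIndex.from_frame(tiles[["chrom", "start"]])
    n_samples = data.meth.shape[1]
    meth_out = np.zeros((len(tiles), n_samples), dtype=np.int64)
    cov_out = np.zeros((len(tiles), n_samples), dtype=np.int64)
    if len(sub) == 0 or len(tiles) == 0:
        return meth_out, cov_out
    meth_df = pd.DataFrame(data.meth[eligible], index=key)
    cov_df = pd.DataFrame(data.cov[eligible], index=key)
    meth_sum = meth_df.groupby(level=[0, 1]).sum()
    cov_sum = cov_df.groupby(level=[0, 1]).sum()
    meth_out = meth_sum.reindex(want, fill_value=0).to_numpy(np.int64)
    cov_out = cov_sum.reindex(want, fill_value=0).to_numpy(np.int64)
    return meth_out, cov_out


def test_tile(tile, method: str = "logistic") -> tuple[float, float]:
    """(p, diff) for one tile row (mapping with the pooled count fields).

    ``logistic``: likelihood-ratio test of the group effect in a binomial
    logistic model (collapses to the pooled G-test; see stats.gtest_pooled).
    ``fisher_pooled``: two-sided exact test on the pooled 2x2.
    diff = pooled mutant percent - pooled control percent.
    """
    m1, n1 = int(tile["meth_ctrl"]), int(tile["cov_ctrl"])
    m2, n2 = int(tile["meth_mut"]), int(tile["cov_mut"])
    if n1 <= 0 or n2 <= 0:
        return float("nan"), float("nan")
    diff = 100.0 * (m2 / n2 - m1 / n1)
    if method == "logistic":
        _, p = gtest_pooled(np.array([m1]), np.array([n1]),
                            np.array([m2]), np.array([n2]))
        p = float(p[0])
    elif method == "fisher_pooled":
        p = fisher_pooled(m1, n1, m2, n2)
    else:
        raise ValueError(f"unknown test method {method!r}")
    return p, diff


def test_tiles(tiles: pd.DataFrame, method: str = "logistic",
               dispersion: float = 1.0) -> pd.DataFrame:
    """Vectorised per-tile test; adds pct/diff/p/status columns.

    ``dispersion`` > 1 scales the likelihood-ratio statistic down by the
    overdispersion factor (ignored by the exact test).
    """
    tiles = tiles.copy()
    if len(tiles) == 0:
        for col in ("pct_control", "pct_mutant", "diff", "p"):
            tiles[col] = pd.Series(dtype=float)
        tiles["status"] = pd.Series(dtype=str)
        return tiles
    m1 = tiles["meth_ctrl"].to_numpy(float)
    n1 = tiles["cov_ctrl"].to_numpy(float)
    m2 = tiles["meth_mut"].to_numpy(float)
    n2 = tiles["cov_mut"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct1 = np.where(n1 > 0, 100.0 * m1 / n1, np.nan)
        pct2 = np.where(n2 > 0, 100.0 * m2 / n2, np.nan)
    if method == "logistic":
        stat, p = gtest_pooled(m1, n1, m2, n2)
        if dispersion > 1.0:
            from scipy import stats as sps
            p = sps.chi2.sf(stat / dispersion, df=1)
    elif method == "fisher_pooled":
        p = fisher_pooled_many(m1, n1, m2, n2)
    else:
        raise ValueError(f"unknown test method {method!r}")
    tiles["pct_control"] = pct1
    tiles["pct_mutant"] = pct2
    tiles["diff"] = pct2 - pct1
    tiles["p"] = p
    tiles["status"] = np.where((n1 > 0) & (n2 > 0), "tested", "not_tested")
    return tiles


def call_dmts(tiles: pd.DataFrame,
              q_threshold: float = DEFAULTS["q_threshold"],
              min_diff: float = DEFAULTS["min_diff"]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """BH-correct tested tiles jointly and call DMTs.

    Returns ``(tiles_with_q, dmts)``; DMTs carry a ``direction`` column
    (hypo iff diff < 0).
    """
    tiles = tiles.copy()
    tested = tiles["status"] == "tested" if "status" in tiles else pd.Series(
        False, index=tiles.index)
    tiles["q"] = np.nan
    if tested.sum() == 0:
        warnings.warn("no tested tiles; DMT set is empty", stacklevel=2)
        dmts = tiles.iloc[0:0].copy()
        dmts["direction"] = pd.Series(dtype=str)
        return tiles, dmts
    tiles.loc[tested, "q"] = bh_adjust(tiles.loc[tested, "p"].to_numpy())
    is_dmt = tested & (tiles["q"] < q_threshold) & (tiles["diff"].abs() >= min_diff)
    dmts = tiles[is_dmt].copy()
    dmts["direction"] = np.where(dmts["diff"] < 0, "hypo", "hyper")
    return tiles, dmts.reset_index(drop=True)


def dmt_workflow(control: list[SampleCallSet], mutant: list[SampleCallSet],
                 tile_size: int = DEFAULTS["tile_size"],
                 min_cpgs: int = DEFAULTS["min_cpgs"],
                 min_cov: int = DEFAULTS["min_cov"],
                 min_diff: float = DEFAULTS["min_diff"],
                 q_threshold: float = DEFAULTS["q_threshold"],
                 method: str = "logistic",
                 overdispersion: str = "mn") -> dict:
    """build -> filter -> test -> call, returning all intermediates.

    ``overdispersion='mn'`` (default) scales the logistic LRT by a common
    variance-inflation factor estimated from within-group replicate
    residuals, which keeps the false-positive rate controlled on
    overdispersed counts; 'none' uses the plain binomial test.
    """
    if overdispersion not in ("mn", "none"):
        raise ValueError("overdispersion must be 'mn' or 'none'")
    data = build_tiles(control, mutant, tile_size=tile_size, step=tile_size)
    eligible = filter_tiles(data, min_cpgs=min_cpgs, min_cov=min_cov)
    dispersion = 1.0
    if overdispersion == "mn" and method == "logistic" and len(eligible) > 0:
        meth2d, cov2d = tile_sample_counts(data, eligible, min_cov=min_cov)
        dispersion = estimate_common_dispersion(meth2d, cov2d, data.is_control)
    tested = test_tiles(eligible, method=method, dispersion=dispersion)
    with warnings.catch_warnings():
        if len(tested) == 0:
            warnings.simplefilter("ignore")
        tiles, dmts = call_dmts(tested, q_threshold=q_threshold,
                                min_diff=min_diff)
    return {"tile_data": data, "tiles": tiles, "dmts": dmts,
            "dispersion": dispersion}


def magnitude_histogram(dmts: pd.DataFrame,
                        edges: tuple[float, ...] = MAGNITUDE_BINS) -> dict[str, int]:
    """Counts of |diff| per magnitude bin (lower-inclusive, upper-exclusive).

    Default bins: 10-15, 15-20, 20-25, 25-30, 30-40 and >40 percentage
    points.  Counts sum to the number of DMTs (values below the first edge,
    impossible at the default min_diff, are clipped into the first bin).
    """
    labels = [f"{edges[i]:g}-{edges[i + 1]:g}" for i in range(len(edges) - 1)]
    labels.append(f">{edges[-1]:g}")
    if len(dmts) == 0:
        return {lab: 0 for lab in labels}
    mags = np.clip(dmts["diff"].abs().to_numpy(float), edges[0], None)
    counts, _ = np.histogram(mags, bins=list(edges) + [np.inf])
    return dict(zip(labels, counts.astype(int).tolist()))
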