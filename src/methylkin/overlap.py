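"""Cross-cohort set operations on tiles and regions.

Tile intersections are exact (chrom, start) identity on the 100 bp grid;
region overlaps use interval search with a four-way nesting taxonomy
(identical / nested either way / partial) plus disjoint.
"""

from __future__ import annotations

import pandas as pd

from methylkin.intervals import IntervalIndex
from methylkin.stats import floor_percent, proportion

OVERLAP_CLASSES = ("identical", "b_within_a", "a_within_b", "partial", "disjoint")


def _tile_keys(tiles: pd.DataFrame, tile_size: int | None) -> set[tuple[str, int]]:
    if len(tiles) == 0:
        return set()
    starts = tiles["start"]
    if tile_size is not None and (starts % tile_size != 0).any():
        bad = tiles[starts % tile_size != 0].iloc[0]
        raise ValueError(
            f"off-grid tile {bad['chrom']}:{bad['start']} (grid {tile_size})")
    return set(zip(tiles["chrom"], starts.astype(int)))


def intersect_tiles(set_a: pd.DataFrame, set_b: pd.DataFrame,
                    tile_size: int = 100) -> dict:
    """Partition two tile sets into shared / A-only / B-only by grid key."""
    keys_a = _tile_keys(set_a, tile_size)
    keys_b = _tile_keys(set_b, tile_size)
    shared = keys_a & keys_b
    out = {
        "n_a": len(keys_a),
        "n_b": len(keys_b),
        "shared": len(shared),
        "a_only": len(keys_a - keys_b),
        "b_only": len(keys_b - keys_a),
        "shared_keys": shared,
    }
    if out["n_b"] > 0:
        out["pct_b_shared"] = proportion(out["shared"], out["n_b"])
    if out["n_a"] > 0:
        out["pct_a_shared"] = proportion(out["shared"], out["n_a"])
    return out


def classify_pair(a, b) -> str:
    """Nesting taxonomy for one interval pair.

    Accepts (chrom, start, end) tuples or objects with those attributes.
    Exactly one of identical / b_within_a / a_within_b / partial / disjoint
    holds; 'identical' requires exact coordinate identity (reciprocal 100%
    overlap), containment excludes identity.
    """
    ac, as_, ae = _coords(a)
    bc, bs, be = _coords(b)
    if ac != bc:
        return "disjoint"
    overlap = min(ae, be) - max(as_, bs)
    if overlap <= 0:
        return "disjoint"
    if as_ == bs and ae == be:
        return "identical"
    if as_ <= bs and be <= ae:
        return "b_within_a"
    if bs <= as_ and ae <= be:
        return "a_within_b"
    return "partial"


def _coords(x):
    if isinstance(x, tuple):
        return x[0], int(x[1]), int(x[2])
    return x.chrom, int(x.start), int(x.end)


def overlap_dmr_sets(set_a: pd.DataFrame, set_b: pd.DataFrame) -> dict:
    """Pair each B region with its best-overlapping A region and classify.

    A B region overlapping at least one A region counts once toward the
    shared total; its class is assigned against the A partner of maximal
    overlap length (ties: leftmost A start).  Percentages use B (the
    later-generation set) as denominator.
    """
    pairs = pd.DataFrame(columns=["b_index", "a_index", "overlap", "klass"])
    rows = []
    if len(set_a) > 0 and len(set_b) > 0:
        a = set_a.reset_index(drop=True)
        index = IntervalIndex.from_frame(a)
        for bi, brow in enumerate(set_b.reset_index(drop=True).itertuples(index=False)):
            hits, lengths = index.overlap_lengths(
                brow.chrom, int(brow.start), int(brow.end))
            if len(hits) == 0:
                continue
            # maximal overlap, ties by leftmost A start
            best, best_len, best_start = None, -1, None
            for ai, ov in zip(hits, lengths):
                astart = int(a.at[ai, "start"])
                if ov > best_len or (ov == best_len and astart < best_start):
                    best, best_len, best_start = int(ai), int(ov), astart
            klass = classify_pair(
                (a.at[best, "chrom"], a.at[best, "start"], a.at[best, "end"]),
                (brow.chrom, brow.start, brow.end))
            rows.append((bi, best, best_len, klass))
    if rows:
        pairs = pd.DataFrame(rows, columns=["b_index", "a_index", "overlap", "klass"])
    shared_b = len(pairs)
    class_counts = {k: 0 for k in OVERLAP_CLASSES[:-1]}
    for k in pairs["klass"]:
        class_counts[k] += 1
    summary = {
        "n_a": int(len(set_a)),
        "n_b": int(len(set_b)),
        "shared_b": shared_b,
        "b_only": int(len(set_b)) - shared_b,
        "class_counts": class_counts,
    }
    if len(set_b) > 0:
        summary["pct_b_shared"] = proportion(shared_b, len(set_b))
    if shared_b > 0:
        summary["class_pct"] = {
            k: proportion(v, shared_b) for k, v in class_counts.items()}
    return {"pairs": pairs, "summary": summary}


def three_way(set_a: pd.DataFrame, set_b: pd.DataFrame, set_c: pd.DataFrame,
              tile_size: int = 100) -> dict:
    """Pairwise and triple intersection counts of three tile sets.

    The triple-as-fraction-of-pairwise percentages are truncated at one
    decimal (the convention of the intersection summaries this mirrors).
    """
    ka = _tile_keys(set_a, tile_size)
    kb = _tile_keys(set_b, tile_size)
    kc = _tile_keys(set_c, tile_size)
    ab, ac, bc = ka & kb, ka & kc, kb & kc
    abc = ka & kb & kc
    out = {
        "n_a": len(ka), "n_b": len(kb), "n_c": len(kc),
        "ab": len(ab), "ac": len(ac), "bc": len(bc), "abc": len(abc),
    }
    for key in ("ab", "ac", "bc"):
        if out[key] > 0:
            out[f"pct_abc_of_{key}"] = three_way_fraction(out["abc"], out[key])
    return out


def three_way_fraction(triple_count: int, pairwise_count: int) -> float:
    """Triple intersection as a truncated percentage of a pairwise one."""
    return floor_percent(triple_count, pairwise_count, decimals=1)
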