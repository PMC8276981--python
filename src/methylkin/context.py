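"""Genomic-element, CpG-island and repeat context annotation with enrichment.

Element assignment is midpoint-based with a fixed precedence
(promoter > TTS > 5UTR > 3UTR > exon > intron > noncoding > intergenic);
promoter and TTS windows default to +/- 1 kb.  CpG-island context uses the
standard shore (<= 2 kb) / shelf (2-4 kb) / open-sea (> 4 kb) windows.
Enrichment against an all-sequenced background is a 2x2 Pearson chi-square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from methylkin.constants import DEFAULTS, YOUNG_LINE_SUBFAMILIES
from methylkin.intervals import IntervalIndex
from methylkin.io import Gene, GenomicInterval, RepeatInterval, intervals_to_frame
from methylkin.stats import chi2_2x2

ELEMENT_LABELS = ("promoter", "TTS", "5UTR", "3UTR", "exon", "intron",
                  "noncoding", "intergenic")


@dataclass(frozen=True)
class EnrichmentResult:
    """Foreground-vs-background proportion comparison for one feature."""

    fg_count: int
    fg_total: int
    bg_count: int
    bg_total: int
    chi2: float
    p: float

    @property
    def fg_prop(self) -> float:
        return self.fg_count / self.fg_total if self.fg_total else float("nan")

    @property
    def bg_prop(self) -> float:
        return self.bg_count / self.bg_total if self.bg_total else float("nan")

    @property
    def fold(self) -> float:
        bg = self.bg_prop
        return self.fg_prop / bg if bg > 0 else float("inf")


def _enrich(fg_count: int, fg_total: int, bg_count: int, bg_total: int) -> EnrichmentResult:
    stat, p = chi2_2x2(fg_count, fg_total - fg_count,
                       bg_count, bg_total - bg_count)
    return EnrichmentResult(fg_count, fg_total, bg_count, bg_total, stat, p)


# ---------------------------------------------------------------------------
# Genomic elements
# ---------------------------------------------------------------------------


def _feature_tables(genes: list[Gene], promoter_window: int, tts_window: int):
    """Per-label interval frames in precedence order."""
    rows: dict[str, list[tuple[str, int, int]]] = {lab: [] for lab in ELEMENT_LABELS[:-1]}
    for g in genes:
        if g.noncoding:
            rows["noncoding"].append((g.chrom, g.start, g.end))
            continue
        rows["promoter"].append(
            (g.chrom, max(0, g.tss - promoter_window), g.tss + promoter_window + 1))
        rows["TTS"].append(
            (g.chrom, max(0, g.tts - tts_window), g.tts + tts_window + 1))
        for s, e in g.utr5:
            rows["5UTR"].append((g.chrom, s, e))
        for s, e in g.utr3:
            rows["3UTR"].append((g.chrom, s, e))
        for s, e in g.exons:
            rows["exon"].append((g.chrom, s, e))
        rows["intron"].append((g.chrom, g.start, g.end))  # body; precedence handles exons
    tables = {}
    for lab, recs in rows.items():
        if recs:
            df = pd.DataFrame(recs, columns=["chrom", "start", "end"])
            tables[lab] = IntervalIndex.from_frame(df)
    return tables


def annotate_elements(queries: pd.DataFrame, genes: list[Gene],
                      promoter_window: int = DEFAULTS["promoter_window"],
                      tts_window: int = DEFAULTS["tts_window"]) -> list[str]:
    """One element label per query interval, assigned at the midpoint."""
    tables = _feature_tables(genes, promoter_window, tts_window)
    labels = []
    for row in queries.itertuples(index=False):
        mid = (int(row.start) + int(row.end)) // 2
        label = "intergenic"
        for lab in ELEMENT_LABELS[:-1]:
            index = tables.get(lab)
            if index is not None and index.any_overlap(row.chrom, mid, mid + 1):
                label = lab
                break
        labels.append(label)
    return labels


def element_distribution(queries: pd.DataFrame, genes: list[Gene], **kw) -> dict[str, int]:
    labels = annotate_elements(queries, genes, **kw)
    out = {lab: 0 for lab in ELEMENT_LABELS}
    for lab in labels:
        out[lab] += 1
    return out


# ---------------------------------------------------------------------------
# CpG-island context
# ---------------------------------------------------------------------------


def cgi_context(queries: pd.DataFrame, cgis: list[GenomicInterval],
                shore_max: int = DEFAULTS["shore_max"],
                shelf_max: int = DEFAULTS["shelf_max"]) -> pd.DataFrame:
    """Island / shore / shelf / open-sea label and island distance per query.

    Distance is between closest bases (adjacent intervals are 1 bp apart);
    overlap gives distance 0 and the island label.  Boundary rule: shore if
    0 < d <= shore_max, shelf if shore_max < d <= shelf_max, else open sea.
    """
    cgi_df = intervals_to_frame(list(cgis))
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if len(cgi_df) > 0:
        for chrom, sub in cgi_df.groupby("chrom"):
            sub = sub.sort_values("start")
            by_chrom[str(chrom)] = (sub["start"].to_numpy(np.int64),
                                    sub["end"].to_numpy(np.int64))
    labels, dists = [], []
    for row in queries.itertuples(index=False):
        qs, qe = int(row.start), int(row.end)
        entry = by_chrom.get(row.chrom)
        d = None
        if entry is not None:
            starts, ends = entry
            overlap = (starts < qe) & (ends > qs)
            if overlap.any():
                d = 0
            else:
                gaps = np.where(starts >= qe, starts - qe + 1,
                                np.where(ends <= qs, qs - ends + 1, 0))
                d = int(gaps.min())
        if d is None:
            labels.append("open_sea")
            dists.append(np.inf)
        elif d == 0:
            labels.append("island")
            dists.append(0)
        elif d <= shore_max:
            labels.append("shore")
            dists.append(d)
        elif d <= shelf_max:
            labels.append("shelf")
            dists.append(d)
        else:
            labels.append("open_sea")
            dists.append(d)
    return pd.DataFrame({"label": labels, "distance": dists})


def cgi_distribution(queries: pd.DataFrame, cgis, **kw) -> dict[str, int]:
    ctx = cgi_context(queries, cgis, **kw)
    out = {lab: 0 for lab in ("island", "shore", "shelf", "open_sea")}
    for lab in ctx["label"]:
        out[lab] += 1
    return out


# ---------------------------------------------------------------------------
# Repeats
# ---------------------------------------------------------------------------

_COMPOSITION_CLASSES = ("LINE", "SINE", "LTR", "other", "none")


def _assign_repeat_class(regions: pd.DataFrame,
                         repeats: list[RepeatInterval]) -> list[str]:
    """Class of maximal overlap per region ('none' if no repeat overlaps).

    Classes outside {LINE, SINE, LTR} collapse to 'other'; ties go to the
    repeat with the leftmost start.
    """
    if not repeats:
        return ["none"] * len(regions)
    rep_df = intervals_to_frame(list(repeats))
    index = IntervalIndex.from_frame(rep_df)
    classes = rep_df["repeat_class"].to_numpy(object)
    starts = rep_df["start"].to_numpy(np.int64)
    out = []
    for row in regions.itertuples(index=False):
        hits, lengths = index.overlap_lengths(row.chrom, int(row.start), int(row.end))
        if len(hits) == 0:
            out.append("none")
            continue
        best, best_len, best_start = None, -1, None
        for ri, ov in zip(hits, lengths):
            if ov > best_len or (ov == best_len and starts[ri] < best_start):
                best, best_len, best_start = ri, int(ov), int(starts[ri])
        klass = str(classes[best])
        out.append(klass if klass in ("LINE", "SINE", "LTR") else "other")
    return out


def repeat_composition(regions: pd.DataFrame, repeats: list[RepeatInterval],
                       background: pd.DataFrame | None = None) -> dict:
    """Per-class proportions and (optionally) enrichment vs background."""
    if background is not None and len(background) == 0:
        raise ValueError("background region set is empty")
    fg_classes = _assign_repeat_class(regions, repeats)
    fg_counts = {k: fg_classes.count(k) for k in _COMPOSITION_CLASSES}
    out = {"fg_counts": fg_counts, "fg_total": len(regions)}
    if not repeats:
        warnings.warn("no repeats supplied; enrichment skipped", stacklevel=2)
        return out
    if background is not None:
        bg_classes = _assign_repeat_class(background, repeats)
        bg_counts = {k: bg_classes.count(k) for k in _COMPOSITION_CLASSES}
        out["bg_counts"] = bg_counts
        out["bg_total"] = len(background)
        out["enrichment"] = {
            k: _enrich(fg_counts[k], len(regions), bg_counts[k], len(background))
            for k in _COMPOSITION_CLASSES if k != "none"
        }
    return out


def young_line_overlap(regions: pd.DataFrame, repeats: list[RepeatInterval],
                       background: pd.DataFrame,
                       young_list=YOUNG_LINE_SUBFAMILIES) -> EnrichmentResult:
    """Enrichment of regions touching a young-LINE subfamily repeat."""
    young = set(young_list)
    young_reps = [r for r in repeats if r.subfamily in young]
    if young_reps:
        df = intervals_to_frame(young_reps)
        index = IntervalIndex.from_frame(df)
        fg = int(sum(index.any_overlap(r.chrom, int(r.start), int(r.end))
                     for r in regions.itertuples(index=False)))
        bg = int(sum(index.any_overlap(r.chrom, int(r.start), int(r.end))
                     for r in background.itertuples(index=False)))
    else:
        fg = bg = 0
    return _enrich(fg, len(regions), bg, len(background))


def dnmt3c_sensitive_subfamilies(expression_table: pd.DataFrame,
                                 fold_threshold: float = DEFAULTS["fold_threshold"]) -> list[str]:
    """Subfamilies with KO/control expression fold strictly above threshold.

    The table needs a ``subfamily`` column plus either ``fold`` or the pair
    ``ko``/``control``.  Subfamilies with non-positive control expression
    are skipped with a warning.
    """
    out = []
    has_fold = "fold" in expression_table.columns
    for row in expression_table.itertuples(index=False):
        if has_fold:
            fold = float(row.fold)
        else:
            ctrl = float(row.control)
            if ctrl <= 0:
                warnings.warn(
                    f"subfamily {row.subfamily}: non-positive control "
                    "expression, skipped", stacklevel=2)
                continue
            fold = float(row.ko) / ctrl
        if fold > fold_threshold:
            out.append(str(row.subfamily))
    return out


def flanked_overlap(regions: pd.DataFrame, elements: pd.DataFrame,
                    flank: int = DEFAULTS["flank"],
                    chrom_sizes: dict[str, int] | None = None) -> dict:
    """Fraction of regions whose +/- flank extension touches an element.

    Extensions are clipped at chromosome bounds; clipping the right edge
    requires ``chrom_sizes`` (missing sizes raise).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if len(regions) == 0:
        return {"count": 0, "total": 0, "fraction": float("nan")}
    index = IntervalIndex.from_frame(elements) if len(elements) else None
    count = 0
    for row in regions.itertuples(index=False):
        start = max(0, int(row.start) - flank)
        end = int(row.end) + flank
        if flank > 0:
            if chrom_sizes is None:
                raise ValueError("chrom_sizes required when flank > 0")
            if row.chrom not in chrom_sizes:
                raise ValueError(f"missing chromosome size for {row.chrom!r}")
            end = min(end, chrom_sizes[row.chrom])
        if index is not None and index.any_overlap(row.chrom, start, end):
            count += 1
    return {"count": count, "total": len(regions),
            "fraction": count / len(regions)}
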