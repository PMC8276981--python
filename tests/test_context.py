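import numpy as np
import pandas as pd
import pytest

from methylkin.constants import YOUNG_LINE_SUBFAMILIES
from methylkin.context import (annotate_elements, cgi_context,
                               dnmt3c_sensitive_subfamilies,
                               element_distribution, flanked_overlap,
                               repeat_composition, young_line_overlap)
from methylkin.io import Gene, GenomicInterval, RepeatInterval
from methylkin.stats import chi2_2x2


def _regions(spans, chrom="chr1"):
    return pd.DataFrame({"chrom": [chrom] * len(spans),
                         "start": [s for s, _ in spans],
                         "end": [e for _, e in spans]})


GENES = [
    Gene("chr1", 10_000, 20_000, "gPlus", "+",
         exons=((10_000, 10_500), (14_000, 14_800), (19_500, 20_000)),
         utr5=((10_000, 10_150),), utr3=((19_850, 20_000),)),
    Gene("chr1", 40_000, 48_000, "gNc", "+", noncoding=True),
]


# ---------------------------------------------------------------------------
# elements
# ---------------------------------------------------------------------------


def test_promoter_upstream_of_tss():
    # midpoint 300 bp upstream of the TSS at 10,000
    labels = annotate_elements(_regions([(9_650, 9_750)]), GENES)
    assert labels == ["promoter"]


def test_intergenic_far_from_any_gene():
    labels = annotate_elements(_regions([(200_000, 200_100)]), GENES)
    assert labels == ["intergenic"]


def test_precedence_exon_vs_intron():
    # midpoint inside the middle exon
    assert annotate_elements(_regions([(14_300, 14_500)]), GENES) == ["exon"]
    # midpoint in gene body but outside exons
    assert annotate_elements(_regions([(12_400, 12_600)]), GENES) == ["intron"]


def test_noncoding_gene_body():
    assert annotate_elements(_regions([(44_000, 44_100)]), GENES) == ["noncoding"]


def _element_oracle(mid, genes, w=1000):
    """Naive precedence scan for a single midpoint."""
    coding = [g for g in genes if not g.noncoding]
    for g in coding:
        if g.tss - w <= mid <= g.tss + w:
            return "promoter"
    for g in coding:
        if g.tts - w <= mid <= g.tts + w:
            return "TTS"
    for field, label in (("utr5", "5UTR"), ("utr3", "3UTR"), ("exons", "exon")):
        for g in coding:
            for s, e in getattr(g, field):
                if s <= mid < e:
                    return label
    for g in coding:
        if g.start <= mid < g.end:
            return "intron"
    for g in genes:
        if g.noncoding and g.start <= mid < g.end:
            return "noncoding"
    return "intergenic"


def test_elements_match_bruteforce_oracle(rng):
    starts = rng.integers(0, 60_000, size=1000)
    queries = _regions([(int(s), int(s) + 100) for s in starts])
    labels = annotate_elements(queries, GENES)
    for (s, label) in zip(starts, labels):
        assert label == _element_oracle(int(s) + 50, GENES), f"start={s}"


def test_element_distribution_partitions():
    starts = np.arange(0, 60_000, 700)
    queries = _regions([(int(s), int(s) + 100) for s in starts])
    dist = element_distribution(queries, GENES)
    assert sum(dist.values()) == len(queries)


# ---------------------------------------------------------------------------
# CGI context
# ---------------------------------------------------------------------------

CGIS = [GenomicInterval("chr1", 50_000, 51_000)]


@pytest.mark.parametrize("span,expected", [
    ((50_200, 50_400), "island"),       # overlap
    ((51_500, 51_600), "shore"),        # 501 bp away
    ((47_999, 48_002), "shore"),        # 1,999 bp away
    ((53_400, 53_500), "shelf"),        # 2,401 bp
    ((55_001, 55_100), "open_sea"),     # 4,002 bp
])
def test_cgi_context_cases(span, expected):
    ctx = cgi_context(_regions([span]), CGIS)
    assert ctx.iloc[0]["label"] == expected


def test_cgi_open_sea_beyond_4kb_boundary():
    # query ending 4,001 bp before the island start
    ctx = cgi_context(_regions([(45_900, 45_999 + 1)]), CGIS)
    assert ctx.iloc[0]["distance"] == 4001
    assert ctx.iloc[0]["label"] == "open_sea"


def test_cgi_shelf_boundary_inclusive():
    # exactly 4,000 bp -> shelf; exactly 2,000 -> shore
    ctx = cgi_context(_regions([(45_901, 46_001), (47_901, 48_001)]), CGIS)
    assert list(ctx["distance"]) == [4000, 2000]
    assert list(ctx["label"]) == ["shelf", "shore"]


def test_cgi_no_islands_everything_open_sea():
    ctx = cgi_context(_regions([(0, 100)]), [])
    assert ctx.iloc[0]["label"] == "open_sea"


def test_cgi_labels_partition(rng):
    starts = rng.integers(0, 100_000, size=300)
    ctx = cgi_context(_regions([(int(s), int(s) + 50) for s in starts]), CGIS)
    assert ctx["label"].isin(["island", "shore", "shelf", "open_sea"]).all()


# ---------------------------------------------------------------------------
# repeats
# ---------------------------------------------------------------------------

REPEATS = [
    RepeatInterval("chr1", 1_000, 1_600, name="L1MdA_I", repeat_class="LINE",
                   family="L1", subfamily="L1MdA_I", young=True),
    RepeatInterval("chr1", 3_000, 3_200, name="L1_Mus3", repeat_class="LINE",
                   family="L1", subfamily="L1_Mus3", young=False),
    RepeatInterval("chr1", 5_000, 5_150, name="B1_Mm", repeat_class="SINE",
                   family="Alu", subfamily="B1_Mm", young=False),
    RepeatInterval("chr1", 7_000, 7_400, name="IAPEz-int", repeat_class="LTR",
                   family="ERVK", subfamily="IAPEz-int", young=False),
]


def test_region_inside_line_classified_line():
    res = repeat_composition(_regions([(1_100, 1_300)]), REPEATS)
    assert res["fg_counts"]["LINE"] == 1


def test_region_without_repeat_is_none():
    res = repeat_composition(_regions([(9_000, 9_100)]), REPEATS)
    assert res["fg_counts"]["none"] == 1


def test_maximal_overlap_class_assignment():
    # overlaps LINE by 100 bp and SINE by 50: assigned LINE
    reps = [REPEATS[0],
            RepeatInterval("chr1", 1_700, 1_750, name="B1_Mm",
                           repeat_class="SINE", family="Alu",
                           subfamily="B1_Mm", young=False)]
    res = repeat_composition(_regions([(1_500, 1_750)]), reps)
    assert res["fg_counts"]["LINE"] == 1
    assert res["fg_counts"]["SINE"] == 0


def test_no_repeats_warns_and_runs():
    with pytest.warns(UserWarning, match="no repeats"):
        res = repeat_composition(_regions([(0, 100)]), [])
    assert res["fg_counts"]["none"] == 1


def test_empty_background_rejected():
    with pytest.raises(ValueError, match="background"):
        repeat_composition(_regions([(0, 100)]), REPEATS, _regions([]))


def test_enrichment_chi2_closed_form():
    fg = _regions([(1_100, 1_200), (1_300, 1_400), (9_000, 9_100)])  # 2 LINE
    bg = _regions([(s, s + 50) for s in range(20_000, 40_000, 1_000)])  # none
    res = repeat_composition(fg, REPEATS, bg)
    enr = res["enrichment"]["LINE"]
    stat, p = chi2_2x2(2, 1, 0, len(bg))
    assert enr.chi2 == pytest.approx(stat)
    assert enr.p == pytest.approx(p)


def test_enrichment_symmetry_under_swap():
    fg = _regions([(1_100, 1_200), (9_000, 9_100)])
    bg = _regions([(s, s + 50) for s in range(20_000, 30_000, 1_000)])
    fwd = repeat_composition(fg, REPEATS, bg)["enrichment"]["LINE"]
    rev = repeat_composition(bg, REPEATS, fg)["enrichment"]["LINE"]
    assert fwd.chi2 == pytest.approx(rev.chi2)
    if fwd.bg_prop > 0 and rev.bg_prop > 0:
        assert fwd.fold == pytest.approx(1.0 / rev.fold)


# ---------------------------------------------------------------------------
# young LINEs
# ---------------------------------------------------------------------------


def test_young_line_overlap_counts_young_only():
    bg = _regions([(s, s + 50) for s in range(20_000, 40_000, 1_000)])
    young_hit = young_line_overlap(_regions([(1_100, 1_200)]), REPEATS, bg)
    assert young_hit.fg_count == 1
    old_hit = young_line_overlap(_regions([(3_050, 3_100)]), REPEATS, bg)
    assert old_hit.fg_count == 0


# ---------------------------------------------------------------------------
# DNMT3C sensitivity
# ---------------------------------------------------------------------------


def test_sensitive_subfamilies_strict_threshold():
    table = pd.DataFrame({"subfamily": ["A", "B", "C"],
                          "fold": [6.0, 4.9, 5.0]})
    assert dnmt3c_sensitive_subfamilies(table) == ["A"]


def test_sensitive_subfamilies_empty_table():
    assert dnmt3c_sensitive_subfamilies(
        pd.DataFrame({"subfamily": [], "fold": []})) == []


def test_sensitive_subfamilies_ko_control_form():
    table = pd.DataFrame({"subfamily": ["A", "B", "Z"],
                          "ko": [60.0, 9.0, 3.0],
                          "control": [10.0, 2.0, 0.0]})
    with pytest.warns(UserWarning, match="non-positive control"):
        out = dnmt3c_sensitive_subfamilies(table)
    assert out == ["A"]        # 6-fold in; 4.5-fold out; Z skipped


def test_sensitive_subfamilies_recovers_young_line_list():
    rows = [{"subfamily": name, "fold": 6.0 + i}
            for i, name in enumerate(YOUNG_LINE_SUBFAMILIES)]
    rows += [{"subfamily": "L1_Mus3", "fold": 1.2},
             {"subfamily": "B1_Mm", "fold": 0.8},
             {"subfamily": "IAPEz-int", "fold": 4.0}]
    out = dnmt3c_sensitive_subfamilies(pd.DataFrame(rows))
    assert out == list(YOUNG_LINE_SUBFAMILIES)


# ---------------------------------------------------------------------------
# flanked overlap
# ---------------------------------------------------------------------------

SIZES = {"chr1": 1_000_000}


def test_flanked_overlap_example():
    res = flanked_overlap(_regions([(5_000, 5_100)]),
                          _regions([(5_600, 5_700)]),
                          flank=1000, chrom_sizes=SIZES)
    assert res["count"] == 1


def test_flank_zero_is_plain_overlap():
    regions = _regions([(5_000, 5_100)])
    elements = _regions([(5_600, 5_700)])
    res = flanked_overlap(regions, elements, flank=0)
    assert res["count"] == 0
    touching = flanked_overlap(regions, _regions([(5_050, 5_060)]), flank=0)
    assert touching["count"] == 1


def test_flanked_overlap_missing_chrom_size():
    with pytest.raises(ValueError, match="chrom"):
        flanked_overlap(_regions([(0, 10)]), _regions([(5, 6)]),
                        flank=10, chrom_sizes={"chr9": 100})


def test_flanked_overlap_matches_bruteforce(rng):
    regions = _regions([(int(s), int(s) + 80)
                        for s in rng.integers(0, 500_000, size=200)])
    elements = _regions([(int(s), int(s) + 120)
                         for s in rng.integers(0, 500_000, size=200)])
    flank = 1000
    res = flanked_overlap(regions, elements, flank=flank, chrom_sizes=SIZES)
    expected = 0
    for _, r in regions.iterrows():
        s = max(0, r["start"] - flank)
        e = min(SIZES["chr1"], r["end"] + flank)
        if any(min(e, er["end"]) > max(s, er["start"])
               for _, er in elements.iterrows()):
            expected += 1
    assert res["count"] == expected
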