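import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from methylkin.constants import YOUNG_LINE_SUBFAMILIES
from methylkin.context import repeat_composition
from methylkin.overlap import classify_pair
from methylkin.simulate import (GroundTruth, SimulationConfig, _draw_counts,
                                simulate_annotation, simulate_chip_track,
                                simulate_developmental_tracks,
                                simulate_methylomes, write_run)
from methylkin.timing import bin_genome, region_methylation, rpkm


def small_config(**kw):
    defaults = dict(seed=1, n_chroms=1, chrom_length=200_000, n_planted=15)
    defaults.update(kw)
    return SimulationConfig(**defaults)


# ---------------------------------------------------------------------------
# config validation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("kw", [
    {"shared_fraction": 1.5},
    {"delta_min": 0.0},
    {"delta_min": 30.0, "delta_max": 20.0},
    {"rho": 1.0},
    {"chrom_length": 10_000},
])
def test_config_rejects_bad_values(kw):
    with pytest.raises(ValueError):
        small_config(**kw)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def test_annotation_deterministic_under_seed():
    a1, t1 = simulate_annotation(small_config())
    a2, t2 = simulate_annotation(small_config())
    assert a1.genes == a2.genes
    assert a1.cgis == a2.cgis
    assert a1.repeats == a2.repeats
    for c in t1.planted:
        pd.testing.assert_frame_equal(t1.planted[c], t2.planted[c])
    for chrom in t1.cpg_positions:
        np.testing.assert_array_equal(t1.cpg_positions[chrom],
                                      t2.cpg_positions[chrom])


def test_annotation_zero_repeats_config():
    config = small_config(repeat_prob=0.0,
                          placement_bias={"intergenic": 1.0, "young_te": 0.0,
                                          "late": 1.0})
    annotation, truth = simulate_annotation(config)
    assert annotation.repeats == []
    # downstream composition still runs (all 'none', warning)
    regions = truth.planted["F1"][["chrom", "start", "end"]]
    with pytest.warns(UserWarning):
        res = repeat_composition(regions, annotation.repeats)
    assert res["fg_counts"]["none"] == len(regions)


def test_default_young_subfamily_list():
    assert SimulationConfig().young_subfamilies == (
        "L1MdA_I", "L1MdTf_I", "L1MdTf_II", "L1MdA_II", "L1MdGf_I",
        "L1MdTf_III", "L1MdGf_II", "L1MdA_III")


def test_annotation_within_bounds_and_plants_have_cpgs():
    config = small_config()
    annotation, truth = simulate_annotation(config)
    annotation.validate()
    for cohort, plants in truth.planted.items():
        for row in plants.itertuples(index=False):
            pos = truth.cpg_positions[row.chrom]
            inside = (pos >= row.start + 1) & (pos <= row.end)
            assert inside.sum() >= 3, f"{cohort} plant without CpGs"


def test_nested_plants_lie_within_parents():
    config = small_config(shared_fraction=1.0, n_planted=10)
    _, truth = simulate_annotation(config)
    f1, f2 = truth.planted["F1"], truth.planted["F2"]
    assert f2["nested"].all()
    for row in f2.itertuples(index=False):
        parent = f1.iloc[row.parent]
        klass = classify_pair((parent.chrom, parent.start, parent.end),
                              (row.chrom, row.start, row.end))
        assert klass in ("identical", "b_within_a")


def test_too_many_plants_rejected():
    with pytest.raises(ValueError, match="host"):
        simulate_annotation(small_config(n_planted=100_000))


# ---------------------------------------------------------------------------
# methylomes
# ---------------------------------------------------------------------------


def test_methylomes_deterministic():
    config = small_config()
    ann, truth = simulate_annotation(config)
    m1 = simulate_methylomes(ann, truth, config)
    m2 = simulate_methylomes(ann, truth, config)
    pd.testing.assert_frame_equal(m1["F1"]["mutant"][0].sites,
                                  m2["F1"]["mutant"][0].sites)


def test_planted_effect_recovered_in_pooled_difference():
    config = SimulationConfig(seed=9, n_chroms=2, chrom_length=500_000,
                              n_planted=100, delta_min=30, delta_max=30,
                              cohorts=("F1",))
    ann, truth = simulate_annotation(config)
    m = simulate_methylomes(ann, truth, config)
    plants = truth.planted["F1"]
    hypo = plants[plants["direction"] == "hypo"]
    regions = hypo[["chrom", "start", "end"]].reset_index(drop=True)

    def pooled(callsets):
        merged = pd.concat([cs.sites for cs in callsets])
        agg = (merged.groupby(["chrom", "pos"], as_index=False)
               [["meth", "cov"]].sum())
        agg["strand"] = "+"
        from methylkin.io import SampleCallSet
        return SampleCallSet.from_frame("pooled", agg)

    ctrl = region_methylation(regions, pooled(m["F1"]["control"]), min_cov=1)
    mut = region_methylation(regions, pooled(m["F1"]["mutant"]), min_cov=1)
    mean_drop = np.nanmean(ctrl - mut)
    assert mean_drop == pytest.approx(30.0, abs=3.0)


def test_rho_zero_reduces_to_binomial_variance(rng):
    # moment check at coverage 50, pi = 0.5
    pi = np.full(40_000, 0.5)
    meth, cov = _draw_counts(rng, pi, mean_cov=50, dispersion=1e9, rho=0.0)
    keep = cov > 0
    props = meth[keep] / cov[keep]
    expected_var = np.mean(0.25 / cov[keep])
    assert props.var() == pytest.approx(expected_var, rel=0.05)


def test_rho_inflates_variance(rng):
    pi = np.full(40_000, 0.5)
    meth, cov = _draw_counts(rng, pi, mean_cov=50, dispersion=1e9, rho=0.1)
    keep = cov > 0
    props = meth[keep] / cov[keep]
    binom_var = np.mean(0.25 / cov[keep])
    assert props.var() > 2 * binom_var


def test_control_and_mutant_match_outside_plants():
    config = small_config(seed=4, n_planted=5, cohorts=("F1",))
    ann, truth = simulate_annotation(config)
    m = simulate_methylomes(ann, truth, config)
    plants = truth.planted["F1"]
    chrom = "chr1"
    pos = truth.cpg_positions[chrom]
    in_plant = np.zeros(len(pos), dtype=bool)
    for row in plants.itertuples(index=False):
        in_plant |= (pos >= row.start + 1) & (pos <= row.end)
    outside = set(pos[~in_plant].tolist())

    def pooled_pct(callsets):
        merged = pd.concat([cs.sites for cs in callsets])
        merged = merged[merged["pos"].isin(outside)]
        return merged["meth"].sum() / merged["cov"].sum()

    p_ctrl = pooled_pct(m["F1"]["control"])
    p_mut = pooled_pct(m["F1"]["mutant"])
    assert abs(p_ctrl - p_mut) < 0.01


# ---------------------------------------------------------------------------
# developmental tracks
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def track_setup():
    config = small_config(seed=2)
    ann, truth = simulate_annotation(config)
    tracks = simulate_developmental_tracks(ann, truth, config)
    return config, ann, truth, tracks


def test_cgi_trajectory_stays_low(track_setup):
    config, ann, truth, tracks = track_setup
    cgis = pd.DataFrame({"chrom": [c.chrom for c in ann.cgis],
                         "start": [c.start for c in ann.cgis],
                         "end": [c.end for c in ann.cgis]})
    for tp in config.timepoints:
        vals = region_methylation(cgis, tracks[tp])
        assert np.nanmean(vals) <= 10.0


def test_late_regions_gain_after_e16(track_setup):
    config, ann, truth, tracks = track_setup
    late = truth.planted["F1"][["chrom", "start", "end"]]
    means = [np.nanmean(region_methylation(late, tracks[tp]))
             for tp in config.timepoints]
    assert means[1] <= 25.0               # still low at the E16.5 analog
    assert means[3] >= 70.0               # high by the sperm analog
    gains = np.diff(means)
    assert gains[1] == max(gains)          # largest gain after E16.5
    assert all(g > -2 for g in gains)      # monotone up to noise


def test_early_regions_high_by_e16(track_setup):
    config, ann, truth, tracks = track_setup
    early = truth.early_regions
    vals = region_methylation(early, tracks[config.timepoints[1]])
    assert np.nanmean(vals) >= 80.0


def test_tracks_deterministic(track_setup):
    config, ann, truth, tracks = track_setup
    again = simulate_developmental_tracks(ann, truth, config)
    for tp in config.timepoints:
        pd.testing.assert_frame_equal(tracks[tp].sites, again[tp].sites)


# ---------------------------------------------------------------------------
# chip track
# ---------------------------------------------------------------------------


def test_chip_enrichment_factor_recovered():
    config = small_config(seed=3, chip_n_reads=1_000_000, chip_enrichment=4.0)
    ann, truth = simulate_annotation(config)
    chip = simulate_chip_track(ann, truth, config)
    e16 = chip[config.timepoints[1]]
    late = truth.all_late_regions()
    # background: genome bins not overlapping late regions
    bins = bin_genome(ann.chrom_sizes)
    from methylkin.intervals import IntervalIndex
    idx = IntervalIndex.from_frame(late)
    keep = [not idx.any_overlap(r.chrom, r.start, r.end)
            for r in bins.itertuples(index=False)]
    bg = bins[keep].reset_index(drop=True)
    b = rpkm(bg, e16["reads"], e16["library_size"]).mean()
    fg = rpkm(late, e16["reads"], e16["library_size"]).mean()
    assert 3.2 * b <= fg <= 4.8 * b


def test_chip_factor_one_indistinguishable():
    config = small_config(seed=6, chip_n_reads=300_000, chip_enrichment=1.0)
    ann, truth = simulate_annotation(config)
    chip = simulate_chip_track(ann, truth, config)
    e16 = chip[config.timepoints[1]]
    late = truth.all_late_regions().copy()
    # length-matched shifted control regions
    shifted = late.copy()
    shifted["start"] = shifted["start"] + 25_000
    shifted["end"] = shifted["end"] + 25_000
    shifted = shifted[shifted["end"] < config.chrom_length]
    fg = rpkm(late, e16["reads"], e16["library_size"])
    bg = rpkm(shifted, e16["reads"], e16["library_size"])
    assert sps.mannwhitneyu(fg, bg).pvalue > 0.01


def test_chip_zero_reads():
    config = small_config(chip_n_reads=0)
    ann, truth = simulate_annotation(config)
    chip = simulate_chip_track(ann, truth, config)
    e16 = chip[config.timepoints[1]]
    vals = rpkm(truth.all_late_regions(), e16["reads"], e16["library_size"])
    assert (vals == 0).all()


# ---------------------------------------------------------------------------
# run emission
# ---------------------------------------------------------------------------


def test_write_run_round_trip_and_determinism(tmp_path):
    from methylkin.io import (read_bed, read_callset, read_chrom_sizes,
                              read_genes)

    config = small_config(seed=8, n_planted=5, n_samples_per_group=2,
                          chip_n_reads=5_000)
    out1 = tmp_path / "run1"
    out2 = tmp_path / "run2"
    res1 = write_run(config, out1)
    res2 = write_run(config, out2)
    assert res1["manifest"] == res2["manifest"]

    sizes = read_chrom_sizes(out1 / "chrom.sizes")
    assert sizes == {"chr1": 200_000}
    genes = read_genes(out1 / "genes.tsv")
    assert genes == sorted(res1["annotation"].genes,
                           key=lambda g: (g.chrom, g.start, g.end))
    repeats = read_bed(out1 / "repeats.tsv", kind="repeat",
                       young_list=YOUNG_LINE_SUBFAMILIES)
    assert len(repeats) == len(res1["annotation"].repeats)
    cs = read_callset(out1 / "calls/F1/control/F1_control_1.cov",
                      "F1_control_1")
    pd.testing.assert_frame_equal(
        cs.sites, res1["methylomes"]["F1"]["control"][0].sites)
    truth_payload = json.loads((out1 / "truth.json").read_text())
    assert set(truth_payload["planted"]) == {"F1", "F2"}
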