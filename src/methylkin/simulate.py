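"""Synthetic cohort generation with known ground truth.

Generates chromosome annotations (genes, CpG islands, repeats with young
LINE subfamilies), two-group RRBS-like count data with planted
hypomethylated regions, developmental methylation tracks in which planted
regions gain methylation only after the E16.5 analog, and histone-read
tracks enriched at planted regions.

Noise model: per-site coverage is negative-binomial; methylated counts are
beta-binomial with correlation ``rho`` (rho = 0 reduces to pure binomial).
Planted effects lower mutant methylation only, except for a configurable
hypermethylated fraction.  Later cohorts nest their planted regions inside
the first cohort's regions with probability ``shared_fraction``.

All generators are fully deterministic under a fixed seed: each stage draws
from its own spawned child of the config seed, so stages can be re-run in
any order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from methylkin.constants import TIMEPOINTS, YOUNG_LINE_SUBFAMILIES
from methylkin.io import (AnnotationBundle, Gene, GenomicInterval,
                          RepeatInterval, SampleCallSet, write_bed,
                          write_callset, write_chrom_sizes, write_genes)

_OLD_LINE = ("L1_Mus3", "L1_Mus2", "Lx8", "Lx9")
_SINE = ("B1_Mm", "B2_Mm1a", "B2_Mm2", "B4A")
_LTR = ("IAPEz-int", "MTA_Mm", "RLTR10C", "ORR1A0")
_DNA = ("Tigger1", "Charlie4", "MER46C")

PLACEMENT_CATEGORIES = ("intergenic", "young_te", "late")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; validated on construction."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 600_000
    cohorts: tuple[str, ...] = ("F1", "F2")
    n_samples_per_group: int = 4
    mean_coverage: float = 30.0
    coverage_dispersion: float = 5.0   # NB size; var = mu + mu^2/size
    rho: float = 0.05                  # beta-binomial overdispersion (a choice;
                                       # no per-site variance is published)
    cpg_spacing: float = 25.0          # mean bp between simulated CpGs
    baseline_cgi: float = 0.05
    baseline_repeat: float = 0.85
    baseline_default: float = 0.75
    n_planted: int = 100
    min_region_len: int = 200
    max_region_len: int = 400
    delta_min: float = 10.0            # percentage points
    delta_max: float = 40.0
    hyper_fraction: float = 0.0        # fraction of plants raised instead
    shared_fraction: float = 0.5       # P(cohort-B plant nests in a cohort-A plant)
    placement_bias: dict = field(default_factory=lambda: {
        "intergenic": 1.0, "young_te": 1.0, "late": 1.0})
    gene_prob: float = 0.25
    repeat_prob: float = 0.35
    young_line_fraction: float = 0.5
    timepoints: tuple[str, ...] = TIMEPOINTS
    young_subfamilies: tuple[str, ...] = YOUNG_LINE_SUBFAMILIES
    track_mean_coverage: float = 20.0
    chip_n_reads: int = 200_000
    chip_read_length: int = 100
    chip_enrichment: float = 4.0

    def __post_init__(self):
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must be in [0, 1]")
        if not (0.0 < self.delta_min <= self.delta_max < 100.0):
            raise ValueError("delta range must satisfy 0 < min <= max < 100")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if self.min_region_len < 10 or self.max_region_len < self.min_region_len:
            raise ValueError("bad planted-region length range")
        if self.gene_prob + self.repeat_prob > 1.0:
            raise ValueError("gene_prob + repeat_prob must be <= 1")
        if self.n_chroms < 1 or self.chrom_length < 50_000:
            raise ValueError("need >= 1 chromosome of >= 50 kb")

    def child_rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(8)[stage])


@dataclass
class GroundTruth:
    """Planted regions per cohort, timing labels and simulated CpG layout."""

    planted: dict[str, pd.DataFrame]
    early_regions: pd.DataFrame
    late_pool: pd.DataFrame
    cpg_positions: dict[str, np.ndarray]    # 1-based
    cpg_strands: dict[str, np.ndarray]

    def all_late_regions(self) -> pd.DataFrame:
        frames = [df[["chrom", "start", "end"]] for df in self.planted.values()]
        if len(self.late_pool):
            frames.append(self.late_pool[["chrom", "start", "end"]])
        if not frames:
            return pd.DataFrame(columns=["chrom", "start", "end"])
        out = pd.concat(frames, ignore_index=True)
        # overlapping plants (nested cohorts) must not double-count
        from methylkin.intervals import merge_bookended
        return merge_bookended(out)


_PLANT_COLUMNS = ["chrom", "start", "end", "delta", "direction", "timing",
                  "young_te", "nested", "parent"]


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def simulate_annotation(config: SimulationConfig) -> tuple[AnnotationBundle, GroundTruth]:
    """Lay out genes/CGIs/repeats and place planted regions per cohort."""
    rng = config.child_rng(0)
    genes: list[Gene] = []
    cgis: list[GenomicInterval] = []
    repeats: list[RepeatInterval] = []
    pools: dict[str, list[tuple[str, int, int]]] = {c: [] for c in PLACEMENT_CATEGORIES}
    chrom_sizes: dict[str, int] = {}
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        chrom_sizes[chrom] = config.chrom_length
        _layout_chromosome(chrom, config, rng, genes, cgis, repeats, pools)
    if config.n_planted > 0 and not any(pools.values()):
        raise ValueError("chromosomes too short to host any planted regions")

    planted = _place_plants(config, rng, pools)
    early = _draw_early_regions(config, rng, pools)
    late_pool = pd.DataFrame(pools["late"], columns=["chrom", "start", "end"])
    positions, strands = _simulate_cpgs(config, rng, cgis, chrom_sizes, planted)
    truth = GroundTruth(planted=planted, early_regions=early,
                        late_pool=late_pool, cpg_positions=positions,
                        cpg_strands=strands)
    bundle = AnnotationBundle(genes=genes, cgis=cgis, repeats=repeats,
                              chrom_sizes=chrom_sizes)
    bundle.validate()
    return bundle, truth


def _layout_chromosome(chrom, config, rng, genes, cgis, repeats, pools):
    cursor = 2_000
    limit = config.chrom_length - 16_000
    gi = 0
    while cursor < limit:
        u = rng.random()
        if u < config.gene_prob:
            glen = int(rng.integers(8_000, 15_000))
            strand = "+" if rng.random() < 0.5 else "-"
            noncoding = rng.random() < 0.15
            start, end = cursor, cursor + glen
            exons = ((start, start + 300),
                     (start + glen // 2, start + glen // 2 + 500),
                     (end - 400, end))
            if strand == "+":
                utr5, utr3 = ((start, start + 150),), ((end - 150, end),)
            else:
                utr5, utr3 = ((end - 150, end),), ((start, start + 150),)
            gi += 1
            genes.append(Gene(chrom=chrom, start=start, end=end,
                              name=f"{chrom}_g{gi}", strand=strand,
                              exons=exons, utr5=utr5, utr3=utr3,
                              noncoding=noncoding))
            if rng.random() < 0.7:
                tss = start if strand == "+" else end - 1
                cgis.append(GenomicInterval(chrom=chrom,
                                            start=max(0, tss - 300),
                                            end=tss + 300,
                                            name=f"CpG_{chrom}_{tss}"))
            cursor = end
        elif u < config.gene_prob + config.repeat_prob:
            n_rep = int(rng.integers(2, 7))
            for _ in range(n_rep):
                rlen = int(rng.integers(300, 601))
                rclass, family, subfamily, young = _draw_repeat(config, rng)
                repeats.append(RepeatInterval(
                    chrom=chrom, start=cursor, end=cursor + rlen,
                    name=subfamily, strand="+" if rng.random() < 0.5 else "-",
                    repeat_class=rclass, family=family, subfamily=subfamily,
                    young=young))
                if young and rlen >= config.min_region_len:
                    pools["young_te"].append((chrom, cursor, cursor + rlen))
                cursor += rlen + int(rng.integers(50, 200))
        else:
            blen = int(rng.integers(3_000, 8_000))
            pool = "late" if rng.random() < 0.4 else "intergenic"
            # split the block into spaced host slots so plants from
            # different cohorts never share a tile unintentionally
            chunk = config.max_region_len + 100
            stride = chunk + 200
            for s in range(cursor, cursor + blen - chunk + 1, stride):
                pools[pool].append((chrom, s, s + chunk))
            cursor += blen
        cursor += int(rng.integers(200, 800))


def _draw_repeat(config, rng):
    u = rng.random()
    if u < 0.40:
        if rng.random() < config.young_line_fraction and config.young_subfamilies:
            sub = str(rng.choice(list(config.young_subfamilies)))
            return "LINE", "L1", sub, True
        sub = str(rng.choice(list(_OLD_LINE)))
        return "LINE", "L1", sub, False
    if u < 0.65:
        return "SINE", "Alu", str(rng.choice(list(_SINE))), False
    if u < 0.85:
        return "LTR", "ERVK", str(rng.choice(list(_LTR))), False
    return "DNA", "TcMar", str(rng.choice(list(_DNA))), False


def _choose_host(config, rng, pools) -> tuple[str, tuple[str, int, int]]:
    cats = [c for c in PLACEMENT_CATEGORIES
            if pools[c] and config.placement_bias.get(c, 0.0) > 0]
    if not cats:
        raise ValueError("no remaining host intervals for planted regions; "
                         "increase n_chroms/chrom_length or lower n_planted")
    weights = np.array([config.placement_bias[c] for c in cats], dtype=float)
    cat = cats[int(rng.choice(len(cats), p=weights / weights.sum()))]
    host = pools[cat].pop(int(rng.integers(len(pools[cat]))))
    return cat, host


def _place_plants(config, rng, pools) -> dict[str, pd.DataFrame]:
    planted: dict[str, pd.DataFrame] = {}
    first = config.cohorts[0] if config.cohorts else "F1"
    for cohort in config.cohorts:
        rows = []
        for i in range(config.n_planted):
            delta = float(rng.uniform(config.delta_min, config.delta_max))
            direction = "hyper" if rng.random() < config.hyper_fraction else "hypo"
            nested = (cohort != first and rng.random() < config.shared_fraction
                      and i < len(planted[first]))
            if nested:
                parent = planted[first].iloc[i]
                plen = int(parent.end - parent.start)
                lo = max(100, (3 * plen) // 4)
                sub_len = min(plen, int(rng.integers(lo, plen + 1)))
                # keep nested plants strictly interior when there is slack,
                # so their tiles sit fully inside the parent's footprint
                slack = plen - sub_len
                margin = min(50, slack // 2)
                offset = margin + int(rng.integers(0, slack - 2 * margin + 1))
                rows.append((parent.chrom, int(parent.start) + offset,
                             int(parent.start) + offset + sub_len, delta,
                             direction, "late", bool(parent.young_te), True, i))
            else:
                cat, (chrom, hstart, hend) = _choose_host(config, rng, pools)
                hlen = hend - hstart
                length = int(rng.integers(config.min_region_len,
                                          min(config.max_region_len, hlen) + 1))
                start = hstart + int(rng.integers(0, hlen - length + 1))
                rows.append((chrom, start, start + length, delta, direction,
                             "late", cat == "young_te", False, -1))
        planted[cohort] = pd.DataFrame(rows, columns=_PLANT_COLUMNS)
    return planted


def _draw_early_regions(config, rng, pools) -> pd.DataFrame:
    n = min(50, len(pools["intergenic"]))
    rows = []
    for _ in range(n):
        chrom, hstart, hend = pools["intergenic"].pop(
            int(rng.integers(len(pools["intergenic"]))))
        length = min(config.max_region_len, hend - hstart)
        rows.append((chrom, hstart, hstart + length))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _simulate_cpgs(config, rng, cgis, chrom_sizes, planted):
    """1-based CpG positions per chromosome; planted regions get >= 3 CpGs."""
    positions: dict[str, np.ndarray] = {}
    strands: dict[str, np.ndarray] = {}
    plants = pd.concat(planted.values(), ignore_index=True) if planted else None
    for chrom, length in chrom_sizes.items():
        n_expect = int(length / config.cpg_spacing * 1.3) + 10
        steps = rng.geometric(1.0 / config.cpg_spacing, size=n_expect)
        pos = np.cumsum(steps) + 1
        pos = pos[pos <= length - 1]
        extras = [pos]
        for cgi in cgis:
            if cgi.chrom == chrom:
                dense = np.arange(cgi.start + 2, cgi.end, 8, dtype=np.int64)
                extras.append(dense)
        if plants is not None:
            for row in plants[plants["chrom"] == chrom].itertuples(index=False):
                inside = pos[(pos >= row.start + 1) & (pos <= row.end)]
                if len(inside) < 3:
                    extras.append(np.linspace(row.start + 5, row.end - 5, 4,
                                              dtype=np.int64))
        pos = np.unique(np.concatenate(extras))
        pos = pos[(pos >= 1) & (pos <= length - 1)]
        positions[chrom] = pos.astype(np.int64)
        strands[chrom] = np.where(rng.random(len(pos)) < 0.5, "+", "-")
    return positions, strands


# ---------------------------------------------------------------------------
# Methylomes
# ---------------------------------------------------------------------------


def _baseline_pi(config, annotation, truth) -> dict[str, np.ndarray]:
    """Per-site baseline methylation proportion (site-level jitter included)."""
    rng = config.child_rng(1)
    out = {}
    cgi_df = _frame([iv for iv in annotation.cgis])
    rep_df = _frame([iv for iv in annotation.repeats])
    for chrom, pos in truth.cpg_positions.items():
        pi = np.full(len(pos), config.baseline_default)
        pos0 = pos - 1
        pi[_mask_in(chrom, pos0, rep_df)] = config.baseline_repeat
        pi[_mask_in(chrom, pos0, cgi_df)] = config.baseline_cgi
        pi = pi + rng.normal(0.0, 0.02, size=len(pos))
        out[chrom] = np.clip(pi, 0.01, 0.99)
    return out


def _frame(intervals) -> pd.DataFrame:
    if not intervals:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.DataFrame({"chrom": [iv.chrom for iv in intervals],
                         "start": [iv.start for iv in intervals],
                         "end": [iv.end for iv in intervals]})


def _mask_in(chrom, pos0, intervals: pd.DataFrame) -> np.ndarray:
    mask = np.zeros(len(pos0), dtype=bool)
    sub = intervals[intervals["chrom"] == chrom]
    for row in sub.itertuples(index=False):
        mask |= (pos0 >= row.start) & (pos0 < row.end)
    return mask


def _apply_plants(pi: np.ndarray, chrom: str, pos0: np.ndarray,
                  plants: pd.DataFrame) -> np.ndarray:
    adj = pi.copy()
    for row in plants[plants["chrom"] == chrom].itertuples(index=False):
        mask = (pos0 >= row.start) & (pos0 < row.end)
        shift = row.delta / 100.0
        if row.direction == "hypo":
            adj[mask] = np.clip(pi[mask] - shift, 0.01, 0.99)
        else:
            adj[mask] = np.clip(pi[mask] + shift, 0.01, 0.99)
    return adj


def _draw_counts(rng, pi, mean_cov, dispersion, rho):
    cov = rng.negative_binomial(dispersion, dispersion / (dispersion + mean_cov),
                                size=len(pi))
    if rho > 0:
        a = pi * (1.0 - rho) / rho
        b = (1.0 - pi) * (1.0 - rho) / rho
        p = rng.beta(a, b)
    else:
        p = pi
    meth = rng.binomial(cov, p)
    return meth, cov


def simulate_methylomes(annotation: AnnotationBundle, truth: GroundTruth,
                        config: SimulationConfig) -> dict:
    """Per-cohort control/mutant call sets.

    Control and mutant samples differ in expectation only inside that
    cohort's planted regions, where mutant methylation is shifted by the
    planted delta.
    """
    pi_base = _baseline_pi(config, annotation, truth)
    rng = config.child_rng(2)
    out: dict[str, dict[str, list[SampleCallSet]]] = {}
    for cohort in config.cohorts:
        plants = truth.planted[cohort]
        out[cohort] = {"control": [], "mutant": []}
        for group in ("control", "mutant"):
            for si in range(config.n_samples_per_group):
                frames = []
                for chrom, pos in truth.cpg_positions.items():
                    pi = pi_base[chrom]
                    if group == "mutant":
                        pi = _apply_plants(pi, chrom, pos - 1, plants)
                    meth, cov = _draw_counts(rng, pi, config.mean_coverage,
                                             config.coverage_dispersion,
                                             config.rho)
                    keep = cov >= 1
                    frames.append(pd.DataFrame({
                        "chrom": chrom,
                        "pos": pos[keep],
                        "strand": truth.cpg_strands[chrom][keep],
                        "meth": meth[keep],
                        "cov": cov[keep],
                    }))
                sid = f"{cohort}_{group}_{si + 1}"
                sites = pd.concat(frames, ignore_index=True)
                out[cohort][group].append(SampleCallSet.from_frame(
                    sid, sites, group=group, cohort=cohort))
    return out


# ---------------------------------------------------------------------------
# Developmental tracks
# ---------------------------------------------------------------------------

_EARLY_TRAJ = (0.10, 0.85, 0.93, 0.95)
_LATE_TRAJ = (0.05, 0.12, 0.60, 0.88)
_CGI_TRAJ = (0.05, 0.05, 0.05, 0.05)


def simulate_developmental_tracks(annotation: AnnotationBundle,
                                  truth: GroundTruth,
                                  config: SimulationConfig) -> dict[str, SampleCallSet]:
    """One call set per timepoint (binomial noise, NB coverage).

    Early sequence reaches high methylation by the E16.5 analog; planted /
    late-pool sequence stays low at E16.5 and gains afterwards; CGIs stay
    low throughout.
    """
    if len(config.timepoints) != 4:
        raise ValueError("timing model expects exactly four timepoints")
    rng = config.child_rng(3)
    cgi_df = _frame(annotation.cgis)
    late_df = truth.all_late_regions()
    tracks: dict[str, SampleCallSet] = {}
    levels: dict[str, dict[str, np.ndarray]] = {}
    for chrom, pos in truth.cpg_positions.items():
        pos0 = pos - 1
        kind = np.zeros(len(pos), dtype=np.int8)       # 0 early, 1 late, 2 cgi
        kind[_mask_in(chrom, pos0, late_df)] = 1
        kind[_mask_in(chrom, pos0, cgi_df)] = 2
        levels[chrom] = kind
    for ti, tp in enumerate(config.timepoints):
        frames = []
        for chrom, pos in truth.cpg_positions.items():
            kind = levels[chrom]
            pi = np.choose(kind, [_EARLY_TRAJ[ti], _LATE_TRAJ[ti], _CGI_TRAJ[ti]])
            meth, cov = _draw_counts(rng, np.full(len(pos), 0.0) + pi,
                                     config.track_mean_coverage,
                                     config.coverage_dispersion, 0.0)
            keep = cov >= 1
            frames.append(pd.DataFrame({
                "chrom": chrom, "pos": pos[keep],
                "strand": truth.cpg_strands[chrom][keep],
                "meth": meth[keep], "cov": cov[keep]}))
        tracks[tp] = SampleCallSet.from_frame(
            tp, pd.concat(frames, ignore_index=True), group="control",
            cohort="custom")
    return tracks


# ---------------------------------------------------------------------------
# Histone (ChIP-like) read tracks
# ---------------------------------------------------------------------------


def simulate_chip_track(annotation: AnnotationBundle, truth: GroundTruth,
                        config: SimulationConfig) -> dict[str, dict]:
    """Read intervals + library size per timepoint.

    Read-start density inside late regions exceeds background by the
    configured enrichment factor at the E16.5 analog; the factor decays
    toward 1 at the flanking timepoints.
    """
    rng = config.child_rng(4)
    late = truth.all_late_regions()
    genome = sum(annotation.chrom_sizes.values())
    chroms = list(annotation.chrom_sizes)
    offsets = np.cumsum([0] + [annotation.chrom_sizes[c] for c in chroms])
    late_len = int((late["end"] - late["start"]).sum()) if len(late) else 0
    f = config.chip_enrichment
    factors = {tp: 1.0 for tp in config.timepoints}
    if len(config.timepoints) == 4:
        factors[config.timepoints[1]] = f
        factors[config.timepoints[2]] = 1.0 + (f - 1.0) / 2.0
    out: dict[str, dict] = {}
    rl = config.chip_read_length
    for tp in config.timepoints:
        fac = factors[tp]
        n = config.chip_n_reads
        if n == 0 or genome == 0:
            out[tp] = {"reads": pd.DataFrame(columns=["chrom", "start", "end"]),
                       "library_size": max(n, 1)}
            continue
        p_late = (fac * late_len) / (fac * late_len + (genome - late_len)) \
            if late_len else 0.0
        k = int(rng.binomial(n, p_late))
        starts_late = _positions_in_regions(rng, late, k)
        starts_bg = _positions_outside(rng, chroms, offsets, genome, late, n - k)
        reads = pd.concat([starts_late, starts_bg], ignore_index=True)
        reads["end"] = reads["start"] + rl
        reads = reads.sort_values(["chrom", "start"]).reset_index(drop=True)
        out[tp] = {"reads": reads[["chrom", "start", "end"]], "library_size": n}
    return out


def _positions_in_regions(rng, regions: pd.DataFrame, k: int) -> pd.DataFrame:
    if k == 0 or len(regions) == 0:
        return pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "start": pd.Series(dtype=np.int64)})
    lengths = (regions["end"] - regions["start"]).to_numpy(np.int64)
    cum = np.cumsum(lengths)
    offs = rng.integers(0, cum[-1], size=k)
    ridx = np.searchsorted(cum, offs, side="right")
    within = offs - (cum[ridx] - lengths[ridx])
    return pd.DataFrame({
        "chrom": regions["chrom"].to_numpy(object)[ridx],
        "start": regions["start"].to_numpy(np.int64)[ridx] + within})


def _positions_outside(rng, chroms, offsets, genome, late: pd.DataFrame,
                       k: int) -> pd.DataFrame:
    if k == 0:
        return pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "start": pd.Series(dtype=np.int64)})
    from methylkin.intervals import IntervalIndex

    index = IntervalIndex.from_frame(late) if len(late) else None
    chrom_out, start_out = [], []
    need = k
    while need > 0:
        draws = rng.integers(0, genome, size=need * 2 + 10)
        cidx = np.searchsorted(offsets, draws, side="right") - 1
        for g, ci in zip(draws, cidx):
            pos = int(g - offsets[ci])
            chrom = chroms[ci]
            if index is not None and index.any_overlap(chrom, pos, pos + 1):
                continue
            chrom_out.append(chrom)
            start_out.append(pos)
            need -= 1
            if need == 0:
                break
    return pd.DataFrame({"chrom": chrom_out,
                         "start": np.array(start_out, dtype=np.int64)})


# ---------------------------------------------------------------------------
# Run emission
# ---------------------------------------------------------------------------


def write_run(config: SimulationConfig, outdir) -> dict:
    """Run every generator and write all outputs under one directory.

    Emits chrom.sizes, genes.tsv, cgis.bed, repeats.tsv, per-sample
    coverage-call files, developmental tracks, ChIP read BEDs with library
    sizes, the ground truth as JSON and a manifest of file hashes.
    """
    os.makedirs(outdir, exist_ok=True)
    annotation, truth = simulate_annotation(config)
    methylomes = simulate_methylomes(annotation, truth, config)
    tracks = simulate_developmental_tracks(annotation, truth, config)
    chip = simulate_chip_track(annotation, truth, config)

    paths: dict[str, str] = {}

    def emit(rel, writer):
        path = os.path.join(outdir, rel)
        os.makedirs(os.path.dirname(path), exist_ok=True)
        writer(path)
        paths[rel] = path

    emit("chrom.sizes", lambda p: write_chrom_sizes(annotation.chrom_sizes, p))
    emit("genes.tsv", lambda p: write_genes(annotation.genes, p))
    emit("cgis.bed", lambda p: write_bed(annotation.cgis, p))
    emit("repeats.tsv", lambda p: write_bed(annotation.repeats, p))
    for cohort, groups in methylomes.items():
        for group, callsets in groups.items():
            for cs in callsets:
                emit(f"calls/{cohort}/{group}/{cs.sample_id}.cov",
                     lambda p, cs=cs: write_callset(cs, p))
    for tp, cs in tracks.items():
        emit(f"tracks/{tp.replace('.', '_')}.cov",
             lambda p, cs=cs: write_callset(cs, p))
    lib_sizes = {}
    for tp, entry in chip.items():
        rel = f"chip/{tp.replace('.', '_')}.bed"
        emit(rel, lambda p, e=entry: e["reads"].to_csv(
            p, sep="\t", header=False, index=False))
        lib_sizes[tp] = entry["library_size"]
    emit("chip/library_sizes.tsv", lambda p: pd.Series(lib_sizes).to_csv(
        p, sep="\t", header=False))
    emit("truth.json", lambda p: _write_truth(truth, p))
    emit("config.json", lambda p: _write_config(config, p))

    manifest = {rel: _sha256(path) for rel, path in sorted(paths.items())}
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"annotation": annotation, "truth": truth, "methylomes": methylomes,
            "tracks": tracks, "chip": chip, "manifest": manifest}


def _write_truth(truth: GroundTruth, path) -> None:
    payload = {
        "planted": {c: df.to_dict(orient="list")
                    for c, df in truth.planted.items()},
        "early_regions": truth.early_regions.to_dict(orient="list"),
        "late_pool": truth.late_pool.to_dict(orient="list"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def load_truth_regions(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    return {
        "planted": {c: pd.DataFrame(d) for c, d in payload["planted"].items()},
        "early_regions": pd.DataFrame(payload["early_regions"]),
        "late_pool": pd.DataFrame(payload["late_pool"]),
    }


def _write_config(config: SimulationConfig, path) -> None:
    payload = dataclasses.asdict(config)
    payload["cohorts"] = list(payload["cohorts"])
    payload["timepoints"] = list(payload["timepoints"])
    payload["young_subfamilies"] = list(payload["young_subfamilies"])
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
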