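"""Readers and writers for the external text formats.

Internal convention: all intervals are 0-based half-open.  Per-CpG call
files are 1-based (coverage-file dialect) and are converted exactly once at
this boundary.  Percent methylation is always on the 0-100 scale.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CALL_COLUMNS = ("chrom", "pos", "strand", "meth", "cov")
STRANDS = ("+", "-")


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CpGSite:
    """A single CpG measurement: 1-based plus-strand C position."""

    chrom: str
    pos: int
    strand: str
    meth: int
    cov: int

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.cov < 1:
            raise ValueError(f"cov must be >= 1, got {self.cov}")
        if not 0 <= self.meth <= self.cov:
            raise ValueError(f"meth exceeds coverage ({self.meth} > {self.cov})")


@dataclass
class SampleCallSet:
    """Ordered, validated per-CpG calls for one sample.

    ``sites`` is a DataFrame with columns (chrom, pos, strand, meth, cov),
    sorted by (chrom, pos, strand) with no duplicate site.
    """

    sample_id: str
    group: str = "control"
    cohort: str = "custom"
    sites: pd.DataFrame = field(default_factory=lambda: _empty_sites())

    @classmethod
    def from_frame(cls, sample_id: str, sites: pd.DataFrame,
                   group: str = "control", cohort: str = "custom") -> "SampleCallSet":
        sites = sites.loc[:, list(CALL_COLUMNS)].copy()
        sites["pos"] = sites["pos"].astype(np.int64)
        sites["meth"] = sites["meth"].astype(np.int64)
        sites["cov"] = sites["cov"].astype(np.int64)
        _validate_sites(sites)
        sites = sites.sort_values(["chrom", "pos", "strand"], kind="mergesort")
        sites = sites.reset_index(drop=True)
        return cls(sample_id=sample_id, group=group, cohort=cohort, sites=sites)

    def __len__(self) -> int:
        return len(self.sites)

    def iter_sites(self):
        for row in self.sites.itertuples(index=False):
            yield CpGSite(row.chrom, int(row.pos), row.strand,
                          int(row.meth), int(row.cov))


def _empty_sites() -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": pd.Series(dtype=str),
        "pos": pd.Series(dtype=np.int64),
        "strand": pd.Series(dtype=str),
        "meth": pd.Series(dtype=np.int64),
        "cov": pd.Series(dtype=np.int64),
    })


def _validate_sites(sites: pd.DataFrame) -> None:
    if len(sites) == 0:
        return
    if (sites["pos"] < 1).any():
        raise FormatError("position must be >= 1")
    if (~sites["strand"].isin(STRANDS)).any():
        raise FormatError("strand must be + or -")
    if (sites["cov"] < 1).any():
        raise FormatError("coverage must be >= 1")
    if (sites["meth"] < 0).any() or (sites["meth"] > sites["cov"]).any():
        raise FormatError("meth exceeds coverage")
    if sites.duplicated(["chrom", "pos", "strand"]).any():
        dup = sites[sites.duplicated(["chrom", "pos", "strand"])].iloc[0]
        raise FormatError(
            f"duplicate site {dup['chrom']}:{dup['pos']}{dup['strand']}")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RepeatInterval(GenomicInterval):
    repeat_class: str = "other"
    family: str = ""
    subfamily: str = ""
    young: bool = False


@dataclass(frozen=True)
class Gene:
    """Gene model with exon/UTR block structure (all 0-based half-open)."""

    chrom: str
    start: int
    end: int
    name: str
    strand: str
    exons: tuple[tuple[int, int], ...] = ()
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()
    noncoding: bool = False

    @property
    def tss(self) -> int:
        """0-based position of the transcription start site."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class AnnotationBundle:
    """Gene model + CpG islands + repeats + chromosome sizes."""

    genes: list[Gene]
    cgis: list[GenomicInterval]
    repeats: list[RepeatInterval]
    chrom_sizes: dict[str, int]

    def validate(self) -> None:
        for iv in list(self.cgis) + list(self.repeats):
            size = self.chrom_sizes.get(iv.chrom)
            if size is None:
                raise ValueError(f"unknown chromosome {iv.chrom!r}")
            if iv.end > size:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} beyond "
                    f"chromosome end {size}")
        for g in self.genes:
            size = self.chrom_sizes.get(g.chrom)
            if size is None or g.end > size:
                raise ValueError(f"gene {g.name} outside chromosome bounds")


# ---------------------------------------------------------------------------
# Per-CpG call files (1-based, whitespace-delimited)
# ---------------------------------------------------------------------------


def read_callset(path, sample_id: str, group: str = "control",
                 cohort: str = "custom") -> SampleCallSet:
    """Read a coverage-call file: chrom, 1-based pos, strand, meth, cov.

    Lines starting with ``#`` and blank lines are ignored.  Errors carry
    the 1-based line number of the offending record.
    """
    chroms: list[str] = []
    poss: list[int] = []
    strands: list[str] = []
    meths: list[int] = []
    covs: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 5:
                raise FormatError(
                    f"{path}:{lineno}: expected 5 fields, got {len(fields)}")
            chrom, pos_s, strand, meth_s, cov_s = fields
            try:
                pos, meth, cov = int(pos_s), int(meth_s), int(cov_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field") from exc
            if pos < 1:
                raise FormatError(f"{path}:{lineno}: position must be >= 1")
            if strand not in STRANDS:
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            if cov < 1:
                raise FormatError(f"{path}:{lineno}: coverage must be >= 1")
            if meth < 0 or meth > cov:
                raise FormatError(f"{path}:{lineno}: meth exceeds coverage")
            chroms.append(chrom)
            poss.append(pos)
            strands.append(strand)
            meths.append(meth)
            covs.append(cov)
    sites = pd.DataFrame({
        "chrom": pd.Series(chroms, dtype=str),
        "pos": pd.Series(poss, dtype=np.int64),
        "strand": pd.Series(strands, dtype=str),
        "meth": pd.Series(meths, dtype=np.int64),
        "cov": pd.Series(covs, dtype=np.int64),
    })
    return SampleCallSet.from_frame(sample_id, sites, group=group, cohort=cohort)


def write_callset(callset: SampleCallSet, path) -> None:
    with open(path, "w") as fh:
        for row in callset.sites.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos}\t{row.strand}\t"
                     f"{row.meth}\t{row.cov}\n")


# ---------------------------------------------------------------------------
# BED-like interval files
# ---------------------------------------------------------------------------


def read_bed(path, kind: str = "generic", chrom_sizes: dict[str, int] | None = None,
             young_list: Sequence[str] | None = None):
    """Read a BED3+ (or RepeatMasker-like TSV) file into sorted intervals.

    kind 'repeat' expects columns chrom, start, end, name, class, family,
    subfamily[, strand]; the young flag is set when the subfamily is in
    *young_list*.  Other kinds parse BED3/BED6.
    """
    if kind not in ("cgi", "repeat", "gene", "generic"):
        raise ValueError(f"unknown kind {kind!r}")
    young = set(young_list or ())
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})")
            if chrom_sizes is not None:
                if chrom not in chrom_sizes:
                    raise FormatError(f"{path}:{lineno}: unknown chrom {chrom!r}")
                if end > chrom_sizes[chrom]:
                    raise FormatError(
                        f"{path}:{lineno}: end beyond chromosome length")
            if kind == "repeat":
                if len(fields) < 7:
                    raise FormatError(
                        f"{path}:{lineno}: repeat records need 7+ columns "
                        "(chrom, start, end, name, class, family, subfamily)")
                name, rclass, family, subfamily = fields[3:7]
                strand = fields[7] if len(fields) > 7 else None
                out.append(RepeatInterval(
                    chrom=chrom, start=start, end=end, name=name,
                    strand=strand, repeat_class=rclass, family=family,
                    subfamily=subfamily, young=subfamily in young))
            else:
                name = fields[3] if len(fields) > 3 else None
                score = None
                if len(fields) > 4 and fields[4] not in (".", ""):
                    score = float(fields[4])
                strand = fields[5] if len(fields) > 5 else None
                out.append(GenomicInterval(
                    chrom=chrom, start=start, end=end, name=name,
                    score=score, strand=strand))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write intervals as BED; repeats get their extra columns appended."""
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if isinstance(iv, RepeatInterval):
                cols += [iv.name or ".", iv.repeat_class, iv.family,
                         iv.subfamily, iv.strand or "."]
            else:
                if iv.name is not None or iv.score is not None or iv.strand is not None:
                    cols.append(iv.name or ".")
                if iv.score is not None or iv.strand is not None:
                    cols.append("." if iv.score is None else f"{iv.score:.1f}")
                if iv.strand is not None:
                    cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Region tables (analysis output)
# ---------------------------------------------------------------------------


def write_regions(regions: pd.DataFrame, path, format: str = "bed") -> None:
    """Write an analysis region table.

    ``bed``: chrom, start, end, name, score (score = mean diff, 1 decimal;
    names auto-generated as DMR_<i> when absent).  ``tsv``: all columns,
    tab-separated with a header, floats at fixed 4-decimal precision so the
    output is byte-stable.
    """
    if format not in ("bed", "tsv"):
        raise ValueError(f"unknown format {format!r}")
    df = regions.copy()
    if format == "bed":
        with open(path, "w") as fh:
            score_col = next(
                (c for c in ("score", "mean_diff", "diff") if c in df.columns),
                None)
            for i, row in enumerate(df.itertuples(index=False), start=1):
                name = getattr(row, "name", None) if "name" in df.columns else None
                if name is None or (isinstance(name, float) and np.isnan(name)):
                    name = f"DMR_{i}"
                score = getattr(row, score_col) if score_col else 0.0
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t"
                         f"{float(score):.1f}\n")
    else:
        df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_regions(path) -> pd.DataFrame:
    """Read a region table written by :func:`write_regions` (either format)."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("chrom\t") or first.startswith("chrom "):
        return pd.read_csv(path, sep="\t")
    ivs = read_bed(path, kind="generic")
    return pd.DataFrame({
        "chrom": [iv.chrom for iv in ivs],
        "start": [iv.start for iv in ivs],
        "end": [iv.end for iv in ivs],
        "name": [iv.name for iv in ivs],
        "score": [iv.score for iv in ivs],
    })


# ---------------------------------------------------------------------------
# Gene models and chromosome sizes
# ---------------------------------------------------------------------------

_GENE_HEADER = ("chrom", "start", "end", "name", "strand",
                "exons", "utr5", "utr3", "biotype")


def _format_blocks(blocks: tuple[tuple[int, int], ...]) -> str:
    return ",".join(f"{s}-{e}" for s, e in blocks) if blocks else "."


def _parse_blocks(text: str) -> tuple[tuple[int, int], ...]:
    if text in (".", ""):
        return ()
    blocks = []
    for part in text.split(","):
        s, e = part.split("-")
        blocks.append((int(s), int(e)))
    return tuple(blocks)


def write_genes(genes: Iterable[Gene], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_HEADER) + "\n")
        for g in genes:
            fh.write("\t".join([
                g.chrom, str(g.start), str(g.end), g.name, g.strand,
                _format_blocks(g.exons), _format_blocks(g.utr5),
                _format_blocks(g.utr3),
                "noncoding" if g.noncoding else "coding",
            ]) + "\n")


def read_genes(path) -> list[Gene]:
    genes: list[Gene] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _GENE_HEADER:
            raise FormatError(f"{path}: unexpected gene-table header")
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != len(_GENE_HEADER):
                raise FormatError(f"{path}:{lineno}: wrong column count")
            chrom, start, end, name, strand, exons, utr5, utr3, biotype = fields
            genes.append(Gene(
                chrom=chrom, start=int(start), end=int(end), name=name,
                strand=strand, exons=_parse_blocks(exons),
                utr5=_parse_blocks(utr5), utr3=_parse_blocks(utr3),
                noncoding=(biotype == "noncoding")))
    genes.sort(key=lambda g: (g.chrom, g.start, g.end))
    return genes


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            fields = raw.split()
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'name length'")
            name, length = fields[0], int(fields[1])
            if length <= 0:
                raise FormatError(f"{path}:{lineno}: non-positive length")
            sizes[name] = length
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def intervals_to_frame(intervals: Sequence[GenomicInterval]) -> pd.DataFrame:
    """Flatten a list of intervals to a (chrom, start, end, ...) DataFrame."""
    if not intervals:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    rows = [dataclasses.asdict(iv) for iv in intervals]
    return pd.DataFrame(rows)
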