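"""Promoter construction and peak-to-promoter target assignment.

Coordinates are 0-based, half-open throughout ([start, end)); touching
intervals do not overlap.  Peaks arrive as BED6/narrowPeak tables, TSS
annotation as BED6; assignment is interval-indexed (one interval tree per
chromosome) and defined to agree exactly with brute-force all-pairs
intersection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from ._errors import ChromosomeNamingError

__all__ = [
    "GenomicInterval",
    "read_bed",
    "write_bed",
    "build_promoters",
    "assign_peaks",
    "binding_lost",
]

_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def read_bed(path) -> pd.DataFrame:
    """Read a BED6 (or narrowPeak; extra columns ignored) file.

    Returns a frame with columns chrom, start, end, name, score, strand;
    absent optional columns are filled (name "", score 0, strand ".").
    Raises on malformed intervals, naming the offending line.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.iloc[:, : min(df.shape[1], 6)]
    df.columns = _BED_COLUMNS[: df.shape[1]]
    for col, default in (("name", ""), ("score", 0), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    bad = df.index[(df["start"] < 0) | (df["start"] >= df["end"])]
    if len(bad):
        raise ValueError(f"{path}: start >= end (or negative) at line {int(bad[0]) + 1}")
    return df[_BED_COLUMNS]


def write_bed(df: pd.DataFrame, path) -> None:
    df[_BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def build_promoters(tss: pd.DataFrame, upstream: int = 2000, downstream: int = 500) -> pd.DataFrame:
    """Strand-aware promoter windows around each gene's TSS.

    ``tss`` is BED-like (chrom, start, end, name, strand) where each record
    is a transcript; the TSS is ``start`` on the + strand and ``end - 1`` on
    the - strand.  With duplicate gene names the longest transcript wins.
    The promoter is [TSS - upstream, TSS + downstream) on +, mirrored on -,
    clipped at 0.  Records without a strand default to + with a warning.

    Returns a frame indexed by gene id with columns chrom, start, end,
    strand, tss.
    """
    df = tss.copy()
    if "strand" not in df.columns:
        df["strand"] = "."
    n_missing = int((~df["strand"].isin(["+", "-"])).sum())
    if n_missing:
        warnings.warn(f"{n_missing} TSS record(s) without strand; assuming +", stacklevel=2)
        df.loc[~df["strand"].isin(["+", "-"]), "strand"] = "+"
    df["_len"] = df["end"] - df["start"]
    df = df.sort_values(["_len", "start"], ascending=[False, True], kind="mergesort")
    df = df.drop_duplicates("name", keep="first")
    minus = df["strand"] == "-"
    tss_pos = df["start"].where(~minus, df["end"] - 1)
    start = (tss_pos - upstream).where(~minus, tss_pos - downstream).clip(lower=0)
    end = (tss_pos + downstream).where(~minus, tss_pos + upstream)
    # minus strand: [TSS - downstream, TSS + upstream), the mirror of the
    # + strand window [TSS - upstream, TSS + downstream) about the TSS.
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "start": start.to_numpy(),
            "end": end.to_numpy(),
            "strand": df["strand"].to_numpy(),
            "tss": tss_pos.to_numpy(),
        },
        index=pd.Index(df["name"].to_numpy(), name="gene_id"),
    )
    return out.sort_index()


def _strip_chr(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


def _check_chrom_naming(peak_chroms: set, promoter_chroms: set) -> None:
    if not peak_chroms or not promoter_chroms:
        return
    if peak_chroms & promoter_chroms:
        return
    stripped_peaks = {_strip_chr(c) for c in peak_chroms}
    stripped_proms = {_strip_chr(c) for c in promoter_chroms}
    if stripped_peaks & stripped_proms:
        raise ChromosomeNamingError(
            "peak and promoter chromosome names differ only by a 'chr' prefix "
            f"(peaks: {sorted(peak_chroms)[:4]}, promoters: {sorted(promoter_chroms)[:4]}); "
            "pass harmonize_chroms=True to normalise both"
        )


def assign_peaks(peaks: pd.DataFrame, promoters: pd.DataFrame, min_overlap: int = 1,
                 harmonize_chroms: bool = False) -> set:
    """Genes whose promoter is overlapped by >= ``min_overlap`` bp of peak.

    Both inputs use 0-based half-open coordinates; a peak ending where a
    promoter starts does not overlap it.  Peaks are indexed in one interval
    tree per chromosome; the result is defined to equal brute-force
    all-pairs intersection.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    pk = peaks.copy()
    pr = promoters.copy()
    if harmonize_chroms:
        pk["chrom"] = pk["chrom"].map(_strip_chr)
        pr["chrom"] = pr["chrom"].map(_strip_chr)
    else:
        _check_chrom_naming(set(pk["chrom"]), set(pr["chrom"]))
    trees: dict[str, IntervalTree] = {}
    for chrom, g in pk.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            zip(g["start"].to_numpy(), g["end"].to_numpy())
        )
    bound = set()
    for gene, row in pr.iterrows():
        tree = trees.get(row["chrom"])
        if tree is None:
            continue
        for hit in tree.overlap(row["start"], row["end"]):
            if min(hit.end, row["end"]) - max(hit.begin, row["start"]) >= min_overlap:
                bound.add(gene)
                break
    return bound


def binding_lost(dmso_peaks: pd.DataFrame, treated_peaks: pd.DataFrame,
                 promoters: pd.DataFrame, min_overlap: int = 1,
                 harmonize_chroms: bool = False) -> set:
    """Genes promoter-bound in the DMSO track but not in the treated track."""
    before = assign_peaks(dmso_peaks, promoters, min_overlap, harmonize_chroms)
    after = assign_peaks(treated_peaks, promoters, min_overlap, harmonize_chroms)
    return before - after


def intersect_bound_with_de(bound: set, de_results, route: str | None = None) -> pd.DataFrame:
    """Bound genes that are also differentially expressed, with direction.

    ``de_results`` is a DifferentialExpressionResults (or its table).
    Returns a frame with columns gene_id, direction, sorted by gene id.
    """
    table = de_results.table if hasattr(de_results, "table") else de_results
    if hasattr(de_results, "pass_genes"):
        passing = de_results.passing(route)
    else:
        passing = table[table["passes_kmcc"] | table["passes_classic"]]
    hit = passing[passing["gene_id"].isin(bound)]
    return hit[["gene_id", "direction"]].sort_values("gene_id").reset_index(drop=True)
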