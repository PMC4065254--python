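"""Multi-line SNV tables: depth filtering, line-specific partitioning,
mutation spectrum and per-bp rate bookkeeping.

A :class:`LineVariantTable` holds per-line single-nucleotide variant calls
against the common reference, plus per-line mean sequencing coverage.
Variants seen in exactly one line (or exactly in a known related line
pair) are the evidence of ENU origin; variants shared more widely reflect
common ancestry or systematic calling artifacts.

Site identity across lines is keyed on (chrom, pos, alt); zygosity is
ignored for specificity classing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = [
    "line_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "depth",
    "genotype_quality",
    "zygosity",
    "flank",
]

_NUCLEOTIDES = {"A", "C", "G", "T"}

#: The four transition substitutions; the remaining eight are transversions.
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _chrom_sort_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


@dataclass
class LineVariantTable:
    """Per-line SNV records plus line metadata (mean coverage)."""

    records: pd.DataFrame
    line_coverage: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.records is None or len(self.records) == 0:
            self.records = pd.DataFrame(columns=VARIANT_COLUMNS)
        missing = [c for c in VARIANT_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        dup = self.records.duplicated(subset=["line_id", "chrom", "pos"])
        if dup.any():
            raise ValueError("duplicate (line, chrom, pos) records in variant table")
        if len(self.records) and (self.records["pos"] < 1).any():
            raise ValueError("positions are 1-based and must be >= 1")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lines(self) -> list[str]:
        return sorted(self.records["line_id"].unique())


@dataclass
class VariantPartition:
    """Disjoint, exhaustive split of sites by line-sharing pattern."""

    exclusive: dict[str, pd.DataFrame]
    shared_pair: pd.DataFrame
    remainder: pd.DataFrame
    related_pair: tuple[str, str] | None = None

    @property
    def n_line_specific(self) -> int:
        return int(sum(len(df) for df in self.exclusive.values()))


def filter_calls(
    table: LineVariantTable,
    min_depth: int = 3,
    max_coverage_mult: float = 2.5,
) -> LineVariantTable:
    """Depth filter: keep records with min_depth <= depth <= mult * line coverage.

    The lower bound removes calls supported by too few reads; the upper
    bound culls copy-number or efficiency artifacts stronger than
    ``max_coverage_mult`` times the line's mean sequencing coverage.
    """
    df = table.records
    if len(df) == 0:
        return LineVariantTable(df.copy(), dict(table.line_coverage))
    missing = set(df["line_id"].unique()) - set(table.line_coverage)
    if missing:
        raise ValueError(f"no mean coverage recorded for line(s): {sorted(missing)}")
    caps = df["line_id"].map(table.line_coverage) * max_coverage_mult
    keep = (df["depth"] >= min_depth) & (df["depth"] <= caps)
    return LineVariantTable(df[keep].reset_index(drop=True), dict(table.line_coverage))


def partition_line_specific(
    table: LineVariantTable,
    related_pair: tuple[str, str] | None = None,
) -> VariantPartition:
    """Partition sites by the set of lines they appear in.

    A site (chrom, pos, alt) is *exclusive* to a line if seen in that line
    only; *shared* if seen in exactly the two related lines; everything
    else (wider sharing) is remainder. Each input site lands in exactly one
    class.
    """
    df = table.records
    lines = table.lines
    if len(df) == 0:
        empty = df.iloc[0:0]
        return VariantPartition({ln: empty.copy() for ln in lines}, empty.copy(), empty.copy(), related_pair)

    site_lines = df.groupby(["chrom", "pos", "alt"], sort=False)["line_id"].agg(frozenset)
    key = pd.MultiIndex.from_frame(df[["chrom", "pos", "alt"]])
    pattern = site_lines.reindex(key).to_numpy()

    # one representative record per site (first occurrence)
    first = ~df.duplicated(subset=["chrom", "pos", "alt"])

    exclusive: dict[str, pd.DataFrame] = {}
    for ln in lines:
        mask = first & (pattern == frozenset([ln]))
        exclusive[ln] = df[mask].reset_index(drop=True)
    if related_pair is not None:
        pair_set = frozenset(related_pair)
        shared_mask = first & (pattern == pair_set)
    else:
        shared_mask = np.zeros(len(df), dtype=bool)
    shared = df[shared_mask].reset_index(drop=True)

    assigned = np.zeros(len(df), dtype=bool)
    for ln in lines:
        assigned |= pattern == frozenset([ln])
    if related_pair is not None:
        assigned |= pattern == frozenset(related_pair)
    remainder = df[first & ~assigned].reset_index(drop=True)
    return VariantPartition(exclusive, shared, remainder, related_pair)


def summarize_partition(
    partition: VariantPartition,
    chrom_order: list[str] | None = None,
) -> pd.DataFrame:
    """Per-chromosome site counts per exclusive line plus the shared pair,
    with a Total row. Record order never affects the table."""
    frames = dict(partition.exclusive)
    if partition.related_pair is not None:
        g, h = partition.related_pair
        frames[f"shared_{g}_{h}"] = partition.shared_pair
    chroms: set[str] = set()
    for df in frames.values():
        chroms.update(df["chrom"].unique())
    if chrom_order is None:
        chrom_order = sorted(chroms, key=_chrom_sort_key)
    out = pd.DataFrame(index=pd.Index(chrom_order, name="chrom"), dtype=int)
    for name, df in frames.items():
        counts = df.groupby("chrom").size()
        out[name] = counts.reindex(chrom_order).fillna(0).astype(int)
    out.loc["Total"] = out.sum()
    return out


def mutation_spectrum(variants: pd.DataFrame | LineVariantTable) -> pd.DataFrame:
    """Counts and percentages per ordered ref>alt substitution.

    Returns a frame indexed by (ref, alt) with columns ``mutation_type``
    (transition/transversion), ``count`` and ``percent``; percentages are
    of the total and sum to 100 within rounding.
    """
    df = variants.records if isinstance(variants, LineVariantTable) else variants
    if len(df):
        bad = ~(
            df["ref"].isin(_NUCLEOTIDES)
            & df["alt"].isin(_NUCLEOTIDES)
            & (df["ref"] != df["alt"])
        )
        if bad.any():
            raise ValueError(
                f"non-SNV records in spectrum input (first at row {int(np.flatnonzero(bad)[0])})"
            )
    pairs = [
        ("A", "G"), ("T", "C"), ("C", "T"), ("G", "A"),  # transitions
        ("A", "C"), ("T", "G"), ("C", "A"), ("G", "T"),
        ("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"),
    ]
    idx = pd.MultiIndex.from_tuples(pairs, names=["ref", "alt"])
    counts = (
        df.groupby(["ref", "alt"]).size().reindex(idx).fillna(0).astype(int)
        if len(df)
        else pd.Series(0, index=idx)
    )
    total = counts.sum()
    out = pd.DataFrame({"count": counts})
    out["mutation_type"] = [
        "transition" if (r, a) in TRANSITIONS else "transversion" for r, a in out.index
    ]
    out["percent"] = 100.0 * out["count"] / total if total else 0.0
    return out[["mutation_type", "count", "percent"]]


def spectrum_share(spectrum: pd.DataFrame, pairs) -> float:
    """Percent of the spectrum in the given set of (ref, alt) pairs,
    e.g. ``[('A','T'), ('T','A')]`` for the AT<->TA transversion share."""
    total = spectrum["count"].sum()
    if total == 0:
        raise ValueError("empty spectrum")
    sub = sum(int(spectrum.loc[p, "count"]) for p in pairs)
    return 100.0 * sub / total


def per_bp_rate(n_variants: int, genome_bp: float, significant: int = 2) -> float:
    """Mutations per base pair, rounded to ``significant`` figures."""
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    if n_variants < 0:
        raise ValueError("n_variants must be non-negative")
    rate = n_variants / genome_bp
    if rate == 0.0:
        return 0.0
    from math import floor, log10

    digits = significant - 1 - floor(log10(abs(rate)))
    return round(rate, digits)
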