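"""Marker-panel construction for an isogenic mapping-partner line.

From the partitioned variant table, candidate genotyping markers are
ranked by (i) specificity class — sites shared by exactly the related
line pair first (strongest evidence of early ENU origin), then
single-line sites, then more widely shared sites — and (ii) ENU-typical
mutation type: A>T / T>A transversions first, then A>G / T>C
transitions, then G>A / C>T transitions, then everything else.
Candidates must carry the maximum Phred genotyping quality (99) and a
flank free of significant repeats. Each autosome is split into three
equal physical thirds (proximal / middle / distal — a pragmatic stand-in
for centromere / middle / telomere on the acrocentric mouse karyotype)
and the best-ranked candidate per bin is selected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import ChromSizes

#: mutation-type preference groups, best (0) first
PREFERENCE_GROUPS: dict[tuple[str, str], int] = {
    ("A", "T"): 0, ("T", "A"): 0,
    ("A", "G"): 1, ("T", "C"): 1,
    ("G", "A"): 2, ("C", "T"): 2,
}

SPECIFICITY_ORDER = {"related-pair-only": 0, "single-line": 1, "other": 2}

BIN_NAMES = ("proximal", "middle", "distal")


@dataclass(frozen=True)
class RepeatRule:
    """Flank repeat screen: reject a homopolymer run of >= ``homopolymer_run``
    nt or >= ``dinucleotide_units`` tandem copies of a dinucleotide."""

    homopolymer_run: int = 8
    dinucleotide_units: int = 4

    def is_repetitive(self, flank: str) -> bool:
        if re.search(r"(.)\1{%d,}" % (self.homopolymer_run - 1), flank):
            return True
        if re.search(r"(..)\1{%d,}" % (self.dinucleotide_units - 1), flank):
            return True
        return False


def candidates_from_partition(partition, focal_line: str) -> pd.DataFrame:
    """Candidate marker sites for one line, labelled by specificity class."""
    frames = []
    shared = partition.shared_pair
    if partition.related_pair and focal_line in partition.related_pair and len(shared):
        frames.append(shared.assign(specificity="related-pair-only"))
    own = partition.exclusive.get(focal_line)
    if own is not None and len(own):
        frames.append(own.assign(specificity="single-line"))
    rem = partition.remainder
    if len(rem):
        in_focal = rem[rem["line_id"] == focal_line]
        if len(in_focal):
            frames.append(in_focal.assign(specificity="other"))
    if not frames:
        cols = list(partition.remainder.columns) + ["specificity"]
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)


def rank_candidates(
    candidates: pd.DataFrame,
    repeat_rule: RepeatRule | None = None,
    min_quality: int = 99,
    relax_types: bool = True,
) -> pd.DataFrame:
    """Filter and order candidate marker sites.

    Candidates below the maximum Phred genotyping quality or with
    repetitive flanks are excluded outright. The survivors are ordered by
    specificity class, then mutation-type preference, then (chrom, pos).
    With ``relax_types=False`` only the three preferred substitution
    groups are admitted; the default keeps lower-preference types at the
    bottom of the order so sparse regions can still be served.
    """
    repeat_rule = repeat_rule or RepeatRule()
    df = candidates.copy()
    if len(df) == 0:
        df["preference"] = pd.Series(dtype=int)
        df["rank_class"] = pd.Series(dtype=int)
        return df
    df = df[df["genotype_quality"] >= min_quality]
    if len(df):
        df = df[~df["flank"].map(repeat_rule.is_repetitive)]
    pref = [
        PREFERENCE_GROUPS.get((r, a), 3)
        for r, a in zip(df["ref"], df["alt"])
    ]
    df = df.assign(preference=pref)
    if not relax_types:
        df = df[df["preference"] < 3]
    spec = df["specificity"].map(SPECIFICITY_ORDER)
    df = df.assign(rank_class=spec * 4 + df["preference"])
    df = df.sort_values(
        ["rank_class", "chrom", "pos"],
        key=lambda s: s.map(_chrom_key) if s.name == "chrom" else s,
    )
    return df.reset_index(drop=True)


def _chrom_key(c: str):
    return int(c) if str(c).isdigit() else 100


def assign_bins(positions: np.ndarray, chrom_length: int) -> np.ndarray:
    """Equal-thirds bin index (0, 1, 2) for 1-based positions."""
    idx = (3 * (np.asarray(positions) - 1)) // chrom_length
    return np.minimum(idx, 2).astype(int)


def select_panel(
    ranked: pd.DataFrame,
    chrom_sizes: ChromSizes,
    per_autosome: int = 3,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Pick the top-ranked candidate in each third of each autosome.

    Ties within a rank class go to the candidate nearer the bin midpoint,
    then to the lower position, so selection is deterministic and
    idempotent. Returns (panel, unfilled) where ``unfilled`` lists
    (chrom, bin_name) pairs with no eligible candidate. The X chromosome
    is excluded.
    """
    if per_autosome != len(BIN_NAMES):
        raise NotImplementedError("panel selection is defined for 3 bins per autosome")
    picks = []
    unfilled: list[tuple[str, str]] = []
    for chrom in chrom_sizes.autosomes:
        length = chrom_sizes[chrom]
        sub = ranked[ranked["chrom"] == chrom]
        bins = assign_bins(sub["pos"].to_numpy(), length) if len(sub) else np.array([], dtype=int)
        for b, name in enumerate(BIN_NAMES):
            cand = sub[bins == b]
            if len(cand) == 0:
                unfilled.append((chrom, name))
                continue
            mid = length * (2 * b + 1) / 6.0
            key = cand.assign(_dist=(cand["pos"] - mid).abs())
            best = key.sort_values(["rank_class", "_dist", "pos"]).iloc[0]
            picks.append({**best.drop("_dist").to_dict(), "bin": name})
    panel = pd.DataFrame(picks)
    if len(panel):
        panel = panel.sort_values(
            ["chrom", "pos"], key=lambda s: s.map(_chrom_key) if s.name == "chrom" else s
        ).reset_index(drop=True)
    return panel, unfilled


def intermarker_distances(sites: pd.DataFrame) -> dict[str, float]:
    """Quantiles of adjacent-site distances, within chromosomes, pooled.

    Returns median and the 25th/75th percentiles of the pooled distances
    between neighbouring sites on the same chromosome.
    """
    dists: list[np.ndarray] = []
    for _, sub in sites.groupby("chrom"):
        pos = np.sort(sub["pos"].to_numpy())
        if len(pos) >= 2:
            dists.append(np.diff(pos))
    if not dists:
        raise ValueError("need at least two sites on some chromosome")
    pooled = np.concatenate(dists)
    q25, q50, q75 = np.percentile(pooled, [25, 50, 75])
    return {"median": float(q50), "q25": float(q25), "q75": float(q75), "n": int(pooled.size)}


def find_gaps(
    sites: pd.DataFrame,
    chrom_sizes: ChromSizes,
    min_gap: float = 3e7,
) -> pd.DataFrame:
    """Maximal marker-free intervals of at least ``min_gap`` bp.

    Intervals are 0-based half-open and include chromosome ends; a
    chromosome with no sites yields one gap spanning it entirely. The gap
    between 1-based sites p < q is [p, q-1).
    """
    rows = []
    by_chrom = {c: g["pos"].to_numpy() for c, g in sites.groupby("chrom")} if len(sites) else {}
    for chrom in chrom_sizes:
        length = chrom_sizes[chrom]
        pos = np.sort(by_chrom.get(chrom, np.array([], dtype=int)))
        # 0-based uncovered stretches between consecutive covered bases
        starts = np.concatenate(([0], pos))
        ends = np.concatenate((pos - 1, [length]))
        for s, e in zip(starts, ends):
            if e - s >= min_gap:
                rows.append({"chrom": chrom, "start": int(s), "end": int(e)})
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    out["length"] = out["end"] - out["start"] if len(out) else pd.Series(dtype=int)
    return out
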