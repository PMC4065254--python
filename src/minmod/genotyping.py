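"""Classification of candidate-marker genotyping assays.

Each candidate site is assayed across up to three sample groups: the
reference colony (expected ref/ref), the SNV line itself (expected
alt/alt if the induced variant went to fixation), and F1 hybrids
(expected ref/alt). The classifier applies these rules in order:

1. every sample no-call                         -> assay_failure
2. any reference-colony sample carries alt      -> reference_divergence
   (colony divergence from the canonical reference, or a reference error)
3. SNV-line samples all ref/ref                 -> call_error
   (the site does not vary; a sequencing call error)
4. SNV-line samples mixed (alt present plus at
   least one ref/ref or ref/alt)                -> residual_heterozygous
5. otherwise (SNV line fixed alt/alt)           -> validated_homozygous

Partial no-calls are classified on the called subset. Classification is
total: every syntactically valid record receives exactly one label.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .genome import ChromSizes

GENOTYPES = {"ref/ref", "ref/alt", "alt/alt", "no-call"}
GROUPS = ("reference_colony", "snv_line", "f1")

CATEGORIES = (
    "assay_failure",
    "reference_divergence",
    "call_error",
    "residual_heterozygous",
    "validated_homozygous",
)


@dataclass
class GenotypeAssayResult:
    """Genotyping calls for one candidate site, keyed by sample group."""

    site_id: str
    calls: dict[str, list[str]] = field(default_factory=dict)
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        unknown_groups = set(self.calls) - set(GROUPS)
        if unknown_groups:
            raise ValueError(f"unknown sample groups: {sorted(unknown_groups)}")
        for group, genotypes in self.calls.items():
            bad = set(genotypes) - GENOTYPES
            if bad:
                raise ValueError(
                    f"site {self.site_id}: invalid genotypes {sorted(bad)} in group {group}"
                )

    def called(self, group: str) -> list[str]:
        return [g for g in self.calls.get(group, []) if g != "no-call"]


def classify_site(result: GenotypeAssayResult) -> str:
    """Apply the validation rules; returns one of :data:`CATEGORIES`."""
    all_calls = [g for calls in result.calls.values() for g in calls]
    if not all_calls or all(g == "no-call" for g in all_calls):
        return "assay_failure"
    ref_called = result.called("reference_colony")
    if any(g in ("ref/alt", "alt/alt") for g in ref_called):
        return "reference_divergence"
    line_called = result.called("snv_line")
    if line_called and all(g == "ref/ref" for g in line_called):
        return "call_error"
    has_alt = any(g in ("ref/alt", "alt/alt") for g in line_called)
    has_nonfixed = any(g in ("ref/ref", "ref/alt") for g in line_called)
    if has_alt and has_nonfixed:
        return "residual_heterozygous"
    return "validated_homozygous"


def summarize_validation(classifications) -> dict[str, int]:
    """Counts per category; every category present, counts sum to the input size."""
    counts = Counter(classifications)
    unknown = set(counts) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown classification labels: {sorted(unknown)}")
    return {cat: counts.get(cat, 0) for cat in CATEGORIES}


def read_genotype_calls_tsv(path) -> list[GenotypeAssayResult]:
    """Read long-format genotype calls (site_id, sample, group, genotype,
    and optionally chrom/pos) into per-site assay results."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    required = {"site_id", "sample", "group", "genotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    results = []
    for site_id, sub in df.groupby("site_id", sort=False):
        calls: dict[str, list[str]] = {}
        for group, gsub in sub.groupby("group", sort=False):
            calls[group] = list(gsub["genotype"])
        chrom = str(sub["chrom"].iloc[0]) if "chrom" in sub else None
        pos = int(sub["pos"].iloc[0]) if "pos" in sub else None
        results.append(GenotypeAssayResult(str(site_id), calls, chrom=chrom, pos=pos))
    return results


def write_genotype_calls_tsv(results: list[GenotypeAssayResult], path) -> None:
    """Long-format inverse of :func:`read_genotype_calls_tsv`."""
    rows = []
    for res in results:
        for group, genotypes in res.calls.items():
            for i, g in enumerate(genotypes):
                row = {
                    "site_id": res.site_id,
                    "sample": f"{group}-{i}",
                    "group": group,
                    "genotype": g,
                }
                if res.chrom is not None:
                    row["chrom"] = res.chrom
                    row["pos"] = res.pos
                rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def export_panel_map(
    results: list[GenotypeAssayResult],
    classifications: list[str],
    chrom_sizes: ChromSizes,
    out_dir: str | Path,
    prefix: str = "panel",
) -> dict[str, Path]:
    """Write the validated mapping-panel map as BED + TSV tracks.

    Validated-homozygous and residual-heterozygous sites go to separate
    tracks. Sites must fall within their chromosome.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for res, label in zip(results, classifications, strict=True):
        if label not in ("validated_homozygous", "residual_heterozygous"):
            continue
        if res.chrom is None or res.pos is None:
            raise ValueError(f"site {res.site_id} lacks coordinates")
        if res.pos < 1 or res.pos > chrom_sizes[res.chrom]:
            raise ValueError(
                f"site {res.site_id} at {res.chrom}:{res.pos} outside chromosome"
            )
        rows.append(
            {"site_id": res.site_id, "chrom": res.chrom, "pos": res.pos, "status": label}
        )
    df = pd.DataFrame(rows, columns=["site_id", "chrom", "pos", "status"])
    paths: dict[str, Path] = {}
    for label, tag in (
        ("validated_homozygous", "validated"),
        ("residual_heterozygous", "heterozygous"),
    ):
        sub = df[df["status"] == label]
        bed = sub.assign(start=sub["pos"] - 1, end=sub["pos"])[
            ["chrom", "start", "end", "site_id"]
        ]
        bed_path = out_dir / f"{prefix}.{tag}.bed"
        bed.to_csv(bed_path, sep="\t", header=False, index=False)
        tsv_path = out_dir / f"{prefix}.{tag}.tsv"
        sub.to_csv(tsv_path, sep="\t", index=False)
        paths[f"{tag}_bed"] = bed_path
        paths[f"{tag}_tsv"] = tsv_path
    return paths
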