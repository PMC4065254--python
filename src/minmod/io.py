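"""Readers/writers for the package's interchange formats.

TSV is the canonical interchange; VCF 4.2 (via pysam) and BED (0-based
half-open) are supported at the boundaries. Every writer prepends a
provenance comment header (tool version, seed, config hash) which the
readers skip.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import pysam
import yaml

from . import __version__
from .genome import ChromSizes
from .variants import VARIANT_COLUMNS, LineVariantTable

logger = logging.getLogger("minmod")

_NUCLEOTIDES = {"A", "C", "G", "T"}


def provenance_lines(seed: int | None = None, config_hash: str | None = None) -> list[str]:
    parts = [f"minmod v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    return ["# " + " ".join(parts)]


def _write_tsv(df: pd.DataFrame, path, seed=None, config_hash=None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in provenance_lines(seed, config_hash):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


# -- phenotype cohorts -------------------------------------------------------

COHORT_COLUMNS = ["kindred_id", "animal_id", "carrier", "tumor_count", "lifespan_days"]


def write_cohort_tsv(cohort: pd.DataFrame, path, seed=None) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    _write_tsv(cohort[COHORT_COLUMNS], path, seed=seed)


def read_cohort_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: not a cohort table, missing {missing}")
    return df


# -- chromosome sizes --------------------------------------------------------

def write_chrom_sizes(sizes: ChromSizes, path) -> None:
    df = pd.DataFrame({"chrom": list(sizes), "length": [sizes[c] for c in sizes]})
    df.to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path) -> ChromSizes:
    df = pd.read_csv(path, sep="\t", names=["chrom", "length"], comment="#", dtype={"chrom": str})
    return ChromSizes(dict(zip(df["chrom"], df["length"].astype(int))))


# -- variant tables ----------------------------------------------------------

def write_variants_tsv(table: LineVariantTable, path, seed=None) -> None:
    df = table.records
    path = Path(path)
    with path.open("w") as fh:
        for line in provenance_lines(seed):
            fh.write(line + "\n")
        for ln in sorted(table.line_coverage):
            fh.write(f"# coverage {ln} {table.line_coverage[ln]}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_variants_tsv(path) -> LineVariantTable:
    coverage: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].split()
            if parts[:1] == ["coverage"] and len(parts) == 3:
                coverage[parts[1]] = float(parts[2])
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "line_id": str})
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: not a variant table, missing {missing}")
    return LineVariantTable(df[VARIANT_COLUMNS], coverage)


def write_variants_vcf(table: LineVariantTable, path, chrom_sizes: ChromSizes) -> None:
    """Minimal VCF 4.2: one record per (line, site), LINE/DP/GQ/ZYG/FLANK in INFO."""
    header = pysam.VariantHeader()
    for chrom in chrom_sizes:
        header.contigs.add(chrom, length=chrom_sizes[chrom])
    header.info.add("LINE", 1, "String", "SNV line carrying the variant")
    header.info.add("DP", 1, "Integer", "Read depth")
    header.info.add("GQ", 1, "Integer", "Phred genotyping quality")
    header.info.add("ZYG", 1, "String", "Zygosity (hom/het)")
    header.info.add("FLANK", 1, "String", "Flanking sequence around the site")
    header.add_line(f"##source=minmod_v{__version__}")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        df = table.records.sort_values(
            ["chrom", "pos"], key=lambda s: s if s.name == "pos" else s.astype(str)
        )
        for row in df.itertuples(index=False):
            rec = out.new_record(
                contig=row.chrom, start=row.pos - 1, alleles=(row.ref, row.alt)
            )
            rec.info["LINE"] = row.line_id
            rec.info["DP"] = int(row.depth)
            rec.info["GQ"] = int(row.genotype_quality)
            rec.info["ZYG"] = row.zygosity
            rec.info["FLANK"] = row.flank
            out.write(rec)


def read_variants_vcf(path, line_coverage: dict[str, float] | None = None) -> LineVariantTable:
    """Read a (possibly hand-made) VCF; positions stay 1-based.

    Records whose REF or ALT is not a single nucleotide are skipped with
    a warning naming the offending position; unknown INFO keys are
    ignored.
    """
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alt = rec.alts[0] if rec.alts else None
            if alt is None or len(rec.ref) != 1 or len(alt) != 1 or alt not in _NUCLEOTIDES:
                warnings.warn(
                    f"{path}: skipping non-SNV record at {rec.contig}:{rec.pos}",
                    stacklevel=2,
                )
                continue
            info = dict(rec.info)
            rows.append(
                {
                    "line_id": info.get("LINE", "unknown"),
                    "chrom": rec.contig,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": alt,
                    "depth": int(info.get("DP", 0)),
                    "genotype_quality": int(info.get("GQ", 0)),
                    "zygosity": info.get("ZYG", "hom"),
                    "flank": info.get("FLANK", ""),
                }
            )
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return LineVariantTable(df, line_coverage or {})


# -- BED ---------------------------------------------------------------------

def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write (chrom, start, end[, name]) rows as BED (0-based half-open)."""
    cols = [c for c in ("chrom", "start", "end", "name", "site_id") if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    return df


# -- run configuration -------------------------------------------------------

@dataclass
class RunConfig:
    """Validated run parameters; defaults are the colony's published values."""

    mean_tumor_count: float = 99.8
    nb_shape: float = 9.8
    class_weights: tuple[float, float, float] = (0.39, 0.41, 0.20)
    suppressor_median: float = 0.6
    enhancer_median: float = 1.8
    effect_log_sd: float = 0.2
    segregation: float = 0.5
    alpha: float = 0.05
    fdr_q: float = 0.05
    power_target: float = 0.9
    discovery_prob: float = 0.95
    min_depth: int = 3
    max_coverage_mult: float = 2.5
    min_genotype_quality: int = 99
    min_gap_bp: float = 3.0e7
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mean_tumor_count <= 0 or self.nb_shape <= 0:
            raise ValueError("colony parameters must be positive")
        w = self.class_weights
        if len(w) != 3 or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("class_weights must be three probabilities summing to 1")
        for name in ("alpha", "fdr_q", "power_target", "discovery_prob"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "class_weights" in raw:
            raw["class_weights"] = tuple(raw["class_weights"])
        return cls(**raw)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha1(canon.encode()).hexdigest()[:12]
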