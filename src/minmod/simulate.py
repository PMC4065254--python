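"""Synthetic cohorts, variant tables and genotyping fixtures.

These generators emulate the statistical structure the screen analysis
assumes, so every downstream stage is testable without any external data:

* Min/+ phenotype cohorts — tumor counts NB(99.8, 9.8) as in the closed
  C57BL/6JD colony, kindreds with a latent modifier class drawn from the
  segregating three-component mixture, Bernoulli(1/2) carrier
  segregation, multiplicative fold effects on the NB mean only, and
  lifespans negatively linked to tumor burden;
* multi-line SNV tables at ~1.1e-6 mutations/bp with the published ENU
  substitution spectrum, one related line pair sharing early-origin
  variants, and residual heterozygosity from incomplete inbreeding;
* genotyping-assay fixtures realising any requested mix of the five
  Sequenom validation outcomes.

All generators are deterministic per master seed, drawing from named
substreams (:func:`minmod.rng.substream`) so the modules stay decoupled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import datasets
from .effects import FoldEffect, TruncatedLogNormalEffect
from .genome import ChromSizes
from .genotyping import CATEGORIES, GenotypeAssayResult
from .phenotype import GaussianLogPhenotype, NegativeBinomialPhenotype
from .rng import substream
from .variants import VARIANT_COLUMNS, LineVariantTable

CLASS_NAMES = ("none", "suppressor", "enhancer")


@dataclass(frozen=True)
class SurvivalLink:
    """log(lifespan) = intercept - slope * log(count + 1) + N(0, noise_sd).

    Defaults put an animal with ~100 tumors at ~180 days with a ~20%
    coefficient of variation, a realistic lifespan scale for Min mice.
    """

    intercept: float = 7.5
    slope: float = 0.5
    noise_sd: float = 0.2

    def sample_lifespans(self, rng: np.random.Generator, counts: np.ndarray) -> np.ndarray:
        mu = self.intercept - self.slope * np.log(np.asarray(counts, dtype=float) + 1.0)
        return np.exp(mu + rng.normal(0.0, self.noise_sd, size=len(mu)))


@dataclass(frozen=True)
class ColonyModel:
    """Baseline colony phenotype: NB tumor counts plus the survival link."""

    mean_tumor_count: float = datasets.COLONY_MEAN_TUMOR_COUNT
    nb_shape: float = datasets.COLONY_NB_SHAPE
    survival_link: SurvivalLink = field(default_factory=SurvivalLink)

    def __post_init__(self) -> None:
        if self.mean_tumor_count <= 0 or self.nb_shape <= 0:
            raise ValueError("mean_tumor_count and nb_shape must be positive")

    def phenotype_model(self) -> NegativeBinomialPhenotype:
        return NegativeBinomialPhenotype(self.mean_tumor_count, self.nb_shape)

    def lifespan_model(self) -> GaussianLogPhenotype:
        """Normal log-lifespan channel induced by the survival link.

        Approximates log(count + 1) by log(mean) at the baseline; the
        fold effect enters through the link slope.
        """
        link = self.survival_link
        mu = link.intercept - link.slope * np.log(self.mean_tumor_count)
        # count dispersion propagated through the link plus link noise
        cv2 = (1.0 / self.mean_tumor_count) + 1.0 / self.nb_shape
        sigma = float(np.sqrt(link.noise_sd**2 + link.slope**2 * cv2))
        return GaussianLogPhenotype(float(mu), sigma, effect_slope=link.slope)


@dataclass(frozen=True)
class ModifierClassParams:
    """Segregating three-component mixture over kindreds.

    ``class_weights`` = (unaffected, suppressor, enhancer); each progeny
    of a modifier kindred inherits the modifier with probability
    ``segregation_prob``. Defaults are the estimated class weights
    (0.39, 0.41, 0.20) with log-normal fold effects (suppressor median
    0.6, enhancer median 1.8, log-SD 0.2).
    """

    class_weights: tuple[float, float, float] = datasets.MODIFIER_CLASS_WEIGHTS
    suppressor_effect: FoldEffect = field(
        default_factory=TruncatedLogNormalEffect.suppressor
    )
    enhancer_effect: FoldEffect = field(
        default_factory=TruncatedLogNormalEffect.enhancer
    )
    segregation_prob: float = 0.5

    def __post_init__(self) -> None:
        w = np.asarray(self.class_weights, dtype=float)
        if w.shape != (3,) or np.any(w < 0) or np.any(w > 1):
            raise ValueError("class_weights must be three probabilities")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"class_weights sum to {w.sum():.12f}, not 1")
        if not 0.0 < self.segregation_prob <= 1.0:
            raise ValueError("segregation_prob must be in (0, 1]")

    def effect(self, latent_class: str) -> FoldEffect | None:
        if latent_class == "suppressor":
            return self.suppressor_effect
        if latent_class == "enhancer":
            return self.enhancer_effect
        return None


@dataclass(frozen=True)
class AnimalRecord:
    """One Min/+ animal of a phenotyped kindred."""

    kindred_id: str
    animal_id: str
    is_carrier: bool
    tumor_count: int
    lifespan_days: float

    def __post_init__(self) -> None:
        if self.tumor_count < 0:
            raise ValueError("tumor_count must be non-negative")
        if self.lifespan_days <= 0:
            raise ValueError("lifespan_days must be positive")


@dataclass(frozen=True)
class Kindred:
    """A G1 founder's progeny cluster with its latent modifier state."""

    kindred_id: str
    latent_class: str
    fold_effect: float
    animals: tuple[AnimalRecord, ...]

    def __post_init__(self) -> None:
        if self.latent_class not in CLASS_NAMES:
            raise ValueError(f"unknown latent class {self.latent_class!r}")
        if (self.latent_class == "none") != (self.fold_effect == 1.0):
            raise ValueError("fold_effect must be 1 exactly when latent_class is 'none'")

    @property
    def tumor_counts(self) -> np.ndarray:
        return np.array([a.tumor_count for a in self.animals])

    @property
    def lifespans(self) -> np.ndarray:
        return np.array([a.lifespan_days for a in self.animals])


def simulate_control_cohort(
    colony: ColonyModel, n_animals: int, seed: int
) -> list[AnimalRecord]:
    """Unmodified Min/+ animals: i.i.d. NB counts, linked lifespans."""
    if n_animals < 0:
        raise ValueError("n_animals must be non-negative")
    rng = substream(seed, "control_cohort")
    model = colony.phenotype_model()
    counts = model.rvs(rng, n_animals)
    lifespans = colony.survival_link.sample_lifespans(rng, counts)
    return [
        AnimalRecord("control", f"control-{i}", False, int(c), float(t))
        for i, (c, t) in enumerate(zip(counts, lifespans))
    ]


def simulate_kindreds(
    colony: ColonyModel,
    classes: ModifierClassParams,
    n_kindreds: int,
    progeny_per_kindred: int,
    seed: int,
) -> list[Kindred]:
    """Kindred cohort under the segregating three-component mixture.

    Each kindred draws a latent class from ``class_weights``; modifier
    kindreds draw one fold effect and pass it to each progeny with
    probability ``segregation_prob``. Carriers have counts NB(f * mean,
    shape); non-carriers and unaffected-kindred animals NB(mean, shape).
    """
    if n_kindreds < 0 or progeny_per_kindred < 0:
        raise ValueError("n_kindreds and progeny_per_kindred must be non-negative")
    rng = substream(seed, "kindreds")
    classes_drawn = rng.choice(3, size=n_kindreds, p=np.asarray(classes.class_weights))
    kindreds: list[Kindred] = []
    for k in range(n_kindreds):
        latent = CLASS_NAMES[classes_drawn[k]]
        effect = classes.effect(latent)
        fold = 1.0 if effect is None else float(effect.rvs(rng, 1)[0])
        if latent == "none":
            carriers = np.zeros(progeny_per_kindred, dtype=bool)
        else:
            carriers = rng.random(progeny_per_kindred) < classes.segregation_prob
        folds = np.where(carriers, fold, 1.0)
        if progeny_per_kindred:
            counts = rng.negative_binomial(
                colony.nb_shape, colony.nb_shape / (colony.nb_shape + folds * colony.mean_tumor_count)
            )
        else:
            counts = np.array([], dtype=int)
        lifespans = colony.survival_link.sample_lifespans(rng, counts)
        animals = tuple(
            AnimalRecord(
                f"K{k:05d}", f"K{k:05d}-{j}", bool(carriers[j]), int(counts[j]),
                float(lifespans[j]),
            )
            for j in range(progeny_per_kindred)
        )
        kindreds.append(Kindred(f"K{k:05d}", latent, fold, animals))
    return kindreds


def cohort_to_frame(kindreds: list[Kindred]) -> pd.DataFrame:
    """Flatten a kindred cohort to the canonical phenotype table."""
    rows = [
        {
            "kindred_id": a.kindred_id,
            "animal_id": a.animal_id,
            "carrier": int(a.is_carrier),
            "tumor_count": a.tumor_count,
            "lifespan_days": a.lifespan_days,
        }
        for kin in kindreds
        for a in kin.animals
    ]
    return pd.DataFrame(
        rows, columns=["kindred_id", "animal_id", "carrier", "tumor_count", "lifespan_days"]
    )


def _random_flank(rng: np.random.Generator, ref: str, half: int = 20) -> str:
    left = "".join(rng.choice(list("ACGT"), size=half))
    right = "".join(rng.choice(list("ACGT"), size=half))
    return left + ref + right


def simulate_variant_lines(
    genome: ChromSizes,
    rate_per_bp: float = 1.1e-6,
    spectrum: dict[tuple[str, str], float] | None = None,
    n_lines: int = 6,
    line_names: tuple[str, ...] | None = None,
    related_pair: tuple[str, str] | None = None,
    shared_fraction: float = 792.0 / (792 + 1225 + 2520),
    residual_het_rate: float = 0.125,
    mean_coverage: float = 5.7,
    seed: int = 0,
) -> LineVariantTable:
    """Multi-line SNV table with Poisson variant placement.

    Per-line variant counts are Poisson(rate * genome length) placed
    uniformly along chromosomes (no hotspots); substitution categories
    follow ``spectrum`` (default: the published ENU spectrum
    proportions); the related pair shares a fraction of its union of
    variants (default: the published shared/(shared + both exclusives)
    ratio); ``residual_het_rate`` of records are flagged heterozygous.
    """
    if rate_per_bp < 0:
        raise ValueError("rate_per_bp must be non-negative")
    if not 0.0 <= shared_fraction < 1.0:
        raise ValueError("shared_fraction must be in [0, 1)")
    if spectrum is None:
        total = sum(datasets.ENU_SPECTRUM_COUNTS.values())
        spectrum = {k: v / total for k, v in datasets.ENU_SPECTRUM_COUNTS.items()}
    probs = np.asarray(list(spectrum.values()), dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("spectrum probabilities must sum to 1")
    pairs = list(spectrum.keys())
    if line_names is None:
        line_names = tuple(datasets.SNV_LINES[:n_lines])
    if len(line_names) != n_lines:
        raise ValueError("line_names length must equal n_lines")
    if related_pair is not None and not set(related_pair) <= set(line_names):
        raise ValueError("related_pair must name simulated lines")

    rng = substream(seed, "variant_lines")
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    chrom_p = lengths / lengths.sum()
    lam = rate_per_bp * lengths.sum()

    def draw_sites(n: int, line_ids: list[str]) -> list[dict]:
        chrom_idx = rng.choice(len(chroms), size=n, p=chrom_p)
        pos = (rng.random(n) * lengths[chrom_idx]).astype(np.int64) + 1
        cat = rng.choice(len(pairs), size=n, p=probs)
        rows = []
        for i in range(n):
            ref, alt = pairs[cat[i]]
            flank = _random_flank(rng, ref)
            for ln in line_ids:
                rows.append(
                    {
                        "line_id": ln,
                        "chrom": chroms[chrom_idx[i]],
                        "pos": int(pos[i]),
                        "ref": ref,
                        "alt": alt,
                        "depth": int(rng.poisson(mean_coverage)) + 1,
                        "genotype_quality": 99 if rng.random() < 0.9 else int(rng.integers(30, 99)),
                        "zygosity": "het" if rng.random() < residual_het_rate else "hom",
                        "flank": flank,
                    }
                )
        return rows

    rows: list[dict] = []
    # shared fraction sigma of the pair's union translates to a per-draw
    # shared share sigma' = 2*sigma/(1+sigma) so each related line's
    # expected total stays at rate * genome length
    for ln in line_names:
        if related_pair is not None and ln in related_pair:
            continue
        rows.extend(draw_sites(rng.poisson(lam), [ln]))
    if related_pair is not None:
        sigma_draw = 2.0 * shared_fraction / (1.0 + shared_fraction)
        rows.extend(draw_sites(rng.poisson(lam * sigma_draw), list(related_pair)))
        for ln in related_pair:
            rows.extend(draw_sites(rng.poisson(lam * (1.0 - sigma_draw)), [ln]))

    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    if len(df):
        df = df.drop_duplicates(subset=["line_id", "chrom", "pos"]).reset_index(drop=True)
    coverage = {ln: mean_coverage for ln in line_names}
    return LineVariantTable(df, coverage)


def variant_table_from_published_counts(
    seed: int = 0, spacing: int = 100_000
) -> LineVariantTable:
    """Synthetic variant table realising the published per-chromosome counts.

    Reconstructs a table whose line-specific and related-pair-shared site
    counts per chromosome equal the published Table of line-specific
    candidate variants for the six B6.SNV lines (totals 3246, 2932, 2051,
    1198, 1225, 2520; shared 792), and whose line-specific substitution
    categories realise the published spectrum counts exactly (their
    totals coincide at 13,172). Positions are evenly spaced and
    synthetic; only the bookkeeping is faithful.
    """
    rng = substream(seed, "published_counts_fixture")
    # exact category multiset for the line-specific sites, in a
    # deterministic shuffled order
    spec_pairs = list(datasets.ENU_SPECTRUM_COUNTS)
    cat_queue: list[tuple[str, str]] = [
        pair for pair, n in datasets.ENU_SPECTRUM_COUNTS.items() for _ in range(n)
    ]
    rng.shuffle(cat_queue)  # type: ignore[arg-type]
    spec_probs = np.array(list(datasets.ENU_SPECTRUM_COUNTS.values()), dtype=float)
    spec_probs /= spec_probs.sum()
    rows: list[dict] = []

    def add_site(lines: list[str], chrom: str, pos: int, pair: tuple[str, str]) -> None:
        ref, alt = pair
        flank = _random_flank(rng, ref)
        for ln in lines:
            rows.append(
                {
                    "line_id": ln,
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "depth": 6,
                    "genotype_quality": 99,
                    "zygosity": "hom",
                    "flank": flank,
                }
            )

    qi = 0
    for chrom, counts in datasets.LINE_SPECIFIC_COUNTS.items():
        pos = 1
        for ln, n in zip(datasets.SNV_LINES, counts):
            for _ in range(n):
                add_site([ln], chrom, pos, cat_queue[qi])
                qi += 1
                pos += spacing
        for _ in range(datasets.RELATED_PAIR_SHARED_COUNTS[chrom]):
            pair = spec_pairs[rng.choice(len(spec_pairs), p=spec_probs)]
            add_site(list(datasets.RELATED_PAIR), chrom, pos, pair)
            pos += spacing
    coverage = {ln: 5.7 for ln in datasets.SNV_LINES}
    return LineVariantTable(pd.DataFrame(rows, columns=VARIANT_COLUMNS), coverage)


def simulate_genotyping_fixture(
    category_counts: dict[str, int],
    seed: int = 0,
    chrom_sizes: ChromSizes | None = None,
) -> list[GenotypeAssayResult]:
    """Assay fixtures that classify back to exactly the requested counts.

    For each validation category the generator emits records whose
    genotype patterns trigger precisely that classification rule:
    all-no-call (failure), alt in the reference colony (divergence),
    all-ref SNV line (call error), mixed SNV-line genotypes (residual
    heterozygosity), or textbook concordance (validated homozygous).
    """
    unknown = set(category_counts) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    if any(v < 0 for v in category_counts.values()):
        raise ValueError("category counts must be non-negative")
    if chrom_sizes is None:
        chrom_sizes = datasets.mm9_chrom_sizes()
    rng = substream(seed, "genotyping_fixture")
    patterns = {
        "assay_failure": {
            "reference_colony": ["no-call"] * 3,
            "snv_line": ["no-call"] * 3,
            "f1": ["no-call"] * 3,
        },
        "reference_divergence": {
            "reference_colony": ["ref/alt", "alt/alt", "ref/alt"],
            "snv_line": ["alt/alt"] * 3,
            "f1": ["ref/alt"] * 3,
        },
        "call_error": {
            "reference_colony": ["ref/ref"] * 3,
            "snv_line": ["ref/ref"] * 3,
            "f1": ["ref/ref"] * 3,
        },
        "residual_heterozygous": {
            "reference_colony": ["ref/ref"] * 3,
            "snv_line": ["alt/alt", "ref/alt", "ref/ref"],
            "f1": ["ref/alt"] * 3,
        },
        "validated_homozygous": {
            "reference_colony": ["ref/ref"] * 3,
            "snv_line": ["alt/alt"] * 3,
            "f1": ["ref/alt"] * 3,
        },
    }
    chroms = list(chrom_sizes)
    results: list[GenotypeAssayResult] = []
    i = 0
    for category in CATEGORIES:
        for _ in range(category_counts.get(category, 0)):
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(1, chrom_sizes[chrom] + 1))
            results.append(
                GenotypeAssayResult(
                    site_id=f"site-{i:04d}",
                    calls={g: list(v) for g, v in patterns[category].items()},
                    chrom=chrom,
                    pos=pos,
                )
            )
            i += 1
    return results
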