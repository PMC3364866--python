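"""Synthetic genotype panels with the statistical structure of a
focal-species-ascertained SNP survey across hybridising duck species.

No genotype data accompany the study this package models, so every pipeline
stage is exercised on panels generated here: ancestral allele frequencies
are drawn, each satellite species' frequency drifts away from the focal
species under Wright-Fisher sampling with one-way gametic migration from
the focal gene pool (a star topology around the abundant focal species),
a SNP panel is ascertained by requiring polymorphism in a finite focal
discovery sample (which produces the classic ascertainment bias towards
high-MAF loci), and finally individual genotypes are drawn under
Hardy-Weinberg proportions with per-species missingness and optional F1
hybrids.

The default configuration mirrors the study's shape: a 364-locus panel,
six species sampled at 197/7/9/14/10/17 individuals, 4% missingness in the
focal species and 14-24% in the others, and one F1 hybrid. Divergence
durations and population sizes are desk-scale (hundreds of generations,
hundreds of diploids) so the qualitative structure — a gradient of shared
polymorphism declining with divergence and rising with hybridisation —
emerges in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "SpeciesRecipe",
    "PanelConfig",
    "SyntheticTruth",
    "evolve_panel",
    "ascertain_loci",
    "sample_genotypes",
    "generate_panel",
]


@dataclass(frozen=True)
class SpeciesRecipe:
    """Per-species demography and sampling for the generator.

    ``divergence`` is the number of generations since the species branched
    off the focal lineage (0 for the focal species itself);
    ``hybridisation_rate`` is the per-generation fraction of its gamete
    pool contributed by the focal species.
    """

    name: str
    diploid_size: int
    divergence: int
    hybridisation_rate: float
    sample_size: int
    missingness: float

    def __post_init__(self) -> None:
        if self.diploid_size < 1 or self.sample_size < 0 or self.divergence < 0:
            raise ValueError(f"invalid recipe for {self.name}")
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must be in [0, 1)")
        if not 0.0 <= self.hybridisation_rate <= 0.5:
            raise ValueError("hybridisation_rate must be in [0, 0.5]")


def _default_species() -> tuple[SpeciesRecipe, ...]:
    # Satellite divergences are several multiples of their diploid size, so
    # drift purges most ancestral polymorphism unless gene flow from the
    # focal species sustains it; the focal lineage is large relative to the
    # tree depth and keeps most of its panel segregating.
    return (
        SpeciesRecipe("platyrhynchos", 5000, 0, 0.0, 197, 0.04),
        SpeciesRecipe("acuta", 200, 800, 0.001, 7, 0.14),
        SpeciesRecipe("crecca", 200, 800, 0.001, 9, 0.16),
        SpeciesRecipe("penelope", 200, 1200, 0.00025, 14, 0.20),
        SpeciesRecipe("strepera", 200, 1200, 0.00025, 10, 0.18),
        SpeciesRecipe("fuligula", 200, 2000, 0.000, 17, 0.24),
    )


@dataclass(frozen=True)
class PanelConfig:
    """Recipe for one synthetic panel.

    ``n_candidate_loci`` candidates are evolved and the first
    ``panel_size`` loci polymorphic in the focal discovery sample are kept;
    oversampling candidates absorbs ascertainment losses. The ancestral
    minor-allele frequency is uniform on ``ancestral_maf_range``.
    """

    panel_size: int = 364
    n_candidate_loci: int = 1500
    focal_species: str = "platyrhynchos"
    ascertainment_sample_size: int = 20
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    species: tuple[SpeciesRecipe, ...] = field(default_factory=_default_species)
    n_hybrids: int = 1
    hybrid_parents: tuple[str, str] = ("platyrhynchos", "acuta")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.panel_size < 1 or self.n_candidate_loci < self.panel_size:
            raise ValueError("need n_candidate_loci >= panel_size >= 1")
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names")
        if self.focal_species not in names:
            raise ValueError(f"focal species {self.focal_species!r} not in recipe")
        if self.n_hybrids:
            if len(set(self.hybrid_parents)) != 2 or any(
                p not in names for p in self.hybrid_parents
            ):
                raise ValueError("hybrid parents must be two distinct panel species")

    def recipe(self, name: str) -> SpeciesRecipe:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass
class SyntheticTruth:
    """Population-level ground truth behind a generated panel."""

    locus_ids: list[str]
    ancestral_frequency: np.ndarray  # (n_loci,)
    terminal_frequency: dict[str, np.ndarray]  # species -> (n_loci,)

    def polymorphic_truth(self, species: str) -> np.ndarray:
        """Boolean flag per locus: segregating at the population level."""
        f = self.terminal_frequency[species]
        return (f > 0) & (f < 1)


def evolve_panel(config: PanelConfig, rng: np.random.Generator | None = None) -> SyntheticTruth:
    """Draw ancestral frequencies and drift each species to the present.

    The focal lineage is simulated once over the deepest divergence; each
    satellite species branches off the focal trajectory at its divergence
    time and then drifts with migration from the focal species'
    contemporaneous frequency (rate m per generation). Deterministic given
    the config seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_loci = config.n_candidate_loci
    lo, hi = config.ancestral_maf_range
    anc = rng.uniform(lo, hi, size=n_loci)

    focal = config.recipe(config.focal_species)
    depth = max(s.divergence for s in config.species)
    two_nf = 2 * focal.diploid_size

    # focal trajectory: index g = generations before present
    traj = np.empty((depth + 1, n_loci))
    traj[depth] = anc
    for g in range(depth - 1, -1, -1):
        traj[g] = rng.binomial(two_nf, traj[g + 1]) / two_nf

    terminal: dict[str, np.ndarray] = {focal.name: traj[0].copy()}
    for sp in config.species:
        if sp.name == focal.name:
            continue
        p = traj[sp.divergence].copy()
        two_n = 2 * sp.diploid_size
        m = sp.hybridisation_rate
        for g in range(sp.divergence - 1, -1, -1):
            pool = (1 - m) * p + m * traj[g + 1]
            p = rng.binomial(two_n, pool) / two_n
        terminal[sp.name] = p

    locus_ids = [f"snp{j:04d}" for j in range(n_loci)]
    return SyntheticTruth(locus_ids, anc, terminal)


def ascertain_loci(
    truth: SyntheticTruth,
    config: PanelConfig,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Ascertain the SNP panel in a finite focal discovery sample.

    Genotypes of ``ascertainment_sample_size`` focal individuals are drawn
    at every candidate locus; a locus enters the panel only if both
    alleles are observed in that sample. The first ``panel_size`` retained
    loci (in candidate order) form the panel. Raises if the candidates
    cannot fill the panel.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    f = truth.terminal_frequency[config.focal_species]
    n = config.ascertainment_sample_size
    # allele copies observed among 2n sampled gametes
    alt = rng.binomial(2 * n, f)
    keep = (alt > 0) & (alt < 2 * n)
    retained = [lid for lid, k in zip(truth.locus_ids, keep) if k]
    if len(retained) < config.panel_size:
        raise RuntimeError(
            f"only {len(retained)} of {config.n_candidate_loci} candidate loci "
            f"were polymorphic in the discovery sample; cannot fill a "
            f"{config.panel_size}-locus panel — increase n_candidate_loci"
        )
    return retained[: config.panel_size]


def sample_genotypes(
    truth: SyntheticTruth,
    panel: list[str],
    config: PanelConfig,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Draw the study sample's genotypes at the panel loci.

    Within each species genotypes follow Hardy-Weinberg proportions at the
    species' terminal frequency; entries are masked missing independently
    at the species' missingness rate. F1 hybrids receive one gamete from
    each parent species' frequency at every locus.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    idx = {lid: j for j, lid in enumerate(truth.locus_ids)}
    cols = np.array([idx[lid] for lid in panel])

    ids: list[str] = []
    species_labels: list[str] = []
    rows: list[np.ndarray] = []

    for sp in config.species:
        f = truth.terminal_frequency[sp.name][cols]
        for i in range(sp.sample_size):
            geno = rng.binomial(1, f) + rng.binomial(1, f)  # two gametes
            miss = rng.random(len(cols)) < sp.missingness
            geno = geno.astype(np.int8)
            geno[miss] = MISSING
            rows.append(geno)
            ids.append(f"{sp.name[:4].upper()}{i + 1:03d}")
            species_labels.append(sp.name)

    if config.n_hybrids:
        pa, pb = config.hybrid_parents
        fa = truth.terminal_frequency[pa][cols]
        fb = truth.terminal_frequency[pb][cols]
        miss_rate = (config.recipe(pa).missingness + config.recipe(pb).missingness) / 2
        for i in range(config.n_hybrids):
            geno = (rng.binomial(1, fa) + rng.binomial(1, fb)).astype(np.int8)
            miss = rng.random(len(cols)) < miss_rate
            geno[miss] = MISSING
            rows.append(geno)
            ids.append(f"HYB{i + 1:03d}")
            species_labels.append(f"F1_{pa}_x_{pb}")

    return GenotypeMatrix(
        individual_ids=ids,
        group_labels=species_labels,
        locus_ids=list(panel),
        genotypes=np.vstack(rows),
        localities=["synthetic"] * len(ids),
    )


def generate_panel(
    config: PanelConfig | None = None,
) -> tuple[GenotypeMatrix, SyntheticTruth, list[str]]:
    """Run the full generator: evolve, ascertain, sample.

    Returns the genotype matrix, the ground truth, and the panel locus
    ids. All randomness flows from ``config.seed``.
    """
    if config is None:
        config = PanelConfig()
    truth = evolve_panel(config)
    panel = ascertain_loci(truth, config)
    matrix = sample_genotypes(truth, panel, config)
    return matrix, truth, panel
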