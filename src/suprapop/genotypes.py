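"""Genotype-matrix data model, I/O, per-group QC and polymorphism sharing.

Genotypes are coded per individual and biallelic locus as 0 (homozygous
reference), 1 (heterozygous), 2 (homozygous alternate) or missing. The
on-disk dialect is a TSV with one row per individual, the first three
columns ``individual_id``, ``species``, ``locality``, the remaining columns
one per locus, and missing genotypes written ``NA``. Biallelic VCF is also
read (GT field; multi-allelic records are skipped with a warning) with a
two-column sidecar TSV mapping sample id to species.

QC statistics are computed per group (species or locality): minor-allele
frequency over called genotypes, observed heterozygosity, missingness, and
an exact Hardy-Weinberg test. A locus is "polymorphic in a group" when both
alleles are observed among that group's called genotypes — the sample-level
definition under which a genotyped panel can actually be assessed.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "LocusSummary",
    "SharingReport",
    "read_genotype_table",
    "write_genotype_table",
    "read_vcf",
    "summarize_locus",
    "summaries_to_frame",
    "hwe_exact_test",
    "hwe_null_distribution",
    "hwe_calibration_pit",
    "polymorphic_loci",
    "sharing_venn",
    "pairwise_test_count",
    "bonferroni_alpha",
]

#: Internal missing-genotype code (the TSV dialect writes ``NA``).
MISSING: int = -1

_VALID_CODES = frozenset({0, 1, 2, MISSING})
_MISSING_TOKEN = "NA"
_META_COLUMNS = ("individual_id", "species", "locality")


@dataclass
class GenotypeMatrix:
    """Individuals x loci matrix of biallelic genotype codes.

    ``genotypes`` is an int8 array of shape (n_individuals, n_loci) holding
    codes 0/1/2 or :data:`MISSING`. ``group_labels`` are species labels;
    ``localities`` are optional finer-grained labels.
    """

    individual_ids: list[str]
    group_labels: list[str]
    locus_ids: list[str]
    genotypes: np.ndarray
    localities: list[str] | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n_ind, n_loc = self.genotypes.shape
        if len(self.individual_ids) != n_ind:
            raise ValueError("individual_ids length does not match genotype rows")
        if len(self.group_labels) != n_ind:
            raise ValueError("group_labels length does not match genotype rows")
        if len(self.locus_ids) != n_loc:
            raise ValueError("locus_ids length does not match genotype columns")
        if len(set(self.individual_ids)) != n_ind:
            raise ValueError("duplicate individual ids")
        if len(set(self.locus_ids)) != n_loc:
            raise ValueError("duplicate locus ids")
        bad = ~np.isin(self.genotypes, list(_VALID_CODES))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"illegal genotype code {self.genotypes[i, j]} for individual "
                f"{self.individual_ids[i]!r} at locus {self.locus_ids[j]!r}"
            )
        if self.localities is None:
            self.localities = [""] * n_ind

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        return list(dict.fromkeys(self.group_labels))

    def subset_group(self, group: str) -> np.ndarray:
        """Genotype rows belonging to ``group`` (raises on unknown label)."""
        mask = np.array([g == group for g in self.group_labels])
        if not mask.any():
            raise KeyError(f"unknown group label {group!r}")
        return self.genotypes[mask]


@dataclass(frozen=True)
class LocusSummary:
    """Per-locus, per-group QC record.

    Statistics are computed over called (non-missing) genotypes only; at a
    locus with no called genotypes in the group they are undefined (NaN)
    and ``polymorphic`` is False.
    """

    locus_id: str
    group_label: str
    n_called: int
    maf: float
    h_obs: float
    missing_fraction: float
    hwe_p: float
    polymorphic: bool


def read_genotype_table(path: str | Path) -> GenotypeMatrix:
    """Read the genotype TSV dialect into a validated :class:`GenotypeMatrix`.

    Unparseable genotype tokens raise a ``ValueError`` naming the
    individual (row) and locus (column).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_meta = [c for c in _META_COLUMNS if c not in df.columns]
    if missing_meta:
        raise ValueError(f"{path}: missing metadata columns {missing_meta}")
    locus_ids = [c for c in df.columns if c not in _META_COLUMNS]
    if not locus_ids:
        raise ValueError(f"{path}: no locus columns")
    codes = np.full((len(df), len(locus_ids)), MISSING, dtype=np.int8)
    for j, locus in enumerate(locus_ids):
        col = df[locus]
        for i, token in enumerate(col):
            if token == _MISSING_TOKEN:
                continue
            if token not in ("0", "1", "2"):
                raise ValueError(
                    f"{path}: illegal genotype token {token!r} for individual "
                    f"{df['individual_id'].iloc[i]!r} at locus {locus!r}"
                )
            codes[i, j] = int(token)
    return GenotypeMatrix(
        individual_ids=df["individual_id"].tolist(),
        group_labels=df["species"].tolist(),
        locus_ids=locus_ids,
        genotypes=codes,
        localities=df["locality"].tolist(),
    )


def write_genotype_table(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a matrix in the genotype TSV dialect (round-trips exactly)."""
    data = {
        "individual_id": matrix.individual_ids,
        "species": matrix.group_labels,
        "locality": matrix.localities,
    }
    tokens = matrix.genotypes.astype(object)
    tokens[matrix.genotypes == MISSING] = _MISSING_TOKEN
    for j, locus in enumerate(matrix.locus_ids):
        data[locus] = [str(t) for t in tokens[:, j]]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_vcf(path: str | Path, species_map: str | Path | dict) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF into a genotype matrix.

    GT 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> missing; phasing is
    ignored. Records with more than one ALT allele are skipped with a
    logged warning. Species labels come from ``species_map``: either a
    two-column TSV (sample id, species) or a dict.
    """
    from cyvcf2 import VCF

    if not isinstance(species_map, dict):
        map_df = pd.read_csv(
            species_map, sep="\t", header=None, names=["sample", "species"], dtype=str
        )
        species_map = dict(zip(map_df["sample"], map_df["species"]))

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in species_map]
    if unknown:
        raise ValueError(f"samples missing from species map: {unknown}")

    locus_ids: list[str] = []
    columns: list[np.ndarray] = []
    for record in vcf:
        if len(record.ALT) != 1:
            logger.warning(
                "skipping multi-allelic record %s:%s (ALT=%s)",
                record.CHROM, record.POS, ",".join(record.ALT),
            )
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = record.gt_types
        col = np.full(len(samples), MISSING, dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 1] = 1
        col[gt == 3] = 2
        columns.append(col)
        locus_ids.append(record.ID or f"{record.CHROM}:{record.POS}")
    if not columns:
        raise ValueError(f"{path}: no biallelic SNP records")
    return GenotypeMatrix(
        individual_ids=samples,
        group_labels=[species_map[s] for s in samples],
        locus_ids=locus_ids,
        genotypes=np.column_stack(columns),
    )


def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def _het_log_weights(n_ref: int, n_alt: int) -> dict[int, float]:
    """Unnormalised log-probabilities of each attainable heterozygote count
    conditional on the allele counts (random union of gametes)."""
    n_minor = min(n_ref, n_alt)

    def log_weight(h: int) -> float:
        return (
            h * math.log(2.0)
            - math.lgamma(h + 1)
            - math.lgamma((n_ref - h) // 2 + 1)
            - math.lgamma((n_alt - h) // 2 + 1)
        )

    return {h: log_weight(h) for h in range(n_minor % 2, n_minor + 1, 2)}


def hwe_null_distribution(n_called: int, n_minor_copies: int) -> dict[int, float]:
    """Null distribution of the heterozygote count given allele counts.

    Returns ``{het_count: probability}`` for a locus with ``n_called``
    diploid individuals and ``n_minor_copies`` copies of the minor allele.
    This is the distribution the exact test enumerates; it is also what a
    calibration check (e.g. a randomised probability-integral transform of
    observed p-values) needs.
    """
    if not 0 <= n_minor_copies <= n_called:
        raise ValueError("n_minor_copies must be in [0, n_called]")
    logw = _het_log_weights(2 * n_called - n_minor_copies, n_minor_copies)
    log_total = _logsumexp(list(logw.values()))
    return {h: math.exp(lw - log_total) for h, lw in logw.items()}


def hwe_calibration_pit(
    n_hom_ref: int, n_het: int, n_hom_alt: int, rng: np.random.Generator
) -> float:
    """Randomised probability-integral transform of the exact HWE p-value.

    The exact test's p-value is discrete and conservative, so it is not
    uniform under the null; the randomised PIT ``F(p-) + V [F(p) - F(p-)]``
    (V uniform) is exactly Uniform(0,1) when genotypes follow
    Hardy-Weinberg proportions, which makes aggregate calibration checks
    (e.g. Kolmogorov-Smirnov against the uniform) valid.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_alt, 2 * n - n_alt)
    dist = hwe_null_distribution(n, n_minor)
    p_obs = dist[n_het]
    f_lt = sum(q for q in dist.values() if q < p_obs - 1e-12)
    f_le = sum(q for q in dist.values() if q <= p_obs + 1e-12)
    return f_lt + rng.uniform() * (f_le - f_lt)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test for a biallelic locus.

    Conditional on the observed allele counts, enumerates every attainable
    heterozygote count, computes each configuration's probability under
    random union of gametes, and sums the probabilities of configurations
    no more likely than the observed one (a two-sided test by probability
    ordering, the analogue of Fisher's exact test). Returns a p-value in
    (0, 1].
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("at least one genotype count must be positive")
    n_ref = 2 * n_hom_ref + n_het  # reference allele copies
    n_alt = 2 * n - n_ref
    n_minor = min(n_ref, n_alt)
    if n_minor == 0:
        return 1.0  # monomorphic: the observed configuration is the only one

    # P(het = h | allele counts) ∝ 2^h / (h! * ((n_ref-h)/2)! * ((n_alt-h)/2)!)
    logw = _het_log_weights(n_ref, n_alt)
    log_total = _logsumexp(list(logw.values()))
    log_obs = logw[n_het]
    # sum probabilities <= observed probability (tolerance for float ties)
    acc = [lw for lw in logw.values() if lw <= log_obs + 1e-9]
    p = math.exp(_logsumexp(acc) - log_total)
    return min(p, 1.0)


def _logsumexp(values: list[float]) -> float:
    m = max(values)
    return m + math.log(sum(math.exp(v - m) for v in values))


def summarize_locus(matrix: GenotypeMatrix, group: str) -> list[LocusSummary]:
    """Per-locus QC statistics for one group of individuals.

    maf = minor-allele count / (2 x n_called); h_obs = heterozygotes /
    n_called; missing_fraction over the group's individuals; hwe_p from
    :func:`hwe_exact_test`. Loci with no called genotypes get NaN
    statistics and ``polymorphic=False``.
    """
    geno = matrix.subset_group(group)
    n_group = geno.shape[0]
    out: list[LocusSummary] = []
    for j, locus in enumerate(matrix.locus_ids):
        col = geno[:, j]
        called = col[col != MISSING]
        n_called = called.size
        missing_fraction = 1.0 - n_called / n_group
        if n_called == 0:
            out.append(
                LocusSummary(locus, group, 0, math.nan, math.nan,
                             missing_fraction, math.nan, False)
            )
            continue
        n_het = int((called == 1).sum())
        n_alt_copies = int(called.sum())  # codes count alt-allele copies
        n_ref_copies = 2 * n_called - n_alt_copies
        maf = min(n_ref_copies, n_alt_copies) / (2 * n_called)
        h_obs = n_het / n_called
        n_hom_ref = int((called == 0).sum())
        n_hom_alt = int((called == 2).sum())
        hwe_p = hwe_exact_test(n_hom_ref, n_het, n_hom_alt)
        out.append(
            LocusSummary(locus, group, n_called, maf, h_obs,
                         missing_fraction, hwe_p, maf > 0)
        )
    return out


def summaries_to_frame(summaries: list[LocusSummary]) -> pd.DataFrame:
    """Tabulate :class:`LocusSummary` records as a DataFrame."""
    return pd.DataFrame([s.__dict__ for s in summaries])


def polymorphic_loci(matrix: GenotypeMatrix, species: str) -> set[str]:
    """Locus ids at which both alleles are observed in a species' sample.

    Loci with all genotypes missing in the species are excluded (logged).
    """
    geno = matrix.subset_group(species)
    result: set[str] = set()
    n_all_missing = 0
    for j, locus in enumerate(matrix.locus_ids):
        col = geno[:, j]
        called = col[col != MISSING]
        if called.size == 0:
            n_all_missing += 1
            continue
        n_alt = int(called.sum())
        if 0 < n_alt < 2 * called.size:
            result.add(locus)
    if n_all_missing:
        logger.info(
            "%s: %d loci with no called genotypes excluded from sharing set",
            species, n_all_missing,
        )
    return result


@dataclass
class SharingReport:
    """Cross-species polymorphism-sharing summary (Venn decomposition).

    ``regions`` maps each non-empty subset of species names (as a sorted
    tuple) to the count of loci polymorphic in exactly those species.
    ``counts``/``fractions`` are per-species totals; ``core_count`` is the
    number of loci polymorphic in every species.
    """

    sets: dict[str, set[str]]
    panel_size: int
    regions: dict[tuple[str, ...], int]
    counts: dict[str, int]
    fractions: dict[str, float]
    core_count: int

    def to_dict(self) -> dict:
        return {
            "panel_size": self.panel_size,
            "counts": self.counts,
            "fractions": self.fractions,
            "core_count": self.core_count,
            "regions": {"&".join(k): v for k, v in self.regions.items()},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def sharing_venn(sets: dict[str, set[str]], panel_size: int | None = None) -> SharingReport:
    """Decompose named polymorphic-locus sets into exclusive Venn regions.

    Accepts 2-6 named sets. Region counts over all 2^k - 1 non-empty name
    subsets sum to the size of the union; ``core_count`` is the full
    intersection. ``panel_size`` (default: union size) is the denominator
    for per-species fractions.
    """
    names = sorted(sets)
    if not 2 <= len(names) <= 6:
        raise ValueError(f"need 2-6 named sets, got {len(names)}")
    if panel_size is None:
        panel_size = len(set().union(*sets.values()))
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for members in itertools.combinations(names, r):
            inside = set.intersection(*(sets[m] for m in members))
            outside = set().union(
                *(sets[m] for m in names if m not in members), set()
            )
            regions[members] = len(inside - outside)
    counts = {m: len(sets[m]) for m in names}
    fractions = {
        m: counts[m] / panel_size if panel_size else math.nan for m in names
    }
    return SharingReport(
        sets={m: set(sets[m]) for m in names},
        panel_size=panel_size,
        regions=regions,
        counts=counts,
        fractions=fractions,
        core_count=len(set.intersection(*(sets[m] for m in names))),
    )


def pairwise_test_count(n_loci: int) -> int:
    """Number of locus pairs: n(n-1)/2 (each pair tested once for LD)."""
    if n_loci < 2:
        raise ValueError(f"need at least 2 loci, got {n_loci}")
    return n_loci * (n_loci - 1) // 2


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected per-test significance level."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
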