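"""Per-variant contributions and per-gene, per-individual burden scores.

The score models the loss of integrity of a gene ``g`` in an individual
``h`` as the additive burden of the ``k`` variants observed in that
individual across the gene's coding region:

    S_gh = - sum_{i=1..k}  D_i * log10(f_i1 * f_i2)

where ``D_i`` in [0, 1] is the variant's deleteriousness on the common
scale, and ``f_i1``, ``f_i2`` are the population frequencies of the two
observed alleles.  A homozygous genotype contributes the allele frequency
squared; a heterozygote contributes the product of its two observed allele
frequencies (which accommodates multi-allelic sites exactly); hemizygous
calls (male X, and by the same logic Y and mitochondrial single-allele
genotypes) are treated as homozygous.  The log link upweights rare
variation: with the 1e-5 frequency floor, a single variant contributes at
most 10 (homozygous rare, D = 1) and about 5 for a rare heterozygote.

Because larger genes accrue more variants by size alone, a corrected score
divides by the gene's targeted length in bp and multiplies by a cohort
median targeted length (default 1461 bp) to keep the scale familiar.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ingest import (
    DEFAULT_FREQUENCY_FLOOR,
    AnnotatedVariant,
    GenotypeCall,
    resolve_allele_frequencies,
)
from .metrics import (
    MetricSpec,
    assign_truncating,
    exclude_variant,
    get_metric,
    transform,
)
from .regions import TargetRegions

__all__ = [
    "DEFAULT_MEDIAN_LENGTH",
    "VariantContribution",
    "GeneScoreMatrix",
    "MatrixSummary",
    "ScoringError",
    "variant_score",
    "gene_score",
    "length_correct",
    "build_matrix",
    "summarize_matrix",
    "profile_zscores",
    "read_matrix_tsv",
]

log = logging.getLogger(__name__)

#: Cohort-median targeted gene length (bp) used to rescale length-corrected
#: scores back onto a familiar range; recomputable from supplied regions.
DEFAULT_MEDIAN_LENGTH = 1461


class ScoringError(ValueError):
    """A contract violation in scoring inputs."""


def variant_score(D: float, f1: float, f2: float) -> float:
    """Contribution ``-D * log10(f1 * f2)`` of one observed variant genotype.

    ``f1`` and ``f2`` are the population frequencies of the two observed
    alleles (equal for homozygous and hemizygous genotypes).  The result is
    non-negative and, with the default 1e-5 floor, bounded by 10.
    """
    if not 0.0 <= D <= 1.0:
        raise ScoringError(f"deleteriousness D={D} outside [0, 1]")
    for f in (f1, f2):
        if not 0.0 < f <= 1.0:
            raise ScoringError(f"allele frequency {f} outside (0, 1]")
    return -D * math.log10(f1 * f2)


@dataclass(frozen=True)
class VariantContribution:
    """One variant's scored contribution for one sample/gene/metric."""

    D: float
    f1: float
    f2: float
    score: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "score", variant_score(self.D, self.f1, self.f2))


def gene_score(contributions: Iterable[VariantContribution | float]) -> float:
    """Additive gene-level burden: the plain sum of variant contributions."""
    total = 0.0
    for c in contributions:
        total += c.score if isinstance(c, VariantContribution) else float(c)
    return total


def length_correct(
    score: float, targeted_length: float, median_length: float = DEFAULT_MEDIAN_LENGTH,
    gene: str | None = None,
) -> float:
    """Rescale a gene score by targeted length: ``score * median / length``."""
    if targeted_length is None or targeted_length <= 0:
        name = f" for gene {gene!r}" if gene else ""
        raise ScoringError(
            f"targeted length{name} must be positive (gene absent from target regions?)"
        )
    return score * median_length / targeted_length


@dataclass
class GeneScoreMatrix:
    """Samples x genes score table for one deleteriousness metric.

    ``values`` is a DataFrame indexed by sample id with gene symbols as
    columns.  A gene with no included variants in a sample scores exactly 0.
    """

    values: pd.DataFrame
    metric_name: str
    corrected: bool = False
    median_length_constant: float = DEFAULT_MEDIAN_LENGTH

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.values.columns)

    def write_tsv(self, path: str) -> None:
        """Write the matrix as TSV (6 significant digits, sample_id first column)."""
        self.values.to_csv(path, sep="\t", float_format="%.6g", index_label="sample_id")


def read_matrix_tsv(
    path: str, metric_name: str = "unknown", corrected: bool = False
) -> GeneScoreMatrix:
    """Read a matrix written by :meth:`GeneScoreMatrix.write_tsv`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GeneScoreMatrix(values=df.astype(float), metric_name=metric_name, corrected=corrected)


def _effective_deleteriousness(
    variant: AnnotatedVariant, spec: MetricSpec
) -> tuple[list[float | None], bool, bool]:
    """Per-alt effective D after exclusion / truncating override / transform.

    Returns ``(d_per_alt, any_excluded, any_missing_metric)`` where each
    ``d_per_alt`` entry is ``None`` when that allele cannot contribute.
    """
    d_eff: list[float | None] = []
    any_excluded = any_missing = False
    for j, fc in enumerate(variant.functional_class):
        if exclude_variant(fc):
            d_eff.append(None)
            any_excluded = True
            continue
        override = assign_truncating(fc) if fc is not None else None
        if override is not None:
            d_eff.append(override)
            continue
        raw = variant.raw_annotations[j].get(spec.name) if variant.raw_annotations else None
        d = transform(raw, spec)
        if d is None:
            any_missing = True
        d_eff.append(d)
    return d_eff, any_excluded, any_missing


def _genotype_contribution(
    call: GenotypeCall, freqs: np.ndarray, d_per_alt: Sequence[float | None]
) -> float | None:
    """Score one genotype at one site, or ``None`` when nothing is observed.

    For heterozygous-alt genotypes (e.g. 1/2) the deleteriousness applied is
    the maximum over the observed, scoreable alt alleles — a conservative
    single-D summary of a genuinely two-allele genotype.
    """
    if call.allele_indices is None:
        return None
    observed_alts = {a for a in call.allele_indices if a > 0}
    if not observed_alts:
        return None
    ds = [d_per_alt[a - 1] for a in observed_alts if d_per_alt[a - 1] is not None]
    if not ds:
        return None
    D = max(ds)
    if call.ploidy == 1:
        f1 = f2 = float(freqs[call.allele_indices[0]])
    else:
        f1 = float(freqs[call.allele_indices[0]])
        f2 = float(freqs[call.allele_indices[1]])
    return variant_score(D, f1, f2)


def build_matrix(
    cohort: Iterable[tuple[AnnotatedVariant, list[GenotypeCall]]],
    metric: str | MetricSpec,
    regions: TargetRegions | None = None,
    corrected: bool = False,
    *,
    floor: float = DEFAULT_FREQUENCY_FLOOR,
    median_length: float | None = DEFAULT_MEDIAN_LENGTH,
    metric_table: Mapping[str, MetricSpec] | None = None,
    recompute_median: bool = False,
) -> GeneScoreMatrix:
    """Aggregate a cohort stream into a samples x genes score matrix.

    Per-variant pipeline: drop variants outside the target regions; exclude
    synonymous/splicing alleles; apply the truncating D = 1 override or the
    metric transform; resolve floored allele frequencies; score each
    non-reference genotype; sum within (sample, gene).  With
    ``corrected=True`` every gene column is rescaled by
    ``median_length / targeted_length`` using ``regions.gene_lengths``
    (genes without a targeted length are dropped with a warning).

    The result is deterministic given identical inputs and configuration.
    """
    spec = get_metric(metric, metric_table) if isinstance(metric, str) else metric
    if corrected and (regions is None or not regions.gene_lengths):
        raise ScoringError(
            "length correction requires target regions with per-gene lengths"
        )
    if recompute_median:
        if regions is None or not regions.gene_lengths:
            raise ScoringError("cannot recompute the median length without gene lengths")
        median_length = float(np.median(sorted(regions.gene_lengths.values())))
    if median_length is None:
        median_length = DEFAULT_MEDIAN_LENGTH

    counts = {"read": 0, "outside_target": 0, "excluded_class": 0,
              "missing_metric": 0, "scored": 0}
    sample_ids: list[str] | None = None
    acc: dict[str, np.ndarray] = {}
    gene_order: list[str] = []

    for variant, calls in cohort:
        counts["read"] += 1
        if sample_ids is None:
            sample_ids = [c.sample_id for c in calls]
        if regions is not None and not regions.contains(variant.chrom, variant.pos):
            counts["outside_target"] += 1
            continue
        d_per_alt, any_excluded, any_missing = _effective_deleteriousness(variant, spec)
        if any_excluded:
            counts["excluded_class"] += 1
        if any_missing:
            counts["missing_metric"] += 1
        for gene in variant.gene_symbols:
            if gene not in acc:
                acc[gene] = np.zeros(len(sample_ids))
                gene_order.append(gene)
        if all(d is None for d in d_per_alt):
            continue
        freqs = resolve_allele_frequencies(variant, floor)
        scored_any = False
        for idx, call in enumerate(calls):
            contribution = _genotype_contribution(call, freqs, d_per_alt)
            if contribution is None:
                continue
            scored_any = True
            for gene in variant.gene_symbols:
                acc[gene][idx] += contribution
        if scored_any:
            counts["scored"] += 1

    if sample_ids is None:
        raise ScoringError("cohort stream is empty")
    values = pd.DataFrame(
        {g: acc[g] for g in gene_order}, index=pd.Index(sample_ids, name="sample_id")
    )
    if values.empty and not gene_order:
        values = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))

    if corrected:
        kept, dropped = [], []
        for gene in values.columns:
            if regions.gene_lengths.get(gene, 0) > 0:
                kept.append(gene)
            else:
                dropped.append(gene)
        if dropped:
            log.warning(
                "dropping %d gene(s) without a targeted length: %s",
                len(dropped), ", ".join(dropped[:5]),
            )
        values = values[kept]
        for gene in kept:
            values[gene] = length_correct(
                values[gene], regions.gene_lengths[gene], median_length, gene=gene
            )

    log.info(
        "scored %s: %d variants read, %d outside target, %d with excluded class, "
        "%d with missing metric, %d contributing",
        spec.name, counts["read"], counts["outside_target"],
        counts["excluded_class"], counts["missing_metric"], counts["scored"],
    )
    matrix = GeneScoreMatrix(
        values=values,
        metric_name=spec.name,
        corrected=corrected,
        median_length_constant=median_length,
    )
    matrix.counts = counts  # per-stage variant counts, for logging/inspection
    return matrix


@dataclass
class MatrixSummary:
    """Cohort-level summary statistics of a gene-score matrix.

    ``cv`` is the coefficient of variation (population sigma / mu) over all
    matrix cells, ``None`` when the mean is zero.  The histogram uses fixed
    bins of ``bin_width`` starting at 0; when ``exclude_low`` was set, bins
    below 0.01 are masked out (invariant genes dominate that bin).
    """

    n_samples: int
    n_genes: int
    max_score: float
    mean_score: float
    cv: float | None
    zero_genes_per_sample: pd.Series
    low_genes_per_sample: pd.Series
    median_zero_genes: float
    median_low_genes: float
    histogram_counts: np.ndarray
    bin_edges: np.ndarray


def summarize_matrix(
    matrix: GeneScoreMatrix, bin_width: float = 0.01, exclude_low: bool = False
) -> MatrixSummary:
    """Summary statistics mirroring the standard cohort-matrix report."""
    values = matrix.values.to_numpy(dtype=float)
    if values.size == 0:
        raise ScoringError("cannot summarize an empty matrix")
    flat = values.ravel()
    mean = float(flat.mean())
    cv = float(flat.std(ddof=0) / mean) if mean > 0 else None
    zero = pd.Series((values == 0).sum(axis=1), index=matrix.values.index)
    low = pd.Series((values < 0.01).sum(axis=1), index=matrix.values.index)
    top = max(float(flat.max()), bin_width)
    edges = np.arange(0.0, top + 2 * bin_width, bin_width)
    counts, edges = np.histogram(flat, bins=edges)
    if exclude_low:
        counts = counts.copy()
        counts[edges[:-1] < 0.01] = 0
    return MatrixSummary(
        n_samples=values.shape[0],
        n_genes=values.shape[1],
        max_score=float(flat.max()),
        mean_score=mean,
        cv=cv,
        zero_genes_per_sample=zero,
        low_genes_per_sample=low,
        median_zero_genes=float(zero.median()),
        median_low_genes=float(low.median()),
        histogram_counts=counts,
        bin_edges=edges,
    )


def profile_zscores(
    matrix: GeneScoreMatrix,
    gene_subset: Sequence[str] | None = None,
    sample_subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene Z-scores for patient profiling.

    Standardisation is computed per gene across the *full* cohort
    (population standard deviation), then restricted to the requested
    samples/genes, so a profile is always relative to the whole reference
    population.  Zero-variance genes are reported as all-zero with a warning.
    """
    df = matrix.values
    genes = list(gene_subset) if gene_subset is not None else list(df.columns)
    unknown = [g for g in genes if g not in df.columns]
    if unknown:
        raise ScoringError(f"genes not in matrix: {', '.join(unknown)}")
    sub = df[genes]
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=0)
    flat_genes = [g for g in genes if sd[g] == 0]
    if flat_genes:
        warnings.warn(
            f"{len(flat_genes)} gene(s) have zero score variance; Z set to 0: "
            + ", ".join(flat_genes[:5]),
            stacklevel=2,
        )
    z = (sub - mu).div(sd.replace(0.0, np.nan), axis=1).fillna(0.0)
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in z.index]
        if missing:
            raise ScoringError(f"samples not in matrix: {', '.join(missing)}")
        z = z.loc[list(sample_subset)]
    return z
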