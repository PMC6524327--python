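"""Reading multi-sample variant data and annotations into scoring inputs.

The scorer consumes the product of a standard joint-calling pipeline: a
multi-sample VCF with per-sample ``GT`` fields, annotated ANNOVAR-style with
gene symbol, exonic functional class, a population allele frequency, and
raw values for one or more deleteriousness metrics.  Annotations may sit in
the VCF INFO column or in a sidecar TSV keyed by ``chrom:pos:ref:alt``.

Multi-allelic sites are kept intact (one record, per-alt annotations) rather
than decomposed, so that the frequency of every observed allele — including
the reference — is available to the zygosity model.

Allele-frequency resolution applies the rarity floor: novel alleles or
alleles absent from the reference database are assigned the configured
minimum frequency (default 1e-5, roughly the rarest frequency observable in
large exome repositories), and the reference-allele frequency is
``1 - sum(alt frequencies)``, itself floored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .metrics import AnnotationParseError, RawAnnotation

__all__ = [
    "AnnotatedVariant",
    "GenotypeCall",
    "IngestError",
    "DEFAULT_COLUMN_MAP",
    "DEFAULT_FREQUENCY_FLOOR",
    "read_cohort",
    "read_sex_file",
    "read_phenotypes",
    "resolve_allele_frequencies",
]

log = logging.getLogger(__name__)

DEFAULT_FREQUENCY_FLOOR = 1e-5

#: ANNOVAR/dbNSFP-style default column names; metric columns default to the
#: metric name itself and can be remapped under the ``"metrics"`` key.
DEFAULT_COLUMN_MAP: dict[str, object] = {
    "gene": "Gene.refGene",
    "functional_class": "ExonicFunc.refGene",
    "allele_freq": "ExAC_ALL",
    "mutationtaster_class": "MutationTaster_pred",
    "metrics": {},
}

_MISSING_TOKENS = {"", ".", "na", "nan", "none"}
_X_CONTIGS = {"x", "chrx"}
_HEMI_CONTIGS = {"x", "chrx", "y", "chry", "m", "mt", "chrm", "chrmt"}
_MALE_TOKENS = {"m", "male", "1"}


class IngestError(ValueError):
    """A structural problem in the variant file or its annotations."""


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's observed alleles at one locus.

    ``allele_indices`` uses VCF allele numbering (0 = reference) and is
    ``None`` for missing genotypes; its length equals ``ploidy`` (1 for
    hemizygous calls, 2 for diploid).  ``is_male_x`` marks the hemizygous
    male-X context.
    """

    sample_id: str
    ploidy: int
    allele_indices: tuple[int, ...] | None
    is_male_x: bool = False


@dataclass
class AnnotatedVariant:
    """One variant site with alleles, gene assignment and per-alt annotations.

    Per-alt sequences (``functional_class``, ``allele_freqs``,
    ``raw_annotations``) are ordered like ``alt_alleles``.  ``allele_freqs``
    entries are population fractions in ``(0, 1]`` or ``None`` when the
    allele is absent from the frequency database.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    gene_symbols: tuple[str, ...]
    functional_class: tuple[str | None, ...]
    allele_freqs: tuple[float | None, ...]
    raw_annotations: tuple[dict[str, RawAnnotation], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise IngestError(f"{self.chrom}:{self.pos}: positions are 1-based")
        if not self.alt_alleles:
            raise IngestError(f"{self.chrom}:{self.pos}: no alternate allele")


def _parse_float(token, locus: str, column: str) -> float | None:
    if token is None:
        return None
    if isinstance(token, (int, float)):
        return None if token != token else float(token)
    text = str(token).strip()
    if text.lower() in _MISSING_TOKENS:
        return None
    try:
        return float(text)
    except ValueError:
        raise AnnotationParseError(
            f"{locus}: column {column!r}: cannot parse {token!r} as a number"
        ) from None


def read_sex_file(path: str) -> dict[str, str]:
    """Read a two-column sample/sex TSV into ``{sample_id: "M"|"F"}``."""
    out: dict[str, str] = {}
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.shape[1] < 2:
        raise IngestError(f"{path}: sex file needs two columns (sample, sex)")
    header_like = df.iloc[0, 0].strip().lower() in {"sample", "sample_id"}
    for _, row in df.iloc[1 if header_like else 0 :].iterrows():
        sex = str(row.iloc[1]).strip().lower()
        out[str(row.iloc[0]).strip()] = "M" if sex in _MALE_TOKENS else "F"
    return out


def read_phenotypes(path: str) -> dict[str, str]:
    """Read a two-column sample/group TSV into ``{sample_id: group}``."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise IngestError(f"{path}: phenotype file needs two columns (sample, group)")
    return dict(zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip()))


def _load_sidecar(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    required = {"CHROM", "POS", "REF", "ALT"}
    if not required <= set(df.columns):
        raise IngestError(
            f"{path}: sidecar annotations need columns {sorted(required)}"
        )
    key = (
        df["CHROM"].astype(str)
        + ":"
        + df["POS"].astype(str)
        + ":"
        + df["REF"].astype(str)
        + ":"
        + df["ALT"].astype(str)
    )
    df = df.set_index(key)
    if not df.index.is_unique:
        dupes = df.index[df.index.duplicated()][:3].tolist()
        raise IngestError(f"{path}: duplicate annotation keys, e.g. {dupes}")
    return df


def _split_genes(value: str | None) -> tuple[str, ...]:
    if value is None:
        return ()
    parts = [g.strip() for g in str(value).replace(",", ";").split(";")]
    return tuple(dict.fromkeys(p for p in parts if p and p.lower() not in _MISSING_TOKENS))


def _info_per_alt(variant, key: str, n_alt: int) -> list[str | None]:
    """Fetch an INFO value, broadcasting scalars and splitting per-alt lists."""
    value = variant.INFO.get(key)
    if value is None:
        return [None] * n_alt
    if isinstance(value, tuple):
        vals = [str(v) if v is not None else None for v in value]
    else:
        vals = str(value).split(",")
    if len(vals) == 1 and n_alt > 1:
        vals = vals * n_alt
    if len(vals) != n_alt:
        raise IngestError(
            f"{variant.CHROM}:{variant.POS}: INFO {key!r} has {len(vals)} values "
            f"for {n_alt} alt alleles"
        )
    return [None if v is not None and v.strip().lower() in _MISSING_TOKENS else v for v in vals]


def read_cohort(
    variant_file: str,
    annotation_source: str | None = None,
    column_map: Mapping[str, object] | None = None,
    metrics: Sequence[str] | None = None,
    sex_map: Mapping[str, str] | None = None,
) -> Iterator[tuple[AnnotatedVariant, list[GenotypeCall]]]:
    """Stream ``(AnnotatedVariant, per-sample GenotypeCall list)`` records.

    Parameters
    ----------
    variant_file
        Multi-sample VCF v4.x with ``GT`` genotypes.
    annotation_source
        Optional sidecar TSV keyed by ``CHROM``/``POS``/``REF``/``ALT``
        columns; when absent, annotations are read from VCF INFO keys.
    column_map
        Overrides for :data:`DEFAULT_COLUMN_MAP`.
    metrics
        Deleteriousness metrics whose raw columns should be loaded (default:
        every metric with a resolvable column present).
    sex_map
        ``{sample_id: "M"/"F"}`` used to flag hemizygous male-X genotypes.

    Notes
    -----
    Missing genotypes (``./.``) are yielded with ``allele_indices=None`` and
    contribute nothing downstream.  Multi-gene annotations
    (``GENE1;GENE2``) become multiple gene assignments.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    metric_cols: dict[str, str] = dict(cmap.get("metrics") or {})

    from .metrics import METRIC_NAMES  # late import to avoid cycles

    wanted_metrics = list(metrics) if metrics is not None else list(METRIC_NAMES)
    for m in wanted_metrics:
        metric_cols.setdefault(m, m)

    sidecar = _load_sidecar(annotation_source) if annotation_source else None
    vcf = VCF(variant_file)
    samples = list(vcf.samples)
    if not samples:
        raise IngestError(f"{variant_file}: no sample columns in VCF")
    if "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise IngestError(f"{variant_file}: VCF lacks a GT FORMAT definition")
    sex_map = sex_map or {}
    male = {s for s in samples if sex_map.get(s, "F") == "M"}
    warned_missing: set[str] = set()

    for record_no, v in enumerate(vcf, start=1):
        locus = f"{v.CHROM}:{v.POS}"
        alts = tuple(v.ALT)
        if not alts:
            continue
        n_alt = len(alts)

        def lookup(column: str) -> list[str | None]:
            if sidecar is not None:
                out = []
                for alt in alts:
                    key = f"{v.CHROM}:{v.POS}:{v.REF}:{alt}"
                    if key in sidecar.index and column in sidecar.columns:
                        cell = sidecar.at[key, column]
                        cell = None if pd.isna(cell) else str(cell)
                        if cell is not None and cell.strip().lower() in _MISSING_TOKENS:
                            cell = None
                        out.append(cell)
                    else:
                        out.append(None)
                return out
            return _info_per_alt(v, column, n_alt)

        genes: tuple[str, ...] = ()
        for g in lookup(str(cmap["gene"])):
            genes = genes + tuple(x for x in _split_genes(g) if x not in genes)
        func = tuple(lookup(str(cmap["functional_class"])))
        freq_raw = lookup(str(cmap["allele_freq"]))
        freqs = tuple(
            _parse_float(x, locus, str(cmap["allele_freq"])) for x in freq_raw
        )
        mt_classes = lookup(str(cmap["mutationtaster_class"]))

        raw_ann: list[dict[str, RawAnnotation]] = [dict() for _ in range(n_alt)]
        for metric, column in metric_cols.items():
            values = lookup(column)
            if all(x is None for x in values):
                if metric not in warned_missing and metric in wanted_metrics:
                    # only warn once per metric; absence is normal for
                    # metrics the annotation run did not include
                    warned_missing.add(metric)
                continue
            for j, token in enumerate(values):
                value = _parse_float(token, locus, column)
                aux = mt_classes[j] if metric == "MutationTaster" else None
                raw_ann[j][metric] = RawAnnotation(metric, value, aux)

        variant = AnnotatedVariant(
            chrom=v.CHROM,
            pos=v.POS,
            ref_allele=v.REF,
            alt_alleles=alts,
            gene_symbols=genes,
            functional_class=func,
            allele_freqs=freqs,
            raw_annotations=tuple(raw_ann),
        )

        is_x = v.CHROM.lower() in _X_CONTIGS
        calls: list[GenotypeCall] = []
        genotypes = v.genotypes
        if len(genotypes) != len(samples):
            raise IngestError(
                f"{variant_file} record {record_no} ({locus}): "
                f"{len(genotypes)} genotypes for {len(samples)} samples"
            )
        for sample, g in zip(samples, genotypes):
            alleles = tuple(int(a) for a in g[:-1])
            ploidy = len(alleles)
            missing = any(a < 0 for a in alleles)
            calls.append(
                GenotypeCall(
                    sample_id=sample,
                    ploidy=ploidy,
                    allele_indices=None if missing else alleles,
                    is_male_x=is_x and sample in male,
                )
            )
        yield variant, calls


def resolve_allele_frequencies(
    variant: AnnotatedVariant, floor: float = DEFAULT_FREQUENCY_FLOOR
) -> np.ndarray:
    """Per-allele population frequencies ``[ref, alt1, alt2, ...]`` after flooring.

    Each alt allele gets ``max(annotated frequency, floor)``; missing or
    novel annotations get exactly the floor.  The reference frequency is
    ``1 - sum(alt)``, itself floored — so every returned frequency lies in
    ``[floor, 1]`` and the log-product in the score stays finite.
    """
    if not 0.0 < floor < 0.5:
        raise ValueError(f"frequency floor must be in (0, 0.5), got {floor}")
    alt = []
    for f in variant.allele_freqs:
        if f is None or f <= 0.0:
            alt.append(floor)
        else:
            alt.append(max(min(float(f), 1.0), floor))
    ref = 1.0 - sum(alt)
    if ref < floor:
        if sum(alt) > 1.0:
            warnings.warn(
                f"{variant.chrom}:{variant.pos}: alt frequencies sum to "
                f"{sum(alt):.4g} > 1; reference frequency clamped to the floor",
                stacklevel=2,
            )
        ref = floor
    return np.asarray([ref] + alt, dtype=float)
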