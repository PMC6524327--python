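"""Self-contained synthetic cohorts with known ground-truth gene scores.

The generator emits everything the scoring pipeline consumes — a
multi-sample VCF with per-sample genotypes, an ANNOVAR-style sidecar
annotation TSV, two deliberately offset capture-kit BED files whose
intersection covers the genes exactly, a gene-model BED, phenotype and sex
TSVs — together with a ``truth_matrix.tsv`` of expected per-sample,
per-gene scores computed by a direct, independent implementation of the
scoring equation.

Genotypes are drawn at Hardy-Weinberg proportions implied by the diploid
allele-frequency-product model: each of a sample's two allele draws picks
allele ``a`` with probability ``f_a`` (males carry a single draw for
X-linked genes).  Raw deleteriousness values are generated by *inverting*
each metric's transformation (pre-complement), so the metric normalisation
layer is exercised rather than bypassed.  A case group can be enriched for
carriers of a rare, highly deleterious variant in designated causal genes,
mimicking the known-gene positive-control design used to validate the
score on real cohorts.

All output is a pure function of the configuration (including its seed):
reruns are byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .metrics import MetricSpec, default_metric_table

__all__ = [
    "GeneSpec",
    "CausalSpec",
    "SimulationConfig",
    "CohortBundle",
    "SimulationError",
    "default_gene_panel",
    "simulate_cohort",
    "archetype_cohort",
    "causal_gene_scores",
    "load_sim_config",
]

_BASES = ("A", "C", "G", "T")
_MISSENSE = "nonsynonymous SNV"
_TRUNCATING = ("stopgain", "stoploss", "frameshift deletion", "frameshift insertion")
_MT_CLASSES = ("A", "D", "N", "P")
_GENE_GAP = 2000  # bp between gene spans; keeps kit-BED padding disjoint


class SimulationError(ValueError):
    """An inconsistent simulation configuration."""


@dataclass(frozen=True)
class GeneSpec:
    """One simulated gene: its targeted span and background variant model.

    ``maf_log10_range`` draws background minor allele frequencies
    log-uniformly (default 1e-4 .. 0.5, a crude stand-in for the rare-heavy
    site-frequency spectrum of exomes); ``d_alpha``/``d_beta`` parameterise
    a Beta distribution for deleteriousness (default uniform).  Class
    fractions control how many variants are protein-truncating, synonymous,
    or splicing (the latter two are excluded from scores by construction).
    """

    symbol: str
    targeted_length: int = 1461
    n_variants: int = 8
    maf_log10_range: tuple[float, float] = (-4.0, math.log10(0.5))
    d_alpha: float = 1.0
    d_beta: float = 1.0
    truncating_fraction: float = 0.05
    synonymous_fraction: float = 0.10
    splicing_fraction: float = 0.05
    on_x: bool = False


@dataclass(frozen=True)
class CausalSpec:
    """Enrichment of one gene for a carried risk variant in cases vs controls."""

    gene: str
    case_carrier_fraction: float
    control_carrier_fraction: float
    maf: float = 1e-4
    deleteriousness: float = 0.9
    zygosity: str = "het"  # "het" or "hom"


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a synthetic case/control exome cohort."""

    n_cases: int = 170
    n_controls: int = 170
    genes: tuple[GeneSpec, ...] = ()
    causal: tuple[CausalSpec, ...] = ()
    metrics: tuple[str, ...] = ("CADD",)
    seed: int = 0
    male_fraction: float = 0.5
    maf_noise: float = 0.0
    multiallelic_fraction: float = 0.1
    floor: float = 1e-5

    def __post_init__(self) -> None:
        symbols = [g.symbol for g in self.genes]
        if len(set(symbols)) != len(symbols):
            raise SimulationError("duplicate gene symbols in configuration")
        for c in self.causal:
            if c.gene not in symbols:
                raise SimulationError(f"causal gene {c.gene!r} absent from gene list")
            if c.zygosity not in ("het", "hom"):
                raise SimulationError(f"causal zygosity must be het or hom, got {c.zygosity!r}")
            for frac in (c.case_carrier_fraction, c.control_carrier_fraction):
                if not 0.0 <= frac <= 1.0:
                    raise SimulationError(f"carrier fraction {frac} outside [0, 1]")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise SimulationError("male fraction outside [0, 1]")


def default_gene_panel(n_genes: int = 50, x_genes: int = 2) -> tuple[GeneSpec, ...]:
    """A deterministic gene panel with lengths spread around the 1461 bp median."""
    rng = np.random.default_rng(20190516)
    lengths = np.clip(
        np.round(np.exp(rng.normal(math.log(1461), 0.6, size=n_genes))), 300, 12000
    ).astype(int)
    return tuple(
        GeneSpec(
            symbol=f"GENE{i + 1:04d}",
            targeted_length=int(lengths[i]),
            on_x=i >= n_genes - x_genes,
        )
        for i in range(n_genes)
    )


@dataclass(frozen=True)
class _Alt:
    seq: str
    af: float  # annotated population frequency
    true_af: float  # sampling frequency (equals af unless maf_noise > 0)
    d: float
    kind: str  # missense | truncating | synonymous | splicing
    func: str  # annotation class string written to the TSV
    mt_class: str | None


@dataclass
class _Record:
    chrom: str
    pos: int  # 1-based
    ref: str
    alts: list[_Alt]
    genotypes: np.ndarray  # (n_samples, 2); second slot -9 where haploid
    haploid: np.ndarray  # (n_samples,) bool
    gene: str


@dataclass
class CohortBundle:
    """Paths of a generated cohort plus its ground truth."""

    directory: Path
    vcf: Path
    annotations: Path
    bed_files: list[Path]
    gene_model: Path
    phenotypes: Path
    sex_file: Path
    truth_path: Path
    truth: pd.DataFrame  # samples x genes expected (uncorrected) scores
    gene_lengths: dict[str, int]
    sample_ids: list[str]
    archetypes: dict[str, str] = field(default_factory=dict)


def _draw_kind(rng: np.random.Generator, spec: GeneSpec) -> str:
    r = rng.random()
    if r < spec.truncating_fraction:
        return "truncating"
    r -= spec.truncating_fraction
    if r < spec.synonymous_fraction:
        return "synonymous"
    r -= spec.synonymous_fraction
    if r < spec.splicing_fraction:
        return "splicing"
    return "missense"


def _invert_transform(d: float, spec: MetricSpec, mt_class: str | None) -> float:
    """Raw metric value whose forward transform recovers ``d``."""
    if spec.conditional_rule == "mutationtaster":
        scaled = d if mt_class in ("A", "D") else 1.0 - d
    elif spec.complement:
        scaled = 1.0 - d
    else:
        scaled = d
    return scaled * (spec.upper_bound - spec.lower_bound) + spec.lower_bound


def _sample_allele_pairs(
    rng: np.random.Generator, freqs: np.ndarray, haploid: np.ndarray
) -> np.ndarray:
    """Hardy-Weinberg genotype draws: independent allele picks per chromosome."""
    n = haploid.size
    draws = rng.choice(freqs.size, size=(n, 2), p=freqs)
    draws[haploid, 1] = -9
    return draws


def _genotype_token(row: np.ndarray, haploid: bool) -> str:
    if haploid:
        return str(int(row[0]))
    return f"{int(row[0])}/{int(row[1])}"


def _truth_contribution(record: _Record, sample: int, floor: float) -> float:
    """Direct evaluation of -D * log10(f1 * f2) for one genotype.

    Written straight from the equation, independently of the scoring
    pipeline: floored per-allele frequencies, reference = 1 - sum(alt)
    floored, synonymous/splicing excluded, truncating D = 1, hemizygous
    treated as homozygous, and the maximum D over observed alt alleles for
    heterozygous-alt genotypes.
    """
    alt_f = [max(a.af, floor) for a in record.alts]
    freqs = [max(1.0 - sum(alt_f), floor)] + alt_f
    row = record.genotypes[sample]
    hap = bool(record.haploid[sample])
    alleles = [int(row[0])] if hap else [int(row[0]), int(row[1])]
    if any(a < 0 for a in alleles):
        return 0.0
    observed = {a for a in alleles if a > 0}
    if not observed:
        return 0.0
    ds = []
    for a in observed:
        alt = record.alts[a - 1]
        if alt.kind in ("synonymous", "splicing"):
            continue
        ds.append(1.0 if alt.kind == "truncating" else alt.d)
    if not ds:
        return 0.0
    d = max(ds)
    if hap:
        f1 = f2 = freqs[alleles[0]]
    else:
        f1, f2 = freqs[alleles[0]], freqs[alleles[1]]
    return -d * math.log10(f1 * f2)


def _write_vcf(path: Path, records: Sequence[_Record], sample_ids: Sequence[str]) -> None:
    contigs = list(dict.fromkeys(r.chrom for r in records)) or ["chr1"]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=geneburden-simulate\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c},length=250000000>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for r in records:
            alt_field = ",".join(a.seq for a in r.alts)
            tokens = [
                _genotype_token(r.genotypes[i], bool(r.haploid[i]))
                for i in range(len(sample_ids))
            ]
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{alt_field}\t.\tPASS\t.\tGT\t"
                + "\t".join(tokens)
                + "\n"
            )


def _write_annotations(
    path: Path, records: Sequence[_Record], metrics: Sequence[str]
) -> None:
    table = default_metric_table()
    specs = [table[m] for m in metrics]
    header = (
        ["CHROM", "POS", "REF", "ALT", "Gene.refGene", "ExonicFunc.refGene", "ExAC_ALL"]
        + [s.name for s in specs]
        + ["MutationTaster_pred"]
    )
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in records:
            for a in r.alts:
                raws = []
                for s in specs:
                    if a.kind == "truncating":
                        raws.append(".")  # predictors do not score truncations
                    else:
                        raws.append(repr(_invert_transform(a.d, s, a.mt_class)))
                row = [
                    r.chrom, str(r.pos), r.ref, a.seq, r.gene, a.func, repr(a.af),
                ] + raws + [a.mt_class or "."]
                fh.write("\t".join(row) + "\n")


def _make_alt(
    rng: np.random.Generator, spec: GeneSpec, ref: str, used: set[str],
    noise: float, floor: float,
) -> _Alt:
    kind = _draw_kind(rng, spec)
    lo, hi = spec.maf_log10_range
    true_af = float(10 ** rng.uniform(lo, hi))
    d = float(rng.beta(spec.d_alpha, spec.d_beta))
    seq = str(rng.choice([b for b in _BASES if b != ref and b not in used]))
    if kind == "truncating":
        func = str(rng.choice(_TRUNCATING))
    elif kind == "synonymous":
        func = "synonymous SNV"
    elif kind == "splicing":
        func = "splicing"
    else:
        func = _MISSENSE
    mt = str(rng.choice(_MT_CLASSES)) if kind == "missense" else None
    af = true_af
    if noise > 0:
        af = float(np.clip(true_af * math.exp(noise * rng.normal()), floor, 0.999))
    return _Alt(seq=seq, af=af, true_af=true_af, d=d, kind=kind, func=func, mt_class=mt)


def simulate_cohort(config: SimulationConfig, out_dir: str | Path) -> CohortBundle:
    """Generate the full file bundle plus the ground-truth score matrix."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    n = config.n_cases + config.n_controls
    sample_ids = [f"CASE{i + 1:04d}" for i in range(config.n_cases)] + [
        f"CTRL{i + 1:04d}" for i in range(config.n_controls)
    ]
    is_case = np.array([True] * config.n_cases + [False] * config.n_controls)
    is_male = rng.random(n) < config.male_fraction

    causal_by_gene = {c.gene: c for c in config.causal}
    records: list[_Record] = []
    gene_lengths: dict[str, int] = {}
    gene_rows: list[tuple[str, str, int, int]] = []  # (chrom, gene, start0, end0)
    cursors = {"chr1": 10_000, "chrX": 10_000}

    for spec in config.genes:
        chrom = "chrX" if spec.on_x else "chr1"
        start = cursors[chrom]
        end = start + spec.targeted_length
        cursors[chrom] = end + _GENE_GAP
        gene_lengths[spec.symbol] = spec.targeted_length
        gene_rows.append((chrom, spec.symbol, start, end))
        haploid = is_male & spec.on_x

        causal = causal_by_gene.get(spec.symbol)
        if causal is not None and spec.on_x:
            raise SimulationError(f"causal gene {spec.symbol!r} must be autosomal")
        n_positions = spec.n_variants + (1 if causal else 0)
        if n_positions > spec.targeted_length:
            raise SimulationError(f"gene {spec.symbol!r} too short for its variant count")
        positions = np.sort(rng.choice(spec.targeted_length, size=n_positions, replace=False))

        for v in range(spec.n_variants):
            ref = str(rng.choice(_BASES))
            alts = [_make_alt(rng, spec, ref, set(), config.maf_noise, config.floor)]
            if rng.random() < config.multiallelic_fraction:
                alts.append(
                    _make_alt(rng, spec, ref, {alts[0].seq}, config.maf_noise, config.floor)
                )
            alt_true = np.array([a.true_af for a in alts])
            if alt_true.sum() >= 1.0:  # rescale degenerate multi-allelic draws
                alt_true = alt_true / (alt_true.sum() + 0.05)
                alts = [replace(a, true_af=float(f), af=float(f))
                        for a, f in zip(alts, alt_true)]
            freqs = np.concatenate([[1.0 - alt_true.sum()], alt_true])
            genotypes = _sample_allele_pairs(rng, freqs, haploid)
            records.append(
                _Record(
                    chrom=chrom, pos=int(start + positions[v]) + 1, ref=ref,
                    alts=alts, genotypes=genotypes, haploid=haploid, gene=spec.symbol,
                )
            )

        if causal is not None:
            ref = str(rng.choice(_BASES))
            alt = _Alt(
                seq=str(rng.choice([b for b in _BASES if b != ref])),
                af=causal.maf, true_af=causal.maf,
                d=causal.deleteriousness, kind="missense", func=_MISSENSE,
                mt_class="D",
            )
            carrier_p = np.where(
                is_case, causal.case_carrier_fraction, causal.control_carrier_fraction
            )
            carriers = rng.random(n) < carrier_p
            genotypes = np.zeros((n, 2), dtype=int)
            genotypes[carriers, 1] = 1
            if causal.zygosity == "hom":
                genotypes[carriers, 0] = 1
            records.append(
                _Record(
                    chrom=chrom, pos=int(start + positions[-1]) + 1, ref=ref,
                    alts=[alt], genotypes=genotypes,
                    haploid=np.zeros(n, dtype=bool), gene=spec.symbol,
                )
            )

    records.sort(key=lambda r: (r.chrom, r.pos))

    truth = pd.DataFrame(
        0.0,
        index=pd.Index(sample_ids, name="sample_id"),
        columns=[g.symbol for g in config.genes],
    )
    for r in records:
        col = truth.columns.get_loc(r.gene)
        for s in range(n):
            contribution = _truth_contribution(r, s, config.floor)
            if contribution:
                truth.iat[s, col] += contribution

    vcf = out / "cohort.vcf"
    ann = out / "annotations.tsv"
    _write_vcf(vcf, records, sample_ids)
    _write_annotations(ann, records, config.metrics)

    beds = [out / "kit_a.bed", out / "kit_b.bed"]
    with open(beds[0], "w") as a, open(beds[1], "w") as b:
        for chrom, gene, start, end in gene_rows:
            a.write(f"{chrom}\t{start - 30}\t{end}\t{gene}\n")
            b.write(f"{chrom}\t{start}\t{end + 30}\t{gene}\n")
    gene_model = out / "gene_model.bed"
    with open(gene_model, "w") as fh:
        for chrom, gene, start, end in gene_rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{gene}\n")

    phen = out / "phenotypes.tsv"
    with open(phen, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sid, case in zip(sample_ids, is_case):
            fh.write(f"{sid}\t{'case' if case else 'control'}\n")
    sexf = out / "sex.tsv"
    with open(sexf, "w") as fh:
        fh.write("sample_id\tsex\n")
        for sid, m in zip(sample_ids, is_male):
            fh.write(f"{sid}\t{'M' if m else 'F'}\n")

    truth_path = out / "truth_matrix.tsv"
    truth.to_csv(truth_path, sep="\t", float_format="%.12g")

    return CohortBundle(
        directory=out, vcf=vcf, annotations=ann, bed_files=beds,
        gene_model=gene_model, phenotypes=phen, sex_file=sexf,
        truth_path=truth_path, truth=truth, gene_lengths=gene_lengths,
        sample_ids=sample_ids,
    )


def archetype_cohort(
    out_dir: str | Path,
    n_genes: int = 200,
    n_samples: int = 8,
    seed: int = 7,
    metrics: Sequence[str] = ("CADD",),
) -> CohortBundle:
    """A cohort in which every gene carries exactly one archetypal variant.

    Genes alternate between the two single-variant archetypes that dominate
    real uncorrected score histograms: a common (MAF = 0.5) highly
    deleterious (D = 1) variant carried homozygously (score
    ``-log10(0.25) = 0.60206``), and a very rare (MAF = 1e-5) highly
    deleterious variant carried heterozygously (score ~= 5).  Targeted gene
    lengths are deliberately heterogeneous so that length correction
    disperses the two spikes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    n = n_samples

    records: list[_Record] = []
    gene_rows: list[tuple[str, str, int, int]] = []
    gene_lengths: dict[str, int] = {}
    archetypes: dict[str, str] = {}
    truth = pd.DataFrame(
        0.0,
        index=pd.Index(sample_ids, name="sample_id"),
        columns=[f"ARCH{i + 1:04d}" for i in range(n_genes)],
    )
    cursor = 10_000
    for i in range(n_genes):
        gene = f"ARCH{i + 1:04d}"
        length = int(round(10 ** rng.uniform(math.log10(300), math.log10(6000))))
        start, end = cursor, cursor + length
        cursor = end + _GENE_GAP
        gene_rows.append(("chr1", gene, start, end))
        gene_lengths[gene] = length
        common = i % 2 == 0
        archetypes[gene] = "common_hom" if common else "rare_het"
        ref = str(rng.choice(_BASES))
        alt = _Alt(
            seq=str(rng.choice([b for b in _BASES if b != ref])),
            af=0.5 if common else 1e-5,
            true_af=0.5 if common else 1e-5,
            d=1.0, kind="missense", func=_MISSENSE, mt_class="D",
        )
        genotypes = np.ones((n, 2), dtype=int)
        if not common:
            genotypes[:, 0] = 0
        record = _Record(
            chrom="chr1", pos=start + length // 2 + 1, ref=ref, alts=[alt],
            genotypes=genotypes, haploid=np.zeros(n, dtype=bool), gene=gene,
        )
        records.append(record)
        for s in range(n):
            truth.iloc[s, i] = _truth_contribution(record, s, 1e-5)

    vcf = out / "cohort.vcf"
    ann = out / "annotations.tsv"
    _write_vcf(vcf, records, sample_ids)
    _write_annotations(ann, records, metrics)
    beds = [out / "kit_a.bed", out / "kit_b.bed"]
    with open(beds[0], "w") as a, open(beds[1], "w") as b:
        for chrom, gene, start, end in gene_rows:
            a.write(f"{chrom}\t{start - 30}\t{end}\t{gene}\n")
            b.write(f"{chrom}\t{start}\t{end + 30}\t{gene}\n")
    gene_model = out / "gene_model.bed"
    with open(gene_model, "w") as fh:
        for chrom, gene, start, end in gene_rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{gene}\n")
    phen = out / "phenotypes.tsv"
    with open(phen, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sid in sample_ids:
            fh.write(f"{sid}\tcase\n")
    sexf = out / "sex.tsv"
    with open(sexf, "w") as fh:
        fh.write("sample_id\tsex\n")
        for sid in sample_ids:
            fh.write(f"{sid}\tF\n")
    truth_path = out / "truth_matrix.tsv"
    truth.to_csv(truth_path, sep="\t", float_format="%.12g")
    return CohortBundle(
        directory=out, vcf=vcf, annotations=ann, bed_files=beds,
        gene_model=gene_model, phenotypes=phen, sex_file=sexf,
        truth_path=truth_path, truth=truth, gene_lengths=gene_lengths,
        sample_ids=sample_ids, archetypes=archetypes,
    )


def causal_gene_scores(
    n: int,
    carrier_fraction: float,
    maf: float,
    deleteriousness: float,
    zygosity: str = "het",
    floor: float = 1e-5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Gene scores for a group where only carriers of one variant score.

    Direct evaluation of the single-variant score (non-carriers score 0),
    used to study power of group comparisons without file round-trips.
    """
    rng = rng or np.random.default_rng()
    f_alt = max(maf, floor)
    if zygosity == "hom":
        score = -deleteriousness * math.log10(f_alt * f_alt)
    elif zygosity == "het":
        f_ref = max(1.0 - f_alt, floor)
        score = -deleteriousness * math.log10(f_alt * f_ref)
    else:
        raise SimulationError(f"zygosity must be het or hom, got {zygosity!r}")
    return np.where(rng.random(n) < carrier_fraction, score, 0.0)


def load_sim_config(path: str | Path) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a YAML file.

    Top-level keys mirror the dataclass fields; ``genes`` and ``causal`` are
    lists of mappings mirroring :class:`GeneSpec` / :class:`CausalSpec`.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    genes = tuple(GeneSpec(**{**g, "maf_log10_range": tuple(g.get("maf_log10_range", (-4.0, math.log10(0.5))))})
                  for g in raw.pop("genes", []))
    causal = tuple(CausalSpec(**c) for c in raw.pop("causal", []))
    if not genes:
        genes = default_gene_panel()
    for key in ("metrics",):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SimulationConfig(genes=genes, causal=causal, **raw)
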