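"""Per-variant contributions, gene aggregation, and matrix operations."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from geneburden.ingest import AnnotatedVariant, GenotypeCall
from geneburden.metrics import RawAnnotation
from geneburden.scoring import (
    GeneScoreMatrix,
    ScoringError,
    VariantContribution,
    build_matrix,
    gene_score,
    length_correct,
    profile_zscores,
    read_matrix_tsv,
    summarize_matrix,
    variant_score,
)

FLOOR = 1e-5


class TestVariantScore:
    def test_homozygous_rare_maximum_is_ten(self):
        assert variant_score(1.0, FLOOR, FLOOR) == 10.0

    def test_heterozygous_rare_limit_is_about_five(self):
        assert variant_score(1.0, FLOOR, 1 - FLOOR) == pytest.approx(5.000004342966534)

    def test_common_homozygous_spike_value(self):
        assert variant_score(1.0, 0.5, 0.5) == pytest.approx(0.6020599913279624)

    def test_zero_deleteriousness_scores_zero(self):
        assert variant_score(0.0, 1e-5, 0.3) == 0.0

    def test_fixed_allele_scores_zero(self):
        assert variant_score(1.0, 1.0, 1.0) == 0.0

    @pytest.mark.parametrize("bad", [(-0.1, 0.5, 0.5), (1.1, 0.5, 0.5), (0.5, 0.0, 0.5), (0.5, 0.5, 1.5)])
    def test_contract_violations_raise(self, bad):
        with pytest.raises(ScoringError):
            variant_score(*bad)


@settings(max_examples=200, derandomize=True)
@given(
    d1=st.floats(0.01, 1.0),
    d2=st.floats(0.0, 1.0),
    f1=st.floats(FLOOR, 1.0),
    f2=st.floats(FLOOR, 1.0),
)
def test_score_monotone_in_deleteriousness_and_rarity(d1, d2, f1, f2):
    s = variant_score(d1, f1, f2)
    assert 0.0 <= s <= 10.0 + 1e-9  # bound with the default floor
    if f1 * f2 < 1.0 and d2 > d1:
        assert variant_score(d2, f1, f2) > s
    shrunk = max(f1 * 0.5, FLOOR)
    if shrunk < f1:
        assert variant_score(d1, shrunk, f2) > s or d1 == 0.0


@pytest.mark.parametrize("f", [1e-5, 1e-4, 1e-3, 0.01])
def test_rare_homozygote_scores_twice_the_heterozygote(f):
    """The multiplicative zygosity model: hom/het ratio ~= 2 for rare alleles."""
    hom = variant_score(1.0, f, f)
    het = variant_score(1.0, f, 1.0 - f)
    assert 1.99 < hom / het < 2.01


class TestGeneScore:
    def test_empty_gene_scores_zero(self):
        assert gene_score([]) == 0.0

    def test_single_contribution_identity(self):
        assert gene_score([10.0]) == 10.0

    def test_sum_of_archetypal_contributions(self):
        assert gene_score([0.60206, 5.0]) == pytest.approx(5.60206)

    def test_contribution_objects_are_summed(self):
        c = VariantContribution(D=1.0, f1=0.5, f2=0.5)
        assert c.score == pytest.approx(0.6020599913279624)
        assert gene_score([c, c]) == pytest.approx(2 * c.score)

    def test_additivity_over_concatenation(self):
        a = [0.3, 1.7, 2.0]
        b = [5.0, 0.1]
        assert gene_score(a + b) == pytest.approx(gene_score(a) + gene_score(b))


class TestLengthCorrection:
    def test_double_length_gene_halves_score(self):
        assert length_correct(2.0, 2922, 1461) == 1.0

    def test_median_length_gene_unchanged(self):
        assert length_correct(5.0, 1461) == 5.0

    def test_short_gene_inflates(self):
        assert length_correct(0.6, 487, 1461) == pytest.approx(1.8)

    def test_nonpositive_length_names_the_gene(self):
        with pytest.raises(ScoringError, match="NOD2"):
            length_correct(1.0, 0, gene="NOD2")


def _matrix(values, genes=None, metric="CADD", **kw):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"G{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, columns=genes,
                      index=[f"S{i}" for i in range(values.shape[0])])
    return GeneScoreMatrix(values=df, metric_name=metric, **kw)


class TestSummarize:
    def test_all_zero_matrix_has_missing_cv(self):
        s = summarize_matrix(_matrix(np.zeros((3, 4))))
        assert s.cv is None
        assert s.zero_genes_per_sample.tolist() == [4, 4, 4]
        assert s.median_low_genes == 4

    def test_two_cell_matrix_statistics(self):
        s = summarize_matrix(_matrix([[1.0, 3.0]]))
        assert s.mean_score == 2.0
        assert s.cv == pytest.approx(0.5)  # population sigma/mu
        assert s.max_score == 3.0

    def test_spike_lands_in_its_hundredth_bin(self):
        s = summarize_matrix(_matrix([[0.602, 0.602, 0.602]]))
        occupied = np.flatnonzero(s.histogram_counts)
        assert occupied.tolist() == [60]  # bin [0.60, 0.61)
        assert s.histogram_counts[60] == 3

    def test_exclude_low_masks_sub_hundredth_bin(self):
        s = summarize_matrix(_matrix([[0.0, 0.005, 0.5]]), exclude_low=True)
        assert s.histogram_counts[0] == 0
        assert s.histogram_counts[50] == 1


class TestProfileZscores:
    def test_three_sample_standardization(self):
        z = profile_zscores(_matrix([[1.0], [2.0], [3.0]], genes=["G"]))
        assert z["G"].tolist() == pytest.approx([-1.2247448, 0.0, 1.2247448], abs=1e-6)
        assert z["G"].mean() == pytest.approx(0.0)

    def test_constant_gene_flagged_and_zeroed(self):
        with pytest.warns(UserWarning, match="zero score variance"):
            z = profile_zscores(_matrix([[2.0], [2.0], [2.0]], genes=["G"]))
        assert (z["G"] == 0).all()

    def test_subsets_select_but_standardize_on_full_cohort(self):
        m = _matrix([[1.0, 0.0], [2.0, 0.5], [3.0, 1.0]], genes=["A", "B"])
        z = profile_zscores(m, gene_subset=["A"], sample_subset=["S2"])
        assert z.shape == (1, 1)
        assert z.loc["S2", "A"] == pytest.approx(1.2247448, abs=1e-6)

    def test_unknown_gene_or_sample_raises(self):
        m = _matrix([[1.0], [2.0]], genes=["A"])
        with pytest.raises(ScoringError):
            profile_zscores(m, gene_subset=["NOPE"])
        with pytest.raises(ScoringError):
            profile_zscores(m, sample_subset=["NOPE"])


def _mk_variant(pos, alts, genes, funcs, freqs, cadd_raws, chrom="chr1"):
    return AnnotatedVariant(
        chrom=chrom, pos=pos, ref_allele="A", alt_alleles=tuple(alts),
        gene_symbols=tuple(genes), functional_class=tuple(funcs),
        allele_freqs=tuple(freqs),
        raw_annotations=tuple(
            {"CADD": RawAnnotation("CADD", r)} if r is not None else {}
            for r in cadd_raws
        ),
    )


def _calls(genos, chrom="chr1"):
    out = []
    for i, g in enumerate(genos):
        if g is None:
            out.append(GenotypeCall(f"S{i}", 2, None))
        elif len(g) == 1:
            out.append(GenotypeCall(f"S{i}", 1, tuple(g), is_male_x=chrom == "chrX"))
        else:
            out.append(GenotypeCall(f"S{i}", 2, tuple(g)))
    return out


@pytest.fixture()
def mini_cohort():
    """Five samples, three genes, hand-checkable variants."""
    v1 = _mk_variant(100, ["G"], ["A1"], ["nonsynonymous SNV"], [1e-5], [35.79])
    g1 = _calls([(0, 1), (1, 1), (0, 0), None, (0, 1)])
    v2 = _mk_variant(200, ["G"], ["A1"], ["synonymous SNV"], [0.3], [35.79])
    g2 = _calls([(1, 1)] * 5)
    v3 = _mk_variant(300, ["G"], ["B1"], ["stopgain"], [0.5], [None])
    g3 = _calls([(0, 1), (0, 0), (1, 1), (0, 0), (0, 0)])
    return [(v1, g1), (v2, g2), (v3, g3)]


class TestBuildMatrix:
    def test_rare_het_approaches_five(self, mini_cohort):
        m = build_matrix(iter(mini_cohort), "CADD")
        assert m.values.loc["S0", "A1"] == pytest.approx(5.000004342966534)

    def test_missing_genotype_and_homref_score_zero(self, mini_cohort):
        m = build_matrix(iter(mini_cohort), "CADD")
        assert m.values.loc["S3", "A1"] == 0.0  # ./. contributes nothing
        assert m.values.loc["S3", "B1"] == 0.0

    def test_synonymous_variant_excluded(self, mini_cohort):
        m = build_matrix(iter(mini_cohort), "CADD")
        # S2 is hom-ref at v1 and synonymous-only at v2: exactly zero for A1
        assert m.values.loc["S2", "A1"] == 0.0

    def test_truncating_override_without_metric_annotation(self, mini_cohort):
        m = build_matrix(iter(mini_cohort), "CADD")
        assert m.values.loc["S2", "B1"] == pytest.approx(-math.log10(0.25))

    def test_determinism(self, mini_cohort):
        a = build_matrix(iter(mini_cohort), "CADD").values
        b = build_matrix(iter(mini_cohort), "CADD").values
        assert a.equals(b)

    def test_empty_stream_raises(self):
        with pytest.raises(ScoringError):
            build_matrix(iter([]), "CADD")


def test_matrix_tsv_roundtrip_preserves_anchor_precision(tmp_path, mini_cohort):
    m = build_matrix(iter(mini_cohort), "CADD")
    path = tmp_path / "m.tsv"
    m.write_tsv(str(path))
    back = read_matrix_tsv(str(path), metric_name="CADD")
    assert back.values.columns.tolist() == m.values.columns.tolist()
    # 6 significant digits survive the round trip
    assert back.values.loc["S0", "A1"] == pytest.approx(5.00000, abs=5e-6)
    assert f"{back.values.loc['S2', 'B1']:.5f}" == "0.60206"
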