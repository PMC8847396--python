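import numpy as np
import pandas as pd
import pytest

from clonoscope._errors import ValidationError
from clonoscope.clonotype import build_clones
from clonoscope.germline_usage import (
    compare_external_usage,
    external_usage_from_table,
    normalize_gene_name,
    pairing_matrix,
    usage_correlation,
    usage_vector,
)
from conftest import make_cell
from oracles import pearson_literal


def rep_with_vgenes(sample_id, pairs, group="g"):
    """One cell per (TRBV, TRAV) entry; distinct clonotypes throughout."""
    cells = [
        make_cell(f"{sample_id}.b{i}", trb_nt=f"TGT{i:03d}B", tra_nt=f"TGT{i:03d}A",
                  sample_id=sample_id, trbv=b, trav=a)
        for i, (b, a) in enumerate(pairs)
    ]
    return build_clones(cells, group, sample_id=sample_id)


class TestNormalizeGeneName:
    @pytest.mark.parametrize("raw,expected", [
        ("TRBV13-1", "TRBV13-1"),
        ("TRBV13.1", "TRBV13-1"),
        ("trbv13-1*01", "TRBV13-1"),
        ("TRAV9-1*02", "TRAV9-1"),
    ])
    def test_canonical_forms(self, raw, expected):
        assert normalize_gene_name(raw) == expected

    def test_unresolvable_name_left_as_is(self):
        assert normalize_gene_name("IGHV1-2") == "IGHV1-2"


class TestUsageVector:
    def test_single_gene_is_frequency_one(self):
        rep = rep_with_vgenes("s1", [("TRBV19", "TRAV1")] * 4)
        v = usage_vector(rep, "TRBV")
        assert v.frequencies.to_dict() == {"TRBV19": 1.0}

    def test_per_cell_frequencies(self):
        rep = rep_with_vgenes("s1", [("TRBV13-1", "TRAV1"),
                                     ("TRBV13-1", "TRAV1"),
                                     ("TRBV29", "TRAV1")])
        v = usage_vector(rep, "TRBV", "per_cell")
        assert v.frequencies["TRBV13-1"] == pytest.approx(2 / 3)
        assert v.frequencies["TRBV29"] == pytest.approx(1 / 3)

    def test_per_clone_majority_rule(self):
        # one clone of 5 cells with mixed V calls: majority TRBV19
        cells = [
            make_cell(f"b{i}", trbv="TRBV19" if i < 3 else "TRBV29")
            for i in range(5)
        ]
        rep = build_clones(cells, "g")
        v = usage_vector(rep, "TRBV", "per_clone")
        assert v.counts.to_dict() == {"TRBV19": 1.0}

    def test_frequencies_sum_to_one(self):
        rep = rep_with_vgenes("s1", [("TRBV1", "TRAV1"), ("TRBV2", "TRAV2"),
                                     ("TRBV3", "TRAV3-3")])
        for space in ("TRBV", "TRAV", "TRBV+TRAV"):
            v = usage_vector(rep, space)
            assert v.frequencies.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_repertoire_rejected(self):
        rep = build_clones([], "g", sample_id="s1")
        with pytest.raises(ValidationError):
            usage_vector(rep)


class TestPairingMatrix:
    def test_single_cell_entry(self):
        rep = rep_with_vgenes("s1", [("TRBV19", "TRAV14-1")])
        pm = pairing_matrix(rep)
        assert pm.counts.loc["TRBV19", "TRAV14-1"] == 1

    def test_marginals_equal_usage_counts(self):
        pairs = [("TRBV19", "TRAV1"), ("TRBV19", "TRAV2"),
                 ("TRBV29", "TRAV1"), ("TRBV29", "TRAV1"), ("TRBV5", "TRAV2")]
        rep = rep_with_vgenes("s1", pairs)
        pm = pairing_matrix(rep)
        trbv = usage_vector(rep, "TRBV").counts
        trav = usage_vector(rep, "TRAV").counts
        assert pm.counts.sum(axis=1).sort_index().equals(trbv.astype(int).sort_index())
        assert pm.counts.sum(axis=0).sort_index().equals(trav.astype(int).sort_index())

    def test_label_threshold_selects_pairs(self):
        pairs = [("TRBV19", "TRAV1")] * 7 + [("TRBV29", "TRAV2")] * 4
        rep = rep_with_vgenes("s1", pairs)
        pm = pairing_matrix(rep, label_threshold=5)
        labeled = pm.labeled_pairs()
        assert len(labeled) == 1
        assert labeled.iloc[0][["TRBV", "TRAV", "count"]].tolist() == ["TRBV19", "TRAV1", 7]


class TestUsageCorrelation:
    def test_identical_vectors_correlate_perfectly(self):
        # non-uniform usage: a constant frequency vector has no defined r
        pairs = [("TRBV19", "TRAV1"), ("TRBV19", "TRAV2"), ("TRBV5", "TRAV1")]
        v1 = usage_vector(rep_with_vgenes("s1", pairs), "TRBV")
        v2 = usage_vector(rep_with_vgenes("s2", pairs), "TRBV")
        corr, order = usage_correlation([v1, v2])
        assert corr.loc["s1", "s2"] == pytest.approx(1.0)
        assert sorted(order) == ["s1", "s2"]

    def test_opposite_vectors_anticorrelate(self):
        v1 = usage_vector(rep_with_vgenes("s1", [("TRBV1", "TRAV1")]), "TRBV")
        v2 = usage_vector(rep_with_vgenes("s2", [("TRBV2", "TRAV1")]), "TRBV")
        corr, _ = usage_correlation([v1, v2])
        assert corr.loc["s1", "s2"] == pytest.approx(-1.0)

    def test_symmetric_unit_diagonal_and_gene_order_invariance(self):
        reps = [
            rep_with_vgenes("s1", [("TRBV1", "TRAV1"), ("TRBV2", "TRAV1"), ("TRBV2", "TRAV1")]),
            rep_with_vgenes("s2", [("TRBV2", "TRAV1"), ("TRBV3", "TRAV1")]),
            rep_with_vgenes("s3", [("TRBV1", "TRAV1"), ("TRBV3", "TRAV1")]),
        ]
        vectors = [usage_vector(r, "TRBV") for r in reps]
        corr, _ = usage_correlation(vectors)
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)
        # reversing the input vector list must not change any pairwise value
        corr_rev, _ = usage_correlation(vectors[::-1])
        assert np.allclose(corr, corr_rev.loc[corr.index, corr.columns])

    def test_dendrogram_groups_same_profile_samples(self):
        from clonoscope.synthetic_data import (
            GeneProfile, GeneratorConfig, GermlineModel, SampleSpec, SizeLaw,
            generate_cohort,
        )
        from clonoscope.vdj_io import assemble_cells, contigs_from_frame

        profile_a = GeneProfile(trbv={"TRBV1": 0.7, "TRBV2": 0.1, "TRBV3": 0.1, "TRBV4": 0.1})
        profile_b = GeneProfile(trbv={"TRBV1": 0.1, "TRBV2": 0.1, "TRBV3": 0.1, "TRBV4": 0.7})
        config = GeneratorConfig(
            seed=42,
            samples=tuple(
                SampleSpec(sample_id=f"{p}{i}", group_label=p, n_clones=80,
                           size_law=SizeLaw("geometric", 0.6, 50), profile=p)
                for p in ("A", "B") for i in (1, 2)
            ),
            germline=GermlineModel(profiles={"A": profile_a, "B": profile_b}, kappa=300),
            public_clone_rate=0.0,
        )
        cohort = generate_cohort(config)
        vectors = []
        for sid, df in cohort.contigs.items():
            cells, _ = assemble_cells(contigs_from_frame(df, "tenx_csv", sid))
            rep = build_clones(cells, sid[0], sample_id=sid)
            vectors.append(usage_vector(rep, "TRBV"))
        _, order = usage_correlation(vectors)
        # same-profile samples must be adjacent leaves
        assert order[0][0] == order[1][0] and order[2][0] == order[3][0]

    def test_constant_vector_reported_na(self):
        v1 = usage_vector(rep_with_vgenes("s1", [("TRBV1", "TRAV1")]), "TRBV")
        v2 = usage_vector(rep_with_vgenes("s2", [("TRBV1", "TRAV1")]), "TRBV")
        # both concentrated on the same single gene -> zero variance on the
        # union space of one gene: correlation undefined
        corr, _ = usage_correlation([v1, v2])
        assert np.isnan(corr.loc["s1", "s2"])


class TestExternalUsage:
    def test_identical_external_vector(self):
        pairs = [("TRBV19", "TRAV1"), ("TRBV19", "TRAV2"), ("TRBV29", "TRAV2")]
        v = usage_vector(rep_with_vgenes("s1", pairs), "TRBV")
        ext = external_usage_from_table(
            pd.DataFrame({"gene": ["TRBV19", "TRBV29"], "frequency": [2 / 3, 1 / 3]}),
            sample_id="naive_ref",
        )
        corr, _ = compare_external_usage([v], [ext])
        assert corr.loc["s1", "naive_ref"] == pytest.approx(1.0)

    def test_dialect_normalization(self):
        v = usage_vector(rep_with_vgenes("s1", [("TRBV13-1", "TRAV1"),
                                                ("TRBV13-1", "TRAV2"),
                                                ("TRBV5", "TRAV2")]), "TRBV")
        ext = external_usage_from_table(
            pd.DataFrame({"gene": ["TRBV13.1", "trbv5*01"], "frequency": [2 / 3, 1 / 3]}),
            sample_id="ext",
        )
        corr, _ = compare_external_usage([v], [ext])
        assert corr.loc["s1", "ext"] == pytest.approx(1.0)

    def test_disjoint_support_matches_hand_pearson(self):
        v = usage_vector(
            rep_with_vgenes("s1", [("TRBV1", "TRAV1")] * 3 + [("TRBV2", "TRAV1")] * 2
                            + [("TRBV3", "TRAV1")]), "TRBV")
        ext = external_usage_from_table(
            pd.DataFrame({"gene": ["TRBV4", "TRBV5", "TRBV6"],
                          "frequency": [0.5, 0.3, 0.2]}),
            sample_id="ext",
        )
        corr, _ = compare_external_usage([v], [ext])
        # union space of 6 genes, each vector zero where the other lives
        x = [3 / 6, 2 / 6, 1 / 6, 0, 0, 0]
        y = [0, 0, 0, 0.5, 0.3, 0.2]
        assert corr.loc["s1", "ext"] == pytest.approx(pearson_literal(x, y), abs=1e-12)
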