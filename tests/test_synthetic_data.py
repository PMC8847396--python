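import json

import numpy as np
import pandas as pd
import pytest

from clonoscope._errors import ValidationError
from clonoscope.clonotype import build_clones
from clonoscope.diversity import shannon_evenness
from clonoscope.synthetic_data import (
    ClusterModel,
    ContaminationModel,
    GeneratorConfig,
    SampleSpec,
    SizeLaw,
    beta1_for_target_log_or,
    default_cohort_config,
    generate_cohort,
    generate_repertoire,
    implied_target_log_or,
    sample_clone_sizes,
)
from clonoscope.vdj_io import assemble_cells, contigs_from_frame


def clean_config(seed=0, n_clones=40, **kwargs):
    base = default_cohort_config(seed=seed, n_clones=n_clones)
    return GeneratorConfig(
        seed=seed, samples=base.samples,
        contamination=ContaminationModel(0.0, 0.0, 0.0),
        public_clone_rate=kwargs.pop("public_clone_rate", 0.0),
        **kwargs,
    )


def pipeline_repertoire(contigs_df, sample_id, group):
    cells, report = assemble_cells(contigs_from_frame(contigs_df, "tenx_csv", sample_id))
    return build_clones(cells, group, sample_id=sample_id), report


class TestSampleCloneSizes:
    def test_steep_powerlaw_limit_all_singletons(self):
        rng = np.random.default_rng(0)
        sizes = sample_clone_sizes(200, SizeLaw("powerlaw", 60.0, 100), rng)
        assert set(sizes) == {1}

    def test_geometric_q_one_all_singletons(self):
        rng = np.random.default_rng(0)
        sizes = sample_clone_sizes(50, SizeLaw("geometric", 1.0, 100), rng)
        assert set(sizes) == {1}

    def test_nonnormalizable_law_rejected(self):
        with pytest.raises(ValidationError):
            SizeLaw("powerlaw", 0.9, None)

    def test_shallow_law_gives_lower_evenness(self):
        """alpha=1.8 concentrates mass in large clones relative to alpha=3.0."""
        rng = np.random.default_rng(123)
        diffs = []
        for _ in range(100):
            acute = sample_clone_sizes(300, SizeLaw("powerlaw", 3.0, 1000), rng)
            chronic = sample_clone_sizes(300, SizeLaw("powerlaw", 1.8, 1000), rng)
            diffs.append(shannon_evenness(acute) - shannon_evenness(chronic))
        assert np.mean(diffs) > 0
        assert np.mean([d > 0 for d in diffs]) >= 0.99


class TestClusterModel:
    def test_baseline_at_size_one(self):
        m = ClusterModel()
        p = m.probabilities(1, "acute")
        expected = np.array([m.baseline[c] for c in m.cluster_ids])
        assert np.allclose(p, expected / expected.sum())

    def test_target_enrichment_grows_with_size(self):
        m = ClusterModel(beta1=1.0)
        probs = [m.target_probability(k, "chronic") for k in (1, 5, 50)]
        assert probs[0] < probs[1] < probs[2]

    def test_beta1_solver_hits_requested_log_or(self):
        rng = np.random.default_rng(7)
        sizes = sample_clone_sizes(300, SizeLaw("powerlaw", 1.8, 1000), rng)
        m = ClusterModel()
        b1 = beta1_for_target_log_or(sizes, m, "latent", 1.5)
        m2 = ClusterModel(beta1=b1)
        assert implied_target_log_or(sizes, m2, "latent") == pytest.approx(1.5, abs=1e-8)

    def test_empty_cluster_list_rejected(self):
        with pytest.raises(ValidationError):
            ClusterModel(cluster_ids=(), baseline={})


class TestGenerateRepertoire:
    def test_zero_contamination_retains_all_cells(self):
        config = clean_config(seed=3, n_clones=30)
        contigs, annotations, truth = generate_repertoire(config, 0)
        rep, report = pipeline_repertoire(contigs, truth.sample_id, truth.group_label)
        assert report.n_retained == report.n_barcodes == len(annotations)
        assert rep.n_cells == truth.clones["size"].sum()

    def test_full_tra_dropout_retains_nothing(self):
        base = clean_config(seed=3, n_clones=10)
        config = GeneratorConfig(
            seed=3, samples=base.samples,
            contamination=ContaminationModel(p_drop_tra=1.0),
            public_clone_rate=0.0,
        )
        contigs, _, truth = generate_repertoire(config, 0)
        _, report = pipeline_repertoire(contigs, truth.sample_id, truth.group_label)
        assert report.n_retained == 0

    def test_determinism_byte_identical(self, tmp_path):
        config = default_cohort_config(seed=11, n_clones=15)
        a = generate_cohort(config, out_dir=tmp_path / "a")
        b = generate_cohort(config, out_dir=tmp_path / "b")
        for name in ("acute1_filtered_contig_annotations.csv", "annotations.tsv",
                     "manifest.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_contigs_translate_consistently(self):
        from Bio.Seq import Seq

        config = clean_config(seed=5, n_clones=10)
        contigs, _, _ = generate_repertoire(config, 0)
        for row in contigs.itertuples(index=False):
            assert str(Seq(row.cdr3_nt).translate()) == row.cdr3
            assert row.cdr3.startswith("C") and row.cdr3.endswith("F")


class TestGenerateCohort:
    def test_six_samples_two_per_group(self):
        cohort = generate_cohort(clean_config(seed=1, n_clones=10))
        assert len(cohort.contigs) == 6
        groups = [t.group_label for t in cohort.truths.values()]
        assert sorted(set(groups)) == ["acute", "chronic", "latent"]

    def test_duplicate_sample_ids_rejected(self):
        spec = SampleSpec(sample_id="x", group_label="acute")
        with pytest.raises(ValidationError):
            GeneratorConfig(samples=(spec, spec))

    def test_zero_public_rate_no_overlap(self):
        from clonoscope.overlap import overlap_matrix

        cohort = generate_cohort(clean_config(seed=2, n_clones=40))
        reps = [
            pipeline_repertoire(df, sid, cohort.truths[sid].group_label)[0]
            for sid, df in cohort.contigs.items()
        ]
        mat = overlap_matrix(reps)
        off = mat.counts[~np.isnan(mat.counts)]
        assert np.all(off == 0)

    def test_planted_public_clones_recovered_exactly(self):
        from clonoscope.overlap import overlap_matrix

        cohort = generate_cohort(clean_config(seed=4, n_clones=100,
                                              public_clone_rate=0.05))
        planted = cohort.manifest["planted_public_clones"]
        assert planted, "expected at least one planted public clone"
        reps = {
            sid: pipeline_repertoire(df, sid, cohort.truths[sid].group_label)[0]
            for sid, df in cohort.contigs.items()
        }
        mat = overlap_matrix(list(reps.values()))
        ids = mat.sample_ids
        expected = np.zeros((len(ids), len(ids)))
        for entry in planted:
            i, j = ids.index(entry["source"]), ids.index(entry["dest"])
            expected[i, j] += 1
            expected[j, i] += 1
        off = ~np.eye(len(ids), dtype=bool)
        assert np.array_equal(mat.counts[off], expected[off])

    def test_manifest_sizes_match_emitted_cells(self, tmp_path):
        cohort = generate_cohort(clean_config(seed=6, n_clones=20), out_dir=tmp_path)
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        for sid, df in cohort.contigs.items():
            n_cells = df["barcode"].nunique()
            assert manifest["samples"][sid]["n_cells"] == n_cells

    def test_evenness_recovery_exact(self):
        cohort = generate_cohort(clean_config(seed=8, n_clones=50))
        for sid, df in cohort.contigs.items():
            truth = cohort.truths[sid]
            rep, _ = pipeline_repertoire(df, sid, truth.group_label)
            planted = shannon_evenness(truth.clones["size"])
            assert shannon_evenness(rep.sizes()) == pytest.approx(planted, abs=1e-12)

    def test_clone_sizes_recovered_exactly(self):
        cohort = generate_cohort(clean_config(seed=9, n_clones=60))
        for sid, df in cohort.contigs.items():
            truth = cohort.truths[sid]
            rep, _ = pipeline_repertoire(df, sid, truth.group_label)
            got = {c.clone_id: c.size for c in rep.clones}
            want = dict(zip(truth.clones["clone_id"], truth.clones["size"]))
            assert got == want
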