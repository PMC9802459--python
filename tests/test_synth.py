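"""Tests of the synthetic-data generators against their own ground truth."""

import numpy as np
import pandas as pd
import pytest

from sdvar import synth


class TestGenerateStudy:
    def test_determinism(self):
        cfg = synth.SynthConfig(n_genes=50, n_male=30, n_female=30, seed=7)
        a = synth.generate_study(cfg)
        b = synth.generate_study(cfg)
        assert a.counts.equals(b.counts)
        assert a.sample_meta.equals(b.sample_meta)
        assert a.truth.equals(b.truth)

    def test_no_planted_effects_when_fraction_zero(self):
        cfg = synth.SynthConfig(n_genes=40, n_male=20, n_female=20, sdv_fraction=0.0, seed=3)
        st = synth.generate_study(cfg)
        assert not st.truth["is_sdv"].any()
        assert (st.truth["sdv_direction"] == "none").all()

    def test_single_sex_rejected(self):
        with pytest.raises(ValueError):
            synth.SynthConfig(n_male=0).validate()

    def test_planted_dispersion_ordering(self):
        # for a log-sigma effect of 1.5 at 200 samples/sex, the affected sex
        # shows the larger sample variance in nearly all planted genes
        cfg = synth.SynthConfig(
            n_genes=400, n_male=200, n_female=200, sdv_fraction=0.25,
            sbe_fraction=0.0, outlier_fraction=0.0, seed=11,
        )
        st = synth.generate_study(cfg)
        male = st.sample_meta["sex"].to_numpy() == "male"
        counts = st.counts.to_numpy(dtype=float)
        # compare variances of log counts to damp the mean dependence
        lc = np.log1p(counts)
        vm = lc[:, male].var(axis=1)
        vf = lc[:, ~male].var(axis=1)
        planted = st.truth["is_sdv"].to_numpy()
        expect_male = st.truth["sdv_direction"].to_numpy() == "male_higher"
        agree = np.where(expect_male[planted], vm[planted] > vf[planted],
                         vf[planted] > vm[planted])
        assert agree.mean() >= 0.95

    def test_null_gene_nb_moments(self):
        # Var = mu + sigma * mu^2 for unplanted genes at large n
        cfg = synth.SynthConfig(
            n_genes=12, n_male=5000, n_female=5000, sdv_fraction=0.0,
            sbe_fraction=0.0, outlier_fraction=0.0, covariate_effect_scale=0.0,
            library_size_range=(10_000_000, 10_000_000), seed=5,
        )
        st = synth.generate_study(cfg)
        counts = st.counts.to_numpy(dtype=float)
        m = counts.mean(axis=1)
        v = counts.var(axis=1)
        sigma = st.truth["baseline_sigma"].to_numpy()
        expected = m + sigma * m**2
        # relative MC error of a variance estimate at n=1e4 is a few percent
        assert np.all(np.abs(v - expected) / expected < 0.15)

    def test_outlier_samples_detectable_after_cpm(self):
        # planted outliers must survive CPM normalization (they perturb the
        # expression profile, not just the library size) and be caught by
        # the PCA screen
        from sdvar import pipeline

        cfg = synth.SynthConfig(
            n_genes=300, n_male=50, n_female=50, outlier_fraction=0.04,
            outlier_scale=3.0, seed=9,
        )
        st = synth.generate_study(cfg)
        out = st.sample_meta.index[st.sample_meta["is_outlier"]].tolist()
        assert len(out) == 4
        cpm = pipeline.compute_cpm(st.counts)
        kept = pipeline.pca_outlier_removal(np.log2(cpm + 1.0))
        assert not set(out) & set(kept)


class TestGeneSets:
    def test_full_overlap_gives_expected_fold(self):
        rng_genes = [f"G{i}" for i in range(1000)]
        labels = pd.Series("none", index=rng_genes)
        labels.iloc[:100] = "hit"  # 10% label frequency
        sets, planted = synth.generate_gene_sets(
            10, rng_genes, labels=labels, target_label="hit",
            planted_overlap=1.0, n_planted=5, set_size_range=(40, 40), seed=1,
        )
        for name in planted:
            members = sets[name]
            overlap = sum(labels[g] == "hit" for g in members)
            fold = (overlap / len(members)) / 0.1
            assert fold == pytest.approx(10.0)

    def test_zero_overlap_independent_of_labels(self):
        genes = [f"G{i}" for i in range(2000)]
        labels = pd.Series("none", index=genes)
        labels.iloc[:200] = "hit"
        sets, _ = synth.generate_gene_sets(
            40, genes, labels=labels, target_label="hit",
            planted_overlap=0.0, n_planted=0, set_size_range=(50, 50), seed=2,
        )
        overlaps = [sum(labels[g] == "hit" for g in m) for m in sets.values()]
        # mean overlap should match set_size * label frequency = 5
        assert np.mean(overlaps) == pytest.approx(5.0, abs=1.5)

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError):
            synth.generate_gene_sets(3, [], seed=0)

    def test_bad_overlap_raises(self):
        with pytest.raises(ValueError):
            synth.generate_gene_sets(3, ["a"], planted_overlap=1.2, seed=0)


class TestEgeneLabels:
    def _calls(self, genes, frac, seed):
        rng = np.random.default_rng(seed)
        s = pd.Series(False, index=genes)
        s.iloc[rng.choice(len(genes), int(frac * len(genes)), replace=False)] = True
        return s

    def test_depletion_factor_recovered(self):
        genes = [f"G{i}" for i in range(100_000)]
        calls = {"t": self._calls(genes, 0.3, 1)}
        eg = synth.generate_egene_labels(["t"], genes, calls, depletion_factor=0.5,
                                         base_rate=0.4, seed=2)["t"]
        sdv = calls["t"]
        assert eg[sdv].mean() == pytest.approx(0.2, abs=0.01)
        assert eg[~sdv].mean() == pytest.approx(0.4, abs=0.01)

    def test_factor_zero_excludes_sdv(self):
        genes = [f"G{i}" for i in range(5000)]
        calls = {"t": self._calls(genes, 0.2, 3)}
        eg = synth.generate_egene_labels(["t"], genes, calls, depletion_factor=0.0, seed=4)["t"]
        assert not eg[calls["t"]].any()

    def test_factor_one_independent(self):
        genes = [f"G{i}" for i in range(50_000)]
        calls = {"t": self._calls(genes, 0.3, 5)}
        eg = synth.generate_egene_labels(["t"], genes, calls, depletion_factor=1.0,
                                         base_rate=0.3, seed=6)["t"]
        sdv = calls["t"]
        assert abs(eg[sdv].mean() - eg[~sdv].mean()) < 0.02


class TestSingleCell:
    def test_markers_exclusive_and_deterministic(self):
        c1, l1 = synth.generate_sc_counts(seed=8)
        c2, _ = synth.generate_sc_counts(seed=8)
        assert c1.equals(c2)
        for t in ["L1", "L2", "basal"]:
            markers = [g for g in c1.columns if g.startswith(f"MARK_{t}_")]
            other = l1 != t
            assert c1.loc[other, markers].to_numpy().sum() == 0

    def test_min_one_cell_per_type(self):
        with pytest.raises(ValueError):
            synth.generate_sc_counts(n_cells_per_type=(0, 5, 5))
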