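import numpy as np
import pandas as pd
import pytest

from chipbiome import differential as df
from chipbiome import synthetic_data as sd
from chipbiome import array_quant as aq
from chipbiome.containers import AbundanceMatrix
from chipbiome.exceptions import InputError

from .oracles import exact_ranksum_p, lda_effect_oracle


def _matrix(rows, species=None):
    rows = np.asarray(rows, dtype=float)
    species = species or [f"sp{j}" for j in range(rows.shape[1])]
    ab = pd.DataFrame(rows, index=[f"s{i}" for i in range(rows.shape[0])], columns=species)
    return AbundanceMatrix(abundance=ab, detected=ab > 0)


def _groups(matrix, n_first, labels=("ALL", "NC")):
    n = len(matrix.abundance)
    return pd.Series(
        [labels[0]] * n_first + [labels[1]] * (n - n_first), index=matrix.abundance.index
    )


class TestKruskalScreen:
    def test_constant_taxon_flagged_with_p_one(self):
        m = _matrix([[0.5, 0.5], [0.5, 0.5], [0.5, 0.5], [0.5, 0.5]])
        out = df.kruskal_wallis_screen(m, _groups(m, 2))
        assert out.at["sp0", "kw_p"] == 1.0
        assert out.at["sp0", "constant"]

    def test_separated_taxon_agrees_with_permutation_oracle(self):
        a = [0.1, 0.12, 0.11, 0.13, 0.09]
        b = [0.3, 0.32, 0.31, 0.33, 0.29]
        col = np.array(a + b)
        m = _matrix(np.column_stack([col, 1 - col]))
        out = df.kruskal_wallis_screen(m, _groups(m, 5))
        p_exact = exact_ranksum_p(a, b)
        assert p_exact == pytest.approx(2 / 252, rel=1e-9)
        # chi-square approximation of the same decision
        assert abs(out.at["sp0", "kw_p"] - p_exact) < 0.005
        assert out.at["sp0", "kw_p"] < 0.05

    def test_sample_rescaling_leaves_p_unchanged(self):
        """Doubling a sample's raw signal and renormalizing is a no-op on
        a composition, hence on ranks and on the screen p-values."""
        rng = np.random.default_rng(0)
        raw = rng.gamma(2.0, size=(10, 5))
        m1 = _matrix(raw / raw.sum(axis=1, keepdims=True))
        doubled = raw.copy()
        doubled[3] *= 2.0
        m2 = _matrix(doubled / doubled.sum(axis=1, keepdims=True))
        out1 = df.kruskal_wallis_screen(m1, _groups(m1, 5))
        out2 = df.kruskal_wallis_screen(m2, _groups(m2, 5))
        pd.testing.assert_frame_equal(out1, out2)

    def test_single_group_rejected(self):
        m = _matrix(np.random.default_rng(1).dirichlet(np.ones(3), size=4))
        with pytest.raises(InputError):
            df.kruskal_wallis_screen(m, pd.Series(["A"] * 4, index=m.abundance.index))


class TestLdaEffectSize:
    def _strong_matrix(self):
        rng = np.random.default_rng(2)
        n = 16
        base = rng.dirichlet(np.ones(3) * 50, size=n)
        x = base.copy()
        # 100-fold separation on sp0 with tiny within-class spread
        x[:8, 0] = 0.5 + rng.normal(0, 1e-4, 8)
        x[8:, 0] = 0.005 + rng.normal(0, 1e-5, 8)
        x = x / x.sum(axis=1, keepdims=True)
        return _matrix(x)

    def test_strong_separation_scores_at_least_four(self):
        m = self._strong_matrix()
        res = df.lda_effect_size(m, _groups(m, 8), taxa=["sp0", "sp1", "sp2"], seed=0)
        scores = {r.taxon: r.lda_score for r in res}
        assert abs(scores["sp0"]) >= 4.0

    def test_duplicated_taxon_gets_identical_score(self):
        rng = np.random.default_rng(3)
        x = rng.dirichlet(np.ones(3), size=12)
        x[:6, 0] *= 3
        x = x / x.sum(axis=1, keepdims=True)
        ab = pd.DataFrame(x, index=[f"s{i}" for i in range(12)], columns=["a", "b", "c"])
        ab["a2"] = ab["a"]
        ab = ab.div(ab.sum(axis=1), axis=0)
        m = AbundanceMatrix(abundance=ab, detected=ab > 0)
        res = df.lda_effect_size(m, _groups(m, 6), taxa=["a", "a2"], seed=1)
        scores = {r.taxon: r.lda_score for r in res}
        assert scores["a"] == pytest.approx(scores["a2"], rel=1e-9)

    def test_group_swap_flips_enrichment_not_magnitude(self):
        m = self._strong_matrix()
        g = _groups(m, 8)
        swapped = g.map({"ALL": "NC", "NC": "ALL"})
        r1 = df.lda_effect_size(m, g, taxa=["sp0"], seed=4)[0]
        r2 = df.lda_effect_size(m, swapped, taxa=["sp0"], seed=4)[0]
        assert abs(r1.lda_score) == pytest.approx(abs(r2.lda_score), rel=1e-12)
        assert r1.enriched_group != r2.enriched_group

    def test_single_full_round_matches_closed_form_oracle(self):
        """With one bootstrap round on the full cohort the effect size must
        equal the explicit pooled-covariance LDA computation."""
        rng = np.random.default_rng(5)
        x = rng.dirichlet(np.ones(4) * 5, size=14)
        x[:7, 1] *= 2.5
        x = x / x.sum(axis=1, keepdims=True)
        m = _matrix(x)
        g = _groups(m, 7)
        # three of the four parts: full-rank within-class scatter
        res = df.lda_effect_size(
            m, g, taxa=["sp0", "sp1", "sp2"], n_boot=1, subsample_fraction=1.0, seed=0
        )
        expected = lda_effect_oracle(
            x[:, :3] * df.LEFSE_SCALE, np.array([True] * 7 + [False] * 7)
        )
        for r, e in zip(sorted(res, key=lambda r: r.taxon), expected):
            assert abs(r.lda_score) == pytest.approx(np.log10(1 + e), rel=1e-6)


class TestLefseCascade:
    def test_recovers_planted_species_with_direction(self, small_cohort, small_matrix):
        groups = small_cohort.metadata.groups
        res = df.run_lefse(small_matrix, groups, seed=0)
        reported = res.set_index("taxon")
        hits = 0
        for sp, (fold, up_group) in small_cohort.truth.differential.items():
            if sp in reported.index:
                assert reported.at[sp, "enriched_group"] == up_group
                hits += 1
        assert hits >= len(small_cohort.truth.differential) // 2

    def test_null_pass_rate_bounded(self):
        """Without a planted effect the full cascade reports few taxa."""
        passed = total = 0
        for seed in range(8):
            cfg = sd.SimulationConfig(
                n_all=15, n_nc=10, n_species=40, n_differential=0, seed=100 + seed
            )
            cohort = sd.simulate_cohort(cfg)
            m = aq.quantify_cohort(cohort.spot_tables, cohort.manifest)
            res = df.run_lefse(m, cohort.metadata.groups, seed=0)
            passed += len(res)
            total += len(m.taxa)
        rate = passed / total
        alpha = 0.05
        mc_sd = np.sqrt(alpha * (1 - alpha) / total)
        assert rate <= alpha + 2 * mc_sd

    def test_empty_screen_gives_empty_table(self):
        m = _matrix(np.tile([0.25, 0.25, 0.5], (8, 1)))
        res = df.run_lefse(m, _groups(m, 4), seed=0)
        assert res.empty


class TestCladogram:
    def test_lineage_propagation(self, small_cohort, small_matrix):
        groups = small_cohort.metadata.groups
        table = df.build_cladogram_table(small_matrix, groups, small_cohort.manifest, seed=0)
        species_rows = table[table["rank"] == "species"]
        if not species_rows.empty:
            assert {"genus", "family", "order"} <= set(table.columns)
            assert species_rows["genus"].notna().all()
        assert set(table["rank"].unique()) <= {"species", "genus", "family", "order"}

    def test_no_signal_gives_empty_table(self):
        m = _matrix(np.tile([0.25, 0.25, 0.5], (8, 1)))
        manifest_df = pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(3)],
                "species": ["sp0", "sp1", "sp2"],
                "genus": ["g0", "g0", "g1"],
                "family": ["f0"] * 3,
                "order": ["o0"] * 3,
            }
        ).set_index("probe_id")
        from chipbiome.containers import ArrayManifest

        table = df.build_cladogram_table(
            m, _groups(m, 4), ArrayManifest(manifest_df), seed=0
        )
        assert table.empty
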