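import numpy as np
import pytest

from connectogene import (
    RegionalMap,
    SyntheticSpec,
    gene_similarity,
    generate_annotations,
    generate_cohort,
    generate_embeddings,
    generate_expression,
    generate_interactome,
    generate_modular_network,
)


class TestModularNetwork:
    def test_block_diagonal_when_between_zero(self):
        spec = SyntheticSpec(n_nodes=40, n_modules=2, p_between=0.0, seed=3)
        W = generate_modular_network(spec).r
        member = spec.membership()
        cross = member[:, None] != member[None, :]
        assert W[cross].sum() == 0
        assert W[~cross].sum() > 0

    def test_deterministic_given_seed(self):
        spec = SyntheticSpec(n_nodes=40, seed=5)
        assert np.array_equal(generate_modular_network(spec).r, generate_modular_network(spec).r)

    def test_edge_densities_near_binomial_expectation(self):
        spec = SyntheticSpec(n_nodes=120, n_modules=4, seed=7)
        W = generate_modular_network(spec).r
        member = spec.membership()
        same = member[:, None] == member[None, :]
        iu = np.triu_indices(120, 1)
        within = (W[iu] > 0)[same[iu]]
        between = (W[iu] > 0)[~same[iu]]
        for obs, p in ((within, spec.p_within), (between, spec.p_between)):
            n = obs.size
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(obs.mean() - p) < 3 * sd

    def test_matrix_contract(self):
        W = generate_modular_network(SyntheticSpec(n_nodes=30, seed=1)).r
        assert np.allclose(W, W.T)
        assert W.min() >= 0
        assert np.all(np.diag(W) == 0)


class TestCohort:
    def test_null_effect_centers_wd_dt_correlation_on_zero(self):
        from connectogene import cohort_wd
        spec = SyntheticSpec(n_subjects=30, n_nodes=60, n_timepoints=100,
                             effect_size=0.0, seed=21)
        series, pheno, _, effect = generate_cohort(spec)
        wd = cohort_wd(series, pheno["subject_id"], q=0.05)
        dt = pheno["dt_score"].to_numpy()
        cors = [np.corrcoef(wd.iloc[:, j], dt)[0, 1] for j in effect
                if wd.iloc[:, j].std() > 0]
        assert abs(np.nanmean(cors)) < 0.15

    def test_negative_effect_drives_negative_wd_dt_correlation(self):
        from connectogene import cohort_wd
        neg = 0
        for seed in range(10):
            spec = SyntheticSpec(n_subjects=30, n_nodes=60, n_timepoints=100,
                                 effect_size=-0.5, seed=100 + seed)
            series, pheno, _, effect = generate_cohort(spec)
            wd = cohort_wd(series, pheno["subject_id"], q=0.05)
            dt = pheno["dt_score"].to_numpy()
            cors = [np.corrcoef(wd.iloc[:, j], dt)[0, 1] for j in effect
                    if wd.iloc[:, j].std() > 0]
            neg += np.nanmean(cors) < 0
        assert neg >= 9

    def test_phenotype_deterministic(self):
        spec = SyntheticSpec(n_subjects=15, n_nodes=40, seed=9)
        _, p1, _, _ = generate_cohort(spec)
        _, p2, _, _ = generate_cohort(spec)
        assert p1.equals(p2)


class TestExpression:
    def regional(self, rng, n=68):
        return RegionalMap(rng.standard_normal(n), [f"R{i}" for i in range(n)])

    def test_noise_free_planted_scores_exactly_minus_one(self, rng):
        spec = SyntheticSpec(n_genes=200, n_planted=10, expr_noise_sd=0.0, seed=2)
        reg = self.regional(rng)
        expr, planted = generate_expression(spec, reg)
        res = gene_similarity(expr, reg)
        assert np.allclose(res.scores[planted], -1.0)

    def test_background_scores_center_on_zero(self, rng):
        spec = SyntheticSpec(n_genes=1000, n_planted=0, seed=4)
        reg = self.regional(rng)
        expr, _ = generate_expression(spec, reg)
        res = gene_similarity(expr, reg)
        assert abs(res.scores.mean()) < 0.1

    def test_deterministic(self, rng):
        spec = SyntheticSpec(n_genes=100, n_planted=5, seed=8)
        reg = self.regional(rng)
        e1, p1 = generate_expression(spec, reg)
        e2, p2 = generate_expression(spec, reg)
        assert e1.equals(e2) and p1 == p2


class TestAnnotationsAndInteractome:
    def test_planted_term_composition_and_roundtrip(self, tmp_path, small_spec):
        planted = [f"p{i}" for i in range(20)]
        background = [f"b{i}" for i in range(200)]
        ann = generate_annotations(planted, background, small_spec)
        name, genes = ann.terms["TERM_PLANTED"]
        assert len(genes & set(planted)) == 16  # 80% of 20
        from connectogene import read_gmt, write_gmt
        path = tmp_path / "ann.gmt"
        write_gmt(ann, path)
        back = read_gmt(path)
        assert back.terms["TERM_PLANTED"][1] == genes

    def test_interactome_core_denser_than_periphery(self, small_spec):
        planted = [f"p{i}" for i in range(20)]
        background = [f"b{i}" for i in range(150)]
        G = generate_interactome(planted, background, small_spec)
        core = [(u, v) for u, v in G.edges() if u in set(planted) and v in set(planted)]
        peri = [(u, v) for u, v in G.edges() if u in set(background) and v in set(background)]
        core_density = len(core) / (20 * 19 / 2)
        peri_density = len(peri) / (150 * 149 / 2)
        assert core_density > 10 * peri_density

    def test_planted_mean_closeness_rank_above_median(self, small_spec):
        from connectogene import closeness
        planted = [f"p{i}" for i in range(20)]
        background = [f"b{i}" for i in range(150)]
        G = generate_interactome(planted, background, small_spec)
        res = closeness(G)
        ranks = res["closeness"].rank()
        assert ranks.loc[planted].mean() > ranks.median()


class TestEmbeddings:
    def test_same_word_across_spaces_close_to_base(self, small_spec):
        spaces, _, _ = generate_embeddings(small_spec, vocab_size=50, dim=50)
        w = "w0007"
        vs = [sp[w] for sp in spaces]
        for i in range(1, 5):
            cos = vs[0] @ vs[i] / (np.linalg.norm(vs[0]) * np.linalg.norm(vs[i]))
            assert cos >= 0.7

    def test_high_novelty_subjects_get_higher_distance(self, small_spec):
        from connectogene import aggregate_subject, score_responses
        spaces, responses, novelty = generate_embeddings(small_spec, vocab_size=50)
        recs = score_responses(responses, spaces)
        mat = aggregate_subject(recs)
        mean_d = mat.mean(axis=1).loc[novelty.index]
        assert np.corrcoef(mean_d, novelty)[0, 1] > 0.8

    def test_deterministic(self, small_spec):
        _, r1, n1 = generate_embeddings(small_spec, vocab_size=30)
        _, r2, n2 = generate_embeddings(small_spec, vocab_size=30)
        assert r1.equals(r2) and n1.equals(n2)
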