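"""Synthetic-data generator: determinism, expression model, fragments."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dtubench.annotation import Annotation
from dtubench.simulate import (
    CHROM,
    SimParams,
    apply_dtu_swap,
    build_expression_model,
    dispersion_from_mean,
    effective_length,
    generate_annotation,
    project_to_genome,
    read_fragments_bed12,
    read_truth,
    select_dtu_genes,
    simulate_fragments,
    simulate_sample_expression,
    true_abundance_table,
    write_fragments_bed12,
    write_truth,
)
from conftest import make_transcript


def _ann_fingerprint(ann: Annotation):
    return [
        (g.gene_id, [(t.transcript_id, t.exon_tuple()) for t in g.transcripts])
        for g in ann.genes
    ]


class TestGenerateAnnotation:
    def test_deterministic_given_seed(self):
        p = SimParams(n_genes=50, n_dtu=0, seed=1)
        a = generate_annotation(p)
        b = generate_annotation(p)
        assert _ann_fingerprint(a) == _ann_fingerprint(b)

    def test_regimes_differ_in_isoform_count_and_exon_length(self):
        iso = {"fruitfly_like": [], "human_like": []}
        exlen = {"fruitfly_like": [], "human_like": []}
        for regime in iso:
            for seed in range(20):
                ann = generate_annotation(
                    SimParams(n_genes=20, n_dtu=0, regime=regime, seed=seed)
                )
                iso[regime].append(
                    np.mean([len(g.transcripts) for g in ann.genes])
                )
                exlen[regime].append(
                    np.mean([
                        len(e)
                        for g in ann.genes
                        for t in g.transcripts
                        for e in t.exons
                    ])
                )
        assert np.mean(iso["human_like"]) > np.mean(iso["fruitfly_like"])
        assert np.mean(exlen["fruitfly_like"]) > np.mean(exlen["human_like"])

    def test_no_duplicate_isoform_structures_within_gene(self):
        for seed in range(5):
            ann = generate_annotation(
                SimParams(n_genes=30, n_dtu=0, regime="human_like", seed=seed)
            )
            for g in ann.genes:
                structs = [t.exon_tuple() for t in g.transcripts]
                assert len(structs) == len(set(structs))

    def test_overlap_rate_produces_aggregatable_genes(self):
        from dtubench.annotation import flatten

        ann = generate_annotation(
            SimParams(n_genes=60, n_dtu=0, gene_overlap_rate=0.4, seed=2)
        )
        bs = flatten(ann, "aggregate")
        complexes = [f for f in bs.complex_map if "+" in f]
        assert complexes


class TestSeedContract:
    def test_simulation_requires_a_seed(self):
        with pytest.raises(ValueError, match="seed"):
            generate_annotation(SimParams(n_genes=5, n_dtu=0))

    def test_model_json_round_trip(self, small_experiment):
        from dtubench.simulate import ExpressionModel

        back = ExpressionModel.from_json(small_experiment.model.to_json())
        assert back.gene_ids == small_experiment.model.gene_ids
        assert np.array_equal(back.mu, small_experiment.model.mu)
        gid = back.gene_ids[0]
        assert np.array_equal(back.pi2[gid], small_experiment.model.pi2[gid])


class TestDispersionAndLengths:
    def test_dispersion_formula(self):
        assert dispersion_from_mean(300.0, (0.01, 3.0)) == pytest.approx(0.02)
        assert dispersion_from_mean(50.0, (0.04, 0.0)) == pytest.approx(0.04)
        mus = [10, 100, 1000]
        phis = [dispersion_from_mean(m, (0.01, 3.0)) for m in mus]
        assert phis == sorted(phis, reverse=True)
        with pytest.raises(ValueError):
            dispersion_from_mean(0.0)

    def test_effective_length(self):
        assert effective_length(1000, 250.0) == 751.0
        assert effective_length(100, 250.0) == 1.0
        assert effective_length(500, 1.0) == 500.0


class TestExpressionModel:
    @pytest.fixture(scope="class")
    @staticmethod
    def model_setup():
        p = SimParams(n_genes=120, n_dtu=20, library_size=100_000, seed=3)
        ann = generate_annotation(p)
        model = build_expression_model(ann, p)
        return p, ann, model

    def test_mu_sums_to_nonbackground_library(self, model_setup):
        p, _, model = model_setup
        target = p.library_size * (1 - p.background_fraction)
        assert model.mu.sum() == pytest.approx(target, rel=1e-3)

    def test_fractions_sum_to_one_and_sorted(self, model_setup):
        _, _, model = model_setup
        for gid in model.gene_ids:
            pi = model.pi1[gid]
            assert pi.sum() == pytest.approx(1.0)
            assert (np.diff(pi) <= 1e-12).all()

    def test_deterministic(self, model_setup):
        p, ann, model = model_setup
        again = build_expression_model(ann, p)
        assert np.array_equal(model.mu, again.mu)
        assert np.array_equal(model.phi, again.phi)


class TestDtuSelectionAndSwap:
    def _tiny_model(self, pis, mus):
        from dtubench.simulate import ExpressionModel

        gene_ids = [f"g{i}" for i in range(len(pis))]
        return ExpressionModel(
            gene_ids=gene_ids,
            mu=np.array(mus, dtype=float),
            phi=np.full(len(pis), 0.05),
            gene_eff_len=np.full(len(pis), 1000.0),
            isoforms={g: [f"{g}.t{j}" for j in range(len(pi))]
                      for g, pi in zip(gene_ids, pis)},
            pi1={g: np.array(pi) for g, pi in zip(gene_ids, pis)},
            pi2={g: np.array(pi) for g, pi in zip(gene_ids, pis)},
            tx_len={f"{g}.t{j}": 1000 for g, pi in zip(gene_ids, pis)
                    for j in range(len(pi))},
            tx_eff_len={f"{g}.t{j}": 751.0 for g, pi in zip(gene_ids, pis)
                        for j in range(len(pi))},
        )

    def test_eligibility_rules(self):
        model = self._tiny_model(
            [(0.6, 0.3, 0.1), (0.95, 0.05), (0.6, 0.4)],
            [600.0, 10_000.0, 499.0],
        )
        p = SimParams(n_genes=3, n_dtu=1, seed=1)
        truth = select_dtu_genes(model, p)
        # only g0 is eligible: g1 has one expressed isoform, g2 mu <= 500
        assert truth.loc[truth.dtu_status, "gene_id"].tolist() == ["g0"]

    def test_too_few_eligible_reports_count(self):
        model = self._tiny_model([(0.95, 0.05)], [1000.0])
        with pytest.raises(ValueError, match="0 genes eligible"):
            select_dtu_genes(model, SimParams(n_genes=1, n_dtu=1, seed=1))

    def test_swap_exchanges_top_two_only(self):
        model = self._tiny_model([(0.7, 0.2, 0.1), (0.5, 0.5)], [600.0, 600.0])
        p = SimParams(n_genes=2, n_dtu=1, seed=0)
        truth = select_dtu_genes(model, p)
        swapped = apply_dtu_swap(model, truth)
        dtu_gene = truth.loc[truth.dtu_status, "gene_id"].iloc[0]
        other = [g for g in model.gene_ids if g != dtu_gene][0]
        if dtu_gene == "g0":
            assert np.allclose(swapped.pi2["g0"], [0.2, 0.7, 0.1])
        else:
            assert np.allclose(swapped.pi2["g1"], [0.5, 0.5])
        assert np.allclose(swapped.pi2[other], model.pi1[other])

    def test_dominance_diff_recorded_for_all_genes(self):
        model = self._tiny_model([(0.7, 0.2, 0.1), (0.5, 0.5)], [600.0, 600.0])
        truth = select_dtu_genes(model, SimParams(n_genes=2, n_dtu=1, seed=0))
        assert truth["dominance_diff"].tolist() == pytest.approx([0.5, 0.0])


class TestSampleExpression:
    def test_nb_moments(self):
        from dtubench.simulate import _nb_draw

        rng = np.random.default_rng(0)
        mu, phi = 100.0, 0.1
        draws = _nb_draw(rng, np.full(2000, mu), np.full(2000, phi))
        assert np.mean(draws) == pytest.approx(mu, rel=0.05)
        assert np.var(draws) == pytest.approx(mu + phi * mu**2, rel=0.15)

    def test_tpm_sums_to_million_and_dirichlet_params(self):
        p = SimParams(n_genes=30, n_dtu=5, library_size=50_000, seed=5)
        ann = generate_annotation(p)
        model = build_expression_model(ann, p)
        expr = simulate_sample_expression(model, 1, "s01", p)
        assert expr.table["tpm"].sum() == pytest.approx(1e6, rel=1e-6)
        for gid in model.gene_ids[:10]:
            sub = expr.table[expr.table.gene_id == gid]
            assert sub["frac"].sum() == pytest.approx(1.0)

    def test_zero_fraction_isoforms_stay_zero(self):
        from dtubench.simulate import ExpressionModel

        model = ExpressionModel(
            gene_ids=["g0"],
            mu=np.array([500.0]),
            phi=np.array([0.05]),
            gene_eff_len=np.array([800.0]),
            isoforms={"g0": ["g0.t0", "g0.t1", "g0.t2"]},
            pi1={"g0": np.array([0.7, 0.3, 0.0])},
            pi2={"g0": np.array([0.7, 0.3, 0.0])},
            tx_len={"g0.t0": 1000, "g0.t1": 1000, "g0.t2": 1000},
            tx_eff_len={"g0.t0": 751.0, "g0.t1": 751.0, "g0.t2": 751.0},
        )
        p = SimParams(n_genes=1, n_dtu=0, seed=1)
        expr = simulate_sample_expression(model, 1, "s01", p)
        assert expr.table.loc[expr.table.transcript_id == "g0.t2", "frac"].iloc[0] == 0.0

    def test_dirichlet_concentrates_at_large_scale(self):
        rng = np.random.default_rng(1)
        pi = np.array([0.5, 0.3, 0.2])
        draws = rng.dirichlet(1e6 * pi, size=200)
        assert np.max(np.abs(draws - pi)) < 0.01

    def test_no_gene_level_differential_expression(self):
        # mean total count equal across conditions over replicate pairs
        p = SimParams(n_genes=25, n_dtu=5, library_size=20_000, seed=6)
        ann = generate_annotation(p)
        model = build_expression_model(ann, p)
        truth = select_dtu_genes(model, p)
        model = apply_dtu_swap(model, truth)
        diffs = []
        for k in range(50):
            e1 = simulate_sample_expression(model, 1, f"a{k:03d}", p)
            e2 = simulate_sample_expression(model, 2, f"b{k:03d}", p)
            diffs.append(e1.gene_counts.sum() - e2.gene_counts.sum())
        diffs = np.array(diffs, dtype=float)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * se + 1e-9


class TestFragments:
    def test_projection_single_exon(self):
        tx = make_transcript("t", "g", [(0, 1000)])
        m1 = project_to_genome(tx, 0, 101)
        m2 = project_to_genome(tx, 149, 250)
        assert [(b.start, b.end) for b in m1] == [(0, 101)]
        assert [(b.start, b.end) for b in m2] == [(149, 250)]

    def test_projection_across_junction(self):
        tx = make_transcript("t", "g", [(0, 100), (200, 300)])
        blocks = project_to_genome(tx, 50, 151)
        assert [(b.start, b.end) for b in blocks] == [(50, 100), (200, 251)]

    def test_background_fraction(self, small_experiment):
        frags = [f for f in small_experiment.fragments if f.sample_id == "s01"]
        n_bg = sum(f.origin == "background" for f in frags)
        p = small_experiment.params
        assert n_bg == round(p.background_fraction * p.library_size)

    def test_fragment_starts_uniform_on_single_exon_transcript(self):
        # distribution of fragment starts along a lone single-exon transcript
        from dtubench.simulate import ExpressionModel

        model = ExpressionModel(
            gene_ids=["g0"],
            mu=np.array([10_000.0]),
            phi=np.array([1e-13]),
            gene_eff_len=np.array([9751.0]),
            isoforms={"g0": ["g0.t0"]},
            pi1={"g0": np.array([1.0])},
            pi2={"g0": np.array([1.0])},
            tx_len={"g0.t0": 10_000},
            tx_eff_len={"g0.t0": 9751.0},
        )
        from dtubench.annotation import Gene

        tx = make_transcript("g0.t0", "g0", [(0, 10_000)], chrom=CHROM)
        ann = Annotation([Gene("g0", [tx])])
        p = SimParams(n_genes=1, n_dtu=0, library_size=10_000,
                      background_fraction=0.0, fragment_length_sd=0.0, seed=8)
        expr = simulate_sample_expression(model, 1, "s01", p)
        frags = simulate_fragments(ann, expr, p)
        starts = np.array([f.mate1_blocks[0].start for f in frags])
        span = 10_000 - 250  # fixed fragment length => valid starts
        ks = stats.kstest(starts / span, "uniform")
        assert ks.pvalue > 0.01

    def test_bed12_round_trip(self, tmp_path, small_experiment):
        frags = [f for f in small_experiment.fragments[:500]]
        path = tmp_path / "frags.bed"
        write_fragments_bed12(frags, path)
        back = read_fragments_bed12(path)
        assert len(back) == len(frags)
        a = {f.fragment_id: f for f in frags}
        for f in back:
            orig = a[f.fragment_id]
            assert f.origin == orig.origin
            assert [(b.start, b.end) for b in f.mate1_blocks] == [
                (b.start, b.end) for b in orig.mate1_blocks
            ]
            assert [(b.start, b.end) for b in f.mate2_blocks] == [
                (b.start, b.end) for b in orig.mate2_blocks
            ]


class TestTruthIO:
    def test_round_trip_and_extra_column(self, tmp_path, small_experiment):
        truth = small_experiment.truth.copy()
        truth["note"] = "x"
        path = tmp_path / "truth.tsv"
        write_truth(truth, path)
        back = read_truth(path)
        assert back["note"].eq("x").all()
        pd.testing.assert_frame_equal(
            back.drop(columns="note"), small_experiment.truth,
            check_dtype=False,
        )

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"gene_id": ["g1"]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="missing columns"):
            read_truth(path)

    def test_abundance_table_matches_model(self, small_experiment):
        tab = true_abundance_table(small_experiment.model)
        gid = small_experiment.model.gene_ids[0]
        sub = tab[tab.gene_id == gid]
        assert sub["cond1"].to_numpy() == pytest.approx(
            small_experiment.model.pi1[gid]
        )
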