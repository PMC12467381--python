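import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from offtarget.model import InteractionModel, ModelConfig
from offtarget.screening import (
    LatentEmbedding,
    ProjectedPoint,
    aggregate_by_organ,
    compare_to_controls,
    extract_entity_embeddings,
    interaction_distance,
    manifold_project_2d,
    rank_targets,
    sample_control_proteins,
)


def _embeddings(vectors, kind="ae_target", prefix="e"):
    return [LatentEmbedding(f"{prefix}{i}", kind, v) for i, v in enumerate(vectors)]


class TestExtractEmbeddings:
    def test_zero_weight_model_gives_zero_vectors(self):
        m = InteractionModel(ModelConfig(d_protein=4, d_compound=6, p=8, seed=0))
        for k, v in m.params.items():
            if k.startswith(("t.", "c.")):
                m.params[k] = np.zeros_like(v)
        out = extract_entity_embeddings(
            m, {"c1": np.ones(6)}, {"p1": np.ones(4)},
            protein_kinds={"p1": "control_protein"},
        )
        assert all(np.array_equal(e.vector, np.zeros(8)) for e in out)
        assert {e.entity_kind for e in out} == {"compound", "control_protein"}

    def test_deterministic(self):
        m = InteractionModel(ModelConfig(d_protein=4, d_compound=6, p=8, seed=1))
        a = extract_entity_embeddings(m, {"c": np.ones(6)}, {"p": np.ones(4)})
        b = extract_entity_embeddings(m, {"c": np.ones(6)}, {"p": np.ones(4)})
        for x, y in zip(a, b):
            assert np.array_equal(x.vector, y.vector)


class TestManifoldProjection:
    def test_seeded_determinism(self, rng):
        emb = _embeddings(rng.normal(size=(80, 10)))
        a = manifold_project_2d(emb, seed=3)
        b = manifold_project_2d(emb, seed=3)
        assert [(p.x, p.y) for p in a] == [(q.x, q.y) for q in b]

    def test_two_separated_clusters_recovered(self, rng):
        """2-D projection keeps well-separated Gaussian clusters apart."""
        X = np.vstack([
            rng.normal(0.0, 0.1, size=(100, 8)),
            rng.normal(0.0, 0.1, size=(100, 8)) + 100.0,
        ])
        labels = np.array([0] * 100 + [1] * 100)
        pts = manifold_project_2d(_embeddings(X), seed=0)
        Y = np.array([[p.x, p.y] for p in pts])
        c0, c1 = Y[labels == 0].mean(axis=0), Y[labels == 1].mean(axis=0)
        assigned = (np.linalg.norm(Y - c1, axis=1) < np.linalg.norm(Y - c0, axis=1))
        agreement = max((assigned == labels).mean(), (assigned != labels).mean())
        assert agreement >= 0.95

    def test_single_point_errors(self):
        with pytest.raises(ValueError):
            manifold_project_2d(_embeddings(np.ones((1, 3))), seed=0)

    def test_small_input_principal_axes_fallback(self, rng):
        emb = _embeddings(rng.normal(size=(5, 4)))
        pts = manifold_project_2d(emb, seed=9)
        assert len(pts) == 5
        assert all(np.isfinite([p.x, p.y]).all() for p in pts)


class TestInteractionDistance:
    def test_closed_forms(self):
        a = ProjectedPoint("a", 0.0, 0.0, 1)
        b = ProjectedPoint("b", 3.0, 4.0, 1)
        assert interaction_distance(a, a) == 0.0
        assert interaction_distance(a, b) == 5.0

    def test_mismatched_runs_rejected(self):
        a = ProjectedPoint("a", 0, 0, 1)
        b = ProjectedPoint("b", 1, 1, 2)
        with pytest.raises(ValueError, match="projection runs"):
            interaction_distance(a, b)

    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                    min_size=3, max_size=3))
    def test_metric_axioms_on_triples(self, coords):
        pts = [ProjectedPoint(f"p{i}", x, y, 0) for i, (x, y) in enumerate(coords)]
        d01 = interaction_distance(pts[0], pts[1])
        d10 = interaction_distance(pts[1], pts[0])
        d02 = interaction_distance(pts[0], pts[2])
        d12 = interaction_distance(pts[1], pts[2])
        assert d01 == d10 >= 0
        assert d02 <= d01 + d12 + 1e-9


class TestRankTargets:
    def test_single_target_rank_one(self):
        c = ProjectedPoint("c", 0, 0, 0)
        out = rank_targets(c, [ProjectedPoint("t", 1, 0, 0)])
        assert out[0].rank == 1

    def test_tie_break_is_lexicographic(self):
        c = ProjectedPoint("c", 0, 0, 0)
        tA = ProjectedPoint("tA", 1, 0, 0)
        tB = ProjectedPoint("tB", 0, 1, 0)
        out = rank_targets(c, [tB, tA])
        assert [(s.target_id, s.rank) for s in out] == [("tA", 1), ("tB", 2)]

    def test_matches_full_sort_oracle(self, rng):
        c = ProjectedPoint("c", 0, 0, 0)
        targets = [ProjectedPoint(f"t{i:03d}", *rng.normal(size=2), 0)
                   for i in range(100)]
        out = rank_targets(c, targets)
        oracle = sorted(targets, key=lambda t: (np.hypot(t.x, t.y), t.entity_id))
        assert [s.target_id for s in out] == [t.entity_id for t in oracle]
        assert sorted(s.rank for s in out) == list(range(1, 101))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            rank_targets(ProjectedPoint("c", 0, 0, 0), [])


class TestControlSampling:
    def test_exact_remainder(self):
        ids = [f"P{i}" for i in range(10)]
        out = sample_control_proteins(ids, exclude=ids[3:], n=3, seed=0)
        assert sorted(out) == ["P0", "P1", "P2"]

    def test_isoform_suffix_excluded_with_base(self):
        out = sample_control_proteins(
            ["P00742-2", "P11111", "P22222"], exclude={"P00742"}, n=2, seed=1
        )
        assert "P00742-2" not in out

    def test_seeded_reproducibility(self):
        ids = [f"Q{i:03d}" for i in range(50)]
        assert sample_control_proteins(ids, set(), 10, seed=5) == \
            sample_control_proteins(ids, set(), 10, seed=5)

    def test_shortfall(self):
        with pytest.raises(ValueError):
            sample_control_proteins(["P1"], {"P1"}, 1, seed=0)


class TestCompareToControls:
    def test_no_effect_gives_large_p(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        _, p = compare_to_controls("c", vals, list(vals))
        assert p >= 0.49

    def test_extreme_separation(self, rng):
        ae = 1.0 + rng.normal(0, 1e-3, size=50)
        ctl = 10.0 + rng.normal(0, 1e-3, size=50)
        _, p = compare_to_controls("c", ae, ctl)
        assert p < 1e-10

    def test_matches_textbook_welch_formula(self, rng):
        """Statistic and p agree with the hand-computed Welch formula."""
        for _ in range(20):
            a = rng.normal(0, 1, size=13)
            b = rng.normal(0.3, 2, size=29)
            t_got, p_got = compare_to_controls("c", a, b)
            va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
            t_exp = (a.mean() - b.mean()) / np.sqrt(va + vb)
            dof = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
            p_exp = stats.t.cdf(t_exp, dof)
            assert t_got == pytest.approx(t_exp, abs=1e-6)
            assert p_got == pytest.approx(p_exp, abs=1e-6)

    def test_degenerate_equal_constants(self):
        assert compare_to_controls("c", [2.0, 2.0], [2.0, 2.0]) == (0.0, 0.5)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            compare_to_controls("c", [1.0], [1.0, 2.0])


class TestOrganAggregate:
    def _embeddings(self, rng, n_targets=3):
        emb = [LatentEmbedding("drug", "compound", rng.normal(size=6))]
        emb += [LatentEmbedding(f"t{i}", "ae_target", rng.normal(size=6))
                for i in range(n_targets)]
        return emb

    def test_multi_organ_target_duplicated_with_same_stats(self, rng):
        emb = self._embeddings(rng)
        out = aggregate_by_organ(
            emb, {"t0": ["Lung", "Heart"], "t1": ["Kidney"], "t2": ["Skin"]},
            n_repetitions=3, master_seed=0,
        )
        t0 = [a for a in out if a.target_id == "t0"]
        assert {a.organ_group for a in t0} == {"Lung", "Heart"}
        assert t0[0].mean_distance == t0[1].mean_distance
        assert t0[0].se_distance == t0[1].se_distance

    def test_unmapped_target_warns(self, rng):
        emb = self._embeddings(rng, n_targets=2)
        with pytest.warns(UserWarning, match="unmapped"):
            out = aggregate_by_organ(emb, {"t0": ["Lung"]}, 2, 0)
        assert any(a.organ_group == "unmapped" for a in out)

    def test_mean_se_match_spreadsheet_recomputation(self, rng):
        """Aggregate equals direct arithmetic over per-repetition tables."""
        from offtarget.screening import interaction_distance, manifold_project_2d

        # large enough for the stochastic neighbour-graph path, so the
        # repetition seeds genuinely vary the coordinates
        emb = self._embeddings(rng, n_targets=40)
        organ_map = {f"t{i}": [f"O{i}"] for i in range(40)}
        reps = []
        for r in range(3):
            pts = {p.entity_id: p for p in manifold_project_2d(emb, seed=10 + r)}
            reps.append(interaction_distance(pts["drug"], pts["t1"]))
        out = aggregate_by_organ(emb, organ_map, n_repetitions=3, master_seed=10)
        t1 = next(a for a in out if a.target_id == "t1")
        arr = np.asarray(reps)
        assert arr.std() > 0
        assert t1.mean_distance == pytest.approx(arr.mean())
        assert t1.se_distance == pytest.approx(arr.std(ddof=1) / np.sqrt(3))

    def test_deterministic_projection_gives_zero_se(self, rng):
        # small inputs use the seed-independent principal-axes fallback, so
        # every repetition yields identical coordinates
        emb = self._embeddings(rng)
        out = aggregate_by_organ(emb, {"t0": ["A"], "t1": ["B"], "t2": ["C"]},
                                 n_repetitions=3, master_seed=0)
        assert all(a.se_distance == 0.0 for a in out)

    def test_single_repetition_rejected(self, rng):
        with pytest.raises(ValueError):
            aggregate_by_organ(self._embeddings(rng), {}, n_repetitions=1)
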