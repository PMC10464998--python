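import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protacable.aa_tables import CANONICAL_AA
from protacable.embedding import Embedder
from protacable.eshap import (DEFAULT_OPPOSITE, FeatureSelection,
                              MutationScheme, difference_score, eshap_scan,
                              key_positions, motif_enrichment,
                              opposite_mutation, select_top_features)
from protacable.seq_io import ProteinRecord
from protacable.synthetic import SimulationConfig, make_synthetic_embedder


def selection_of(indices):
    return FeatureSelection(np.array(indices),
                            np.zeros(len(indices)))


class TestMutationScheme:
    def test_default_charge_flips(self):
        assert opposite_mutation("K") == "E"   # positive -> negative
        assert opposite_mutation("D") == "K"   # negative -> positive

    def test_mapping_never_identity_and_total(self):
        scheme = MutationScheme()
        assert set(scheme.mapping) == set(CANONICAL_AA)
        for a in CANONICAL_AA:
            assert scheme.mapping[a] != a

    def test_rejects_identity_or_partial(self):
        bad = dict(DEFAULT_OPPOSITE)
        bad["K"] = "K"
        with pytest.raises(ValueError, match="itself"):
            MutationScheme(bad)
        with pytest.raises(ValueError, match="missing"):
            MutationScheme({"K": "E"})

    def test_non_canonical_residue(self):
        with pytest.raises(ValueError):
            opposite_mutation("X")

    def test_tsv_roundtrip(self, tmp_path):
        p = tmp_path / "scheme.tsv"
        MutationScheme().to_tsv(p)
        assert MutationScheme.from_tsv(p).mapping == DEFAULT_OPPOSITE


class TestSelectTopFeatures:
    def test_full_selection_sorted(self):
        imp = np.array([0.1, 0.5, 0.3])
        sel = select_top_features(imp, k=3)
        assert sel.indices.tolist() == [1, 2, 0]
        assert np.all(np.diff(sel.importance) <= 0)

    def test_dominant_column_first(self, rng):
        phi = rng.normal(scale=0.01, size=(30, 8))
        phi[:, 5] += 3.0
        assert select_top_features(phi, k=2).indices[0] == 5

    def test_ties_broken_by_lower_index(self):
        imp = np.array([0.2, 0.5, 0.5, 0.1])
        assert select_top_features(imp, k=2).indices.tolist() == [1, 2]

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            select_top_features(np.ones(5), k=0)
        with pytest.raises(ValueError):
            select_top_features(np.ones(5), k=6)


class TestDifferenceScore:
    def test_identity_is_zero(self):
        v = np.arange(10.0)
        assert difference_score(v, v, selection_of([0, 3, 7])) == 0.0

    def test_single_feature_delta(self):
        a = np.zeros(10)
        b = np.zeros(10)
        b[4] = 3.0
        assert difference_score(a, b, selection_of([4])) == 3.0
        # delta outside the selection is invisible
        assert difference_score(a, b, selection_of([0, 1])) == 0.0

    def test_three_four_five(self):
        a = np.zeros(10)
        b = np.zeros(10)
        b[2], b[6] = 3.0, 4.0
        assert difference_score(a, b, selection_of([2, 6])) == 5.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            difference_score(np.zeros(3), np.zeros(4), selection_of([0]))

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rng.normal(size=(3, 12))
        sel = selection_of(sorted(rng.choice(12, size=5, replace=False)))
        assert difference_score(a, b, sel) == pytest.approx(
            difference_score(b, a, sel))
        assert difference_score(a, c, sel) <= (
            difference_score(a, b, sel) + difference_score(b, c, sel) + 1e-9)


class _DeadZoneEmbedder(Embedder):
    """Sensitive to the first `live` residues only; positions beyond are dead."""

    name = "deadzone"

    def __init__(self, live=5, dimension=8):
        self.live = live
        self.dimension = dimension

    def embed(self, sequence):
        prefix = sequence[:self.live]
        v = np.zeros(self.dimension)
        for i, a in enumerate(prefix):
            v[i % self.dimension] += CANONICAL_AA.index(a) + 1
        return v


class TestEshapScan:
    def test_one_row_per_residue_and_determinism(self):
        cfg = SimulationConfig(embed_dim=16, signal_dims=(1, 2), seed=1)
        emb = make_synthetic_embedder(cfg)
        rec = ProteinRecord("p", "MKVACDEFGHIKLMNPQRSTVWY")
        sel = selection_of(list(range(8)))
        t1 = eshap_scan(rec, emb, sel)
        t2 = eshap_scan(rec, emb, sel)
        assert len(t1) == len(rec.sequence)
        assert t1.table["position"].tolist() == list(range(1, len(rec) + 1))
        np.testing.assert_array_equal(t1.table["score"], t2.table["score"])
        assert (t1.table["score"] >= 0).all()

    def test_dead_zone_positions_score_zero(self):
        emb = _DeadZoneEmbedder(live=5)
        rec = ProteinRecord("p", "MKVACDEFGH")
        table = eshap_scan(rec, emb, selection_of(list(range(8))))
        scores = table.table["score"].to_numpy()
        assert np.all(scores[5:] == 0.0)
        assert np.all(scores[:5] > 0.0)

    def test_motif_positions_score_higher_than_background(self):
        cfg = SimulationConfig(embed_dim=32, signal_dims=(1, 2, 3, 4), seed=0)
        emb = make_synthetic_embedder(cfg)
        rng = np.random.default_rng(0)
        background = "".join(rng.choice(list(CANONICAL_AA), size=80))
        seq = background[:40] + cfg.motif + background[40:]
        rec = ProteinRecord("p", seq)
        sel = selection_of([0, 1, 2, 3])  # the signal coordinates
        table = eshap_scan(rec, emb, sel)
        scores = table.table["score"].to_numpy()
        motif_pos = np.arange(40, 48)
        inside = scores[motif_pos].mean()
        outside = np.delete(scores, motif_pos).mean()
        assert inside > outside

    def test_records_wild_type_prediction_when_model_given(self):
        class _Const:
            def predict_proba(self, X):
                return np.full(len(X), 0.7)

        emb = _DeadZoneEmbedder()
        rec = ProteinRecord("p", "MKVACD")
        table = eshap_scan(rec, emb, selection_of([0]), model=_Const())
        assert table.wild_type_score == pytest.approx(0.7)


class TestKeyPositions:
    def _table(self, scores):
        import pandas as pd
        from protacable.eshap import PositionScoreTable
        df = pd.DataFrame({
            "position": range(1, len(scores) + 1),
            "wt": ["A"] * len(scores),
            "mut": ["S"] * len(scores),
            "score": scores,
        })
        return PositionScoreTable("p", df, selection_of([0]))

    def test_ceiling_count(self):
        t = self._table(list(np.linspace(1, 0, 100)))
        assert len(key_positions(t, top_fraction=0.05)) == 5
        assert len(key_positions(t, top_fraction=0.051)) == 6

    def test_full_fraction_returns_all_sorted(self):
        t = self._table([0.2, 0.9, 0.5])
        assert key_positions(t, top_fraction=1.0) == [2, 3, 1]

    def test_absolute_count_selector(self):
        t = self._table([0.2, 0.9, 0.5, 0.7])
        assert key_positions(t, k=2) == [2, 4]

    def test_ties_prefer_smaller_position(self):
        t = self._table([0.5, 0.9, 0.5])
        assert key_positions(t, k=2) == [2, 1]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            key_positions(self._table([]))


def test_motif_enrichment_hand_example():
    import pandas as pd
    from protacable.eshap import PositionScoreTable
    scores = np.zeros(50)
    scores[[10, 11, 12]] = [3.0, 2.0, 1.0]  # motif positions dominate
    df = pd.DataFrame({"position": range(1, 51), "wt": "A", "mut": "S",
                       "score": scores})
    t = PositionScoreTable("p", df, selection_of([0]))
    # top 10% -> 5 key positions; motif = 11..13 all hit
    # expected uniform = 5 * 3 / 50 = 0.3 -> ratio 10
    ratio = motif_enrichment([t], {"p": [(11, 13)]}, top_fraction=0.1)
    assert ratio == pytest.approx(3 / 0.3)
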