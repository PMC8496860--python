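"""Bimodal-range boundaries, delta metrics, matrix assembly, embedding."""
import numpy as np
import pandas as pd
import pytest

from galvar import (
    BimodalBoundaries,
    SolverConfig,
    bimodal_boundaries,
    build_matrix,
    classify_rows,
    delta_full,
    delta_level,
    delta_on,
    embed_matrix,
    make_variant,
)
from galvar.survey import (
    INSENSITIVE,
    MORE_INDUCIBLE,
    MORE_REPRESSED,
    PerturbationMatrix,
)

LADDER = tuple(sorted(4.0 * 2.0 ** -k for k in range(11)))


def _bounds(gal_on, gal_full, always_off=False, always_bimodal=False,
            level=1.0, glucose=0.125):
    return BimodalBoundaries(
        glucose=glucose, gal_on=gal_on, gal_full=gal_full,
        always_off=always_off, always_bimodal=always_bimodal,
        level_full=level, ladder=LADDER,
    )


class TestDeltaMetrics:
    def test_delta_on_fourfold_up(self):
        v, deg = delta_on(_bounds(0.0625, 0.5), _bounds(0.25, 2.0))
        assert v == pytest.approx(2.0) and not deg

    def test_delta_on_twofold_down(self):
        v, deg = delta_on(_bounds(0.125, 0.5), _bounds(0.0625, 0.25))
        assert v == pytest.approx(-1.0) and not deg

    def test_delta_on_identity(self):
        b = _bounds(0.125, 0.5)
        v, deg = delta_on(b, b)
        assert v == 0.0 and not deg

    def test_delta_on_degeneration_caps_and_flags(self):
        v, deg = delta_on(_bounds(0.0625, 0.5),
                          _bounds(None, None, always_off=True))
        assert v == pytest.approx(np.log2(2 * LADDER[-1] / 0.0625))
        assert deg

    def test_delta_on_requires_reference(self):
        with pytest.raises(ValueError):
            delta_on(_bounds(None, None, always_off=True), _bounds(0.125, 0.5))

    def test_delta_full_fourfold_up(self):
        v, deg = delta_full(_bounds(0.0625, 0.0625), _bounds(0.25, 0.25))
        assert v == pytest.approx(2.0) and not deg

    def test_delta_full_identity_and_degeneration(self):
        b = _bounds(0.0625, 0.25)
        assert delta_full(b, b) == (0.0, False)
        v, deg = delta_full(b, _bounds(None, None, always_off=True))
        assert deg and v == pytest.approx(np.log2(2 * LADDER[-1] / 0.25))

    def test_delta_full_always_bimodal_reference_convention(self):
        ref = _bounds(0.0625, None, always_bimodal=True)
        pert = _bounds(0.0625, 2.0)
        v, deg = delta_full(ref, pert)
        assert v == pytest.approx(np.log2(2.0 / (2 * LADDER[-1])))
        assert not deg

    def test_delta_on_antisymmetry(self):
        a, b = _bounds(0.125, 1.0), _bounds(0.5, 2.0)
        va, _ = delta_on(a, b)
        vb, _ = delta_on(b, a)
        assert va == pytest.approx(-vb)

    def test_delta_level_arithmetic(self):
        assert delta_level(0.8, 0.8) == 0.0
        assert delta_level(0.4, 0.8) == pytest.approx(1.0)
        assert delta_level(0.4, 0.0) == pytest.approx(-1.0)
        with pytest.raises(ValueError):
            delta_level(0.0, 0.4)


class TestBoundaries:
    def test_reference_row_has_both_boundaries(self, ref_params):
        b = bimodal_boundaries(ref_params, 0.125)
        assert b.gal_on is not None and b.gal_full is not None
        assert b.gal_on <= b.gal_full
        assert not b.always_off and not b.always_bimodal
        assert b.level_full > 0

    def test_strong_repression_is_always_off(self, ref_params):
        ref = bimodal_boundaries(ref_params, 0.125)
        pert = make_variant(ref_params, {"ag80": 100.0})
        b = bimodal_boundaries(pert, 0.125, half_max=0.5 * ref.row_max)
        assert b.always_off
        assert b.gal_on is None and b.gal_full is None

    def test_boundaries_agree_with_fine_ladder(self, ref_params):
        """4x finer titration brackets the twofold-ladder boundaries."""
        coarse = bimodal_boundaries(ref_params, 0.0625)
        fine_ladder = tuple(
            sorted(4.0 * 2.0 ** (-k / 4.0) for k in range(41))
        )
        fine = bimodal_boundaries(ref_params, 0.0625, fine_ladder)
        # fine boundary within one coarse ladder step of the coarse one
        assert coarse.gal_on / 2 <= fine.gal_on <= coarse.gal_on
        assert coarse.gal_full / 2 <= fine.gal_full <= coarse.gal_full

    def test_rejects_unsorted_ladder(self, ref_params):
        with pytest.raises(ValueError):
            bimodal_boundaries(ref_params, 0.125, (0.5, 0.25))


@pytest.fixture(scope="module")
def mini_matrix(ref_params):
    """Two parameters x two factors over two glucose levels."""
    return build_matrix(
        ref_params,
        free_names=("kf83", "KR1"),
        factors=(0.1, 10.0),
        glucose_levels=(0.125, 0.03125),
    )


class TestBuildMatrix:
    def test_identity_factor_rows_are_zero(self, ref_params):
        m = build_matrix(
            ref_params, free_names=("kf83", "a2"), factors=(1.0,),
            glucose_levels=(0.125, 0.03125),
        )
        vals = m.values.to_numpy(float)
        assert np.nanmax(np.abs(vals)) == 0.0
        assert not m.degenerate.to_numpy().any()

    def test_shape_and_columns(self, mini_matrix):
        assert mini_matrix.shape == (4, 6)   # 2 params x 2 factors, 3 x 2 cols
        assert all(
            c.split("[")[0] in ("delta_on", "delta_full", "delta_level")
            for c in mini_matrix.values.columns
        )

    def test_ladder_deltas_are_integers(self, mini_matrix):
        on_full = [
            c for c in mini_matrix.values.columns
            if c.startswith(("delta_on", "delta_full"))
        ]
        vals = mini_matrix.values[on_full].to_numpy(float)
        finite = vals[~np.isnan(vals)]
        np.testing.assert_allclose(finite, np.round(finite), atol=1e-9)

    def test_increasing_ag80_represses(self, ref_params):
        m = build_matrix(
            ref_params, free_names=("ag80",), factors=(100.0,),
            glucose_levels=(0.125, 0.03125),
        )
        row = m.values.loc[("ag80", 100.0)]
        deg = m.degenerate.loc[("ag80", 100.0)]
        on_cols = [c for c in m.values.columns if c.startswith("delta_on")]
        assert all(
            (row[c] > 0) or deg[c] for c in on_cols if not np.isnan(row[c])
        )


class TestClassifyRows:
    def _matrix_from(self, rows: dict) -> PerturbationMatrix:
        glucs = (0.5, 0.125)
        cols = (
            [f"delta_on[{g:g}]" for g in glucs]
            + [f"delta_full[{g:g}]" for g in glucs]
            + [f"delta_level[{g:g}]" for g in glucs]
        )
        idx = pd.MultiIndex.from_tuples(rows.keys(),
                                        names=["parameter", "factor"])
        values = pd.DataFrame(
            [rows[k][0] for k in rows], index=idx, columns=cols, dtype=float
        )
        degen = pd.DataFrame(
            [rows[k][1] for k in rows], index=idx, columns=cols
        )
        missing = values.isna()
        return PerturbationMatrix(values, degen, missing, glucs)

    def test_rule_based_labels(self):
        z = [0.0] * 6
        rows = {
            ("p_zero", 1.0): (z, [False] * 6),
            ("p_ind", 0.1): ([-3, -4, -1, -1, 0.5, 0.5], [False] * 6),
            ("p_rep", 10.0): ([3, 4, 1, 1, -0.5, -0.5], [False] * 6),
            ("p_deg", 100.0): ([6, 0, 6, 0, -1, 0], [True] + [False] * 5),
            ("p_other", 10.0): ([2, 2, 2, 2, 0, 0], [False] * 6),
        }
        m = self._matrix_from(rows)
        labels = classify_rows(m)
        assert labels[("p_zero", 1.0)] == INSENSITIVE
        assert labels[("p_ind", 0.1)] == MORE_INDUCIBLE
        assert labels[("p_rep", 10.0)] == MORE_REPRESSED
        assert labels[("p_deg", 100.0)] == MORE_REPRESSED
        assert labels[("p_other", 10.0)] == "other"


class TestEmbedding:
    def _block_matrix(self):
        rng = np.random.default_rng(0)
        glucs = (0.5, 0.125)
        cols = (
            [f"delta_on[{g:g}]" for g in glucs]
            + [f"delta_full[{g:g}]" for g in glucs]
            + [f"delta_level[{g:g}]" for g in glucs]
        )
        a = rng.normal(0, 0.3, size=(15, 6))
        b = rng.normal(8, 0.3, size=(15, 6))
        X = np.vstack([a, b])
        idx = pd.MultiIndex.from_tuples(
            [(f"p{i}", 2.0) for i in range(30)], names=["parameter", "factor"]
        )
        values = pd.DataFrame(X, index=idx, columns=cols)
        return PerturbationMatrix(
            values, values.astype(bool) & False, values.isna(), glucs
        )

    def test_deterministic_under_seed(self):
        m = self._block_matrix()
        c1 = embed_matrix(m, seed=4)
        c2 = embed_matrix(m, seed=4)
        pd.testing.assert_frame_equal(c1, c2)

    def test_identical_rows_land_together(self):
        m = self._block_matrix()
        m.values.iloc[1] = m.values.iloc[0]
        coords = embed_matrix(m, seed=4)
        d01 = np.hypot(
            coords.x[0] - coords.x[1], coords.y[0] - coords.y[1]
        )
        span = np.hypot(
            coords.x.max() - coords.x.min(), coords.y.max() - coords.y.min()
        )
        assert d01 < 0.05 * span

    def test_separated_blocks_stay_separated(self):
        from sklearn.metrics import silhouette_score

        m = self._block_matrix()
        coords = embed_matrix(m, seed=4)
        labels = [0] * 15 + [1] * 15
        assert silhouette_score(coords[["x", "y"]], labels) > 0.5

    def test_constant_matrix_rejected(self):
        m = self._block_matrix()
        m.values.iloc[:, :] = 1.0
        with pytest.raises(ValueError):
            embed_matrix(m, seed=0)


class TestQualitativeLabels:
    """Directional effects of the key mechanisms on the full survey.

    Weakening the Gal3* production or Gal80-sequestration machinery, the
    sugar supply, or the transporters represses the pathway; the Gal2p
    node and the Gal80p/Gal4p balance can move the bimodal range in both
    directions.  (The inducible direction of the binding rates shifts the
    onset by less than the 8-fold label threshold for this reference set,
    so those rows classify as insensitive rather than inducible.)
    """

    @pytest.fixture(autouse=True)
    def _labels(self, full_matrix):
        from galvar import classify_rows

        labels = classify_rows(full_matrix).reset_index()
        labels.columns = ["parameter", "factor", "label"]
        self.by_param = {
            p: set(g.label) for p, g in labels.groupby("parameter")
        }

    @pytest.mark.parametrize(
        "name", ["kf83", "kr83", "kf3", "kr3", "dsugar", "kG2", "rcat"]
    )
    def test_core_movers_can_repress(self, name):
        assert MORE_REPRESSED in self.by_param[name]

    @pytest.mark.parametrize("name", ["kG2", "ag2", "rG2", "a80"])
    def test_bidirectional_movers(self, name):
        assert MORE_INDUCIBLE in self.by_param[name]
        assert MORE_REPRESSED in self.by_param[name]

    def test_some_parameters_are_insensitive(self, full_matrix):
        from galvar import classify_rows

        labels = classify_rows(full_matrix)
        assert (labels == INSENSITIVE).sum() > 0
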