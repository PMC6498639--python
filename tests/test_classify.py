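import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as stn

from ssdfate.classify import (
    RetentionModel,
    classify_retention,
    combine_profiles,
    compute_divergence_cutoff,
    cutoff_from_distances,
)
from ssdfate.family import DuplicateTrio
from ssdfate.io import ExpressionMatrix, ExpressionProfile


def _prof(values, gene="g", log_scale=True):
    return ExpressionProfile(
        gene=gene,
        tissues=tuple("t%d" % i for i in range(len(values))),
        values=np.asarray(values, float),
        log_scale=log_scale,
    )


class TestCutoff:
    def test_quantile_maximum_and_median(self):
        assert cutoff_from_distances([1, 2, 3], q=1.0).e_div == 3.0
        assert cutoff_from_distances([1, 2, 3], q=0.5).e_div == 2.0

    def test_identical_profiles_warn_zero_cutoff(self):
        pairs = [(_prof([1, 2, 0]), _prof([1, 2, 0]))] * 40
        with pytest.warns(UserWarning, match="E_div is 0"):
            model = compute_divergence_cutoff(pairs)
        assert model.e_div == 0.0

    def test_few_pairs_warn(self):
        pairs = [(_prof([1, 0]), _prof([0, 1]))] * 5
        with pytest.warns(UserWarning, match="ortholog pairs"):
            compute_divergence_cutoff(pairs)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_divergence_cutoff([])

    def test_fixed_method_and_json_round_trip(self):
        from ssdfate.classify import CutoffModel

        model = cutoff_from_distances([1.0, 2.0], method="fixed", e_div=1.7)
        assert model.e_div == 1.7
        back = CutoffModel.from_json(model.to_json())
        assert back.e_div == model.e_div and back.method == "fixed"


class TestCombineProfiles:
    def test_silent_child_leaves_parent_profile(self):
        parent = _prof([3.0, 1.0, 0.0], "p")
        child = _prof([0.0, 0.0, 0.0], "c")
        comb = combine_profiles(parent, child)
        assert np.allclose(comb.values, parent.values)

    def test_raw_scale_addition(self):
        # TPM 1 + TPM 2 -> log2(4) = 2
        parent = _prof([1.0], "p")  # log2(1+1) -> TPM 1
        child = _prof([np.log2(3.0)], "c")  # TPM 2
        assert combine_profiles(parent, child).values[0] == pytest.approx(2.0)

    def test_symmetric(self):
        p, c = _prof([1.0, 2.0], "p"), _prof([0.5, 3.0], "c")
        assert np.allclose(combine_profiles(p, c).values, combine_profiles(c, p).values)

    def test_requires_log_scale_and_matching_tissues(self):
        with pytest.raises(ValueError):
            combine_profiles(_prof([1.0], log_scale=False), _prof([1.0]))


class TestRuleTable:
    @pytest.mark.parametrize(
        "e_pa,e_ca,e_pca,expected,diverged",
        [
            (0.5, 0.4, 9.0, "conservation", None),
            (0.5, 1.5, 9.0, "neofunctionalization", "child"),
            (1.5, 0.5, 9.0, "neofunctionalization", "parent"),
            (1.5, 1.5, 0.5, "subfunctionalization", None),
            (1.5, 1.5, 1.5, "specialization", None),
            (1.0, 1.0, 1.0, "conservation", None),  # <= is not diverged
        ],
    )
    def test_reference_rules(self, e_pa, e_ca, e_pca, expected, diverged):
        mech, div = classify_retention(e_pa, e_ca, e_pca, 1.0)
        assert mech == expected and div == diverged

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            classify_retention(-0.1, 1.0, 1.0, 1.0)

    def test_exhaustive_and_mutually_exclusive(self):
        # every non-negative quadruple gets exactly one label
        rng = np.random.default_rng(0)
        quads = rng.exponential(1.0, size=(100_000, 4))
        labels = {
            "conservation": 0,
            "neofunctionalization": 0,
            "subfunctionalization": 0,
            "specialization": 0,
        }
        for e_pa, e_ca, e_pca, e_div in quads:
            mech, div = classify_retention(e_pa, e_ca, e_pca, e_div)
            labels[mech] += 1
            assert (div is not None) == (mech == "neofunctionalization")
        assert sum(labels.values()) == len(quads)
        assert all(v > 0 for v in labels.values())

    @given(
        stn.floats(0, 10),
        stn.floats(0, 10),
        stn.floats(0, 10),
        stn.floats(0, 10),
        stn.floats(0.01, 10),
    )
    def test_raising_cutoff_never_leaves_conservation(self, e_pa, e_ca, e_pca, e_div, bump):
        mech1, _ = classify_retention(e_pa, e_ca, e_pca, e_div)
        mech2, _ = classify_retention(e_pa, e_ca, e_pca, e_div + bump)
        if mech1 == "conservation":
            assert mech2 == "conservation"


class TestSubfunctionalizationIdentifiability:
    def test_complementary_partition_construction(self):
        # the ancestral raw profile is split across the copies: each copy
        # alone is far from the ancestor, but the combined profile matches
        anc_tpm = np.array([40.0, 30.0, 20.0, 10.0])
        mask = np.array([True, False, True, False])
        anc = _prof(np.log2(anc_tpm + 1), "a")
        parent = _prof(np.log2(anc_tpm * mask + 1), "p")
        child = _prof(np.log2(anc_tpm * ~mask + 1), "c")
        from ssdfate.expression import euclidean_distance

        e_div = 1.0
        e_pa = euclidean_distance(parent, anc)
        e_ca = euclidean_distance(child, anc)
        e_pca = euclidean_distance(combine_profiles(parent, child), anc)
        assert e_pa > e_div and e_ca > e_div
        assert e_pca == pytest.approx(0.0, abs=1e-12)
        assert classify_retention(e_pa, e_ca, e_pca, e_div)[0] == "subfunctionalization"


def _tiny_model():
    tissues = ["t1", "t2", "t3"]
    focal = pd.DataFrame(
        {
            "p1": [40.0, 0.0, 0.0],
            "c1": [40.0, 0.0, 0.0],
            "p2": [0.4, 0.3, 0.2],  # lowly expressed pair
            "c2": [0.4, 0.3, 0.2],
            "o1": [10.0, 5.0, 1.0],
            "o2": [4.0, 2.0, 8.0],
        },
        index=tissues,
    ).T
    sister = pd.DataFrame(
        {
            "a1": [40.0, 0.0, 0.0],
            "a2": [0.4, 0.3, 0.2],
            "s1": [10.0, 5.0, 1.0],
            "s2": [4.0, 2.0, 8.0],
        },
        index=tissues,
    ).T
    trios = [
        DuplicateTrio("T1", "f1", "b", "F", "S", "p1", "c1", "a1", parent="p1", child="c1"),
        DuplicateTrio("T2", "f2", "b", "F", "S", "p2", "c2", "a2", parent="p2", child="c2"),
        DuplicateTrio("T3", "f3", "b", "F", "S", "p1", "c1", "a1"),  # unresolved polarity
    ]
    return (
        RetentionModel(
            trios,
            ExpressionMatrix(focal, "F"),
            ExpressionMatrix(sister, "S"),
            [("o1", "s1"), ("o2", "s2")],
        ),
        trios,
    )


class TestRetentionModel:
    def test_exclusions_and_call(self):
        model, trios = _tiny_model()
        with pytest.warns(UserWarning):  # few ortholog pairs
            res = model.fit(q=1.0)
        reasons = {e.trio_id: e.reason for e in res.excluded}
        assert reasons["T2"] == "lowly expressed"
        assert reasons["T3"] == "unresolved polarity"
        assert len(res.calls) == 1
        assert res.calls[0].mechanism == "conservation"
        assert "conservation" in res.summary()

    def test_rejects_pretransformed_matrices(self, raw_matrix):
        from ssdfate.expression import log_transform

        t = log_transform(raw_matrix)
        with pytest.raises(ValueError):
            RetentionModel([], t, t, [])

    def test_counts_and_frame_layout(self):
        model, _ = _tiny_model()
        with pytest.warns(UserWarning):
            res = model.fit(q=1.0)
        counts = res.counts()
        assert counts.sum() == 1
        frame = res.calls_frame()
        assert {"E_PA", "E_CA", "E_PCA", "mechanism"} <= set(frame.columns)
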