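"""Mutual-information scoring (estimator vs brute-force oracle), threshold
selection, and Pearson redundancy analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cysurv.datatypes import SelectionError
from cysurv.selection import (
    MutualInfoSelector,
    _bin_feature,
    estimate_mutual_information,
    pearson_matrix,
    select_by_mi,
)
from cysurv.simulate import SimConfig, generate_cohort
from cysurv.radiomics import extract_cohort_features


def brute_force_mi(x, y, n_bins=None):
    """Independent oracle: direct sum p*log(p/(p_f*p_c)) over the binned joint."""
    b = _bin_feature(np.asarray(x, float), n_bins)
    y = np.asarray(y).astype(int)
    mi = 0.0
    for bv in np.unique(b):
        for cv in np.unique(y):
            p = np.mean((b == bv) & (y == cv))
            if p > 0:
                mi += p * np.log(p / (np.mean(b == bv) * np.mean(y == cv)))
    return mi


class TestMIEstimator:
    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(25):
            n = int(rng.integers(16, 300))
            x = rng.normal(size=n)
            y = (rng.random(n) < 0.5).astype(int)
            if y.min() == y.max():
                continue
            assert estimate_mutual_information(x, y) == pytest.approx(
                brute_force_mi(x, y), abs=1e-12
            )

    def test_matches_brute_force_on_printed_joint_table(self):
        """A small discrete joint distribution written out explicitly.

        Feature values {0,1,2} and classes {0,1} with joint counts
        rows=value, cols=class: [[10, 2], [4, 8], [6, 6]]; with 3 bins the
        binned joint equals the table itself, so the plug-in MI must equal
        the direct evaluation over that table.
        """
        counts = np.array([[10, 2], [4, 8], [6, 6]])
        x, y = [], []
        for v in range(3):
            for c in range(2):
                x += [float(v)] * counts[v, c]
                y += [c] * counts[v, c]
        x, y = np.array(x), np.array(y)
        est = estimate_mutual_information(x, y, n_bins=3)
        n = counts.sum()
        joint = counts / n
        pf = joint.sum(axis=1, keepdims=True)
        pc = joint.sum(axis=0, keepdims=True)
        direct = float(np.nansum(joint * np.log(joint / (pf * pc))))
        assert est == pytest.approx(direct, abs=1e-12)
        assert est == pytest.approx(brute_force_mi(x, y, n_bins=3), abs=1e-12)

    def test_feature_equal_to_label_reaches_class_entropy(self):
        y = np.tile([0, 1], 500)
        assert estimate_mutual_information(y.astype(float), y) == pytest.approx(
            np.log(2), abs=1e-9
        )

    def test_independent_feature_scores_near_zero(self, rng):
        # Null bound at n=1000, k=10: plug-in bias ~(k-1)/(2n) plus noise.
        vals = [
            estimate_mutual_information(rng.normal(size=1000),
                                        rng.integers(0, 2, 1000))
            for _ in range(30)
        ]
        assert max(vals) <= 0.02

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_strictly_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=120)
        y = rng.integers(0, 2, 120)
        if y.min() == y.max():
            return
        base = estimate_mutual_information(x, y)
        for f in (np.exp, lambda v: v**3, lambda v: 1.0 / (1 + np.exp(-v))):
            assert estimate_mutual_information(f(x), y) == base

    def test_preconditions(self, rng):
        with pytest.raises(SelectionError):
            estimate_mutual_information(rng.normal(size=4), [0, 1, 0, 1][:4])
        with pytest.raises(SelectionError):
            estimate_mutual_information(rng.normal(size=20), np.zeros(20))


@pytest.fixture(scope="module")
def matrix():
    rng = np.random.default_rng(5)
    y = rng.integers(0, 2, 120)
    df = pd.DataFrame(rng.normal(size=(120, 15)),
                      columns=[f"f{i:02d}" for i in range(15)])
    df["f00"] = y * 3.0 + rng.normal(scale=0.2, size=120)
    df["f14"] = np.nan  # a missing column
    return df, y


class TestSelection:
    def test_threshold_zero_selects_all_non_missing(self, matrix):
        df, y = matrix
        res = select_by_mi(df, y, threshold=0.0)
        assert set(res.selected_names) == set(df.columns) - {"f14"}
        assert res.excluded_missing == ["f14"]

    def test_threshold_above_max_selects_nothing(self, matrix):
        df, y = matrix
        with pytest.warns(UserWarning, match="empty"):
            res = select_by_mi(df, y, threshold=10.0)
        assert res.selected_names == []

    def test_default_rank_cut_keeps_k_features_ordered_by_score(self, matrix):
        df, y = matrix
        res = select_by_mi(df, y, k_features=12)
        assert len(res.selected_names) == 12
        assert res.selected_names[0] == "f00"
        scores = [res.mi_score[n] for n in res.selected_names]
        assert scores == sorted(scores, reverse=True)

    def test_selector_transform_keeps_selected_columns(self, matrix):
        df, y = matrix
        sel = MutualInfoSelector(k_features=5).fit(df, y)
        out = sel.transform(df)
        assert list(out.columns) == sel.selected_names_
        assert out.shape == (120, 5)

    def test_planted_shrinkage_selects_difference_morphology(self):
        """With a strong shrinkage effect, a diff.* morphology feature should
        reach the default selection in a majority of replicate cohorts."""
        hits = 0
        seeds = range(200, 210)
        morpho = ("area", "perimeter", "equivalent_diameter", "major_axis",
                  "minor_axis", "feret_diameter_max")
        for seed in seeds:
            cfg = SimConfig(n_patients=24, seed=seed, shrinkage_effect=0.5,
                            texture_effect=0.0, clinical_effect=0.0)
            pairs, masks, records, truth = generate_cohort(cfg)
            feats = extract_cohort_features(pairs, masks)
            y = truth.set_index("patient_id").loc[feats.index, "survivor"]
            if y.nunique() < 2:
                continue
            res = select_by_mi(feats, y)
            if any(n.startswith("diff.") and n.split(".", 1)[1] in morpho
                   for n in res.selected_names):
                hits += 1
        assert hits > len(seeds) / 2


class TestPearson:
    def test_diagonal_and_antisymmetry(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"x": x, "neg": -x, "z": rng.normal(size=50)})
        res = pearson_matrix(df)
        assert np.allclose(np.diag(res.matrix), 1.0)
        assert res.matrix.loc["x", "neg"] == pytest.approx(-1.0)
        assert res.matrix.equals(res.matrix.T)

    def test_independent_columns_weakly_correlated(self, rng):
        df = pd.DataFrame(rng.normal(size=(500, 2)), columns=["a", "b"])
        res = pearson_matrix(df)
        assert abs(res.matrix.loc["a", "b"]) < 0.15

    def test_constant_column_flagged_and_zeroed(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=20), "c": np.ones(20)})
        res = pearson_matrix(df)
        assert res.constant_features == ["c"]
        assert res.matrix.loc["a", "c"] == 0.0
        assert res.matrix.loc["c", "c"] == 1.0

    def test_weakly_redundant_selection_concentrates_within_0_3(self, rng):
        """On features built independent, most off-diagonal |r| stay < 0.3."""
        df = pd.DataFrame(rng.normal(size=(100, 12)),
                          columns=[f"g{i}" for i in range(12)])
        res = pearson_matrix(df)
        off = res.matrix.to_numpy()[~np.eye(12, dtype=bool)]
        assert (np.abs(off) < 0.3).mean() > 0.9
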