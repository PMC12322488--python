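"""Species-pair matrices, DTW alignment and the permutation matrix test."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from titplayback import (
    SpeciesMatrix,
    aggression_matrix,
    dtw_distance,
    mass_difference_matrix,
    permutation_matrix_test,
    simulate_song_exemplars,
    song_similarity_matrix,
)

from oracles import brute_force_dtw


def random_sequence(rng, n, k=3):
    return rng.normal(size=(n, k))


# ---------------------------------------------------------------- DTW

def test_dtw_self_distance_zero():
    rng = np.random.default_rng(0)
    a = random_sequence(rng, 6)
    assert dtw_distance(a, a) == 0.0


@pytest.mark.parametrize("seed", range(8))
def test_dtw_matches_exhaustive_path_enumeration(seed):
    rng = np.random.default_rng(seed)
    a = random_sequence(rng, int(rng.integers(1, 6)))
    b = random_sequence(rng, int(rng.integers(1, 6)))
    assert dtw_distance(a, b) == pytest.approx(brute_force_dtw(a, b), abs=1e-12)
    assert dtw_distance(a, b) == pytest.approx(dtw_distance(b, a), abs=1e-12)


def test_dtw_tolerates_syllable_duplication():
    rng = np.random.default_rng(3)
    a = random_sequence(rng, 4)
    b = np.vstack([a[:2], a[1:2], a[2:]])  # duplicate the second syllable
    assert dtw_distance(a, b) == pytest.approx(0.0, abs=1e-12)


def test_dtw_input_validation():
    rng = np.random.default_rng(1)
    a = random_sequence(rng, 3)
    with pytest.raises(ValueError, match="empty"):
        dtw_distance(a, np.empty((0, 3)))
    with pytest.raises(ValueError, match="dimensions"):
        dtw_distance(a, random_sequence(rng, 3, k=4))


# ------------------------------------------------ aggression matrix

def index_frame(cells):
    rows = []
    for i, (focal, pb, vals) in enumerate(cells):
        for v in np.atleast_1d(vals):
            rows.append(
                {"trial_id": f"t{len(rows)}", "species": focal,
                 "playback_species": pb, "aggression_index": float(v)}
            )
    return pd.DataFrame(rows)


def test_aggression_matrix_single_trial_cells():
    labels = ("a", "b")
    cells = [("a", "a", 0.1), ("a", "b", -0.4), ("b", "a", 0.7), ("b", "b", 0.2)]
    m = aggression_matrix(index_frame(cells), labels=labels)
    np.testing.assert_allclose(m.values, [[0.1, -0.4], [0.7, 0.2]])


def test_aggression_matrix_averages_trials():
    cells = [("a", "a", [1.0, 3.0]), ("a", "b", 0.0), ("b", "a", 0.0), ("b", "b", 0.0)]
    m = aggression_matrix(index_frame(cells), labels=("a", "b"))
    assert m.values[0, 0] == 2.0


def test_aggression_matrix_missing_pair_listed():
    cells = [("a", "a", 0.1), ("b", "b", 0.2), ("b", "a", 0.0)]
    with pytest.raises(ValueError, match=r"\('a', 'b'\)"):
        aggression_matrix(index_frame(cells), labels=("a", "b"))


def test_paper_scale_aggression_matrix(paper_experiment):
    m = aggression_matrix(paper_experiment["index"])
    assert m.values.shape == (5, 5)
    counts = paper_experiment["index"].groupby(
        ["species", "playback_species"]
    ).size()
    offdiag = [v for (f, p), v in counts.items() if f != p]
    assert min(offdiag) >= 8


# ------------------------------------------------------- song matrix

def test_song_similarity_matrix_symmetric_with_identical_species():
    table = simulate_song_exemplars(n_exemplars=2, syllables_per_exemplar=5, seed=2)
    # clone one species' exemplars into a fake sixth species
    clone = table[table["species"] == "great tit"].copy()
    clone["species"] = "copy tit"
    clone["exemplar_id"] = clone["exemplar_id"].str.replace("great", "copy")
    songs = pd.concat([table, clone], ignore_index=True)
    m = song_similarity_matrix(songs)
    assert np.allclose(m.values, m.values.T, atol=1e-12)
    labels = list(m.labels)
    i, j = labels.index("great tit"), labels.index("copy tit")
    offdiag = m.values[~np.eye(len(labels), dtype=bool)]
    assert m.values[i, j] == pytest.approx(offdiag.max())


def test_mass_matrix_symmetric_absolute():
    m = mass_difference_matrix()
    assert np.allclose(m.values, m.values.T)
    assert (np.diag(m.values) == 0).all()
    s = mass_difference_matrix(signed=True)
    assert np.allclose(s.values, -s.values.T)


# ------------------------------------------------- permutation test

def random_matrices(seed, k=5):
    rng = np.random.default_rng(seed)
    labels = tuple(f"sp{i}" for i in range(k))
    resp = SpeciesMatrix(labels, rng.normal(size=(k, k)), "aggression_mean")
    sym = rng.normal(size=(k, k))
    sym = (sym + sym.T) / 2
    np.fill_diagonal(sym, 0.0)
    pred = SpeciesMatrix(labels, np.abs(sym), "mass_difference")
    return resp, pred


def test_identity_predictor_r_one_minimal_p():
    resp, _ = random_matrices(0)
    res = permutation_matrix_test(resp, resp, n_perm=999)
    assert res["r"] == pytest.approx(1.0)
    assert res["exact"]
    assert res["n_perm"] == math.factorial(5) - 1
    assert res["p_value"] == pytest.approx(1.0 / math.factorial(5))


def test_identical_relabeling_leaves_r_unchanged():
    resp, pred = random_matrices(1)
    base = permutation_matrix_test(resp, pred, seed=0)
    perm = [2, 0, 4, 1, 3]
    labels = tuple(resp.labels[i] for i in perm)
    resp2 = SpeciesMatrix(labels, resp.values[np.ix_(perm, perm)], "aggression_mean")
    pred2 = SpeciesMatrix(labels, pred.values[np.ix_(perm, perm)], "mass_difference")
    moved = permutation_matrix_test(resp2, pred2, seed=0)
    assert moved["r"] == pytest.approx(base["r"], abs=1e-12)
    assert moved["p_value"] == pytest.approx(base["p_value"])


def test_spearman_mode_invariant_under_monotone_transform():
    resp, pred = random_matrices(2)
    a = permutation_matrix_test(resp, pred, method="spearman")
    pred2 = SpeciesMatrix(pred.labels, np.exp(pred.values), "mass_difference")
    b = permutation_matrix_test(resp, pred2, method="spearman")
    assert a["r"] == pytest.approx(b["r"], abs=1e-12)
    assert a["p_value"] == pytest.approx(b["p_value"])


def test_constant_matrix_rejected():
    resp, pred = random_matrices(3)
    flat = SpeciesMatrix(pred.labels, np.ones((5, 5)), "mass_difference")
    with pytest.raises(ValueError, match="constant"):
        permutation_matrix_test(resp, flat)


def test_label_mismatch_rejected():
    resp, pred = random_matrices(4)
    other = SpeciesMatrix(tuple("vwxyz"), pred.values, "mass_difference")
    with pytest.raises(ValueError, match="labels"):
        permutation_matrix_test(resp, other)


def test_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        SpeciesMatrix(("a", "b"), np.array([[0, 1.0], [2.0, 0]]), "mass_difference")
    with pytest.raises(ValueError, match="unique"):
        SpeciesMatrix(("a", "a"), np.zeros((2, 2)), "aggression_mean")
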