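"""Species-pair matrices and Mantel-style permutation tests.

Three 5x5 matrices over the guild are compared:

* the directed mean-aggression matrix — cell (i, j) is the mean aggression
  index of focal species i responding to playback of species j;
* the body-mass difference matrix — |m_i - m_j| (or signed m_i - m_j);
* the song-similarity matrix — negative mean dynamic-time-warping distance
  between syllable feature sequences of the two species' exemplars.

Association between the aggression matrix and a predictor matrix is tested
by correlating off-diagonal cells and building the null distribution from
joint row/column permutations of the predictor's species labels.  With K
species the permutation group has K! elements, so for small guilds the test
enumerates all non-identity permutations exactly; otherwise it samples
``n_perm`` random permutations and uses the add-one estimator.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import derive_seed
from .species import SONG_FEATURES, SpeciesSpec, default_species_table

MATRIX_KINDS = ("aggression_mean", "mass_difference", "song_similarity")


@dataclass
class SpeciesMatrix:
    """A labelled species-pair grid.

    ``aggression_mean`` is directed (rows = focal, columns = playback) and
    its diagonal (conspecific cells) is excluded from matrix tests;
    ``mass_difference`` and ``song_similarity`` are symmetric.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in MATRIX_KINDS:
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if len(set(self.labels)) != k:
            raise ValueError("matrix labels must be unique")
        if self.values.shape != (k, k):
            raise ValueError(
                f"values shape {self.values.shape} does not match {k} labels"
            )
        if self.kind != "aggression_mean" and not np.allclose(
            self.values, self.values.T, atol=1e-9
        ):
            raise ValueError(f"{self.kind} matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, kind: str) -> "SpeciesMatrix":
        return cls(tuple(df.index), df.to_numpy(dtype=float), kind)


def aggression_matrix(index_table: pd.DataFrame,
                      labels: tuple[str, ...] | None = None) -> SpeciesMatrix:
    """Directed focal x playback mean aggression-index matrix."""
    if labels is None:
        labels = tuple(sorted(set(index_table["species"]) | set(index_table["playback_species"])))
    means = index_table.groupby(["species", "playback_species"])["aggression_index"].mean()
    k = len(labels)
    vals = np.full((k, k), np.nan)
    missing = []
    for i, fi in enumerate(labels):
        for j, pj in enumerate(labels):
            if (fi, pj) in means.index:
                vals[i, j] = means[(fi, pj)]
            else:
                missing.append((fi, pj))
    if missing:
        raise ValueError(f"no trials for focal x playback pairs: {missing}")
    return SpeciesMatrix(labels, vals, "aggression_mean")


def mass_difference_matrix(
    species_table: list[SpeciesSpec] | None = None, signed: bool = False
) -> SpeciesMatrix:
    """Pairwise body-mass difference matrix (|m_i - m_j| by default)."""
    table = default_species_table() if species_table is None else species_table
    labels = tuple(sp.species_id for sp in table)
    m = np.array([sp.body_mass for sp in table])
    diff = m[:, None] - m[None, :]
    if not signed:
        diff = np.abs(diff)
    kind = "mass_difference"
    if signed:
        # a signed matrix is antisymmetric; wrap it without the symmetry check
        mat = SpeciesMatrix.__new__(SpeciesMatrix)
        mat.labels, mat.values, mat.kind = labels, diff, kind
        return mat
    return SpeciesMatrix(labels, diff, kind)


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Dynamic-time-warping distance between two syllable feature sequences.

    Euclidean local cost, symmetric step pattern with diagonal weight 2
    (insert/delete weight 1), boundary-to-boundary path, normalized by the
    path-independent constant n + m.  Symmetric in its arguments, zero for
    identical sequences, and tolerant of syllable repetition (a sequence
    and its copy with one syllable duplicated are at distance 0).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("cannot align an empty syllable sequence")
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"feature dimensions differ: {a.shape[1]} vs {b.shape[1]}"
        )
    n, m = a.shape[0], b.shape[0]
    cost = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2))
    D = np.full((n, m), np.inf)
    D[0, 0] = cost[0, 0]
    for i in range(n):
        for j in range(m):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i > 0:
                best = min(best, D[i - 1, j] + cost[i, j])
            if j > 0:
                best = min(best, D[i, j - 1] + cost[i, j])
            if i > 0 and j > 0:
                best = min(best, D[i - 1, j - 1] + 2.0 * cost[i, j])
            D[i, j] = best
    return float(D[n - 1, m - 1] / (n + m))


def _zscore_features(songs: pd.DataFrame, features: tuple[str, ...]) -> pd.DataFrame:
    out = songs.copy()
    for f in features:
        v = out[f].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        out[f] = (v - v.mean()) / sd if sd > 0 else 0.0
    return out


def song_similarity_matrix(
    songs: pd.DataFrame,
    features: tuple[str, ...] = SONG_FEATURES,
    labels: tuple[str, ...] | None = None,
    zscore: bool = True,
) -> SpeciesMatrix:
    """Species-level song-similarity matrix from a syllable feature table.

    Features are z-scored across the whole dataset before alignment; the
    species-pair distance is the mean DTW distance over all between-species
    exemplar pairs and similarity is its negation (a rank-equivalent
    monotone transform, so less-negative = more similar).  The diagonal
    holds the within-species value aggregated the same way (0 for a single
    exemplar).
    """
    if labels is None:
        labels = tuple(sorted(songs["species"].unique()))
    feats = [f for f in features if f in songs.columns]
    if not feats:
        raise ValueError("no feature columns found in song table")
    data = _zscore_features(songs, tuple(feats)) if zscore else songs
    seqs: dict[str, list[np.ndarray]] = {sp: [] for sp in labels}
    for (sp, _), grp in data.groupby(["species", "exemplar_id"], sort=True):
        seqs[sp].append(grp.sort_values("syllable_idx")[feats].to_numpy(dtype=float))
    for sp in labels:
        if not seqs[sp]:
            raise ValueError(f"no song exemplars for species {sp!r}")
    k = len(labels)
    vals = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            if i == j:
                pairs = list(itertools.combinations(seqs[labels[i]], 2))
            else:
                pairs = list(itertools.product(seqs[labels[i]], seqs[labels[j]]))
            d = float(np.mean([dtw_distance(x, y) for x, y in pairs])) if pairs else 0.0
            vals[i, j] = vals[j, i] = -d
    return SpeciesMatrix(labels, vals, "song_similarity")


def _offdiag_vectors(
    response: SpeciesMatrix, predictor_values: np.ndarray, use_diagonal: bool
) -> tuple[np.ndarray, np.ndarray]:
    k = len(response.labels)
    mask = np.ones((k, k), dtype=bool)
    if not use_diagonal:
        np.fill_diagonal(mask, False)
    return response.values[mask], predictor_values[mask]


def permutation_matrix_test(
    response: SpeciesMatrix,
    predictor: SpeciesMatrix,
    n_perm: int = 10_000,
    seed: int = 0,
    use_diagonal: bool = False,
    method: str = "pearson",
    symmetrize_response: bool = False,
) -> dict:
    """Mantel-style permutation test of matrix association.

    The observed statistic is the Pearson (or Spearman, ``method``)
    correlation over matched off-diagonal cells; the null jointly permutes
    the predictor's row/column species labels.  All K!-1 non-identity label
    permutations are enumerated when that is no more than ``n_perm``,
    giving an exact p-value ``(1 + #{|r_perm| >= |r_obs|}) / K!``;
    otherwise ``n_perm`` random permutations are sampled and the add-one
    estimator is used.  ``symmetrize_response`` averages cells (i, j) and
    (j, i) of the directed aggression matrix first.
    """
    if response.labels != predictor.labels:
        raise ValueError("response and predictor matrices must share labels")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    k = len(response.labels)
    resp = response
    if symmetrize_response:
        resp = SpeciesMatrix(
            response.labels, (response.values + response.values.T) / 2.0, response.kind
        )

    def corr(x, y):
        if method == "pearson":
            return float(stats.pearsonr(x, y)[0])
        return float(stats.spearmanr(x, y)[0])

    x, y = _offdiag_vectors(resp, predictor.values, use_diagonal)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("correlation undefined: a matrix is constant off-diagonal")
    r_obs = corr(x, y)

    n_all = math.factorial(k) - 1
    exact = n_all <= n_perm
    if exact:
        perms = [
            p for p in itertools.permutations(range(k)) if p != tuple(range(k))
        ]
    else:
        rng = np.random.default_rng(derive_seed(seed, "matrix-test"))
        perms = [tuple(rng.permutation(k)) for _ in range(n_perm)]

    count = 0
    r_perm = np.empty(len(perms))
    for idx, p in enumerate(perms):
        pv = predictor.values[np.ix_(p, p)]
        _, yp = _offdiag_vectors(resp, pv, use_diagonal)
        r_perm[idx] = corr(x, yp)
        if abs(r_perm[idx]) >= abs(r_obs) - 1e-12:
            count += 1
    p_value = (1 + count) / (len(perms) + 1)
    return {
        "r": r_obs,
        "p_value": float(p_value),
        "n_perm": len(perms),
        "exact": exact,
        "method": method,
        "r_perm_mean": float(r_perm.mean()),
    }
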