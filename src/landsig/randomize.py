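"""Scrambling engine for building the random-landscape null distribution.

A "random" landscape is produced by shuffling which molecule carries which
fingerprint (equivalently, simultaneously permuting the rows and columns of
the similarity matrix) and, independently, scrambling the activity values
over the molecules.  Recomputing SALI on the scrambled data and repeating N
times yields N random SALI vectors whose concatenation — a single vector of
N·m(m-1)/2 elements when no pair is undefined — is the empirical null
against which the observed landscape is judged.

The two permutations per iteration are drawn independently: applying the
*same* permutation to both fingerprints and activities merely relabels the
pairs and reproduces the observed SALI multiset exactly, so it cannot serve
as a null.  Bits within a fingerprint are never scrambled; whole
fingerprints change owners.

Per iteration the seeded generator is consumed in a fixed order —
similarity permutation first, then activity permutation — so pools are
reproducible and replayable from the recorded permutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    ActivityVector,
    FingerprintSet,
    SALIVector,
    SimilarityMatrix,
    TestConfig,
    _check_ids,
    _sali_from_pairs,
    similarity_matrix,
)

logger = logging.getLogger("landsig")

__all__ = [
    "RandomSALIPool",
    "shuffle_fingerprints",
    "permute_similarity",
    "scramble_activities",
    "build_random_pool",
]


def _check_permutation(perm, m: int) -> np.ndarray:
    p = np.asarray(perm, dtype=np.intp)
    if p.shape != (m,) or not np.array_equal(np.sort(p), np.arange(m)):
        raise ValueError(f"permutation must be a bijection on 0..{m - 1}")
    return p


def shuffle_fingerprints(fps: FingerprintSet, permutation) -> FingerprintSet:
    """Reassign fingerprints to molecules: molecule i receives the
    fingerprint originally held by molecule permutation[i].  Ids and the
    multiset of fingerprints are unchanged."""
    p = _check_permutation(permutation, fps.n_molecules)
    return FingerprintSet(fps.molecule_ids, fps.bits[p], fps.representation_name)


def permute_similarity(sim: SimilarityMatrix, permutation) -> SimilarityMatrix:
    """Simultaneous row/column reindexing: output(i, j) = input(p(i), p(j)).

    Exact matrix-level equivalent of shuffling fingerprints, for datasets
    supplied only as precomputed similarity matrices.
    """
    p = _check_permutation(permutation, sim.n_molecules)
    return SimilarityMatrix(sim.molecule_ids, sim.values[np.ix_(p, p)], sim.representation_name)


def scramble_activities(acts: ActivityVector, permutation) -> ActivityVector:
    """Permute activity values over molecules; ids stay in place."""
    p = _check_permutation(permutation, len(acts))
    return ActivityVector(acts.molecule_ids, acts.values[p], acts.unit_label)


@dataclass(frozen=True)
class RandomSALIPool:
    """N scrambled SALI vectors plus their accumulated null distribution.

    ``per_iteration`` has shape (N, n_pairs) with NaN at undefined entries;
    ``per_iteration_mask`` marks defined entries.  ``accumulated`` is the
    concatenation of all defined values across iterations.
    """

    per_iteration: np.ndarray
    per_iteration_mask: np.ndarray
    accumulated: np.ndarray
    n_iterations: int
    seed: int
    n_molecules: int

    def __post_init__(self):
        if self.per_iteration.shape[0] != self.n_iterations:
            raise ValueError("per_iteration must hold one row per iteration")
        if len(self.accumulated) != int(self.per_iteration_mask.sum()):
            raise ValueError("accumulated length must equal the total defined count")

    def iteration_values(self, k: int) -> np.ndarray:
        """Defined SALI values of iteration k."""
        return self.per_iteration[k][self.per_iteration_mask[k]]

    def pair_values(self, pair_pos: int) -> np.ndarray:
        """Defined random SALI values at one pair position across iterations."""
        col = self.per_iteration[:, pair_pos]
        return col[self.per_iteration_mask[:, pair_pos]]


def build_random_pool(acts: ActivityVector,
                      sim_source: FingerprintSet | SimilarityMatrix,
                      cfg: TestConfig) -> RandomSALIPool:
    """Build the null pool of N scrambled SALI vectors.

    Each iteration draws two independent uniform permutations from a single
    generator seeded with ``cfg.seed`` (similarity first, then activities),
    recomputes the SALI vector under ``cfg`` and appends its defined values
    to the accumulated pool.
    """
    if isinstance(sim_source, FingerprintSet):
        # shuffling fingerprints and recomputing Tanimoto is exactly a
        # simultaneous row/column permutation of the precomputed matrix
        logger.debug("fingerprint input: shuffling realised as matrix permutation")
        sim = similarity_matrix(sim_source)
    else:
        sim = sim_source
    _check_ids(acts.molecule_ids, sim.molecule_ids)
    m = len(acts)
    if m < 2:
        raise ValueError("need at least 2 molecules")

    rng = np.random.default_rng(cfg.seed)
    iu = np.triu_indices(m, k=1)
    n_pairs = m * (m - 1) // 2
    N = cfg.n_iterations
    per_iter = np.empty((N, n_pairs))
    per_mask = np.empty((N, n_pairs), dtype=bool)
    A = acts.values
    S = sim.values
    for k in range(N):
        p_sim = rng.permutation(m)
        p_act = rng.permutation(m)
        s_k = S[np.ix_(p_sim, p_sim)][iu]
        a_k = A[p_act]
        dA = np.abs(a_k[:, None] - a_k[None, :])[iu]
        sv = _sali_from_pairs(dA, s_k, m, cfg)
        per_iter[k] = sv.values
        per_mask[k] = sv.defined_mask
    accumulated = per_iter[per_mask]
    return RandomSALIPool(per_iteration=per_iter, per_iteration_mask=per_mask,
                          accumulated=accumulated, n_iterations=N,
                          seed=cfg.seed, n_molecules=m)
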