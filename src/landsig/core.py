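"""Core domain types and the SALI statistic.

The Structure-Activity Landscape Index for a pair of molecules (i, j) is

    SALI_ij = |A_i - A_j| / (1 - sim(i, j))

where A_i, A_j are real-valued activities on a log scale (pIC50, pKi) and
sim(i, j) in [0, 1] is the structural similarity under some molecular
representation.  Large SALI values flag *activity cliffs*: pairs of similar
molecules with very different activities.

Pairs with sim(i, j) = 1 make the denominator vanish.  When the activities
also agree the pair is a genuine duplicate and SALI is defined as 0; when
they differ the value is infinite and a policy decides the treatment
(exclude the pair from every distribution, or cap it at a finite sentinel).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

logger = logging.getLogger("landsig")

__all__ = [
    "ActivityVector",
    "FingerprintSet",
    "SimilarityMatrix",
    "SALIVector",
    "TestConfig",
    "tanimoto",
    "similarity_matrix",
    "compute_sali",
    "mean_fusion",
]

_SYM_TOL = 1e-8  # asymmetry / diagonal tolerance when validating matrices


def _as_ids(molecule_ids: Sequence) -> tuple:
    ids = tuple(str(x) for x in molecule_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("molecule ids must be unique")
    return ids


@dataclass(frozen=True)
class ActivityVector:
    """Per-molecule real-valued activities (log-scale potency units)."""

    molecule_ids: tuple
    values: np.ndarray
    unit_label: str = "pIC50"

    def __post_init__(self):
        object.__setattr__(self, "molecule_ids", _as_ids(self.molecule_ids))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or len(vals) != len(self.molecule_ids):
            raise ValueError("ids and values must be 1-D and the same length")
        if len(vals) < 2:
            raise ValueError("need at least 2 molecules")
        if not np.all(np.isfinite(vals)):
            raise ValueError("activity values must be finite")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class FingerprintSet:
    """m binary fingerprints of common length L for one representation."""

    molecule_ids: tuple
    bits: np.ndarray
    representation_name: str = "fingerprint"

    def __post_init__(self):
        object.__setattr__(self, "molecule_ids", _as_ids(self.molecule_ids))
        bits = np.asarray(self.bits)
        if bits.ndim != 2:
            raise ValueError("bits must be a 2-D array of shape (m, L)")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("fingerprint entries must be 0 or 1")
        bits = bits.astype(np.uint8)
        object.__setattr__(self, "bits", bits)
        if bits.shape[0] != len(self.molecule_ids):
            raise ValueError("one fingerprint per molecule id required")
        if bits.shape[0] < 2:
            raise ValueError("need at least 2 molecules")
        if bits.shape[1] < 1:
            raise ValueError("fingerprint length must be >= 1")

    @property
    def n_molecules(self) -> int:
        return self.bits.shape[0]

    @property
    def n_bits(self) -> int:
        return self.bits.shape[1]


@dataclass(frozen=True)
class SimilarityMatrix:
    """m x m symmetric similarities in [0, 1] with unit diagonal."""

    molecule_ids: tuple
    values: np.ndarray
    representation_name: str = "similarity"

    def __post_init__(self):
        object.__setattr__(self, "molecule_ids", _as_ids(self.molecule_ids))
        vals = np.asarray(self.values, dtype=float)
        m = len(self.molecule_ids)
        if vals.shape != (m, m):
            raise ValueError(f"similarity matrix must be {m}x{m}, got {vals.shape}")
        asym = np.abs(vals - vals.T).max() if m else 0.0
        if asym > _SYM_TOL:
            raise ValueError(f"matrix asymmetry {asym:.3g} exceeds tolerance {_SYM_TOL:g}")
        if asym > 0:
            vals = (vals + vals.T) / 2.0
        diag_err = np.abs(np.diag(vals) - 1.0).max()
        if diag_err > _SYM_TOL:
            raise ValueError(f"diagonal deviates from 1 by {diag_err:.3g}")
        if diag_err > 0:
            logger.warning("forcing diagonal to 1 (max deviation %.3g)", diag_err)
            np.fill_diagonal(vals, 1.0)
        if vals.size and (vals.min() < -_SYM_TOL or vals.max() > 1 + _SYM_TOL):
            raise ValueError("similarities must lie in [0, 1]")
        vals = np.clip(vals, 0.0, 1.0)
        vals.flags.writeable = False
        object.__setattr__(self, "values", vals)

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_ids)


@dataclass(frozen=True)
class SALIVector:
    """Upper-triangle SALI values with a mask for undefined pairs.

    ``pair_index`` lists (i, j) with i < j in row-major order, length
    m(m-1)/2.  ``values`` is aligned with it; entries where ``defined_mask``
    is False carry no meaningful number (stored as NaN).
    """

    pair_index: np.ndarray  # (n_pairs, 2) int
    values: np.ndarray  # (n_pairs,) float, NaN where undefined
    defined_mask: np.ndarray  # (n_pairs,) bool
    n_molecules: int

    def __post_init__(self):
        m = self.n_molecules
        expect = m * (m - 1) // 2
        if len(self.values) != expect:
            raise ValueError(f"expected {expect} pairs for m={m}, got {len(self.values)}")
        if (self.defined_mask & ~np.isfinite(self.values)).any():
            raise ValueError("defined entries must be finite")
        if np.any(self.values[self.defined_mask] < 0):
            raise ValueError("defined SALI values must be nonnegative")

    @property
    def defined_values(self) -> np.ndarray:
        return self.values[self.defined_mask]

    @property
    def n_pairs(self) -> int:
        return len(self.values)

    @property
    def n_defined(self) -> int:
        return int(self.defined_mask.sum())


@dataclass(frozen=True)
class TestConfig:
    """Configuration of the permutation tests.

    Defaults: N = 1000 scramblings, alpha = 0.05, magnitude threshold at the
    0.95 quantile of the observed SALI values, undefined pairs excluded.
    """

    __test__ = False  # name pattern collides with pytest collection

    n_iterations: int = 1000
    alpha: float = 0.05
    threshold_quantile: float = 0.95
    seed: int = 0
    undefined_pair_policy: str = "exclude"
    cap_value: float | None = None

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be a positive integer")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.threshold_quantile < 1.0:
            raise ValueError("threshold_quantile must lie in (0, 1)")
        if self.undefined_pair_policy not in ("exclude", "cap"):
            raise ValueError("undefined_pair_policy must be 'exclude' or 'cap'")
        if self.undefined_pair_policy == "cap":
            if self.cap_value is None or self.cap_value <= 0:
                raise ValueError("cap policy requires a positive cap_value")

    def with_(self, **kw) -> "TestConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# operations


def tanimoto(fp_a, fp_b) -> float:
    """Tanimoto coefficient c / (a + b - c) between two binary vectors.

    ``a`` and ``b`` are the on-bit counts of each fingerprint and ``c`` the
    count of shared on-bits.  Two all-zero fingerprints are treated as
    identical objects and return 1.
    """
    a = np.asarray(fp_a, dtype=np.uint8)
    b = np.asarray(fp_b, dtype=np.uint8)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint lengths differ: {a.shape} vs {b.shape}")
    ca, cb = int(a.sum()), int(b.sum())
    c = int((a & b).sum())
    denom = ca + cb - c
    if denom == 0:
        logger.debug("tanimoto of two all-zero fingerprints; returning 1 (degenerate)")
        return 1.0
    return c / denom


def similarity_matrix(fps: FingerprintSet) -> SimilarityMatrix:
    """Pairwise Tanimoto similarity matrix of a fingerprint set."""
    bits = fps.bits.astype(np.float64)
    on = bits.sum(axis=1)
    common = bits @ bits.T
    denom = on[:, None] + on[None, :] - common
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, common / np.where(denom > 0, denom, 1.0), 1.0)
    np.fill_diagonal(sim, 1.0)
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 1.0)
    return SimilarityMatrix(fps.molecule_ids, sim, fps.representation_name)


def _check_ids(a_ids, b_ids):
    if tuple(a_ids) != tuple(b_ids):
        raise ValueError("molecule ids must match in identical order")


def compute_sali(acts: ActivityVector, sim: SimilarityMatrix, cfg: TestConfig | None = None) -> SALIVector:
    """Observed SALI vector over all m(m-1)/2 unordered pairs.

    Pairs with sim = 1 and equal activities get SALI = 0 and stay defined;
    pairs with sim = 1 and differing activities follow
    ``cfg.undefined_pair_policy`` (``exclude``: masked out of every
    downstream distribution; ``cap``: set to ``cfg.cap_value``).
    """
    cfg = cfg or TestConfig()
    _check_ids(acts.molecule_ids, sim.molecule_ids)
    m = len(acts)
    iu = np.triu_indices(m, k=1)
    dA = np.abs(acts.values[:, None] - acts.values[None, :])[iu]
    s = sim.values[iu]
    out = _sali_from_pairs(dA, s, m, cfg, pair_index=np.column_stack(iu))
    n_undef = out.n_pairs - out.n_defined
    if n_undef:
        logger.warning("%d pair(s) with sim=1 and differing activities excluded "
                       "from the observed SALI distribution", n_undef)
    return out


def _sali_from_pairs(dA: np.ndarray, s: np.ndarray, m: int, cfg: TestConfig,
                     pair_index: np.ndarray | None = None) -> SALIVector:
    """SALI from precomputed |dA| and similarity arrays over the upper triangle."""
    if pair_index is None:
        pair_index = np.column_stack(np.triu_indices(m, k=1))
    denom = 1.0 - s
    singular = denom <= 0.0
    values = np.empty_like(dA)
    defined = np.ones(len(dA), dtype=bool)
    ok = ~singular
    values[ok] = dA[ok] / denom[ok]
    # sim == 1 pairs: duplicates (dA == 0) are defined zeros
    dup = singular & (dA == 0)
    values[dup] = 0.0
    bad = singular & (dA > 0)
    if bad.any():
        if cfg.undefined_pair_policy == "exclude":
            logger.debug("%d pair(s) with sim=1 and differing activities excluded", int(bad.sum()))
            values[bad] = np.nan
            defined[bad] = False
        else:
            values[bad] = cfg.cap_value
    return SALIVector(pair_index=pair_index, values=values, defined_mask=defined, n_molecules=m)


def mean_fusion(mats: Sequence[SimilarityMatrix]) -> SimilarityMatrix:
    """Consensus similarity by element-wise mean across representations.

    Mean fusion of similarity matrices from different molecular
    representations; the fused name concatenates the inputs with "+".
    """
    mats = list(mats)
    if not mats:
        raise ValueError("mean_fusion requires at least one matrix")
    ids = mats[0].molecule_ids
    for mat in mats[1:]:
        _check_ids(ids, mat.molecule_ids)
    fused = np.mean([mat.values for mat in mats], axis=0)
    name = "+".join(mat.representation_name for mat in mats)
    return SimilarityMatrix(ids, fused, name)
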