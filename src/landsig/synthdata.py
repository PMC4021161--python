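"""Seeded synthetic landscapes with controlled structure.

Real benchmark sets for landscape analysis pair tens to hundreds of
molecules, binary fingerprints (e.g. 166-bit structural keys) and log-scale
potencies spanning a few orders of magnitude.  The generators here emulate
only the *statistical* structure of such data — no chemistry, scaffolds or
R-group series — in four archetypes:

``flat``
    every molecule has the same activity: a landscape with no cliffs at
    all, whose SALI values are identically zero.
``random``
    activities drawn independently of the fingerprints; the truth of the
    null hypothesis of the validity test.
``planted_sar``
    activity is an affine function of a few informative fingerprint bits
    plus Gaussian noise, rescaled to the activity range: similar molecules
    really do have similar activities, so the landscape is non-random.
``jagged``
    random activities, after which the members of the most-similar pairs
    are pushed to opposite extremes of the activity range, manufacturing
    activity cliffs exactly where similarity is highest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ActivityVector, FingerprintSet, similarity_matrix

__all__ = ["LandscapeSpec", "gen_fingerprints", "gen_landscape"]

KINDS = ("flat", "random", "planted_sar", "jagged")


@dataclass(frozen=True)
class LandscapeSpec:
    """Recipe for one synthetic landscape.

    Defaults mirror a typical benchmark set: m around a hundred molecules,
    166-bit keys at moderate bit density, activities on a pIC50-like scale
    of 4-9 log units.
    """

    kind: str = "random"
    m: int = 100
    L: int = 166
    bit_density: float = 0.3
    noise_sd: float = 0.0
    n_informative_bits: int = 5
    cliff_pairs: int = 5
    activity_range: tuple[float, float] = (4.0, 9.0)
    seed: int = 0
    activity_marginal: str = "uniform"  # or "mixture": normal core + exp tail

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if not 0.0 < self.bit_density < 1.0:
            raise ValueError("bit_density must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        low, high = self.activity_range
        if not low < high:
            raise ValueError("activity_range must satisfy low < high")
        if self.activity_marginal not in ("uniform", "mixture"):
            raise ValueError("activity_marginal must be 'uniform' or 'mixture'")


def gen_fingerprints(m: int, L: int, density: float, seed: int,
                     rng: np.random.Generator | None = None) -> FingerprintSet:
    """Random binary fingerprints, each bit on independently with
    probability ``density``.  All-zero fingerprints are resampled so no
    molecule is structurally empty."""
    if not 0.0 < density < 1.0:
        raise ValueError("density must lie in (0, 1)")
    rng = rng if rng is not None else np.random.default_rng(seed)
    bits = (rng.random((m, L)) < density).astype(np.uint8)
    for _ in range(1000):
        empty = bits.sum(axis=1) == 0
        if not empty.any():
            break
        bits[empty] = (rng.random((int(empty.sum()), L)) < density).astype(np.uint8)
    else:  # pragma: no cover - density>0 makes this astronomically unlikely
        raise RuntimeError("could not avoid all-zero fingerprints")
    ids = [f"mol{i:04d}" for i in range(m)]
    return FingerprintSet(ids, bits, "synthetic")


def _random_activities(spec: LandscapeSpec, rng: np.random.Generator) -> np.ndarray:
    low, high = spec.activity_range
    if spec.activity_marginal == "uniform":
        return rng.uniform(low, high, spec.m)
    # normal core + exponential tail, clipped to range: crude emulation of
    # the skewed, long-tailed potency marginals of real assay data
    mid = (low + high) / 2.0
    core = rng.normal(mid, (high - low) / 6.0, spec.m)
    tail = rng.random(spec.m) < 0.15
    core[tail] += rng.exponential((high - low) / 4.0, int(tail.sum()))
    return np.clip(core, low, high)


def gen_landscape(spec: LandscapeSpec) -> tuple[FingerprintSet, ActivityVector]:
    """Generate one (FingerprintSet, ActivityVector) pair per the spec."""
    rng = np.random.default_rng(spec.seed)
    fps = gen_fingerprints(spec.m, spec.L, spec.bit_density, spec.seed, rng=rng)
    low, high = spec.activity_range

    if spec.kind == "flat":
        acts = np.full(spec.m, (low + high) / 2.0)
    elif spec.kind == "random":
        acts = _random_activities(spec, rng)
    elif spec.kind == "planted_sar":
        # Hierarchical scaffold model.  Real substructure keys are strongly
        # correlated: a scaffold or pharmacophore toggles many keys at once
        # and alternative substituents light up *different* keys.  Each
        # informative bit therefore owns a block of background keys —
        # geometric block sizes, so the "scaffold" bit has the largest
        # structural footprint — half of each block copying the bit and
        # half its complement (Tanimoto counts shared on-bits only, so the
        # complement halves make agreement on informative zeros visible in
        # similarity too), each key flipped independently with probability
        # 0.1.  The activity weight of a bit equals its block size: the
        # feature that moves similarity most also moves activity most, as
        # in a congeneric series where the scaffold dominates both.
        k = min(spec.n_informative_bits, spec.L)
        info = rng.choice(spec.L, size=k, replace=False)
        bits = fps.bits.copy()
        others = np.setdiff1d(np.arange(spec.L), info)
        rng.shuffle(others)
        n_bg = len(others)
        frac = 2.0 ** -np.arange(1, k + 1)
        frac /= frac.sum()
        counts = np.maximum(1, np.round(frac * n_bg).astype(int))
        while counts.sum() > n_bg:
            counts[np.argmax(counts)] -= 1
        owner = np.repeat(info, counts)
        owner = np.concatenate([owner, np.full(n_bg - len(owner), info[-1])])
        polarity = np.zeros(n_bg, np.uint8)
        for b in info:
            idx = np.where(owner == b)[0]
            polarity[idx[: len(idx) // 2]] = 1
        flips = (rng.random((spec.m, n_bg)) < 0.1).astype(np.uint8)
        bits[:, others] = bits[:, owner] ^ polarity[None, :] ^ flips
        fps = FingerprintSet(fps.molecule_ids, bits, fps.representation_name)
        weights = counts.astype(float)
        raw = fps.bits[:, info].astype(float) @ weights
        span = raw.max() - raw.min()
        if span > 0:
            acts = low + (raw - raw.min()) * (high - low) / span
        else:
            acts = np.full(spec.m, (low + high) / 2.0)
        acts = acts + rng.normal(0.0, spec.noise_sd, spec.m)
    else:  # jagged
        acts = _random_activities(spec, rng)
        sim = similarity_matrix(fps).values
        iu = np.triu_indices(spec.m, k=1)
        order = np.argsort(sim[iu])[::-1]  # most similar first
        placed = 0
        extreme: dict[int, float] = {}  # molecules already pinned to an extreme
        for idx in order:
            if placed >= spec.cliff_pairs:
                break
            i, j = int(iu[0][idx]), int(iu[1][idx])
            if sim[i, j] >= 1.0:
                continue  # a duplicate pair cannot carry a finite cliff
            if i in extreme and j in extreme:
                if extreme[i] != extreme[j]:
                    placed += 1  # already a cliff by earlier assignments
                continue
            if i in extreme:
                extreme[j] = high if extreme[i] == low else low
            elif j in extreme:
                extreme[i] = high if extreme[j] == low else low
            else:
                extreme[i], extreme[j] = low, high
            placed += 1
        for mol, val in extreme.items():
            acts[mol] = val

    ids = fps.molecule_ids
    return fps, ActivityVector(ids, acts, "pIC50")
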