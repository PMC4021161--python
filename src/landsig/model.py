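"""Model/results interface for activity-landscape significance analysis.

``ActivityLandscape`` binds an activity vector to one molecular
representation (fingerprints or a precomputed similarity matrix).  Its
``fit()`` runs the full permutation analysis — observed SALI, the N-fold
scrambled null pool, the KS validity test and per-pair cliff significance —
and returns a ``LandscapeResults`` carrying the estimates, the per-pair
table and a ``summary()``.

    >>> from landsig import ActivityLandscape, LandscapeSpec, gen_landscape
    >>> fps, acts = gen_landscape(LandscapeSpec(kind="planted_sar", m=40, seed=7))
    >>> res = ActivityLandscape(acts, fingerprints=fps).fit()
    >>> res.valid, res.f_magnitude           # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    ActivityVector,
    FingerprintSet,
    SimilarityMatrix,
    TestConfig,
    compute_sali,
    similarity_matrix,
)
from .randomize import build_random_pool
from .sigtest import cliff_significance, landscape_validity_test, per_iteration_check

__all__ = ["ActivityLandscape", "LandscapeResults"]


class ActivityLandscape:
    """Activity landscape of one dataset under one representation.

    Parameters
    ----------
    activities : ActivityVector
    similarity : SimilarityMatrix, optional
        Precomputed similarities (e.g. shipped with a published dataset).
    fingerprints : FingerprintSet, optional
        Binary fingerprints; Tanimoto similarities are computed from them.
        Exactly one of ``similarity`` / ``fingerprints`` must be given.
    config : TestConfig, optional
        Permutation-test configuration (N, alpha, threshold quantile, seed,
        undefined-pair policy).
    """

    def __init__(self, activities: ActivityVector,
                 similarity: SimilarityMatrix | None = None,
                 fingerprints: FingerprintSet | None = None,
                 config: TestConfig | None = None):
        if (similarity is None) == (fingerprints is None):
            raise ValueError("provide exactly one of 'similarity' or 'fingerprints'")
        self.activities = activities
        self.fingerprints = fingerprints
        self.similarity = similarity if similarity is not None else similarity_matrix(fingerprints)
        if tuple(self.similarity.molecule_ids) != tuple(activities.molecule_ids):
            raise ValueError("activity and representation molecule ids must match in order")
        self.config = config or TestConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, activity_col: str = "activity",
                       bits_col: str = "bits", id_col: str | None = None,
                       representation_name: str = "fingerprint",
                       config: TestConfig | None = None) -> "ActivityLandscape":
        """Build from a tidy DataFrame with an activity column and a column
        of fixed-length 0/1 bitstrings (index or ``id_col`` holds ids)."""
        ids = df[id_col] if id_col else df.index
        ids = [str(x) for x in ids]
        acts = ActivityVector(ids, df[activity_col].to_numpy(dtype=float))
        bits = np.array([[int(ch) for ch in str(s)] for s in df[bits_col]], dtype=np.uint8)
        fps = FingerprintSet(ids, bits, representation_name)
        return cls(acts, fingerprints=fps, config=config)

    @property
    def n_molecules(self) -> int:
        return len(self.activities)

    @property
    def representation_name(self) -> str:
        return self.similarity.representation_name

    def fit(self, n_iterations: int | None = None, seed: int | None = None,
            iteration_check: bool = False) -> "LandscapeResults":
        """Run the permutation analysis and return the results object."""
        cfg = self.config
        if n_iterations is not None:
            cfg = cfg.with_(n_iterations=n_iterations)
        if seed is not None:
            cfg = cfg.with_(seed=seed)
        observed = compute_sali(self.activities, self.similarity, cfg)
        pool = build_random_pool(self.activities, self.similarity, cfg)
        landscape = landscape_validity_test(observed, pool, cfg, self.representation_name)
        cliffs = cliff_significance(observed, pool, landscape, cfg, self.representation_name)
        n_distinguishable = per_iteration_check(pool, cfg) if iteration_check else None
        return LandscapeResults(self, cfg, observed, pool, landscape, cliffs, n_distinguishable)


class LandscapeResults:
    """Fitted results: validity test, cliff table and summary statistics."""

    def __init__(self, model, config, observed, pool, landscape, cliffs,
                 n_distinguishable=None):
        self.model = model
        self.config = config
        self.observed = observed
        self.pool = pool
        self.landscape = landscape
        self.cliffs = cliffs
        self.n_distinguishable = n_distinguishable

    # -- scalar accessors ---------------------------------------------------
    @property
    def ks_statistic(self) -> float:
        return self.landscape.ks_statistic

    @property
    def p_value(self) -> float:
        return self.landscape.p_value

    @property
    def valid(self) -> bool:
        return self.landscape.valid

    @property
    def f_magnitude(self) -> float | None:
        return self.cliffs.f_magnitude

    @property
    def f_significant(self) -> float | None:
        return self.cliffs.f_significant

    @property
    def threshold_value(self) -> float:
        return self.cliffs.threshold_value

    @property
    def n_significant_cliffs(self) -> int:
        return self.cliffs.n_significant

    @property
    def pairs(self) -> pd.DataFrame:
        """Per-pair table with molecule ids, SALI, empirical p, decisions."""
        ids = self.model.activities.molecule_ids
        df = self.cliffs.pairs.copy()
        df.insert(0, "id_i", [ids[i] for i in df["i"]])
        df.insert(1, "id_j", [ids[j] for j in df["j"]])
        return df

    def to_dict(self) -> dict:
        d = {
            "representation": self.landscape.representation_name,
            "n_molecules": self.model.n_molecules,
            "n_pairs": self.observed.n_pairs,
            "n_defined_pairs": self.observed.n_defined,
            "ks_statistic": self.ks_statistic,
            "p_value": self.p_value,
            "alpha": self.landscape.alpha,
            "valid": bool(self.valid),
            "threshold_quantile": self.cliffs.threshold_quantile,
            "threshold_value": self.threshold_value,
            "f_magnitude": self.f_magnitude,
            "f_significant": self.f_significant,
            "n_above_threshold": self.cliffs.n_above_threshold,
            "n_significant": self.n_significant_cliffs,
            "n_iterations": self.config.n_iterations,
            "seed": self.config.seed,
        }
        if self.n_distinguishable is not None:
            d["n_iterations_distinguishable"] = int(self.n_distinguishable)
        return d

    def summary(self) -> str:
        """Human-readable summary table of the fitted landscape test."""
        d = self.to_dict()
        fsig = "NA" if d["f_significant"] is None else f"{d['f_significant']:.3f}"
        lines = [
            "Activity Landscape Significance Test",
            "=" * 52,
            f"Representation:        {d['representation']}",
            f"Molecules / pairs:     {d['n_molecules']} / {d['n_defined_pairs']} defined",
            f"Scramblings (N):       {d['n_iterations']}   seed={d['seed']}",
            "-" * 52,
            f"KS statistic D:        {d['ks_statistic']:.4f}",
            f"KS p-value:            {d['p_value']:.4g}",
            f"Landscape valid:       {d['valid']}  (alpha={d['alpha']})",
            "-" * 52,
            f"SALI threshold (q={d['threshold_quantile']:.2f}): {d['threshold_value']:.4f}",
            f"F_magnitude:           {d['f_magnitude']:.3f}",
            f"F_significant:         {fsig}",
            f"Significant cliffs:    {d['n_significant']}",
        ]
        if self.n_distinguishable is not None:
            lines.append(f"Distinguishable iters: {d['n_iterations_distinguishable']} / {d['n_iterations']}")
        lines.append("=" * 52)
        return "\n".join(lines)

    def plot_cliffs(self, ax=None):
        """Scatter of observed SALI vs empirical p with the magnitude
        threshold; significant cliffs highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.cliffs.pairs[self.cliffs.pairs["defined"]]
        sig = df["significant"]
        ax.scatter(df.loc[~sig, "sali"], df.loc[~sig, "empirical_p"], s=8, c="grey", label="not significant")
        ax.scatter(df.loc[sig, "sali"], df.loc[sig, "empirical_p"], s=10, c="crimson", label="significant cliff")
        ax.axvline(self.threshold_value, ls="--", c="k", lw=0.8)
        ax.axhline(self.config.alpha, ls=":", c="k", lw=0.8)
        ax.set_xlabel("observed SALI")
        ax.set_ylabel("empirical p-value")
        ax.set_title(f"{self.landscape.representation_name}: per-pair cliff significance")
        ax.legend(frameon=False, fontsize=8)
        return ax
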