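"""Spatial clustering of missense de novo mutations along a coding sequence.

The proximity statistic is the geometric mean, over all unordered pairs of
observed mutations, of the pairwise coding distance plus one.  (The +1 offset
keeps the geometric mean defined when two mutations share a position; it is
applied identically to observed and simulated values, so the empirical p-value
ranking is unchanged.)  Small values indicate clustering.  Significance is
assessed against a Monte-Carlo null in which the same number of mutations is
drawn independently, with replacement, from the gene's missense-producing
sites weighted by their trinucleotide-context mutation rates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .genes import GeneModel, SiteWeightTable, TrinucleotideRateTable, site_weights


def proximity(coding_positions) -> float:
    """Geometric mean of (pairwise coding distance + 1) over all pairs."""
    pos = [int(p) for p in coding_positions]
    if len(pos) < 2:
        raise ValueError("proximity requires at least 2 positions")
    logs = [
        math.log(abs(a - b) + 1.0) for a, b in itertools.combinations(pos, 2)
    ]
    return math.exp(math.fsum(logs) / len(logs))


def _proximity_array(positions: np.ndarray) -> np.ndarray:
    """Vectorised proximity: positions has shape (n_sim, m)."""
    n_sim, m = positions.shape
    logsum = np.zeros(n_sim)
    n_pairs = 0
    for i in range(m):
        for j in range(i + 1, m):
            logsum += np.log(np.abs(positions[:, i] - positions[:, j]) + 1.0)
            n_pairs += 1
    return np.exp(logsum / n_pairs)


def sample_null_proximities(weights: SiteWeightTable, m: int, n_sim: int,
                            seed) -> np.ndarray:
    """Monte-Carlo null: draw m rate-weighted sites per replicate, with
    replacement, and record each replicate's proximity statistic."""
    if m < 2:
        raise ValueError("need at least 2 mutations to measure proximity")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    pos = np.asarray(weights.positions)
    w = np.asarray(weights.weights, dtype=float)
    probs = w / w.sum()
    idx = rng.choice(len(pos), size=(int(n_sim), m), replace=True, p=probs)
    return _proximity_array(pos[idx])


def empirical_p(observed: float, simulated) -> tuple:
    """Proportion of simulated proximities <= observed, raw and add-one smoothed."""
    sim = np.asarray(simulated, dtype=float)
    if sim.size == 0:
        raise ValueError("simulated proximities must be non-empty")
    n_sim = sim.size
    count = int(np.count_nonzero(sim <= observed))
    return count / n_sim, (count + 1) / (n_sim + 1)


def exact_null_distribution(weights: SiteWeightTable, m: int,
                            max_positions: int = 30) -> dict:
    """Exact null distribution of the proximity statistic by full enumeration.

    Enumerates all ordered m-tuples of per-position draws (alternates summed
    into per-position weights).  Intended as a small-instance oracle for the
    Monte-Carlo sampler; limited to m <= 3 and few positions.
    """
    if m > 3:
        raise ValueError("exact enumeration supported only for m <= 3")
    per_pos = weights.per_position_weights()
    if len(per_pos) > max_positions:
        raise ValueError(
            f"{len(per_pos)} positions exceeds enumeration limit {max_positions}"
        )
    positions = sorted(per_pos)
    total = math.fsum(per_pos.values())
    probs = {p: per_pos[p] / total for p in positions}
    dist: dict = {}
    for tup in itertools.product(positions, repeat=m):
        prob = math.prod(probs[p] for p in tup)
        stat = round(proximity(tup), 12)
        dist[stat] = dist.get(stat, 0.0) + prob
    return dist


def exact_p(observed: float, dist: dict) -> float:
    """P(statistic <= observed) under an exact null distribution."""
    return math.fsum(p for s, p in dist.items() if s <= observed + 1e-12)


class MissenseClusteringModel:
    """Rate-weighted Monte-Carlo clustering test for missense de novos.

    Parameters
    ----------
    weights : SiteWeightTable
        Missense site weights (from :func:`denovotest.genes.site_weights`).
    observed_positions : sequence of int
        0-based coding positions of the observed missense de novos (>= 2).
    """

    def __init__(self, weights: SiteWeightTable, observed_positions):
        self.weights = weights
        self.observed_positions = tuple(int(p) for p in observed_positions)
        if len(self.observed_positions) < 2:
            raise ValueError("clustering requires at least 2 observed mutations")
        for p in self.observed_positions:
            if not 0 <= p < weights.coding_length:
                raise ValueError(f"position {p} outside CDS of length {weights.coding_length}")

    @classmethod
    def from_gene(cls, model: GeneModel, rates: TrinucleotideRateTable,
                  observed_positions) -> "MissenseClusteringModel":
        return cls(site_weights(model, rates, "missense"), observed_positions)

    def fit(self, n_sim: int = 1_000_000, seed=None) -> "ClusteringResults":
        """Run the Monte-Carlo test.  The default simulation count follows the
        published analysis; ``seed`` is mandatory for reproducible output."""
        if seed is None:
            raise ValueError("seed is required for a reproducible clustering test")
        obs = proximity(self.observed_positions)
        sims = sample_null_proximities(
            self.weights, m=len(self.observed_positions), n_sim=n_sim, seed=seed
        )
        p_raw, p_smooth = empirical_p(obs, sims)
        return ClusteringResults(
            model=self,
            observed_proximity=obs,
            n_sim=int(n_sim),
            p_empirical=p_raw,
            p_smoothed=p_smooth,
            seed=seed,
        )


@dataclass(frozen=True)
class ClusteringResults:
    """Observed proximity and its empirical p against the Monte-Carlo null."""

    model: MissenseClusteringModel = field(repr=False)
    observed_proximity: float
    n_sim: int
    p_empirical: float
    p_smoothed: float
    seed: object

    def to_dict(self) -> dict:
        return {
            "observed_proximity": self.observed_proximity,
            "n_observed": len(self.model.observed_positions),
            "n_sim": self.n_sim,
            "p_empirical": self.p_empirical,
            "p_smoothed": self.p_smoothed,
            "seed": self.seed,
        }

    def summary(self) -> str:
        return "\n".join(
            [
                "Missense clustering test",
                "=" * 45,
                f"observed mutations:   {len(self.model.observed_positions)}",
                f"observed proximity:   {self.observed_proximity:.4f}",
                f"simulations:          {self.n_sim}",
                f"p (empirical):        {self.p_empirical:.6g}",
                f"p (add-one smoothed): {self.p_smoothed:.6g}",
                f"seed:                 {self.seed}",
            ]
        )
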