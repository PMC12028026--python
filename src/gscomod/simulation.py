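"""Split-simulation validation of the gene-set similarity score.

The idea: if the similarity score really captures shared biology, then
splitting one disease's gene list into two disjoint halves should yield
two pseudo-diseases with highly similar enrichment profiles (they come
from the same pathophysiology), while splitting a same-sized random draw
from the gene universe should not. The simulation repeats both settings
at several split ratios and compares matched replicates with a paired
t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geneset_io import DiseaseGeneSet, GeneSetCollection, filter_to_universe
from .measures import gs_sim
from .ora import profile

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "split_genes",
    "null_split",
    "run_simulation",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Settings of one split-simulation run.

    ``ratios`` are the fractions assigned to the first pseudo-disease
    (0 < r <= 0.5); ``reps_per_ratio`` replicates are drawn per ratio for
    both the real-split and the matched null-split settings.
    """

    ratios: tuple[float, ...] = (0.3, 0.35, 0.4, 0.45, 0.5)
    reps_per_ratio: int = 200
    seed: int = 0
    transform: str = "exp"

    def __post_init__(self) -> None:
        if not self.ratios:
            raise ValueError("at least one ratio is required")
        for r in self.ratios:
            if not 0.0 < r <= 0.5:
                raise ValueError(f"ratio {r} outside (0, 0.5]")
        if self.reps_per_ratio < 0:
            raise ValueError("reps_per_ratio must be >= 0")


@dataclass
class SimulationResult:
    """Per-replicate scores and the paired-test summary."""

    replicates: pd.DataFrame  # columns: ratio, rep, real_score, null_score, flags
    summary: dict = field(default_factory=dict)


def split_genes(
    genes: frozenset[str] | set[str], ratio: float, rng: np.random.Generator
) -> tuple[frozenset[str], frozenset[str]]:
    """Uniform random partition of a gene set into parts of sizes
    round(ratio*m) and m - round(ratio*m)."""
    if not 0.0 < ratio <= 0.5:
        raise ValueError(f"ratio {ratio} outside (0, 0.5]")
    pool = sorted(genes)
    m = len(pool)
    if m < 2:
        raise ValueError("need at least 2 genes to split")
    k = int(round(ratio * m))
    if k < 1 or m - k < 1:
        raise ValueError(f"ratio {ratio} yields an empty part for {m} genes")
    perm = rng.permutation(m)
    part1 = frozenset(pool[i] for i in perm[:k])
    part2 = frozenset(pool[i] for i in perm[k:])
    return part1, part2


def null_split(
    universe: frozenset[str] | set[str],
    m: int,
    ratio: float,
    rng: np.random.Generator,
) -> tuple[frozenset[str], frozenset[str]]:
    """Sample m genes from the universe without replacement, then split."""
    pool = sorted(universe)
    if m > len(pool):
        raise ValueError(f"cannot sample {m} genes from a universe of {len(pool)}")
    idx = rng.choice(len(pool), size=m, replace=False)
    sample = frozenset(pool[i] for i in idx)
    return split_genes(sample, ratio, rng)


def _score_pair(
    part1: frozenset[str],
    part2: frozenset[str],
    collection: GeneSetCollection,
    transform: str,
) -> tuple[float, tuple[str, ...]]:
    pa = profile(DiseaseGeneSet("part1", part1), collection)
    pb = profile(DiseaseGeneSet("part2", part2), collection)
    score = gs_sim(pa, pb, transform=transform)
    return score.value, score.flags


def run_simulation(
    disease: DiseaseGeneSet,
    collection: GeneSetCollection,
    config: SimulationConfig,
) -> SimulationResult:
    """Run the real-vs-null split simulation for one disease gene list.

    For every ratio and replicate, the disease genes (restricted to the
    collection universe) are partitioned and scored, and a same-sized
    random draw from the universe is partitioned and scored; replicate i
    of the real setting is paired with replicate i of the null at the
    same ratio. Degenerate scores (zero-variance profiles) are kept and
    flagged. All randomness flows from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    filtered = filter_to_universe(disease, collection.universe)
    m = len(filtered.genes)

    rows: list[dict] = []
    for ratio in config.ratios:
        for rep in range(config.reps_per_ratio):
            flags: list[str] = []
            real_parts = split_genes(filtered.genes, ratio, rng)
            real_score, f = _score_pair(*real_parts, collection, config.transform)
            flags += [f"real_{x}" for x in f]
            null_parts = null_split(collection.universe, m, ratio, rng)
            null_score, f = _score_pair(*null_parts, collection, config.transform)
            flags += [f"null_{x}" for x in f]
            rows.append(
                {
                    "ratio": ratio,
                    "rep": rep,
                    "real_score": real_score,
                    "null_score": null_score,
                    "flags": ";".join(flags),
                }
            )

    reps = pd.DataFrame(
        rows, columns=["ratio", "rep", "real_score", "null_score", "flags"]
    )
    if reps.empty:
        return SimulationResult(
            replicates=reps, summary={"error": "no replicates (reps_per_ratio = 0)"}
        )

    per_ratio = (
        reps.groupby("ratio")[["real_score", "null_score"]].mean().reset_index()
    )
    t_stat, p_val = stats.ttest_rel(reps["real_score"], reps["null_score"])
    summary = {
        "disease_id": disease.disease_id,
        "n_genes": m,
        "transform": config.transform,
        "seed": config.seed,
        "per_ratio_means": {
            float(r.ratio): {
                "real": float(r.real_score),
                "null": float(r.null_score),
            }
            for r in per_ratio.itertuples()
        },
        "mean_real": float(reps["real_score"].mean()),
        "mean_null": float(reps["null_score"].mean()),
        "paired_t": float(t_stat),
        "paired_t_p": float(p_val),
    }
    return SimulationResult(replicates=reps, summary=summary)
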