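"""Synthetic data generators for benchmarks and tests.

Everything downstream of this module is exercised on generated data
emulating the statistical structure of curated disease-gene resources
and claims-style diagnosis data:

* a gene universe and a collection of functional gene sets drawn from it;
* disease gene sets with *planted pathway coherence*: each disease draws
  most of its genes from a handful of driver functional sets, plus a
  background fraction from the rest of the universe. A pair sharing
  drivers but no genes is functionally comorbid yet invisible to any
  overlap-based measure;
* patient cohorts with planted relative risks, built so each disease's
  marginal prevalence is honoured exactly whatever the planted RR.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geneset_io import CohortTable, DiseaseGeneSet, GeneSet, GeneSetCollection

__all__ = [
    "SyntheticSpec",
    "make_collection",
    "make_disease_pair",
    "make_cohort",
    "conditional_outcome_rate",
    "make_no_overlap_benchmark",
]

PAIR_DESIGNS = (
    "shared_drivers_overlapping_genes",
    "shared_drivers_disjoint_genes",
    "independent",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs of the synthetic generators, with field-realistic defaults.

    Disease sizes default to 30-300 genes, the typical spread of curated
    disease gene sets; the background fraction models genes with no
    pathway coherence (noise annotations).
    """

    universe_size: int = 5000
    n_functional_sets: int = 50
    set_size_range: tuple[int, int] = (150, 300)
    n_driver_sets: int = 5
    background_fraction: float = 0.2
    disease_size_range: tuple[int, int] = (30, 300)
    overlap_fraction: float = 0.5  # planted gene sharing (overlapping design only)
    pair_design: str = "shared_drivers_disjoint_genes"
    n_samples: int = 50_000
    prevalence_range: tuple[float, float] = (0.05, 0.15)
    target_rr: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.universe_size < 1 or self.n_functional_sets < 1:
            raise ValueError("sizes must be positive")
        lo, hi = self.set_size_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid set_size_range")
        if hi > self.universe_size:
            raise ValueError(
                f"set_size_range max {hi} exceeds universe size {self.universe_size}"
            )
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background_fraction must lie in [0, 1)")
        if self.pair_design not in PAIR_DESIGNS:
            raise ValueError(f"unknown pair_design {self.pair_design!r}")
        if self.target_rr < 1.0:
            raise ValueError("target_rr must be >= 1")
        plo, phi = self.prevalence_range
        if not 0.0 < plo <= phi < 1.0:
            raise ValueError("prevalences must lie in (0, 1)")


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def make_collection(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> GeneSetCollection:
    """Generate a functional gene-set collection over a synthetic universe."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    universe = _gene_names(spec.universe_size)
    lo, hi = spec.set_size_range
    sets = []
    for i in range(spec.n_functional_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(spec.universe_size, size=size, replace=False)
        sets.append(
            GeneSet(
                name=f"FS{i:04d}",
                genes=frozenset(universe[j] for j in members),
                description="synthetic functional set",
            )
        )
    return GeneSetCollection.from_sets(
        sets, universe=universe, collection_id=f"synthetic_seed{spec.seed}"
    )


def _sample(rng: np.random.Generator, pool: list[str], k: int) -> set[str]:
    if k > len(pool):
        raise ValueError(f"cannot sample {k} genes from a pool of {len(pool)}")
    idx = rng.choice(len(pool), size=k, replace=False)
    return {pool[i] for i in idx}


def _compose_disease(
    rng: np.random.Generator,
    driver_pool: list[str],
    background_pool: list[str],
    size: int,
    background_fraction: float,
) -> set[str]:
    n_bg = int(round(background_fraction * size))
    n_drv = size - n_bg
    genes = _sample(rng, driver_pool, n_drv)
    genes |= _sample(rng, [g for g in background_pool if g not in genes], n_bg)
    return genes


def make_disease_pair(
    spec: SyntheticSpec,
    collection: GeneSetCollection,
    rng: np.random.Generator | None = None,
    pair_id: str = "pair",
) -> tuple[DiseaseGeneSet, DiseaseGeneSet]:
    """Generate a disease pair under the spec's pair design.

    ``shared_drivers_overlapping_genes``: both diseases draw from the
    same driver sets, and a planted fraction of B's driver genes is
    copied from A, so the pair shares genes *and* function.

    ``shared_drivers_disjoint_genes``: same driver sets, but B's genes
    are drawn excluding A's, so the gene sets are disjoint while the
    functional signal is shared — comorbidity invisible to overlap
    measures.

    ``independent``: disjoint driver sets; B additionally avoids A's
    literal genes so that overlap-based scores are exactly zero and any
    similarity must be spurious.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    if spec.n_driver_sets > len(collection):
        raise ValueError("more driver sets requested than the collection holds")
    universe = sorted(collection.universe)
    lo, hi = spec.disease_size_range
    size_a = int(rng.integers(lo, hi + 1))
    size_b = int(rng.integers(lo, hi + 1))

    set_idx = np.arange(len(collection))
    if spec.pair_design == "independent":
        chosen = rng.choice(set_idx, size=2 * spec.n_driver_sets, replace=False)
        drivers_a = [collection[i] for i in chosen[: spec.n_driver_sets]]
        drivers_b = [collection[i] for i in chosen[spec.n_driver_sets :]]
    else:
        chosen = rng.choice(set_idx, size=spec.n_driver_sets, replace=False)
        drivers_a = drivers_b = [collection[i] for i in chosen]

    pool_a = sorted(set().union(*(s.genes for s in drivers_a)))
    genes_a = _compose_disease(
        rng, pool_a, universe, size_a, spec.background_fraction
    )

    pool_b_all = sorted(set().union(*(s.genes for s in drivers_b)))
    if spec.pair_design == "shared_drivers_overlapping_genes":
        n_bg = int(round(spec.background_fraction * size_b))
        n_drv = size_b - n_bg
        n_shared = min(int(round(spec.overlap_fraction * n_drv)), len(genes_a & set(pool_b_all)))
        n_shared = max(n_shared, 1)
        shared = _sample(rng, sorted(genes_a & set(pool_b_all)), n_shared)
        fresh_pool = [g for g in pool_b_all if g not in shared]
        genes_b = shared | _sample(rng, fresh_pool, n_drv - n_shared)
        bg_pool = [g for g in universe if g not in genes_b]
        genes_b |= _sample(rng, bg_pool, n_bg)
    else:
        # disjoint designs: B never reuses a gene of A
        pool_b = [g for g in pool_b_all if g not in genes_a]
        bg_pool = [g for g in universe if g not in genes_a]
        n_bg = int(round(spec.background_fraction * size_b))
        n_drv = size_b - n_bg
        if n_drv > len(pool_b):
            raise ValueError(
                "driver sets too small to supply disjoint samples for both diseases"
            )
        genes_b = _sample(rng, pool_b, n_drv)
        genes_b |= _sample(rng, [g for g in bg_pool if g not in genes_b], n_bg)

    return (
        DiseaseGeneSet(disease_id=f"{pair_id}_A", genes=frozenset(genes_a)),
        DiseaseGeneSet(disease_id=f"{pair_id}_B", genes=frozenset(genes_b)),
    )


def conditional_outcome_rate(p_a: float, p_b: float, rr: float) -> float:
    """Baseline outcome rate q = P(B | A=0) that yields marginal
    prevalence p_b for disease B at the planted relative risk:
    q = p_b / (p_a * rr + 1 - p_a), with P(B | A=1) = rr * q."""
    q = p_b / (p_a * rr + 1.0 - p_a)
    if rr * q > 1.0:
        raise ValueError(
            f"infeasible RR: rr*q = {rr * q:.3f} > 1 for p_a={p_a}, p_b={p_b}, rr={rr}"
        )
    return q


def make_cohort(
    spec: SyntheticSpec,
    pair_labels: list[tuple[str, str, bool]],
    rng: np.random.Generator | None = None,
) -> CohortTable:
    """Simulate a diagnosis matrix with planted relative risks.

    ``pair_labels`` lists (disease_a, disease_b, comorbid) with every
    disease code appearing in exactly one pair. Comorbid pairs get the
    spec's target RR via the marginal-preserving construction of
    :func:`conditional_outcome_rate`; other pairs are drawn
    independently (true RR = 1). Prevalences are drawn uniformly from
    ``spec.prevalence_range`` per disease.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    seen: set[str] = set()
    for a, b, _ in pair_labels:
        for d in (a, b):
            if d in seen:
                raise ValueError(f"disease {d!r} appears in more than one pair")
            seen.add(d)

    n = spec.n_samples
    plo, phi = spec.prevalence_range
    columns: dict[str, np.ndarray] = {}
    for a, b, comorbid in pair_labels:
        p_a = float(rng.uniform(plo, phi))
        p_b = float(rng.uniform(plo, phi))
        status_a = rng.random(n) < p_a
        rr = spec.target_rr if comorbid else 1.0
        q = conditional_outcome_rate(p_a, p_b, rr)
        p_b_given_a = np.where(status_a, rr * q, q)
        status_b = rng.random(n) < p_b_given_a
        columns[a] = status_a.astype(np.int8)
        columns[b] = status_b.astype(np.int8)

    df = pd.DataFrame(columns, index=[f"S{i:06d}" for i in range(n)])
    return CohortTable(data=df)


def make_no_overlap_benchmark(
    spec: SyntheticSpec | None = None,
    n_pairs: int = 60,
    n_comorbid: int = 20,
    seed: int | None = None,
) -> tuple[GeneSetCollection, dict[str, DiseaseGeneSet], list[tuple[str, str]], np.ndarray]:
    """Benchmark of disease pairs that share no genes within any pair.

    ``n_comorbid`` pairs are built under the shared-drivers /
    disjoint-genes design (functionally comorbid, gene-disjoint); the
    remainder under the independent design (also gene-disjoint). By
    construction every overlap-based score is exactly zero, so only a
    functional measure can separate the two groups. Returns the
    collection, disease table, pair list, and 0/1 comorbidity labels.
    """
    if spec is None:
        spec = SyntheticSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    if not 0 < n_comorbid < n_pairs:
        raise ValueError("need 0 < n_comorbid < n_pairs")
    rng = np.random.default_rng(spec.seed)
    collection = make_collection(spec, rng)
    diseases: dict[str, DiseaseGeneSet] = {}
    pairs: list[tuple[str, str]] = []
    labels = np.zeros(n_pairs, dtype=int)
    for i in range(n_pairs):
        comorbid = i < n_comorbid
        design = "shared_drivers_disjoint_genes" if comorbid else "independent"
        pair_spec = replace(spec, pair_design=design)
        da, db = make_disease_pair(pair_spec, collection, rng, pair_id=f"D{i:03d}")
        diseases[da.disease_id] = da
        diseases[db.disease_id] = db
        pairs.append((da.disease_id, db.disease_id))
        labels[i] = int(comorbid)
    return collection, diseases, pairs, labels
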