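"""Over-representation analysis: the semantic profiling vector.

For one disease gene list and an ordered collection of n functional gene
sets, the semantic profile is the length-n vector of one-sided Fisher
exact (hypergeometric tail) p-values, one per functional set. The
position of each entry is fixed by the collection order, so profiles of
two diseases built on the same collection are directly comparable.

The profile stores raw p-values; a monotone transform (``exp``,
``identity`` or ``neglog10``) is applied at comparison time and recorded
as a tag, because the downstream similarity score is a Pearson
correlation of the transformed vectors and the choice of scale matters
for magnitudes even though it never changes rank order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import hypergeom

from .geneset_io import DiseaseGeneSet, GeneSetCollection, filter_to_universe

__all__ = [
    "P_FLOOR",
    "TRANSFORMS",
    "SemanticProfile",
    "fisher_ora_p",
    "profile",
    "transform_profile",
]

#: smallest reportable p-value; avoids exact zeros from extreme enrichment
P_FLOOR = 1e-320

TRANSFORMS = ("exp", "identity", "neglog10")


@dataclass(frozen=True)
class SemanticProfile:
    """ORA p-value vector of one disease over one functional collection."""

    collection_id: str
    disease_id: str
    set_names: tuple[str, ...]
    pvalues: np.ndarray  # raw p in (0, 1], index-aligned to set_names
    transform_tag: str = "identity"

    def __post_init__(self) -> None:
        object.__setattr__(self, "pvalues", np.asarray(self.pvalues, dtype=float))
        if self.pvalues.ndim != 1 or len(self.pvalues) != len(self.set_names):
            raise ValueError("pvalues must be 1-D and index-aligned to set_names")
        if np.any(self.pvalues <= 0) or np.any(self.pvalues > 1):
            raise ValueError("p-values must lie in (0, 1]")
        if self.transform_tag not in TRANSFORMS:
            raise ValueError(f"unknown transform tag {self.transform_tag!r}")

    def __len__(self) -> int:
        return len(self.pvalues)


def fisher_ora_p(
    list_genes: frozenset[str] | set[str],
    functional_set: frozenset[str] | set[str],
    universe: frozenset[str] | set[str],
) -> float:
    """One-sided over-representation p-value P(X >= k).

    k is the observed overlap between the query list and the functional
    set; X is hypergeometric with population size \\|universe\\|, \\|set\\|
    successes, and \\|list\\| draws. This is the right tail of Fisher's
    exact test on the 2x2 in-list/in-set table: only enrichment, never
    depletion, yields a small p.

    Degenerate inputs (empty list or empty set after restriction to the
    universe) return 1.0: no evidence either way.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    n_universe = len(universe)
    n_set = len(frozenset(functional_set) & frozenset(universe))
    drawn = frozenset(list_genes) & frozenset(universe)
    n_list = len(drawn)
    if n_list == 0 or n_set == 0:
        return 1.0
    k = len(drawn & frozenset(functional_set))
    if k == 0:
        return 1.0
    # survival function at k-1 gives P(X >= k); scipy evaluates the tail
    # stably in log space internally, we only guard the final underflow
    p = float(hypergeom.sf(k - 1, n_universe, n_set, n_list))
    return float(min(max(p, P_FLOOR), 1.0))


def profile(
    disease: DiseaseGeneSet, collection: GeneSetCollection
) -> SemanticProfile:
    """Semantic profiling vector of a disease gene list.

    Disease genes outside the collection's universe are dropped first;
    an empty result raises because no enrichment table can be formed.
    The returned profile holds raw (untransformed) p-values.
    """
    filtered = filter_to_universe(disease, collection.universe)
    pvals = np.array(
        [
            fisher_ora_p(filtered.genes, s.genes, collection.universe)
            for s in collection
        ],
        dtype=float,
    )
    return SemanticProfile(
        collection_id=collection.collection_id,
        disease_id=disease.disease_id,
        set_names=collection.names,
        pvalues=pvals,
        transform_tag="identity",
    )


def transform_profile(
    values: SemanticProfile | np.ndarray, mode: str = "exp"
) -> np.ndarray:
    """Apply a monotone transform to a p-value vector.

    ``exp``      elementwise e**p (the default scale for the similarity
                 score); ``identity`` leaves p as is; ``neglog10`` maps p
                 to -log10(max(p, 1e-320)), the conventional significance
                 scale, useful when p-values span many orders of magnitude.
    All three are strictly increasing or decreasing, so profile rank
    order is preserved in absolute value.
    """
    if mode not in TRANSFORMS:
        raise ValueError(f"unknown transform mode {mode!r}; expected one of {TRANSFORMS}")
    arr = values.pvalues if isinstance(values, SemanticProfile) else np.asarray(values, dtype=float)
    if mode == "identity":
        return arr.copy()
    if mode == "exp":
        return np.exp(arr)
    return -np.log10(np.maximum(arr, P_FLOOR))
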