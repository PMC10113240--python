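"""Per-sample gene-set over-representation and cross-sample recurrence.

For each sample, the genes carrying at least one deleterious point
mutation are tested against every set of a collection with a one-sided
hypergeometric test; p-values are Benjamini-Hochberg adjusted across the
sets of that sample (reported as ``q``). Terms with q below a cutoff in
at least a given fraction of samples (excluded samples removed from both
numerator and denominator, ceiling rule) form the recurrent shortlist.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .types import GeneSetCollection


@dataclass
class EnrichmentResult:
    """One sample's over-representation table.

    ``table`` columns: set_name, k (mutated genes in set), K (set size in
    background), n (mutated genes in background), N (background size),
    p, q.
    """

    sample_id: str
    table: pd.DataFrame

    def significant_sets(self, q_cut: float = 0.2) -> set[str]:
        return set(self.table.loc[self.table["q"] < q_cut, "set_name"])


def overrepresentation(
    mutated_genes: set[str],
    collection: GeneSetCollection,
    sample_id: str = "",
) -> EnrichmentResult:
    """One-sided hypergeometric over-representation against every set."""
    if not mutated_genes:
        raise ValueError("mutated gene set is empty")
    background = collection.effective_background()
    bg = set(background)
    outside = mutated_genes - bg
    if outside:
        warnings.warn(
            f"{len(outside)} mutated gene(s) absent from background dropped",
            stacklevel=2,
        )
    mutated = mutated_genes & bg
    n_total = len(bg)
    n_mut = len(mutated)
    rows = []
    for name, genes in collection.sets.items():
        members = set(genes) & bg
        k = len(mutated & members)
        big_k = len(members)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, n_total, big_k, n_mut))
        rows.append(
            {"set_name": name, "k": k, "K": big_k, "n": n_mut, "N": n_total, "p": p}
        )
    table = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p"])
    table["q"] = bh_adjust(table["p"].to_numpy()).clip(max=1.0)
    return EnrichmentResult(sample_id=sample_id, table=table)


def recurrent_terms(
    results: list[EnrichmentResult],
    q_cut: float = 0.2,
    recurrence: float = 0.20,
    excluded_samples: list[str] | tuple[str, ...] = (),
) -> pd.DataFrame:
    """Shortlist terms enriched (q < q_cut) in >= ceil(recurrence * n) of
    the non-excluded samples.

    Returns a table with per-term support counts and the retained flag.
    """
    excluded = set(excluded_samples)
    included = [r for r in results if r.sample_id not in excluded]
    if not included:
        raise ValueError("all samples excluded; recurrence undefined")
    n_included = len(included)
    threshold = math.ceil(recurrence * n_included)
    counts: dict[str, int] = {}
    all_terms: dict[str, None] = {}
    for res in included:
        for term in res.table["set_name"]:
            all_terms.setdefault(term)
        for term in res.significant_sets(q_cut):
            counts[term] = counts.get(term, 0) + 1
    rows = [
        {
            "set_name": term,
            "n_significant": counts.get(term, 0),
            "n_included": n_included,
            "retained": counts.get(term, 0) >= threshold,
        }
        for term in all_terms
    ]
    return pd.DataFrame(rows, columns=["set_name", "n_significant", "n_included", "retained"])
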