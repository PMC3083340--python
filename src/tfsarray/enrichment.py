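"""Gene-set over-representation per TFS group, with clustering of results.

Each TFS group of genes is intersected with every gene set of a collection
(GO terms, transcription-factor motif target sets, miRNA target sets).  With
universe size N, group size m, set size K (within the universe) and overlap
k, the over-representation p-value is the upper hypergeometric tail
P(X >= k) — the one-sided Fisher's exact test — and the enrichment score is
the fold enrichment (k/m)/(K/N), observed over expected overlap.  No
multiple-testing correction is applied across sets; instead the selection
filter keeps sets reaching p < 0.001 with more than 5 overlapping genes in
at least one group (a stricter display preset, p < 0.0001 and > 10 genes,
mirrors heat-map-level filtering).  Selected -log10 p matrices are ordered
by average-linkage hierarchical clustering on correlation distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import hypergeom

#: default selection filter: p < 0.001 and overlap > 5 genes
DEFAULT_P_CUT = 1e-3
DEFAULT_MIN_GENES = 5
#: stricter display-level preset: p < 0.0001 and overlap > 10 genes
DISPLAY_P_CUT = 1e-4
DISPLAY_MIN_GENES = 10


@dataclass(frozen=True)
class EnrichmentRecord:
    """Overlap of one TFS group with one gene set."""

    tfs_group: str
    set_name: str
    k: int       # overlap
    m: int       # group size
    K: int       # set size within the universe
    N: int       # universe size
    score: float  # fold enrichment (k/m)/(K/N); 0 when k == 0
    p: float      # one-sided Fisher / hypergeometric upper tail


def hypergeom_tail(k, m, K, N):
    """Upper-tail hypergeometric probability P(X >= k).

    X counts white balls in m draws without replacement from an urn of N
    balls of which K are white.  Accepts scalars or numpy arrays.
    """
    return hypergeom.sf(np.asarray(k) - 1, N, K, m)


def fisher_enrichment(
    group_genes: Iterable[str],
    gene_set,
    universe: Iterable[str],
    tfs_group: str = "",
) -> EnrichmentRecord:
    """One-sided Fisher's exact over-representation of ``gene_set`` in a group.

    The gene set is intersected with the universe before testing; the group
    must be a subset of the universe.  k = 0 yields score 0 and p = 1.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    group = frozenset(group_genes)
    if not group <= universe:
        extra = sorted(group - universe)[:3]
        raise ValueError(f"group genes not in universe, e.g. {extra}")
    members = gene_set.members & universe
    k = len(group & members)
    m, K, N = len(group), len(members), len(universe)
    if k == 0:
        score, p = 0.0, 1.0
    else:
        score = (k / m) / (K / N)
        p = float(min(hypergeom_tail(k, m, K, N), 1.0))
    return EnrichmentRecord(tfs_group, gene_set.name, k, m, K, N, score, p)


def enrich_groups(
    groups: Mapping[str, Iterable[str]],
    collection: Sequence,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Enrichment records for every (TFS group, gene set) pair of a collection."""
    universe = frozenset(universe)
    rows = []
    for group_name in sorted(groups):
        genes = frozenset(groups[group_name])
        for gene_set in collection:
            rec = fisher_enrichment(genes, gene_set, universe, tfs_group=group_name)
            rows.append(rec.__dict__)
    columns = ["tfs_group", "set_name", "k", "m", "K", "N", "score", "p"]
    return pd.DataFrame(rows, columns=columns)


@dataclass
class EnrichmentSelection:
    """Sets/groups surviving the enrichment filter, and their record matrix."""

    records: pd.DataFrame     # records restricted to kept sets x kept groups
    kept_sets: list[str]
    kept_groups: list[str]

    def matrix(self) -> pd.DataFrame:
        """-log10 p matrix, rows = kept sets, columns = kept groups."""
        if not self.kept_sets or not self.kept_groups:
            return pd.DataFrame(index=self.kept_sets, columns=self.kept_groups, dtype=float)
        wide = self.records.pivot(index="set_name", columns="tfs_group", values="p")
        wide = wide.reindex(index=self.kept_sets, columns=self.kept_groups)
        return -np.log10(wide.fillna(1.0))


def select_enriched(
    records: pd.DataFrame,
    p_cut: float = DEFAULT_P_CUT,
    min_genes: int = DEFAULT_MIN_GENES,
) -> EnrichmentSelection:
    """Apply the enrichment selection filter.

    A set is kept if in at least one TFS group it reaches p < ``p_cut`` with
    an overlap of more than ``min_genes`` genes (both strict); a group is
    kept if at least one kept set is enriched in it by the same rule.
    """
    hit = (records["p"] < p_cut) & (records["k"] > min_genes)
    kept_sets = sorted(records.loc[hit, "set_name"].unique())
    kept_groups = sorted(
        records.loc[hit & records["set_name"].isin(kept_sets), "tfs_group"].unique()
    )
    sub = records[
        records["set_name"].isin(kept_sets) & records["tfs_group"].isin(kept_groups)
    ].reset_index(drop=True)
    return EnrichmentSelection(sub, kept_sets, kept_groups)


def _correlation_distance(mat: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance over rows, safe for constant rows."""
    centered = mat - mat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    n = mat.shape[0]
    out = np.empty(n * (n - 1) // 2)
    idx = 0
    for i in range(n):
        for j in range(i + 1, n):
            if norms[i] == 0.0 and norms[j] == 0.0:
                d = 0.0 if np.array_equal(mat[i], mat[j]) else 1.0
            elif norms[i] == 0.0 or norms[j] == 0.0:
                d = 1.0
            else:
                d = 1.0 - float(centered[i] @ centered[j]) / (norms[i] * norms[j])
            out[idx] = max(d, 0.0)
            idx += 1
    return out


@dataclass
class ClusteredMatrix:
    """A matrix with row/column leaf orderings from hierarchical clustering."""

    matrix: pd.DataFrame      # reordered
    row_order: list
    col_order: list
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None


def cluster_matrix(matrix: pd.DataFrame) -> ClusteredMatrix:
    """Average-linkage clustering of rows and columns on correlation distance.

    Matrices smaller than 2x2 pass through in input order.  Deterministic
    for fixed input (scipy's linkage has no random component; ties resolve
    by input order).
    """
    values = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("matrix contains non-finite cells")
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        return ClusteredMatrix(
            matrix.copy(), list(matrix.index), list(matrix.columns), None, None
        )
    row_link = hierarchy.linkage(_correlation_distance(values), method="average")
    col_link = hierarchy.linkage(_correlation_distance(values.T), method="average")
    row_order = [matrix.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [matrix.columns[i] for i in hierarchy.leaves_list(col_link)]
    return ClusteredMatrix(
        matrix.loc[row_order, col_order], row_order, col_order, row_link, col_link
    )


def run_collections(
    groups: Mapping[str, Iterable[str]],
    collections: Mapping[str, Sequence],
    universe: Iterable[str],
    p_cut: float = DEFAULT_P_CUT,
    min_genes: int = DEFAULT_MIN_GENES,
) -> dict[str, dict]:
    """Enrich every TFS group against every collection (GO / motif / miRNA).

    Returns per collection: the full record table, the filtered selection,
    and the clustered -log10 p matrix.  Warns when the universe overlaps the
    union of a collection's sets by less than 50% (identifier-space
    mismatch).
    """
    universe = frozenset(universe)
    out: dict[str, dict] = {}
    for name in collections:
        collection = collections[name]
        union: set[str] = set()
        for s in collection:
            union |= s.members
        if union and len(universe & union) < 0.5 * len(universe):
            warnings.warn(
                f"collection {name!r}: only {len(universe & union)}/{len(universe)} "
                "universe genes appear in its sets; identifier spaces may not match",
                stacklevel=2,
            )
        records = enrich_groups(groups, collection, universe)
        selection = select_enriched(records, p_cut=p_cut, min_genes=min_genes)
        clustered = cluster_matrix(selection.matrix()) if len(selection.kept_sets) else None
        out[name] = {
            "records": records,
            "selection": selection,
            "clustered": clustered,
        }
    return out
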