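"""Operon co-occurrence analysis of co-gained and co-lost tRNA pairs.

If two tRNA species were gained together through the transfer of an operon,
organisms descending from the co-gain node are expected to retain an operon
containing genes of both species; for co-losses, the signal is sought in the
nearest neighbors (tips descending from the parent of the co-loss branch but
not from the co-loss branch itself). Organisms without operon annotation are
excluded from denominators rather than counted as negatives, and "shared
operon" requires both genes under the same operon id.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .phylo import TreeIndex


@dataclass
class OperonMap:
    """Mapping (organism, gene id) -> operon id; unannotated genes absent."""

    assignments: dict

    @classmethod
    def from_tsv(cls, path) -> "OperonMap":
        df = pd.read_csv(Path(path), sep="\t",
                         names=["organism", "operon_id", "gene_id"], header=None,
                         comment="#", dtype=str)
        if list(df.iloc[0]) == ["organism", "operon_id", "gene_id"]:
            df = df.iloc[1:]
        return cls({(r.organism, r.gene_id): r.operon_id for r in df.itertuples()})

    def to_tsv(self, path) -> None:
        rows = [(org, op, gid) for (org, gid), op in sorted(self.assignments.items())]
        pd.DataFrame(rows, columns=["organism", "operon_id", "gene_id"]).to_csv(
            path, sep="\t", index=False)

    def operon_of(self, organism: str, gene_id: str):
        return self.assignments.get((organism, gene_id))

    def organisms_with_data(self) -> set:
        return {org for org, _ in self.assignments}


def _shared_operon(organism: str, genes_a: list[str], genes_b: list[str],
                   operons: OperonMap) -> tuple[bool, bool]:
    """(has data for both species, shares an operon) for one organism."""
    ops_a = {operons.operon_of(organism, g) for g in genes_a} - {None}
    ops_b = {operons.operon_of(organism, g) for g in genes_b} - {None}
    return bool(ops_a and ops_b), bool(ops_a & ops_b)


def _pair_counts(organisms, pair, matrix, gene_index, operons):
    """Counts (with both species, with operon data for both, sharing an
    operon) over a set of organisms."""
    a, b = pair
    col_a = dict(zip(matrix.organisms, matrix.values[:, matrix.species.index(a)]))
    col_b = dict(zip(matrix.organisms, matrix.values[:, matrix.species.index(b)]))
    n_both = n_data = n_shared = 0
    for org in organisms:
        if not (col_a.get(org, 0) and col_b.get(org, 0)):
            continue
        n_both += 1
        has_data, shared = _shared_operon(org, gene_index.get((org, a), []),
                                          gene_index.get((org, b), []), operons)
        if has_data:
            n_data += 1
            if shared:
                n_shared += 1
    return n_both, n_data, n_shared


def build_gene_index(gene_db) -> dict:
    """(organism, anticodon) -> gene ids, from a list of TrnaGene records."""
    out: dict = {}
    for g in gene_db:
        out.setdefault((g.organism, g.anticodon), []).append(g.gene_id)
    return out


def cogain_operon_counts(pair, cogain_nodes, tree, matrix, operons: OperonMap,
                         gene_index: dict) -> dict:
    """Operon co-occurrence among descendants of co-gain nodes vs background.

    Returns counts (organisms with both species / with operon data for both /
    with a shared operon) for descendants of any co-gain node and for all
    other organisms.
    """
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    descendants: set = set()
    for node in cogain_nodes:
        descendants.update(idx.descendant_tips(int(node)))
    background = [o for o in matrix.organisms if o not in descendants]
    d = _pair_counts(sorted(descendants), pair, matrix, gene_index, operons)
    b = _pair_counts(background, pair, matrix, gene_index, operons)
    return dict(pair=pair, n_cogain_nodes=len(list(cogain_nodes)),
                descendants_both=d[0], descendants_with_data=d[1], descendants_shared=d[2],
                background_both=b[0], background_with_data=b[1], background_shared=b[2])


def coloss_neighbor_counts(pair, coloss_nodes, tree, matrix, operons: OperonMap,
                           gene_index: dict) -> dict:
    """Operon co-occurrence among nearest neighbors of co-loss nodes.

    Nearest neighbors descend from the parent of the co-loss branch but not
    from the co-loss branch itself; a co-loss on the root branch has no
    neighbors and is skipped with a warning entry in the result.
    """
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    neighbors: set = set()
    skipped = []
    for node in coloss_nodes:
        node = int(node)
        parent = idx.parent[node]
        if parent < 0:
            skipped.append(node)
            continue
        below_event = set(idx.descendant_tips(node))
        neighbors.update(t for t in idx.descendant_tips(parent) if t not in below_event)
    background = [o for o in matrix.organisms if o not in neighbors]
    n = _pair_counts(sorted(neighbors), pair, matrix, gene_index, operons)
    b = _pair_counts(background, pair, matrix, gene_index, operons)
    return dict(pair=pair, n_coloss_nodes=len(list(coloss_nodes)), skipped_root_events=skipped,
                neighbors_both=n[0], neighbors_with_data=n[1], neighbors_shared=n[2],
                background_both=b[0], background_with_data=b[1], background_shared=b[2])


def operon_coverage(operons: OperonMap, reps) -> pd.DataFrame:
    """Per organism: fraction of tRNA genes with operon annotation and
    fraction of annotated genes sharing an operon with another tRNA gene."""
    rows = []
    for rep in reps:
        total = len(rep.genes)
        annotated = []
        for gene_id, *_ in rep.genes:
            op = operons.operon_of(rep.organism_id, gene_id)
            if op is not None:
                annotated.append(op)
        coverage = len(annotated) / total if total else float("nan")
        if annotated:
            counts = pd.Series(annotated).value_counts()
            co_genes = int(counts[counts > 1].sum())
            co_frac = co_genes / len(annotated)
        else:
            co_frac = float("nan")
        rows.append(dict(organism=rep.organism_id, n_genes=total,
                         coverage=coverage, co_operonic_fraction=co_frac))
    return pd.DataFrame(rows, columns=["organism", "n_genes", "coverage",
                                       "co_operonic_fraction"])
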