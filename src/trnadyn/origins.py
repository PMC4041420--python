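"""Origin of newly gained tRNA genes.

Most recent gain events (MRGEs) are called gain events with no further gain
of the same species below them in the tree. Genes descending from an MRGE
are compared against the full tRNA gene database by local alignment
(match +1, mismatch -3, gap open -5, gap extension -2, both strands); hits
scoring at least 80% of the query's self-score (boundary inclusive) are kept
and classified as vertical inheritance (same anticodon, same MRGE descent)
or non-vertical, the latter split into scenarios: horizontal transfer of the
same species, horizontal transfer followed by an anticodon mutation,
ortholog anticodon mutation in closely related organisms, and gene
duplication followed by anticodon mutation within one organism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .genetic_code import normalize_rna, reverse_complement
from .phylo import TreeIndex

VERTICAL = "vertical"
NON_VERTICAL = "non_vertical"

HGT_SAME_ANTICODON = "hgt_same_anticodon"
HGT_PLUS_MUTATION = "hgt_plus_mutation"
ORTHOLOG_MUTATION = "ortholog_mutation"
DUPLICATION_MUTATION = "duplication_mutation"
UNCLASSIFIED = "unclassified"

SELF_SCORE_FRACTION = 0.8


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


_ALIGNER = _make_aligner()


def align_score(a: str, b: str, both_strands: bool = True) -> float:
    """Best local-alignment score between two tRNA gene sequences
    (+1 match, -3 mismatch, gaps -5 first position and -2 thereafter);
    the reverse complement of ``b`` is also scanned by default."""
    a, b = normalize_rna(a), normalize_rna(b)
    if not a or not b:
        raise ValueError("empty sequence")
    score = _ALIGNER.score(a, b)
    if both_strands:
        score = max(score, _ALIGNER.score(a, reverse_complement(b)))
    return float(score)


@dataclass(frozen=True)
class TrnaGene:
    """One tRNA gene of the database: organism, id, anticodon, sequence."""

    organism: str
    gene_id: str
    anticodon: str
    sequence: str


@dataclass
class MRGE:
    """A most recent gain event of one tRNA species."""

    species: str
    node: int
    descendant_organisms: list[str] = field(default_factory=list)
    descendant_genes: list[str] = field(default_factory=list)


def find_mrges(events, tree, matrix, gene_db: list[TrnaGene] | None = None) -> list[MRGE]:
    """Gain events with no other gain of the same species strictly below them.

    Descendant organisms are the tips below the gain node that retain the
    species; when a gene database is supplied their gene ids are collected.
    """
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    gains = events[events["event"] == "gain"]
    genes_of = {}
    if gene_db is not None:
        for g in gene_db:
            genes_of.setdefault((g.organism, g.anticodon), []).append(g.gene_id)
    out = []
    for species, grp in gains.groupby("species"):
        nodes = sorted(grp["node"])
        s_col = dict(zip(matrix.organisms,
                         matrix.values[:, matrix.species.index(species)]))
        for u in nodes:
            if any(v != u and idx.is_ancestor(u, v) for v in nodes):
                continue  # a later gain of the same species lies below u
            descendants = [lab for lab in idx.descendant_tips(u) if s_col.get(lab, 0) == 1]
            genes = [gid for lab in descendants for gid in genes_of.get((lab, species), [])]
            out.append(MRGE(species, int(u), descendants, genes))
    return out


@dataclass
class SimilarityHit:
    """A database hit scoring at least 80% of the query's self-score."""

    query: str
    subject: str
    score: float
    self_score: float
    subject_anticodon: str
    subject_organism: str
    category: str
    query_organism: str | None = None
    scenario: str = UNCLASSIFIED


def _mrge_of_gene(mrges: list[MRGE]) -> dict[str, int]:
    """gene id -> index of the MRGE whose descent it belongs to."""
    out = {}
    for k, m in enumerate(mrges):
        for gid in m.descendant_genes:
            out[gid] = k
    return out


def search_similar(mrge: MRGE, gene_db: list[TrnaGene], mrges: list[MRGE],
                   threshold: float = SELF_SCORE_FRACTION) -> list[SimilarityHit]:
    """Query every descendant gene of an MRGE against the full database.

    Hits below ``threshold`` x self-score are dropped; per query, the
    best-scoring hit is retained in each category (vertical / non-vertical),
    ties broken by lexicographic subject gene id.
    """
    by_id = {g.gene_id: g for g in gene_db}
    membership = _mrge_of_gene(mrges)
    my_idx = mrges.index(mrge)
    hits: list[SimilarityHit] = []
    for qid in mrge.descendant_genes:
        q = by_id.get(qid)
        if q is None or not q.sequence:
            warnings.warn(f"descendant gene {qid} has no sequence; skipped")
            continue
        self_score = align_score(q.sequence, q.sequence, both_strands=False)
        best: dict[str, SimilarityHit] = {}
        for subj in gene_db:
            if subj.gene_id == qid:
                continue
            score = align_score(q.sequence, subj.sequence)
            if score < threshold * self_score:
                continue
            same_mrge = membership.get(subj.gene_id) == my_idx
            category = VERTICAL if (subj.anticodon == mrge.species and same_mrge) else NON_VERTICAL
            hit = SimilarityHit(qid, subj.gene_id, score, self_score,
                                subj.anticodon, subj.organism, category,
                                query_organism=q.organism)
            cur = best.get(category)
            if cur is None or score > cur.score or (score == cur.score
                                                   and hit.subject < cur.subject):
                best[category] = hit
        hits.extend(best.values())
    return hits


def classify_hit(hit: SimilarityHit, mrge: MRGE, tree,
                 distance_quantile: float = 0.9,
                 patristic: np.ndarray | None = None) -> str:
    """Scenario of a non-vertical hit.

    Same anticodon but different MRGE descent suggests horizontal transfer of
    the species; a different anticodon points to an anticodon mutation, with
    the context deciding between duplication (same organism), transfer plus
    mutation (distant organisms, patristic distance above the
    ``distance_quantile`` quantile of all pairwise tip distances) and an
    ortholog mutation in close relatives.
    """
    if hit.category == VERTICAL:
        return VERTICAL
    if hit.subject_anticodon == mrge.species:
        return HGT_SAME_ANTICODON
    query_org = hit.query_organism
    if query_org is None and "|" in hit.query:
        query_org = hit.query.split("|")[0]
    if query_org is not None and hit.subject_organism == query_org:
        return DUPLICATION_MUTATION
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    if patristic is None:
        patristic = idx.patristic_matrix()
    labels = idx.tip_labels
    if query_org in labels and hit.subject_organism in labels:
        i, j = labels.index(query_org), labels.index(hit.subject_organism)
        cutoff = np.quantile(patristic[np.triu_indices(len(labels), 1)], distance_quantile)
        return HGT_PLUS_MUTATION if patristic[i, j] >= cutoff else ORTHOLOG_MUTATION
    return UNCLASSIFIED


def classify_mrge_hits(mrges: list[MRGE], gene_db: list[TrnaGene], tree,
                       threshold: float = SELF_SCORE_FRACTION) -> list[SimilarityHit]:
    """Run the full origin pipeline: similarity search for every MRGE and
    scenario classification of each retained hit."""
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    patristic = idx.patristic_matrix()
    out = []
    for m in mrges:
        for hit in search_similar(m, gene_db, mrges, threshold):
            hit.scenario = classify_hit(hit, m, idx, patristic=patristic)
            out.append(hit)
    return out


def flanking_support(flank_a: tuple[str, str] | None,
                     flank_b: tuple[str, str] | None):
    """Ungapped identity fraction of the (upstream, downstream) flanks of two
    genes, reported per flank; None when flanks are unavailable (the
    duplication call stands without support)."""
    if flank_a is None or flank_b is None:
        return None

    def identity(x: str, y: str) -> float:
        x, y = normalize_rna(x), normalize_rna(y)
        n = min(len(x), len(y))
        if n == 0:
            raise ValueError("empty flank")
        return sum(a == b for a, b in zip(x[:n], y[:n])) / n

    return identity(flank_a[0], flank_b[0]), identity(flank_a[1], flank_b[1])
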