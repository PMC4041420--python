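"""Codon-bias and genomic-trait statistics.

Implements Wright's effective number of codons (ENC), its
background-composition-corrected variant ENC', the organism-level
translational-selection proxy ENC'_diff, GC content, the usage-shift and
variability statistics of presence/absence profiles, and Hamming clustering
of tRNA species profiles.

ENC summarizes how evenly a gene uses synonymous codons: 20 when exactly one
codon per amino acid is used, 61 when all synonymous codons are used evenly.
ENC' replaces the equal-usage null by the usage expected from the gene's own
nucleotide composition, so a gene whose codon usage merely reflects its
composition scores 61 and only composition-independent bias lowers the value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import mannwhitneyu

from .genetic_code import FAMILIES, SENSE_CODONS, normalize_rna

_SENSE = set(SENSE_CODONS)


def gc_content(sequence: str) -> float:
    """(G+C) / (A+C+G+T/U); ambiguity codes are ignored on both sides."""
    seq = normalize_rna(sequence)
    counts = {b: seq.count(b) for b in "ACGU"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("sequence contains no unambiguous nucleotides")
    return (counts["G"] + counts["C"]) / denom


@dataclass
class CodonCounts:
    """Sense-codon counts of one gene plus its background nucleotide frequencies."""

    counts: dict[str, int]
    background: dict[str, float]

    def __post_init__(self):
        bad = set(self.counts) - _SENSE
        if bad:
            raise ValueError(f"non-sense codons in counts: {sorted(bad)}")
        total = sum(self.background.get(b, 0.0) for b in "ACGU")
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError("background frequencies must sum to 1")

    @classmethod
    def from_sequence(cls, seq: str) -> "CodonCounts":
        """Count sense codons of an in-frame coding sequence; background from
        the same sequence's nucleotides."""
        s = normalize_rna(seq)
        counts: dict[str, int] = {}
        for i in range(0, len(s) - len(s) % 3, 3):
            codon = s[i:i + 3]
            if codon in _SENSE:
                counts[codon] = counts.get(codon, 0) + 1
        nt = {b: s.count(b) for b in "ACGU"}
        denom = sum(nt.values())
        if denom == 0:
            raise ValueError("empty sequence")
        background = {b: nt[b] / denom for b in "ACGU"}
        return cls(counts, background)

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())


# class weights of Wright's formula: ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6
_CLASS_WEIGHTS = {2: 9, 3: 1, 4: 5, 6: 3}


def _family_props(counts: CodonCounts, codons: tuple[str, ...]):
    n_vec = np.array([counts.counts.get(c, 0) for c in codons], dtype=float)
    n = n_vec.sum()
    return n_vec, n


def _wright_F(counts: CodonCounts, codons: tuple[str, ...]) -> float | None:
    """Wright's codon homozygosity F = (n*sum p^2 - 1)/(n - 1); None when
    undefined (n < 2 or F <= 0)."""
    n_vec, n = _family_props(counts, codons)
    if n < 2:
        return None
    p = n_vec / n
    f = (n * (p ** 2).sum() - 1) / (n - 1)
    return f if f > 0 else None


def _expected_family_freqs(codons: tuple[str, ...], background: dict[str, float]) -> np.ndarray:
    """Expected within-family codon frequencies: proportional to the product
    of background nucleotide frequencies over the codon positions, normalized
    within the synonymous family (for 2-/4-fold families this is the
    third-position background; for 6-fold families the subfamily split is
    weighted by the differing positions as well)."""
    w = np.array([np.prod([background[b] for b in codon]) for codon in codons])
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate background composition for family " + "/".join(codons))
    return w / total


def _chisq_F(counts: CodonCounts, codons: tuple[str, ...]) -> float | None:
    """Background-corrected homozygosity F = (X^2 + n - m) / (m (n - 1))."""
    n_vec, n = _family_props(counts, codons)
    if n < 2:
        return None
    m = len(codons)
    e = _expected_family_freqs(codons, counts.background)
    p = n_vec / n
    if ((e == 0) & (p > 0)).any():
        raise ValueError("observed codon with zero expected frequency (degenerate background)")
    keep = e > 0
    x2 = n * (((p[keep] - e[keep]) ** 2) / e[keep]).sum()
    f = (x2 + n - m) / (m * (n - 1))
    return f if f > 0 else None


def _enc_from_F(class_means: dict[int, float]) -> float:
    observed = {m: f for m, f in class_means.items() if f is not None}
    if not observed:
        raise ValueError("no usable synonymous family in gene")
    filled = dict(class_means)
    # Wright's conventions for missing classes: F3 (Ile only) from the 2- and
    # 4-fold neighbours when both exist, otherwise the mean of observed class means.
    for m in _CLASS_WEIGHTS:
        if filled.get(m) is None:
            if m == 3 and class_means.get(2) and class_means.get(4):
                filled[m] = (class_means[2] + class_means[4]) / 2
            else:
                filled[m] = float(np.mean(list(observed.values())))
    enc_val = 2 + sum(w / filled[m] for m, w in _CLASS_WEIGHTS.items())
    return min(enc_val, 61.0)


def _enc_generic(counts: CodonCounts, family_F) -> float:
    class_F: dict[int, list[float]] = {m: [] for m in _CLASS_WEIGHTS}
    for aa, codons in FAMILIES.items():
        m = len(codons)
        if m == 1:
            continue
        f = family_F(counts, codons)
        if f is not None:
            class_F[m].append(f)
    class_means = {m: (float(np.mean(v)) if v else None) for m, v in class_F.items()}
    return _enc_from_F(class_means)


def enc(counts: CodonCounts) -> float:
    """Wright's effective number of codons of one gene, in [20, 61]."""
    return _enc_generic(counts, _wright_F)


def enc_prime(counts: CodonCounts) -> float:
    """Background-corrected effective number of codons (chi-square
    homozygosity against the expectation implied by the gene's own nucleotide
    composition). Equals 61 when codon usage matches the background
    expectation."""
    return _enc_generic(counts, _chisq_F)


def enc_diff(gene_encs: list[tuple[float, bool]]) -> float:
    """Translational-selection proxy:
    (mean ENC' of all genes - mean ENC' of ribosomal genes) / mean of all.

    ``gene_encs`` holds (enc_prime, is_ribosomal) per gene. Stronger codon
    bias in the highly expressed ribosomal genes gives larger values.
    """
    if not gene_encs:
        raise ValueError("no genes")
    all_vals = np.array([v for v, _ in gene_encs], dtype=float)
    ribo = np.array([v for v, is_r in gene_encs if is_r], dtype=float)
    if ribo.size == 0:
        raise ValueError("no ribosomal genes")
    mean_all = all_vals.mean()
    return (mean_all - ribo.mean()) / mean_all


def nearest_rank_percentile(values, p: float) -> float:
    """Nearest-rank percentile: the ceil(p/100 * n)-th order statistic."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty sample")
    k = max(1, math.ceil(p / 100 * v.size))
    return float(v[k - 1])


def _mann_whitney(a, b) -> float:
    """Two-sided Mann-Whitney p: exact null when min group <= 8 (and no ties
    prevent it), otherwise normal approximation with tie correction."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    method = "exact" if min(a.size, b.size) <= 8 else "asymptotic"
    try:
        return float(mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
    except ValueError:
        return float(mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)


def usage_shift(presence_column, gc_by_organism, alpha: float = 0.05):
    """GC content at which a tRNA species tends to appear.

    Splits organisms into absent/present groups, tests their GC distributions
    (two-sided Mann-Whitney) and, when significant at ``alpha``, returns the
    mean of the absent group's 75th and the present group's 25th nearest-rank
    percentiles. Returns ``(shift or None, p-value or None)``; with an empty
    group, no test is performed.
    """
    pres = np.asarray(presence_column, dtype=int)
    gc = np.asarray(gc_by_organism, dtype=float)
    absent, present = gc[pres == 0], gc[pres == 1]
    if absent.size == 0 or present.size == 0:
        return None, None
    p = _mann_whitney(absent, present)
    if p >= alpha:
        return None, p
    shift = (nearest_rank_percentile(absent, 75) + nearest_rank_percentile(present, 25)) / 2
    return shift, p


def variability_measure(presence_column) -> float:
    """max(% organisms possessing, % organisms lacking), in [50, 100]."""
    pres = np.asarray(presence_column, dtype=int)
    if pres.size == 0:
        raise ValueError("empty presence column")
    frac = pres.mean()
    return 100 * max(frac, 1 - frac)


def hamming_cluster(matrix, gc_by_organism=None):
    """Cluster tRNA species by Hamming distance between presence profiles.

    Distances count profile differences; agglomeration uses average linkage.
    Returns ``(species_order, linkage_matrix, organism_order)`` where
    ``organism_order`` sorts organisms by GC content when provided (input
    order otherwise), matching the display convention of profile heatmaps.
    """
    species = matrix.species
    if len(species) < 2:
        raise ValueError("need at least two species to cluster")
    profiles = matrix.values.T.astype(float)
    d = pdist(profiles, metric="hamming") * matrix.values.shape[0]
    z = linkage(d, method="average")
    species_order = [species[i] for i in leaves_list(z)]
    if gc_by_organism is not None:
        gc = np.asarray([gc_by_organism[o] for o in matrix.organisms])
        organism_order = [matrix.organisms[i] for i in np.argsort(gc, kind="stable")]
    else:
        organism_order = list(matrix.organisms)
    return species_order, z, organism_order


TRAIT_COLUMNS = ("genome_size", "gc_content", "enc_diff")


def build_trait_table(genome_size: dict, gc: dict, enc_diff_by_org: dict) -> pd.DataFrame:
    """Per-organism trait table with z-normalized columns (``*_z``).

    Normalization uses the sample (n-1) standard deviation so coefficients of
    downstream regressions are effect sizes.
    """
    orgs = sorted(genome_size)
    df = pd.DataFrame({
        "genome_size": [genome_size[o] for o in orgs],
        "gc_content": [gc[o] for o in orgs],
        "enc_diff": [enc_diff_by_org[o] for o in orgs],
    }, index=orgs)
    for col in TRAIT_COLUMNS:
        sd = df[col].std(ddof=1)
        if sd == 0:
            raise ValueError(f"trait {col} has zero variance")
        df[col + "_z"] = (df[col] - df[col].mean()) / sd
    return df
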