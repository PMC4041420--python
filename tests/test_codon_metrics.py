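"""ENC / ENC' codon-bias statistics, traits and descriptive repertoire
measures."""

import numpy as np
import pytest

from trnadyn.codon_metrics import (CodonCounts, build_trait_table, enc,
                                   enc_diff, enc_prime, gc_content,
                                   hamming_cluster, nearest_rank_percentile,
                                   usage_shift, variability_measure)
from trnadyn.genetic_code import FAMILIES, SENSE_CODONS
from trnadyn.repertoire import PresenceMatrix
from trnadyn.simulate import codon_usage_for_gc

UNIFORM_BG = {"A": 0.25, "C": 0.25, "G": 0.25, "U": 0.25}


def one_codon_per_family(n_per_family=500):
    return CodonCounts({codons[0]: n_per_family for codons in FAMILIES.values()},
                       UNIFORM_BG)


def expectation_gene(gc, n=10_000):
    """Codon counts set exactly to the expectation of a GC-composition
    background (deterministic, expected counts rounded)."""
    p = codon_usage_for_gc(gc)
    bg = {"G": gc / 2, "C": gc / 2, "A": (1 - gc) / 2, "U": (1 - gc) / 2}
    return CodonCounts({c: round(pi * n) for c, pi in zip(SENSE_CODONS, p)}, bg)


def oracle_enc(counts):
    """Straight evaluation of Wright's formula, kept independent of the
    implementation's family bookkeeping."""
    fbar = {}
    for m in (2, 3, 4, 6):
        fs = []
        for aa, codons in FAMILIES.items():
            if len(codons) != m:
                continue
            ns = [counts.counts.get(c, 0) for c in codons]
            n = sum(ns)
            if n < 2:
                continue
            f = (n * sum((x / n) ** 2 for x in ns) - 1) / (n - 1)
            if f > 0:
                fs.append(f)
        if fs:
            fbar[m] = sum(fs) / len(fs)
    val = 2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6]
    return min(val, 61.0)


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [
        ("GCGC", 1.0), ("ATAT", 0.0), ("ATGC", 0.5), ("augc", 0.5),
        ("ANNGC", 2 / 3),
    ])
    def test_values(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            gc_content("NNN")


class TestEnc:
    def test_one_codon_per_family_gives_twenty(self):
        assert enc(one_codon_per_family()) == pytest.approx(20.0)

    def test_uniform_usage_gives_sixty_one(self):
        counts = CodonCounts({c: 200 for c in SENSE_CODONS}, UNIFORM_BG)
        assert enc(counts) == pytest.approx(61.0)

    def test_matches_straight_formula_on_random_tables(self, rng):
        for _ in range(10):
            counts = CodonCounts(
                {c: int(k) for c, k in zip(SENSE_CODONS,
                                           rng.integers(0, 30, len(SENSE_CODONS)))},
                UNIFORM_BG)
            assert enc(counts) == pytest.approx(oracle_enc(counts), abs=1e-9)

    def test_invariant_to_synonymous_relabeling(self, rng):
        base = {c: int(k) for c, k in zip(SENSE_CODONS,
                                          rng.integers(1, 40, len(SENSE_CODONS)))}
        relabeled = dict(base)
        for codons in FAMILIES.values():
            vals = [base[c] for c in codons]
            perm = rng.permutation(len(vals))
            for c, j in zip(codons, perm):
                relabeled[c] = vals[j]
        a = enc(CodonCounts(base, UNIFORM_BG))
        b = enc(CodonCounts(relabeled, UNIFORM_BG))
        assert a == pytest.approx(b, abs=1e-9)


class TestEncPrime:
    def test_expectation_matched_gene_scores_sixty_one(self):
        assert enc_prime(expectation_gene(0.5)) == pytest.approx(61.0, abs=0.5)
        assert enc_prime(expectation_gene(0.65)) == pytest.approx(61.0, abs=0.5)

    def test_maximal_bias_at_uniform_background_matches_plain_enc(self):
        counts = one_codon_per_family()
        assert enc_prime(counts) == pytest.approx(enc(counts), abs=1e-6)

    def test_composition_driven_bias_is_corrected(self):
        # a GC-rich gene whose usage merely mirrors its composition: plain
        # ENC drops, the background-corrected variant stays at 61
        gene = expectation_gene(0.7)
        assert enc(gene) < 55
        assert enc_prime(gene) == pytest.approx(61.0, abs=0.5)

    def test_degenerate_background_raises(self):
        counts = CodonCounts({"UUU": 10, "UUC": 10},
                             {"A": 0.5, "U": 0.5, "C": 0.0, "G": 0.0})
        with pytest.raises(ValueError):
            enc_prime(counts)


class TestEncDiff:
    def test_arithmetic(self):
        genes = [(50.0, False)] * 3 + [(45.0, True)]
        # mean_all = 48.75, mean_ribo = 45
        assert enc_diff(genes) == pytest.approx((48.75 - 45) / 48.75)

    def test_identical_genes_give_zero(self):
        assert enc_diff([(52.0, True), (52.0, False)]) == 0.0

    def test_no_ribosomal_raises(self):
        with pytest.raises(ValueError):
            enc_diff([(50.0, False)])


class TestUsageShift:
    def test_symmetric_groups(self):
        pres = [0, 0, 0, 1, 1, 1, 0, 0, 0, 1, 1, 1]
        gc = [0.4] * 3 + [0.6] * 3 + [0.4] * 3 + [0.6] * 3
        shift, p = usage_shift(pres, gc)
        assert shift == pytest.approx(0.5)
        assert p < 0.05

    def test_nearest_rank_hand_example(self):
        pres = [0] * 4 + [1] * 4
        gc = [30, 35, 40, 45, 50, 55, 60, 65]
        shift, p = usage_shift(pres, gc, alpha=0.05)
        # 75th percentile of absent = 40, 25th of present = 50
        assert shift == pytest.approx(45.0)

    def test_insignificant_returns_none_with_p(self, rng):
        gc = rng.normal(0.5, 0.05, 40)
        pres = rng.integers(0, 2, 40)
        if pres.min() == pres.max():
            pres[0] = 1 - pres[0]
        shift, p = usage_shift(pres, gc, alpha=1e-6)
        assert shift is None and 0 <= p <= 1

    def test_empty_group_undefined(self):
        assert usage_shift([1, 1, 1], [0.3, 0.4, 0.5]) == (None, None)

    def test_rank_based_p_is_monotone_invariant(self):
        pres = [0] * 5 + [1] * 5
        gc = np.linspace(0.3, 0.7, 10)
        _, p1 = usage_shift(pres, gc)
        shift2, p2 = usage_shift(pres, np.exp(gc))
        assert p1 == pytest.approx(p2)
        assert shift2 == pytest.approx(
            (np.exp(nearest_rank_percentile(gc[:5], 75))
             + np.exp(nearest_rank_percentile(gc[5:], 25))) / 2)


class TestVariability:
    @pytest.mark.parametrize("n_present,n_total,expected", [
        (319, 319, 100.0), (160, 319, 100 * 160 / 319), (0, 10, 100.0),
    ])
    def test_values(self, n_present, n_total, expected):
        col = [1] * n_present + [0] * (n_total - n_present)
        assert variability_measure(col) == pytest.approx(expected)

    def test_160_of_319_to_one_decimal(self):
        col = [1] * 160 + [0] * 159
        assert round(variability_measure(col), 1) == 50.2

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            variability_measure([])


class TestHammingCluster:
    def test_identical_profiles_merge_first_at_distance_zero(self):
        values = np.array([[1, 1, 0, 1],
                           [0, 0, 1, 0],
                           [1, 1, 0, 1]]).T  # 4 organisms x 3 species? no:
        m = PresenceMatrix([f"O{i}" for i in range(4)],
                           ["s1", "s2", "s3"], values)
        order, z, orgs = hamming_cluster(m)
        assert z[0, 2] == pytest.approx(0.0)       # first merge distance
        assert {order.index("s1"), order.index("s3")} in \
            ({0, 1}, {1, 2})  # the identical pair is adjacent

    def test_hand_traced_toy(self):
        # species profiles over 3 organisms: a=(0,0,1) b=(1,0,1) c=(1,1,1)
        values = np.array([[0, 1, 1], [0, 0, 1], [1, 1, 1]])
        m = PresenceMatrix(["O1", "O2", "O3"], ["a", "b", "c"], values)
        order, z, _ = hamming_cluster(m)
        # d(a,b)=1, d(b,c)=1, d(a,c)=2: the first merge is at distance 1 and
        # involves b; b ends adjacent to one of its distance-1 partners
        assert z[0, 2] == pytest.approx(1.0)
        assert abs(order.index("b") - order.index("a")) == 1 or \
            abs(order.index("b") - order.index("c")) == 1

    def test_organisms_ordered_by_gc(self):
        values = np.array([[0, 1], [1, 0], [1, 1]])
        m = PresenceMatrix(["O1", "O2", "O3"], ["a", "b"], values)
        _, _, orgs = hamming_cluster(m, gc_by_organism={"O1": 0.6, "O2": 0.3,
                                                        "O3": 0.5})
        assert orgs == ["O2", "O3", "O1"]


def test_trait_table_z_normalization():
    orgs = [f"O{i}" for i in range(6)]
    table = build_trait_table(
        {o: 1e6 * (i + 1) for i, o in enumerate(orgs)},
        {o: 0.3 + 0.05 * i for i, o in enumerate(orgs)},
        {o: 0.01 * i for i, o in enumerate(orgs)})
    for col in ("genome_size_z", "gc_content_z", "enc_diff_z"):
        assert table[col].mean() == pytest.approx(0.0, abs=1e-9)
        assert table[col].std(ddof=1) == pytest.approx(1.0, abs=1e-9)
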