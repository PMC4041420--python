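"""Standard bacterial genetic code (translation table 11 sense codons).

Codons and anticodons are handled in the RNA alphabet throughout; anticodons
are written 5'->3' so that position 34 (the wobble base) is the first letter
and pairs the third codon position.
"""

from __future__ import annotations

from itertools import product

RNA_BASES = ("A", "C", "G", "U")

_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}

# amino acid of each codon, RNA alphabet; '*' marks stops
_CODE = {
    "UUU": "F", "UUC": "F", "UUA": "L", "UUG": "L",
    "CUU": "L", "CUC": "L", "CUA": "L", "CUG": "L",
    "AUU": "I", "AUC": "I", "AUA": "I", "AUG": "M",
    "GUU": "V", "GUC": "V", "GUA": "V", "GUG": "V",
    "UCU": "S", "UCC": "S", "UCA": "S", "UCG": "S",
    "CCU": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACU": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCU": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "UAU": "Y", "UAC": "Y", "UAA": "*", "UAG": "*",
    "CAU": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAU": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAU": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "UGU": "C", "UGC": "C", "UGA": "*", "UGG": "W",
    "CGU": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGU": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGU": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in _CODE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c, aa in _CODE.items() if aa != "*"))

#: anticodons whose reverse complement is a stop codon (invalid tRNA species)
STOP_ANTICODONS = frozenset({"UUA", "CUA", "UCA"})


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA to RNA alphabet (T -> U)."""
    return seq.strip().upper().replace("T", "U")


def complement(base: str) -> str:
    return _COMPLEMENT[base]


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def translate_codon(codon: str) -> str:
    """One-letter amino acid of a codon; '*' for stops."""
    return _CODE[normalize_rna(codon)]


def codon_for_anticodon(anticodon: str) -> str:
    """Watson-Crick cognate codon of an anticodon (both read 5'->3')."""
    return reverse_complement(normalize_rna(anticodon))


def codon_box(codon: str) -> tuple[str, ...]:
    """The codon quartet sharing the first two codon positions."""
    head = codon[:2]
    return tuple(head + b for b in RNA_BASES)


def box_degeneracy(codon: str) -> int:
    """Number of codons in the quartet coding the same amino acid as `codon`."""
    aa = _CODE[codon]
    if aa == "*":
        raise ValueError(f"{codon} is a stop codon")
    return sum(1 for c in codon_box(codon) if _CODE[c] == aa)


def is_family_box(codon: str) -> bool:
    """True when all four codons of the quartet code one amino acid."""
    return box_degeneracy(codon) == 4


def synonymous_family(aa: str) -> tuple[str, ...]:
    """All sense codons of one amino acid."""
    fam = tuple(sorted(c for c, a in _CODE.items() if a == aa))
    if not fam:
        raise ValueError(f"unknown amino acid {aa!r}")
    return fam


#: amino acid -> codons, for the 20 standard amino acids
FAMILIES = {aa: synonymous_family(aa) for aa in sorted({a for a in _CODE.values() if a != "*"})}

#: family size m -> amino acids, the grouping used by the effective-number-of-codons statistic
FAMILY_SIZE_CLASSES = {}
for _aa, _codons in FAMILIES.items():
    FAMILY_SIZE_CLASSES.setdefault(len(_codons), []).append(_aa)
FAMILY_SIZE_CLASSES = {m: tuple(sorted(v)) for m, v in FAMILY_SIZE_CLASSES.items()}


def all_valid_anticodons() -> tuple[str, ...]:
    """The 61 anticodons whose reverse complement is a sense codon."""
    out = []
    for tup in product(RNA_BASES, repeat=3):
        ac = "".join(tup)
        if ac not in STOP_ANTICODONS:
            out.append(ac)
    return tuple(sorted(out))


VALID_ANTICODONS = all_valid_anticodons()
assert len(VALID_ANTICODONS) == 61
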