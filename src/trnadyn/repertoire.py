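"""tRNA repertoires: wobble decoding rules, mandatory/auxiliary classification,
gene-table parsing and the organisms x species presence/absence matrix.

An organism's tRNA repertoire is the set of tRNA species it encodes, where a
species is identified by its anticodon (positions 34-35-36, 5'->3', RNA
alphabet). Because of wobble pairing at codon position 3, a subset of the 61
possible species suffices to decode all sense codons; species are classified
as mandatory (required given the near-universal avoidance of A34 anticodons),
auxiliary (their codons are already covered by mandatory species), avoided
(A34 species, read as inosine) or special (the rarely used U34A35U36-Ile).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genetic_code import (
    RNA_BASES,
    SENSE_CODONS,
    STOP_ANTICODONS,
    VALID_ANTICODONS,
    box_degeneracy,
    codon_for_anticodon,
    is_family_box,
    normalize_rna,
    translate_codon,
)

logger = logging.getLogger(__name__)

MANDATORY = "mandatory"
AUXILIARY = "auxiliary"
AVOIDED = "avoided"
SPECIAL = "special"

WATSON_CRICK = "watson_crick"
WOBBLE = "wobble"
INOSINE = "inosine"
SUPERWOBBLE = "superwobble"


@dataclass(frozen=True)
class WobbleRuleSet:
    """Allowed pairings between the wobble base N34 and the codon third position.

    ``edges`` maps N34 -> tuple of (third-position base, interaction class).
    The default encodes the commonly occurring bacterial interactions:
    G34 reads C (Watson-Crick) and U (wobble); C34 reads only G; U34 reads A
    (Watson-Crick), G (modification-dependent wobble) and, by superwobbling,
    U and C; A34 is taken as inosine-modified and reads U, C and A.
    """

    edges: dict = field(default_factory=lambda: {
        "G": (("C", WATSON_CRICK), ("U", WOBBLE)),
        "C": (("G", WATSON_CRICK),),
        "U": (("A", WATSON_CRICK), ("G", WOBBLE),
              ("U", SUPERWOBBLE), ("C", SUPERWOBBLE)),
        "A": (("U", WATSON_CRICK), ("C", INOSINE), ("A", INOSINE)),
    })

    def __post_init__(self):
        for base in RNA_BASES:
            if base not in self.edges or not self.edges[base]:
                raise ValueError(f"wobble base {base} has no edges")
        if len(self.edges["C"]) != 1 or self.edges["C"][0][0] != "G":
            raise ValueError("C34 must pair G3 and nothing else")


DEFAULT_RULES = WobbleRuleSet()


def decoded_codons(anticodon: str, rules: WobbleRuleSet = DEFAULT_RULES,
                   superwobble_family_only: bool = True,
                   inosine_for_a34: bool = True) -> dict[str, str]:
    """Codons decodable by a tRNA species, with their interaction class.

    The codon's first two positions are the reverse complement of anticodon
    positions 36 and 35; the reachable third-position bases follow from the
    rule set applied to N34. Superwobble edges (U34 reading U3/C3) count only
    inside four-codon family boxes unless ``superwobble_family_only`` is
    False. Codons coding a different amino acid than the cognate codon (or
    stops) are never reported as decoded.
    """
    ac = normalize_rna(anticodon)
    if len(ac) != 3 or any(b not in RNA_BASES for b in ac):
        raise ValueError(f"invalid anticodon {anticodon!r}")
    if ac in STOP_ANTICODONS:
        raise ValueError(f"anticodon {ac} pairs a stop codon")
    cognate = codon_for_anticodon(ac)
    aa = translate_codon(cognate)
    head = cognate[:2]
    n34 = ac[0]
    edges = rules.edges[n34]
    out = {}
    for third, kind in edges:
        if kind == INOSINE and not inosine_for_a34:
            continue
        codon = head + third
        if kind == SUPERWOBBLE and superwobble_family_only and not is_family_box(cognate):
            continue
        if translate_codon(codon) != aa:
            continue
        out[codon] = kind
    return out


def classify_species(anticodon: str, rules: WobbleRuleSet = DEFAULT_RULES) -> str:
    """Mandatory/auxiliary/avoided/special status of a tRNA species.

    U34 species are mandatory (sole decoders of A-ending codons) except
    U34A35U36-Ile (special, replaced in nature by a modified C34A35U36) and
    U34C35G36-Arg (auxiliary, the Arg box special case). G34 species in 2- or
    3-fold boxes are mandatory, those in family boxes auxiliary. C34A35U36-Met
    and C34C35A36-Trp are the sole decoders of their codons and mandatory;
    the remaining C34 species are auxiliary. A34 species are avoided, apart
    from A34C35G36-Arg which is regularly used (classified mandatory here and
    flagged by :func:`is_arg_box`).
    """
    ac = normalize_rna(anticodon)
    if ac not in VALID_ANTICODONS:
        raise ValueError(f"anticodon {anticodon!r} is not one of the 61 sense-decoding species")
    if ac == "UAU":
        return SPECIAL
    n34 = ac[0]
    if n34 == "A":
        return MANDATORY if ac == "ACG" else AVOIDED
    if n34 == "C":
        return MANDATORY if ac in ("CAU", "CCA") else AUXILIARY
    if n34 == "G":
        return AUXILIARY if is_family_box(codon_for_anticodon(ac)) else MANDATORY
    # U34
    return AUXILIARY if ac == "UCG" else MANDATORY


def is_arg_box(anticodon: str) -> bool:
    """True for the context-dependent N34-C35-G36 Arg-box species."""
    return normalize_rna(anticodon) in ("ACG", "GCG", "UCG", "CCG")


@dataclass(frozen=True)
class AnticodonSpecies:
    """A tRNA species: anticodon, amino acid, box degeneracy and status."""

    anticodon: str
    amino_acid: str
    box_degeneracy: int
    status: str
    arg_box: bool = False

    @classmethod
    def from_anticodon(cls, anticodon: str, rules: WobbleRuleSet = DEFAULT_RULES) -> "AnticodonSpecies":
        ac = normalize_rna(anticodon)
        codon = codon_for_anticodon(ac)
        aa = translate_codon(codon)
        if aa == "*":
            raise ValueError(f"anticodon {anticodon!r} decodes a stop codon")
        return cls(ac, aa, box_degeneracy(codon), classify_species(ac, rules), is_arg_box(ac))


def all_species(rules: WobbleRuleSet = DEFAULT_RULES) -> tuple[AnticodonSpecies, ...]:
    """The 61 valid tRNA species with their classification."""
    return tuple(AnticodonSpecies.from_anticodon(ac, rules) for ac in VALID_ANTICODONS)


@dataclass
class GenomeRepertoire:
    """All identified tRNA genes of one organism."""

    organism_id: str
    genes: list = field(default_factory=list)  # (gene_id, anticodon, sequence|None, coords|None)

    @property
    def species_copy_number(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, ac, *_ in self.genes:
            out[ac] = out.get(ac, 0) + 1
        return out

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted(self.species_copy_number))

    def add_gene(self, gene_id: str, anticodon: str, sequence: str | None = None,
                 coords: tuple | None = None) -> None:
        self.genes.append((gene_id, normalize_rna(anticodon),
                           normalize_rna(sequence) if sequence else None, coords))


_SKIP_TYPES = {"SEC", "SELC", "UNDET", "SUP"}


def _row_ok(organism: str, anticodon: str, trna_type: str | None, note: str | None,
            line_no: int) -> str | None:
    """Normalized anticodon if the row should be kept, else None (with warning
    for stop-pairing anticodons)."""
    ac = normalize_rna(anticodon)
    if note and "PSEUDO" in note.upper():
        return None
    if trna_type and trna_type.upper() in _SKIP_TYPES:
        return None
    if "N" in ac or len(ac) != 3 or any(b not in RNA_BASES for b in ac):
        return None
    if ac in STOP_ANTICODONS:
        warnings.warn(
            f"line {line_no}: anticodon {ac} of {organism} pairs a stop codon; row dropped",
            stacklevel=3)
        return None
    return ac


def parse_trna_table(path) -> list[GenomeRepertoire]:
    """Read per-genome tRNA gene tables.

    Two dialects are accepted and sniffed automatically:

    * tRNAscan-SE tabular output: three header lines then whitespace-separated
      columns (sequence name, tRNA#, begin, end, type, anticodon, intron
      begin, intron end, score[, note]); rows whose note mentions "pseudo",
      whose type is SeC/Undet/Sup or whose anticodon is undetermined are
      dropped.
    * simple TSV with columns organism_id, gene_id, anticodon[, sequence],
      optional header line.

    Anticodons are normalized to the RNA alphabet; anticodons pairing a stop
    codon are dropped with a warning. Malformed rows raise ``ValueError``
    naming the line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    reps: dict[str, GenomeRepertoire] = {}

    def rep(org: str) -> GenomeRepertoire:
        if org not in reps:
            reps[org] = GenomeRepertoire(org)
        return reps[org]

    is_scan = any(line.lstrip().startswith("-----") for line in lines[:5]) or any(
        "tRNA #" in line or "Begin" in line for line in lines[:3])
    if is_scan:
        body_start = 0
        for i, line in enumerate(lines[:5]):
            if line.lstrip().startswith("-----"):
                body_start = i + 1
        for i, line in enumerate(lines[body_start:], start=body_start + 1):
            if not line.strip():
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            parts = [p.strip() for p in parts]
            if len(parts) < 9:
                raise ValueError(f"malformed tRNAscan-SE row at line {i}: {line!r}")
            org, num, begin, end, trna_type, ac = parts[0], parts[1], parts[2], parts[3], parts[4], parts[5]
            note = " ".join(parts[9:]) if len(parts) > 9 else None
            try:
                coords = (int(begin), int(end))
            except ValueError as exc:
                raise ValueError(f"malformed coordinates at line {i}: {line!r}") from exc
            ac_norm = _row_ok(org, ac, trna_type, note, i)
            if ac_norm is None:
                continue
            rep(org).add_gene(f"{org}.trna{num}", ac_norm, None, coords)
    else:
        for i, line in enumerate(lines, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if i == 1 and parts[0].lower() in ("organism", "organism_id"):
                continue
            if len(parts) < 3:
                raise ValueError(f"malformed row at line {i}: {line!r}")
            org, gene_id, ac = parts[0], parts[1], parts[2]
            seq = parts[3] if len(parts) > 3 and parts[3] else None
            note = parts[4] if len(parts) > 4 else None
            ac_norm = _row_ok(org, ac, None, note, i)
            if ac_norm is None:
                continue
            rep(org).add_gene(gene_id, ac_norm, seq)
    return list(reps.values())


MIN_GENOME_SIZE = 1_000_000
MIN_SPECIES = 31


def filter_genomes(reps: list[GenomeRepertoire], genome_sizes: dict[str, float],
                   min_size: float = MIN_GENOME_SIZE, min_species: int = MIN_SPECIES,
                   ) -> tuple[list[GenomeRepertoire], list[str]]:
    """Drop reduced genomes: size < 10^6 bp or fewer than 31 distinct species.

    Returns the retained repertoires and a removal log. Missing genome size
    raises ``KeyError`` naming the organism.
    """
    kept, log = [], []
    for r in reps:
        if r.organism_id not in genome_sizes:
            raise KeyError(f"no genome size for organism {r.organism_id}")
        size = genome_sizes[r.organism_id]
        n_sp = len(r.species)
        if size < min_size:
            log.append(f"{r.organism_id}: removed (genome {size:.0f} bp < {min_size:.0f})")
        elif n_sp < min_species:
            log.append(f"{r.organism_id}: removed ({n_sp} tRNA species < {min_species})")
        else:
            kept.append(r)
    for entry in log:
        logger.info(entry)
    return kept, log


def check_decoding_completeness(rep: GenomeRepertoire,
                                rules: WobbleRuleSet = DEFAULT_RULES) -> list[str]:
    """Sense codons not reachable from any species present in the repertoire."""
    covered: set[str] = set()
    for ac in rep.species:
        covered.update(decoded_codons(ac, rules))
    return sorted(set(SENSE_CODONS) - covered)


class PresenceMatrix:
    """Binary organisms x tRNA-species matrix (1 = at least one gene copy).

    Organisms keep input order; species are sorted alphabetically by
    anticodon. Species never observed in any organism are not represented.
    """

    def __init__(self, organisms: list[str], species: list[str], values: np.ndarray):
        values = np.asarray(values, dtype=int)
        if len(set(organisms)) != len(organisms):
            raise ValueError("duplicate organism ids")
        if len(set(species)) != len(species):
            raise ValueError("duplicate species")
        if values.shape != (len(organisms), len(species)):
            raise ValueError("matrix shape mismatch")
        if not np.isin(values, (0, 1)).all():
            raise ValueError("matrix values must be binary")
        self.organisms = list(organisms)
        self.species = list(species)
        self.values = values

    def column(self, species: str) -> np.ndarray:
        return self.values[:, self.species.index(species)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.organisms, columns=self.species)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="organism")

    @classmethod
    def from_tsv(cls, path) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def __repr__(self):
        return f"PresenceMatrix({len(self.organisms)} organisms x {len(self.species)} species)"


def build_presence_matrix(reps: list[GenomeRepertoire]) -> PresenceMatrix:
    """Binarize repertoires into a presence/absence matrix."""
    if not reps:
        raise ValueError("no repertoires")
    species = sorted({ac for r in reps for ac in r.species})
    organisms = [r.organism_id for r in reps]
    values = np.zeros((len(reps), len(species)), dtype=int)
    col = {s: j for j, s in enumerate(species)}
    for i, r in enumerate(reps):
        for ac in r.species:
            values[i, col[ac]] = 1
    return PresenceMatrix(organisms, species, values)
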