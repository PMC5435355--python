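"""tRNA gene catalogs: parsing, deduplication to species, isoacceptor grouping.

A *gene* is one chromosomal copy of a tRNA; identical mature sequences are
collapsed into a single *species* carrying a gene-copy count. Species sharing
an anticodon form an *isoacceptor family* (its members are isodecoders).
Mature tRNA bodies are stored without the universal 3'-terminal CCA so that
downstream probe windows never have to re-handle it; a flag records whether
the input carried the CCA.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping

from Bio import SeqIO

__all__ = [
    "TrnaGene",
    "TrnaSpecies",
    "TrnaCatalog",
    "parse_gene_fasta",
    "group_isoacceptors",
    "assign_size_class",
    "read_bed_loci",
    "write_catalog_tsv",
    "read_catalog_tsv",
    "AMINO_ACIDS_3",
]

_DNA = set("ACGT")

# 3-letter amino-acid codes accepted in headers, plus selenocysteine and the
# initiator-methionine aliases some gene sets use.
AMINO_ACIDS_3 = {
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
    "SeC",
}

_ONE_TO_THREE = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "U": "SeC",
}

_ALIASES = {"iMet": "Met", "fMet": "Met", "Sec": "SeC", "SeC": "SeC"}

#: amino acids whose tRNAs have the long variable arm (class II)
CLASS_II_ACCEPTORS = frozenset({"Leu", "Ser", "SeC", "Tyr"})

CLASS_I_LENGTH = (74, 77)   # mature length range, CCA included
CLASS_II_LENGTH = (85, 93)

#: header regexes per convention; must expose groups ``aa`` and ``ac``
HEADER_CONVENTIONS = {
    # e.g. ">Escherichia_coli_K12_tRNA-Ala-GGC-1-1" (gtRNAdb naming)
    "gtrnadb": r"tRNA-(?P<aa>[A-Za-z]{1,4})-(?P<ac>[ACGT]{3})",
    # e.g. ">anything aa=Ala ac=GGC"
    "keyvalue": r"aa=(?P<aa>[A-Za-z]{1,4})\s+ac=(?P<ac>[ACGT]{3})",
}


def normalize_amino_acid(code: str) -> str:
    """Return the canonical 3-letter code; raise on unknown codes."""
    code = _ALIASES.get(code, code)
    if code in AMINO_ACIDS_3:
        return code
    if len(code) == 1 and code.upper() in _ONE_TO_THREE:
        return _ONE_TO_THREE[code.upper()]
    cap = code.capitalize()
    if cap in AMINO_ACIDS_3:
        return cap
    raise ValueError(f"unknown amino-acid code: {code!r}")


@dataclass(frozen=True)
class TrnaGene:
    """One chromosomal tRNA gene copy.

    ``sequence`` is the mature sense-strand DNA as given in the input;
    ``has_cca`` records whether it ends with the 3'-terminal CCA.
    ``locus`` is ``(replicon, start, end, strand)`` with 0-based half-open
    coordinates, or ``None`` when no loci were supplied.
    """

    gene_id: str
    amino_acid: str
    anticodon: str
    sequence: str
    has_cca: bool
    locus: tuple[str, int, int, str] | None = None

    def __post_init__(self) -> None:
        if len(self.anticodon) != 3 or not set(self.anticodon) <= _DNA:
            raise ValueError(
                f"{self.gene_id}: anticodon must be 3 nt over ACGT, "
                f"got {self.anticodon!r}"
            )
        if len(self.sequence) < 70:
            raise ValueError(
                f"{self.gene_id}: mature tRNA sequence shorter than 70 nt "
                f"({len(self.sequence)})"
            )
        if self.locus is not None and not self.locus[1] < self.locus[2]:
            raise ValueError(f"{self.gene_id}: locus start must be < end")


@dataclass(frozen=True)
class TrnaSpecies:
    """A unique mature tRNA sequence with its gene-copy multiplicity.

    ``sequence`` is the CCA-less body; ``had_cca`` records the input form.
    """

    species_id: str
    sequence: str
    amino_acid: str
    anticodon: str
    gene_copies: int
    size_class: str
    had_cca: bool

    def __post_init__(self) -> None:
        if self.gene_copies < 1:
            raise ValueError(f"{self.species_id}: gene_copies must be >= 1")
        if self.size_class not in ("I", "II"):
            raise ValueError(f"{self.species_id}: size_class must be I or II")

    @property
    def mature_length(self) -> int:
        """Mature length including the terminal CCA."""
        return len(self.sequence) + 3


@dataclass
class TrnaCatalog:
    genes: list[TrnaGene]
    species: list[TrnaSpecies]
    operon_annotation: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(s.gene_copies for s in self.species) != len(self.genes):
            raise ValueError("species gene_copies do not sum to gene count")

    def species_by_id(self) -> dict[str, TrnaSpecies]:
        return {s.species_id: s for s in self.species}


def _strip_cca(seq: str) -> tuple[str, bool]:
    if seq.endswith("CCA"):
        return seq[:-3], True
    return seq, False


def assign_size_class(amino_acid: str, mature_length: int | None = None) -> str:
    """Size class of a tRNA: ``"II"`` for Leu/Ser/SeC/Tyr acceptors, else ``"I"``.

    The amino-acid rule is authoritative. When ``mature_length`` (CCA included)
    is given and falls inside the *other* class's canonical range (class I
    74-77 nt, class II 85-93 nt), a warning reports the disagreement; lengths
    in the undefined 78-84 nt gap are not checked.
    """
    aa = normalize_amino_acid(amino_acid)
    cls = "II" if aa in CLASS_II_ACCEPTORS else "I"
    if mature_length is not None:
        by_len = None
        if CLASS_I_LENGTH[0] <= mature_length <= CLASS_I_LENGTH[1]:
            by_len = "I"
        elif CLASS_II_LENGTH[0] <= mature_length <= CLASS_II_LENGTH[1]:
            by_len = "II"
        if by_len is not None and by_len != cls:
            warnings.warn(
                f"{aa} tRNA of {mature_length} nt: length suggests class "
                f"{by_len} but acceptor identity dictates class {cls}",
                stacklevel=2,
            )
    return cls


def parse_gene_fasta(
    fasta,
    header_convention: str = "gtrnadb",
    header_regex: str | None = None,
    loci: Mapping[str, tuple[str, int, int, str]] | None = None,
    operon_annotation: Mapping[str, str] | None = None,
) -> TrnaCatalog:
    """Parse a tRNA gene FASTA into a deduplicated catalog.

    Headers must yield an amino acid and an anticodon under the declared
    convention (``header_regex`` overrides the built-in table). Identical
    mature sequences collapse into one species whose ``gene_copies`` is the
    multiplicity; species are ordered by (amino acid, anticodon, sequence)
    and isodecoders within a family are numbered by that order.
    """
    pattern = re.compile(header_regex or HEADER_CONVENTIONS[header_convention])
    genes: list[TrnaGene] = []
    loci = dict(loci or {})
    for rec in SeqIO.parse(str(fasta), "fasta"):
        header = rec.description or rec.id
        m = pattern.search(header)
        if m is None:
            raise ValueError(
                f"header {header!r} does not match convention "
                f"{header_convention!r}"
            )
        aa = normalize_amino_acid(m.group("aa"))
        seq = str(rec.seq).upper().replace("U", "T")
        if not set(seq) <= _DNA:
            raise ValueError(f"{rec.id}: non-ACGT symbols in sequence")
        genes.append(
            TrnaGene(
                gene_id=rec.id,
                amino_acid=aa,
                anticodon=m.group("ac"),
                sequence=seq,
                has_cca=seq.endswith("CCA"),
                locus=loci.get(rec.id),
            )
        )
    if not genes:
        raise ValueError(f"no FASTA records found in {fasta}")
    return _build_catalog(genes, operon_annotation)


def _build_catalog(
    genes: list[TrnaGene],
    operon_annotation: Mapping[str, str] | None = None,
) -> TrnaCatalog:
    by_body: dict[str, list[TrnaGene]] = {}
    for g in genes:
        body, _ = _strip_cca(g.sequence)
        by_body.setdefault(body, []).append(g)
    for body, members in by_body.items():
        keys = {(g.amino_acid, g.anticodon) for g in members}
        if len(keys) > 1:
            ids = ", ".join(g.gene_id for g in members)
            raise ValueError(
                f"identical sequences annotated inconsistently: {ids}"
            )
    ordered = sorted(
        by_body.items(),
        key=lambda kv: (kv[1][0].amino_acid, kv[1][0].anticodon, kv[0]),
    )
    # number isodecoders within each (aa, anticodon) family
    counters: dict[tuple[str, str], int] = {}
    species: list[TrnaSpecies] = []
    for body, members in ordered:
        g0 = members[0]
        key = (g0.amino_acid, g0.anticodon)
        counters[key] = counters.get(key, 0) + 1
        had_cca = any(g.has_cca for g in members)
        mature_len = len(body) + 3 if had_cca else None
        species.append(
            TrnaSpecies(
                species_id=f"{g0.amino_acid}-{g0.anticodon}-{counters[key]}",
                sequence=body,
                amino_acid=g0.amino_acid,
                anticodon=g0.anticodon,
                gene_copies=len(members),
                size_class=assign_size_class(g0.amino_acid, mature_len),
                had_cca=had_cca,
            )
        )
    return TrnaCatalog(
        genes=genes,
        species=species,
        operon_annotation=dict(operon_annotation or {}),
    )


def group_isoacceptors(catalog: TrnaCatalog) -> dict[str, list[TrnaSpecies]]:
    """Group species into isoacceptor families keyed by anticodon."""
    if not catalog.species:
        raise ValueError("empty catalog")
    families: dict[str, list[TrnaSpecies]] = {}
    for sp in catalog.species:
        families.setdefault(sp.anticodon, []).append(sp)
    return families


def read_bed_loci(path) -> dict[str, tuple[str, int, int, str]]:
    """Read 6-column BED into gene_id -> (replicon, start, end, strand)."""
    loci: dict[str, tuple[str, int, int, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns")
            chrom, start, end, name, _score, strand = parts[:6]
            loci[name] = (chrom, int(start), int(end), strand)
    return loci


_CATALOG_COLUMNS = [
    "species_id", "amino_acid", "anticodon", "gene_copies", "size_class",
    "had_cca", "sequence",
]


def write_catalog_tsv(catalog: TrnaCatalog, path) -> None:
    """Write the species table as TSV (one row per unique species)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_CATALOG_COLUMNS) + "\n")
        for s in catalog.species:
            fh.write(
                f"{s.species_id}\t{s.amino_acid}\t{s.anticodon}\t"
                f"{s.gene_copies}\t{s.size_class}\t{int(s.had_cca)}\t"
                f"{s.sequence}\n"
            )


def read_catalog_tsv(path) -> TrnaCatalog:
    """Re-read a species TSV written by :func:`write_catalog_tsv`.

    Gene entries are reconstructed as anonymous copies (no loci), so the
    round trip preserves species, copy counts and classes.
    """
    species: list[TrnaSpecies] = []
    genes: list[TrnaGene] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _CATALOG_COLUMNS:
            raise ValueError(f"{path}: unexpected catalog header {header}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_CATALOG_COLUMNS):
                raise ValueError(f"{path}:{lineno}: malformed row")
            sid, aa, ac, copies, cls, had_cca, seq = parts
            sp = TrnaSpecies(
                species_id=sid, sequence=seq, amino_acid=aa, anticodon=ac,
                gene_copies=int(copies), size_class=cls,
                had_cca=bool(int(had_cca)),
            )
            species.append(sp)
            full = seq + "CCA" if sp.had_cca else seq
            for i in range(sp.gene_copies):
                genes.append(
                    TrnaGene(
                        gene_id=f"{sid}.copy{i + 1}",
                        amino_acid=aa, anticodon=ac, sequence=full,
                        has_cca=sp.had_cca,
                    )
                )
    return TrnaCatalog(genes=genes, species=species)
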