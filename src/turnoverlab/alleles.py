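"""Assignment of tryptic peptides to HLA class I alleles and isotypes.

HLA class I heavy chains are encoded at three polymorphic loci (HLA-A, -B,
-C; the "isotypes"), with up to two alleles expressed per locus in any one
donor. After tryptic digestion of an immunoprecipitated heavy-chain band,
an observed peptide can be traced back to its molecule of origin only if its
sequence is unique within the donor's genotype. This module digests allele
protein sequences in silico and partitions the resulting peptides into

* ``allele_specific`` — found in exactly one allele of a heterozygous locus;
* ``isotype_specific`` — shared by both alleles of one locus (or unique to
  the single allele of a homozygous locus) and absent from the other loci;
* ``ambiguous`` — present at two or more loci; excluded from kinetic
  analysis downstream because its signal mixes molecules with potentially
  different turnover.

Classification operates on the sequences as supplied; if precursor
(signal-peptide-containing) sequences are given, trimming is the caller's
responsibility.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

from Bio import SeqIO
from pyteomics import parser as _pyt_parser

from .errors import GenotypeError, PanelError, SequenceError

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
CLASS_I_LOCI = ("A", "B", "C")

#: Trypsin cleaves C-terminal to K or R, except when the next residue is P.
TRYPSIN_RULE = r"[KR](?!P)"

#: Default digest window, in residues. Typical LC-MS-observable tryptic
#: peptides fall in this range; both bounds are configurable everywhere.
DEFAULT_MIN_LEN = 6
DEFAULT_MAX_LEN = 30
DEFAULT_MAX_MISSED = 2

_ALLELE_RE = re.compile(r"\b([ABC])\*([0-9]{1,3}(?::[0-9]{1,4})*)")


def check_sequence(seq: str, context: str = "sequence") -> str:
    """Validate that *seq* is a non-empty uppercase canonical protein string."""
    if not seq:
        raise SequenceError(f"{context}: empty sequence")
    bad = set(seq) - CANONICAL_RESIDUES
    if bad:
        raise SequenceError(
            f"{context}: non-canonical residue(s) {sorted(bad)} in sequence"
        )
    return seq


@dataclass(frozen=True)
class TrypticPeptide:
    """A tryptic fragment of a parent protein.

    ``start``/``end`` are 1-based inclusive coordinates in the parent;
    ``missed_cleavages`` counts internal K/R sites not followed by P.
    """

    sequence: str
    missed_cleavages: int
    start: int
    end: int


@dataclass
class AllelePanel:
    """Named allele protein sequences, each assigned to one locus."""

    entries: dict[str, str]
    locus_of: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.entries.items():
            check_sequence(seq, context=f"allele {name!r}")
            locus = self.locus_of.get(name)
            if locus is None:
                raise PanelError(f"allele {name!r} has no locus assignment")
            if locus not in CLASS_I_LOCI:
                raise PanelError(
                    f"allele {name!r}: unknown locus {locus!r} "
                    f"(expected one of {CLASS_I_LOCI})"
                )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def loci(self) -> set[str]:
        return set(self.locus_of[name] for name in self.entries)


@dataclass(frozen=True)
class DonorGenotype:
    """Alleles carried by one donor: 1-2 per locus across HLA-A, -B, -C.

    A locus listed with a single allele is treated as homozygous.
    """

    donor_id: str
    alleles: tuple[str, ...]

    @staticmethod
    def from_list(donor_id: str, alleles: Iterable[str]) -> "DonorGenotype":
        return DonorGenotype(donor_id=donor_id, alleles=tuple(alleles))

    def validate_against(self, panel: AllelePanel) -> None:
        missing = [a for a in self.alleles if a not in panel.entries]
        if missing:
            raise GenotypeError(
                f"donor {self.donor_id!r}: allele(s) {missing} not in panel"
            )
        per_locus: dict[str, set[str]] = {}
        for a in self.alleles:
            per_locus.setdefault(panel.locus_of[a], set()).add(a)
        for locus, names in per_locus.items():
            if len(names) > 2:
                raise GenotypeError(
                    f"donor {self.donor_id!r}: {len(names)} distinct alleles "
                    f"at locus {locus} (max 2)"
                )


def default_locus_rule(header: str) -> tuple[str, str]:
    """Parse a FASTA header into ``(allele_name, locus)``.

    Accepts plain headers (``A*01:01``) and IMGT/HLA-style headers
    (``HLA:HLA00001 A*01:01:01:01 365 bp``): the first token matching the
    HLA nomenclature pattern ``<locus>*<field>:<field>...`` is used.
    """
    m = _ALLELE_RE.search(header)
    if m is None:
        raise PanelError(
            f"cannot parse allele name/locus from FASTA header {header!r}"
        )
    return m.group(0), m.group(1)


def load_allele_sequences(
    path: str | Path,
    locus_rule: Callable[[str], tuple[str, str]] = default_locus_rule,
) -> AllelePanel:
    """Read an allele panel from a FASTA file of protein sequences.

    Raises
    ------
    PanelError
        On an empty file, unparseable headers, duplicate allele names.
    SequenceError
        If a record contains non-canonical residues (names the record).
    """
    path = Path(path)
    entries: dict[str, str] = {}
    locus_of: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name, locus = locus_rule(record.description)
        if name in entries:
            raise PanelError(f"duplicate allele name {name!r} in {path}")
        seq = str(record.seq).upper()
        check_sequence(seq, context=f"record {name!r}")
        entries[name] = seq
        locus_of[name] = locus
    if not entries:
        raise PanelError(f"no records in FASTA file {path}")
    return AllelePanel(entries=entries, locus_of=locus_of)


def _count_missed(pep: str) -> int:
    """Internal K/R cleavage sites in *pep*, excluding K/R-before-P."""
    return sum(
        1
        for i in range(len(pep) - 1)
        if pep[i] in "KR" and pep[i + 1] != "P"
    )


def digest(
    sequence: str,
    max_missed: int = DEFAULT_MAX_MISSED,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[TrypticPeptide]:
    """In-silico tryptic digest with up to *max_missed* missed cleavages.

    Cleavage occurs after K or R except when the next residue is P. Returns
    every fragment whose length lies within ``[min_len, max_len]``, with
    1-based inclusive coordinates, sorted by (start, end).
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if not (1 <= min_len <= max_len):
        raise ValueError("require 1 <= min_len <= max_len")
    check_sequence(sequence)
    seen: set[tuple[int, str]] = set()
    out: list[TrypticPeptide] = []
    for start0, pep in _pyt_parser.icleave(
        sequence, TRYPSIN_RULE, missed_cleavages=max_missed
    ):
        if not (min_len <= len(pep) <= max_len):
            continue
        key = (start0, pep)
        if key in seen:
            continue
        seen.add(key)
        out.append(
            TrypticPeptide(
                sequence=pep,
                missed_cleavages=_count_missed(pep),
                start=start0 + 1,
                end=start0 + len(pep),
            )
        )
    out.sort(key=lambda p: (p.start, p.end))
    return out


@dataclass(frozen=True)
class SpecificityAssignment:
    """Classification of one peptide sequence within a donor genotype."""

    peptide_sequence: str
    category: str  # "allele_specific" | "isotype_specific" | "ambiguous"
    carriers: tuple[str, ...]
    locus: str | None
    #: (allele, start, end) for every occurrence across carrier digests
    occurrences: tuple[tuple[str, int, int], ...] = field(default=())


def collapse_il(seq: str) -> str:
    """Map I to L: mass spectrometry cannot distinguish the two residues."""
    return seq.replace("I", "L")


def classify_peptides(
    panel: AllelePanel,
    genotype: DonorGenotype,
    max_missed: int = DEFAULT_MAX_MISSED,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    il_equivalent: bool = False,
) -> list[SpecificityAssignment]:
    """Classify every distinct tryptic peptide of a donor's alleles.

    Each peptide occurring in any genotype allele's digest is assigned
    exactly one category (see module docstring). With ``il_equivalent``,
    I and L are treated as identical for sequence matching (the reported
    ``peptide_sequence`` is then the first-seen raw sequence).

    Homozygous loci: a peptide unique to the single allele of a homozygous
    locus is ``isotype_specific`` (it tracks the whole isotype, and there is
    no second allele to distinguish it from).
    """
    genotype.validate_against(panel)
    alleles = sorted(set(genotype.alleles))
    alleles_per_locus: dict[str, set[str]] = {}
    for a in alleles:
        alleles_per_locus.setdefault(panel.locus_of[a], set()).add(a)

    key_of = collapse_il if il_equivalent else (lambda s: s)
    carriers: dict[str, set[str]] = {}
    first_seq: dict[str, str] = {}
    occurrences: dict[str, list[tuple[str, int, int]]] = {}
    for allele in alleles:
        for pep in digest(panel.entries[allele], max_missed, min_len, max_len):
            key = key_of(pep.sequence)
            carriers.setdefault(key, set()).add(allele)
            first_seq.setdefault(key, pep.sequence)
            occurrences.setdefault(key, []).append(
                (allele, pep.start, pep.end)
            )

    out: list[SpecificityAssignment] = []
    for key in sorted(carriers, key=lambda k: first_seq[k]):
        carrier_set = carriers[key]
        loci = {panel.locus_of[a] for a in carrier_set}
        if len(loci) >= 2:
            category, locus = "ambiguous", None
        else:
            locus = next(iter(loci))
            heterozygous = len(alleles_per_locus[locus]) > 1
            if len(carrier_set) == 1 and heterozygous:
                category = "allele_specific"
            else:
                category = "isotype_specific"
        out.append(
            SpecificityAssignment(
                peptide_sequence=first_seq[key],
                category=category,
                carriers=tuple(sorted(carrier_set)),
                locus=locus,
                occurrences=tuple(sorted(occurrences[key])),
            )
        )
    return out


def assignments_to_records(
    assignments: Iterable[SpecificityAssignment],
) -> list[dict]:
    """Flatten assignments into TSV/CSV-ready records."""
    rows = []
    for a in assignments:
        rows.append(
            {
                "peptide": a.peptide_sequence,
                "category": a.category,
                "carriers": ";".join(a.carriers),
                "locus": a.locus if a.locus is not None else "",
                "positions": ";".join(
                    f"{al}:{s}-{e}" for al, s, e in a.occurrences
                ),
            }
        )
    return rows
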