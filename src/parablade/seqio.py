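"""Sequence and structure IO: FASTA, NCBI substitution matrices, PDB
coordinate records, and per-residue attribute files for molecular viewers.

All residue strings use the 20 standard one-letter amino-acid codes plus
``X`` (unknown/ambiguous).  The only gap character recognised anywhere in
the package is ``-``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.PDB import PDBParser
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = STANDARD_AA + "X"
GAP = "-"

#: three-letter -> one-letter codes for the 20 standard residues
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class ParseError(ValueError):
    """Raised for malformed input files."""


@dataclass(frozen=True)
class ProteinSequence:
    """An ungapped protein sequence with species and paralog-group labels."""

    id: str
    residues: str
    species: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: empty residue string")
        for pos, aa in enumerate(self.residues, start=1):
            if aa not in ALPHABET:
                raise ParseError(
                    f"sequence {self.id!r}: illegal residue {aa!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class MultipleAlignment:
    """A gapped alignment; columns are 1-based throughout the package."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        lengths = {len(r) for _, r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        ids = [i for i, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate row ids in alignment")

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    def row(self, seq_id: str) -> str:
        for i, r in self.rows:
            if i == seq_id:
                return r
        raise KeyError(f"no alignment row with id {seq_id!r}")

    def column(self, col: int) -> dict[str, str]:
        """Residues (or gaps) of 1-based column *col*, keyed by row id."""
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} out of range 1..{self.length}")
        return {i: r[col - 1] for i, r in self.rows}

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")


class SubstitutionMatrix:
    """Symmetric integer substitution scores over the residue alphabet."""

    def __init__(self, name: str, scores: dict[tuple[str, str], int]):
        self.name = name
        self._scores = dict(scores)
        letters = {a for a, _ in self._scores} | {b for _, b in self._scores}
        missing = set(STANDARD_AA) - letters
        if missing:
            raise ParseError(
                f"matrix {name!r}: missing residues {''.join(sorted(missing))}"
            )
        for (a, b), s in self._scores.items():
            if self._scores.get((b, a), s) != s:
                raise ParseError(f"matrix {name!r}: asymmetric entry ({a},{b})")

    @property
    def letters(self) -> str:
        return "".join(sorted({a for a, _ in self._scores}))

    def score(self, a: str, b: str) -> int:
        try:
            return self._scores[(a, b)]
        except KeyError:
            raise KeyError(f"no score for residue pair ({a},{b})") from None

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._scores


@dataclass(frozen=True)
class ResidueRecord:
    """One residue of a reference structure, in author numbering."""

    number: int
    amino_acid: str
    ca_xyz: Optional[tuple[float, float, float]]

    @property
    def disordered(self) -> bool:
        return self.ca_xyz is None


@dataclass
class StructureModel:
    """CA-only model of one chain, covering a contiguous author-numbered span."""

    source: str
    residues: list[ResidueRecord]

    def __post_init__(self) -> None:
        numbers = [r.number for r in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ValueError(f"{self.source}: residue numbers not strictly increasing")
        self._by_number = {r.number: r for r in self.residues}

    @property
    def seq_span(self) -> tuple[int, int]:
        return self.residues[0].number, self.residues[-1].number

    def residue(self, number: int) -> ResidueRecord:
        return self._by_number[number]

    def __contains__(self, number: int) -> bool:
        return number in self._by_number

    @property
    def resolved_numbers(self) -> list[int]:
        return [r.number for r in self.residues if not r.disordered]

    @property
    def disordered_numbers(self) -> list[int]:
        return [r.number for r in self.residues if r.disordered]


# ---------------------------------------------------------------------------
# FASTA


def _parse_header(description: str) -> tuple[str, str, str]:
    """Split a FASTA description into (id, species, group).

    Annotations ride in the description as ``species=...;`` / ``group=...;``
    key-value pairs; anything else after the id token is ignored.
    """
    tokens = description.split(None, 1)
    seq_id = tokens[0]
    species = group = ""
    if len(tokens) == 2:
        for part in tokens[1].replace(";", " ").split():
            if part.startswith("species="):
                species = part[len("species="):]
            elif part.startswith("group="):
                group = part[len("group="):]
    return seq_id, species, group


def read_fasta(handle) -> list[ProteinSequence]:
    """Read protein sequences from a FASTA handle or path.

    Headers may carry ``species=...;group=...`` annotations.  Lowercase
    residues are uppercased; characters outside the 20 standard residues
    plus ``X`` are a parse error naming the offending residue.
    """
    if isinstance(handle, str):
        with open(handle) as fh:
            return read_fasta(fh)
    records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise ParseError("empty FASTA input")
    out: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in records:
        seq_id, species, group = _parse_header(rec.description)
        if seq_id in seen:
            raise ParseError(f"duplicate sequence id {seq_id!r}")
        seen.add(seq_id)
        residues = str(rec.seq).upper()
        if GAP in residues:
            raise ParseError(f"sequence {seq_id!r}: gap characters not allowed in FASTA input")
        out.append(ProteinSequence(id=seq_id, residues=residues, species=species, group=group))
    return out


def write_fasta(seqs: Iterable[ProteinSequence], handle) -> None:
    """Write sequences with ``species=...;group=...`` header annotations."""
    if isinstance(handle, str):
        with open(handle, "w") as fh:
            write_fasta(seqs, fh)
            return
    records = []
    for s in seqs:
        desc = ""
        if s.species or s.group:
            desc = f"species={s.species};group={s.group};"
        records.append(SeqRecord(Seq(s.residues), id=s.id, description=desc))
    SeqIO.write(records, handle, "fasta")


# ---------------------------------------------------------------------------
# Substitution matrices


def read_substitution_matrix(handle, name: str = "") -> SubstitutionMatrix:
    """Parse an NCBI-format whitespace-delimited substitution matrix."""
    if isinstance(handle, str):
        with open(handle) as fh:
            return read_substitution_matrix(fh, name=name)
    try:
        arr = substitution_matrices.read(handle)
    except Exception as exc:  # malformed table
        raise ParseError(f"cannot parse substitution matrix: {exc}") from exc
    scores: dict[tuple[str, str], int] = {}
    for a in arr.alphabet:
        for b in arr.alphabet:
            scores[(a, b)] = int(arr[a, b])
    return SubstitutionMatrix(name or "matrix", scores)


def load_blosum62() -> SubstitutionMatrix:
    """The packaged NCBI BLOSUM62 table (half-bit log-odds scores)."""
    text = resources.files("parablade.data").joinpath("BLOSUM62.txt").read_text()
    return read_substitution_matrix(io.StringIO(text), name="BLOSUM62")


# ---------------------------------------------------------------------------
# Structures


def read_structure(handle, chain: str, seq_span: tuple[int, int],
                   source: str = "") -> StructureModel:
    """Read CA coordinates for one chain from PDB-format ATOM records.

    Every author residue number in ``seq_span`` (inclusive) becomes a
    :class:`ResidueRecord`; numbers absent from the coordinate records are
    marked disordered.  Only the first-listed alternate conformer is kept;
    non-standard residues are rejected.
    """
    if isinstance(handle, str):
        with open(handle) as fh:
            return read_structure(fh, chain, seq_span, source=source or handle)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", handle)
    model = next(structure.get_models())
    if chain not in [c.id for c in model]:
        raise ParseError(f"chain not found: {chain!r}")
    lo, hi = seq_span
    if hi < lo:
        raise ValueError(f"invalid seq_span {seq_span}")
    resolved: dict[int, tuple[str, tuple[float, float, float]]] = {}
    last_seen: Optional[int] = None
    for residue in model[chain]:
        hetflag, resseq, _icode = residue.id
        if hetflag.strip():
            continue
        if last_seen is not None and resseq <= last_seen:
            raise ParseError(f"non-monotonic residue numbering in chain {chain} at {resseq}")
        last_seen = resseq
        resname = residue.get_resname().strip().upper()
        if resname not in THREE_TO_ONE:
            raise ParseError(f"non-standard residue {resname!r} at {resseq} in chain {chain}")
        if "CA" not in residue:
            continue
        atom = residue["CA"]
        if atom.is_disordered():
            atom = atom.disordered_get_list()[0]  # first-listed conformer
        x, y, z = (float(v) for v in atom.coord)
        resolved[resseq] = (THREE_TO_ONE[resname], (x, y, z))
    numbers = sorted(resolved)
    if not numbers:
        raise ParseError(f"no CA records for chain {chain!r}")
    records = []
    for num in range(lo, hi + 1):
        if num in resolved:
            aa, xyz = resolved[num]
            records.append(ResidueRecord(number=num, amino_acid=aa, ca_xyz=xyz))
        else:
            records.append(ResidueRecord(number=num, amino_acid="X", ca_xyz=None))
    return StructureModel(source=source or f"chain {chain}", residues=records)


# ---------------------------------------------------------------------------
# Viewer attribute files


def write_attribute_map(sites: Sequence[tuple[int, str]], handle,
                        attribute: str = "divergence_category") -> None:
    """Write a per-residue attribute file (TSV with one header line).

    Molecular viewers can load this to colour residues by category.  A
    residue listed twice with conflicting categories is an error.
    """
    if isinstance(handle, str):
        with open(handle, "w") as fh:
            write_attribute_map(sites, fh, attribute=attribute)
            return
    seen: dict[int, str] = {}
    for number, category in sites:
        if number in seen and seen[number] != category:
            raise ValueError(
                f"residue {number} assigned conflicting categories "
                f"{seen[number]!r} and {category!r}"
            )
        seen[number] = category
    handle.write(f"residue\t{attribute}\n")
    for number in sorted(seen):
        handle.write(f"{number}\t{seen[number]}\n")
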