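"""Readers and writers for the formats the pipeline touches.

The structure dialect is the AlphaFold one: a single chain, residue numbering
identical to UniProt 1-based numbering, and the per-residue model confidence
(pLDDT, 0-100) stored in the B-factor column of every atom of the residue.
PTM tables follow the PhosphoSitePlus bulk-download dialect (tab-separated,
``ACC_ID`` + ``MOD_RSD`` columns, modification encoded as e.g. ``S417-p``).
Multiple sequence alignments are aligned FASTA as produced by Clustal Omega.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO

from .errors import DataError, DialectWarning, FormatError

logger = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
ONE_TO_THREE["X"] = "UNK"

STANDARD_AA = set(THREE_TO_ONE.values())

#: atom names that belong to the peptide backbone (everything else is side chain)
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

#: MOD_RSD suffix -> modification class
PTM_SUFFIXES = {
    "p": "phospho",
    "ub": "ubiquityl",
    "ac": "acetyl",
    "m1": "methyl",
    "m2": "methyl",
    "m3": "methyl",
    "sm": "sumoyl",
    "gl": "glycosyl",
    "ga": "glycosyl",
}


@dataclass
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]


@dataclass
class Residue:
    """One residue: 1-based UniProt position, one-letter code, heavy atoms, pLDDT."""

    position: int
    aa: str
    atoms: list[Atom]
    plddt: float

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.position} has no atom {name!r}")

    def side_chain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.name not in BACKBONE_ATOMS]


@dataclass
class Structure:
    """A parsed single-chain model with per-residue confidence scores."""

    chain_id: str
    residues: list[Residue]
    source_name: str = ""

    def __post_init__(self) -> None:
        positions = [r.position for r in self.residues]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise FormatError("residue positions must be strictly increasing")
        for r in self.residues:
            if not r.atoms:
                raise FormatError(f"residue {r.position} has no atoms")
            if not 0.0 <= r.plddt <= 100.0:
                raise FormatError(f"residue {r.position}: pLDDT {r.plddt} outside [0, 100]")
            names = [a.name for a in r.atoms]
            if len(names) != len(set(names)):
                raise FormatError(f"residue {r.position}: duplicate atom names")

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, position: int) -> Residue | None:
        for r in self.residues:
            if r.position == position:
                return r
        return None

    def all_coords(self) -> np.ndarray:
        return np.concatenate([r.coords() for r in self.residues])


@dataclass
class SiteRecord:
    """One PTM site with computed annotations and append-only filter provenance."""

    accession: str
    position: int
    aa: str
    ptm_class: str
    sasa: float | None = None
    rsa: float | None = None
    plddt: float | None = None
    status: str = "raw"
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.history:
            self.history = [self.status]

    def mark(self, status: str) -> None:
        """Advance the record's status, never erasing prior provenance."""
        if self.status.startswith("excluded:"):
            # an exclusion reason is terminal; record the attempt only
            self.history.append(f"(ignored transition to {status})")
            return
        self.status = status
        self.history.append(status)

    @property
    def excluded(self) -> bool:
        return self.status.startswith("excluded:")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else ""


def read_pdb_structure(pdb_text: str, source_name: str = "") -> Structure:
    """Parse ATOM records of a single-chain AlphaFold-style PDB file.

    Hydrogens, HETATM and waters are ignored; pLDDT is taken from the
    B-factor of each residue's first atom (a dialect warning is emitted if
    B-factors within one residue disagree by more than 0.01).  altLoc
    indicators, insertion codes, multiple chains and duplicate residue
    numbers are hard format errors: the pipeline's PTM mapping relies on the
    residue numbering being exactly the UniProt one.
    """
    residues: list[Residue] = []
    current_pos: int | None = None
    current: Residue | None = None
    seen_positions: set[int] = set()
    chain_id: str | None = None

    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        record = line[:6]
        if record not in ("ATOM  ", "ATOM"):
            continue
        if len(line) < 66:
            raise FormatError(f"line {lineno}: ATOM record shorter than 66 columns")
        name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:20].strip()
        chain = line[21]
        icode = line[26]
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = _element_from_name(name)
        element = element.capitalize()
        if element == "H":
            continue
        if altloc != " ":
            raise FormatError(f"line {lineno}: altLoc {altloc!r} not supported in this dialect")
        if icode != " ":
            raise FormatError(f"line {lineno}: insertion code {icode!r} not supported")
        if chain_id is None:
            chain_id = chain
        elif chain != chain_id:
            raise FormatError(f"line {lineno}: multiple chains ({chain_id!r}, {chain!r})")
        try:
            pos = int(line[22:26])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            bfac = float(line[60:66])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: unparseable numeric field") from exc

        if pos != current_pos:
            if pos in seen_positions:
                raise FormatError(f"line {lineno}: duplicate residue position {pos}")
            seen_positions.add(pos)
            current = Residue(
                position=pos,
                aa=THREE_TO_ONE.get(resname, "X"),
                atoms=[],
                plddt=bfac,
            )
            residues.append(current)
            current_pos = pos
        else:
            assert current is not None
            if abs(bfac - current.plddt) > 0.01:
                warnings.warn(
                    f"residue {pos}: B-factors differ by more than 0.01 "
                    f"({current.plddt} vs {bfac}); first atom wins",
                    DialectWarning,
                    stacklevel=2,
                )
        assert current is not None
        current.atoms.append(Atom(name=name, element=element, xyz=(x, y, z)))

    if not residues:
        raise FormatError("no ATOM records found")
    return Structure(chain_id=chain_id or "A", residues=residues, source_name=source_name)


def write_pdb_structure(s: Structure) -> str:
    """Serialize a Structure to fixed-width PDB ATOM records.

    The pLDDT is written to the B-factor field with 2 decimals; reading the
    output back yields an identical data model.
    """
    if not s.residues:
        raise FormatError("cannot write a structure with no residues")
    lines = []
    serial = 0
    for r in s.residues:
        resname = ONE_TO_THREE.get(r.aa, "UNK")
        for a in r.atoms:
            serial += 1
            for c in a.xyz:
                if abs(c) >= 10000:
                    raise FormatError(f"coordinate magnitude {c} exceeds PDB field width")
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {serial:>5d} {name:<4.4s} {resname:<3s} {s.chain_id}"
                f"{r.position:>4d}    "
                f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
                f"{1.00:6.2f}{r.plddt:6.2f}          {a.element:>2.2s}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# PTM tables (PhosphoSitePlus dialect)
# ---------------------------------------------------------------------------

def parse_mod_rsd(mod_rsd: str) -> tuple[str, int, str] | None:
    """Parse a MOD_RSD string like ``S417-p`` into (aa, position, ptm_class).

    Returns None when the string does not follow the dialect or the suffix is
    unknown.
    """
    text = mod_rsd.strip()
    if "-" not in text:
        return None
    body, _, suffix = text.rpartition("-")
    ptm_class = PTM_SUFFIXES.get(suffix.lower())
    if ptm_class is None:
        return None
    if len(body) < 2 or not body[0].isalpha() or not body[1:].isdigit():
        return None
    return body[0].upper(), int(body[1:]), ptm_class


def read_ptm_table(tsv_text: str, skip_preamble: int = 3) -> list[SiteRecord]:
    """Read a PhosphoSitePlus-dialect PTM table into raw SiteRecords.

    ``skip_preamble`` leading lines are discarded (the public download ships a
    3-line header block).  Rows whose MOD_RSD cannot be parsed are skipped
    with a logged warning; the reader never filters or classifies.
    """
    try:
        df = pd.read_csv(io.StringIO(tsv_text), sep="\t", skiprows=skip_preamble, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"unreadable PTM table: {exc}") from exc
    for col in ("ACC_ID", "MOD_RSD"):
        if col not in df.columns:
            raise FormatError(f"PTM table lacks required column {col!r}")

    records: list[SiteRecord] = []
    n_skipped = 0
    for _, row in df.iterrows():
        parsed = parse_mod_rsd(str(row["MOD_RSD"]))
        if parsed is None:
            n_skipped += 1
            logger.warning("skipping unparseable MOD_RSD %r (ACC_ID %r)",
                           row["MOD_RSD"], row["ACC_ID"])
            continue
        aa, position, ptm_class = parsed
        records.append(SiteRecord(accession=str(row["ACC_ID"]).strip(),
                                  position=position, aa=aa, ptm_class=ptm_class))
    if n_skipped:
        logger.info("read_ptm_table: %d rows parsed, %d skipped", len(records), n_skipped)
    return records


# ---------------------------------------------------------------------------
# Aligned FASTA
# ---------------------------------------------------------------------------

ALIGNMENT_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY-XBZUO")


@dataclass
class Alignment:
    """A rectangular multiple sequence alignment with one designated human row."""

    ids: list[str]
    matrix: np.ndarray  # (n_seq, n_col) of single characters
    human_id: str = ""

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2:
            raise FormatError("alignment matrix must be 2-D")
        if not self.human_id:
            humans = [i for i in self.ids if "HUMAN" in i.upper()]
            self.human_id = humans[0] if humans else self.ids[0]
        if self.human_id not in self.ids:
            raise DataError(f"human id {self.human_id!r} not among alignment ids")

    @property
    def n_seq(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_col(self) -> int:
        return self.matrix.shape[1]

    def row(self, seq_id: str) -> np.ndarray:
        return self.matrix[self.ids.index(seq_id)]

    def column(self, col: int) -> np.ndarray:
        """0-based column accessor."""
        return self.matrix[:, col]


def read_alignment_fasta(fasta_text: str, human_id: str = "") -> Alignment:
    """Read an aligned FASTA file (Clustal Omega output style)."""
    if not fasta_text.strip():
        raise FormatError("empty alignment file")
    try:
        aln = AlignIO.read(io.StringIO(fasta_text), "fasta")
    except ValueError as exc:
        raise FormatError(f"invalid aligned FASTA: {exc}") from exc
    ids = [rec.id for rec in aln]
    matrix = np.array([list(str(rec.seq).upper()) for rec in aln], dtype="U1")
    bad = set(matrix.ravel()) - ALIGNMENT_ALPHABET
    if bad:
        raise FormatError(f"alignment contains unexpected symbols: {sorted(bad)}")
    return Alignment(ids=ids, matrix=matrix, human_id=human_id)
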