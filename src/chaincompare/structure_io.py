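"""Read PDB and mmCIF files into a uniform chain model.

The unit of comparison throughout the package is a :class:`Chain`: an ordered
list of residues with heavy-atom coordinates, B-factors, author numbering and
resolution metadata, for one MODEL of one author chain.  Parsing is delegated
to Biopython's ``Bio.PDB``; this module flattens its hierarchy, resolves
alternate locations, drops hydrogens and non-polymer residues, and attaches
the full-sequence record (SEQRES / ``entity_poly``) needed for missing-residue
bookkeeping.
"""

from __future__ import annotations

import io
import math
import os
import warnings
from dataclasses import dataclass, replace

import numpy as np
from Bio import SeqIO
from Bio.PDB import MMCIFParser, PDBParser
from Bio.PDB.MMCIF2Dict import MMCIF2Dict
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from Bio.SeqUtils import seq1

#: Resolution (Å) assumed for structures without a resolution record
#: (NMR ensembles, models); a reliable average for solved NMR structures.
DEFAULT_RESOLUTION = 2.8

MAIN_CHAIN_ATOMS = ("N", "CA", "C", "O")


class StructureFormatError(ValueError):
    """Raised when a file cannot be parsed in the stated format."""


class EmptyInputError(ValueError):
    """Raised when a parsed file contains no polymer chain."""


class ChainLookupError(KeyError):
    """Raised when a requested (model, chain) pair does not exist."""


class EmptySelectionError(ValueError):
    """Raised when a residue range selects nothing."""


@dataclass(frozen=True)
class Atom:
    """A heavy atom with PDB-convention name, coordinates and B-factor."""

    name: str
    element: str
    coord: tuple[float, float, float]
    bfactor: float = 0.0
    occupancy: float = 1.0
    altloc: str = " "

    def __post_init__(self):
        if len(self.coord) != 3 or not all(math.isfinite(c) for c in self.coord):
            raise ValueError(f"atom {self.name}: coord must be 3 finite components")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord, dtype=float)


@dataclass(frozen=True)
class Residue:
    """One residue: author number (+ insertion code), 3-letter name, atoms."""

    author_number: int
    name: str
    atoms: tuple[Atom, ...]
    seq_index: int
    insertion_code: str = ""

    @property
    def author_id(self) -> tuple[int, str]:
        return (self.author_number, self.insertion_code)

    @property
    def author_label(self) -> str:
        return f"{self.author_number}{self.insertion_code}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> np.ndarray | None:
        a = self.atom(name)
        return None if a is None else a.xyz

    @property
    def one_letter(self) -> str:
        code = seq1(self.name.capitalize(), undef_code="X")
        return code if code.isalpha() else "X"

    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in MAIN_CHAIN_ATOMS)

    def mean_bfactor(self) -> float:
        return float(np.mean([a.bfactor for a in self.atoms]))


@dataclass(frozen=True)
class ResidueRange:
    """Inclusive author-numbering range; insertion-coded residues whose
    integer part falls inside the range are retained."""

    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"range start {self.start} > end {self.end}")

    def __contains__(self, author_number: int) -> bool:
        return self.start <= author_number <= self.end


@dataclass(frozen=True)
class Chain:
    """Ordered residues of one author chain in one MODEL."""

    chain_id: str
    model_id: int
    residues: tuple[Residue, ...]
    resolution: float | None = None
    full_sequence: str | None = None  # SEQRES / entity_poly one-letter record
    source: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    @property
    def missing_positions(self) -> frozenset[int]:
        return frozenset(detect_missing(self))

    def ca_coords(self) -> np.ndarray:
        """Cα coordinates of residues that have a Cα (others skipped)."""
        return np.array(
            [r.coord("CA") for r in self.residues if r.atom("CA") is not None]
        )


# ---------------------------------------------------------------------------
# parsing


def _looks_like_mmcif(text: str) -> bool:
    head = text[:4000]
    return head.lstrip().startswith("data_") or "_atom_site." in head


def _detect_format(source: str, text: str) -> str:
    if os.path.exists(source):
        ext = os.path.splitext(source)[1].lower()
        if ext in (".cif", ".mmcif"):
            return "mmcif"
        if ext in (".pdb", ".ent"):
            return "pdb"
    return "mmcif" if _looks_like_mmcif(text) else "pdb"


def _read_text(source) -> tuple[str, str]:
    """Return (text, label) for a path or raw text input."""
    if hasattr(source, "read"):
        return source.read(), "<stream>"
    if isinstance(source, os.PathLike) or (
        isinstance(source, str) and "\n" not in source and os.path.exists(source)
    ):
        with open(source) as fh:
            return fh.read(), str(source)
    return str(source), "<text>"


def _pick_altloc(bio_residue):
    """Resolve disordered atoms: highest occupancy, ties broken by altloc id."""
    chosen = {}
    for atom in bio_residue.get_unpacked_list():
        elem = (atom.element or "").strip().upper()
        if elem in ("H", "D"):
            continue
        name = atom.get_name()
        occ = atom.get_occupancy()
        occ = 1.0 if occ is None else float(occ)
        key = (occ, -ord(atom.get_altloc() or " "))
        if name not in chosen or key > chosen[name][0]:
            chosen[name] = (key, atom)
    return [a for _, a in chosen.values()]


def _pdb_resolution(structure, text: str) -> float | None:
    res = structure.header.get("resolution") if structure.header else None
    if res is not None:
        try:
            res = float(res)
        except (TypeError, ValueError):
            return None
        return res if res > 0 else None
    return None


def _pdb_seqres(text: str) -> dict[str, str]:
    if "SEQRES" not in text:
        return {}
    out = {}
    try:
        for rec in SeqIO.parse(io.StringIO(text), "pdb-seqres"):
            out[rec.annotations.get("chain", "")] = str(rec.seq)
    except Exception:  # malformed SEQRES never blocks coordinate parsing
        return {}
    return out


def _mmcif_resolution(d: dict) -> float | None:
    for key in (
        "_refine.ls_d_res_high",
        "_em_3d_reconstruction.resolution",
        "_reflns.d_resolution_high",
    ):
        vals = d.get(key)
        if vals:
            v = vals[0] if isinstance(vals, list) else vals
            try:
                f = float(v)
            except (TypeError, ValueError):
                continue
            if f > 0:
                return f
    return None


def _mmcif_seqres(d: dict) -> dict[str, str]:
    """Per-author-chain one-letter full sequence from entity_poly categories."""
    ent_ids = d.get("_entity_poly.entity_id")
    strands = d.get("_entity_poly.pdbx_strand_id")
    if not ent_ids or not strands:
        return {}
    if not isinstance(ent_ids, list):
        ent_ids, strands = [ent_ids], [strands]
    seq_ent = d.get("_entity_poly_seq.entity_id", [])
    seq_mon = d.get("_entity_poly_seq.mon_id", [])
    if not isinstance(seq_ent, list):
        seq_ent, seq_mon = [seq_ent], [seq_mon]
    per_entity: dict[str, str] = {}
    for ent, mon in zip(seq_ent, seq_mon):
        code = seq1(mon.capitalize(), undef_code="X")
        per_entity[ent] = per_entity.get(ent, "") + (code if code.isalpha() else "X")
    out = {}
    for ent, strand in zip(ent_ids, strands):
        for ch in strand.replace(" ", "").split(","):
            if ch and ent in per_entity:
                out[ch] = per_entity[ent]
    return out


def _convert(structure, seqres, resolution, label) -> list[Chain]:
    chains: list[Chain] = []
    for model in structure:
        model_id = model.serial_num if getattr(model, "serial_num", 0) else model.id + 1
        for bio_chain in model:
            residues = []
            for bio_res in bio_chain:
                het, num, icode = bio_res.id
                if het.strip():  # waters and ligands are not polymer residues
                    continue
                atoms = []
                for atom in _pick_altloc(bio_res):
                    occ = atom.get_occupancy()
                    atoms.append(
                        Atom(
                            name=atom.get_name(),
                            element=(atom.element or "").strip().upper(),
                            coord=tuple(float(x) for x in atom.get_coord()),
                            bfactor=float(atom.get_bfactor() or 0.0),
                            occupancy=1.0 if occ is None else float(occ),
                            altloc=atom.get_altloc() or " ",
                        )
                    )
                if not atoms:
                    continue
                residues.append(
                    Residue(
                        author_number=int(num),
                        name=bio_res.get_resname().strip(),
                        atoms=tuple(atoms),
                        seq_index=len(residues),
                        insertion_code=icode.strip(),
                    )
                )
            if not residues:
                continue
            chains.append(
                Chain(
                    chain_id=bio_chain.id,
                    model_id=model_id,
                    residues=tuple(residues),
                    resolution=resolution,
                    full_sequence=seqres.get(bio_chain.id),
                    source=label,
                )
            )
    return chains


def read_structure(source, format: str = "auto") -> list[Chain]:
    """Parse a PDB or mmCIF file (path, text, or handle) into Chains.

    Every polymer chain of every MODEL is returned, HETATM-only chains
    (waters, ligands) excluded.  ``format`` is ``pdb``, ``mmcif`` or ``auto``
    (detect by extension, then content).
    """
    text, label = _read_text(source)
    fmt = _detect_format(label, text) if format == "auto" else format
    if fmt not in ("pdb", "mmcif"):
        raise StructureFormatError(f"unknown format {format!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            if fmt == "pdb":
                structure = PDBParser(QUIET=True).get_structure("s", io.StringIO(text))
                resolution = _pdb_resolution(structure, text)
                seqres = _pdb_seqres(text)
            else:
                structure = MMCIFParser(QUIET=True).get_structure(
                    "s", io.StringIO(text)
                )
                d = MMCIF2Dict(io.StringIO(text))
                resolution = _mmcif_resolution(d)
                seqres = _mmcif_seqres(d)
        except StructureFormatError:
            raise
        except Exception as exc:
            raise StructureFormatError(f"{label}: cannot parse as {fmt}: {exc}") from exc
    chains = _convert(structure, seqres, resolution, label)
    if not chains:
        raise EmptyInputError(f"{label}: no polymer chains found")
    return chains


# ---------------------------------------------------------------------------
# selection and metadata


def effective_resolution(chain: Chain) -> float:
    """Header resolution, or :data:`DEFAULT_RESOLUTION` (2.8 Å) when the
    structure has none (NMR ensembles, models)."""
    if chain.resolution is not None and chain.resolution > 0:
        return float(chain.resolution)
    return DEFAULT_RESOLUTION


def select_chain(
    chains: list[Chain],
    model_id: int,
    chain_id: str,
    residue_range: ResidueRange | None = None,
) -> Chain:
    """Pick one (model, chain) and optionally restrict to an author-numbering
    range (inclusive; insertion-coded residues inside the range retained)."""
    match = [c for c in chains if c.model_id == model_id and c.chain_id == chain_id]
    if not match:
        avail = sorted({(c.model_id, c.chain_id) for c in chains})
        raise ChainLookupError(
            f"no chain (model={model_id}, chain={chain_id!r}); available: {avail}"
        )
    chain = match[0]
    if residue_range is None:
        return chain
    kept = [r for r in chain.residues if r.author_number in residue_range]
    if not kept:
        raise EmptySelectionError(
            f"range {residue_range.start}-{residue_range.end} selects no residues"
        )
    kept = [replace(r, seq_index=i) for i, r in enumerate(kept)]
    return replace(chain, residues=tuple(kept))


def detect_missing(chain: Chain) -> set[int]:
    """Author numbers of residues absent from the coordinates.

    Uses the full-sequence record (SEQRES / entity_poly) when available,
    locating unmodelled positions by global alignment of the record sequence
    against the coordinate sequence; otherwise falls back to gaps in the
    author numbering.
    """
    if chain.full_sequence and len(chain.full_sequence) > len(chain.residues):
        return _missing_from_seqres(chain)
    return _missing_from_numbering(chain)


def _missing_from_numbering(chain: Chain) -> set[int]:
    missing: set[int] = set()
    for prev, cur in zip(chain.residues, chain.residues[1:]):
        gap = cur.author_number - prev.author_number
        if gap > 1:
            missing.update(range(prev.author_number + 1, cur.author_number))
    return missing


def _missing_from_seqres(chain: Chain) -> set[int]:
    # identity-scored global alignment of record vs coordinate sequence;
    # unmatched record positions are the missing residues
    from .chain_alignment import align_strings

    pairs = align_strings(chain.full_sequence, chain.sequence)
    # author number for each matched record position
    matched: dict[int, int] = {}
    for i_full, i_coord in pairs:
        if i_full is not None and i_coord is not None:
            matched[i_full] = chain.residues[i_coord].author_number
    missing: set[int] = set()
    for i_full, i_coord in pairs:
        if i_full is None or i_coord is not None:
            continue
        # extrapolate an author number from the nearest matched neighbour
        left = [k for k in matched if k < i_full]
        right = [k for k in matched if k > i_full]
        if left:
            k = max(left)
            missing.add(matched[k] + (i_full - k))
        elif right:
            k = min(right)
            missing.add(matched[k] - (k - i_full))
    return missing
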