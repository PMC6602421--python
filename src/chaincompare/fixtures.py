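"""Deterministic synthetic protein fixtures.

Generators for idealized poly-alanine chains — α-helices, extended strands,
β-hairpins, hinged chain pairs and perturbed copies — built in torsion space
with standard peptide geometry, so that every comparison metric in the
package can be exercised without downloading real structures.  Geometry is
idealized: bond lengths and angles come from standard tables, side chains
beyond Cβ (the arginine variant) are schematic extended arms, and nothing
here samples a physical ensemble.  All randomness is seeded.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace

import numpy as np
from Bio.PDB import MMCIFIO, PDBIO
from Bio.PDB.StructureBuilder import StructureBuilder

from .structure_io import Atom, Chain, Residue

# standard peptide geometry (Å / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 117.2
ANGLE_CA_C_O = 120.5

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of one synthetic fixture."""

    kind: str  # ideal_helix | extended_strand | beta_hairpin | hinge_pair | perturbed_copy
    n_residues: int
    seed: int = 0
    params: tuple = ()


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Internal-to-Cartesian (NeRF): position D from A-B-C with |CD|=bond,
    angle(B,C,D)=angle, dihedral(A,B,C,D)=dihedral."""
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(dih),
            bond * math.sin(ang) * math.sin(dih),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _place_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    u1 = (n - ca) / np.linalg.norm(n - ca)
    u2 = (c - ca) / np.linalg.norm(c - ca)
    bisec = -(u1 + u2)
    bisec /= np.linalg.norm(bisec)
    perp = np.cross(u2, u1)
    perp /= np.linalg.norm(perp)
    direction = bisec * math.cos(0.615) + perp * math.sin(0.615)
    return ca + 1.53 * direction


_ARG_TAIL = ("CG", "CD", "NE", "CZ")


def _side_chain_atoms(name: str, n, ca, c, bfactor: float) -> list[Atom]:
    """Schematic side chain: Cβ at the tetrahedral position; for arginine an
    extended zigzag arm CG-CD-NE-CZ with NH1/NH2 branching off CZ."""
    if name == "GLY":
        return []
    cb = _place_cb(n, ca, c)
    atoms = [Atom("CB", "C", tuple(np.round(cb, 6)), bfactor)]
    if name != "ARG":
        return atoms
    axis = (cb - ca) / np.linalg.norm(cb - ca)
    perp = np.cross(axis, (c - n) / np.linalg.norm(c - n))
    perp /= np.linalg.norm(perp)
    pos = cb
    for k, nm in enumerate(_ARG_TAIL):
        wobble = perp * (0.35 if k % 2 == 0 else -0.35)
        pos = pos + 1.5 * axis + wobble
        elem = nm[0]
        atoms.append(Atom(nm, elem, tuple(np.round(pos, 6)), bfactor))
    cz = pos
    for nm, sign in (("NH1", 1.0), ("NH2", -1.0)):
        nh = cz + 1.33 * (axis * math.cos(1.05) + sign * perp * math.sin(1.05))
        atoms.append(Atom(nm, "N", tuple(np.round(nh, 6)), bfactor))
    return atoms


def build_backbone(
    torsions: list[tuple[float, float, float]],
    residue_names: list[str] | None = None,
    chain_id: str = "A",
    start_number: int = 1,
) -> Chain:
    """Build a full-backbone chain from per-residue (φ, ψ, ω) torsions.

    φ of the first residue and ψ/ω of the last are unused, as in any real
    chain.  Residues are poly-alanine unless ``residue_names`` says
    otherwise; B-factors ramp deterministically (10 + seq_index) so that
    percentile tracks are non-trivial.
    """
    n = len(torsions)
    if n < 1:
        raise ValueError("need at least one residue")
    names = residue_names or ["ALA"] * n
    if len(names) != n:
        raise ValueError("residue_names length mismatch")
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    ang = math.radians(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, n):
        psi_prev = torsions[i - 1][1]
        omega_prev = torsions[i - 1][2]
        phi = torsions[i][0]
        N[i] = _place_atom(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        CA[i] = _place_atom(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANGLE_C_N_CA, omega_prev)
        C[i] = _place_atom(C[i - 1], N[i], CA[i], BOND_CA_C, ANGLE_N_CA_C, phi)
    residues = []
    for i in range(n):
        bfac = 10.0 + i
        atoms = [
            Atom("N", "N", tuple(np.round(N[i], 6)), bfac),
            Atom("CA", "C", tuple(np.round(CA[i], 6)), bfac),
            Atom("C", "C", tuple(np.round(C[i], 6)), bfac),
        ]
        # carbonyl O in the peptide plane, trans to the next N
        if i < n - 1:
            psi = torsions[i][1]
            o = _place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        else:
            o = _place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, 0.0)
        atoms.append(Atom("O", "O", tuple(np.round(o, 6)), bfac))
        atoms.extend(_side_chain_atoms(names[i], N[i], CA[i], C[i], bfac))
        residues.append(
            Residue(
                author_number=start_number + i,
                name=names[i],
                atoms=tuple(atoms),
                seq_index=i,
            )
        )
    return Chain(chain_id=chain_id, model_id=1, residues=tuple(residues), source="fixture")


def make_ideal_helix(
    n: int, residue_names: list[str] | None = None, chain_id: str = "A"
) -> Chain:
    """Ideal α-helix (φ=-57°, ψ=-47°, ω=180°), poly-alanine by default."""
    if n < 4:
        raise ValueError("an ideal helix fixture needs n >= 4 residues")
    phi, psi = HELIX_PHI_PSI
    return build_backbone([(phi, psi, 180.0)] * n, residue_names, chain_id)


def make_extended_strand(n: int, chain_id: str = "A") -> Chain:
    """Single fully extended β-strand with no pairing partner."""
    if n < 2:
        raise ValueError("need n >= 2")
    phi, psi = STRAND_PHI_PSI
    return build_backbone([(phi, psi, 180.0)] * n, chain_id=chain_id)


def make_beta_hairpin(n_per_strand: int = 6, chain_id: str = "A") -> Chain:
    """Two-strand antiparallel hairpin joined by a tight type-I' turn."""
    if n_per_strand < 3:
        raise ValueError("need at least 3 residues per strand")
    phi_e, psi_e = STRAND_PHI_PSI
    torsions = [(phi_e, psi_e, 180.0)] * n_per_strand
    # left-handed two-residue turn calibrated so the strands register
    # cross-strand H-bonds (a laddered hairpin, not just two loose strands)
    torsions += [(45.0, -90.0, 180.0), (-90.0, -30.0, 180.0)]
    torsions += [(phi_e, psi_e, 180.0)] * n_per_strand
    names = ["ALA"] * n_per_strand + ["GLY", "GLY"] + ["ALA"] * n_per_strand
    return build_backbone(torsions, names, chain_id)


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(a) * K + (1 - math.cos(a)) * (K @ K)


def hinge_axis(chain: Chain, hinge_at: int) -> tuple[np.ndarray, np.ndarray]:
    """Rotation axis used by :func:`make_hinge_pair`: through the hinge Cα,
    perpendicular to the local helix axis (and chosen radially, so that the
    arc displacement grows monotonically along the moving arm).

    Returns ``(pivot, axis_unit_vector)``; ``hinge_at`` is 1-based.
    """
    idx = hinge_at - 1
    ca = chain.ca_coords()
    lo = max(0, idx - 3)
    hi = min(len(ca) - 1, idx + 3)
    local_axis = ca[hi] - ca[lo]
    local_axis /= np.linalg.norm(local_axis)
    # radial direction: from the local axis line towards the pivot Cα
    centroid = ca[lo : hi + 1].mean(axis=0)
    radial = ca[idx] - centroid
    radial -= (radial @ local_axis) * local_axis
    if np.linalg.norm(radial) < 1e-6:
        ref = np.array([0.0, 0.0, 1.0])
        if abs(local_axis @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        radial = np.cross(local_axis, ref)
    return ca[idx].copy(), radial / np.linalg.norm(radial)


def _transform_chain(chain: Chain, move, start_index: int) -> Chain:
    residues = []
    for r in chain.residues:
        if r.seq_index < start_index:
            residues.append(r)
            continue
        atoms = tuple(
            replace(a, coord=tuple(move(a.xyz))) for a in r.atoms
        )
        residues.append(replace(r, atoms=atoms))
    return replace(chain, residues=tuple(residues))


def make_hinge_pair(
    n: int = 30, hinge_at: int = 15, angle: float = 20.0
) -> tuple[Chain, Chain]:
    """Two chains identical up to ``hinge_at`` (1-based); in the second, all
    residues after the hinge are rigidly rotated by ``angle`` degrees about
    an axis through the hinge Cα perpendicular to the local helix axis.

    The base chain is two α-helical arms joined by a short extended linker
    centred on the hinge, so the rotation moves one intact helix relative to
    the other and the secondary structure of the pair is identical by
    construction (a pure hinge: tertiary change without secondary change).
    """
    if not (1 < hinge_at < n):
        raise ValueError(f"hinge_at must lie strictly inside the chain (1 < {hinge_at} < {n})")
    phi_h, psi_h = HELIX_PHI_PSI
    # linker torsions chosen so that neither assigner's state at the loop
    # sits near a threshold: states stay identical for hinge angles ≤ ~25°
    phi_l, psi_l = 20.0, 0.0
    torsions = []
    linker = {hinge_at - 1, hinge_at, hinge_at + 1}  # 1-based positions
    for pos in range(1, n + 1):
        if pos in linker:
            torsions.append((phi_l, psi_l, 180.0))
        else:
            torsions.append((phi_h, psi_h, 180.0))
    base = build_backbone(torsions)
    if angle == 0.0:
        return base, base
    pivot, axis = hinge_axis(base, hinge_at)
    R = _rotation_about_axis(axis, angle)
    moved = _transform_chain(
        base, lambda x: pivot + R @ (x - pivot), start_index=hinge_at
    )
    return base, replace(moved, chain_id=base.chain_id)


def transform_chain(
    chain: Chain, rotation: np.ndarray, translation: np.ndarray
) -> Chain:
    """Exact rigid copy: every atom moved to ``R @ x + t``."""
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)
    return _transform_chain(chain, lambda x: R @ x + t, start_index=0)


def make_perturbed_line(n: int = 30, sigma: float = 2.0, seed: int = 0) -> Chain:
    """Cα-only random-coil stand-in: a straight 3.8 Å-spaced Cα trace with
    isotropic Gaussian noise of ``sigma`` Å (seeded)."""
    rng = np.random.default_rng(seed)
    coords = np.zeros((n, 3))
    coords[:, 0] = 3.8 * np.arange(n)
    coords += rng.normal(0.0, sigma, size=(n, 3))
    residues = tuple(
        Residue(
            author_number=i + 1,
            name="ALA",
            atoms=(Atom("CA", "C", tuple(coords[i]), 10.0 + i),),
            seq_index=i,
        )
        for i in range(n)
    )
    return Chain(chain_id="A", model_id=1, residues=residues, source="fixture")


def perturb(
    chain: Chain, sigma: float, seed: int, atoms: str = "side_chain_only"
) -> Chain:
    """Seeded isotropic Gaussian displacement of the selected atom set.

    ``atoms`` is ``side_chain_only`` (backbone N/CA/C/O untouched) or
    ``all``.  ``sigma=0`` returns an exact copy.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if atoms not in ("side_chain_only", "all"):
        raise ValueError(f"unknown atom set {atoms!r}")
    rng = np.random.default_rng(seed)
    backbone = {"N", "CA", "C", "O"}
    residues = []
    for r in chain.residues:
        new_atoms = []
        for a in r.atoms:
            if atoms == "side_chain_only" and a.name in backbone:
                new_atoms.append(a)
                continue
            shift = rng.normal(0.0, sigma, size=3) if sigma > 0 else np.zeros(3)
            new_atoms.append(replace(a, coord=tuple(a.xyz + shift)))
        residues.append(replace(r, atoms=tuple(new_atoms)))
    return replace(chain, residues=tuple(residues))


def round_coords(chain: Chain, ndigits: int = 3) -> Chain:
    """Chain with coordinates rounded to file precision (PDB: 3 decimals);
    useful for exact round-trip comparisons against written fixtures."""
    residues = tuple(
        replace(
            r,
            atoms=tuple(
                replace(a, coord=tuple(round(c, ndigits) for c in a.coord))
                for a in r.atoms
            ),
        )
        for r in chain.residues
    )
    return replace(chain, residues=residues)


# ---------------------------------------------------------------------------
# writing


def _to_bio_structure(chains: list[Chain], multi_model: bool):
    builder = StructureBuilder()
    builder.init_structure("fixture")
    builder.init_seg("    ")
    for k, chain in enumerate(chains):
        if multi_model or k == 0:
            builder.init_model(k, k + 1)
        builder.init_chain(chain.chain_id if not multi_model else chains[0].chain_id)
        for res in chain.residues:
            builder.init_residue(
                res.name, " ", res.author_number, res.insertion_code or " "
            )
            for atom in res.atoms:
                builder.init_atom(
                    atom.name,
                    np.asarray(atom.coord, dtype=float),
                    atom.bfactor,
                    atom.occupancy,
                    atom.altloc if atom.altloc.strip() else " ",
                    f" {atom.name:<3s}"[:4],
                    element=atom.element,
                )
    return builder.get_structure()


def write_fixture(
    chain_or_pair, path, format: str = "pdb", multi_model: bool = False
) -> None:
    """Write one Chain, or a pair/list of Chains, as PDB or mmCIF.

    With ``multi_model`` each chain becomes its own MODEL record (emulating
    NMR-ensemble / MD-trajectory files); otherwise multiple chains share one
    model under their own chain ids.  Output round-trips through
    :func:`chaincompare.structure_io.read_structure` at file precision.
    """
    chains = (
        [chain_or_pair] if isinstance(chain_or_pair, Chain) else list(chain_or_pair)
    )
    structure = _to_bio_structure(chains, multi_model)
    writer = PDBIO() if format == "pdb" else MMCIFIO()
    if format not in ("pdb", "mmcif"):
        raise ValueError(f"unknown format {format!r}")
    writer.set_structure(structure)
    writer.save(str(path))
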