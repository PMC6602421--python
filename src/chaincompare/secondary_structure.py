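"""Per-residue secondary-structure assignment.

Two assigners are implemented in-repo:

* :func:`assign_hbond` — the classic hydrogen-bond pattern method of Kabsch
  and Sander: backbone amide hydrogens are reconstructed, an electrostatic
  H-bond energy is evaluated for every donor/acceptor pair, and n-turns,
  bridges, helices and ladders are composed into the 8-state alphabet
  ``H G I E B T S -``.
* :func:`assign_ca_geometry` — a Cα-only geometric assigner in the P-SEA
  tradition: sliding windows of Cα(i)-Cα(i+k) distances (k = 2, 3, 4), the
  pseudo bond angle τ and pseudo dihedral α are tested against threshold
  windows, giving the three working states ``H E -``.

Outputs of external assigners (classic DSSP columnar reports, STRIDE ASG
records) enter through :func:`parse_assignment_file`.  Every extended string
reduces to the three-state alphabet H/E/O via :func:`to_three_state`.

A method that cannot produce output for a chain (too few residues with the
required atoms) is *disabled* — returned with ``enabled=False`` and an
all-'-' string — rather than raising, so that downstream consensus simply
drops it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .structure_io import Chain

#: Kabsch-Sander electrostatic constant, kcal·Å/mol (q1*q2*332 with
#: partial charges 0.42 and 0.20).
HBOND_Q = 27.888
#: H-bond acceptance threshold, kcal/mol.
HBOND_CUTOFF = -0.5
#: Peptide-bond C(i)-N(i+1) distance beyond which the chain is broken, Å.
CHAIN_BREAK_DISTANCE = 2.5

THREE_STATE_MAP = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E", "b": "E"}

METHOD_LABELS = {
    "hbond": "HBOND",
    "ca_geom": "CAGEOM",
    "dssp_file": "DSSP",
    "stride_file": "STRIDE",
}


class AssignmentMappingError(ValueError):
    """External assignment file shares no residues with the chain."""


class AssignmentDialectError(ValueError):
    """External assignment file violates its declared dialect."""


@dataclass(frozen=True)
class SSAssignment:
    """Per-residue states for one chain under one method."""

    method: str
    extended: str
    three_state: str
    enabled: bool = True

    def __post_init__(self):
        if len(self.extended) != len(self.three_state):
            raise ValueError("extended and three_state lengths differ")


@dataclass(frozen=True)
class HBond:
    donor: int  # seq_index of the N-H residue
    acceptor: int  # seq_index of the C=O residue
    energy: float  # kcal/mol


def to_three_state(a: SSAssignment) -> SSAssignment:
    """Reduce the extended alphabet: H,G,I → H; E,B → E; all else → O."""
    reduced = "".join(THREE_STATE_MAP.get(c, "O") for c in a.extended)
    return replace(a, three_state=reduced)


def _disabled(method: str, n: int) -> SSAssignment:
    return SSAssignment(method=method, extended="-" * n, three_state="O" * n, enabled=False)


# ---------------------------------------------------------------------------
# hydrogen-bond (Kabsch-Sander) method


def _backbone_arrays(chain: Chain):
    n = len(chain.residues)
    coords = {name: np.full((n, 3), np.nan) for name in ("N", "CA", "C", "O")}
    for i, res in enumerate(chain.residues):
        for name in coords:
            c = res.coord(name)
            if c is not None:
                coords[name][i] = c
    valid = ~np.isnan(np.hstack([coords[k] for k in coords])).any(axis=1)
    return coords, valid


def _chain_breaks(coords, valid) -> np.ndarray:
    """break_after[i] is True when the peptide bond i → i+1 is absent."""
    n = len(valid)
    break_after = np.zeros(n, dtype=bool)
    for i in range(n - 1):
        if not (valid[i] and valid[i + 1]):
            break_after[i] = True
            continue
        d = np.linalg.norm(coords["C"][i] - coords["N"][i + 1])
        if d > CHAIN_BREAK_DISTANCE:
            break_after[i] = True
    return break_after


def _amide_hydrogens(chain: Chain, coords, valid, break_after) -> np.ndarray:
    """Reconstruct backbone H: 1.0 Å from N along the bisector opposite the
    C(i-1)-N and CA-N directions (the amide plane assumption).  First
    residue, prolines and residues after a chain break have no donor
    hydrogen (NaN)."""
    n = len(valid)
    H = np.full((n, 3), np.nan)
    for i in range(1, n):
        if not (valid[i] and valid[i - 1]) or break_after[i - 1]:
            continue
        if chain.residues[i].name == "PRO":
            continue
        v1 = coords["N"][i] - coords["C"][i - 1]
        v2 = coords["N"][i] - coords["CA"][i]
        v1 /= np.linalg.norm(v1)
        v2 /= np.linalg.norm(v2)
        bisector = v1 + v2
        norm = np.linalg.norm(bisector)
        if norm < 1e-9:
            continue
        H[i] = coords["N"][i] + bisector / norm
    return H


def backbone_hbonds(
    chain: Chain, cutoff: float = HBOND_CUTOFF, max_ca_dist: float = 9.0
) -> list[HBond]:
    """Kabsch-Sander backbone H-bonds: donor N-H of residue *d*, acceptor
    C=O of residue *a*, energy

        E = 27.888 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol,

    kept when E < ``cutoff``.  Following the original method, only the two
    lowest-energy acceptors per donor are retained."""
    coords, valid = _backbone_arrays(chain)
    break_after = _chain_breaks(coords, valid)
    H = _amide_hydrogens(chain, coords, valid, break_after)
    ca = coords["CA"]
    n = len(valid)
    per_donor: dict[int, list[HBond]] = {}
    for d in range(n):
        if np.isnan(H[d]).any():
            continue
        for a in range(n):
            if a == d or not valid[a]:
                continue
            if np.linalg.norm(ca[d] - ca[a]) > max_ca_dist:
                continue
            r_on = np.linalg.norm(coords["O"][a] - coords["N"][d])
            r_ch = np.linalg.norm(coords["C"][a] - H[d])
            r_oh = np.linalg.norm(coords["O"][a] - H[d])
            r_cn = np.linalg.norm(coords["C"][a] - coords["N"][d])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                energy = -9.9  # clash clamp, as in the original method
            else:
                energy = HBOND_Q * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if energy < cutoff:
                per_donor.setdefault(d, []).append(HBond(d, a, energy))
    bonds: list[HBond] = []
    for d, lst in per_donor.items():
        lst.sort(key=lambda b: b.energy)
        bonds.extend(lst[:2])
    return bonds


def _compose_states(chain: Chain, bonds: list[HBond], break_after) -> str:
    """Compose 8-state string from the H-bond set per the published rules."""
    n = len(chain.residues)
    hb = {(b.donor, b.acceptor) for b in bonds}

    def bond(donor: int, acceptor: int) -> bool:
        return (donor, acceptor) in hb

    def contiguous(lo: int, hi: int) -> bool:
        lo, hi = max(lo, 0), min(hi, n - 1)
        return not break_after[lo:hi].any()

    # n-turns: C=O of i accepts from N-H of i+k
    turns = {k: np.zeros(n, dtype=bool) for k in (3, 4, 5)}
    for k in (3, 4, 5):
        for i in range(n - k):
            if bond(i + k, i) and contiguous(i, i + k):
                turns[k][i] = True

    # bridges
    parallel = set()
    antiparallel = set()
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            if not (contiguous(i - 1, i + 1) and contiguous(j - 1, j + 1)):
                continue
            if (bond(j, i - 1) and bond(i + 1, j)) or (
                bond(i, j - 1) and bond(j + 1, i)
            ):
                parallel.add((i, j))
            if (bond(i, j) and bond(j, i)) or (
                bond(j + 1, i - 1) and bond(i + 1, j - 1)
            ):
                antiparallel.add((i, j))

    # ladders: runs of consecutive bridges of one type
    ladders = []  # (type, [(i, j), ...])
    for typ, bridges in (("P", parallel), ("A", antiparallel)):
        remaining = set(bridges)
        step = 1 if typ == "P" else -1
        for i, j in sorted(bridges):
            if (i, j) not in remaining:
                continue
            run = [(i, j)]
            remaining.discard((i, j))
            while (run[-1][0] + 1, run[-1][1] + step) in remaining:
                nxt = (run[-1][0] + 1, run[-1][1] + step)
                run.append(nxt)
                remaining.discard(nxt)
            ladders.append((typ, run))

    # bulge linkage: same-type ladders joined by ≤1 residue on one strand
    # and ≤4 on the other merge into one sheet-worthy ladder
    extended = np.zeros(n, dtype=bool)
    bridge_only = np.zeros(n, dtype=bool)
    merged = [set(idx for pr in run for idx in pr) for _, run in ladders]
    types = [typ for typ, _ in ladders]
    spans = [run for _, run in ladders]
    linked = np.zeros(len(ladders), dtype=bool)
    for x in range(len(ladders)):
        for y in range(len(ladders)):
            if x == y or types[x] != types[y]:
                continue
            ix, jx = spans[x][-1]
            iy, jy = spans[y][0]
            gi = iy - ix - 1
            gj = abs(jy - jx) - 1
            if gi < 0 or gj < 0:
                continue
            if (gi <= 1 and gj <= 4) or (gi <= 4 and gj <= 1):
                linked[x] = linked[y] = True
                # residues spanning the bulge on each strand become E
                for idx in range(min(ix, iy), max(ix, iy) + 1):
                    extended[idx] = True
                for idx in range(min(jx, jy), max(jx, jy) + 1):
                    extended[idx] = True
    for k, (typ, run) in enumerate(ladders):
        members = merged[k]
        if len(run) >= 2 or linked[k]:
            for idx in members:
                extended[idx] = True
        else:
            for idx in members:
                bridge_only[idx] = True

    # helices: two consecutive n-turns start a minimal helix
    helix = {k: np.zeros(n, dtype=bool) for k in (3, 4, 5)}
    for k in (3, 4, 5):
        for i in range(1, n - k):
            if turns[k][i - 1] and turns[k][i]:
                helix[k][i : i + k] = True

    # turn flag: any residue inside an n-turn span
    turn_flag = np.zeros(n, dtype=bool)
    for k in (3, 4, 5):
        for i in range(n):
            if turns[k][i]:
                turn_flag[i + 1 : i + k] = True

    # bend: Cα direction change > 70°
    bend = np.zeros(n, dtype=bool)
    ca = np.array(
        [
            r.coord("CA") if r.atom("CA") is not None else [np.nan] * 3
            for r in chain.residues
        ]
    )
    for i in range(2, n - 2):
        if not contiguous(i - 2, i + 2):
            continue
        u = ca[i] - ca[i - 2]
        v = ca[i + 2] - ca[i]
        if np.isnan(u).any() or np.isnan(v).any():
            continue
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1e-9 or nv < 1e-9:
            continue
        ang = np.degrees(np.arccos(np.clip(u @ v / (nu * nv), -1, 1)))
        if ang > 70:
            bend[i] = True

    out = []
    for i in range(n):
        if helix[4][i]:
            out.append("H")
        elif extended[i]:
            out.append("E")
        elif bridge_only[i]:
            out.append("B")
        elif helix[3][i]:
            out.append("G")
        elif helix[5][i]:
            out.append("I")
        elif turn_flag[i]:
            out.append("T")
        elif bend[i]:
            out.append("S")
        else:
            out.append("-")
    return "".join(out)


def assign_hbond(chain: Chain, cutoff: float = HBOND_CUTOFF) -> SSAssignment:
    """Hydrogen-bond pattern assignment (8-state ``H G I E B T S -``).

    Amide hydrogens are reconstructed geometrically; chain breaks
    (C-N > 2.5 Å) terminate all patterns.  Chains with fewer than five
    full-backbone residues disable the method instead of raising.
    """
    n = len(chain.residues)
    coords, valid = _backbone_arrays(chain)
    if int(valid.sum()) < 5:
        return _disabled("hbond", n)
    break_after = _chain_breaks(coords, valid)
    bonds = backbone_hbonds(chain, cutoff=cutoff)
    extended = _compose_states(chain, bonds, break_after)
    return to_three_state(SSAssignment("hbond", extended, "O" * n))


# ---------------------------------------------------------------------------
# Cα-geometry method (P-SEA-tradition windows)


@dataclass(frozen=True)
class CaGeomParams:
    """Threshold windows for the Cα-geometry assigner (Å / degrees).

    Defaults are the published P-SEA windows: mean ± tolerance for
    Cα(i-1)-Cα(i+1) (d2), Cα(i)-Cα(i+3) (d3), Cα(i)-Cα(i+4) (d4) distances
    and for the pseudo bond angle τ(i-1,i,i+1) and pseudo dihedral
    α(i-1,i,i+1,i+2).
    """

    helix_d2: tuple[float, float] = (5.0, 6.0)
    helix_d3: tuple[float, float] = (4.8, 5.8)
    helix_d4: tuple[float, float] = (5.8, 7.0)
    helix_tau: tuple[float, float] = (77.0, 101.0)
    helix_alpha: tuple[float, float] = (30.0, 70.0)
    strand_d2: tuple[float, float] = (6.1, 7.3)
    strand_d3: tuple[float, float] = (9.0, 10.8)
    strand_d4: tuple[float, float] = (11.3, 13.5)
    strand_tau: tuple[float, float] = (110.0, 138.0)
    strand_alpha_abs: tuple[float, float] = (125.0, 180.0)
    min_helix: int = 5
    min_strand: int = 3


def _pseudo_angles(ca: np.ndarray):
    n = len(ca)
    d2 = np.full(n, np.nan)
    d3 = np.full(n, np.nan)
    d4 = np.full(n, np.nan)
    tau = np.full(n, np.nan)
    alpha = np.full(n, np.nan)
    if n >= 3:
        d2[1 : n - 1] = np.linalg.norm(ca[2:] - ca[: n - 2], axis=1)
    if n >= 4:
        d3[1 : n - 2] = np.linalg.norm(ca[3:] - ca[: n - 3], axis=1)
    if n >= 5:
        d4[1 : n - 3] = np.linalg.norm(ca[4:] - ca[: n - 4], axis=1)
    for i in range(1, n - 1):
        u = ca[i - 1] - ca[i]
        v = ca[i + 1] - ca[i]
        tau[i] = np.degrees(
            np.arccos(np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1))
        )
    for i in range(1, n - 2):
        b1 = ca[i] - ca[i - 1]
        b2 = ca[i + 1] - ca[i]
        b3 = ca[i + 2] - ca[i + 1]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.linalg.norm(b2))
        alpha[i] = np.degrees(np.arctan2(m1 @ n2, n1 @ n2))
    return d2, d3, d4, tau, alpha


def _in(win, x):
    with np.errstate(invalid="ignore"):
        return (x >= win[0]) & (x <= win[1])


def _runs_at_least(mask: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros_like(mask)
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= k:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def _extend(region: np.ndarray, relaxed: np.ndarray) -> np.ndarray:
    out = region.copy()
    n = len(out)
    changed = True
    while changed:
        changed = False
        for i in range(n):
            if not out[i] and relaxed[i] and (
                (i > 0 and out[i - 1]) or (i < n - 1 and out[i + 1])
            ):
                out[i] = True
                changed = True
    return out


def assign_ca_geometry(
    chain: Chain, params: CaGeomParams | None = None
) -> SSAssignment:
    """Cα-only geometric assignment (states ``H``, ``E``, ``-``).

    A residue is a strict helix/strand candidate when its distance windows
    (d2, d3, d4) or its angle windows (τ, α) all match; runs of strict
    candidates seed segments which are extended by relaxed (d3-or-τ / d3)
    candidates.  Segments shorter than ``min_helix`` / ``min_strand`` are
    suppressed.  Fewer than five Cα atoms disable the method.
    """
    p = params or CaGeomParams()
    n = len(chain.residues)
    ca = np.array(
        [
            r.coord("CA") if r.atom("CA") is not None else [np.nan] * 3
            for r in chain.residues
        ]
    )
    if int((~np.isnan(ca).any(axis=1)).sum()) < 5:
        return _disabled("ca_geom", n)
    d2, d3, d4, tau, alpha = _pseudo_angles(ca)

    strict_h = (_in(p.helix_d3, d3) & _in(p.helix_d4, d4)) | (
        _in(p.helix_tau, tau) & _in(p.helix_alpha, alpha)
    )
    relaxed_h = _in(p.helix_d3, d3) | _in(p.helix_tau, tau)
    with np.errstate(invalid="ignore"):
        alpha_abs = np.abs(alpha)
    strict_e = (
        _in(p.strand_d2, d2) & _in(p.strand_d3, d3) & _in(p.strand_d4, d4)
    ) | (_in(p.strand_tau, tau) & _in(p.strand_alpha_abs, alpha_abs))
    relaxed_e = _in(p.strand_d3, d3)

    helix = _extend(_runs_at_least(strict_h, p.min_helix), relaxed_h)
    strand = _extend(_runs_at_least(strict_e, p.min_strand), relaxed_e)
    helix = _runs_at_least(helix, p.min_helix)
    strand = _runs_at_least(strand & ~helix, p.min_strand)

    extended = "".join(
        "H" if helix[i] else ("E" if strand[i] else "-") for i in range(n)
    )
    return to_three_state(SSAssignment("ca_geom", extended, "O" * n))


# ---------------------------------------------------------------------------
# external assignment files


def parse_assignment_file(path, dialect: str, chain: Chain) -> SSAssignment:
    """Map an external assigner's report onto ``chain``.

    ``dialect`` is ``dssp_file`` (classic columnar DSSP report) or
    ``stride_file`` (STRIDE ASG records).  States are matched by
    (chain id, author residue number, insertion code); chain residues absent
    from the file get '-'.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    if dialect == "dssp_file":
        states = _parse_dssp(text)
    elif dialect == "stride_file":
        states = _parse_stride(text)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    per_res = []
    hits = 0
    for res in chain.residues:
        key = (chain.chain_id, res.author_number, res.insertion_code)
        state = states.get(key)
        if state is None:
            per_res.append("-")
        else:
            per_res.append(state)
            hits += 1
    if hits == 0:
        raise AssignmentMappingError(
            f"{dialect} file shares no residues with chain {chain.chain_id!r}"
        )
    n = len(chain.residues)
    return to_three_state(SSAssignment(dialect, "".join(per_res), "O" * n))


def _parse_dssp(text: str) -> dict[tuple[str, int, str], str]:
    lines = text.splitlines()
    start = None
    for k, line in enumerate(lines):
        if line.lstrip().startswith("#  RESIDUE"):
            start = k + 1
            break
    if start is None:
        raise AssignmentDialectError("no '#  RESIDUE' header line in DSSP report")
    states: dict[tuple[str, int, str], str] = {}
    for k in range(start, len(lines)):
        line = lines[k]
        if len(line) < 17 or line[13] == "!":  # chain-break marker rows
            continue
        try:
            num = int(line[5:10])
        except ValueError as exc:
            raise AssignmentDialectError(
                f"DSSP report line {k + 1}: bad residue number field"
            ) from exc
        icode = line[10].strip()
        chain_id = line[11].strip()
        ss = line[16]
        states[(chain_id, num, icode)] = "-" if ss == " " else ss
    return states


def _parse_stride(text: str) -> dict[tuple[str, int, str], str]:
    states: dict[tuple[str, int, str], str] = {}
    for k, line in enumerate(text.splitlines()):
        if not line.startswith("ASG"):
            continue
        fields = line.split()
        if len(fields) < 7:
            raise AssignmentDialectError(f"STRIDE ASG line {k + 1}: too few fields")
        chain_id = fields[2]
        if chain_id == "-":
            chain_id = " "
        token = fields[3]
        num_part = token.rstrip("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
        icode = token[len(num_part) :]
        try:
            num = int(num_part)
        except ValueError as exc:
            raise AssignmentDialectError(
                f"STRIDE ASG line {k + 1}: bad residue number {token!r}"
            ) from exc
        ss = fields[5]
        states[(chain_id, num, icode)] = "-" if ss in ("C", "-") else ss
    if not states:
        raise AssignmentDialectError("no ASG records found in STRIDE report")
    return states
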