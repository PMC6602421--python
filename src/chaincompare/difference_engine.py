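"""Per-residue difference tracks between two aligned, superposed chains.

Everything here is a pure function of its inputs, so a new residue selection
or method set is handled by simple recomputation: consensus (with the
disagreement state X), secondary-structure difference flags, per-position Cα
displacement, per-residue side-chain displacement, contact-set differences,
B-factor percentile ranks, and the whole-chain / selection summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import rankdata

from .chain_alignment import PairAlignment, Superposition, kabsch_fit
from .structure_io import MAIN_CHAIN_ATOMS, Chain, Residue, effective_resolution
from .secondary_structure import THREE_STATE_MAP, SSAssignment

DEFAULT_CONTACT_CUTOFF = 5.0


class NoMethodError(ValueError):
    """Consensus requested with zero enabled methods."""


@dataclass(frozen=True)
class ConsensusTrack:
    """Per-residue consensus over the enabled methods for one chain.

    At a residue where every enabled method reports the same *extended*
    state, the consensus is that state's three-state reduction; where any
    two enabled methods disagree in extended format the residue is undefined
    and designated X.  With a single enabled method the consensus is exactly
    its three-state string.
    """

    states: str  # over {H, E, O, X}
    methods_used: tuple[str, ...]


@dataclass(frozen=True)
class Summary:
    """Three-state content and RMSD for a chain or a residue selection."""

    pct_H: float
    pct_E: float
    pct_O: float
    rmsd: float
    scope: str  # whole_chain | selection
    include_missing_as_other: bool
    pct_X: float = 0.0  # reported separately; counted inside pct_O
    n_residues: int = 0
    n_missing: int = 0


def consensus(assignments: list[SSAssignment]) -> ConsensusTrack:
    """Combine enabled assignments for one chain into a consensus track."""
    enabled = [a for a in assignments if a.enabled]
    if not enabled:
        raise NoMethodError("no enabled secondary-structure methods")
    n = len(enabled[0].extended)
    if any(len(a.extended) != n for a in enabled):
        raise ValueError("assignments cover different residue counts")
    if len(enabled) == 1:
        return ConsensusTrack(enabled[0].three_state, (enabled[0].method,))
    out = []
    for i in range(n):
        states = {a.extended[i] for a in enabled}
        if len(states) == 1:
            out.append(THREE_STATE_MAP.get(states.pop(), "O"))
        else:
            out.append("X")
    return ConsensusTrack("".join(out), tuple(a.method for a in enabled))


def map_states(states: str, alignment: PairAlignment, side: str) -> list[str | None]:
    """Project a per-residue state string into alignment space; ``None`` at
    gap positions.  ``side`` is 'a' or 'b'."""
    k = 0 if side == "a" else 1
    return [None if pair[k] is None else states[pair[k]] for pair in alignment.pairs]


def differences_line(
    a_track: list[str | None], b_track: list[str | None]
) -> list[bool | None]:
    """Flag aligned positions whose assigned states differ.

    ``None`` marks not-comparable positions (a gap on either side).
    """
    if len(a_track) != len(b_track):
        raise ValueError("tracks have different alignment lengths")
    out: list[bool | None] = []
    for sa, sb in zip(a_track, b_track):
        out.append(None if sa is None or sb is None else sa != sb)
    return out


def ca_dist(
    a: Chain, b: Chain, alignment: PairAlignment, superposition: Superposition
) -> list[float | None]:
    """Per aligned position: ``||CA_A - T(CA_B)||`` after superposition;
    ``None`` at gaps or where either residue lacks a Cα."""
    out: list[float | None] = []
    for i, j in alignment.pairs:
        if i is None or j is None:
            out.append(None)
            continue
        ca_a = a.residues[i].coord("CA")
        ca_b = b.residues[j].coord("CA")
        if ca_a is None or ca_b is None:
            out.append(None)
        else:
            out.append(float(np.linalg.norm(ca_a - superposition.transform(ca_b))))
    return out


def sc_dist(res_a: Residue, res_b: Residue) -> float | None:
    """Maximum like-atom displacement after per-residue main-chain fit.

    Defined for identical residue types only (same 3-letter code): the two
    residues are superposed on their shared main-chain atoms (N, CA, C, O)
    and the maximum distance over identically named shared heavy atoms is
    returned.  Glycine pairs give 0 by convention.  Mismatched names or
    fewer than 3 shared main-chain atoms → ``None`` (undefined, not an
    error).
    """
    if res_a.name != res_b.name:
        return None
    mc_pairs = [
        (res_a.coord(nm), res_b.coord(nm))
        for nm in MAIN_CHAIN_ATOMS
        if res_a.atom(nm) is not None and res_b.atom(nm) is not None
    ]
    if len(mc_pairs) < 3:
        return None
    A = np.array([p[0] for p in mc_pairs])
    B = np.array([p[1] for p in mc_pairs])
    R, t, _ = kabsch_fit(A, B)
    if res_a.name == "GLY":
        return 0.0
    shared = sorted(
        {a.name for a in res_a.atoms} & {a.name for a in res_b.atoms}
    )
    dmax = 0.0
    for nm in shared:
        d = float(np.linalg.norm(res_a.coord(nm) - (R @ res_b.coord(nm) + t)))
        dmax = max(dmax, d)
    return dmax


def sc_dist_line(
    a: Chain, b: Chain, alignment: PairAlignment
) -> list[float | None]:
    """Side-chain displacement at every aligned position (None at gaps or
    mismatched residue types)."""
    out: list[float | None] = []
    for i, j in alignment.pairs:
        if i is None or j is None:
            out.append(None)
        else:
            out.append(sc_dist(a.residues[i], b.residues[j]))
    return out


# ---------------------------------------------------------------------------
# contacts


def _heavy_coords(chain: Chain):
    coords = []
    owner = []
    for idx, res in enumerate(chain.residues):
        for atom in res.atoms:
            if atom.element not in ("H", "D"):
                coords.append(atom.coord)
                owner.append(idx)
    return np.asarray(coords, dtype=float), np.asarray(owner)


def contact_sets(
    chain: Chain,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    exclude_neighbours: bool = True,
) -> list[set[tuple[int, str]]]:
    """Contact set of every residue: author ids of all other residues with
    any heavy-atom pair within ``cutoff`` Å (sequence neighbours i±1
    excluded by default)."""
    coords, owner = _heavy_coords(chain)
    n = len(chain.residues)
    sets: list[set[tuple[int, str]]] = [set() for _ in range(n)]
    if len(coords) == 0:
        return sets
    tree = cKDTree(coords)
    for ai, bi in tree.query_pairs(cutoff):
        ra, rb = int(owner[ai]), int(owner[bi])
        if ra == rb:
            continue
        if exclude_neighbours and abs(ra - rb) <= 1:
            continue
        sets[ra].add(chain.residues[rb].author_id)
        sets[rb].add(chain.residues[ra].author_id)
    return sets


def contact_set(
    chain: Chain,
    residue: Residue,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    exclude_neighbours: bool = True,
) -> set[tuple[int, str]]:
    """Contact set of a single residue of ``chain`` (author ids)."""
    return contact_sets(chain, cutoff, exclude_neighbours)[residue.seq_index]


def contact_difference(set_a: set, set_b: set) -> int:
    """|A ∪ B| − |A ∩ B|: the size of the symmetric difference of the two
    mapped contact sets."""
    return len(set_a ^ set_b)


def contacts_line(
    a: Chain,
    b: Chain,
    alignment: PairAlignment,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    exclude_neighbours: bool = True,
) -> list[int | None]:
    """Per aligned position: contact-set difference count.

    Both residues' contact sets are mapped into alignment-position space;
    a contact to a residue with no aligned partner keeps a chain-specific
    sentinel identity, so it always counts as a difference.
    """
    sets_a = contact_sets(a, cutoff, exclude_neighbours)
    sets_b = contact_sets(b, cutoff, exclude_neighbours)
    pos_of_a = {}
    pos_of_b = {}
    for pos, (i, j) in enumerate(alignment.pairs):
        if i is not None:
            pos_of_a[a.residues[i].author_id] = pos if j is not None else ("A", i)
        if j is not None:
            pos_of_b[b.residues[j].author_id] = pos if i is not None else ("B", j)
    out: list[int | None] = []
    for i, j in alignment.pairs:
        if i is None or j is None:
            out.append(None)
            continue
        mapped_a = {pos_of_a.get(c, ("A",) + c) for c in sets_a[i]}
        mapped_b = {pos_of_b.get(c, ("B",) + c) for c in sets_b[j]}
        out.append(contact_difference(mapped_a, mapped_b))
    return out


# ---------------------------------------------------------------------------
# B-factors and summaries


def bfactor_percentiles(chain: Chain) -> list[float] | None:
    """Mid-rank percentile of each residue's mean heavy-atom B-factor within
    the chain, in [0, 100].  Returns ``None`` (track disabled) when
    B-factors are absent or all zero.  The resolution context for these
    values is :func:`effective_resolution`.
    """
    means = np.array([r.mean_bfactor() for r in chain.residues])
    if len(means) == 0 or np.allclose(means, 0.0):
        return None
    ranks = rankdata(means, method="average")
    return [float(100.0 * (r - 0.5) / len(means)) for r in ranks]


def summarize(
    chain: Chain,
    consensus_track: ConsensusTrack,
    superposition: Superposition,
    selection: set[int] | None = None,
    include_missing_as_other: bool = True,
) -> Summary:
    """H/E/O percentage content plus RMSD.

    ``selection`` restricts to the given seq_index set ('Summary of
    Selection'); otherwise the whole chain is summarised and, when
    ``include_missing_as_other``, residues missing from the coordinates are
    counted in the 'Other' denominator.  X (no consensus) residues count
    within O for the percentages and are also reported separately.
    """
    states = consensus_track.states
    if len(states) != len(chain.residues):
        raise ValueError("consensus does not cover the chain")
    if selection is not None:
        idx = sorted(selection)
        if not idx:
            raise ValueError("empty selection")
        sel_states = [states[i] for i in idx]
        n_missing = 0
        scope = "selection"
    else:
        sel_states = list(states)
        n_missing = len(chain.missing_positions) if include_missing_as_other else 0
        scope = "whole_chain"
    denom = len(sel_states) + n_missing
    n_h = sum(1 for s in sel_states if s == "H")
    n_e = sum(1 for s in sel_states if s == "E")
    n_x = sum(1 for s in sel_states if s == "X")
    n_o = denom - n_h - n_e
    return Summary(
        pct_H=100.0 * n_h / denom,
        pct_E=100.0 * n_e / denom,
        pct_O=100.0 * n_o / denom,
        pct_X=100.0 * n_x / denom,
        rmsd=superposition.rmsd,
        scope=scope,
        include_missing_as_other=include_missing_as_other and selection is None,
        n_residues=len(sel_states),
        n_missing=n_missing,
    )
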