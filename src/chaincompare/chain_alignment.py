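"""Residue correspondence and rigid-body superposition.

Two similar chains are paired by Needleman-Wunsch global sequence alignment
(affine gaps, BLOSUM62 by default) and then fitted by least-squares (Kabsch)
superposition over the aligned Cα pairs.  An optional iterative trim drops
the worst-deviating pairs and refits, emulating core-based structural
alignment for the highly-similar-chain regime this package targets; an
externally computed transform can be injected instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices
from scipy.spatial.transform import Rotation

from .structure_io import Chain

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

DEFAULT_GAP_OPEN = -10.0
DEFAULT_GAP_EXTEND = -0.5


class InsufficientCorrespondenceError(ValueError):
    """Fewer than three usable Cα pairs for superposition."""


@dataclass(frozen=True)
class PairAlignment:
    """Position-wise mapping between two chains.

    ``pairs`` lists ``(index_in_a, index_in_b)`` seq-index tuples in
    alignment order; ``None`` marks a gap on that side.  ``identity`` is the
    fraction of gap-free pairs with identical residue one-letter codes.
    """

    pairs: tuple[tuple[int | None, int | None], ...]
    identity: float
    score: float = 0.0

    @property
    def aligned_pairs(self) -> list[tuple[int, int]]:
        return [(i, j) for i, j in self.pairs if i is not None and j is not None]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class Superposition:
    """Rotation + translation fitting chain B onto chain A.

    ``rmsd`` is over the final (possibly trimmed) fitted Cα set;
    ``rmsd_all`` over every aligned Cα pair under the same transform.
    """

    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3-vector, Å
    rmsd: float
    n_fitted: int
    rmsd_all: float

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fit to coordinates of chain B."""
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "Superposition":
        rot = self.rotation.T
        return Superposition(
            rotation=rot,
            translation=-rot @ self.translation,
            rmsd=self.rmsd,
            n_fitted=self.n_fitted,
            rmsd_all=self.rmsd_all,
        )


# ---------------------------------------------------------------------------
# sequence alignment (Gotoh, deterministic high-road traceback)


def _score_fn(substitution):
    if substitution is None:
        substitution = _BLOSUM62
    if isinstance(substitution, str):
        substitution = substitution_matrices.load(substitution)
    alphabet = set(getattr(substitution, "alphabet", ""))

    def score(x: str, y: str) -> float:
        x = x if x in alphabet else "X"
        y = y if y in alphabet else "X"
        try:
            return float(substitution[x, y])
        except (KeyError, IndexError):
            return 0.0

    return score


def align_strings(
    seq_a: str,
    seq_b: str,
    substitution=None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> list[tuple[int | None, int | None]]:
    """Global affine-gap alignment of two strings; returns pair list.

    The first residue of a gap scores ``gap_open``, each further residue
    ``gap_extend``.  Ties are broken high-road: an aligned (mis)match is
    preferred over a gap in A, which is preferred over a gap in B.
    """
    if substitution == "identity":
        score = lambda x, y: 1.0 if x == y else -1.0  # noqa: E731
    else:
        score = _score_fn(substitution)
    n, m = len(seq_a), len(seq_b)
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    Ia = np.full((n + 1, m + 1), NEG)  # gap in A (consumes B)
    Ib = np.full((n + 1, m + 1), NEG)  # gap in B (consumes A)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        Ia[0, j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        Ib[i, 0] = gap_open + gap_extend * (i - 1)
    for i in range(1, n + 1):
        row_scores = [score(seq_a[i - 1], b) for b in seq_b]
        for j in range(1, m + 1):
            M[i, j] = max(M[i - 1, j - 1], Ia[i - 1, j - 1], Ib[i - 1, j - 1]) + row_scores[j - 1]
            Ia[i, j] = max(
                M[i, j - 1] + gap_open,
                Ia[i, j - 1] + gap_extend,
                Ib[i, j - 1] + gap_open,
            )
            Ib[i, j] = max(
                M[i - 1, j] + gap_open,
                Ib[i - 1, j] + gap_extend,
                Ia[i - 1, j] + gap_open,
            )
    # traceback, preferring M > Ia > Ib at every tie
    pairs: list[tuple[int | None, int | None]] = []
    i, j = n, m
    state = max(("M", "Ia", "Ib"), key=lambda s: {"M": M, "Ia": Ia, "Ib": Ib}[s][n, m])
    # resolve preference explicitly (max of generator keeps first max, but
    # order the candidates so the high-road one wins)
    best = max(M[n, m], Ia[n, m], Ib[n, m])
    for s, mat in (("M", M), ("Ia", Ia), ("Ib", Ib)):
        if mat[n, m] == best:
            state = s
            break
    eps = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            pairs.append((i - 1, j - 1))
            target = M[i, j] - score(seq_a[i - 1], seq_b[j - 1])
            i, j = i - 1, j - 1
            for s, mat in (("M", M), ("Ia", Ia), ("Ib", Ib)):
                if abs(mat[i, j] - target) < eps:
                    state = s
                    break
        elif state == "Ia":
            pairs.append((None, j - 1))
            val = Ia[i, j]
            j -= 1
            if abs(M[i, j] + gap_open - val) < eps:
                state = "M"
            elif abs(Ia[i, j] + gap_extend - val) < eps:
                state = "Ia"
            else:
                state = "Ib"
        else:
            pairs.append((i - 1, None))
            val = Ib[i, j]
            i -= 1
            if abs(M[i, j] + gap_open - val) < eps:
                state = "M"
            elif abs(Ib[i, j] + gap_extend - val) < eps:
                state = "Ib"
            else:
                state = "Ia"
        if i == 0 and j == 0:
            break
        if i == 0 and state == "Ib":
            state = "Ia"
        if j == 0 and state == "Ia":
            state = "Ib"
    pairs.reverse()
    return pairs


def alignment_score(
    pairs,
    seq_a: str,
    seq_b: str,
    substitution=None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Score an existing pair list under the given scheme (for transparency)."""
    score = _score_fn(substitution)
    total = 0.0
    prev_gap = None  # which side the previous gap was on
    for i, j in pairs:
        if i is not None and j is not None:
            total += score(seq_a[i], seq_b[j])
            prev_gap = None
        else:
            side = "a" if i is None else "b"
            total += gap_extend if prev_gap == side else gap_open
            prev_gap = side
    return total


def align_sequences(
    a: Chain,
    b: Chain,
    substitution=None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> PairAlignment:
    """Needleman-Wunsch global alignment of two chains' sequences.

    Non-standard residues score as 'X' (mismatch-neutral under BLOSUM62's X
    column).  Deterministic high-road tie-breaking.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both chains must have at least one residue")
    seq_a, seq_b = a.sequence, b.sequence
    pairs = align_strings(seq_a, seq_b, substitution, gap_open, gap_extend)
    aligned = [(i, j) for i, j in pairs if i is not None and j is not None]
    ident = (
        sum(1 for i, j in aligned if seq_a[i] == seq_b[j]) / len(aligned)
        if aligned
        else 0.0
    )
    score = alignment_score(pairs, seq_a, seq_b, substitution, gap_open, gap_extend)
    return PairAlignment(pairs=tuple(pairs), identity=ident, score=score)


# ---------------------------------------------------------------------------
# superposition


def rmsd_between(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Root-mean-square deviation of two equal-length coordinate sets.

    No fitting is performed: ``sqrt(mean ||a_i - b_i||^2)``.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 1:
        raise ValueError(f"coordinate shapes differ or invalid: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_fit(coords_a: np.ndarray, coords_b: np.ndarray):
    """Least-squares rotation/translation mapping ``coords_b`` onto
    ``coords_a``; returns ``(rotation, translation, rmsd)``."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    cen_a, cen_b = a.mean(axis=0), b.mean(axis=0)
    rot, _ = Rotation.align_vectors(a - cen_a, b - cen_b)
    R = rot.as_matrix()
    t = cen_a - R @ cen_b
    # rssd from align_vectors cancels catastrophically near zero; recompute
    return R, t, rmsd_between(a, b @ R.T + t)


def superpose(
    a: Chain,
    b: Chain,
    alignment: PairAlignment,
    trim_fraction: float = 0.1,
    trim_rounds: int = 2,
    external: tuple[np.ndarray, np.ndarray] | None = None,
) -> Superposition:
    """Kabsch superposition of chain B onto chain A over aligned Cα pairs.

    ``trim_rounds`` rounds of trimming remove the worst-deviating
    ``trim_fraction`` of pairs and refit (set ``trim_fraction=0`` for a plain
    all-pair fit).  ``external`` injects a pre-computed
    ``(rotation, translation)`` — e.g. parsed from a structural-alignment
    program's output — in place of the internal fit; RMSDs are still computed
    here.
    """
    coords = [
        (a.residues[i].coord("CA"), b.residues[j].coord("CA"))
        for i, j in alignment.aligned_pairs
    ]
    coords = [(ca, cb) for ca, cb in coords if ca is not None and cb is not None]
    if len(coords) < 3:
        raise InsufficientCorrespondenceError(
            f"only {len(coords)} aligned Cα pairs; need at least 3"
        )
    A = np.array([c[0] for c in coords])
    B = np.array([c[1] for c in coords])

    if external is not None:
        R = np.asarray(external[0], dtype=float).reshape(3, 3)
        t = np.asarray(external[1], dtype=float).reshape(3)
        fitted = rmsd_between(A, B @ R.T + t)
        return Superposition(R, t, fitted, len(A), fitted)

    keep = np.arange(len(A))
    R, t, rmsd = kabsch_fit(A, B)
    rounds = trim_rounds if trim_fraction > 0 else 0
    for _ in range(rounds):
        dev = np.linalg.norm(A[keep] - (B[keep] @ R.T + t), axis=1)
        n_drop = int(np.ceil(trim_fraction * len(keep)))
        if n_drop == 0 or len(keep) - n_drop < 3:
            break
        order = np.argsort(dev)  # stable: ties keep earlier pairs
        keep = np.sort(keep[order[: len(keep) - n_drop]])
        R, t, rmsd = kabsch_fit(A[keep], B[keep])
    rmsd_all = rmsd_between(A, B @ R.T + t)
    return Superposition(R, t, rmsd, len(keep), rmsd_all)


def load_transform(path) -> tuple[np.ndarray, np.ndarray]:
    """Read an external transform file: 12 whitespace-separated numbers,
    9 row-major rotation entries then 3 translation components."""
    values = np.loadtxt(path).ravel()
    if values.size != 12:
        raise ValueError(f"transform file must hold 12 numbers, got {values.size}")
    return values[:9].reshape(3, 3), values[9:]
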