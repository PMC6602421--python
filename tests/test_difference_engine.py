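"""Consensus, difference flags, distance tracks, contacts, percentiles and
summaries."""

from dataclasses import replace

import numpy as np
import pytest

from chaincompare.chain_alignment import Superposition, align_sequences, superpose
from chaincompare.difference_engine import (
    NoMethodError,
    bfactor_percentiles,
    ca_dist,
    consensus,
    contact_difference,
    contact_set,
    contact_sets,
    contacts_line,
    differences_line,
    map_states,
    sc_dist,
    sc_dist_line,
    summarize,
)
from chaincompare.fixtures import (
    hinge_axis,
    make_ideal_helix,
    perturb,
    transform_chain,
)
from chaincompare.secondary_structure import SSAssignment
from chaincompare.structure_io import Atom, Chain, Residue


def _ss(method, extended, enabled=True):
    from chaincompare.secondary_structure import to_three_state

    return to_three_state(
        SSAssignment(method, extended, "O" * len(extended), enabled=enabled)
    )


def _identity_sup(n=1):
    return Superposition(np.eye(3), np.zeros(3), 0.0, n, 0.0)


class TestConsensus:
    def test_single_method_rule(self):
        track = consensus([_ss("hbond", "HHH--")])
        assert track.states == "HHHOO"
        assert "X" not in track.states

    def test_extended_disagreement_gives_x(self):
        """H vs G disagree in extended format even though both reduce to
        helix three-state."""
        track = consensus([_ss("hbond", "HHHH"), _ss("ca_geom", "HHHG")])
        assert track.states == "HHHX"

    def test_full_agreement(self):
        track = consensus([_ss("hbond", "E-"), _ss("ca_geom", "E-")])
        assert track.states == "EO"

    def test_disabled_methods_never_contribute(self):
        track = consensus([_ss("hbond", "HHHH"), _ss("ca_geom", "EEEE", enabled=False)])
        assert track.states == "HHHH"
        assert track.methods_used == ("hbond",)

    def test_zero_enabled_raises(self):
        with pytest.raises(NoMethodError):
            consensus([_ss("hbond", "HH", enabled=False)])

    def test_adding_methods_monotone_in_x(self):
        """Adding a method can only keep or increase the X count."""
        base = [_ss("hbond", "HHHHEE--"), _ss("ca_geom", "HHHHEE-H")]
        x2 = consensus(base).states.count("X")
        x3 = consensus(base + [_ss("dssp_file", "HHGHEE--")]).states.count("X")
        assert x3 >= x2


class TestDifferencesLine:
    def test_self_comparison_all_false(self, helix15):
        aln = align_sequences(helix15, helix15)
        track = map_states("H" * 15, aln, "a")
        flags = differences_line(track, track)
        assert flags == [False] * 15

    def test_positional_flags(self):
        flags = differences_line(list("HHHO"), list("HHOO"))
        assert flags == [False, False, True, False]

    def test_gap_not_comparable(self):
        flags = differences_line(["H", "H", None, "O"], ["H", "O", "H", "O"])
        assert flags == [False, True, None, False]


class TestCaDist:
    def test_exact_copy_zero(self, helix15):
        aln = align_sequences(helix15, helix15)
        sup = superpose(helix15, helix15, aln)
        assert all(d <= 1e-8 for d in ca_dist(helix15, helix15, aln, sup))

    def test_hinge_arc_oracle(self, hinge_pair):
        """Closed-form check: with the chains in their construction frame,
        each moved Cα travels 2·sin(θ/2)·(distance to the hinge axis)."""
        a, b = hinge_pair
        aln = align_sequences(a, b)
        dists = ca_dist(a, b, aln, _identity_sup())
        pivot, axis = hinge_axis(a, 15)
        theta = np.radians(20.0)
        for pos, d in enumerate(dists):
            ca = a.residues[pos].coord("CA")
            rel = ca - pivot
            radial = rel - (rel @ axis) * axis
            expected = 2 * np.sin(theta / 2) * np.linalg.norm(radial)
            if pos < 15:
                assert d <= 1e-8
            else:
                assert d == pytest.approx(expected, abs=1e-8)

    def test_hinge_monotone_after_pivot(self, hinge_pair):
        a, b = hinge_pair
        aln = align_sequences(a, b)
        dists = ca_dist(a, b, aln, _identity_sup())
        post = dists[15:]
        assert all(x < y for x, y in zip(post, post[1:]))

    def test_missing_ca_undefined(self, helix15):
        stripped = replace(
            helix15,
            residues=tuple(
                replace(r, atoms=tuple(a for a in r.atoms if a.name != "CA"))
                if r.seq_index == 7
                else r
                for r in helix15.residues
            ),
        )
        aln = align_sequences(helix15, stripped)
        dists = ca_dist(helix15, stripped, aln, _identity_sup())
        assert dists[7] is None


class TestScDist:
    def test_rigid_copy_zero(self, arg_helix):
        rng = np.random.default_rng(2)
        from conftest import random_rotation

        moved = transform_chain(arg_helix, random_rotation(rng), rng.normal(0, 10, 3))
        for ra, rb in zip(arg_helix.residues, moved.residues):
            assert sc_dist(ra, rb) == pytest.approx(0.0, abs=1e-8)

    def test_displaced_guanidinium_atom(self, arg_helix):
        """Arginine pair identical except NH1 moved 2.0 Å: after the
        backbone frames coincide the max like-atom distance is exactly 2."""
        res = next(r for r in arg_helix.residues if r.name == "ARG")
        atoms = tuple(
            replace(a, coord=(a.coord[0], a.coord[1], a.coord[2] + 2.0))
            if a.name == "NH1"
            else a
            for a in res.atoms
        )
        moved = replace(res, atoms=atoms)
        assert sc_dist(res, moved) == pytest.approx(2.0, abs=1e-8)
        # and still 2.0 after a global rigid motion of the partner
        rng = np.random.default_rng(4)
        from conftest import random_rotation

        R = random_rotation(rng)
        t = rng.normal(0, 5, 3)
        moved_rigid = replace(
            moved,
            atoms=tuple(
                replace(a, coord=tuple(R @ np.array(a.coord) + t)) for a in moved.atoms
            ),
        )
        assert sc_dist(res, moved_rigid) == pytest.approx(2.0, abs=1e-7)

    def test_mismatched_names_undefined(self, arg_helix):
        ala = arg_helix.residues[0]
        arg = next(r for r in arg_helix.residues if r.name == "ARG")
        assert sc_dist(ala, arg) is None

    def test_glycine_zero_by_convention(self):
        helix = make_ideal_helix(6, residue_names=["GLY"] * 6)
        moved = perturb(helix, 0.3, seed=1, atoms="all")
        line = sc_dist_line(helix, moved, align_sequences(helix, moved))
        assert all(v == 0.0 for v in line)


def _ca_only_chain(coords, names=None):
    names = names or ["ALA"] * len(coords)
    residues = tuple(
        Residue(i + 1, names[i], (Atom("CA", "C", tuple(map(float, c)), 10.0),), i)
        for i, c in enumerate(coords)
    )
    return Chain("A", 1, residues)


class TestContacts:
    def test_isolated_residue_empty(self):
        chain = _ca_only_chain([(0, 0, 0), (50, 0, 0), (100, 0, 0)])
        assert contact_set(chain, chain.residues[1]) == set()

    def test_collinear_fixture(self):
        """Three residues 4 Å apart, 5 Å cutoff: the middle one touches both
        ends with neighbour exclusion off, none with it on."""
        chain = _ca_only_chain([(0, 0, 0), (4, 0, 0), (8, 0, 0)])
        mid = chain.residues[1]
        assert contact_set(chain, mid, cutoff=5.0, exclude_neighbours=False) == {
            (1, ""),
            (3, ""),
        }
        assert contact_set(chain, mid, cutoff=5.0, exclude_neighbours=True) == set()

    def test_against_brute_force(self, hairpin):
        """KD-tree contact sets equal an all-pairs distance scan."""
        cutoff = 5.0
        fast = contact_sets(hairpin, cutoff, exclude_neighbours=True)
        for i, ri in enumerate(hairpin.residues):
            expected = set()
            for j, rj in enumerate(hairpin.residues):
                if j == i or abs(i - j) <= 1:
                    continue
                for ai in ri.atoms:
                    for aj in rj.atoms:
                        if np.linalg.norm(ai.xyz - aj.xyz) <= cutoff:
                            expected.add(rj.author_id)
            assert fast[i] == expected

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"p", "q", "r"}, {"q", "r", "s"}, 2),
            ({"p"}, {"p"}, 0),
            ({"p", "q"}, {"r", "s", "t"}, 5),
            (set(), set(), 0),
        ],
    )
    def test_symmetric_difference_examples(self, a, b, expected):
        assert contact_difference(a, b) == expected
        assert contact_difference(b, a) == expected

    def test_zero_iff_equal(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            a = set(rng.integers(0, 12, rng.integers(0, 8)).tolist())
            b = set(rng.integers(0, 12, rng.integers(0, 8)).tolist())
            assert (contact_difference(a, b) == 0) == (a == b)

    def test_unaligned_contacts_count_as_differences(self):
        """A contact to a residue the partner chain lacks is always a
        difference (chain-specific sentinel)."""
        # distinct names pin the alignment: the missing GLU aligns to a gap
        a = _ca_only_chain(
            [(0, 0, 0), (4, 0, 0), (8, 0, 0), (8, 4, 0)],
            ["ALA", "CYS", "ASP", "GLU"],
        )
        b = _ca_only_chain([(0, 0, 0), (4, 0, 0), (8, 0, 0)], ["ALA", "CYS", "ASP"])
        aln = align_sequences(a, b)
        line = contacts_line(a, b, aln, cutoff=5.0, exclude_neighbours=False)
        # position 2 (0-based) contacts residue 4 only in chain A
        assert line[2] == 1


class TestBfactorPercentiles:
    def test_stated_rank_formula(self):
        chain = _ca_only_chain([(i * 10.0, 0, 0) for i in range(4)])
        chain = replace(
            chain,
            residues=tuple(
                replace(r, atoms=(replace(r.atoms[0], bfactor=b),))
                for r, b in zip(chain.residues, [10.0, 20.0, 30.0, 40.0])
            ),
        )
        assert bfactor_percentiles(chain) == pytest.approx([12.5, 37.5, 62.5, 87.5])

    def test_all_ties_give_fifty(self):
        chain = _ca_only_chain([(i * 10.0, 0, 0) for i in range(3)])
        assert bfactor_percentiles(chain) == pytest.approx([50.0, 50.0, 50.0])

    def test_single_residue(self):
        chain = _ca_only_chain([(0.0, 0, 0)])
        assert bfactor_percentiles(chain) == pytest.approx([50.0])

    def test_monotone_transform_invariance(self, helix15):
        base = bfactor_percentiles(helix15)
        transformed = replace(
            helix15,
            residues=tuple(
                replace(
                    r,
                    atoms=tuple(
                        replace(a, bfactor=np.exp(a.bfactor / 20.0)) for a in r.atoms
                    ),
                )
                for r in helix15.residues
            ),
        )
        assert bfactor_percentiles(transformed) == pytest.approx(base)
        assert all(0 <= p <= 100 for p in base)

    def test_absent_bfactors_disable_track(self):
        chain = _ca_only_chain([(0.0, 0, 0), (4.0, 0, 0)])
        chain = replace(
            chain,
            residues=tuple(
                replace(r, atoms=(replace(r.atoms[0], bfactor=0.0),))
                for r in chain.residues
            ),
        )
        assert bfactor_percentiles(chain) is None


class TestSummarize:
    def _chain_with_missing(self, n, k):
        helix = make_ideal_helix(n + k)
        kept = [r for r in helix.residues if r.author_number <= n]
        # author numbers 1..n, then a gap of k implied by full_sequence
        return replace(
            helix,
            residues=tuple(kept),
            full_sequence=helix.sequence,
        )

    def test_equal_thirds(self):
        from chaincompare.difference_engine import ConsensusTrack

        chain = make_ideal_helix(6)
        track = ConsensusTrack("HHEEOO", ("hbond",))
        s = summarize(chain, track, _identity_sup())
        assert (s.pct_H, s.pct_E, s.pct_O) == pytest.approx((100 / 3,) * 3)
        assert s.pct_H + s.pct_E + s.pct_O == pytest.approx(100.0, abs=1e-9)

    def test_missing_toggle(self):
        """k missing residues enlarge the 'Other' denominator by exactly k
        when the include-missing flag is on."""
        from chaincompare.difference_engine import ConsensusTrack

        chain = self._chain_with_missing(4, 4)
        assert len(chain.missing_positions) == 4
        track = ConsensusTrack("HHHH", ("hbond",))
        on = summarize(chain, track, _identity_sup(), include_missing_as_other=True)
        off = summarize(chain, track, _identity_sup(), include_missing_as_other=False)
        assert (on.pct_H, on.pct_O) == pytest.approx((50.0, 50.0))
        assert (off.pct_H, off.pct_O) == pytest.approx((100.0, 0.0))

    def test_selection(self):
        from chaincompare.difference_engine import ConsensusTrack

        chain = make_ideal_helix(4)
        track = ConsensusTrack("HHEE", ("hbond",))
        s = summarize(chain, track, _identity_sup(), selection={0, 1})
        assert s.pct_H == pytest.approx(100.0)
        assert s.scope == "selection"

    def test_empty_selection_raises(self):
        from chaincompare.difference_engine import ConsensusTrack

        chain = make_ideal_helix(4)
        with pytest.raises(ValueError):
            summarize(chain, ConsensusTrack("HHEE", ("hbond",)), _identity_sup(), selection=set())

    def test_x_counts_in_other(self):
        from chaincompare.difference_engine import ConsensusTrack

        chain = make_ideal_helix(4)
        s = summarize(chain, ConsensusTrack("HHXX", ("hbond", "ca_geom")), _identity_sup())
        assert s.pct_O == pytest.approx(50.0)
        assert s.pct_X == pytest.approx(50.0)


class TestSwapSymmetry:
    def test_tracks_symmetric_under_chain_swap(self, hinge_pair):
        a, b = hinge_pair
        aln_ab = align_sequences(a, b)
        aln_ba = align_sequences(b, a)
        sup_ab = superpose(a, b, aln_ab, trim_fraction=0.0)
        sup_ba = superpose(b, a, aln_ba, trim_fraction=0.0)
        assert ca_dist(a, b, aln_ab, sup_ab) == pytest.approx(
            ca_dist(b, a, aln_ba, sup_ba), abs=1e-6
        )
        assert sc_dist_line(a, b, aln_ab) == pytest.approx(
            sc_dist_line(b, a, aln_ba), abs=1e-8
        )
        assert contacts_line(a, b, aln_ab) == contacts_line(b, a, aln_ba)
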