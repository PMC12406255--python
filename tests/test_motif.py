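import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scaffoldmatch.motif import (
    DisulfidePattern,
    HelixLoopHelixMotif,
    ScaffoldCandidate,
    candidate_from_structure,
    dedupe_candidates,
    detect_disulfides,
    extract_hlh_motifs,
    scaffold_filter,
)
from scaffoldmatch.secstruct import SecStructAssignment, assign_secstruct
from scaffoldmatch.structure_io import AtomRecord, Residue, Structure

from conftest import ca_structure


class TestExtractMotifs:
    def test_hlh_fixture_single_motif(self, hlh_clean):
        s, truth = hlh_clean
        labels = assign_secstruct(s, "A")
        motifs = extract_hlh_motifs(s, "A", labels)
        assert len(motifs) == 1
        m = motifs[0]
        assert m.helix1 == truth.helix1
        assert m.loop == truth.loop
        assert m.helix2 == truth.helix2
        assert len(m.loop_ids) == 5

    def test_single_helix_no_motif(self):
        labels = SecStructAssignment(labels="H" * 12)
        s = ca_structure(np.zeros((12, 3)) + np.arange(12)[:, None])
        assert extract_hlh_motifs(s, "A", labels) == []

    def test_three_helices_two_motifs(self):
        labels = SecStructAssignment(labels="HHHHHCCCCHHHHHCCCCHHHHH")
        s = ca_structure(np.zeros((23, 3)) + np.arange(23)[:, None])
        motifs = extract_hlh_motifs(s, "A", labels)
        assert len(motifs) == 2
        assert motifs[0].helix2 == motifs[1].helix1

    def test_long_gap_not_a_loop(self):
        labels = SecStructAssignment(labels="H" * 5 + "C" * 13 + "H" * 5)
        s = ca_structure(np.zeros((23, 3)) + np.arange(23)[:, None])
        assert extract_hlh_motifs(s, "A", labels) == []

    def test_span_ordering_enforced(self):
        with pytest.raises(ValueError):
            HelixLoopHelixMotif(chain="A", helix1=(5, 9), loop=(1, 4), helix2=(10, 14))


class TestDisulfides:
    def test_planted_hairpinin_connectivity(self, hlh_clean):
        s, truth = hlh_clean
        pattern = detect_disulfides(s, "A")
        assert pattern.pairs == ((1, 4), (2, 3))
        assert pattern.roman == "I–IV, II–III"

    def test_no_cysteines(self):
        s = ca_structure(np.arange(15.0).reshape(5, 3))
        pattern = detect_disulfides(s, "A")
        assert pattern.pairs == ()
        assert pattern.roman == ""

    def test_distant_sg_not_bonded(self):
        residues = []
        for i, x in enumerate([0.0, 6.0]):
            residues.append(Residue(
                name="CYS", seq_id=i + 1, label_id=i + 1,
                atoms=[AtomRecord(name="CA", element="C", position=[x, 0, 0]),
                       AtomRecord(name="SG", element="S", position=[x, 1.8, 0])]))
        s = Structure(id="X", chains={"A": residues})
        assert detect_disulfides(s, "A").pairs == ()

    def test_cb_fallback_when_sg_missing(self):
        residues = []
        for i, x in enumerate([0.0, 4.0]):
            residues.append(Residue(
                name="CYS", seq_id=i + 1, label_id=i + 1,
                atoms=[AtomRecord(name="CA", element="C", position=[x, 0, 0]),
                       AtomRecord(name="CB", element="C", position=[x, 1.5, 0])]))
        s = Structure(id="X", chains={"A": residues})
        assert detect_disulfides(s, "A").pairs == ((1, 2),)

    def test_invariant_under_rigid_transform(self, hlh_clean, random_rigid):
        s, _ = hlh_clean
        R, t = random_rigid(3)
        moved = []
        for r in s.chain("A"):
            atoms = [AtomRecord(name=a.name, element=a.element,
                                position=a.position @ R.T + t) for a in r.atoms]
            moved.append(Residue(name=r.name, seq_id=r.seq_id,
                                 label_id=r.label_id, atoms=atoms))
        s2 = Structure(id="X", chains={"A": moved})
        assert detect_disulfides(s2, "A").pairs == detect_disulfides(s, "A").pairs


class TestScaffoldFilter:
    @pytest.mark.parametrize(
        "length,n_cys,expected,reason",
        [
            (27, 4, True, []),          # scaffold-sized cystine peptide
            (14, 0, False, ["too_few_cys"]),  # linear epitope, no Cys
            (9, 2, False, ["too_short"]),
            (10, 2, True, []),          # inclusive lower bound
            (50, 2, True, []),          # inclusive upper bound
            (51, 2, False, ["too_long"]),
            (9, 1, False, ["too_short", "too_few_cys"]),
        ],
    )
    def test_rule(self, length, n_cys, expected, reason):
        c = ScaffoldCandidate(source="X", chain="A", length=length, n_cys=n_cys)
        ok, reasons = scaffold_filter(c)
        assert ok is expected
        assert reasons == reason

    @given(length=st.integers(1, 80), n_cys=st.integers(0, 10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_pure_function_of_length_and_cys(self, length, n_cys):
        a = ScaffoldCandidate(source="A", chain="A", length=length, n_cys=n_cys)
        b = ScaffoldCandidate(source="B", chain="Z", length=length, n_cys=n_cys,
                              sequence="X" * length)
        assert scaffold_filter(a) == scaffold_filter(b)


class TestDedupe:
    def _cand(self, source, seq):
        return ScaffoldCandidate(source=source, chain="A", length=len(seq),
                                 n_cys=seq.count("C"), sequence=seq)

    def test_identical_sequences_collapse(self):
        cs = [self._cand("2ABC", "ACDEF"), self._cand("1XYZ", "ACDEF")]
        out = dedupe_candidates(cs)
        assert len(out) == 1
        assert out[0].source == "1XYZ"  # lexicographically smallest id wins

    def test_empty(self):
        assert dedupe_candidates([]) == []

    def test_three_unique_of_five(self):
        seqs = ["AAAA", "CCCC", "AAAA", "DDDD", "CCCC"]
        out = dedupe_candidates([self._cand(f"S{i}", q) for i, q in enumerate(seqs)])
        assert sorted(c.sequence for c in out) == ["AAAA", "CCCC", "DDDD"]

    def test_permutation_invariant_survivor_multiset(self):
        cs = [self._cand(f"S{i}", q)
              for i, q in enumerate(["AA", "BB", "AA", "CC", "BB", "AA"])]
        fwd = {c.sequence for c in dedupe_candidates(cs)}
        rev = {c.sequence for c in dedupe_candidates(cs[::-1])}
        assert fwd == rev


def test_candidate_from_structure(hlh_clean):
    s, _ = hlh_clean
    c = candidate_from_structure(s, "A")
    assert c.length == 25
    assert c.n_cys == 4
    assert c.motif is not None
    assert c.disulfides.roman == "I–IV, II–III"
    assert scaffold_filter(c) == (True, [])
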