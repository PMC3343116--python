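import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pfcpersist.morphology import (
    BranchLocation, CalibrationError, Morphology, MorphologyError, Section,
    SWCStructureError, load_swc, make_surrogate_morphology,
    passive_input_resistance, write_swc,
)


def _write(tmp_path, text, name="m.swc"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadSWC:
    def test_three_point_chain_merges_into_one_basal_section(self, tmp_path):
        # soma + two chained dendrite points 50 um apart, radius 1 um
        p = _write(tmp_path, """
1 1 0 0 0 10 -1
2 3 50 0 0 1 1
3 3 100 0 0 1 2
""".strip())
        m = load_swc(p)
        assert m.counts_by_region == {"soma": 1, "axon": 0, "basal": 1, "apical": 0}
        basal = m.basal_sections()[0]
        assert basal.length == pytest.approx(100.0)
        assert basal.diameter == pytest.approx(2.0)

    def test_undefined_parent_is_a_structure_error(self, tmp_path):
        p = _write(tmp_path, """
1 1 0 0 0 10 -1
2 3 50 0 0 1 1
5 3 100 0 0 1 99
""".strip())
        with pytest.raises(SWCStructureError, match="99"):
            load_swc(p)

    def test_no_soma_is_a_structure_error(self, tmp_path):
        p = _write(tmp_path, "1 3 0 0 0 1 -1")
        with pytest.raises(SWCStructureError, match="soma"):
            load_swc(p)

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = _write(tmp_path, "1 1 0 0 0 10 -1\n2 3 oops 0 0 1 1")
        with pytest.raises(ValueError, match="line 2"):
            load_swc(p)

    def test_branch_point_starts_new_sections(self, tmp_path):
        p = _write(tmp_path, """
1 1 0 0 0 10 -1
2 3 30 0 0 1 1
3 3 60 0 0 1 2
4 3 30 30 0 1 2
""".strip())
        m = load_swc(p)
        assert m.counts_by_region["basal"] == 3  # stem + two daughters


class TestRoundTrip:
    def test_surrogate_swc_round_trip_preserves_geometry(self, surrogate, tmp_path):
        p = tmp_path / "s.swc"
        write_swc(surrogate, p)
        m2 = load_swc(p)
        a = sorted((s.region, s.length, s.diameter) for s in surrogate.sections)
        b = sorted((s.region, s.length, s.diameter) for s in m2.sections)
        assert len(a) == len(b)
        for (ra, la, da), (rb, lb, db) in zip(a, b):
            assert ra == rb
            assert la == pytest.approx(lb, abs=1e-6)
            assert da == pytest.approx(db, abs=1e-6)
        da = sorted(surrogate.branch_center_distance(s.id) for s in surrogate.basal_sections())
        db = sorted(m2.branch_center_distance(s.id) for s in m2.basal_sections())
        assert np.allclose(da, db, atol=1e-6)


class TestSurrogate:
    def test_default_counts_and_input_resistance(self, surrogate):
        assert len(surrogate) == 45
        assert surrogate.counts_by_region == {"soma": 1, "axon": 1, "basal": 18, "apical": 25}
        rin = passive_input_resistance(surrogate)
        assert 79.4 <= rin <= 82.6

    def test_same_seed_is_bit_identical(self, surrogate):
        m2 = make_surrogate_morphology(seed=1)
        assert all(a == b for a, b in zip(surrogate.sections, m2.sections))

    def test_different_seed_differs(self, surrogate):
        m2 = make_surrogate_morphology(seed=2)
        assert any(a != b for a, b in zip(surrogate.sections, m2.sections))

    def test_basal_centres_span_proximal_to_distal(self, surrogate):
        d = [surrogate.branch_center_distance(s.id) for s in surrogate.basal_sections()]
        assert min(d) < 40.0
        assert max(d) > 60.0

    def test_two_section_stick_matches_finite_cable_formula(self):
        m = make_surrogate_morphology(
            seed=2, counts={"soma": 1, "axon": 0, "basal": 1, "apical": 0},
            target_rin=1800.0)
        soma, dend = m.sections
        rm, ra = 30.0, 100.0  # kOhm cm^2, Ohm cm
        # finite sealed-end cable in parallel with the isopotential soma
        d_cm = dend.diameter * 1e-4
        lam = math.sqrt((rm * 1e3 / (ra * 4.0)) * d_cm)  # cm
        r_inf = (rm * 1e3 * ra / (math.pi ** 2) / d_cm ** 3) ** 0.5  # Ohm... via standard form
        r_inf = 2.0 / (math.pi * d_cm ** 1.5) * math.sqrt(rm * 1e3 * ra)  # Ohm
        L = dend.length * 1e-4 / lam
        r_cable = r_inf / math.tanh(L)
        r_soma = rm * 1e3 / (math.pi * soma.diameter * soma.length * 1e-8)
        expected = 1.0 / (1.0 / r_cable + 1.0 / r_soma) * 1e-6  # MOhm
        measured = passive_input_resistance(m, rm, ra, seg_um=1.0)
        assert measured == pytest.approx(expected, rel=0.02)

    def test_unreachable_target_reports_achieved_value(self):
        with pytest.raises(CalibrationError) as exc:
            make_surrogate_morphology(
                seed=1, counts={"soma": 1, "axon": 0, "basal": 1, "apical": 0},
                target_rin=5.0)
        assert exc.value.achieved > 5.0


class TestPathDistance:
    def test_soma_centre_is_zero(self, chain_morphology):
        assert chain_morphology.path_distance(BranchLocation(0, 0.5)) == 0.0

    def test_chain_midpoint(self, chain_morphology):
        # soma -> A(50) -> B(50); middle of B is 75 um out
        assert chain_morphology.path_distance(BranchLocation(2, 0.5)) == pytest.approx(75.0)
        assert chain_morphology.path_distance(BranchLocation(1, 1.0)) == pytest.approx(50.0)

    def test_unknown_section_raises(self, chain_morphology):
        with pytest.raises(MorphologyError):
            chain_morphology.path_distance(BranchLocation(99, 0.5))

    def test_matches_graph_shortest_path_oracle(self, surrogate):
        import networkx as nx
        g = nx.Graph()
        for s in surrogate.sections:
            if s.parent_id is not None:
                g.add_edge(s.parent_id, s.id, weight=s.length)
        for s in surrogate.sections:
            if s.parent_id is None:
                continue
            # distance to the distal end of each section, taking the soma as
            # a point origin (its own length excluded)
            dist = nx.shortest_path_length(g, 0, s.id, weight="weight")
            dist -= surrogate.section(
                [x for x in nx.shortest_path(g, 0, s.id)][1]
            ).length * 0.0  # path includes full child lengths already
            expected = dist
            got = surrogate.path_distance(BranchLocation(s.id, 1.0))
            assert got == pytest.approx(expected, abs=1e-9)

    @given(pos=st.floats(0.0, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_additive_and_monotone_along_section(self, pos):
        chain = Morphology([
            Section(0, "soma", None, 20.0, 20.0),
            Section(1, "basal", 0, 50.0, 1.0),
            Section(2, "basal", 1, 50.0, 1.0),
        ])
        d = chain.path_distance(BranchLocation(2, pos))
        assert d == pytest.approx(50.0 + 50.0 * pos)
        assert d >= 0.0


def test_invalid_sections_rejected():
    with pytest.raises(MorphologyError):
        Section(0, "soma", None, -1.0, 20.0)
    with pytest.raises(MorphologyError):
        Section(0, "nowhere", None, 10.0, 1.0)
    with pytest.raises(MorphologyError):
        Morphology([Section(0, "basal", None, 10.0, 1.0)])  # root must be soma
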