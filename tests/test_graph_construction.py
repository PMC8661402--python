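"""Bond/interaction detectors and the assembled energy-weighted graph."""

import numpy as np
import pytest

from allograph import fixtures
from allograph.graph_construction import (
    AtomisticGraph,
    BondType,
    EnergyConfig,
    UnknownElementError,
    build_graph,
    detect_covalent,
    detect_electrostatic_and_salt_bridges,
    detect_hydrogen_bonds,
    detect_hydrophobic,
    detect_pi_pi,
)
from allograph.structure_io import AtomRecord, Structure


def mk(records):
    """Structure from (name, element, res_name, chain, seq, xyz) tuples."""
    atoms = [
        AtomRecord(
            serial=i + 1, name=nm, element=el, alt_loc="", res_name=rn,
            chain_id=ch, res_seq=sq, i_code="", xyz=tuple(map(float, xyz)),
        )
        for i, (nm, el, rn, ch, sq, xyz) in enumerate(records)
    ]
    return Structure(atoms=atoms)


class TestCovalent:
    @pytest.mark.parametrize("dist,expect", [(1.50, 1), (5.0, 0)])
    def test_carbon_pair_distance_rule(self, dist, expect):
        st = mk([
            ("C1", "C", "LIG", "A", 1, (0, 0, 0)),
            ("C2", "C", "LIG", "A", 1, (dist, 0, 0)),
        ])
        assert len(detect_covalent(st)) == expect

    def test_tripeptide_matches_template_count(self, tripeptide):
        """Covalent count equals an independent count from the residue
        templates (heavy-atom intra-residue bonds) plus the two peptide
        bonds."""
        import biotite.structure.info as info

        expected = 2  # peptide bonds
        for res, present in [
            ("GLY", {"N", "CA", "C", "O"}),
            ("ALA", {"N", "CA", "C", "O", "CB"}),
            ("SER", {"N", "CA", "C", "O", "CB", "OG"}),
        ]:
            tmpl = info.residue(res)
            names = tmpl.atom_name
            for i, j, _ in tmpl.bonds.as_array():
                if names[i] in present and names[j] in present:
                    expected += 1
        edges = detect_covalent(tripeptide)
        assert len(edges) == expected

    def test_double_bond_energy_from_template(self, tripeptide):
        edges = detect_covalent(tripeptide)
        atoms = tripeptide.atoms
        co = [e for e in edges
              if {atoms[e.atom_u].name, atoms[e.atom_v].name} == {"C", "O"}]
        assert co and all(e.weight == pytest.approx(749.0) for e in co)

    def test_unknown_element_raises(self):
        st = mk([("Q1", "Qq", "LIG", "A", 1, (0, 0, 0)),
                 ("C1", "C", "LIG", "A", 1, (1.5, 0, 0))])
        with pytest.raises(UnknownElementError, match="Q1"):
            detect_covalent(st)

    def test_conect_hint_adds_stretched_bond(self):
        st = mk([("FE", "FE", "HEM", "A", 1, (0, 0, 0)),
                 ("N1", "N", "HEM", "A", 1, (2.6, 0, 0))])
        assert len(detect_covalent(st)) == 0
        st.conect_pairs = [(1, 2)]
        assert len(detect_covalent(st)) == 1


class TestHydrogenBonds:
    def linear_nho(self, r_da, angle_deg=180.0):
        """N-H...O geometry: N at origin, H on x, O at D...A distance r_da
        with the given D-H...A angle."""
        h = np.array([1.0, 0.0, 0.0])
        ang = np.deg2rad(angle_deg)
        direction = np.array([-np.cos(ang), np.sin(ang), 0.0])
        # place O so that the D-H...A angle is angle_deg
        o = h + direction * 1.0
        # scale H->O so |N-O| = r_da
        lo, hi = 0.1, 10.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            o = h + direction * mid
            if np.linalg.norm(o) < r_da:
                lo = mid
            else:
                hi = mid
        return mk([
            ("N", "N", "GLN", "A", 1, (0, 0, 0)),
            ("H", "H", "GLN", "A", 1, tuple(h)),
            ("O", "O", "GLN", "A", 2, tuple(o)),
        ])

    def test_ideal_linear_bond_weight_equals_well_depth(self):
        cfg = EnergyConfig()
        st = self.linear_nho(cfg.hb_r0, 180.0)
        edges = detect_hydrogen_bonds(st, cfg)
        assert len(edges) == 1
        assert edges[0].bond_type is BondType.HYDROGEN
        assert edges[0].weight == pytest.approx(cfg.hb_well_depth, rel=0.01)

    def test_bent_geometry_rejected(self):
        st = self.linear_nho(2.8, 60.0)
        assert detect_hydrogen_bonds(st) == []

    def test_helix_backbone_count_matches_geometric_oracle(self, helix10):
        """Heavy-atom H-bond detection agrees with an independent
        re-application of the same geometric criteria."""
        cfg = EnergyConfig()
        edges = detect_hydrogen_bonds(helix10, cfg)
        coords = helix10.coords
        atoms = helix10.atoms
        cov = detect_covalent(helix10, cfg)
        adj = [set() for _ in atoms]
        for e in cov:
            adj[e.atom_u].add(e.atom_v)
            adj[e.atom_v].add(e.atom_u)
        donors = [i for i, a in enumerate(atoms) if a.name == "N"]
        accs = [i for i, a in enumerate(atoms) if a.name == "O"]
        expected = set()
        for d in donors:
            for a in accs:
                if a in adj[d] or (adj[d] & adj[a]):
                    continue
                r = np.linalg.norm(coords[d] - coords[a])
                if r > cfg.hb_da_cutoff:
                    continue
                ok = True
                for x in adj[d]:
                    v1 = coords[x] - coords[d]
                    v2 = coords[a] - coords[d]
                    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    if np.degrees(np.arccos(np.clip(cosang, -1, 1))) < cfg.hb_angle_min_deg:
                        ok = False
                if ok:
                    expected.add((min(d, a), max(d, a)))
        got = {(e.atom_u, e.atom_v) for e in edges}
        assert got == expected
        # the alpha-helical i -> i+4 backbone contacts are all present
        idx_of = {(a.res_seq, a.name): i for i, a in enumerate(atoms)}
        for i in range(1, 7):
            o, n = idx_of[(i, "O")], idx_of[(i + 4, "N")]
            assert (min(o, n), max(o, n)) in got


class TestHydrophobic:
    def test_contact_weight_formula(self):
        cfg = EnergyConfig()
        st = mk([("CD1", "C", "LEU", "A", 1, (0, 0, 0)),
                 ("CD1", "C", "LEU", "A", 2, (4.0, 0, 0))])
        edges = detect_hydrophobic(st, cfg)
        assert len(edges) == 1
        expected = cfg.hydrophobic_eps * np.exp(
            -(4.0 - cfg.hydrophobic_r0) / cfg.hydrophobic_sigma
        )
        assert edges[0].weight == pytest.approx(expected, rel=1e-9)

    def test_same_residue_excluded(self):
        st = mk([("CD1", "C", "LEU", "A", 1, (0, 0, 0)),
                 ("CD2", "C", "LEU", "A", 1, (4.0, 0, 0))])
        assert detect_hydrophobic(st) == []

    def test_polar_adjacent_carbon_excluded(self):
        # CA bonded to backbone N is polar-adjacent, hence not apolar
        st = mk([
            ("N", "N", "GLY", "A", 1, (0, 0, 0)),
            ("CA", "C", "GLY", "A", 1, (1.46, 0, 0)),
            ("CD1", "C", "LEU", "A", 2, (1.46, 4.0, 0)),
        ])
        assert detect_hydrophobic(st) == []


class TestElectrostatics:
    def pair(self, dist):
        return mk([
            ("NZ", "N", "LYS", "A", 1, (0, 0, 0)),
            ("OE1", "O", "GLU", "A", 2, (dist, 0, 0)),
        ])

    def test_salt_bridge_weight(self):
        cfg = EnergyConfig()
        edges = detect_electrostatic_and_salt_bridges(self.pair(3.0), cfg)
        assert len(edges) == 1
        assert edges[0].bond_type is BondType.SALT_BRIDGE
        expected = cfg.coulomb_k / (cfg.dielectric_slope * 3.0**2)
        assert edges[0].weight == pytest.approx(expected, rel=1e-9)

    def test_intermediate_distance_is_electrostatic(self):
        edges = detect_electrostatic_and_salt_bridges(self.pair(6.0))
        assert len(edges) == 1
        assert edges[0].bond_type is BondType.ELECTROSTATIC

    def test_beyond_cutoff_no_edge(self):
        assert detect_electrostatic_and_salt_bridges(self.pair(9.0)) == []

    def test_like_charges_no_edge(self):
        st = mk([
            ("NZ", "N", "LYS", "A", 1, (0, 0, 0)),
            ("NZ", "N", "LYS", "A", 2, (3.0, 0, 0)),
        ])
        assert detect_electrostatic_and_salt_bridges(st) == []


class TestPiPi:
    def test_dna4_stacking_count(self, dna4):
        edges = detect_pi_pi(dna4)
        assert len(edges) == 3  # adjacent steps of a 4-mer strand
        for e in edges:
            assert e.bond_type is BondType.PI_PI
            assert e.length == pytest.approx(3.62, abs=0.05)

    def test_perpendicular_rings_rejected(self):
        ring = [(np.cos(t), np.sin(t), 0.0) for t in np.linspace(0, 2 * np.pi, 7)[:-1]]
        perp = [(x, 3.8 + z * 0.0, y) for x, y, z in ring]  # rotated 90 deg
        names = ["N1", "C2", "N3", "C4", "C5", "C6"]
        recs = [(nm, nm[0], "DA", "X", 1, xyz) for nm, xyz in zip(names, ring)]
        recs += [(nm, nm[0], "DA", "X", 2, xyz) for nm, xyz in zip(names, perp)]
        assert detect_pi_pi(mk(recs)) == []


class TestBuildGraph:
    def test_single_glycine_covalent_only(self):
        st = mk([
            ("N", "N", "GLY", "A", 1, (0, 0, 0)),
            ("CA", "C", "GLY", "A", 1, (1.46, 0, 0)),
            ("C", "C", "GLY", "A", 1, (2.0, 1.4, 0)),
            ("O", "O", "GLY", "A", 1, (1.5, 2.3, -0.7)),
        ])
        g = build_graph(st)
        assert all(e.bond_type is BondType.COVALENT for e in g.edges)

    def test_disabling_weak_detectors(self, tripeptide):
        cfg = EnergyConfig(
            enable_hydrogen=False, enable_hydrophobic=False,
            enable_electrostatic=False, enable_pi_pi=False,
        )
        g = build_graph(tripeptide, cfg)
        cov = detect_covalent(tripeptide, cfg)
        assert len(g.edges) == len(cov)

    def test_handshake_identity_exact(self, tripeptide_graph):
        g = tripeptide_graph
        assert g.weighted_degree.sum() == pytest.approx(
            2.0 * g.pair_weight.sum(), rel=0, abs=1e-9
        )

    def test_determinism(self, tripeptide):
        g1 = build_graph(tripeptide)
        g2 = build_graph(tripeptide)
        assert [(e.pair(), e.bond_type, e.weight) for e in g1.edges] == [
            (e.pair(), e.bond_type, e.weight) for e in g2.edges
        ]

    def test_rigid_motion_invariance(self, tripeptide):
        from dataclasses import replace

        theta = 0.7
        R = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ])
        t = np.array([11.0, -3.0, 5.0])
        moved = Structure(atoms=[
            replace(a, xyz=tuple(R @ np.asarray(a.xyz) + t))
            for a in tripeptide.atoms
        ])
        g0 = build_graph(tripeptide)
        g1 = build_graph(moved)
        assert [(e.pair(), e.bond_type) for e in g0.edges] == [
            (e.pair(), e.bond_type) for e in g1.edges
        ]
        w0 = np.array([e.weight for e in g0.edges])
        w1 = np.array([e.weight for e in g1.edges])
        np.testing.assert_allclose(w1, w0, rtol=1e-9)

    def test_monotone_cutoff_never_removes_edges(self, tripeptide):
        small = detect_hydrophobic(tripeptide, EnergyConfig(hydrophobic_cutoff=5.0))
        large = detect_hydrophobic(tripeptide, EnergyConfig(hydrophobic_cutoff=8.0))
        small_pairs = {e.pair() for e in small}
        large_pairs = {e.pair() for e in large}
        assert small_pairs <= large_pairs

    def test_zero_edge_graph_rejected(self):
        from allograph.graph_construction import EmptyGraphError

        with pytest.raises(EmptyGraphError):
            AtomisticGraph.from_edges(2, [])

    def test_multi_type_pairs_collapse_with_summed_weight(self):
        edges_itemized = [
            (0, 1, 2.0),
            (0, 1, 3.0),
        ]
        from allograph.graph_construction import BondEdge

        g = AtomisticGraph(
            2,
            [
                BondEdge(0, 1, BondType.HYDROGEN, 2.0, 1.0),
                BondEdge(0, 1, BondType.ELECTROSTATIC, 3.0, 1.0),
            ],
            np.array([[0.0, 0, 0], [1.0, 0, 0]]),
            AtomisticGraph.from_edges(2, [(0, 1, 1.0)]).residue_of_atom,
        )
        assert g.n_bonds == 1
        assert g.pair_weight[0] == pytest.approx(5.0)
        assert g.pair_types[0] == "ELECTROSTATIC+HYDROGEN"
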