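"""Tetrad detection, core assembly, topology, grooves, loops and ions."""

import itertools

import numpy as np
import pytest

from g4kit import quadruplex, synthetic_data
from g4kit.geometry import ls_plane
from g4kit.quadruplex import (
    assemble_cores,
    base_ring_points,
    channel_ions,
    classify_loops,
    classify_topology,
    detect_hbonds,
    detect_tetrads,
    groove_widths,
)
from g4kit.structure_io import GUANINE_RING_ATOMS, Atom, Residue, StructureModel
from g4kit.synthetic_data import G4BuildSpec, build_g4

from conftest import random_rotation, residue_from_ccd


def two_distant_guanines() -> StructureModel:
    m = StructureModel()
    m.add_residue(residue_from_ccd("DG", seq_num=1))
    far = residue_from_ccd("DG", seq_num=2)
    for a in far.atoms:
        a.pos = a.pos + np.array([20.0, 0.0, 0.0])
    m.add_residue(far)
    return m


def brute_force_tetrads(model, dist_cutoff=3.4, planarity_rms_max=1.0, slack=1.0):
    """Exhaustive oracle: every 4-subset, every cyclic order, same acceptance
    rule (candidate bonds within cutoff+slack, mean of 8 within cutoff,
    common plane within rms cutoff)."""
    gs = [g for g in model.guanines() if g.has_atoms(("N1", "N2", "O6", "N7"))]
    found = set()
    for subset in itertools.combinations(range(len(gs)), 4):
        for perm in itertools.permutations(subset[1:]):
            cycle = (subset[0],) + perm
            dists = []
            ok = True
            for k in range(4):
                u, v = gs[cycle[k]], gs[cycle[(k + 1) % 4]]
                d1 = np.linalg.norm(u.coord("N1") - v.coord("O6"))
                d2 = np.linalg.norm(u.coord("N2") - v.coord("N7"))
                if min(d1, d2) > dist_cutoff + slack:
                    ok = False
                    break
                dists.extend([d1, d2])
            if not ok or np.mean(dists) > dist_cutoff:
                continue
            pts = np.vstack([base_ring_points(gs[i]) for i in cycle])
            if ls_plane(pts).rms_dev > planarity_rms_max:
                continue
            found.add(frozenset(gs[i].key for i in cycle))
    return found


class TestHBonds:
    def test_distant_guanines_no_bonds(self):
        assert detect_hbonds(two_distant_guanines()) == []

    def test_ideal_tetrad_has_exactly_eight_hoogsteen_bonds(self):
        m = build_g4(G4BuildSpec(n_layers=2, loops=False, place_ions=False))
        # restrict to one layer: residues of the bottom tetrad
        layer = StructureModel()
        for r in m.guanines():
            if abs(r.coord("N9")[2]) < 1.0:
                layer.add_residue(r)
        bonds = detect_hbonds(layer)
        assert len(bonds) == 8
        assert {(b.donor_atom, b.acceptor_atom) for b in bonds} == {("N1", "O6"), ("N2", "N7")}
        assert all(2.7 <= b.dist <= 3.1 for b in bonds)

    def test_tight_cutoff_empties(self):
        m = build_g4(G4BuildSpec(n_layers=2, loops=False, place_ions=False))
        assert detect_hbonds(m, dist_cutoff=2.0) == []


class TestTetradDetection:
    def test_monomer_has_four_tetrads(self, parallel_monomer):
        tets = detect_tetrads(parallel_monomer)
        assert len(tets) == 4
        labels = {t.label() for t in tets}
        assert "G1·G7·G13·G19" in labels

    def test_dimer_has_eight_tetrads(self, parallel_dimer):
        assert len(detect_tetrads(parallel_dimer)) == 8

    def test_no_cycles_means_no_tetrads(self):
        assert detect_tetrads(two_distant_guanines()) == []

    def test_matches_brute_force_oracle(self):
        # 12 guanines (3 layers), noisy coordinates
        m = build_g4(G4BuildSpec(n_layers=3, loops=False, place_ions=False,
                                 noise_sigma=0.2, seed=5))
        got = {t.member_keys() for t in detect_tetrads(m)}
        want = brute_force_tetrads(m)
        assert got == want
        assert len(got) == 3

    def test_rotation_invariance(self, parallel_monomer):
        rng = np.random.default_rng(17)
        R = random_rotation(rng)
        t = rng.uniform(-30, 30, 3)
        rotated = StructureModel()
        for r in parallel_monomer.residues():
            rr = Residue(r.chain_id, r.seq_num, r.res_name, r.ins_code)
            rr.atoms = [Atom(a.name, a.element, R @ a.pos + t) for a in r.atoms]
            rotated.add_residue(rr)
        got = {t.member_keys() for t in detect_tetrads(rotated)}
        want = {t.member_keys() for t in detect_tetrads(parallel_monomer)}
        assert got == want

    def test_reference_normal_flips_directionality(self, parallel_monomer):
        for t in detect_tetrads(parallel_monomer):
            d1 = t.directionality(np.array([0.0, 0.0, 1.0]))
            d2 = t.directionality(np.array([0.0, 0.0, -1.0]))
            assert {d1, d2} == {"clockwise", "anticlockwise"}


class TestCoreAssembly:
    def test_monomer_core_shape(self, parallel_core):
        assert parallel_core.n_layers == 4
        assert len(parallel_core.columns) == 4
        assert all(len(col) == 4 for col in parallel_core.columns)
        # every tetrad guanine sits in exactly one column
        keys = [r.key for col in parallel_core.columns for r in col]
        assert len(keys) == len(set(keys)) == 16

    def test_separated_cores_stay_separate(self, parallel_monomer):
        shifted = StructureModel()
        for r in parallel_monomer.residues():
            rr = Residue(r.chain_id + "X", r.seq_num, r.res_name, r.ins_code)
            rr.atoms = [Atom(a.name, a.element, a.pos + np.array([50.0, 0, 0])) for a in r.atoms]
            shifted.add_residue(rr)
        merged = StructureModel()
        for r in itertools.chain(parallel_monomer.residues(), shifted.residues()):
            merged.add_residue(r)
        cores = assemble_cores(detect_tetrads(merged))
        assert len(cores) == 2

    def test_dimer_single_eight_layer_stack(self, parallel_dimer):
        cores = assemble_cores(detect_tetrads(parallel_dimer))
        assert len(cores) == 1
        core = cores[0]
        assert core.n_layers == 8
        units = core.units()
        # the 5'-5' interface separates the two monomer units mid-stack
        assert units[:4] != units[4:]
        assert len(set(units[:4])) == 1 and len(set(units[4:])) == 1


class TestTopology:
    @pytest.mark.parametrize("topo", ["parallel", "antiparallel", "hybrid"])
    def test_builder_topology_recovered(self, topo):
        m = build_g4(G4BuildSpec(topology=topo))
        core = assemble_cores(detect_tetrads(m))[0]
        assert classify_topology(core) == topo

    def test_parallel_is_all_anti(self, parallel_core):
        for t in parallel_core.tetrads:
            assert set(t.glycosidic_pattern()) == {"anti"}

    def test_antiparallel_alternates_syn_anti(self, antiparallel_monomer):
        core = assemble_cores(detect_tetrads(antiparallel_monomer))[0]
        for t in core.tetrads:
            assert t.glycosidic_pattern() in (
                ("syn", "anti", "syn", "anti"),
                ("anti", "syn", "anti", "syn"),
            )


class TestGrooves:
    def test_parallel_four_medium(self, parallel_core):
        grooves = groove_widths(parallel_core)
        assert [g.groove_class for g in grooves] == ["medium"] * 4
        for g in grooves:
            assert g.width_mean == pytest.approx(16.0, abs=0.2)
            assert g.width_mean == pytest.approx(np.mean(g.width_per_layer))

    def test_antiparallel_two_wide_two_narrow(self, antiparallel_monomer):
        core = assemble_cores(detect_tetrads(antiparallel_monomer))[0]
        grooves = groove_widths(core)
        classes = [g.groove_class for g in grooves]
        assert sorted(classes) == ["narrow", "narrow", "wide", "wide"]
        widths = sorted(g.width_mean for g in grooves)
        assert widths[0] == pytest.approx(8.7, abs=0.2)
        assert widths[-1] == pytest.approx(21.6, abs=0.2)

    def test_classes_partition(self, parallel_core):
        for g in groove_widths(parallel_core):
            assert g.groove_class in ("narrow", "medium", "wide")


class TestLoops:
    def test_parallel_three_propeller(self, parallel_monomer, parallel_core):
        loops = classify_loops(parallel_monomer, parallel_core)
        assert [lp.loop_class for lp in loops] == ["propeller"] * 3
        assert [[r.label for r in lp.residues] for lp in loops] == [
            ["C5", "C6"], ["C11", "C12"], ["C17", "C18"],
        ]

    def test_antiparallel_three_lateral_spanning_narrow_wide_narrow(
        self, antiparallel_monomer
    ):
        core = assemble_cores(detect_tetrads(antiparallel_monomer))[0]
        groove_widths(core)
        loops = classify_loops(antiparallel_monomer, core)
        assert [lp.loop_class for lp in loops] == ["lateral"] * 3
        spanned = []
        for lp in loops:
            pair = lp.spanned_groove
            (match,) = [g for g in core.grooves if tuple(g.strand_pair) == pair]
            spanned.append(match.groove_class)
        assert spanned == ["narrow", "wide", "narrow"]

    def test_diagonal_loop_on_synthetic_basket(self):
        # antiparallel core whose chain jumps between diagonal columns on the
        # same face: renumber one diagonal tract so it follows the first
        m = build_g4(G4BuildSpec(topology="antiparallel", loops=False, place_ions=False))
        core = assemble_cores(detect_tetrads(m))[0]
        col_of = {id(r): c for c, col in enumerate(core.columns) for r in col}
        chain = m.chains["A"]
        g1 = next(r for r in chain if r.seq_num == 1)
        g1_col = col_of[id(g1)]
        diag_col = (g1_col + 2) % 4
        bottom_layer_z = min(r.coord("N9")[2] for r in chain)
        # renumber the diagonal tract 7..10 running bottom->top (starts on the
        # same face where tract 1 ends: the bottom); remaining tracts follow
        new_seq: dict[int, int] = {}
        diag = sorted(
            (r for r in chain if col_of[id(r)] == diag_col),
            key=lambda r: r.coord("N9")[2],
        )
        for i, r in enumerate(diag):
            new_seq[id(r)] = 7 + i
        others = sorted({0, 1, 2, 3} - {g1_col, diag_col})
        for col, start in zip(others, (13, 19)):
            members = sorted(
                (r for r in chain if col_of[id(r)] == col), key=lambda r: r.seq_num
            )
            for i, r in enumerate(members):
                new_seq[id(r)] = start + i
        for r in chain:
            r.seq_num = new_seq.get(id(r), r.seq_num)
        basket = StructureModel()
        for r in sorted(chain, key=lambda r: r.seq_num):
            basket.add_residue(r)
        # a schematic loop residue between tract 1 and the diagonal tract
        loop_res = Residue("A", 5, "DC")
        loop_res.atoms = [Atom("N1", "N", np.array([15.0, 0.0, bottom_layer_z - 3.0]))]
        basket.add_residue(loop_res)
        basket.sort()
        core2 = assemble_cores(detect_tetrads(basket))[0]
        loops = classify_loops(basket, core2)
        assert any(lp.loop_class == "diagonal" for lp in loops)


class TestChannelIons:
    def test_monomer_ion_count_and_intervals(self, parallel_monomer, parallel_core):
        ions = channel_ions(parallel_monomer, parallel_core)
        assert len(ions) == 3
        assert sorted(i.interval for i in ions) == [(0, 1), (1, 2), (2, 3)]
        assert all(i.n_O6 == 8 for i in ions)
        assert not any(i.interface for i in ions)

    def test_displaced_ion_not_channel(self, parallel_monomer, parallel_core):
        displaced = StructureModel()
        for r in parallel_monomer.residues():
            rr = Residue(r.chain_id, r.seq_num, r.res_name, r.ins_code)
            shift = np.array([6.0, 0, 0]) if rr.res_name == "K" else np.zeros(3)
            rr.atoms = [Atom(a.name, a.element, a.pos + shift) for a in r.atoms]
            displaced.add_residue(rr)
        core = assemble_cores(detect_tetrads(displaced))[0]
        assert channel_ions(displaced, core) == []

    def test_dimer_seven_ions_middle_is_interface(self, parallel_dimer):
        core = assemble_cores(detect_tetrads(parallel_dimer))[0]
        ions = channel_ions(parallel_dimer, core)
        assert len(ions) == 7
        interface = [i for i in ions if i.interface]
        assert len(interface) == 1
        assert interface[0].interval == (3, 4)


class TestReport:
    def test_core_report_is_json_ready(self, parallel_monomer, parallel_core):
        import json

        classify_loops(parallel_monomer, parallel_core)
        channel_ions(parallel_monomer, parallel_core)
        report = quadruplex.core_report(parallel_core)
        json.dumps(report, sort_keys=True)  # must serialize cleanly
        assert report["tetrads"][0]["members"] == "G1·G7·G13·G19"
        assert report["topology"] == "parallel"
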