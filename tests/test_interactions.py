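"""Geometric interaction detection: criteria, invariances, occupancy."""

import numpy as np
import pytest

from alchemtraj import synthetic
from alchemtraj.core import Topology, Trajectory
from alchemtraj.interactions import (
    InteractionCriteria,
    detect_hbonds,
    detect_hydrophobic,
    detect_water_bridges,
    occupancy_table,
)
from conftest import random_rotation


def _hb_fixture(distance, angle):
    pc = synthetic.gen_planted_complex(
        synthetic.PlantedComplexSpec(
            hbonds=[
                synthetic.HBondPlant(
                    distance, angle,
                    negative=not (distance <= 2.9 and angle >= 125.0),
                )
            ]
        )
    )
    return pc.trajectory.coordinates[0], pc.topology


class TestHbondCriteria:
    @pytest.mark.parametrize(
        "distance,angle,detected",
        [
            (2.8, 165.0, True),
            (3.2, 170.0, False),  # distance cutoff
            (2.8, 110.0, False),  # angle cutoff
        ],
    )
    def test_criteria(self, distance, angle, detected):
        frame, top = _hb_fixture(distance, angle)
        assert bool(detect_hbonds(frame, top)) is detected

def test_donor_without_hydrogen_rejected_at_construction():
    with pytest.raises(ValueError, match="no bonded hydrogen"):
        Topology(
            names=["N1", "O1"],
            elements=["N", "O"],
            masses=np.array([14.007, 15.999]),
            resids=np.array([1, 2]),
            resnames=["LIG", "ALA"],
            segids=["L", "P"],
            molecule_class=["ligand", "protein"],
            donor=np.array([True, False]),
        )


class TestWaterBridges:
    def test_planted_bridge_detected_once(self):
        pc = synthetic.gen_planted_complex(
            synthetic.PlantedComplexSpec(bridges=[synthetic.WaterBridgePlant(2.8)])
        )
        found = detect_water_bridges(pc.trajectory.coordinates[0], pc.topology)
        assert found == pc.expected_bridges

    def test_water_bonded_to_ligand_only_is_no_bridge(self):
        pc = synthetic.gen_planted_complex(
            synthetic.PlantedComplexSpec(
                bridges=[synthetic.WaterBridgePlant(2.8, negative=True)]
            )
        )
        assert detect_water_bridges(pc.trajectory.coordinates[0], pc.topology) == []

    def test_two_water_chain_not_reported(self):
        # ligand - W1 - W2 - protein: every adjacent pair H-bonds, but no
        # single water bridges both ends, so no bridge is reported.
        # Verified by exhaustive scan: W1 bonds {ligand, W2}, W2 bonds {W1, protein}.
        oh = 0.96
        names, elements, pos, resids, resnames, segids, cls = [], [], [], [], [], [], []
        bonds = []

        def add(name, el, p, rid, rn, seg, c):
            names.append(name)
            elements.append(el)
            pos.append(p)
            resids.append(rid)
            resnames.append(rn)
            segids.append(seg)
            cls.append(c)
            return len(names) - 1

        la = add("O1", "O", [0.0, 0, 0], 1, "LIG", "L", "ligand")
        w1 = add("OW", "O", [2.8, 0, 0], 501, "HOH", "W", "water")
        h1a = add("HW1", "H", [2.8 - oh, 0, 0], 501, "HOH", "W", "water")
        h1b = add("HW2", "H", [2.8 + oh, 0, 0], 501, "HOH", "W", "water")
        w2 = add("OW", "O", [2.8 * 2, 0, 0], 502, "HOH", "W", "water")
        h2b = add("HW2", "H", [2.8 * 2 + oh, 0, 0], 502, "HOH", "W", "water")
        h2c = add("HW1", "H", [2.8 * 2, oh, 0], 502, "HOH", "W", "water")
        pa = add("O", "O", [2.8 * 3, 0, 0], 101, "SER", "P", "protein")
        bonds = [(w1, h1a), (w1, h1b), (w2, h2b), (w2, h2c)]
        top = Topology(
            names=names, elements=elements, masses=np.where(
                np.array([e == "H" for e in elements]), 1.008, 15.999
            ),
            resids=np.array(resids), resnames=resnames, segids=segids,
            molecule_class=cls, bonds=bonds,
            donor=np.array([e == "O" and n == "OW" for e, n in zip(elements, names)]),
            acceptor=np.array([e == "O" for e in elements]),
        )
        frame = np.array(pos)
        hbonds = detect_hbonds(frame, top)
        partners = {(d, a) for d, _h, a in hbonds}
        assert (w1, la) in partners and (w1, w2) in partners and (w2, pa) in partners
        assert detect_water_bridges(frame, top) == []


class TestHydrophobic:
    def test_three_plants_two_detections(self):
        pc = synthetic.gen_planted_complex(
            synthetic.PlantedComplexSpec(
                hydrophobics=[
                    synthetic.HydrophobicPlant(3.5),
                    synthetic.HydrophobicPlant(3.9),
                    synthetic.HydrophobicPlant(4.1, negative=True),
                ]
            )
        )
        frame = pc.trajectory.coordinates[0]
        found = detect_hydrophobic(frame, pc.topology)
        assert found == pc.expected_hydrophobic
        # brute-force all-pairs oracle over flagged intermolecular pairs
        idx = np.flatnonzero(pc.topology.hydrophobic)
        brute = [
            (int(i), int(j))
            for k, i in enumerate(idx)
            for j in idx[k + 1 :]
            if pc.topology.molecule_class[i] != pc.topology.molecule_class[j]
            and np.linalg.norm(frame[i] - frame[j]) <= 4.0
        ]
        assert found == brute


class TestInvariants:
    def test_detection_rigid_motion_invariant(self, mixed_planted_complex):
        pc = mixed_planted_complex
        frame = pc.trajectory.coordinates[0]
        rng = np.random.default_rng(5)
        rot = random_rotation(rng)
        moved = frame @ rot.T + np.array([11.0, -3.0, 8.0])
        for detect in (detect_hbonds, detect_water_bridges, detect_hydrophobic):
            assert detect(frame, pc.topology) == detect(moved, pc.topology)

    def test_shrinking_cutoffs_monotone(self, mixed_planted_complex):
        pc = mixed_planted_complex
        frame = pc.trajectory.coordinates[0]
        prev_hb, prev_ph = None, None
        for scale in (1.0, 0.9, 0.75, 0.5):
            crit = InteractionCriteria(
                hbond_min_angle=120.0,
                hbond_max_heavy_dist=3.0 * scale,
                hydrophobic_max_dist=4.0 * scale,
            )
            hb = set(detect_hbonds(frame, pc.topology, crit))
            ph = set(detect_hydrophobic(frame, pc.topology, crit))
            if prev_hb is not None:
                assert hb <= prev_hb and ph <= prev_ph
            prev_hb, prev_ph = hb, ph

    def test_precision_recall_unity_on_plants(self, mixed_planted_complex):
        pc = mixed_planted_complex
        frame = pc.trajectory.coordinates[0]
        cls = pc.topology.molecule_class
        hb = [
            t
            for t in detect_hbonds(frame, pc.topology)
            if {cls[t[0]], cls[t[2]]} == {"ligand", "protein"}
        ]
        assert hb == pc.expected_hbonds
        assert detect_water_bridges(frame, pc.topology) == pc.expected_bridges
        assert detect_hydrophobic(frame, pc.topology) == pc.expected_hydrophobic


class TestOccupancy:
    def test_full_and_half_presence(self):
        mask = [True] * 50 + [False] * 50
        pc = synthetic.gen_planted_complex(
            synthetic.PlantedComplexSpec(
                hbonds=[
                    synthetic.HBondPlant(2.8, 160.0),
                    synthetic.HBondPlant(2.7, 150.0, present_mask=mask),
                ],
                n_frames=100,
            )
        )
        records = occupancy_table(pc.trajectory, pc.topology)
        assert [r.occupancy for r in records] == [1.0, 0.5]
        assert all(r.kind == "hbond" for r in records)

    def test_residue_grouping_ors_bitmaps(self):
        # two H-bonds from the same ligand residue to the same protein
        # residue, present in complementary halves -> one residue-level
        # record with occupancy 1.0 (OR of the bitmaps), while atom-level
        # grouping keeps two records of occupancy 0.5 each
        first = [True] * 50 + [False] * 50
        second = [not x for x in first]
        spec = synthetic.PlantedComplexSpec(
            hbonds=[
                synthetic.HBondPlant(2.8, 160.0, present_mask=first),
                synthetic.HBondPlant(2.8, 160.0, present_mask=second),
            ],
            n_frames=100,
        )
        pc = synthetic.gen_planted_complex(spec)
        # collapse the two protein acceptors onto one residue (distinct atom
        # names) so residue grouping merges what atom grouping keeps apart
        top = pc.topology
        acceptor_idx = [i for i in range(top.n_atoms) if top.acceptor[i]]
        for k, i in enumerate(acceptor_idx):
            top.resids[i] = 101
            top.names[i] = f"O{'AB'[k]}"
        atom_level = occupancy_table(pc.trajectory, top, grouping="atom")
        res_level = occupancy_table(pc.trajectory, top, grouping="residue")
        assert sorted(r.occupancy for r in atom_level) == [0.5, 0.5]
        assert len(res_level) == 1 and res_level[0].occupancy == 1.0
        # brute-force: occupancy of OR'd bitmaps
        ored = np.zeros(100, dtype=bool)
        for r in atom_level:
            ored |= r.bitmap
        assert res_level[0].occupancy == np.mean(ored)

    def test_sorted_descending_with_deterministic_ties(self, mixed_planted_complex):
        records = occupancy_table(
            mixed_planted_complex.trajectory, mixed_planted_complex.topology
        )
        occs = [r.occupancy for r in records]
        assert occs == sorted(occs, reverse=True)

    def test_empty_trajectory_rejected(self, mixed_planted_complex):
        with pytest.raises(ValueError):
            occupancy_table(
                Trajectory(np.empty((0, 3, 3)), np.empty(0)),
                mixed_planted_complex.topology,
            )
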