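"""Interaction detection, occupancy, classification and network assembly."""

import numpy as np
import pandas as pd
import pytest

import mgatekit as mg
from mgatekit.errors import ConfigError, DataError
from mgatekit.interactions import INTER, INTRA, OTHER, round_half_away

from conftest import make_arg_guanidinium, make_ca_structure


def _pair_structure(d, basic_atoms=("NZ",), acidic_atoms=("OD1", "OD2")):
    """ARG/LYS-like residue 1 at origin, ASP-like residue 2 at distance d."""
    atoms1 = [mg.Atom(1, "CA", "C", np.array([0.0, 0, 0]))]
    for k, n in enumerate(basic_atoms):
        atoms1.append(mg.Atom(2 + k, n, "N", np.array([0.0, 0, 0.5 * k])))
    atoms2 = [mg.Atom(10, "CA", "C", np.array([d + 1.0, 0, 0]))]
    for k, n in enumerate(acidic_atoms):
        atoms2.append(mg.Atom(11 + k, n, "O", np.array([d + 0.4 * k, 0, 0])))
    r1 = mg.Residue(1, "LYS", "A", atoms1)
    r2 = mg.Residue(2, "ASP", "A", atoms2)
    return mg.Structure([r1, r2])


class TestDetectSaltBridge:
    @pytest.mark.parametrize("d,expected", [(3.0, True), (8.0, False), (4.0, True)])
    def test_distance_criterion_with_boundary(self, d, expected):
        s = _pair_structure(d)
        formed, dmin = mg.detect_salt_bridge(s, s.coords, 1, 2)
        assert formed is expected
        assert dmin == pytest.approx(d, abs=1e-9)

    def test_missing_sites_error(self):
        s = make_ca_structure([1, 2], [[0, 0, 0], [3, 0, 0]])
        with pytest.raises(DataError, match="charge-site"):
            mg.detect_salt_bridge(s, s.coords, 1, 2)

    def test_pseudo_atom_fallback(self):
        r1 = mg.Residue(1, "ARG", "A", [mg.Atom(1, "CA", "C", np.zeros(3)),
                                        mg.Atom(2, "CS", "N", np.array([1.0, 0, 0]))])
        r2 = mg.Residue(2, "ASP", "A", [mg.Atom(3, "CA", "C", np.array([9.0, 0, 0])),
                                        mg.Atom(4, "CS", "O", np.array([4.5, 0, 0]))])
        s = mg.Structure([r1, r2])
        formed, dmin = mg.detect_salt_bridge(s, s.coords, 1, 2)
        assert formed and dmin == pytest.approx(3.5)

    def test_equals_brute_force_scan(self):
        """Min over canonical N x O pairs equals an explicit double loop."""
        rng = np.random.default_rng(17)
        s = _pair_structure(5.0, basic_atoms=("NH1", "NH2", "NE"))
        n_idx = [s.atom_index(1, n) for n in ("NH1", "NH2", "NE")]
        o_idx = [s.atom_index(2, n) for n in ("OD1", "OD2")]
        for _ in range(50):
            frame = s.coords + rng.normal(0, 2.0, s.coords.shape)
            _, dmin = mg.detect_salt_bridge(s, frame, 1, 2)
            brute = min(np.linalg.norm(frame[i] - frame[j]) for i in n_idx for j in o_idx)
            assert dmin == pytest.approx(brute, abs=1e-12)


class TestDetectHbond:
    def _structure(self, da, h_offset_deg=None):
        atoms = [mg.Atom(1, "OG", "O", np.zeros(3))]
        if h_offset_deg is not None:
            a = np.radians(h_offset_deg)
            atoms.append(mg.Atom(2, "HG", "H", np.array([np.cos(a), np.sin(a), 0.0])))
        r1 = mg.Residue(1, "SER", "A", atoms)
        r2 = mg.Residue(2, "ASP", "A", [mg.Atom(3, "OD1", "O", np.array([da, 0.0, 0.0]))])
        return mg.Structure([r1, r2])

    def test_close_and_aligned(self):
        s = self._structure(2.9, h_offset_deg=10)
        assert mg.detect_hbond(s, s.coords, "resid 1 and name OG",
                               "resid 2 and name OD1", hydrogen_sel="name HG")

    def test_close_but_misaligned(self):
        s = self._structure(2.9, h_offset_deg=60)
        assert not mg.detect_hbond(s, s.coords, "resid 1 and name OG",
                                   "resid 2 and name OD1", hydrogen_sel="name HG")

    def test_hydrogen_free_fallback(self):
        s = self._structure(3.4)
        assert mg.detect_hbond(s, s.coords, "resid 1 and name OG",
                               "resid 2 and name OD1")
        s_far = self._structure(3.6)
        assert not mg.detect_hbond(s_far, s_far.coords, "resid 1 and name OG",
                                   "resid 2 and name OD1")


class TestDetectStacking:
    def _two_args(self, separation, normal_j, axis=(0, 0, 1)):
        r1 = make_arg_guanidinium(1, (0, 0, 0), (0, 0, 1), serial_start=1)
        r2 = make_arg_guanidinium(2, np.asarray(axis, dtype=float) * separation,
                                  normal_j, serial_start=10)
        return mg.Structure([r1, r2])

    def test_parallel_close(self):
        s = self._two_args(4.0, (0, 0, 1))
        assert mg.detect_stacking(s, s.coords, 1, 2)

    def test_perpendicular_close(self):
        s = self._two_args(4.0, (1, 0, 0))
        assert not mg.detect_stacking(s, s.coords, 1, 2)

    def test_parallel_far(self):
        s = self._two_args(7.0, (0, 0, 1))
        assert not mg.detect_stacking(s, s.coords, 1, 2)

    def test_antiparallel_counts_as_parallel(self):
        # interplanar angle folded into [0, 90]
        s = self._two_args(4.0, (0, 0, -1))
        assert mg.detect_stacking(s, s.coords, 1, 2)

    def test_non_arg_rejected(self):
        s = _pair_structure(4.0)
        with pytest.raises(DataError, match="ARG"):
            mg.detect_stacking(s, s.coords, 1, 2)


class TestOccupancy:
    def _channel_system(self, k_on=0.3, k_off=0.2, n_frames=500, seed=21):
        spec = mg.ToyCarrierSpec(
            helix_length=12, n_frames=n_frames, seed=seed, noise_sigma=0.1,
            channels=[mg.ChannelSpec(res_a=3, res_b=27, k_on=k_on, k_off=k_off)])
        s, hm, _ = mg.build_toy_carrier(spec)
        traj, truth = mg.simulate_trajectory(s, spec)
        return spec, s, hm, traj, truth

    def test_always_and_never_present(self):
        spec = mg.ToyCarrierSpec(
            helix_length=12, n_frames=50, seed=2,
            channels=[mg.ChannelSpec(res_a=3, res_b=27, k_on=1.0, k_off=0.0)])
        s, _, _ = mg.build_toy_carrier(spec)
        traj, _ = mg.simulate_trajectory(s, spec)
        isp = mg.InteractionSpec(kind="salt_bridge", sel_a="resid 3", sel_b="resid 27")
        pct, _ = mg.occupancy(traj, isp)
        assert pct == 100.0
        spec_off = mg.ToyCarrierSpec(
            helix_length=12, n_frames=50, seed=2,
            channels=[mg.ChannelSpec(res_a=3, res_b=27, k_on=0.0, k_off=1.0)])
        s2, _, _ = mg.build_toy_carrier(spec_off)
        traj2, _ = mg.simulate_trajectory(s2, spec_off)
        pct2, _ = mg.occupancy(traj2, isp)
        assert pct2 == 0.0

    def test_matches_ground_truth_exactly(self):
        _spec, _s, _hm, traj, truth = self._channel_system()
        isp = mg.InteractionSpec(kind="salt_bridge", sel_a="resid 3", sel_b="resid 27")
        pct, series = mg.occupancy(traj, isp, mg.FrameWindow(0, traj.n_frames))
        states = truth.channel_states["3:27"]
        assert np.array_equal(series.present, states)
        assert pct == pytest.approx(100.0 * states.mean(), abs=1e-12)

    def test_window_restriction(self):
        _spec, _s, _hm, traj, truth = self._channel_system()
        isp = mg.InteractionSpec(kind="salt_bridge", sel_a="resid 3", sel_b="resid 27")
        pct, _ = mg.occupancy(traj, isp, mg.FrameWindow(100, 500))
        states = truth.channel_states["3:27"][100:500]
        assert pct == pytest.approx(100.0 * states.mean(), abs=1e-12)

    def test_frame_permutation_invariance(self):
        _spec, s, _hm, traj, _truth = self._channel_system(n_frames=120)
        isp = mg.InteractionSpec(kind="salt_bridge", sel_a="resid 3", sel_b="resid 27")
        pct, _ = mg.occupancy(traj, isp)
        rng = np.random.default_rng(0)
        shuffled = mg.Trajectory(topology=s, coords=traj.coords[rng.permutation(120)])
        pct_shuffled, _ = mg.occupancy(shuffled, isp)
        assert pct_shuffled == pytest.approx(pct)

    def test_monotone_in_cutoff(self):
        _spec, _s, _hm, traj, _ = self._channel_system(n_frames=200)
        pcts = []
        for cutoff in (3.0, 4.0, 6.0, 9.0):
            isp = mg.InteractionSpec(kind="salt_bridge", sel_a="resid 3",
                                     sel_b="resid 27",
                                     cutoff_overrides={"distance": cutoff})
            pct, _ = mg.occupancy(traj, isp)
            pcts.append(pct)
        assert pcts == sorted(pcts)
        assert pcts[-1] == 100.0


class TestClassification:
    @pytest.mark.parametrize("res_i,res_j,expected", [
        (29, 32, INTRA),    # both on H1
        (134, 137, INTRA),  # both on H3
        (231, 234, INTRA),  # both on H5
        (29, 137, INTER),   # H1 x H3
        (134, 234, INTER),  # H3 x H5
        (231, 32, INTER),   # H5 x H1
        (104, 195, OTHER),  # C1 loop x H4
        (137, 71, OTHER),   # H3 x matrix loop
        (30, 151, OTHER),   # H1 x matrix loop
    ])
    def test_named_pairs(self, aac_helix_map, res_i, res_j, expected):
        assert mg.classify_interaction(res_i, res_j, aac_helix_map) == expected

    def test_symmetric(self, aac_helix_map):
        for a, b in ((29, 137), (29, 32), (104, 195)):
            assert (mg.classify_interaction(a, b, aac_helix_map)
                    == mg.classify_interaction(b, a, aac_helix_map))

    def test_uncovered_residue_without_default(self):
        hm = mg.HelixMap(segments={"H1": (1, 10)}, default_segment=None)
        with pytest.raises(ConfigError, match="not covered"):
            mg.classify_interaction(1, 50, hm)


class TestBuildNetwork:
    def _three_channel_system(self):
        spec = mg.ToyCarrierSpec(
            helix_length=12, n_frames=600, seed=31, noise_sigma=0.1,
            channels=[
                mg.ChannelSpec(res_a=3, res_b=27, k_on=0.3, k_off=0.2),
                mg.ChannelSpec(res_a=5, res_b=53, k_on=0.05, k_off=0.4),
                mg.ChannelSpec(res_a=30, res_b=54, k_on=0.01, k_off=0.9),
            ])
        s, hm, _ = mg.build_toy_carrier(spec)
        traj, truth = mg.simulate_trajectory(s, spec)
        cfg = mg.AnalysisConfig(
            helix_map=hm,
            interactions=[
                mg.InteractionSpec(kind="salt_bridge", sel_a=f"resid {c.res_a}",
                                   sel_b=f"resid {c.res_b}",
                                   label_a=str(c.res_a), label_b=str(c.res_b))
                for c in spec.channels
            ],
            frame_window=mg.FrameWindow(0, spec.n_frames),
        )
        return spec, traj, truth, cfg

    def test_rows_match_ground_truth(self):
        spec, traj, truth, cfg = self._three_channel_system()
        table = mg.build_network(traj, cfg)
        assert len(table) == 3
        for ch in spec.channels:
            row = table[(table.res_a == str(ch.res_a))].iloc[0]
            expected = 100.0 * truth.realized_fractions[ch.name]
            assert row.occupancy_pct == pytest.approx(round_half_away(expected, 1))
            assert row.below_floor == (expected < 5.0)

    def test_classification_in_table(self):
        _spec, traj, _truth, cfg = self._three_channel_system()
        table = mg.build_network(traj, cfg)
        # 3->27: H1 x H3 inter; 5->53: H1 x H5 inter; 30->54: H3 x H5 inter
        assert set(table["class"]) == {INTER}

    def test_auto_enumeration_single_pair(self):
        # one LYS/ASP pair 3.5 A apart, another ASP 40 A away
        r1 = mg.Residue(1, "LYS", "A", [mg.Atom(1, "CA", "C", np.zeros(3)),
                                        mg.Atom(2, "NZ", "N", np.zeros(3))])
        r2 = mg.Residue(2, "ASP", "A", [mg.Atom(3, "CA", "C", np.array([3.5, 0, 0])),
                                        mg.Atom(4, "OD1", "O", np.array([3.5, 0, 0]))])
        r3 = mg.Residue(3, "ASP", "A", [mg.Atom(5, "CA", "C", np.array([40.0, 0, 0])),
                                        mg.Atom(6, "OD1", "O", np.array([40.0, 0, 0]))])
        s = mg.Structure([r1, r2, r3])
        traj = mg.Trajectory(topology=s, coords=s.coords[None].repeat(4, axis=0))
        cfg = mg.AnalysisConfig(helix_map=mg.HelixMap(segments={"H1": (1, 3)}),
                                frame_window=mg.FrameWindow(0, 4))
        table = mg.build_network(traj, cfg, auto_enumerate=True, seed_distance=8.0)
        assert len(table) == 1
        assert (table.iloc[0].res_a, table.iloc[0].res_b) == ("1", "2")
        assert table.iloc[0].occupancy_pct == 100.0

    def test_no_candidates_error(self):
        _spec, traj, _truth, cfg = self._three_channel_system()
        cfg.interactions = []
        with pytest.raises(ConfigError, match="no interactions"):
            mg.build_network(traj, cfg)


class TestAttachmentScores:
    DOMAIN_MAP = {"H1": "D1", "H2": "D1", "H3": "D2", "H4": "D2", "H5": "D3", "H6": "D3"}

    def _helix_map(self):
        return mg.HelixMap(segments={f"H{k+1}": (k * 10 + 1, (k + 1) * 10)
                                     for k in range(6)})

    def _row(self, ra, rb, cls, pct):
        return {"res_a": str(ra), "res_b": str(rb), "resnum_a": ra, "resnum_b": rb,
                "type": "salt_bridge", "class": cls, "occupancy_pct": pct,
                "below_floor": pct < 5, "n_frames_window": 100}

    def test_empty_table(self):
        table = pd.DataFrame(columns=["res_a", "res_b", "resnum_a", "resnum_b",
                                      "type", "class", "occupancy_pct",
                                      "below_floor", "n_frames_window"])
        scores = mg.attachment_scores(table, self._helix_map(), self.DOMAIN_MAP)
        assert all(v == 0.0 for v in scores.values())
        assert set(scores) == {("D1", "D2"), ("D1", "D3"), ("D2", "D3")}

    def test_single_edge(self):
        # residue 25 on H3 (D2), residue 45 on H5 (D3), 89% occupancy
        table = pd.DataFrame([self._row(25, 45, INTER, 89.0)])
        scores = mg.attachment_scores(table, self._helix_map(), self.DOMAIN_MAP)
        assert scores[("D2", "D3")] == pytest.approx(89.0)
        assert scores[("D1", "D2")] == 0.0 and scores[("D1", "D3")] == 0.0

    def test_symmetric_network_equal_scores(self):
        rows = [self._row(5, 25, INTER, 70.0),   # D1-D2
                self._row(25, 45, INTER, 70.0),  # D2-D3
                self._row(45, 5, INTER, 70.0)]   # D3-D1
        scores = mg.attachment_scores(pd.DataFrame(rows), self._helix_map(), self.DOMAIN_MAP)
        assert len(set(scores.values())) == 1

    def test_intra_and_other_rows_ignored(self):
        rows = [self._row(5, 8, INTRA, 90.0),
                self._row(5, 65, OTHER, 90.0),
                self._row(5, 25, INTER, 40.0)]
        scores = mg.attachment_scores(pd.DataFrame(rows), self._helix_map(), self.DOMAIN_MAP)
        assert scores[("D1", "D2")] == pytest.approx(40.0)
        assert sum(scores.values()) == pytest.approx(40.0)


class TestCombineOccupancies:
    def _table(self, pcts, n=100):
        return pd.DataFrame([
            {"res_a": "a", "res_b": "b", "resnum_a": 1, "resnum_b": 2,
             "type": "salt_bridge", "class": INTER, "occupancy_pct": pcts[0],
             "below_floor": pcts[0] < 5, "n_frames_window": n},
            {"res_a": "c", "res_b": "d", "resnum_a": 3, "resnum_b": 4,
             "type": "salt_bridge", "class": INTER, "occupancy_pct": pcts[1],
             "below_floor": pcts[1] < 5, "n_frames_window": n},
        ])

    def test_mean_of_replicates(self):
        from mgatekit.interactions import combine_occupancies
        out = combine_occupancies([self._table([80.0, 10.0]),
                                   self._table([40.0, 30.0])], mode="mean")
        assert sorted(out["occupancy_pct"]) == [20.0, 60.0]

    def test_pooled_weights_by_frames(self):
        from mgatekit.interactions import combine_occupancies
        # 100 frames at 100% pooled with 300 frames at 0% -> 25%
        out = combine_occupancies([self._table([100.0, 0.0], n=100),
                                   self._table([0.0, 0.0], n=300)], mode="pool")
        assert out.set_index("res_a").loc["a", "occupancy_pct"] == pytest.approx(25.0)

    def test_mismatched_edges_rejected(self):
        from mgatekit.interactions import combine_occupancies
        other = self._table([50.0, 50.0])
        other.loc[0, "res_a"] = "zz"
        with pytest.raises(ConfigError, match="different edges"):
            combine_occupancies([self._table([10.0, 10.0]), other])


def test_network_graph_export():
    from mgatekit.interactions import network_graph
    hm = mg.HelixMap(segments={"H1": (1, 10), "H3": (21, 30)})
    table = pd.DataFrame([{
        "res_a": "E2", "res_b": "R25", "resnum_a": 2, "resnum_b": 25,
        "type": "salt_bridge", "class": INTER, "occupancy_pct": 78.0,
        "below_floor": False, "n_frames_window": 100}])
    g = network_graph(table, hm, {"H1": "D1", "H3": "D2"})
    assert g.nodes["E2"]["segment"] == "H1" and g.nodes["E2"]["domain"] == "D1"
    assert g.edges["E2", "R25"]["occupancy_pct"] == 78.0


def test_round_half_away():
    assert round_half_away(56.25, 1) == 56.3
    assert round_half_away(-56.25, 1) == -56.3
    assert round_half_away(17.5, 0) == 18.0
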