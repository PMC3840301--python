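"""Trajectory linking against brute-force and ground-truth oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sptpalm.simulate import SimConfig, simulate_motion, simulate_photophysics
from sptpalm.track import Trajectory, default_max_disp_nm, filter_trajectories, link_localizations


def table(rows):
    df = pd.DataFrame(rows, columns=["frame", "x_nm", "y_nm"])
    df["precision_nm"] = 10.0
    return df


def brute_force_link(locs, max_disp_nm):
    """Exhaustive frame-pair assignment oracle (same objective as the
    implementation: minimize sum of squared link costs with per-item
    opt-out cost max_disp^2; links beyond the gate forbidden)."""
    gate2 = max_disp_nm**2
    frames = sorted(locs["frame"].unique())
    locs = locs.sort_values(["frame", "x_nm", "y_nm"], kind="stable").reset_index()
    groups = {f: locs[locs["frame"] == f] for f in frames}
    trajs = []  # each: list of original row indices
    active = []  # (traj_idx, x, y, last_frame)
    for f in range(frames[0], frames[-1] + 1):
        g = groups.get(f)
        cand = [a for a in active if a[3] == f - 1]
        if g is None or len(g) == 0:
            active = []
            continue
        dets = list(g.itertuples())
        best = None
        na, nd = len(cand), len(dets)
        # enumerate all injective partial matchings
        for k in range(min(na, nd), -1, -1):
            for rows_sel in itertools.combinations(range(na), k):
                for cols_sel in itertools.permutations(range(nd), k):
                    cost = 0.0
                    ok = True
                    for r, c in zip(rows_sel, cols_sel):
                        d2 = (cand[r][1] - dets[c].x_nm) ** 2 + (cand[r][2] - dets[c].y_nm) ** 2
                        if d2 > gate2:
                            ok = False
                            break
                        cost += d2
                    if not ok:
                        continue
                    cost += gate2 * (na - k) + gate2 * (nd - k)
                    if best is None or cost < best[0] - 1e-9:
                        best = (cost, rows_sel, cols_sel)
        new_active = []
        matched_dets = set()
        if best is not None:
            for r, c in zip(best[1], best[2]):
                ti = cand[r][0]
                trajs[ti].append(dets[c].index)
                new_active.append((ti, dets[c].x_nm, dets[c].y_nm, f))
                matched_dets.add(c)
        for c, det in enumerate(dets):
            if c not in matched_dets:
                trajs.append([det.index])
                new_active.append((len(trajs) - 1, det.x_nm, det.y_nm, f))
        active = new_active
    return {frozenset(t) for t in trajs}


class TestLink:
    def test_single_emitter_one_trajectory(self):
        rows = [(f, 1000.0 + 5 * f, 2000.0) for f in range(10)]
        trajs = link_localizations(table(rows), max_disp_nm=500.0)
        assert len(trajs) == 1
        assert trajs[0].n_points == 10
        assert np.array_equal(trajs[0].frames, np.arange(10))

    def test_two_distant_emitters_no_swap(self):
        rows = [(f, 1000.0 + 10 * f, 1000.0) for f in range(8)]
        rows += [(f, 9000.0 - 10 * f, 9000.0) for f in range(8)]
        trajs = link_localizations(table(rows), max_disp_nm=500.0)
        assert len(trajs) == 2
        for t in trajs:
            assert np.ptp(t.x_nm) < 100  # each trajectory stays on its side

    def test_gate_breaks_trajectory(self):
        rows = [(0, 1000.0, 1000.0), (1, 1000.0 + 800.0, 1000.0)]
        trajs = link_localizations(table(rows), max_disp_nm=500.0)
        assert len(trajs) == 2

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        pos = rng.uniform(0, 3000, size=(3, 2))
        for f in range(5):
            for e in range(3):
                rows.append((f, pos[e, 0], pos[e, 1]))
            pos = pos + rng.normal(0, 120, size=(3, 2))
        locs = table(rows)
        got = link_localizations(locs, max_disp_nm=700.0)
        want = brute_force_link(locs, 700.0)
        locs_sorted = locs.sort_values(["frame", "x_nm", "y_nm"], kind="stable").reset_index()
        # compare as partitions of (frame, x, y) point sets
        key = {}
        for row in locs_sorted.itertuples():
            key[row.index] = (row.frame, row.x_nm, row.y_nm)
        got_sets = {frozenset((f, x, y) for f, x, y in zip(t.frames, t.x_nm, t.y_nm)) for t in got}
        want_sets = {frozenset(key[i] for i in s) for s in want}
        assert got_sets == want_sets

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_partition_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 40))
        locs = table(
            [(int(rng.integers(0, 8)), rng.uniform(0, 5000), rng.uniform(0, 5000)) for _ in range(n)]
        )
        trajs = link_localizations(locs, max_disp_nm=400.0)
        assert sum(t.n_points for t in trajs) == n
        pts = sorted((f, x, y) for t in trajs for f, x, y in zip(t.frames, t.x_nm, t.y_nm))
        want = sorted(zip(locs.frame, locs.x_nm, locs.y_nm))
        assert pts == want

    def test_row_order_invariance(self):
        rng = np.random.default_rng(9)
        rows = [(f, x, y) for f in range(6) for x, y in rng.uniform(0, 4000, size=(4, 2))]
        locs = table(rows)
        shuffled = locs.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = link_localizations(locs, 600.0)
        b = link_localizations(shuffled, 600.0)
        sets_a = {frozenset(zip(t.frames, t.x_nm)) for t in a}
        sets_b = {frozenset(zip(t.frames, t.x_nm)) for t in b}
        assert sets_a == sets_b

    def test_link_purity_on_sparse_ground_truth(self):
        # sparse noiseless detections of true tracks: >= 95% of linked steps
        # join localizations of the same emitter
        cfg = SimConfig(seed=31, n_frames=300, n_emitters=40,
                        conversion_rate_per_frame=0.004, bleach_rate_per_frame=0.05)
        tracks = simulate_photophysics(simulate_motion(cfg), cfg)
        rows, owner = [], []
        for i in range(tracks.n_emitters):
            for t in tracks.on_frames(i):
                rows.append((t, tracks.x_nm[i, t], tracks.y_nm[i, t]))
                owner.append(i)
        locs = table(rows)
        locs["owner"] = owner
        trajs = link_localizations(locs, default_max_disp_nm(), dt_s=cfg.frame_interval_s)
        lookup = {(f, x): o for f, x, o in zip(locs.frame, locs.x_nm, locs.owner)}
        good = bad = 0
        for t in trajs:
            owners = [lookup[(f, x)] for f, x in zip(t.frames, t.x_nm)]
            for a, b in zip(owners, owners[1:]):
                if a == b:
                    good += 1
                else:
                    bad += 1
        assert good / (good + bad) >= 0.95

    def test_invalid_gate(self):
        with pytest.raises(ValueError):
            link_localizations(table([(0, 1.0, 1.0)]), max_disp_nm=0.0)


class TestFilter:
    def _trajs(self, lengths):
        out = []
        for i, L in enumerate(lengths):
            out.append(
                Trajectory(i, np.arange(L), np.zeros(L), np.zeros(L), np.zeros(L))
            )
        return out

    def test_min_points_10(self):
        assert len(filter_trajectories(self._trajs([3, 5, 10, 12]), 10)) == 2

    def test_min_points_5(self):
        assert len(filter_trajectories(self._trajs([3, 5, 10, 12]), 5)) == 3

    def test_empty_input(self):
        assert filter_trajectories([], 10) == []

    def test_invalid_min_points(self):
        with pytest.raises(ValueError):
            filter_trajectories([], 1)


class TestTrajectoryType:
    def test_frames_must_increase(self):
        with pytest.raises(ValueError):
            Trajectory(0, [0, 0, 1], np.zeros(3), np.zeros(3), np.zeros(3))

    def test_step_count(self):
        t = Trajectory(0, [0, 1, 2], np.zeros(3), np.zeros(3), np.zeros(3))
        assert t.n_points == 3 and t.n_steps == 2
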