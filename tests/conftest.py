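import numpy as np
import pandas as pd


def brute_force_msd(x_um, y_um, dt, n_max):
    """Independent double-loop MSD oracle (naive sum over all (i, i+n) pairs)."""
    N = len(x_um)
    out = []
    for n in range(1, n_max + 1):
        acc = 0.0
        cnt = 0
        for i in range(N - n):
            acc += (x_um[i + n] - x_um[i]) ** 2 + (y_um[i + n] - y_um[i]) ** 2
            cnt += 1
        out.append(acc / cnt)
    return np.array(out)


def random_walk_table(rng, n_emitters, n_frames, step_nm, field_nm):
    """A toy localization table of independent random walks (no imaging)."""
    rows = []
    for e in range(n_emitters):
        x, y = rng.uniform(0, field_nm, 2)
        for f in range(n_frames):
            rows.append((f, x, y))
            x += rng.normal(0, step_nm)
            y += rng.normal(0, step_nm)
    return pd.DataFrame(rows, columns=["frame", "x_nm", "y_nm"])


def match_trajectory_to_emitter(traj, tracks, min_on_overlap=0.5):
    """Nearest ground-truth emitter for a fitted trajectory (test oracle).

    Candidate emitters must be 'on' for at least ``min_on_overlap`` of the
    trajectory's frames; returns (mean distance nm, emitter index) or None.
    """
    best = None
    for i in range(tracks.n_emitters):
        on = tracks.photostate[i] == 1
        sel = on[traj.frames]
        if sel.sum() < min_on_overlap * len(traj.frames):
            continue
        d = np.hypot(
            tracks.x_nm[i, traj.frames[sel]] - traj.x_nm[sel],
            tracks.y_nm[i, traj.frames[sel]] - traj.y_nm[sel],
        ).mean()
        if best is None or d < best[0]:
            best = (d, i)
    return best
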