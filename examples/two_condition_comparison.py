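"""Two-condition comparison of pooled diffusion distributions.

Simulates a control and a 'treated' acquisition in which only the free
population diffuses 1.5x faster (the trapped population is untouched), and
builds the condition-comparison table: median D (n = ...) per group and
condition with Kolmogorov-Smirnov significance stars against control.
"""

import numpy as np

import sptpalm as sp
from sptpalm.diffusion import compute_msd, fit_diffusion_coefficient
from sptpalm.simulate import simulate_trajectories
import pandas as pd


def population(d_free, d_trapped, n_free, n_trapped, seed, condition):
    rows = []
    free = simulate_trajectories(n_free, 30, d_free, 0.02, sigma_loc_nm=20.0, seed=seed)
    trapped = simulate_trajectories(n_trapped, 30, d_trapped, 0.02, sigma_loc_nm=20.0,
                                    confinement_radius_nm=52.5, seed=seed + 1)
    for label, trajs in (("free", free), ("trapped", trapped)):
        for t in trajs:
            fit = fit_diffusion_coefficient(compute_msd(t))
            rows.append((fit.D_um2s, np.nan, label, condition))
    return pd.DataFrame(rows, columns=["D_um2s", "area_per_step_px",
                                       "cluster_label", "condition"])


control = population(0.09, 0.04, 300, 160, seed=10, condition="control")
treated = population(0.09 * 1.5, 0.04, 300, 160, seed=20, condition="treated")

table = sp.condition_report({"control": control, "treated": treated}, "cluster_label")
print(table.to_string())
print()
print("Only the free population shifts: its distribution differs from control "
      "(stars), while the trapped population — whose apparent D is set by the "
      "confinement geometry, not the medium — does not.")
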