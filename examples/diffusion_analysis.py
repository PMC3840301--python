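"""Per-trajectory diffusion analysis and mask classification.

Computes MSD curves, fits D_{2-5} with the localization-noise intercept,
classifies trajectories as trapped/free (nanocluster mask) and
synaptic/extra-synaptic (synapse mask), and pools the per-group medians —
the core readout of a receptor-mobility experiment.
"""

import numpy as np

import sptpalm as sp
from sptpalm.diffusion import records_to_dataframe

cfg = sp.SimConfig(seed=4, photons_per_frame=800.0)
tracks, movie, _, cluster_mask, synapse_mask = sp.simulate_acquisition(cfg)
locs = sp.localize_movie(movie, sp.LocalizeParams())
trajs = sp.filter_trajectories(sp.link_localizations(locs, dt_s=cfg.frame_interval_s), 10)

records, curves = sp.analyze_trajectories(
    trajs, cfg.pixel_size_nm, synapse_mask=synapse_mask, cluster_mask=cluster_mask
)
df = records_to_dataframe(records)

for summary in sp.pool_and_summarize(df, "cluster_label"):
    print(f"{summary.group:8s}: n = {summary.n:3d} ({summary.fraction_pct:4.1f}%), "
          f"median D = {summary.median_D_um2s:.4f} "
          f"[{summary.q25_D_um2s:.4f}-{summary.q75_D_um2s:.4f}] um^2/s")
print("(trapped molecules explore only their ~105 nm domain, so their apparent "
      "D_2-5 is far below the free medium's)")

groups = {
    lab: [curves[t] for t in df.loc[df.cluster_label == lab, "trajectory_id"]]
    for lab in ("free", "trapped")
}
ens = sp.ensemble_msd(groups, n_lags=10)
for lab, tab in ens.items():
    msd5 = tab.loc[tab.lag_index == 5, "mean_msd_um2"].iloc[0]
    print(f"ensemble MSD({lab}) at lag 5 (0.1 s): {msd5 * 1e6:.0f} nm^2")
print("(the trapped curve saturates near R^2 = 2756 nm^2 — the plateau of "
      "diffusion confined to a 52.5 nm-radius disc)")

comparison = sp.ks_compare(
    df.loc[df.cluster_label == "free", "D_um2s"],
    df.loc[df.cluster_label == "trapped", "D_um2s"],
    labels=("free", "trapped"),
)
print(f"KS free vs trapped: statistic {comparison.statistic:.2f}, "
      f"p = {comparison.p_value:.2g} {comparison.stars}")
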