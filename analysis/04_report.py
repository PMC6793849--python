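"""Derived maps from a persisted sweep: correlations, boundaries, hemispheres.

Reads ``results/sweep.h5`` and produces, under ``results/report/``:

* heat maps of the order parameter, mean AM rate and mean TE rates;
* per-gridpoint Pearson correlations of AM rate with local network support
  (motif heuristic) and with the normalized self-loop weight, and of
  outgoing TE / conditional TE with source in-degree and collective TE with
  target in-degree;
* mean AM-rate and TE-rate profiles across the sigma boundary (offset 0 =
  critical index per gamma line);
* the inter-hemispheric TE summary (mean TE on cross-hemisphere causal
  edges; proportion of significant all-pairs TE that is inter-hemispheric).
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from gaindyn import SyntheticConnectomeSpec, generate_connectome
from gaindyn.analysis import (
    boundary_profile,
    correlate_per_gridpoint,
    interhemisphere_te_summary,
)
from gaindyn.connectome import connectome_stats, local_network_support, normalize_coupling
from gaindyn.io import load_results

RESULTS = Path(__file__).resolve().parents[1] / "results"
REPORT = RESULTS / "report"


def heatmap(ax, grid2d, sigma, gamma, title, cmap="viridis"):
    im = ax.imshow(
        grid2d.T, origin="lower", aspect="auto", cmap=cmap,
        extent=(sigma[0], sigma[-1], gamma[0], gamma[-1]),
    )
    ax.set_xlabel("gain sigma")
    ax.set_ylabel("excitability gamma")
    ax.set_title(title, fontsize=9)
    return im


def main(seed: int = 0) -> None:
    REPORT.mkdir(parents=True, exist_ok=True)
    grid, manifest = load_results(RESULTS / "sweep.h5")
    seed = manifest.seeds.get("master_seed", seed)
    c = generate_connectome(SyntheticConnectomeSpec.scaled_down(10, seed=seed))

    nc = normalize_coupling(c)
    psi = local_network_support(nc)
    stats = connectome_stats(c)
    in_deg = stats["in_degree"].astype(float)

    n = c.n_regions
    mean_te = np.nanmean(grid.te_rate, axis=2)
    mean_am = np.nanmean(grid.am_rate, axis=2)
    mean_cte = np.nanmean(grid.cond_te_rate, axis=2)
    mean_coll = np.nanmean(grid.coll_te_rate, axis=2)

    # per-source mean outgoing TE, per grid point
    src_te = np.full(grid.am_rate.shape, np.nan)
    src_cte = np.full(grid.am_rate.shape, np.nan)
    for j in range(n):
        out_edges = np.flatnonzero(grid.edges[:, 1] == j)
        if out_edges.size:
            src_te[:, :, j] = np.nanmean(grid.te_rate[:, :, out_edges], axis=2)
            src_cte[:, :, j] = np.nanmean(grid.cond_te_rate[:, :, out_edges], axis=2)

    corrs = {
        "am_vs_motif_support": correlate_per_gridpoint(grid.am_rate, psi),
        "am_vs_self_loop_share": correlate_per_gridpoint(grid.am_rate, nc.F_diag),
        "out_te_vs_source_in_degree": correlate_per_gridpoint(src_te, in_deg),
        "out_cond_te_vs_source_in_degree": correlate_per_gridpoint(src_cte, in_deg),
        "coll_te_vs_target_in_degree": correlate_per_gridpoint(grid.coll_te_rate, in_deg),
    }
    hemi = interhemisphere_te_summary(grid, c)

    fig, axes = plt.subplots(3, 3, figsize=(12, 10))
    sg, gg = grid.sigma_grid, grid.gamma_grid
    panels = [
        (grid.order_param, "order parameter R", "viridis"),
        (mean_am, "mean AM rate (bits/s)", "viridis"),
        (mean_te, "mean pairwise TE rate (bits/s)", "viridis"),
        (mean_cte, "mean conditional TE rate", "viridis"),
        (mean_coll, "mean collective TE rate", "viridis"),
        (corrs["am_vs_motif_support"], "corr(AM, motif support)", "bwr"),
        (corrs["am_vs_self_loop_share"], "corr(AM, self-loop share)", "bwr"),
        (hemi["mean_interhem_te"], "mean inter-hemispheric TE", "viridis"),
        (hemi["proportion_significant_interhem"], "prop. significant TE inter-hem", "viridis"),
    ]
    for ax, (data, title, cmap) in zip(axes.ravel(), panels):
        if cmap == "bwr":
            im = heatmap(ax, data, sg, gg, title, cmap)
            im.set_clim(-1, 1)
        else:
            im = heatmap(ax, data, sg, gg, title)
        fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(REPORT / "phase_maps.png", dpi=110)
    plt.close(fig)

    # boundary profiles along sigma
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, (vals, label) in zip(
        axes, [(mean_am, "mean AM rate"), (mean_te, "mean TE rate")]
    ):
        off, prof = boundary_profile(vals, grid.order_param, axis=0)
        ax.plot(off, prof, "o-")
        ax.axvline(0, color="k", ls=":")
        ax.set_xlabel("grid offset from sigma boundary")
        ax.set_ylabel(f"{label} (bits/s)")
        pd.DataFrame({"offset": off, label: prof}).to_csv(
            REPORT / f"boundary_profile_{label.split()[1]}.csv", index=False
        )
    fig.tight_layout()
    fig.savefig(REPORT / "boundary_profiles.png", dpi=110)
    plt.close(fig)

    rows = []
    for a, s in enumerate(sg):
        for b, g in enumerate(gg):
            rows.append({
                "sigma": s, "gamma": g,
                "order_param": grid.order_param[a, b],
                "mean_am_rate": mean_am[a, b],
                "mean_te_rate": mean_te[a, b],
                "mean_cond_te_rate": mean_cte[a, b],
                "mean_coll_te_rate": mean_coll[a, b],
                "mean_interhem_te": hemi["mean_interhem_te"][a, b],
                "prop_sig_interhem": hemi["proportion_significant_interhem"][a, b],
                **{k: v[a, b] for k, v in corrs.items()},
            })
    df = pd.DataFrame(rows)
    df.to_csv(REPORT / "gridpoint_summary.csv", index=False)

    # long-format per-edge/per-region table (grid point, source, target,
    # measure, value, p) for downstream use
    long_rows = []
    for a, s in enumerate(sg):
        for b, g in enumerate(gg):
            for e, (i, j) in enumerate(grid.edges):
                long_rows.append((s, g, j, i, "te_rate", grid.te_rate[a, b, e],
                                  grid.te_pvalue[a, b, e]))
                long_rows.append((s, g, j, i, "cond_te_rate",
                                  grid.cond_te_rate[a, b, e], np.nan))
            for i in range(n):
                long_rows.append((s, g, np.nan, i, "am_rate",
                                  grid.am_rate[a, b, i], np.nan))
                long_rows.append((s, g, np.nan, i, "coll_te_rate",
                                  grid.coll_te_rate[a, b, i], np.nan))
    pd.DataFrame(
        long_rows,
        columns=["sigma", "gamma", "source", "target", "measure", "value", "p"],
    ).to_csv(REPORT / "estimates_long.csv", index=False)

    sup = grid.order_param > np.nanmedian(grid.order_param)
    print("supercritical-half means (R above median):")
    print(
        f"  corr(AM, motif support)      = {np.nanmean(corrs['am_vs_motif_support'][sup]):.2f}"
    )
    print(
        f"  corr(outgoing TE, in-degree) = {np.nanmean(corrs['out_te_vs_source_in_degree'][sup]):.2f}"
    )
    print(
        f"  corr(coll TE, in-degree)     = {np.nanmean(corrs['coll_te_vs_target_in_degree'][sup]):.2f}"
    )
    print(
        f"  prop. significant inter-hem  = {np.nanmean(hemi['proportion_significant_interhem'][sup]):.2f}"
    )
    print(f"wrote report under {REPORT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
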