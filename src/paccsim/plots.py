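"""Optional matplotlib overviews of experiment output."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_ode(traj, path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(traj["t"], traj["x1"], color="tab:red", label="2N+")
    ax.plot(traj["t"], traj["x2"], color="tab:blue", label="PACC")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("population ($10^7$ cells)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_experiment(summary, outdir) -> None:
    """Population/trait spaghetti per engine, or extinction-vs-dose curves."""
    outdir = Path(outdir)
    if summary.spec.scenario == "dose_sweep":
        doses = summary.sweep_values
        fig, ax = plt.subplots(figsize=(7, 4))
        for eng, color in (("ET", "magenta"), ("SGM", "black")):
            ax.plot(doses, [summary.extinction_count[(d, eng)] for d in doses],
                    "o-", color=color, label=eng)
        ax.set_xlabel("drug dose m (day$^{-1}$)")
        ax.set_ylabel(f"extinctions (out of {summary.n_trials})")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(outdir / "sweep.png", dpi=150)
        plt.close(fig)
        return

    for key, trials in summary.trials.items():
        tag = key if isinstance(key, str) else f"{key[1]}_zeta{key[0]:g}"
        fig, (ax_pop, ax_v) = plt.subplots(2, 1, sharex=True, figsize=(7, 6))
        for tr in trials:
            ax_pop.plot(tr.times, tr.x1_series, color="tab:red", alpha=0.15)
            ax_pop.plot(tr.times, tr.x2_series, color="tab:blue", alpha=0.15)
            ax_v.plot(tr.times, tr.v_series, color="black", alpha=0.15)
        on = trials[0].m_series > 0
        if on.any():
            ax_pop.fill_between(trials[0].times, 0,
                                max(1.0, max(tr.x1_series.max() for tr in trials)),
                                where=on, color="gray", alpha=0.15, linewidth=0)
        ax_pop.set_ylabel("population ($10^7$ cells)")
        ax_v.set_ylabel("resistance trait v")
        ax_v.set_xlabel("time (days)")
        fig.tight_layout()
        fig.savefig(outdir / f"trajectories_{tag}.png", dpi=150)
        plt.close(fig)
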