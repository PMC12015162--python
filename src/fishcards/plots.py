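"""Marginal-means and diagnostic figures for the objective reports."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402


def plot_report(report, path) -> None:
    """One figure per objective: marginal means plus random-effect Q-Q."""
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2))
    ax = axes[0]
    marg = report.marginal
    obj = report.objective
    if obj == 1:
        ax.errorbar(marg["phase"], marg["estimate"],
                    yerr=[marg["estimate"] - marg["ci_low"],
                          marg["ci_high"] - marg["estimate"]],
                    fmt="o-", capsize=4)
        ax.set_xticks([1, 2])
        ax.set_xlabel("Phase")
        ax.set_ylabel("IRT (s)")
        ax.set_title("Estimated marginal IRT")
    elif obj == 2:
        for group, sub in marg.groupby("age_group"):
            ax.errorbar(sub["phase"], sub["estimate"],
                        yerr=[sub["estimate"] - sub["ci_low"],
                              sub["ci_high"] - sub["estimate"]],
                        fmt="o-", capsize=4, label=group)
        ax.set_xticks([1, 2])
        ax.set_xlabel("Phase")
        ax.set_ylabel("P(radar)")
        ax.legend()
        ax.set_title("Radar-choice proportion")
    else:
        ax.plot(marg["bar_pct_at_choice"], marg["eta"], "-")
        ax.fill_between(marg["bar_pct_at_choice"],
                        marg["eta"] - 1.96 * marg["se_eta"],
                        marg["eta"] + 1.96 * marg["se_eta"], alpha=0.3)
        ax.set_xlabel("Resource level (%)")
        ax.set_ylabel("log-odds of radar")
        ax.set_title("Choice vs resource level")
    for ax2, name in zip(axes[1:], ("participant", "response_index")):
        qq = report.diagnostics[f"qq_{name}"]
        ax2.plot(qq["theoretical"], qq["sample"], ".", ms=3)
        lim = [qq["theoretical"].min(), qq["theoretical"].max()]
        ax2.plot(lim, lim, "k--", lw=0.8)
        ax2.set_title(f"Q-Q: {name} intercepts")
        ax2.set_xlabel("theoretical")
        ax2.set_ylabel("standardized")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
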