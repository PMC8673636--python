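"""Optional plots for sweep results.  Requires matplotlib."""

from __future__ import annotations

import pandas as pd


def plot_success_rates(table: pd.DataFrame, path: str) -> None:
    """Encoding success rate vs sample size, one line per coding space."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = table[table["metric"] == "success_rate"]
    fig, ax = plt.subplots(figsize=(6, 4))
    for n_space, group in data.groupby("N"):
        group = group.sort_values("k")
        ax.plot(group["k"], 100 * group["value"], marker="o", label=f"N = {n_space:,}")
    ax.set_xlabel("participants (k)")
    ax.set_ylabel("encoding success rate (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_anonymity(table: pd.DataFrame, path: str) -> None:
    """Log-log mean hits per slot vs coding space, with min/max whiskers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wide = table.pivot_table(index="N", columns="metric", values="value")
    fig, ax = plt.subplots(figsize=(6, 4))
    mean = wide["mean_hits"].to_numpy()
    low = mean - wide["min_hits"].to_numpy()
    high = wide["max_hits"].to_numpy() - mean
    ax.errorbar(wide.index.to_numpy(), mean, yerr=[low, high], fmt="o-", capsize=3)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("coding space N")
    ax.set_ylabel("phonebook hits per assigned ID")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
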