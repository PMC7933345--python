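"""Post-processing of simulation trajectories into suppression metrics.

All statistics are computed from the tidy trajectory table alone (the same
CSV the runner writes), so summaries can be recomputed offline without any
in-memory simulation state.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "time_to_extinction",
    "extinction_times",
    "extinction_probability",
    "median_time_to_extinction",
    "quantile_ribbon",
    "resistance_trajectory",
    "summarize",
    "suppression_lag_years",
    "plot_ribbon",
]


def time_to_extinction(
    trajectory: pd.DataFrame, generations_per_year: float = 2.0
) -> float | None:
    """First generation with census 0, in years; ``None`` if never extinct.

    Expects the trajectory of a single replicate.
    """
    zero = trajectory.loc[trajectory["census"] == 0, "generation"]
    if zero.empty:
        return None
    return float(zero.min()) / generations_per_year


def extinction_times(
    trajectory: pd.DataFrame, generations_per_year: float = 2.0
) -> pd.Series:
    """Per-replicate time to extinction in years (NaN when never extinct)."""
    def _one(df: pd.DataFrame) -> float:
        t = time_to_extinction(df, generations_per_year)
        return np.nan if t is None else t

    return trajectory.groupby("replicate", sort=True).apply(_one, include_groups=False)


def extinction_probability(trajectory: pd.DataFrame) -> float:
    """Fraction of replicates whose census reaches 0."""
    times = extinction_times(trajectory)
    return float(times.notna().mean())


def median_time_to_extinction(
    trajectory: pd.DataFrame, generations_per_year: float = 2.0
) -> float | None:
    """Median extinction time in years; never-extinct replicates count as
    infinite, so the median is ``None`` unless more than half go extinct."""
    times = extinction_times(trajectory, generations_per_year)
    med = float(np.median(times.fillna(np.inf)))
    return None if np.isinf(med) else med


def quantile_ribbon(trajectory: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Per-generation mean census and empirical central quantile band.

    With ``level=0.95`` the band spans the 2.5th to 97.5th percentile of
    census across replicates, matching the ribbons of the trajectory plots.
    """
    n_rep = trajectory["replicate"].nunique()
    if n_rep < 2:
        raise ValueError("quantile_ribbon needs at least 2 replicates")
    lo = 100.0 * (1.0 - level) / 2.0
    hi = 100.0 - lo
    g = trajectory.groupby("generation")["census"]
    out = pd.DataFrame(
        {
            "generation": sorted(trajectory["generation"].unique()),
            "mean": g.mean().values,
            "lower": g.quantile(lo / 100.0).values,
            "upper": g.quantile(hi / 100.0).values,
        }
    )
    return out


def resistance_trajectory(trajectory: pd.DataFrame) -> pd.DataFrame:
    """Per-generation frequency of functional-resistant carriers among
    living individuals, pooled across replicates (0 where census is 0)."""
    g = trajectory.groupby("generation")[["n_res_functional", "census"]].sum()
    freq = np.where(g["census"] > 0, g["n_res_functional"] / g["census"].clip(lower=1), 0.0)
    return pd.DataFrame({"generation": g.index.to_numpy(), "frequency": freq})


def summarize(
    trajectory: pd.DataFrame,
    generations_per_year: float = 2.0,
    equilibrium_window: int = 10,
) -> dict:
    """Headline suppression summary for one scenario.

    The equilibrium census is the mean census over the last
    ``equilibrium_window`` generations of replicates that never went
    extinct (NaN when all replicates go extinct).
    """
    times = extinction_times(trajectory, generations_per_year)
    finite = times.dropna()
    last_gen = trajectory["generation"].max()
    surviving = times[times.isna()].index
    if len(surviving):
        tail = trajectory[
            trajectory["replicate"].isin(surviving)
            & (trajectory["generation"] > last_gen - equilibrium_window)
        ]
        equilibrium = float(tail["census"].mean())
    else:
        equilibrium = float("nan")
    return {
        "extinction_probability": float(times.notna().mean()),
        "median_tte_years": float(finite.median()) if len(finite) else float("nan"),
        "tte_iqr_years": float(finite.quantile(0.75) - finite.quantile(0.25))
        if len(finite)
        else float("nan"),
        "equilibrium_census": equilibrium,
    }


def suppression_lag_years(
    trajectory_spatial: pd.DataFrame,
    trajectory_random: pd.DataFrame,
    generations_per_year: float = 2.0,
) -> float | None:
    """Difference of median extinction times, spatial minus random mating.

    Defined only when both paired scenarios reach a median extinction.
    """
    m_s = median_time_to_extinction(trajectory_spatial, generations_per_year)
    m_r = median_time_to_extinction(trajectory_random, generations_per_year)
    if m_s is None or m_r is None:
        return None
    return m_s - m_r


def plot_ribbon(trajectories: dict, path, level: float = 0.95, title: str | None = None):
    """Static census-ribbon plot (mean line + quantile band per scenario)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for label, traj in trajectories.items():
        rib = quantile_ribbon(traj, level)
        (line,) = ax.plot(rib["generation"], rib["mean"], label=label)
        ax.fill_between(
            rib["generation"], rib["lower"], rib["upper"], alpha=0.25, color=line.get_color()
        )
    ax.set_xlabel("generation")
    ax.set_ylabel("population size")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
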