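"""Ensemble statistics and reporting shapes for per-snapshot EDA results.

Box-whisker exports follow the convention used throughout this analysis:
the box spans the mean +/- one sample standard deviation with the center
mark at the mean, and whiskers extend to the minimum and maximum values
(not quartiles).  A numeric sidecar table always accompanies a rendered
plot so the encoding can be checked without touching pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class EnsembleSummary:
    component: str
    environment: str           # "bulk" | "interface"
    n: int
    mean: float
    sd: float                  # sample (n-1) standard deviation
    min: float
    max: float

    def __post_init__(self):
        if not (self.min <= self.mean <= self.max):
            raise ValueError("min <= mean <= max violated")
        if self.sd < 0:
            raise ValueError("SD must be non-negative")


def summarize(values: Sequence[float], component: str,
              environment: str) -> EnsembleSummary:
    """Sample statistics (n-1 denominator) of one component's ensemble."""
    v = np.asarray(list(values), float)
    if v.size == 0:
        raise ValueError("empty ensemble")
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return EnsembleSummary(component, environment, int(v.size),
                           float(v.mean()), sd, float(v.min()), float(v.max()))


def compare_environments(bulk: Sequence[EnsembleSummary],
                         interface: Sequence[EnsembleSummary]) -> pd.DataFrame:
    """Pair bulk and interfacial summaries by component.

    Adds the interface - bulk mean difference, the difference in units of
    the bulk SD, and a flag marking differences that exceed one bulk SD
    (the significance criterion used for the CT comparison).
    """
    b = {s.component: s for s in bulk}
    i = {s.component: s for s in interface}
    missing = sorted(set(b) ^ set(i))
    if missing:
        raise KeyError(f"unpaired components between environments: {missing}")
    rows = []
    for comp in b:
        sb, si = b[comp], i[comp]
        diff = si.mean - sb.mean
        in_sd = diff / sb.sd if sb.sd > 0 else np.inf * np.sign(diff) if diff else 0.0
        rows.append({
            "component": comp,
            "bulk_n": sb.n, "bulk_mean": sb.mean, "bulk_sd": sb.sd,
            "bulk_min": sb.min, "bulk_max": sb.max,
            "interface_n": si.n, "interface_mean": si.mean,
            "interface_sd": si.sd, "interface_min": si.min,
            "interface_max": si.max,
            "mean_difference": diff,
            "difference_in_bulk_sd": in_sd,
            "exceeds_one_bulk_sd": bool(abs(diff) >= sb.sd > 0),
        })
    return pd.DataFrame(rows)


def summaries_table(summaries: Sequence[EnsembleSummary]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries])


def boxwhisker_export(summaries: Sequence[EnsembleSummary], path,
                      sidecar_path=None, order: Sequence[str] | None = None):
    """Write a box-whisker figure plus its numeric sidecar CSV.

    Box = mean +/- 1 SD, center line = mean, whiskers = min/max; bulk and
    interfacial boxes sit side by side per component, in the given order.
    Returns the sidecar DataFrame.
    """
    if not summaries:
        raise ValueError("no summaries to plot")
    df = summaries_table(summaries)
    df["box_lo"] = df["mean"] - df["sd"]
    df["box_hi"] = df["mean"] + df["sd"]
    if order is not None:
        df["component"] = pd.Categorical(df["component"], categories=list(order),
                                         ordered=True)
        df = df.sort_values("component", kind="stable").reset_index(drop=True)
    if sidecar_path is None:
        sidecar_path = str(path) + ".csv"
    df.to_csv(sidecar_path, index=False)

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    comps = list(dict.fromkeys(df["component"]))
    envs = ["bulk", "interface"]
    colors = {"bulk": "#4878b0", "interface": "#d65f5f"}
    fig, ax = plt.subplots(figsize=(1.2 + 0.9 * len(comps), 4.0))
    for ci, comp in enumerate(comps):
        for ei, env in enumerate(envs):
            row = df[(df["component"] == comp) & (df["environment"] == env)]
            if row.empty:
                continue
            r = row.iloc[0]
            x = ci + (ei - 0.5) * 0.35
            ax.add_patch(plt.Rectangle((x - 0.12, r["box_lo"]), 0.24,
                                       r["box_hi"] - r["box_lo"],
                                       facecolor=colors[env], alpha=0.6,
                                       edgecolor="black"))
            ax.plot([x - 0.12, x + 0.12], [r["mean"], r["mean"]], color="black")
            ax.plot([x, x], [r["min"], r["box_lo"]], color="black", lw=0.8)
            ax.plot([x, x], [r["box_hi"], r["max"]], color="black", lw=0.8)
            ax.plot([x - 0.06, x + 0.06], [r["min"], r["min"]], color="black", lw=0.8)
            ax.plot([x - 0.06, x + 0.06], [r["max"], r["max"]], color="black", lw=0.8)
    ax.set_xticks(range(len(comps)))
    ax.set_xticklabels(comps, rotation=45, ha="right")
    ax.set_ylabel("energy (kcal/mol)")
    ax.set_xlim(-0.7, len(comps) - 0.3)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return df
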