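"""Figures and summary tables from sweep results.

Renders the 2×2 poresize×affinity panel plots for each observable,
injection-time contour maps (cubic interpolation across the three injection
days), and the c_h-vs-(δ_max, λ) maps with log₁₀-scaled concentration.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402
from scipy.interpolate import griddata  # noqa: E402

OBSERVABLES = {
    "V": "relative tumour volume V",
    "ifv": "averaged IFV (m/s)",
    "ifp": "averaged IFP (Pa)",
    "thp": "averaged THP (Pa)",
    "delta_max_norm": "normalised δ_max",
    "convexity": "convexity index λ",
    "fpv": "fraction of perfused vessels",
}


def _cells(table: pd.DataFrame):
    pores = sorted(table["pore_radius"].unique())
    kons = sorted(table["k_on"].unique())
    return pores, kons


def panel_plot(table: pd.DataFrame, observable: str, out_dir) -> Path:
    """2×2 (poresize × affinity) panel of time series, one line per
    injection day plus the control."""
    pores, kons = _cells(table)
    fig, axes = plt.subplots(len(pores), len(kons), squeeze=False,
                             figsize=(4.2 * len(kons), 3.2 * len(pores)),
                             sharex=True)
    for i, rp in enumerate(pores):
        for j, kon in enumerate(kons):
            ax = axes[i][j]
            cell = table[(table.pore_radius == rp) & (table.k_on == kon)]
            ctrl = table[(table.pore_radius == rp) & table.inject_day.isna()]
            if len(ctrl):
                ax.plot(ctrl.t_day, ctrl[observable], "k-", label="control")
            for day, grp in cell.dropna(subset=["inject_day"]).groupby(
                    "inject_day"):
                ax.plot(grp.t_day, grp[observable], label=f"D{day:g}")
            if not len(cell) and not len(ctrl):
                ax.text(0.5, 0.5, "missing", transform=ax.transAxes,
                        ha="center")
                warnings.warn(f"missing sweep cell rp={rp} kon={kon}")
            ax.set_title(f"r_p={rp * 1e9:g} nm, k_on={kon:g} 1/s", fontsize=9)
            if i == len(pores) - 1:
                ax.set_xlabel("time (days)")
            if j == 0:
                ax.set_ylabel(OBSERVABLES.get(observable, observable))
    axes[0][0].legend(fontsize=7)
    out = Path(out_dir) / f"panel_{observable}.png"
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out


def injection_contour(table: pd.DataFrame, observable: str, out_dir) -> Path:
    """Contours of an observable vs (time, injection day), cubic-interpolated
    across the injection-day columns for each poresize×affinity cell."""
    pores, kons = _cells(table)
    fig, axes = plt.subplots(len(pores), len(kons), squeeze=False,
                             figsize=(4.2 * len(kons), 3.2 * len(pores)))
    for i, rp in enumerate(pores):
        for j, kon in enumerate(kons):
            ax = axes[i][j]
            cell = table[(table.pore_radius == rp) & (table.k_on == kon)
                         ].dropna(subset=["inject_day"])
            if not len(cell):
                ax.text(0.5, 0.5, "missing", transform=ax.transAxes,
                        ha="center")
                continue
            pts = cell[["t_day", "inject_day"]].to_numpy()
            vals = cell[observable].to_numpy()
            tt, jj = np.meshgrid(
                np.linspace(cell.t_day.min(), cell.t_day.max(), 60),
                np.linspace(cell.inject_day.min(), cell.inject_day.max(), 40))
            grid = griddata(pts, vals, (tt, jj), method="cubic")
            cs = ax.contourf(tt, jj, grid, levels=16)
            fig.colorbar(cs, ax=ax, shrink=0.85)
            ax.set_title(f"r_p={rp * 1e9:g} nm, k_on={kon:g} 1/s", fontsize=9)
            ax.set_xlabel("time (days)")
            ax.set_ylabel("injection day")
    out = Path(out_dir) / f"contour_{observable}.png"
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out


def delivery_map(table: pd.DataFrame, out_dir) -> Path:
    """log₁₀ c_h as a function of (δ_max, λ) per poresize×affinity cell."""
    pores, kons = _cells(table)
    fig, axes = plt.subplots(len(pores), len(kons), squeeze=False,
                             figsize=(4.2 * len(kons), 3.2 * len(pores)))
    for i, rp in enumerate(pores):
        for j, kon in enumerate(kons):
            ax = axes[i][j]
            cell = table[(table.pore_radius == rp) & (table.k_on == kon)
                         ].dropna(subset=["inject_day"])
            cell = cell[cell.ch_int > 0]
            if len(cell) < 4:
                ax.text(0.5, 0.5, "insufficient data",
                        transform=ax.transAxes, ha="center")
                continue
            sc = ax.tricontourf(cell.delta_max_norm, cell.convexity,
                                np.log10(cell.ch_int), levels=14)
            fig.colorbar(sc, ax=ax, shrink=0.85)
            ax.set_title(f"r_p={rp * 1e9:g} nm, k_on={kon:g} 1/s", fontsize=9)
            ax.set_xlabel("normalised δ_max")
            ax.set_ylabel("λ")
    out = Path(out_dir) / "delivery_map_ch.png"
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out


def growth_rate_table(table: pd.DataFrame, windows=((10, 15), (20, 25),
                                                    (30, 35))) -> pd.DataFrame:
    """Tumour volume rates (mm³/day) over 5-day windows per run."""
    rows = []
    for run, grp in table.groupby("run"):
        entry = {"run": run,
                 "pore_radius": grp.pore_radius.iloc[0],
                 "k_on": grp.k_on.iloc[0],
                 "inject_day": grp.inject_day.iloc[0]}
        for lo, hi in windows:
            v0 = np.interp(lo, grp.t_day, grp.volume_mm3)
            v1 = np.interp(hi, grp.t_day, grp.volume_mm3)
            entry[f"rate_d{lo}_d{hi}"] = (v1 - v0) / (hi - lo)
        rows.append(entry)
    return pd.DataFrame(rows)


def render_report(table: pd.DataFrame, out_dir) -> dict:
    """All figures + the growth-rate table; returns the artefact paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arts = {}
    for obs in OBSERVABLES:
        arts[f"panel_{obs}"] = panel_plot(table, obs, out_dir)
    for obs in ("delta_max_norm", "convexity", "ch_int"):
        if table.inject_day.notna().sum():
            arts[f"contour_{obs}"] = injection_contour(table, obs, out_dir)
    arts["delivery_map"] = delivery_map(table, out_dir)
    rates = growth_rate_table(table)
    rates.to_csv(out_dir / "growth_rates.csv", index=False)
    arts["growth_rates"] = out_dir / "growth_rates.csv"
    return arts
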