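"""Matplotlib views of the standard diagnostics (optional dependency)."""

from __future__ import annotations

import numpy as np

from .analysis import GeometryDistributions, RDFResult
from .constants import SEED_ANGLE_DEG, SEED_R_OH
from .kriging import SCurve

__all__ = ["plot_s_curve", "plot_rdf", "plot_geometry_distributions", "plot_bond_scan"]


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_s_curve(curves: dict[str, SCurve], xlabel: str = "absolute error", ax=None):
    """Cumulative-error (S-)curves, one line per labelled model."""
    ax = _axes(ax)
    for label, sc in curves.items():
        ax.semilogx(np.maximum(sc.errors, 1e-12), sc.cumulative_percent, label=label)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("cumulative % of validation configurations")
    ax.set_ylim(0, 100)
    ax.legend()
    return ax


def plot_rdf(results: list[RDFResult], ax=None):
    ax = _axes(ax)
    for res in results:
        ax.plot(res.bin_centers, res.g, label=f"g_{res.pair_type}(r)")
    ax.set_xlabel("r / A")
    ax.set_ylabel("g(r)")
    ax.legend()
    return ax


def plot_geometry_distributions(dist: GeometryDistributions, axes=None):
    """Bond-length and angle populations with the equilibrium values marked."""
    if axes is None:
        import matplotlib.pyplot as plt

        _, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    ab, aa = axes
    ab.plot(dist.bond_centers, dist.bond_density)
    ab.axvline(SEED_R_OH, ls="--", color="k", lw=0.8)
    ab.set_xlabel("r(O-H) / A")
    ab.set_ylabel("population density")
    aa.plot(dist.angle_centers_deg, dist.angle_density)
    aa.axvline(SEED_ANGLE_DEG, ls="--", color="k", lw=0.8)
    aa.set_xlabel("H-O-H angle / deg")
    return axes


def plot_bond_scan(scan, axes=None):
    """Model vs oracle along the single-bond stretch (energy and O charge)."""
    if axes is None:
        import matplotlib.pyplot as plt

        _, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    ae, aq = axes
    for ang, group in scan.groupby("theta_deg"):
        ae.plot(group.r_oh, group.e_ref, lw=0.8, label=f"oracle, {ang} deg")
        ae.plot(group.r_oh, group.e_pred, ls="--", label=f"model, {ang} deg")
        aq.plot(group.r_oh, group.q_o_ref, lw=0.8)
        aq.plot(group.r_oh, group.q_o_pred, ls="--")
    ae.set_xlabel("r(O-H) / A")
    ae.set_ylabel("energy / kJ mol$^{-1}$")
    ae.legend(fontsize=7)
    aq.set_xlabel("r(O-H) / A")
    aq.set_ylabel("q(O) / e")
    return axes
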