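"""Diagnostic figures for fitted models: raw protocol data and fit quality."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .experiment import FL_PROTOCOLS, PD_PROTOCOLS, SubjectRecord
from .fitting import FourFiberModel, FourFiberResults

__all__ = ["plot_protocols", "plot_fit"]


def plot_protocols(record: SubjectRecord):
    """Pressure-diameter and force-length panels of one subject's raw record."""
    fig, (ax_pd, ax_fl) = plt.subplots(1, 2, figsize=(9, 3.6))
    for tag in PD_PROTOCOLS:
        pts = record.protocol_points(tag)
        if pts:
            ax_pd.plot(
                [p.outer_diameter_um for p in pts], [p.pressure_mmHg for p in pts],
                ".-", ms=3, label=tag,
            )
    ax_pd.set_xlabel("outer diameter [um]")
    ax_pd.set_ylabel("pressure [mmHg]")
    ax_pd.legend(fontsize=7)
    for tag in FL_PROTOCOLS:
        pts = record.protocol_points(tag)
        if pts:
            ax_fl.plot(
                [p.axial_length_mm for p in pts], [p.axial_force_g for p in pts],
                ".-", ms=3, label=tag,
            )
    ax_fl.set_xlabel("axial length [mm]")
    ax_fl.set_ylabel("axial force [g]")
    ax_fl.legend(fontsize=7)
    fig.suptitle(record.sample_id)
    fig.tight_layout()
    return fig


def plot_fit(model: FourFiberModel, results: FourFiberResults):
    """Model vs experimental wall stresses for both components."""
    from .fitting import _model_stresses

    st_m, sz_m = _model_stresses(results.params.as_vector(), model._u, model._v)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.6))
    for ax, exp, mod, label in (
        (axes[0], model._st_exp, st_m, "circumferential"),
        (axes[1], model._sz_exp, sz_m, "axial"),
    ):
        ax.plot(exp, mod, ".", ms=4)
        lim = [0, max(exp.max(), mod.max()) * 1.05]
        ax.plot(lim, lim, "k--", lw=0.8)
        ax.set_xlabel(f"experimental {label} stress [kPa]")
        ax.set_ylabel(f"model {label} stress [kPa]")
    fig.suptitle(f"RMSE = {results.rmse:.3f}")
    fig.tight_layout()
    return fig
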