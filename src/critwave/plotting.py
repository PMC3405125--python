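"""Diagnostic figures: space-time raster, attenuation profiles, range vs input."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["raster_plot", "attenuation_plot"]


def raster_plot(traj, spec, path) -> None:
    """Space-time raster of the central row (1D slice of the 2D array)."""
    row = spec.n // 2
    sl = traj.states[:, row * spec.n : (row + 1) * spec.n]
    fig, ax = plt.subplots(figsize=(7, 4))
    vmax = np.abs(sl).max() or 1.0
    ax.imshow(
        sl.T, aspect="auto", origin="lower", cmap="RdBu_r",
        vmin=-vmax, vmax=vmax,
        extent=[traj.times[0], traj.times[-1], 0, spec.n],
    )
    ax.set_xlabel("time (1/g)")
    ax.set_ylabel("column (central row)")
    ax.set_title("impulse response, central-row slice")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def attenuation_plot(table, profiles, path) -> None:
    """Left: log M(r) per eta; right: attenuation length vs input amplitude."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    for eta in sorted(profiles):
        prof = profiles[eta]
        pos = prof.M > 0
        ax1.semilogy(prof.radii[pos], prof.M[pos], label=f"$\\eta$={eta:g}")
    ax1.set_xlabel("distance r (lattice units)")
    ax1.set_ylabel("M(r)")
    ax1.legend(fontsize=8)
    ok = table[(table["error"] == "") & (table["eta"] > 0)]
    ax2.plot(ok["eta"], ok["lam"], "o-")
    ax2.set_xlabel("input amplitude $\\eta$")
    ax2.set_ylabel("attenuation length $\\lambda = 1/\\kappa$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
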