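"""Static 3-D rendering of gradient surfaces."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .thermal import GradientSurface  # noqa: E402


def plot_gradient(surface: GradientSurface, path) -> None:
    """Wireframe of rate vs depth position vs temperature, saved to file."""
    pivot = surface.pivot()
    temps = pivot.columns.to_numpy(dtype=float)
    positions = pivot.index.to_numpy(dtype=float)
    tt, pp = np.meshgrid(temps, positions)
    fig = plt.figure(figsize=(7, 5))
    ax = fig.add_subplot(projection="3d")
    ax.plot_wireframe(pp, tt, pivot.to_numpy(), color="tab:blue")
    ax.set_xlabel("attachment carbon n (depth)")
    ax.set_ylabel("temperature (degC)")
    mode = "out-of-plane" if surface.mode == "op" else "in-plane"
    ax.set_zlabel(f"{mode} rate (MHz)")
    ax.set_title(f"{surface.condition_id} — {mode}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
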