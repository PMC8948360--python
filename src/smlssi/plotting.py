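"""Single optional figure: render a precision map."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .crb import PrecisionMap

__all__ = ["plot_precision_map"]


def plot_precision_map(pmap: PrecisionMap, path: str | Path | None = None):
    """Draw a sigma_CRB map; optionally save to ``path``.

    Returns the matplotlib Figure.
    """
    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    extent = (pmap.x[0], pmap.x[-1], pmap.y[0], pmap.y[-1])
    im = ax.imshow(
        pmap.sigma_crb, origin="lower", extent=extent, cmap="viridis"
    )
    fp = pmap.fingerprint
    title = f"{fp.get('method', '?')}  c={fp.get('order', '?')}"
    ax.set(title=title, xlabel="x (nm)", ylabel="y (nm)")
    fig.colorbar(im, ax=ax, label=r"$\sigma_{CRB}$ (nm)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
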