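"""Optional matplotlib figures: cline curves and the ancestry triangle."""

from __future__ import annotations

import numpy as np

from .admixture import TriangleEstimate
from .cline import ClineData, ClineFit, cline_predict


def plot_cline(fit: ClineFit, data: ClineData, ax=None, color="k", label=None):
    """Fitted cline curve over the observed locality frequencies."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xs = np.linspace(data.x.min(), data.x.max(), 400)
    ax.plot(xs, cline_predict(fit.model, xs), color=color, label=label)
    ax.scatter(data.x, data.freq, s=10 + 2 * data.n, alpha=0.6, color=color)
    ax.set_xlabel("distance from isoline (km)")
    ax.set_ylabel("focal-allele frequency")
    return ax


def plot_triangle(estimates: list[TriangleEstimate], ax=None):
    """Interclass heterozygosity against ancestry, with the triangle
    boundary (parentals at the bottom corners, F1s at the apex)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot([0, 0.5, 1, 0], [0, 1, 0, 0], color="0.6", lw=1)
    ax.scatter([e.S for e in estimates], [e.H for e in estimates], alpha=0.6)
    ax.set_xlabel("ancestry S")
    ax.set_ylabel("interclass heterozygosity H")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.05)
    return ax
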