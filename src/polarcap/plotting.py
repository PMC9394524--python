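"""Optional matplotlib figures mirroring the standard readouts."""

from __future__ import annotations

import numpy as np

from .extrema import DistanceCDF
from .registration import AverageDistribution


def plot_average_distribution(avg: AverageDistribution, ax=None, label: str | None = None):
    """Mean fraction-of-protein vs signed distance from the polar cap, with
    the bootstrap confidence band shaded."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(avg.positions_um, avg.mean, label=label)
    ax.fill_between(avg.positions_um, avg.lower, avg.upper, alpha=0.3)
    ax.set_xlabel("distance from polar cap (µm)")
    ax.set_ylabel("fraction of protein")
    if label:
        ax.legend()
    return ax


def plot_distance_cdf(cdf: DistanceCDF, quantile_um: float | None = None, ax=None,
                      label: str | None = None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.step(np.concatenate([[0], cdf.distances_um]),
            np.concatenate([[0], cdf.fractions]), where="post", label=label)
    if quantile_um is not None:
        ax.axvline(quantile_um, linestyle="--", color="gray")
    ax.set_xlabel("distance from polar cap (µm)")
    ax.set_ylabel("cumulative fraction")
    if label:
        ax.legend()
    return ax
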