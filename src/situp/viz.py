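"""Basic dendrogram plotting (requires the 'plot' extra)."""

from __future__ import annotations

from .cluster import Linkage


def plot_dendrogram(linkage: Linkage, ax=None, **kwargs):
    """Draw the merge tree; returns the matplotlib axes.

    Heights follow the sqrt(2*dESS) convention, so the y-axis is in the
    feature units (mmHg/BPM mixtures) for singleton merges.
    """
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    dendrogram(linkage.to_scipy(), ax=ax, **kwargs)
    ax.set_ylabel("merge height")
    return ax
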