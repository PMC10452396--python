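"""Simple chart exports for run reports (requires matplotlib)."""

from __future__ import annotations

from .mvstats import AttributionReport, CCAResults


def plot_attribution(att: AttributionReport, ax=None):
    """Horizontal bar chart of per-variable percentage contributions."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    labels = list(att.x_side_percent.index) + list(att.y_side_percent.index)
    values = list(att.x_side_percent) + list(att.y_side_percent)
    colors = ["C0"] * len(att.x_side_percent) + ["C1"] * len(att.y_side_percent)
    ax.barh(labels[::-1], values[::-1], color=colors[::-1])
    ax.set_xlabel("contribution to canonical pair %d (%%)" % att.pair_used)
    ax.figure.tight_layout()
    return ax


def plot_canonical_pair(res: CCAResults, pair: int = 1, ax=None):
    """Scatter of the canonical variable pair (U_k vs V_k) with its R."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    k = pair - 1
    ax.scatter(res.x_scores[:, k], res.y_scores[:, k], s=12, alpha=0.6)
    ax.set_xlabel(f"canonical variable V{pair} (personal parameters)")
    ax.set_ylabel(f"canonical variable U{pair} (cognitive-load features)")
    ax.set_title(f"pair {pair}: R = {res.corr[k]:.3f}")
    ax.figure.tight_layout()
    return ax
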