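"""Basic scatter and Bland-Altman agreement plots."""

from __future__ import annotations

import numpy as np

from .metrics import bland_altman


def agreement_plots(pred, ref, label: str = "", ax_scatter=None, ax_ba=None):
    """Scatter (with identity line) and Bland-Altman plot side by side.

    Returns the (scatter, bland-altman) axes; creates a new figure when
    no axes are passed.
    """
    import matplotlib.pyplot as plt

    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if ax_scatter is None or ax_ba is None:
        _, (ax_scatter, ax_ba) = plt.subplots(1, 2, figsize=(9, 4))

    lims = [min(ref.min(), pred.min()), max(ref.max(), pred.max())]
    ax_scatter.scatter(ref, pred, s=8, alpha=0.5)
    ax_scatter.plot(lims, lims, "k-", lw=1)
    ax_scatter.set_xlabel("reference $E_{es}$ (mmHg/ml)")
    ax_scatter.set_ylabel("predicted $E_{es}$ (mmHg/ml)")
    ax_scatter.set_title(f"{label} scatter".strip())

    bias, lo, hi = bland_altman(pred, ref)
    mean_pair = 0.5 * (pred + ref)
    ax_ba.scatter(mean_pair, pred - ref, s=8, alpha=0.5)
    for yv, style in ((bias, "k-"), (lo, "k--"), (hi, "k--")):
        ax_ba.axhline(yv, ls=style[1:], color="k", lw=1)
    ax_ba.set_xlabel("mean of pair (mmHg/ml)")
    ax_ba.set_ylabel("predicted - reference (mmHg/ml)")
    ax_ba.set_title(f"{label} Bland-Altman".strip())
    return ax_scatter, ax_ba
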