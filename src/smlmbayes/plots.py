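"""Visual validity checking of the threshold fit."""

from __future__ import annotations

import numpy as np

from .threshold import ThresholdResult, get_model


def plot_threshold(result: ThresholdResult, ax=None, log_y: bool = False):
    """Plot the characteristic histogram, fitted densities and threshold.

    The false and true densities are scaled to expected counts per bin
    (total · P_i · f_i · bin width) so they overlay the raw histogram; the
    vertical line marks the selected threshold.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    hist = result.histogram
    model = get_model(result.model_name)
    x = hist.centers_gray
    ax.bar(hist.centers_raw, hist.counts, width=hist.width, color="#9ecae1",
           label="all potential emitters")
    # densities are per gray level, so expected counts per bin need no rescale
    nf = hist.total * result.p_false * np.exp(model.logpdf_false(x, result.theta_false))
    nt = hist.total * result.p_true * np.exp(model.logpdf_true(x, result.theta_true))
    ax.plot(hist.centers_raw, nf, "r-", label="false-emitter model")
    ax.plot(hist.centers_raw, nt, "g-", label="true-emitter model")
    ax.axvline(result.threshold, color="k", ls="--",
               label=f"threshold = {result.threshold:.1f}")
    ax.set_xlabel("selection characteristic")
    ax.set_ylabel("count")
    if log_y:
        ax.set_yscale("log")
    ax.legend(frameon=False)
    ax.set_title(f"minimum-error threshold ({result.model_name.upper()})")
    return ax
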