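"""Plot helpers for cumulative binding curves and calibration fits."""
from __future__ import annotations

import numpy as np
import pandas as pd


def plot_cumulative(curves: pd.DataFrame, ax=None):
    """Mean cumulative binding-event curves per probe with SD error bands.

    Expects the output of :func:`spiris.spotgrid.per_probe_curves`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for probe, grp in curves.groupby("probe_label"):
        t = grp["time_s"] / 60.0
        ax.plot(t, grp["value"], label=probe)
        ax.fill_between(t, grp["value"] - grp["sd"], grp["value"] + grp["sd"],
                        alpha=0.25)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("cumulative binding events")
    ax.legend()
    return ax


def plot_calibration(results, ax=None):
    """Double-log calibration points with free, theory and threshold lines.

    Accepts a :class:`spiris.quantify.KineticCalibrationResults`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    f = results.fit
    c = 10.0**f.log_c
    ax.loglog(c, 10.0**f.log_response, "o", label="measured rates")
    span = np.array([min(results.lod.lod, c.min()) / 3.0, c.max() * 3.0])
    ax.loglog(span, results.predict(span, "theory"), "-",
              label=f"theory slope {f.theoretical_slope:.2f}")
    ax.loglog(span, results.predict(span, "free"), "--",
              label=f"free slope {f.slope:.2f}")
    ax.axhline(results.threshold, color="k", lw=0.8, ls=":",
               label="blank mean + 3 SD")
    ax.axvline(results.lod.lod, color="r", lw=0.8, ls=":",
               label=f"LOD {results.lod.lod:.3g} M")
    ax.set_xlabel("concentration (M)")
    ax.set_ylabel("binding rate (events/h)")
    ax.legend(fontsize=8)
    return ax
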