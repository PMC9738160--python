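"""Static force–extension figures (matplotlib)."""

from __future__ import annotations

from typing import Optional


def plot_force_extension(results, normalized: bool = True, ax=None):
    """Per-force mean extensions with error bars and the fitted FJC overlay.

    Parameters
    ----------
    results : ElastomerResults
        A fitted model.
    normalized : bool
        Plot F vs L/L_max (True) or F vs L in Å (False).
    ax : matplotlib Axes, optional

    Returns the Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    curve = results.model.curve
    overlay = results.theoretical_overlay()
    if normalized:
        data = results.normalized_data()
        ax.errorbar(
            data["fraction"], data["force_pN"], xerr=data["sd_fraction"],
            fmt="o", ms=4, capsize=2, label=f"{curve.fragment.name} data",
        )
        ax.plot(
            overlay["fraction"], overlay["force_pN"], "-",
            label=f"FJC, a = {results.a_fit:.2f} Å",
        )
        ax.set_xlabel(r"$L/L_\mathrm{max}$")
    else:
        l_max = curve.fragment.l_max
        ax.errorbar(
            curve.mean_l, curve.forces, xerr=curve.sd_l,
            fmt="o", ms=4, capsize=2, label=f"{curve.fragment.name} data",
        )
        ax.plot(
            overlay["fraction"] * l_max, overlay["force_pN"], "-",
            label=f"FJC, a = {results.a_fit:.2f} Å",
        )
        ax.set_xlabel(r"$L$ (Å)")
    ax.set_ylabel("F (pN)")
    ax.legend()
    return ax


def plot_series(series, ylabel: str = "L (Å)", eq_start: Optional[int] = None, ax=None):
    """A scalar time series with an optional equilibration marker."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(series.frame_times, series.values, lw=0.8)
    if eq_start is not None:
        ax.axvline(series.frame_times[eq_start], color="tab:red", ls="--", label="equilibrated")
        ax.legend()
    ax.set_xlabel("time (ps)")
    ax.set_ylabel(ylabel)
    return ax
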