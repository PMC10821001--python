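"""Per-age median profile plots (DLP and per-method ED)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402


def plot_median_profiles(summaries: dict[str, "pandas.DataFrame"], path: str | Path) -> None:
    """Plot per-bin median profiles for several quantities.

    ``summaries`` maps a quantity label (e.g. ``"dlp"``, ``"ed_curve"``)
    to a summary frame with ``bin`` and ``median`` columns; DLP is drawn
    on its own axis because of its different scale.
    """
    dose_keys = [k for k in summaries if k != "dlp"]
    n_axes = (1 if "dlp" in summaries else 0) + (1 if dose_keys else 0)
    fig, axes = plt.subplots(1, max(n_axes, 1), figsize=(6 * max(n_axes, 1), 4))
    if n_axes <= 1:
        axes = [axes]
    ax_i = 0
    if "dlp" in summaries:
        frame = summaries["dlp"]
        axes[ax_i].plot(frame["bin"], frame["median"], marker="o")
        axes[ax_i].set_xlabel("age bin")
        axes[ax_i].set_ylabel("median DLP (mGy·cm)")
        ax_i += 1
    if dose_keys:
        for key in dose_keys:
            frame = summaries[key]
            axes[ax_i].plot(frame["bin"], frame["median"], marker="o", label=key)
        axes[ax_i].set_xlabel("age bin")
        axes[ax_i].set_ylabel("median ED (mSv)")
        axes[ax_i].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
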