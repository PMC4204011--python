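"""Optional plotting helpers (requires matplotlib)."""

from __future__ import annotations

from cpgkit.bisulfite import METHYLATED, UNMETHYLATED, MethylationMatrix
from cpgkit.composition import CompositionProfile


def lollipop(matrix: MethylationMatrix, ax=None):
    """Lollipop diagram: one row per clone, one circle per CpG site.

    Filled circles are methylated calls, open circles unmethylated;
    ambiguous calls are omitted. Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(
            figsize=(max(4, matrix.calls.shape[1] * 0.3), max(2, len(matrix.calls) * 0.25))
        )
    positions = list(matrix.calls.columns)
    for row, (clone_id, calls) in enumerate(matrix.calls.iterrows()):
        y = len(matrix.calls) - 1 - row
        ax.hlines(y, 0, len(positions) - 1, color="0.7", lw=0.8, zorder=1)
        for x, call in enumerate(calls):
            if call == METHYLATED:
                ax.scatter(x, y, s=60, facecolor="black", edgecolor="black", zorder=2)
            elif call == UNMETHYLATED:
                ax.scatter(x, y, s=60, facecolor="white", edgecolor="black", zorder=2)
    ax.set_xticks(range(len(positions)))
    ax.set_xticklabels(positions, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.calls)))
    ax.set_yticklabels(reversed(matrix.calls.index.tolist()), fontsize=7)
    ax.set_xlabel("CpG position")
    ax.set_ylabel("clone")
    return ax


def profile_tracks(profile: CompositionProfile, axes=None):
    """Two stacked tracks: %G+C (top) and CpGs per window (bottom)."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(2, 1, sharex=True, figsize=(8, 4))
    mids = [(r.start + r.end) / 2 for r in profile.records]
    axes[0].plot(mids, [r.gc_percent for r in profile.records], lw=1)
    axes[0].set_ylabel("% G+C")
    axes[1].plot(mids, [r.cpg_count for r in profile.records], lw=1, color="tab:red")
    axes[1].set_ylabel(f"CpGs / {profile.window_size} bp")
    axes[1].set_xlabel(f"position on {profile.seq_id} (bp)")
    return axes
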