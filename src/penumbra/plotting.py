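"""Matplotlib helpers (optional; imported lazily)."""

from __future__ import annotations

from typing import Sequence

from .metrics import normalize
from .projection import Profile


def plot_profiles(profiles: Sequence[Profile], labels: Sequence[str] | None = None, ax=None, normalized: bool = True):
    """Overlay profiles (peak-normalized by default, as in comparison plots)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    labels = labels if labels is not None else [f"profile {i}" for i in range(len(profiles))]
    for p, lab in zip(profiles, labels):
        q = normalize(p) if normalized else p
        ax.plot(q.positions, q.values, label=lab)
    ax.set_xlabel("r (mm)")
    ax.set_ylabel("relative intensity" if normalized else "intensity (a.u.)")
    ax.legend()
    return ax
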