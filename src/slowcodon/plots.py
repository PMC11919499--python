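"""Minimal plotting helpers for density and correlation profiles."""

from __future__ import annotations

import numpy as np

from .stats import CorrelationProfile
from .tasep import DensityProfile


def plot_density_profiles(profiles: dict[str, DensityProfile], ax=None,
                          reference: str | None = None):
    """Per-codon occupancy, one line per construct."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    for name, p in profiles.items():
        lw = 2.0 if name == reference else 1.0
        ax.plot(np.arange(1, p.length + 1), p.rho, label=name, lw=lw)
    ax.set_xlabel("codon position")
    ax.set_ylabel("ribosome density")
    ax.legend(fontsize=7)
    return ax


def plot_correlation_profile(corr: CorrelationProfile, ax=None,
                             sites_nt: dict[str, int] | None = None):
    """Per-codon Pearson r between density and stability; optional siRNA
    site markers (nucleotide positions)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    x = np.arange(1, len(corr.r) + 1)
    ax.plot(x, corr.r, lw=1.0)
    ax.axhline(0.0, color="grey", lw=0.5)
    if sites_nt:
        for name, nt in sites_nt.items():
            ax.axvline(-(-nt // 3), color="orange", ls="--", lw=0.8)
            ax.text(-(-nt // 3), 1.0, name, fontsize=7, rotation=90)
    ax.set_ylim(-1.05, 1.1)
    ax.set_xlabel("codon position")
    ax.set_ylabel("Pearson r")
    return ax
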