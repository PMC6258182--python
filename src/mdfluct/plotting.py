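"""Optional matplotlib views of profiles (headless-safe, text results first)."""

from __future__ import annotations

from pathlib import Path

__all__ = ["plot_significance", "plot_profile"]


def _axes():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_significance(profile, path) -> None:
    """log10 p-value of the symmetrized KS1 test along the backbone."""
    plt = _axes()
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(profile.residue_ids, profile.log10_pv, lw=1)
    ax.axhline(-1.301, color="grey", ls="--", lw=0.8)  # pv = 0.05
    ax.set_xlabel("residue")
    ax.set_ylabel(r"$\log_{10}(pv)$")
    ax.set_title(f"{profile.group} ({profile.mode})")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)


def plot_profile(profile, path) -> None:
    """One collapsed measure along the backbone."""
    plt = _axes()
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(profile.residue_ids, profile.values, lw=1)
    ax.set_xlabel("residue")
    ax.set_ylabel(profile.measure)
    ax.set_title(profile.group)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)
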