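"""Optional plotting helpers (Woods-style difference plots, residue strips).

Matplotlib is imported lazily; these figures are conveniences for
inspection and are not part of any computed result.
"""

from __future__ import annotations

import numpy as np

from .hdx_stats import DifferentialResult

__all__ = ["woods_plot", "residue_strip"]


def woods_plot(result: DifferentialResult, ax=None):
    """Per-peptide summed uptake difference vs sequence position.

    Each peptide is a horizontal segment from start to end at height
    ``sum_dD``; significant peptides are drawn solid, others faded; the
    stage-2 threshold band is shaded.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    pep = result.peptides
    for row in pep.itertuples(index=False):
        color = "tab:red" if row.sum_dD < 0 else "tab:blue"
        alpha = 0.9 if row.significant else 0.25
        ax.plot([row.start, row.end], [row.sum_dD] * 2, color=color, alpha=alpha, lw=2)
    if len(pep):
        thr = float(np.median(pep["test_value_2"]))
        ax.axhspan(-thr, thr, color="0.9", zorder=0)
    ax.axhline(0.0, color="0.5", lw=0.8)
    ax.set_xlabel("residue")
    ax.set_ylabel(r"$\Sigma\,\Delta D$ (Da)")
    return ax


def residue_strip(residue_map, ax=None, cmap="coolwarm_r"):
    """One-row heat strip of the residue-level difference map; residues
    with no covering peptide are hatched gray."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 1.2))
    values = residue_map["value"].to_numpy(float)
    vmax = np.nanmax(np.abs(values)) if np.isfinite(values).any() else 1.0
    ax.imshow(values[None, :], aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax,
              extent=(residue_map.index.min() - 0.5, residue_map.index.max() + 0.5,
                      0, 1))
    uncovered = residue_map.index[~residue_map["covered"]]
    for r in uncovered:
        ax.axvspan(r - 0.5, r + 0.5, color="0.7")
    ax.set_yticks([])
    ax.set_xlabel("residue")
    return ax
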