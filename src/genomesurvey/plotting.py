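"""Plot helpers: k-mer spectrum with fitted components, and trees."""

from __future__ import annotations

import numpy as np


def plot_spectrum(spectrum, fit=None, ax=None, max_depth=None):
    """Depth histogram with the fitted mixture overlaid (if given)."""
    import matplotlib.pyplot as plt
    from scipy import stats

    if ax is None:
        _fig, ax = plt.subplots(figsize=(7, 4))
    depths, counts = spectrum.as_arrays()
    ax.plot(depths[1:], counts[1:], lw=1.2, color="0.2", label="observed")
    if fit is not None:
        lam = fit.depth_refined
        wts = fit.fit_diagnostics.get("weights", {})
        comps = [("het", wts.get("het", 0.0), 0.5)]
        comps.append(("hom", wts.get("hom", 0.0), 1.0))
        for m, wr in enumerate(wts.get("repeats", []), start=2):
            comps.append((f"{m}x", wr, float(m)))
        total = np.zeros_like(depths, dtype=float)
        for _name, w, mult in comps:
            if w <= 0:
                continue
            total += w * stats.poisson.pmf(depths, mult * lam)
        ax.plot(depths[1:], total[1:], lw=1.0, ls="--", color="tab:red",
                label="mixture fit")
        ax.axvline(fit.peak_depth, color="tab:blue", lw=0.8, ls=":",
                   label=f"peak = {fit.peak_depth}x")
    if max_depth:
        ax.set_xlim(0, max_depth)
    ax.set_xlabel("k-mer depth")
    ax.set_ylabel("distinct k-mers")
    ax.legend(frameon=False)
    return ax


def plot_tree(tree, ax=None):
    """Draw a PhyloTree via Biopython's Phylo module."""
    from io import StringIO

    import matplotlib.pyplot as plt
    from Bio import Phylo

    if ax is None:
        _fig, ax = plt.subplots(figsize=(6, 4))
    bt = Phylo.read(StringIO(tree.to_newick()), "newick")
    Phylo.draw(bt, axes=ax, do_show=False)
    return ax
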