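"""Optional plots: DTT curves with null envelopes and traitgrams."""

from __future__ import annotations


from .dtt import DTTResults
from .niche_history import AncestralReconstruction
from .phylo import Phylogeny


def plot_dtt(results: DTTResults, ax=None):
    """Observed DTT curve over the BM null median and 5-95% envelope."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = results.observed.times
    ax.fill_between(
        t,
        results.null.quantile(0.05),
        results.null.quantile(0.95),
        alpha=0.2,
        color="grey",
        label="BM null 5-95%",
    )
    ax.plot(t, results.null.median, "--", color="grey", label="BM null median")
    ax.plot(t, results.observed.disparity, "-", color="black", label="observed")
    ax.set_xlabel("relative time")
    ax.set_ylabel("relative disparity")
    ax.set_title(
        f"{results.mdi_result.variable or 'trait'}  MDI={results.mdi:+.3f}"
    )
    ax.legend(frameon=False)
    return ax


def plot_traitgram(
    reconstruction: AncestralReconstruction, tree: Phylogeny, ax=None
):
    """Node means against node age, with branches connecting parent and
    child estimates (crossing branches indicate convergent evolution)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    means = {}
    for k, node in enumerate(reconstruction.node_ids):
        means[int(node)] = float(reconstruction.node_draws[:, k].mean())
    tip_means = reconstruction.tip_draws.mean(axis=0)
    for t in range(tree.n_tips):
        means[t] = float(tip_means[t])
    for i in range(tree.n_nodes):
        p = tree.parent[i]
        if p >= 0:
            ax.plot(
                [tree.heights[p], tree.heights[i]],
                [means[int(p)], means[int(i)]],
                color="steelblue",
                lw=1,
            )
    for t, label in enumerate(tree.tip_labels):
        ax.annotate(
            label, (tree.heights[t], means[t]), fontsize=7, va="center"
        )
    ax.set_xlabel("time since root (Myr)")
    ax.set_ylabel(reconstruction.variable)
    return ax
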