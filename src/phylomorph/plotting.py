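"""Minimal figures and network exports.

Aesthetics are deliberately plain: edges plus grey internal nodes for the
phylomorphospace, a line per clade for disparity-through-time, and a simple
node/edge network summarising which module pairs exceed the covariation and
integration cut-offs (CR >= 1.00 / rPLS >= 0.75 by default, both
configurable).
"""

from __future__ import annotations

import json
import math

import numpy as np

from .ordination import Phylomorphospace

__all__ = ["plot_phylomorphospace", "plot_dtt", "module_network_json",
           "module_network_svg"]


def plot_phylomorphospace(pm: Phylomorphospace, path, labels: bool = False) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for p, c in pm.edges:
        ax.plot([p[0], c[0]], [p[1], c[1]], color="0.6", lw=0.8, zorder=1)
    nodes = np.array(list(pm.node_scores.values()))
    if nodes.size:
        ax.scatter(nodes[:, 0], nodes[:, 1], s=12, color="0.5", zorder=2)
    ax.scatter(pm.tip_scores[:, 0], pm.tip_scores[:, 1], s=28, zorder=3)
    if labels:
        for t, xy in zip(pm.taxa, pm.tip_scores):
            ax.annotate(t, xy, fontsize=6)
    ax.set_xlabel(f"PC{pm.axes[0] + 1}")
    ax.set_ylabel(f"PC{pm.axes[1] + 1}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_dtt(profiles: dict, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, prof in profiles.items():
        ax.plot(prof.times, prof.disparity, label=label)
        for i, j, _ in prof.bursts:
            ax.axvspan(prof.times[i], prof.times[j], alpha=0.15, color="red")
    ax.set_xlabel("time from root")
    ax.set_ylabel("disparity (mean squared pairwise distance)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def module_network_json(pairwise_cr, pairwise_rpls, path=None,
                        cr_cutoff: float = 1.00, rpls_cutoff: float = 0.75) -> dict:
    """Node/edge summary of high covariation (CR) and high integration (rPLS)."""
    modules = list(pairwise_cr.columns)
    edges = []
    for i, a in enumerate(modules):
        for b in modules[i + 1:]:
            cr = float(pairwise_cr.loc[a, b])
            rp = float(pairwise_rpls.loc[a, b])
            edges.append({
                "source": a, "target": b, "cr": cr, "rpls": rp,
                "high_covariation": bool(cr >= cr_cutoff),
                "high_integration": bool(rp >= rpls_cutoff),
            })
    net = {"nodes": [{"id": m} for m in modules], "edges": edges,
           "cutoffs": {"cr": cr_cutoff, "rpls": rpls_cutoff}}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(net, fh, indent=1)
    return net


def module_network_svg(net: dict, path) -> None:
    """Tiny standalone SVG: modules on a circle, flagged pairs connected."""
    modules = [n["id"] for n in net["nodes"]]
    m = len(modules)
    cx, cy, r = 200, 200, 150
    coords = {mod: (cx + r * math.cos(2 * math.pi * i / m),
                    cy + r * math.sin(2 * math.pi * i / m))
              for i, mod in enumerate(modules)}
    parts = ['<svg xmlns="http://www.w3.org/2000/svg" width="400" height="400">']
    for e in net["edges"]:
        if not (e["high_covariation"] or e["high_integration"]):
            continue
        (x1, y1), (x2, y2) = coords[e["source"]], coords[e["target"]]
        color = "#d62728" if e["high_covariation"] else "#1f77b4"
        parts.append(f'<line x1="{x1:.0f}" y1="{y1:.0f}" x2="{x2:.0f}" '
                     f'y2="{y2:.0f}" stroke="{color}" stroke-width="2"/>')
    for mod, (x, y) in coords.items():
        parts.append(f'<circle cx="{x:.0f}" cy="{y:.0f}" r="18" fill="#ddd" '
                     'stroke="#333"/>')
        parts.append(f'<text x="{x:.0f}" y="{y + 32:.0f}" font-size="9" '
                     f'text-anchor="middle">{mod}</text>')
    parts.append("</svg>")
    with open(path, "w") as fh:
        fh.write("\n".join(parts))
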