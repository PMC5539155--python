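"""Figure rendering for the cohort distance matrix.

Writes the visual battery the analysis is read from: a raw heat map of the
pairwise W1 matrix, one binarized heat map per configured threshold, a 3-D
surface of the matrix, and histograms of within-group and between-group
distances. The histogram bin counts are additionally written as TSV so
downstream checks never need to parse images.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .cohort import DistanceMatrix, binarize_threshold

__all__ = ["render_views"]


def _ordered(d: DistanceMatrix, labels: dict[str, str] | None, order: str) -> DistanceMatrix:
    if order == "input" or not labels:
        return d
    if order != "group":
        raise ValueError(f"unknown heat-map ordering {order!r}")
    perm = sorted(range(d.n), key=lambda i: (labels[d.sample_ids[i]], d.sample_ids[i]))
    return DistanceMatrix(
        sample_ids=tuple(d.sample_ids[i] for i in perm), d=d.d[np.ix_(perm, perm)]
    )


def _heat(ax, matrix: np.ndarray, title: str, ids):
    im = ax.imshow(matrix, cmap="viridis", interpolation="nearest")
    ax.set_title(title)
    if len(ids) <= 50:
        ax.set_xticks(range(len(ids)), ids, rotation=90, fontsize=5)
        ax.set_yticks(range(len(ids)), ids, fontsize=5)
    return im


def _histogram(values: np.ndarray, title: str, png: Path, tsv: Path, bins: int = 20) -> None:
    counts, edges = np.histogram(values, bins=bins)
    pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    ).to_csv(tsv, sep="\t", index=False, float_format="%.17g")
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge", edgecolor="k")
    ax.set_title(title)
    ax.set_xlabel("W1 distance")
    ax.set_ylabel("pairs")
    fig.tight_layout()
    fig.savefig(png, dpi=120)
    plt.close(fig)


def render_views(
    d: DistanceMatrix,
    labels: dict[str, str] | None,
    out_dir: str | Path,
    thresholds: tuple[float, ...] = (0.075, 0.1),
    order: str = "input",
) -> list[Path]:
    """Render all figures and histogram tables; returns the written paths.

    Without labels, only the unlabeled views (raw and thresholded heat
    maps, 3-D surface) are produced — there is nothing to group.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dd = _ordered(d, labels, order)
    written: list[Path] = []

    fig, ax = plt.subplots(figsize=(6, 5))
    im = _heat(ax, dd.d, "Pairwise W1 distance", dd.sample_ids)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    p = out_dir / "heatmap_raw.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    for t in thresholds:
        fig, ax = plt.subplots(figsize=(6, 5))
        _heat(ax, binarize_threshold(dd, t), f"Thresholded at {t:g}", dd.sample_ids)
        fig.tight_layout()
        p = out_dir / f"heatmap_threshold_{t:g}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    xs, ys = np.meshgrid(range(dd.n), range(dd.n))
    ax.plot_surface(xs, ys, dd.d, cmap="viridis")
    ax.set_title("W1 distance surface")
    p = out_dir / "surface_3d.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    if labels:
        lab = np.array([labels[s] for s in dd.sample_ids])
        iu = np.triu_indices(dd.n, k=1)
        vals = dd.d[iu]
        same = lab[iu[0]] == lab[iu[1]]
        for g in sorted(set(lab)):
            mask = same & (lab[iu[0]] == g)
            if not mask.any():
                continue
            png = out_dir / f"hist_within_{g}.png"
            _histogram(vals[mask], f"Within {g}", png, out_dir / f"hist_within_{g}.tsv")
            written.append(png)
        if (~same).any():
            png = out_dir / "hist_between.png"
            _histogram(vals[~same], "Between groups", png, out_dir / "hist_between.tsv")
            written.append(png)
    return written
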