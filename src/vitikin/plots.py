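"""Figure helpers: IBD-sharing heatmaps and colour-score distributions."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .ibd import SharingMatrix  # noqa: E402


def sharing_heatmap(M: SharingMatrix, order: list[str], path: str, title: str = "") -> None:
    """Heatmap of per-pair shared base pairs in the given sample order."""
    idx = [M.sample_ids.index(s) for s in order]
    mat = M.total_bp[np.ix_(idx, idx)].astype(float)
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * len(order)),) * 2)
    im = ax.imshow(mat, cmap="coolwarm")
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=6)
    ax.set_yticks(range(len(order)), order, fontsize=6)
    fig.colorbar(im, ax=ax, label="shared bp")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def score_distribution(
    scores: pd.DataFrame,
    colors: pd.Series,
    focal: list[str],
    path: str,
    categories: tuple[str, ...] = ("white", "black"),
) -> None:
    """Histogram + density of panel polygenic scores with focal samples marked.

    ``scores`` is the output of :func:`vitikin.colorscore.polygenic_scores`;
    ``colors`` maps sample id -> colour category.
    """
    fig, ax = plt.subplots(figsize=(7, 4))
    s = scores.set_index("sample")["score"]
    palette = {"white": "#d9d9d9", "gray": "#969696", "rose": "#f4a6b8",
               "red": "#cb181d", "black": "#252525"}
    for cat in categories:
        ids = [i for i in s.index if colors.get(i) == cat and i not in focal]
        vals = s.loc[ids].dropna()
        if len(vals):
            ax.hist(vals, bins=25, alpha=0.6, density=True,
                    label=f"{cat} (n={len(vals)})", color=palette.get(cat))
    for f in focal:
        if f in s.index and not np.isnan(s.loc[f]):
            ax.axvline(s.loc[f], color="tab:blue", ls="--")
            ax.text(s.loc[f], ax.get_ylim()[1] * 0.95, f, rotation=90,
                    va="top", fontsize=8)
    ax.set_xlabel("polygenic colour score (grade units)")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
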