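"""Shared independent oracles for overlap scores and connected components."""

import numpy as np


def pixel_count_dice(x, y):
    """Dice by explicit pixel counting, independent of the metrics module."""
    inter = sum(1 for i in range(x.shape[0]) for j in range(x.shape[1]) if x[i, j] and y[i, j])
    total = int(x.sum()) + int(y.sum())
    return 1.0 if total == 0 else 2 * inter / total


def pixel_count_jaccard(x, y):
    inter = int((x & y).sum())
    union = int((x | y).sum())
    return 1.0 if union == 0 else inter / union


def flood_fill_components(mask, connectivity=8):
    """Exhaustive BFS flood fill; returns a list of pixel-coordinate sets."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 8:
        nbrs = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask)
    comps = []
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                comp, stack = set(), [(i, j)]
                seen[i, j] = True
                while stack:
                    ci, cj = stack.pop()
                    comp.add((ci, cj))
                    for di, dj in nbrs:
                        ni, nj = ci + di, cj + dj
                        if 0 <= ni < h and 0 <= nj < w and mask[ni, nj] and not seen[ni, nj]:
                            seen[ni, nj] = True
                            stack.append((ni, nj))
                comps.append(comp)
    return comps
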