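"""Independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

import numpy as np


def flood_fill_label(img: np.ndarray, connectivity: int) -> np.ndarray:
    """Label connected foreground components by explicit flood fill.

    Deliberately naive (stack-based depth-first fill, no library calls) so
    it is independent of the labeling routine it checks.
    """
    img = np.asarray(img, dtype=bool)
    h, w = img.shape
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    labels = np.zeros((h, w), dtype=int)
    nxt = 0
    for r in range(h):
        for c in range(w):
            if img[r, c] and labels[r, c] == 0:
                nxt += 1
                stack = [(r, c)]
                labels[r, c] = nxt
                while stack:
                    rr, cc = stack.pop()
                    for dr, dc in steps:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and img[nr, nc] and labels[nr, nc] == 0:
                            labels[nr, nc] = nxt
                            stack.append((nr, nc))
    return labels


def brute_median_filter(img: np.ndarray, kernel: int) -> np.ndarray:
    """Median filter by explicit window extraction with edge replication."""
    img = np.asarray(img)
    h, w = img.shape
    pad = kernel // 2
    padded = np.pad(img, pad, mode="edge")
    out = np.empty_like(img)
    for r in range(h):
        for c in range(w):
            out[r, c] = np.median(padded[r : r + kernel, c : c + kernel])
    return out


def reachable_from_border(img: np.ndarray) -> np.ndarray:
    """Background pixels reachable from the image border (4-connectivity).

    Flood fill over ~foreground; used to test that a closed edge ring
    encloses its interior.
    """
    free = ~np.asarray(img, dtype=bool)
    h, w = free.shape
    seen = np.zeros((h, w), dtype=bool)
    stack = [
        (r, c)
        for r in range(h)
        for c in range(w)
        if (r in (0, h - 1) or c in (0, w - 1)) and free[r, c]
    ]
    for r, c in stack:
        seen[r, c] = True
    while stack:
        rr, cc = stack.pop()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            nr, nc = rr + dr, cc + dc
            if 0 <= nr < h and 0 <= nc < w and free[nr, nc] and not seen[nr, nc]:
                seen[nr, nc] = True
                stack.append((nr, nc))
    return seen
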