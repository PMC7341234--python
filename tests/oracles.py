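"""Independent nested-loop reference implementations.

Deliberately naive pure-Python versions of the motion-mask, segmentation and
activity-index computations, used only to cross-check the vectorized
pipeline on tiny frames. They share no code with the package internals.
"""

from __future__ import annotations

import math


def loop_motion_mask(prev, curr, tau, mode="absolute"):
    """Per-pixel double loop over the inter-frame difference rule."""
    h = len(prev)
    w = len(prev[0])
    mask = [[0] * w for _ in range(h)]
    for y in range(h):
        for x in range(w):
            d = int(curr[y][x]) - int(prev[y][x])
            if mode == "onesided":
                hit = d > tau
            else:
                hit = abs(d) > tau
            mask[y][x] = 1 if hit else 0
    return mask


def loop_segment(frame, background, threshold, min_blob_area):
    """Threshold against background, then BFS 4-connected component filter."""
    h = len(frame)
    w = len(frame[0])
    raw = [
        [1 if abs(float(frame[y][x]) - float(background[y][x])) > threshold else 0 for x in range(w)]
        for y in range(h)
    ]
    if min_blob_area <= 1:
        return raw, sum(map(sum, raw))
    seen = [[False] * w for _ in range(h)]
    out = [[0] * w for _ in range(h)]
    for y in range(h):
        for x in range(w):
            if raw[y][x] and not seen[y][x]:
                queue = [(y, x)]
                seen[y][x] = True
                component = []
                while queue:
                    cy, cx = queue.pop()
                    component.append((cy, cx))
                    for ny, nx in ((cy - 1, cx), (cy + 1, cx), (cy, cx - 1), (cy, cx + 1)):
                        if 0 <= ny < h and 0 <= nx < w and raw[ny][nx] and not seen[ny][nx]:
                            seen[ny][nx] = True
                            queue.append((ny, nx))
                if len(component) >= min_blob_area:
                    for cy, cx in component:
                        out[cy][cx] = 1
    return out, sum(map(sum, out))


def loop_ai_series(frames, background, tau, min_blob_area, mode="absolute"):
    """Full per-pair activity-index series by explicit loops."""
    out = []
    for i in range(len(frames) - 1):
        _, s_prev = loop_segment(frames[i], background, tau, min_blob_area)
        mask = loop_motion_mask(frames[i], frames[i + 1], tau, mode)
        changed = sum(map(sum, mask))
        ai = changed / s_prev if s_prev > 0 else math.nan
        out.append((changed, s_prev, ai))
    return out
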