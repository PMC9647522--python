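"""Independent brute-force oracles used to pin down the fast implementations."""

import numpy as np


def max_project_loops(volume, z0, z1):
    """Triple-loop maximum projection."""
    Z, H, W = volume.shape
    out = np.full((H, W), -np.inf)
    for z in range(z0, z1):
        for i in range(H):
            for j in range(W):
                if volume[z, i, j] > out[i, j]:
                    out[i, j] = volume[z, i, j]
    return out


def flood_fill_filter(values, threshold, min_px):
    """Threshold then drop 8-connected components smaller than min_px (BFS)."""
    mask = values >= threshold
    H, W = mask.shape
    seen = np.zeros_like(mask)
    out = np.zeros_like(mask)
    for i in range(H):
        for j in range(W):
            if not mask[i, j] or seen[i, j]:
                continue
            stack, comp = [(i, j)], []
            seen[i, j] = True
            while stack:
                r, c = stack.pop()
                comp.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < H and 0 <= cc < W and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            if len(comp) >= min_px:
                for r, c in comp:
                    out[r, c] = True
    return out


def onset_scan(f, drug_frame, onset_drop, sustain, end):
    """Exhaustive scan of the depolarization-onset rule."""
    thr = 1.0 - onset_drop
    for k in range(drug_frame, end - sustain + 1):
        if all(f[j] < thr for j in range(k, k + sustain)):
            return k
    return None


def perm_scan(area, drug_frame, floor, sustain, start):
    """Exhaustive scan of the permeabilization (area-collapse) rule."""
    n = len(area)
    for k in range(max(drug_frame, start), n):
        window = area[k:k + sustain]
        if all(a < floor for a in window):
            return k
    return None


def anova_f(groups):
    """Textbook between/within one-way ANOVA F statistic."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = len(all_vals) - len(groups)
    return (ssb / dfb) / (ssw / dfw)
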