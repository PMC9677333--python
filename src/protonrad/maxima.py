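"""Prominence-based local-maxima detection for fluorescence images.

A local maximum is accepted when its topographic prominence reaches a
configured threshold: starting from a summit of height ``v``, every path
to strictly higher ground must first descend to ``v - prominence`` or
lower.  This is the "noise tolerance" semantics familiar from maxima
finders in interactive image-analysis tools, made fully explicit here:

* connectivity is 8-neighbour;
* comparisons are strict, so a connected plateau of equal values counts as
  a single summit and yields one representative point (the plateau
  centroid, rounded to the nearest pixel);
* a summit with no strictly higher ground anywhere (the global maximum) is
  always accepted; its prominence is reported as its height above the
  image minimum;
* a constant image has no maxima;
* output ordering is deterministic: descending value, then row-major.

Two implementations are provided.  :func:`find_maxima` runs a single
descending sweep with union-find bookkeeping (the classical persistence /
dynamics construction), compiled with numba so that full-slide images are
practical.  :func:`find_maxima_reference` is an exhaustive
flood-fill-per-candidate reference implementation, algorithmically
independent, kept for validation; the two agree exactly by construction of
the semantics above.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import ndimage

__all__ = ["find_maxima", "find_maxima_reference", "MAXIMA_DTYPE"]

MAXIMA_DTYPE = np.dtype(
    [("row", np.int64), ("col", np.int64), ("value", np.float64), ("prominence", np.float64)]
)

_NEIGHBORS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)


@njit(cache=True)
def _find_root(parent, i):
    root = i
    while parent[root] != root:
        root = parent[root]
    # path compression
    while parent[i] != root:
        nxt = parent[i]
        parent[i] = root
        i = nxt
    return root


@njit(cache=True)
def _peak_root(alias, k):
    root = k
    while alias[root] != root:
        root = alias[root]
    while alias[k] != root:
        nxt = alias[k]
        alias[k] = root
        k = nxt
    return root


@njit(cache=True)
def _sweep(flat, order, h, w, threshold):  # pragma: no cover - exercised via wrapper
    """Descending union-find sweep; returns accepted peaks (unordered)."""
    n = flat.size
    parent = np.full(n, -1, dtype=np.int64)  # -1: unprocessed
    comp_max = np.zeros(n, dtype=np.float64)  # peak value of comp, indexed by root
    comp_head = np.full(n, -1, dtype=np.int64)  # head of live-peak list per root
    comp_tail = np.full(n, -1, dtype=np.int64)

    # peak records
    peak_val = np.zeros(n, dtype=np.float64)
    peak_sr = np.zeros(n, dtype=np.float64)  # plateau row sum
    peak_sc = np.zeros(n, dtype=np.float64)
    peak_cnt = np.zeros(n, dtype=np.int64)
    peak_next = np.full(n, -1, dtype=np.int64)
    peak_alive = np.zeros(n, dtype=np.uint8)
    peak_alias = np.arange(n)  # fused-plateau redirection (union-find on peaks)
    n_peaks = 0
    plateau_of = np.full(n, -1, dtype=np.int64)  # pixel -> peak id of its summit plateau

    # accepted results
    acc_r = np.zeros(n, dtype=np.int64)
    acc_c = np.zeros(n, dtype=np.int64)
    acc_v = np.zeros(n, dtype=np.float64)
    acc_p = np.zeros(n, dtype=np.float64)
    n_acc = 0

    roots_buf = np.empty(8, dtype=np.int64)
    plat_buf = np.empty(8, dtype=np.int64)

    for k in range(n):
        p = order[k]
        v = flat[p]
        pr = p // w
        pc = p % w

        n_roots = 0
        n_plat = 0
        for d in range(8):
            if d == 0:
                nr, nc = pr - 1, pc - 1
            elif d == 1:
                nr, nc = pr - 1, pc
            elif d == 2:
                nr, nc = pr - 1, pc + 1
            elif d == 3:
                nr, nc = pr, pc - 1
            elif d == 4:
                nr, nc = pr, pc + 1
            elif d == 5:
                nr, nc = pr + 1, pc - 1
            elif d == 6:
                nr, nc = pr + 1, pc
            else:
                nr, nc = pr + 1, pc + 1
            if nr < 0 or nr >= h or nc < 0 or nc >= w:
                continue
            q = nr * w + nc
            if parent[q] < 0:
                continue  # not yet processed (strictly lower, or later tie)
            root = _find_root(parent, q)
            seen = False
            for j in range(n_roots):
                if roots_buf[j] == root:
                    seen = True
                    break
            if not seen:
                roots_buf[n_roots] = root
                n_roots += 1
            # plateau neighbour: same value, member of an alive summit plateau
            if flat[q] == v:
                pk = plateau_of[q]
                if pk >= 0:
                    pk = _peak_root(peak_alias, pk)
                if pk >= 0 and peak_alive[pk] == 1 and peak_val[pk] == v:
                    seen_p = False
                    for j in range(n_plat):
                        if plat_buf[j] == pk:
                            seen_p = True
                            break
                    if not seen_p:
                        plat_buf[n_plat] = pk
                        n_plat += 1

        if n_roots == 0:
            # birth of a new summit
            parent[p] = p
            comp_max[p] = v
            pk = n_peaks
            n_peaks += 1
            peak_val[pk] = v
            peak_sr[pk] = pr
            peak_sc[pk] = pc
            peak_cnt[pk] = 1
            peak_next[pk] = -1
            peak_alive[pk] = 1
            comp_head[p] = pk
            comp_tail[p] = pk
            plateau_of[p] = pk
            continue

        # merge all neighbouring components; p is the saddle pixel at level v
        root = roots_buf[0]
        for j in range(1, n_roots):
            other = roots_buf[j]
            # union by attaching 'other' under 'root' (attribute carrier: root)
            parent[other] = root
            if comp_max[other] > comp_max[root]:
                comp_max[root] = comp_max[other]
            # concatenate live-peak lists
            if comp_head[other] >= 0:
                if comp_head[root] < 0:
                    comp_head[root] = comp_head[other]
                    comp_tail[root] = comp_tail[other]
                else:
                    peak_next[comp_tail[root]] = comp_head[other]
                    comp_tail[root] = comp_tail[other]
        if n_roots > 1:
            # peaks now connected to strictly higher ground die at saddle v
            top = comp_max[root]
            prev = -1
            pk = comp_head[root]
            while pk >= 0:
                nxt = peak_next[pk]
                if peak_val[pk] < top:
                    prom = peak_val[pk] - v
                    if prom >= threshold:
                        rr = int(np.floor(peak_sr[pk] / peak_cnt[pk] + 0.5))
                        cc = int(np.floor(peak_sc[pk] / peak_cnt[pk] + 0.5))
                        acc_r[n_acc] = rr
                        acc_c[n_acc] = cc
                        acc_v[n_acc] = peak_val[pk]
                        acc_p[n_acc] = prom
                        n_acc += 1
                    peak_alive[pk] = 0
                    if prev < 0:
                        comp_head[root] = nxt
                    else:
                        peak_next[prev] = nxt
                    if nxt < 0:
                        comp_tail[root] = prev
                else:
                    prev = pk
                pk = nxt

        parent[p] = root
        if comp_max[root] == v:
            # p extends (and possibly fuses) summit plateaus at the top level
            if n_plat > 0:
                keep = plat_buf[0]
                for j in range(1, n_plat):
                    other_pk = plat_buf[j]
                    # same connected equal-value summit: fuse records
                    peak_sr[keep] += peak_sr[other_pk]
                    peak_sc[keep] += peak_sc[other_pk]
                    peak_cnt[keep] += peak_cnt[other_pk]
                    peak_alive[other_pk] = 0
                    peak_alias[other_pk] = keep
                    # unlink other_pk from the live list
                    prev = -1
                    pk = comp_head[root]
                    while pk >= 0:
                        nxt = peak_next[pk]
                        if pk == other_pk:
                            if prev < 0:
                                comp_head[root] = nxt
                            else:
                                peak_next[prev] = nxt
                            if nxt < 0:
                                comp_tail[root] = prev
                            break
                        prev = pk
                        pk = nxt
                peak_sr[keep] += pr
                peak_sc[keep] += pc
                peak_cnt[keep] += 1
                plateau_of[p] = keep

    # surviving peaks: summits with no strictly higher ground (global maxima)
    img_min = flat[order[n - 1]]
    for pk in range(n_peaks):
        if peak_alive[pk] == 1 and peak_cnt[pk] < n:
            rr = int(np.floor(peak_sr[pk] / peak_cnt[pk] + 0.5))
            cc = int(np.floor(peak_sc[pk] / peak_cnt[pk] + 0.5))
            acc_r[n_acc] = rr
            acc_c[n_acc] = cc
            acc_v[n_acc] = peak_val[pk]
            acc_p[n_acc] = peak_val[pk] - img_min
            n_acc += 1

    return acc_r[:n_acc], acc_c[:n_acc], acc_v[:n_acc], acc_p[:n_acc]


def _sorted_output(rows, cols, vals, proms, width) -> np.ndarray:
    out = np.empty(len(rows), dtype=MAXIMA_DTYPE)
    out["row"], out["col"], out["value"], out["prominence"] = rows, cols, vals, proms
    order = np.lexsort((out["row"] * width + out["col"], -out["value"]))
    return out[order]


def find_maxima(image: np.ndarray, prominence: float) -> np.ndarray:
    """Local maxima with topographic prominence >= ``prominence``.

    Returns a structured array with fields row, col, value, prominence,
    ordered by descending value then row-major position.  See the module
    docstring for the exact semantics.
    """
    if prominence <= 0:
        raise ValueError("prominence threshold must be positive")
    img = np.ascontiguousarray(np.asarray(image, dtype=np.float64))
    if img.ndim != 2:
        raise ValueError("image must be 2D")
    h, w = img.shape
    flat = img.ravel()
    # descending value, ties broken row-major (stable ordering)
    order = np.lexsort((np.arange(flat.size), -flat)).astype(np.int64)
    rows, cols, vals, proms = _sweep(flat, order, h, w, float(prominence))
    return _sorted_output(rows, cols, vals, proms, w)


def _plateaus(img: np.ndarray):
    """All connected equal-value plateaus (8-connectivity), as label arrays."""
    structure = np.ones((3, 3), dtype=bool)
    seen = np.zeros(img.shape, dtype=bool)
    for v in np.unique(img):
        mask = img == v
        labels, nlab = ndimage.label(mask, structure=structure)
        for lab in range(1, nlab + 1):
            region = labels == lab
            if not seen[region].any():
                yield v, region
                seen |= region


def find_maxima_reference(image: np.ndarray, prominence: float) -> np.ndarray:
    """Exhaustive reference implementation of :func:`find_maxima`.

    For each summit plateau it floods the strict superlevel set
    ``image > v - prominence`` and rejects the summit when strictly higher
    ground is reachable inside it; the prominence of accepted summits is
    found by scanning saddle levels.  O(n^2)-ish; for validation on small
    images only.
    """
    if prominence <= 0:
        raise ValueError("prominence threshold must be positive")
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    structure = np.ones((3, 3), dtype=bool)
    img_min = img.min()
    rows, cols, vals, proms = [], [], [], []
    padded = np.pad(img, 1, mode="constant", constant_values=-np.inf)
    for v, region in _plateaus(img):
        if region.all():
            continue  # constant image: no maxima
        # summit check: every pixel bordering the plateau is strictly lower
        dil = ndimage.binary_dilation(region, structure=structure)
        border = dil & ~region
        # pixels outside the image count as lower
        if np.any(padded[1:-1, 1:-1][border] >= v):
            continue
        # reachability of strictly higher ground within image > v - prominence
        mask = img > v - prominence
        labels, _ = ndimage.label(mask, structure=structure)
        lab = labels[region][0]
        reachable = labels == lab
        if np.any(img[reachable] > v):
            continue  # path to higher ground never descends far enough
        # prominence: highest saddle level that connects to higher ground
        higher_exists = np.any(img > v)
        if not higher_exists:
            prom = v - img_min
        else:
            prom = np.inf
            for u in np.unique(img[img < v])[::-1]:
                m = img >= u
                lb, _ = ndimage.label(m, structure=structure)
                if np.any(img[lb == lb[region][0]] > v):
                    prom = v - u
                    break
            if not np.isfinite(prom):
                prom = v - img_min
        rr, cc = np.nonzero(region)
        rows.append(int(np.floor(rr.mean() + 0.5)))
        cols.append(int(np.floor(cc.mean() + 0.5)))
        vals.append(v)
        proms.append(prom)
    return _sorted_output(
        np.array(rows, dtype=np.int64),
        np.array(cols, dtype=np.int64),
        np.array(vals, dtype=np.float64),
        np.array(proms, dtype=np.float64),
        w,
    )
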