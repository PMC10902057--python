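"""Divisive hierarchical clustering with rank-competing random walkers
(DHC-RC) over pixel lipid fingerprints.

The image is segmented top-down: starting from one segment holding every
retained pixel, the leaf with the lowest mean within-segment Pearson
correlation is repeatedly bipartitioned until the requested number of
segments exists.  A bipartition is produced by two competing walkers
seeded at a minimally correlated pixel pair; each step, the walker whose
candidate pixel has the highest mean correlation to its current region
claims that pixel ("rank compete").  Several restarts from alternative
low-correlation seed pairs are run and the bipartition maximizing

    mean within-group correlation - mean between-group correlation

is kept.  Segments at or below ``exact_max`` pixels are split by exact
enumeration of all bipartitions of the same objective, which is feasible
there and removes heuristic error on small segments.

Segment colours reproduce the published convention: the two segments
whose mean fingerprints correlate least sit at the two ends of a
continuous colour bar (values 0 and 1) and every other segment is placed
along it by its relative correlation distance to the two extremes, so
that proximity in colour means similarity of lipid fingerprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "WalkerConfig", "SegmentMap", "CannotSplitError", "UndefinedCorrelationError",
    "pixel_correlation", "split_objective", "split_segment", "dhc_rc_segment",
    "assign_colors", "resegment", "map_segments_to_regions",
]

EXCLUDED = -1


class CannotSplitError(ValueError):
    """Attempt to bipartition a segment with fewer than two pixels."""


class UndefinedCorrelationError(ValueError):
    """Correlation requested for a constant (zero-variance) fingerprint."""


@dataclass(frozen=True)
class WalkerConfig:
    """Walker mechanics and determinism knobs.

    ``restarts`` seed pairs are tried per split: the global
    minimum-correlation pair plus ``restarts - 1`` pairs drawn among the
    lowest ``bottom_frac`` of all pairwise correlations.  ``exact_max``
    is the segment size at or below which the split is solved by exact
    enumeration.  ``max_exact_pixels`` caps the segment size for which
    the full correlation Gram matrix is formed; larger segments use a
    subsample for seed-pair search (assignment itself is always exact).
    """

    n_walkers: int = 2
    restarts: int = 6
    exact_max: int = 12
    bottom_frac: float = 0.01
    max_exact_pixels: int = 20000
    seed: int = 0

    def __post_init__(self):
        if self.n_walkers < 2:
            raise ValueError("need at least two walkers for a split")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class SegmentMap:
    """Partition of the retained pixels with its divisive split history."""

    labels: np.ndarray              # (n_retained,) segment id, contiguous from 0
    coords: np.ndarray              # (n_retained, 2)
    shape: tuple[int, int]
    tree: list = field(default_factory=list)    # node dicts: id,parent,children,pixels
    colors: np.ndarray | None = None            # (n_segments,) in [0, 1]
    mean_fingerprints: np.ndarray | None = None

    @property
    def n_segments(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def segment_pixels(self, seg_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == seg_id)

    def raster(self, fill: int = EXCLUDED) -> np.ndarray:
        img = np.full(self.shape, fill, dtype=int)
        img[self.coords[:, 0], self.coords[:, 1]] = self.labels
        return img

    def color_raster(self, fill=np.nan) -> np.ndarray:
        img = np.full(self.shape, fill, dtype=float)
        img[self.coords[:, 0], self.coords[:, 1]] = self.colors[self.labels]
        return img


def _standardize(X: np.ndarray) -> np.ndarray:
    """Rows centred and scaled to unit norm, so z_i . z_j is the Pearson
    correlation of rows i and j."""
    X = np.asarray(X, float)
    mu = X.mean(axis=1, keepdims=True)
    Z = X - mu
    norms = np.linalg.norm(Z, axis=1)
    if np.any(norms == 0):
        raise UndefinedCorrelationError(
            "constant fingerprint rows present; mask them out before segmentation")
    return Z / norms[:, None]


def pixel_correlation(features: np.ndarray, i: int, j: int) -> float:
    """Pearson correlation between the fingerprints of pixels i and j."""
    Z = _standardize(np.asarray(features, float)[[i, j]])
    return float(np.clip(Z[0] @ Z[1], -1.0, 1.0))


def _group_stats(Z: np.ndarray, idx: np.ndarray):
    S = Z[idx].sum(axis=0)
    n = len(idx)
    within = (S @ S - n) / 2.0          # sum of pairwise corr within the group
    return S, n, within


def split_objective(Z: np.ndarray, idx_a, idx_b) -> float:
    """Mean within-group correlation minus mean between-group correlation.

    Within pairs are pooled over both groups; if neither group has an
    internal pair (two singletons) the within mean is taken as 1.
    ``Z`` must be standardized rows (see :func:`_standardize`).
    """
    idx_a = np.asarray(idx_a, int)
    idx_b = np.asarray(idx_b, int)
    Sa, na, wa = _group_stats(Z, idx_a)
    Sb, nb, wb = _group_stats(Z, idx_b)
    n_within = na * (na - 1) // 2 + nb * (nb - 1) // 2
    mean_within = (wa + wb) / n_within if n_within else 1.0
    mean_between = (Sa @ Sb) / (na * nb)
    return float(mean_within - mean_between)


def _exhaustive_split(Z: np.ndarray):
    """Best bipartition by enumeration (pixel 0 fixed to group A)."""
    n = Z.shape[0]
    best_obj, best = -np.inf, None
    for code in range(0, 2 ** (n - 1) - 1):
        mask = np.array([(code >> k) & 1 for k in range(n - 1)], bool)
        a = np.concatenate([[0], 1 + np.flatnonzero(mask)])
        b = 1 + np.flatnonzero(~mask)
        obj = split_objective(Z, a, b)
        if obj > best_obj + 1e-15:
            best_obj, best = obj, (a, b)
    return best[0], best[1], best_obj


def _rank_compete(Z: np.ndarray, seed_a: int, seed_b: int):
    """Grow two competing regions greedily from a seed pair."""
    n = Z.shape[0]
    in_a = np.zeros(n, bool)
    in_b = np.zeros(n, bool)
    in_a[seed_a] = True
    in_b[seed_b] = True
    Sa = Z[seed_a].copy()
    Sb = Z[seed_b].copy()
    na = nb = 1
    aff_a = Z @ Sa
    aff_b = Z @ Sb
    unassigned = ~(in_a | in_b)
    while unassigned.any():
        cand = np.flatnonzero(unassigned)
        sa = aff_a[cand] / na
        sb = aff_b[cand] / nb
        best_a = cand[np.argmax(sa)]
        best_b = cand[np.argmax(sb)]
        va, vb = aff_a[best_a] / na, aff_b[best_b] / nb
        # highest affinity claims; ties -> walker A (argmax already takes
        # the lowest pixel index within a walker)
        if va >= vb:
            in_a[best_a] = True
            Sa += Z[best_a]
            na += 1
            aff_a += Z @ Z[best_a]
            pick = best_a
        else:
            in_b[best_b] = True
            Sb += Z[best_b]
            nb += 1
            aff_b += Z @ Z[best_b]
            pick = best_b
        unassigned[pick] = False
    return np.flatnonzero(in_a), np.flatnonzero(in_b)


def split_segment(features: np.ndarray, pixel_set=None,
                  config: WalkerConfig | None = None):
    """Bipartition ``pixel_set`` (default: all rows of ``features``).

    Returns ``(idx_a, idx_b)`` as sorted arrays of indices into
    ``features`` rows; the group containing the lowest pixel index comes
    first.  Deterministic given the config seed.
    """
    config = config or WalkerConfig()
    X = np.asarray(features, float)
    if pixel_set is None:
        pixel_set = np.arange(X.shape[0])
    pixel_set = np.asarray(sorted(pixel_set), int)
    n = len(pixel_set)
    if n < 2:
        raise CannotSplitError(f"cannot split a segment of {n} pixel(s)")
    Z = _standardize(X[pixel_set])

    if n <= config.exact_max:
        a, b, _ = _exhaustive_split(Z)
    else:
        rng = np.random.default_rng(config.seed)
        use = np.arange(n)
        if n > config.max_exact_pixels:
            use = np.sort(rng.choice(n, config.max_exact_pixels, replace=False))
        G = Z[use] @ Z[use].T
        iu, ju = np.triu_indices(len(use), k=1)
        vals = G[iu, ju]
        order = np.argsort(vals, kind="stable")
        seed_pairs = [(use[iu[order[0]]], use[ju[order[0]]])]
        k = max(1, int(np.ceil(config.bottom_frac * len(vals))))
        pool = order[:k]
        extra = min(config.restarts - 1, len(pool))
        if extra > 0:
            chosen = rng.choice(len(pool), size=extra, replace=False)
            for c in np.sort(chosen):
                p = pool[c]
                pair = (use[iu[p]], use[ju[p]])
                if pair not in seed_pairs:
                    seed_pairs.append(pair)
        best_obj, best = -np.inf, None
        for sa, sb in seed_pairs:
            ia, ib = _rank_compete(Z, int(sa), int(sb))
            obj = split_objective(Z, ia, ib)
            if obj > best_obj + 1e-12:
                best_obj, best = obj, (ia, ib)
        a, b = best
    a = np.sort(pixel_set[a])
    b = np.sort(pixel_set[b])
    if b[0] < a[0]:
        a, b = b, a
    return a, b


def _mean_within(Z: np.ndarray, idx: np.ndarray) -> float:
    n = len(idx)
    if n < 2:
        return 1.0
    S = Z[idx].sum(axis=0)
    return float((S @ S - n) / (n * (n - 1)))


def dhc_rc_segment(features: np.ndarray, n_segments: int,
                   config: WalkerConfig | None = None,
                   coords: np.ndarray | None = None,
                   shape: tuple[int, int] | None = None) -> SegmentMap:
    """Divisive segmentation of the feature matrix into ``n_segments``.

    At every round the leaf with the lowest mean within-segment
    correlation (singletons count as perfectly coherent) is split next.
    """
    config = config or WalkerConfig()
    X = np.asarray(features, float)
    n = X.shape[0]
    if not 1 <= n_segments <= n:
        raise CannotSplitError(f"n_segments must be in [1, {n}], got {n_segments}")
    if coords is None:
        coords = np.column_stack([np.zeros(n, int), np.arange(n)])
        shape = (1, n)
    coords = np.asarray(coords, int)
    Z = _standardize(X)

    tree = [{"id": 0, "parent": None, "children": [],
             "pixels": np.arange(n)}]
    leaves = [0]
    next_id = 1
    rng_seq = np.random.SeedSequence(config.seed)
    while len(leaves) < n_segments:
        splittable = [l for l in leaves if len(tree[l]["pixels"]) >= 2]
        scores = [_mean_within(Z, tree[l]["pixels"]) for l in splittable]
        target = splittable[int(np.argmin(scores))]
        child_seed = int(np.random.default_rng(rng_seq.spawn(1)[0]).integers(0, 2**31 - 1))
        sub_cfg = replace(config, seed=child_seed)
        a, b = split_segment(X, tree[target]["pixels"], sub_cfg)
        for part in (a, b):
            tree.append({"id": next_id, "parent": target, "children": [],
                         "pixels": part})
            tree[target]["children"].append(next_id)
            next_id += 1
        leaves.remove(target)
        leaves.extend(tree[target]["children"][-2:])

    # contiguous ids ordered by each leaf's lowest pixel index
    leaves_sorted = sorted(leaves, key=lambda l: int(tree[l]["pixels"][0]))
    labels = np.empty(n, int)
    fingerprints = np.empty((len(leaves_sorted), X.shape[1]))
    for new_id, leaf in enumerate(leaves_sorted):
        labels[tree[leaf]["pixels"]] = new_id
        fingerprints[new_id] = X[tree[leaf]["pixels"]].mean(axis=0)
        tree[leaf]["segment_id"] = new_id
    smap = SegmentMap(labels=labels, coords=coords, shape=shape, tree=tree,
                      mean_fingerprints=fingerprints)
    assert_valid_partition(smap, n_segments)
    smap.colors = assign_colors(smap)
    return smap


def assert_valid_partition(smap: SegmentMap, n_segments: int) -> None:
    labels = smap.labels
    assert len(labels) > 0
    assert labels.min() == 0 and labels.max() == n_segments - 1
    assert len(np.unique(labels)) == n_segments


def assign_colors(smap: SegmentMap, features: np.ndarray | None = None) -> np.ndarray:
    """Correlation-ordered colour values in [0, 1] per segment.

    The least-correlated segment pair takes the two ends of the scale;
    the rest are placed by relative correlation distance to the two
    extremes.  A single segment gets 0.5.
    """
    if features is not None:
        k = smap.n_segments
        fingerprints = np.vstack([np.asarray(features, float)[smap.segment_pixels(s)].mean(axis=0)
                                  for s in range(k)])
    else:
        fingerprints = smap.mean_fingerprints
    k = len(fingerprints)
    if k == 1:
        return np.array([0.5])
    Zf = _standardize(fingerprints)
    C = np.clip(Zf @ Zf.T, -1.0, 1.0)
    iu, ju = np.triu_indices(k, k=1)
    worst = np.argmin(C[iu, ju])
    a, b = int(iu[worst]), int(ju[worst])
    da = 1.0 - C[:, a]
    db = 1.0 - C[:, b]
    with np.errstate(invalid="ignore"):
        pos = da / (da + db)
    pos[a], pos[b] = 0.0, 1.0
    pos = np.nan_to_num(pos, nan=0.5)
    # enforce uniqueness with a stable, id-ordered nudge
    order = np.lexsort((np.arange(k), pos))
    for prev, cur in zip(order[:-1], order[1:]):
        if pos[cur] <= pos[prev]:
            pos[cur] = np.nextafter(pos[prev], 2.0) + 1e-9
    return np.clip(pos, 0.0, 1.0 + 1e-6)


def resegment(features: np.ndarray, smap: SegmentMap, segment_ids,
              n_segments: int, config: WalkerConfig | None = None) -> SegmentMap:
    """Re-run the divisive segmentation on the union of the selected
    segments' pixels; all other pixels are dropped from the new map."""
    segment_ids = list(segment_ids)
    if not segment_ids:
        raise ValueError("empty segment selection")
    sel = np.isin(smap.labels, segment_ids)
    if not sel.any():
        raise ValueError(f"segments {segment_ids} contain no pixels")
    idx = np.flatnonzero(sel)
    sub = dhc_rc_segment(np.asarray(features, float)[idx], n_segments,
                         config=config, coords=smap.coords[idx], shape=smap.shape)
    return sub


def map_segments_to_regions(smap: SegmentMap, label_raster: np.ndarray):
    """Majority-overlap assignment of segments to ground-truth regions.

    Returns ``(assignment, purity_table)`` where ``assignment`` maps
    segment id -> region code (ties broken toward the lower region code)
    and the table reports per-segment purity plus per-region recall.
    """
    label_raster = np.asarray(label_raster)
    if label_raster.shape != tuple(smap.shape):
        raise ValueError(f"label raster shape {label_raster.shape} != {smap.shape}")
    true = label_raster[smap.coords[:, 0], smap.coords[:, 1]]
    assignment = {}
    rows = []
    for s in range(smap.n_segments):
        in_seg = smap.labels == s
        codes, counts = np.unique(true[in_seg], return_counts=True)
        best = codes[np.flatnonzero(counts == counts.max())].min()
        assignment[s] = int(best)
        rows.append({"segment": s, "region": int(best),
                     "size": int(in_seg.sum()),
                     "purity": float(counts.max() / in_seg.sum())})
    purity = pd.DataFrame(rows)
    recalls = []
    for code in np.unique(true):
        region_total = int((true == code).sum())
        segs = [s for s, r in assignment.items() if r == code]
        in_assigned = np.isin(smap.labels, segs)
        got = int((in_assigned & (true == code)).sum())
        recalls.append({"region": int(code), "recall": got / region_total,
                        "pixels": region_total})
    return assignment, purity, pd.DataFrame(recalls)
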