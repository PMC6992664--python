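"""Multi-label maximum-flow/minimum-cut clustering around fixed HU guide values.

Voxels inside a domain mask are assigned to classes anchored at guide
intensities by minimising a Potts energy

    E(l) = sum_v  D(I(v), g_{l(v)})  +  reg_weight * sum_{(p,q)} a_pq [l(p) != l(q)]

where ``D`` is the absolute (default) or squared HU deviation from the guide
value and ``a_pq`` is the shared face area of the neighbouring voxel pair in
mm^2, so anisotropic slices do not bias the boundary penalty. Two labels are
solved exactly with a single s-t graph cut; more labels use alpha-expansion,
each move being one graph cut. The underlying max-flow solver is
``scipy.sparse.csgraph.maximum_flow``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

from .volume_io import BinaryMask, CTVolume

__all__ = [
    "MFMCConfig",
    "ProbabilityMapSet",
    "mfmc_cluster",
    "labeling_energy",
    "binarize",
]


@dataclass
class MFMCConfig:
    """Guide values and smoothness settings for one clustering pass."""

    guide_values: tuple[float, ...] = (14.0, 24.0, 34.0)
    reg_weight: float = 0.1
    neighborhood: int = 6
    max_iter: int = 10
    tol: float = 1e-6
    prob_threshold: float = 0.5
    data_term: str = "abs"  # "abs" or "squared"

    def __post_init__(self) -> None:
        self.guide_values = tuple(float(g) for g in self.guide_values)
        if len(set(self.guide_values)) < 2:
            raise ValueError("need at least 2 distinct guide values")
        if self.reg_weight < 0:
            raise ValueError("reg_weight must be non-negative")
        if not 0 < self.prob_threshold < 1:
            raise ValueError("prob_threshold must lie in (0, 1)")
        if self.neighborhood not in (6, 26):
            raise ValueError("neighborhood must be 6 or 26")
        if self.data_term not in ("abs", "squared"):
            raise ValueError("data_term must be 'abs' or 'squared'")


@dataclass
class ProbabilityMapSet:
    """Per-guide soft assignment maps; in-domain values sum to 1 per voxel."""

    maps: list[np.ndarray]
    guide_values: tuple[float, ...]
    labels: np.ndarray = field(repr=False, default=None)  # hard argmin labeling, -1 outside domain
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def map_for(self, guide: float) -> np.ndarray:
        for g, m in zip(self.guide_values, self.maps):
            if np.isclose(g, guide):
                return m
        raise KeyError(f"guide value {guide} not configured (have {self.guide_values})")


# ---------------------------------------------------------------------------
# Energy


def _data_cost(values: np.ndarray, guide: float, cfg: MFMCConfig) -> np.ndarray:
    d = np.abs(values - guide)
    return d * d if cfg.data_term == "squared" else d


def _neighbor_structure(spacing, connectivity: int):
    """Offsets and boundary weights (mm^2-equivalent) for the pairwise term."""
    sx, sy, sz = spacing
    face = {0: sy * sz, 1: sx * sz, 2: sx * sy}
    offsets = []
    for ax in range(3):
        off = [0, 0, 0]
        off[ax] = 1
        offsets.append((tuple(off), face[ax]))
    if connectivity == 26:
        vox = sx * sy * sz
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (0, 1):
                    off = (dx, dy, dz)
                    if off <= (0, 0, 0) or sum(abs(o) for o in off) < 2:
                        continue
                    dist = np.sqrt((dx * sx) ** 2 + (dy * sy) ** 2 + (dz * sz) ** 2)
                    offsets.append((off, vox / dist))
    return offsets


def _pair_slices(offset):
    src, dst = [], []
    for o in offset:
        if o == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif o > 0:
            src.append(slice(0, -o))
            dst.append(slice(o, None))
        else:
            src.append(slice(-o, None))
            dst.append(slice(0, o))
    return tuple(src), tuple(dst)


def labeling_energy(
    vol: CTVolume,
    labels: np.ndarray,
    cfg: MFMCConfig,
    domain: BinaryMask | None = None,
) -> float:
    """Exact Potts energy of a hard labeling (label = guide index, -1 = outside)."""
    labels = np.asarray(labels)
    dom = domain.data if domain is not None else np.ones(vol.shape, bool)
    lab_in = labels[dom]
    if lab_in.size and (lab_in.min() < 0 or lab_in.max() >= len(cfg.guide_values)):
        raise ValueError("label outside the configured guide set")
    guides = np.asarray(cfg.guide_values)
    vals = vol.data[dom]
    d = np.abs(vals - guides[lab_in])
    energy = float((d * d).sum()) if cfg.data_term == "squared" else float(d.sum())
    for offset, w in _neighbor_structure(vol.spacing, cfg.neighborhood):
        s, t = _pair_slices(offset)
        both = dom[s] & dom[t]
        diff = labels[s] != labels[t]
        energy += cfg.reg_weight * w * float(np.count_nonzero(both & diff))
    return energy


# ---------------------------------------------------------------------------
# Binary move solver (s-t min cut)


def _min_cut(u0: np.ndarray, u1: np.ndarray, edges_p, edges_q, edges_w) -> np.ndarray:
    """Minimise sum u0[v](1-x_v) + u1[v] x_v + sum w [x_p=0, x_q=1] over x in {0,1}.

    ``edges_w`` penalises the ordered disagreement (x_p=0, x_q=1); symmetric
    Potts terms are passed as two opposing directed edges. Returns the boolean
    x per node (True = 1, i.e. sink side of the cut).
    """
    n = u0.size
    source, sink = n, n + 1
    cap = np.concatenate([u1, u0, edges_w])
    total = float(cap.sum())
    scale = min(1e6, 1.5e9 / max(total, 1.0))
    rows = np.concatenate([np.full(n, source), np.arange(n), edges_p])
    cols = np.concatenate([np.arange(n), np.full(n, sink), edges_q])
    data = np.rint(cap * scale).astype(np.int32)
    keep = data > 0
    graph = csr_matrix((data[keep], (rows[keep], cols[keep])), shape=(n + 2, n + 2), dtype=np.int32)
    res = maximum_flow(graph, source, sink)
    residual = graph - res.flow
    residual.data = np.where(residual.data > 0, residual.data, 0)
    residual.eliminate_zeros()
    order = breadth_first_order(residual, source, directed=True, return_predecessors=False)
    x = np.ones(n, dtype=bool)
    order = order[order < n]
    x[order] = False  # reachable from source => keeps label 0
    return x


def _solve_expansion(
    values: np.ndarray,
    labels_flat: np.ndarray,
    alpha: int,
    cfg: MFMCConfig,
    guides: np.ndarray,
    pair_p: np.ndarray,
    pair_q: np.ndarray,
    pair_w: np.ndarray,
) -> np.ndarray:
    """One alpha-expansion move over flattened in-domain voxels."""
    free = labels_flat != alpha
    n_free = int(free.sum())
    if n_free == 0:
        return labels_flat
    idx_of = np.full(labels_flat.size, -1, dtype=np.int64)
    idx_of[free] = np.arange(n_free)

    u0 = np.abs(values[free] - guides[labels_flat[free]])
    u1 = np.abs(values[free] - guides[alpha])
    if cfg.data_term == "squared":
        u0, u1 = u0 * u0, u1 * u1

    p_free = free[pair_p]
    q_free = free[pair_q]
    lp = labels_flat[pair_p]
    lq = labels_flat[pair_q]

    ep, eq, ew = [], [], []
    # both endpoints free
    both = p_free & q_free
    same = both & (lp == lq)
    if same.any():
        a = idx_of[pair_p[same]]
        b = idx_of[pair_q[same]]
        w = pair_w[same]
        ep.extend([a, b])
        eq.extend([b, a])
        ew.extend([w, w])
    diff = both & (lp != lq)
    if diff.any():
        a = idx_of[pair_p[diff]]
        b = idx_of[pair_q[diff]]
        w = pair_w[diff]
        # E(0,0)=w, E(0,1)=w, E(1,0)=w, E(1,1)=0  ->  edge a->b cap w, plus w on U0(b)
        ep.append(a)
        eq.append(b)
        ew.append(w)
        np.add.at(u0, b, w)
    # one endpoint fixed at alpha: free endpoint pays w when it keeps its label
    for fr, fx in ((p_free & ~q_free, pair_p), (~p_free & q_free, pair_q)):
        if fr.any():
            np.add.at(u0, idx_of[fx[fr]], pair_w[fr])

    if ep:
        edges_p = np.concatenate(ep)
        edges_q = np.concatenate(eq)
        edges_w = np.concatenate(ew)
    else:
        edges_p = edges_q = np.empty(0, dtype=np.int64)
        edges_w = np.empty(0)

    switch = _min_cut(u0, u1, edges_p, edges_q, edges_w)
    out = labels_flat.copy()
    free_idx = np.flatnonzero(free)
    out[free_idx[switch]] = alpha
    return out


def mfmc_cluster(
    vol: CTVolume,
    domain: BinaryMask,
    cfg: MFMCConfig | None = None,
    provenance: list | None = None,
) -> ProbabilityMapSet:
    """Cluster in-domain voxels around the configured guide values.

    Returns per-class soft maps whose hard argmax reproduces the optimised
    labeling; the relaxed values blend the graph-cut assignment with a
    normalised inverse-distance weighting of the data costs, so the argmax of
    the maps always equals the solver labeling.
    """
    cfg = cfg or MFMCConfig()
    dom = domain.data
    if not dom.any():
        raise ValueError("empty domain mask")
    guides = np.asarray(cfg.guide_values)
    order = np.argsort(guides, kind="stable")  # visit order independent of configured order

    vals = vol.data[dom]
    # nearest-guide initialisation; ties broken toward the lower guide value
    dists = np.abs(vals[:, None] - guides[None, :])
    sorted_cols = dists[:, order]
    init = order[np.argmin(sorted_cols, axis=1)]
    labels_flat = init.astype(np.int64)

    # precompute in-domain neighbour pairs on the flattened index
    flat_id = np.full(vol.shape, -1, dtype=np.int64)
    flat_id[dom] = np.arange(vals.size)
    pp, qq, ww = [], [], []
    for offset, w in _neighbor_structure(vol.spacing, cfg.neighborhood):
        s, t = _pair_slices(offset)
        both = dom[s] & dom[t]
        pp.append(flat_id[s][both])
        qq.append(flat_id[t][both])
        ww.append(np.full(int(both.sum()), cfg.reg_weight * w))
    pair_p = np.concatenate(pp) if pp else np.empty(0, np.int64)
    pair_q = np.concatenate(qq) if qq else np.empty(0, np.int64)
    pair_w = np.concatenate(ww) if ww else np.empty(0)

    def energy_of(lf: np.ndarray) -> float:
        d = np.abs(vals - guides[lf])
        e = float((d * d).sum()) if cfg.data_term == "squared" else float(d.sum())
        e += float(pair_w[lf[pair_p] != lf[pair_q]].sum())
        return e

    energy = energy_of(labels_flat)
    converged = False
    sweeps = 0
    if cfg.reg_weight > 0:
        for sweep in range(cfg.max_iter):
            improved = False
            for alpha in order:
                cand = _solve_expansion(vals, labels_flat, int(alpha), cfg, guides, pair_p, pair_q, pair_w)
                e_cand = energy_of(cand)
                if e_cand < energy - cfg.tol * max(abs(energy), 1.0):
                    labels_flat, energy = cand, e_cand
                    improved = True
            sweeps = sweep + 1
            if not improved:
                converged = True
                break
    else:
        converged = True
    if provenance is not None:
        provenance.append(
            {"stage": "mfmc", "guides": list(cfg.guide_values), "sweeps": sweeps,
             "energy": energy, "converged": converged}
        )
        if not converged:
            provenance.append({"stage": "mfmc", "warning": "alpha-expansion did not converge"})

    labels = np.full(vol.shape, -1, dtype=np.int64)
    labels[dom] = labels_flat

    # relaxed maps: 0.6 hard assignment + 0.4 inverse-distance weighting
    eps = 1e-6
    inv = 1.0 / (dists + eps)
    inv /= inv.sum(axis=1, keepdims=True)
    maps = []
    for c in range(guides.size):
        m = np.zeros(vol.shape)
        m[dom] = 0.6 * (labels_flat == c) + 0.4 * inv[:, c]
        maps.append(m)
    return ProbabilityMapSet(maps=maps, guide_values=cfg.guide_values, labels=labels, spacing=vol.spacing)


def binarize(maps: ProbabilityMapSet, guide: float, cfg: MFMCConfig | None = None) -> BinaryMask:
    """Threshold one class's probability map at ``prob_threshold``."""
    cfg = cfg or MFMCConfig()
    m = maps.map_for(guide)
    return BinaryMask(m >= cfg.prob_threshold, maps.spacing)
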