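"""Topological featurization: delay embedding, Rips persistence, persistence images.

Each band window becomes a point cloud by Takens delay embedding; the
Euclidean Vietoris-Rips filtration of that cloud yields a persistence diagram
(H0 components, H1 loops, optionally H2 voids); finite features of homology
dimension >= 1 are vectorized into a "high-order" persistence image — a fixed
R x R grid of Gaussian bumps in (birth, persistence) coordinates weighted
linearly by persistence and min-max normalized to [0, 1].

Persistence is computed by the standard boundary-matrix reduction over Z/2.
Columns are stored as Python big-integer bitmasks (bit i = face with
filtration index i), which makes the column XOR in the reduction loop a
single machine-word-parallel operation.  The filtration is truncated at the
cloud's enclosing radius (min over points of its eccentricity) — beyond that
scale the complex is a cone, hence contractible, so no finite feature is
lost.  ``brute_force_persistence`` is a deliberately independent
re-implementation (full untruncated filtration, set-based column reduction)
kept as the exact oracle for small clouds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .synthetic import substream_rng

__all__ = [
    "PersistenceDiagram",
    "PersistenceImage",
    "TDAConfig",
    "delay_embed",
    "select_delay_ami",
    "subsample_cloud",
    "rips_persistence",
    "brute_force_persistence",
    "diagram_to_pi",
    "pooled_pi_ranges",
    "window_to_pi",
]


# ---------------------------------------------------------------------------
# Delay embedding
# ---------------------------------------------------------------------------

def delay_embed(series: np.ndarray, embed_dim: int = 3, delay: int = 4) -> np.ndarray:
    """Takens delay embedding of a scalar series.

    Point i is (x[i], x[i+delay], ..., x[i+(m-1)*delay]); the cloud has
    n - (m-1)*delay points in R^m.
    """
    x = np.asarray(series, dtype=float).ravel()
    if embed_dim < 2:
        raise ValueError("embed_dim must be >= 2")
    if delay < 1:
        raise ValueError("delay must be >= 1 sample")
    n_points = x.shape[0] - (embed_dim - 1) * delay
    if n_points < 1:
        raise ValueError(
            f"series of length {x.shape[0]} too short for embed_dim={embed_dim}, "
            f"delay={delay}"
        )
    idx = np.arange(n_points)[:, None] + delay * np.arange(embed_dim)[None, :]
    return x[idx]


def select_delay_ami(series: np.ndarray, max_delay: int = 50, n_bins: int = 16) -> int:
    """Delay at the first local minimum of the average mutual information.

    Histogram-based MI between x[t] and x[t+tau]; falls back to max_delay if
    no interior minimum exists.
    """
    x = np.asarray(series, dtype=float).ravel()
    edges = np.histogram_bin_edges(x, bins=n_bins)
    mis = []
    for tau in range(1, max_delay + 1):
        a, b = x[:-tau], x[tau:]
        joint, _, _ = np.histogram2d(a, b, bins=[edges, edges])
        p = joint / joint.sum()
        px = p.sum(axis=1, keepdims=True)
        py = p.sum(axis=0, keepdims=True)
        mask = p > 0
        mis.append(float(np.sum(p[mask] * np.log(p[mask] / (px @ py)[mask]))))
    for i in range(1, len(mis) - 1):
        if mis[i] < mis[i - 1] and mis[i] <= mis[i + 1]:
            return i + 1
    return max_delay


def subsample_cloud(points: np.ndarray, max_points: int, seed: int = 0) -> np.ndarray:
    """Seeded uniform subsample without replacement (identity if small enough)."""
    pts = np.asarray(points, dtype=float)
    if max_points < 2:
        raise ValueError("max_points must be >= 2")
    n = pts.shape[0]
    if n <= max_points:
        return pts
    rng = substream_rng(seed, "subsample")
    idx = np.sort(rng.choice(n, size=max_points, replace=False))
    return pts[idx]


# ---------------------------------------------------------------------------
# Persistence diagrams
# ---------------------------------------------------------------------------

@dataclass
class PersistenceDiagram:
    """Multiset of (birth, death, hom_dim) features; death may be +inf."""

    features: list[tuple[float, float, int]] = field(default_factory=list)

    def in_dims(self, dims) -> list[tuple[float, float, int]]:
        dims = set(dims)
        return [f for f in self.features if f[2] in dims]

    def finite(self, dims=None) -> np.ndarray:
        """(n, 3) array of finite features, optionally restricted to dims."""
        feats = self.features if dims is None else self.in_dims(dims)
        rows = [f for f in feats if np.isfinite(f[1])]
        return np.array(rows, dtype=float).reshape(-1, 3)

    def sorted_features(self) -> list[tuple[float, float, int]]:
        return sorted(self.features, key=lambda f: (f[2], f[0], f[1]))


def _enclosing_radius(D: np.ndarray) -> float:
    """min over points of max distance to any other point."""
    if D.shape[0] < 2:
        return 0.0
    return float(D.max(axis=1).min())


def _enumerate_simplices(D: np.ndarray, max_dim: int, threshold: float):
    """All simplices of dim <= max_dim with diameter <= threshold.

    Returns a list of (diameter, dim, vertex_tuple); vertices have diameter 0.
    Pairwise-vectorized for edges and triangles; tetrahedra fall back to a
    combination loop over kept triangles' vertex sets.
    """
    n = D.shape[0]
    out = [(0.0, 0, (i,)) for i in range(n)]
    if max_dim < 1 or n < 2:
        return out
    iu, ju = np.triu_indices(n, 1)
    ed = D[iu, ju]
    keep = ed <= threshold
    for i, j, d in zip(iu[keep], ju[keep], ed[keep]):
        out.append((float(d), 1, (int(i), int(j))))
    if max_dim < 2 or n < 3:
        return out
    tri = np.array(list(itertools.combinations(range(n), 3)), dtype=np.intp)
    td = np.maximum(
        np.maximum(D[tri[:, 0], tri[:, 1]], D[tri[:, 0], tri[:, 2]]),
        D[tri[:, 1], tri[:, 2]],
    )
    keep = td <= threshold
    for verts, d in zip(tri[keep], td[keep]):
        out.append((float(d), 2, tuple(int(v) for v in verts)))
    if max_dim < 3 or n < 4:
        return out
    tet = np.array(list(itertools.combinations(range(n), 4)), dtype=np.intp)
    pairs = list(itertools.combinations(range(4), 2))
    qd = np.maximum.reduce([D[tet[:, a], tet[:, b]] for a, b in pairs])
    keep = qd <= threshold
    for verts, d in zip(tet[keep], qd[keep]):
        out.append((float(d), 3, tuple(int(v) for v in verts)))
    return out


def _reduce_and_pair(simplices) -> list[tuple[float, float, int]]:
    """Boundary-matrix reduction over Z/2 with bitmask columns.

    ``simplices`` must be sorted in filtration order with faces before
    cofaces.  Returns (birth, death, hom_dim) features with zero-persistence
    pairs removed; unpaired creators get death = +inf.
    """
    index_of = {s[2]: i for i, s in enumerate(simplices)}
    diam = [s[0] for s in simplices]
    dim = [s[1] for s in simplices]
    pivot_owner: dict[int, int] = {}
    stored: dict[int, int] = {}
    pairs: list[tuple[int, int]] = []
    killed: set[int] = set()
    for j, (d, k, verts) in enumerate(simplices):
        if k == 0:
            continue
        col = 0
        for f in itertools.combinations(verts, k):
            col |= 1 << index_of[f]
        while col:
            piv = col.bit_length() - 1
            owner = pivot_owner.get(piv)
            if owner is None:
                pivot_owner[piv] = j
                stored[j] = col
                pairs.append((piv, j))
                killed.add(piv)
                break
            col ^= stored[owner]
    features: list[tuple[float, float, int]] = []
    for i, j in pairs:
        if diam[j] > diam[i]:
            features.append((diam[i], diam[j], dim[i]))
    # Creators: vertices plus columns that reduced to zero (not stored as a
    # killer), minus creators later killed by a coface.
    zeroed = {j for j in range(len(simplices))
              if (dim[j] == 0 or j not in stored)}
    for j in sorted(zeroed - killed):
        features.append((diam[j], np.inf, dim[j]))
    return features


def rips_persistence(points: np.ndarray, max_hom_dim: int = 1,
                     max_filtration: float | None = None) -> PersistenceDiagram:
    """Persistence of the Euclidean Vietoris-Rips filtration of a cloud.

    Computes homology up to ``max_hom_dim`` (0, 1 or 2).  The filtration is
    truncated at ``max_filtration`` (default: the cloud's enclosing radius,
    which preserves every finite feature).  Zero-persistence pairs are
    discarded; H0 births are all 0 and a connected cloud has exactly one
    infinite H0 feature.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("empty point cloud")
    if max_hom_dim not in (0, 1, 2):
        raise ValueError("max_hom_dim must be 0, 1 or 2")
    if pts.shape[0] == 1:
        return PersistenceDiagram([(0.0, np.inf, 0)])
    D = squareform(pdist(pts))
    thresh = _enclosing_radius(D) if max_filtration is None else float(max_filtration)
    simplices = _enumerate_simplices(D, max_hom_dim + 1, thresh)
    simplices.sort(key=lambda s: (s[0], s[1], s[2]))
    feats = _reduce_and_pair(simplices)
    feats = [f for f in feats if f[2] <= max_hom_dim]
    return PersistenceDiagram(feats)


def brute_force_persistence(points: np.ndarray, max_hom_dim: int = 2) -> PersistenceDiagram:
    """Exact small-cloud persistence by naive full-filtration reduction.

    Independent oracle: enumerates every simplex up to dim max_hom_dim + 1
    with itertools (no threshold, no vectorization) and reduces set-valued
    boundary columns left to right.  Refuses clouds larger than 12 points.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = pts.shape[0]
    if n == 0:
        raise ValueError("empty point cloud")
    if n > 12:
        raise ValueError("brute-force oracle limited to <= 12 points")
    if n == 1:
        return PersistenceDiagram([(0.0, np.inf, 0)])

    def dist(i, j):
        return float(np.linalg.norm(pts[i] - pts[j]))

    simplices = []
    for d in range(0, max_hom_dim + 2):
        for verts in itertools.combinations(range(n), d + 1):
            diam = max((dist(a, b) for a, b in itertools.combinations(verts, 2)),
                       default=0.0)
            simplices.append((diam, d, verts))
    simplices.sort(key=lambda s: (s[0], s[1], s[2]))
    index_of = {s[2]: i for i, s in enumerate(simplices)}

    columns: list[set[int]] = []
    for diam, d, verts in simplices:
        if d == 0:
            columns.append(set())
        else:
            columns.append({index_of[f] for f in itertools.combinations(verts, d)})
    low_owner: dict[int, int] = {}
    pairs = []
    for j, col in enumerate(columns):
        while col:
            piv = max(col)
            if piv not in low_owner:
                low_owner[piv] = j
                pairs.append((piv, j))
                break
            col ^= columns[low_owner[piv]]
    paired = {i for i, _ in pairs} | {j for _, j in pairs}
    features = []
    for i, j in pairs:
        birth, death = simplices[i][0], simplices[j][0]
        if death > birth:
            features.append((birth, death, simplices[i][1]))
    for j, (diam, d, _) in enumerate(simplices):
        if j not in paired and d <= max_hom_dim:
            features.append((diam, np.inf, d))
    return PersistenceDiagram(features)


# ---------------------------------------------------------------------------
# Persistence images
# ---------------------------------------------------------------------------

@dataclass
class PersistenceImage:
    """R x R intensity grid over (birth, persistence) coordinates.

    pixels[i, j]: i indexes the persistence axis (ascending), j the birth
    axis (ascending).  After min-max normalization all pixels lie in [0, 1].
    """

    pixels: np.ndarray
    birth_range: tuple[float, float]
    pers_range: tuple[float, float]
    sigma: float
    hom_dims: tuple[int, ...]

    @property
    def resolution(self) -> int:
        return self.pixels.shape[0]


def diagram_to_pi(diag: PersistenceDiagram, resolution: int = 100,
                  sigma: float | None = None, hom_dims=(1, 2),
                  birth_range: tuple[float, float] | None = None,
                  pers_range: tuple[float, float] | None = None,
                  normalize: bool = True) -> PersistenceImage:
    """Vectorize a diagram into a persistence image.

    Finite features with homology dimension in ``hom_dims`` are mapped to
    (birth, persistence = death - birth); each deposits an isotropic Gaussian
    density (std ``sigma``) weighted linearly by its persistence, evaluated
    at pixel centres on the R x R grid spanning the axis ranges.  Ranges
    default to the span of the diagram itself but should be fixed per band
    (see ``pooled_pi_ranges``) when images must be comparable.  The final
    image is min-max normalized to [0, 1]; an all-zero image stays zero.
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    feats = diag.finite(hom_dims)
    if birth_range is None:
        birth_range = (0.0, float(feats[:, 0].max()) if len(feats) else 1.0)
        if birth_range[1] <= birth_range[0]:
            birth_range = (birth_range[0], birth_range[0] + 1.0)
    if pers_range is None:
        top = float((feats[:, 1] - feats[:, 0]).max()) if len(feats) else 1.0
        pers_range = (0.0, top if top > 0 else 1.0)
    if sigma is None:
        sigma = 0.05 * (pers_range[1] - pers_range[0])
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    img = np.zeros((resolution, resolution))
    b_centres = np.linspace(*birth_range, 2 * resolution + 1)[1::2]
    p_centres = np.linspace(*pers_range, 2 * resolution + 1)[1::2]
    for birth, death, _ in feats:
        pers = death - birth
        if pers <= 0:
            continue
        gb = np.exp(-0.5 * ((b_centres - birth) / sigma) ** 2)
        gp = np.exp(-0.5 * ((p_centres - pers) / sigma) ** 2)
        img += pers * np.outer(gp, gb) / (2 * np.pi * sigma**2)
    if normalize:
        lo, hi = img.min(), img.max()
        img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    return PersistenceImage(img, birth_range, pers_range, float(sigma),
                            tuple(hom_dims))


def pooled_pi_ranges(diagrams, hom_dims=(1, 2), pad: float = 0.05):
    """Fixed (birth, persistence) axis ranges from a pool of diagrams.

    Pads the pooled min/max by ``pad`` of the span so boundary features keep
    most of their Gaussian mass on the grid.
    """
    births, perss = [], []
    for d in diagrams:
        feats = d.finite(hom_dims)
        if len(feats):
            births.append(feats[:, 0])
            perss.append(feats[:, 1] - feats[:, 0])
    if not births:
        return (0.0, 1.0), (0.0, 1.0)
    b = np.concatenate(births)
    p = np.concatenate(perss)
    bspan = max(b.max() - b.min(), 1e-12)
    pspan = max(p.max(), 1e-12)
    return ((float(b.min() - pad * bspan), float(b.max() + pad * bspan)),
            (0.0, float(p.max() + pad * pspan)))


# ---------------------------------------------------------------------------
# Window -> PI pipeline
# ---------------------------------------------------------------------------

@dataclass
class TDAConfig:
    """Parameters of the window -> persistence image transform.

    embed_dim/delay set the Takens embedding (delay in samples);
    max_points caps the cloud before the Rips computation (the filtration's
    cost grows steeply in cloud size); hom_dims selects which homology
    dimensions enter the "high-order" image.
    """

    embed_dim: int = 3
    delay: int = 4
    max_points: int = 200
    max_hom_dim: int = 2
    hom_dims: tuple[int, ...] = (1, 2)
    resolution: int = 100
    sigma: float | None = None
    birth_range: tuple[float, float] | None = None
    pers_range: tuple[float, float] | None = None
    seed: int = 0


def window_to_diagram(series: np.ndarray, cfg: TDAConfig) -> PersistenceDiagram:
    cloud = delay_embed(series, cfg.embed_dim, cfg.delay)
    cloud = subsample_cloud(cloud, cfg.max_points, cfg.seed)
    return rips_persistence(cloud, max_hom_dim=cfg.max_hom_dim)


def window_to_pi(series: np.ndarray, cfg: TDAConfig,
                 diagram: PersistenceDiagram | None = None) -> PersistenceImage:
    """Full transform of one band window into a persistence image."""
    diag = window_to_diagram(series, cfg) if diagram is None else diagram
    return diagram_to_pi(diag, resolution=cfg.resolution, sigma=cfg.sigma,
                         hom_dims=cfg.hom_dims, birth_range=cfg.birth_range,
                         pers_range=cfg.pers_range)
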