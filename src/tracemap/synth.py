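"""Seeded generators for every input the pipeline consumes.

Four generators emulate the data a mesoscale tracing study produces, each
emitting machine-readable ground truth alongside the data so downstream
recovery is testable:

* ``gen_section_image`` — a grayscale section with a bright, irregularly
  shaped injection blob (smoothed superellipse with multiplicative speckle)
  over a textured background of thin fiber-like curves and noise, plus the
  true blob mask.
* ``gen_domain_points`` — per-atlas-level point clouds of tracer-signal
  coordinates for three partially overlapping anatomical domains, drawn
  from truncated anisotropic Gaussians inside a nucleus-shaped polygon,
  plus the Bayes-rule ground-truth labeling.
* ``gen_annotation_matrix`` — a block-structured injection-by-target weight
  matrix with background noise, plus the planted community partition.
* ``gen_neuron`` — a dendritic tree grown as a branching random walk with
  von Mises-Fisher direction persistence around an ellipsoidal soma, with
  independently tunable bifurcation rate, branch length and tortuosity.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from matplotlib.path import Path as MplPath
from skimage.draw import polygon2mask

from .boundary import CLASS_ORDER, BoundaryMap, LabeledPoints
from .connectivity import (
    ANTEROGRADE,
    RETROGRADE,
    AnnotationMatrix,
    inj_node,
    tgt_node,
)
from .swc import DENDRITE_TYPE, SOMA_TYPE, NeuronMorphology

import pandas as pd

# ---------------------------------------------------------------------------
# section images with injection blobs


@dataclass
class SectionSpec:
    """Parameters of a synthetic tracer section image."""

    height: int = 256
    width: int = 256
    blob_center: tuple[float, float] = (128.0, 128.0)  # (x, y) pixels
    blob_radius: float = 25.0
    blob_peak: float = 0.95  # intensity in (0, 1]
    background_level: float = 0.08
    fiber_density: float = 0.02  # fraction of pixels covered by fibers
    noise_sd: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.blob_peak <= 1):
            raise ValueError("blob_peak must lie in (0, 1]")
        if not (0 <= self.background_level <= 1):
            raise ValueError("background_level must lie in [0, 1]")
        cx, cy = self.blob_center
        # 1.25 margin covers the boundary wobble of the rendered blob
        r = 1.25 * self.blob_radius
        if cx - r < 0 or cy - r < 0 or cx + r > self.width or cy + r > self.height:
            raise ValueError(
                f"blob of radius {self.blob_radius} at {self.blob_center} "
                f"does not fit inside a {self.width}x{self.height} raster"
            )


def gen_section_image(spec: SectionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a section image and the ground-truth injection-blob mask.

    The blob is an ellipse whose boundary radius carries a low-order
    angular wobble (irregular outline, area still within a few percent of
    pi*r^2); its interior holds at least half the peak intensity even after
    multiplicative speckle.  Fibers are thin bright random walks; Gaussian
    pixel noise is added last but never pulls blob pixels below the blob
    rendering because the blob is composited with a maximum.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    img = np.full((h, w), spec.background_level, dtype=float)

    # fiber-like background texture: thin random walks
    if spec.fiber_density > 0:
        target_px = int(spec.fiber_density * h * w)
        covered = 0
        while covered < target_px:
            y, x = rng.uniform(0, h), rng.uniform(0, w)
            ang = rng.uniform(0, 2 * math.pi)
            length = int(rng.uniform(20, 80))
            level = rng.uniform(0.25, 0.65)
            for _ in range(length):
                ang += rng.normal(0, 0.25)
                y += math.sin(ang)
                x += math.cos(ang)
                iy, ix = int(y), int(x)
                if 0 <= iy < h and 0 <= ix < w:
                    img[iy, ix] = max(img[iy, ix], level)
                    covered += 1

    if spec.noise_sd > 0:
        img = img + rng.normal(0, spec.noise_sd, size=(h, w))

    # irregular blob: wobbled ellipse boundary, bright interior with speckle
    cx, cy = spec.blob_center
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    ph = rng.uniform(0, 2 * math.pi, size=3)
    wobble = (
        1.0
        + 0.08 * np.sin(3 * theta + ph[0])
        + 0.05 * np.sin(5 * theta + ph[1])
        + 0.03 * np.sin(7 * theta + ph[2])
    )
    boundary = spec.blob_radius * wobble
    mask = r <= boundary

    profile = spec.blob_peak * (1.0 - 0.25 * (r / np.maximum(boundary, 1e-9)) ** 2)
    speckle = np.clip(1.0 + 0.12 * rng.standard_normal((h, w)), 0.7, 1.3)
    blob_values = np.clip(profile * speckle, 0.5 * spec.blob_peak, 1.0)

    img[mask] = np.maximum(img[mask], blob_values[mask])
    return np.clip(img, 0.0, 1.0), mask


# ---------------------------------------------------------------------------
# domain-labeled point clouds


def default_level_polygon(
    width: int = 160, height: int = 120, n_vertices: int = 48
) -> np.ndarray:
    """Elongated, slightly indented nucleus-shaped polygon (x, y vertices)."""
    t = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
    a, b = 0.44 * width, 0.40 * height
    cx, cy = width / 2, height / 2
    radial = 1.0 - 0.12 * np.sin(t) ** 2 + 0.06 * np.cos(2 * t)
    xs = cx + a * np.cos(t) * radial
    ys = cy + b * np.sin(t) * radial
    return np.column_stack([xs, ys])


@dataclass
class DomainCloudSpec:
    """Three-domain labeled point clouds for one atlas level."""

    level_id: str
    centers: dict[str, tuple[float, float]]
    spreads: dict[str, float]  # base Gaussian sigma per domain, pixels
    n_points: dict[str, int]
    overlap_fraction: float = 0.1
    polygon: np.ndarray = field(default_factory=default_level_polygon)
    anisotropy: float = 1.5  # axis ratio of the domain covariances
    seed: int = 0

    def validate(self) -> None:
        if set(self.centers) - set(CLASS_ORDER):
            raise ValueError("domain names must come from the fixed label set")
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must lie in [0, 1)")
        path = MplPath(self.polygon)
        for name, c in self.centers.items():
            if not path.contains_point(c):
                raise ValueError(f"center of domain {name!r} lies outside mask")

    @classmethod
    def default(
        cls,
        level_id: str,
        seed: int,
        n_points_per_domain: int = 500,
        overlap_fraction: float = 0.1,
    ) -> "DomainCloudSpec":
        """Standard three-domain geometry used across atlas levels.

        Medial and lateral domains sit on opposite ends of the elongated
        nucleus with the caudal domain below and between them, matching the
        rostro-caudally varying layout of real sections; centers shift a
        few pixels between levels.
        """
        rng = np.random.default_rng([seed, 901])
        jitter = lambda: rng.uniform(-4, 4)  # noqa: E731
        centers = {
            "medial": (46.0 + jitter(), 52.0 + jitter()),
            "lateral": (116.0 + jitter(), 52.0 + jitter()),
            "caudal": (82.0 + jitter(), 82.0 + jitter()),
        }
        return cls(
            level_id=level_id,
            centers=centers,
            spreads={d: 14.0 for d in centers},
            n_points={d: n_points_per_domain for d in centers},
            overlap_fraction=overlap_fraction,
            seed=seed,
        )


@dataclass
class DomainCloudTruth:
    """Generating mixture of a domain cloud; defines ground-truth labels.

    The ground-truth label of any location is the argmax over domains of
    the mixture-weighted Gaussian density, renormalized for truncation to
    the nucleus mask (a likelihood-ratio boundary surface).
    """

    level_id: str
    domains: tuple[str, ...]
    centers: np.ndarray  # (k, 2)
    covariances: np.ndarray  # (k, 2, 2)
    weights: np.ndarray  # (k,) mixing proportions
    polygon: np.ndarray

    def mask_raster(self, shape: tuple[int, int]) -> np.ndarray:
        # polygon2mask expects (row, col) vertices
        return polygon2mask(shape, self.polygon[:, ::-1])

    def _log_densities(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        out = np.empty((len(pts), len(self.domains)))
        for k in range(len(self.domains)):
            d = pts - self.centers[k]
            prec = np.linalg.inv(self.covariances[k])
            maha = np.einsum("ni,ij,nj->n", d, prec, d)
            logdet = math.log(np.linalg.det(self.covariances[k]))
            out[:, k] = math.log(self.weights[k]) - 0.5 * (maha + logdet)
        return out

    def label_points(
        self, points: np.ndarray, truncation_logz: np.ndarray | None = None
    ) -> np.ndarray:
        logd = self._log_densities(points)
        if truncation_logz is not None:
            logd = logd - truncation_logz
        return np.array(
            [self.domains[k] for k in np.argmax(logd, axis=1)], dtype=object
        )

    def label_raster(self, shape: tuple[int, int]) -> BoundaryMap:
        """Dense Bayes-rule labeling of the mask at raster resolution."""
        mask = self.mask_raster(shape)
        ys, xs = np.nonzero(mask)
        pts = np.column_stack([xs, ys]).astype(float)
        # per-domain truncation mass inside the mask
        logd = self._log_densities(pts)
        logz = np.log(np.exp(logd - logd.max()).sum(axis=0)) + logd.max()
        labels = self.label_points(pts, truncation_logz=logz)
        class_idx = {c: k for k, c in enumerate(CLASS_ORDER)}
        raster = np.full(shape, -1, dtype=np.int8)
        raster[ys, xs] = [class_idx[c] for c in labels]
        return BoundaryMap(level_id=self.level_id, raster=raster, mask=mask)


def _domain_covariances(spec: DomainCloudSpec, scale: float) -> np.ndarray:
    rng = np.random.default_rng([spec.seed, 313])
    covs = []
    ar = spec.anisotropy
    for name in spec.centers:
        ang = rng.uniform(0, math.pi)
        rot = np.array(
            [[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]]
        )
        s = scale * spec.spreads[name]
        cov = rot @ np.diag([(s * ar**0.5) ** 2, (s / ar**0.5) ** 2]) @ rot.T
        covs.append(cov)
    return np.stack(covs)


def _sample_truncated(
    rng: np.random.Generator,
    center: np.ndarray,
    cov: np.ndarray,
    n: int,
    path: MplPath,
    own_cell_of=None,
) -> np.ndarray:
    """Gaussian samples truncated to the polygon (and optionally a cell)."""
    chol = np.linalg.cholesky(cov)
    out = np.empty((0, 2))
    tries = 0
    while len(out) < n:
        m = max(4 * (n - len(out)), 64)
        cand = center + rng.standard_normal((m, 2)) @ chol.T
        keep = path.contains_points(cand)
        if own_cell_of is not None:
            keep &= own_cell_of(cand)
        out = np.vstack([out, cand[keep]])
        tries += 1
        if tries > 200:
            raise RuntimeError("truncated sampling failed; check geometry")
    return out[:n]


def _foreign_fraction(
    rng: np.random.Generator,
    spec: DomainCloudSpec,
    covs: np.ndarray,
    path: MplPath,
    n_cal: int,
) -> float:
    centers = np.array([spec.centers[d] for d in spec.centers])
    foreign = total = 0
    for k, name in enumerate(spec.centers):
        pts = _sample_truncated(rng, centers[k], covs[k], n_cal, path)
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        foreign += int(np.sum(np.argmin(d2, axis=1) != k))
        total += len(pts)
    return foreign / total


def gen_domain_points(
    spec: DomainCloudSpec,
) -> tuple[LabeledPoints, DomainCloudTruth]:
    """Sample labeled domain point clouds with a controlled overlap level.

    ``overlap_fraction`` is the expected fraction of points lying closer
    (Euclidean) to a foreign domain center than to their own.  A global
    scale on the domain covariances is calibrated by bisection against
    that criterion on a large calibration draw; with overlap 0 the clouds
    are instead truncated to their own nearest-center cells, making the
    clouds perfectly separable.
    """
    spec.validate()
    if not MplPath(spec.polygon).contains_point(
        next(iter(spec.centers.values()))
    ):
        raise ValueError("empty or degenerate mask polygon")
    path = MplPath(spec.polygon)
    centers = np.array([spec.centers[d] for d in spec.centers])
    domains = tuple(spec.centers)

    if spec.overlap_fraction == 0:
        scale = 1.0
    else:
        cal_rng = np.random.default_rng([spec.seed, 577])
        lo, hi = 0.05, 6.0
        for _ in range(28):
            mid = math.sqrt(lo * hi)
            covs = _domain_covariances(spec, mid)
            frac = _foreign_fraction(cal_rng, spec, covs, path, n_cal=1500)
            if frac < spec.overlap_fraction:
                lo = mid
            else:
                hi = mid
            if abs(frac - spec.overlap_fraction) < 0.002:
                break
        scale = math.sqrt(lo * hi)

    covs = _domain_covariances(spec, scale)
    rng = np.random.default_rng(spec.seed)
    pts_list, lab_list = [], []
    for k, name in enumerate(domains):
        own_cell = None
        if spec.overlap_fraction == 0:
            d_own = k

            def own_cell(cand, d_own=d_own):
                d2 = ((cand[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
                return np.argmin(d2, axis=1) == d_own

        pts = _sample_truncated(
            rng, centers[k], covs[k], spec.n_points[name], path, own_cell
        )
        pts_list.append(pts)
        lab_list.extend([name] * len(pts))

    n_tot = sum(spec.n_points.values())
    weights = np.array([spec.n_points[d] / n_tot for d in domains])
    points = LabeledPoints(
        level_id=spec.level_id,
        points=np.vstack(pts_list),
        labels=np.array(lab_list, dtype=object),
    )
    truth = DomainCloudTruth(
        level_id=spec.level_id,
        domains=domains,
        centers=centers,
        covariances=covs,
        weights=weights,
        polygon=spec.polygon,
    )
    return points, truth


# ---------------------------------------------------------------------------
# planted annotation matrices


@dataclass
class PlantedMatrixSpec:
    """Block-structured injection-by-target matrix specification."""

    n_injections: int
    n_targets: int
    blocks: list[tuple[list[int], list[int], float]]  # (inj idx, tgt idx, mean)
    noise_rate: float = 0.0
    tracer_kinds: list[str] | None = None  # per injection; default anterograde
    weight_cv: float = 0.25  # lognormal spread of within-block weights
    seed: int = 0

    def validate(self) -> None:
        inj_seen: set[int] = set()
        tgt_seen: set[int] = set()
        for injs, tgts, mean in self.blocks:
            if mean < 0:
                raise ValueError("block mean weights must be non-negative")
            if inj_seen & set(injs) or tgt_seen & set(tgts):
                raise ValueError("blocks overlap")
            inj_seen |= set(injs)
            tgt_seen |= set(tgts)
        if inj_seen != set(range(self.n_injections)):
            raise ValueError("every injection must belong to exactly one block")
        if tgt_seen != set(range(self.n_targets)):
            raise ValueError("every target must belong to exactly one block")
        if not (0 <= self.noise_rate <= 1):
            raise ValueError("noise_rate must lie in [0, 1]")
        if self.tracer_kinds is not None and len(self.tracer_kinds) != self.n_injections:
            raise ValueError("tracer_kinds must list one kind per injection")


def gen_annotation_matrix(
    spec: PlantedMatrixSpec,
) -> tuple[AnnotationMatrix, dict]:
    """Planted block matrix plus the planted community partition.

    Within-block entries are lognormal around the block mean; off-block
    entries are nonzero with probability ``noise_rate`` and carry weights an
    order of magnitude below the weakest block.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    inj_ids = [f"inj{i:02d}" for i in range(spec.n_injections)]
    tgt_ids = [f"tgt{j:03d}" for j in range(spec.n_targets)]
    vals = np.zeros((spec.n_injections, spec.n_targets))
    partition: dict = {}
    sigma = math.sqrt(math.log(1 + spec.weight_cv**2))
    for b, (injs, tgts, mean) in enumerate(spec.blocks):
        for i in injs:
            partition[inj_node(inj_ids[i])] = b
        for j in tgts:
            partition[tgt_node(tgt_ids[j])] = b
        block = mean * rng.lognormal(-0.5 * sigma**2, sigma, (len(injs), len(tgts)))
        vals[np.ix_(injs, tgts)] = block
    if spec.noise_rate > 0:
        min_mean = min(mean for _, _, mean in spec.blocks)
        off = vals == 0
        hits = off & (rng.random(vals.shape) < spec.noise_rate)
        vals[hits] = 0.1 * min_mean * rng.lognormal(0, sigma, int(hits.sum()))
    kinds = spec.tracer_kinds or [ANTEROGRADE] * spec.n_injections
    matrix = AnnotationMatrix(
        pd.DataFrame(vals, index=inj_ids, columns=tgt_ids),
        dict(zip(inj_ids, kinds)),
    )
    return matrix, partition


# ---------------------------------------------------------------------------
# neuron morphologies

BRANCH_LEN_SHAPE = 6.0  # Gamma shape of branch lengths (CV ~ 0.41)


@dataclass
class NeuronSpec:
    """Branching-random-walk neuron with tunable morphometric targets.

    The bifurcation budget is drawn once per neuron as a Poisson count
    whose mean is the stationary branching-process expectation
    ``n_stems * p / (1 - 2p)`` with ``p = bifurcation_rate *
    mean_branch_len`` (p must stay < 0.5); the tree shape is then a
    uniformly random recursive binary forest with that many internal
    nodes.  Drawing the count directly keeps the seed-to-seed dispersion
    Poisson-like — reconstructions of a given cell type branch fairly
    consistently — instead of the heavy-tailed sizes a live
    birth-death cascade would produce.  Branch lengths follow a Gamma law
    (shape 6) with mean ``mean_branch_len``; direction persistence follows
    a von Mises-Fisher step distribution whose concentration is calibrated
    so realized branch tortuosity matches ``tortuosity_target``; growth
    halts at ``max_extent`` from the soma.
    """

    soma_dims: tuple[float, float, float] = (12.0, 14.0, 10.0)  # h, w, d
    n_stems: int = 4
    bifurcation_rate: float = 0.008  # per unit length
    tortuosity_target: float = 1.15
    mean_branch_len: float = 40.0
    max_extent: float = 200.0
    step: float = 2.0
    stem_radius: float = 1.2
    seed: int = 0

    def validate(self) -> None:
        if min(self.soma_dims) <= 0 or self.mean_branch_len <= 0 or self.step <= 0:
            raise ValueError("soma_dims, mean_branch_len and step must be positive")
        if self.tortuosity_target < 1:
            raise ValueError("tortuosity_target must be >= 1")
        p_b = self.bifurcation_rate * self.mean_branch_len
        if p_b >= 0.5:
            raise ValueError(
                "bifurcation_rate * mean_branch_len >= 0.5: supercritical "
                "branching process would not terminate"
            )
        exp_branches = 1.0 / (1.0 - 2.0 * p_b)
        exp_nodes = self.n_stems * exp_branches * self.mean_branch_len / self.step
        if exp_nodes > 1e5:
            raise ValueError(
                f"spec implies ~{exp_nodes:.0f} expected nodes (> 1e5 guard)"
            )


def _sample_vmf(rng: np.random.Generator, mu: np.ndarray, kappa: float) -> np.ndarray:
    """Draw a unit vector from a 3D von Mises-Fisher distribution."""
    if kappa > 1e8:
        return mu
    u = rng.random()
    if kappa < 1e-8:
        w = 2 * u - 1
    elif kappa > 350:  # exp(-2k) underflows; exact in that regime
        w = 1.0 + math.log(u) / kappa if u > 0 else -1.0
    else:
        w = 1.0 + math.log(u + (1 - u) * math.exp(-2 * kappa)) / kappa
    w = min(1.0, max(-1.0, w))
    # orthonormal basis around mu
    a = np.array([1.0, 0.0, 0.0]) if abs(mu[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(mu, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mu, e1)
    phi = rng.uniform(0, 2 * math.pi)
    s = math.sqrt(max(0.0, 1 - w * w))
    return w * mu + s * (math.cos(phi) * e1 + math.sin(phi) * e2)


def _branch_tortuosity_sim(
    kappa: float, step: float, mean_branch_len: float, n_branches: int = 160
) -> float:
    rng = np.random.default_rng(733)
    torts = []
    for _ in range(n_branches):
        length = rng.gamma(BRANCH_LEN_SHAPE, mean_branch_len / BRANCH_LEN_SHAPE)
        n_steps = max(1, int(round(length / step)))
        d = np.array([1.0, 0.0, 0.0])
        pos = np.zeros(3)
        length = 0.0
        for _ in range(n_steps):
            d = _sample_vmf(rng, d, kappa)
            pos = pos + step * d
            length += step
        chord = float(np.linalg.norm(pos))
        if chord > 0:
            torts.append(length / chord)
    return float(np.mean(torts))


@lru_cache(maxsize=64)
def _calibrate_kappa(
    tortuosity_target: float, step: float, mean_branch_len: float
) -> float:
    """Bisection on vMF concentration to hit the branch tortuosity target.

    The calibration is a deterministic function of the target and branch
    geometry (its internal Monte Carlo uses a fixed stream), so it is
    cached across generator calls.
    """
    if tortuosity_target <= 1.0 + 1e-9:
        return math.inf
    lo, hi = 0.5, 2e5  # tortuosity decreasing in kappa
    for _ in range(30):
        mid = math.sqrt(lo * hi)
        t = _branch_tortuosity_sim(mid, step, mean_branch_len)
        if t > tortuosity_target:
            lo = mid
        else:
            hi = mid
        if abs(t - tortuosity_target) < 0.002:
            break
    return math.sqrt(lo * hi)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1 - 2 * (i + 0.5) / n
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def gen_neuron(spec: NeuronSpec) -> NeuronMorphology:
    """Grow a neuron morphology matching the spec's morphometric targets."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    kappa = _calibrate_kappa(spec.tortuosity_target, spec.step, spec.mean_branch_len)
    semi = np.array([spec.soma_dims[1], spec.soma_dims[0], spec.soma_dims[2]]) / 2.0

    ids, types, xyz, radius, parent = [], [], [], [], []

    def add(node_type, pos, rad, par):
        nid = len(ids) + 1
        ids.append(nid)
        types.append(node_type)
        xyz.append(np.asarray(pos, dtype=float))
        radius.append(rad)
        parent.append(par)
        return nid

    root = add(SOMA_TYPE, np.zeros(3), float(np.mean(semi)), -1)
    for p in _fibonacci_sphere(40):
        add(SOMA_TYPE, p * semi, 0.5, root)

    # stem directions: random but mutually separated
    dirs: list[np.ndarray] = []
    while len(dirs) < spec.n_stems:
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        if all(float(d @ e) < math.cos(math.radians(40)) for e in dirs) or len(
            dirs
        ) >= 12:
            dirs.append(d)

    # bifurcation budget: Poisson with the branching-process mean, then
    # distributed over a uniformly random recursive binary forest (each
    # split lands on a uniformly chosen open tip)
    p_b = spec.bifurcation_rate * spec.mean_branch_len
    lam = spec.n_stems * p_b / (1.0 - 2.0 * p_b) if p_b > 0 else 0.0
    n_bifs = int(rng.poisson(lam)) if lam > 0 else 0
    n_slots = spec.n_stems
    child_slots: dict[int, tuple[int, int]] = {}
    open_tips = list(range(n_slots))
    for _ in range(n_bifs):
        slot = open_tips.pop(int(rng.integers(len(open_tips))))
        child_slots[slot] = (n_slots, n_slots + 1)
        open_tips.extend([n_slots, n_slots + 1])
        n_slots += 2

    # branch queue: (start position, direction, radius, parent node id, slot)
    queue = [
        [np.array(semi * d, dtype=float), d, spec.stem_radius, root, k]
        for k, d in enumerate(dirs[: spec.n_stems])
    ]
    while queue:
        pos, d, rad, par, slot = queue.pop(0)
        length = rng.gamma(BRANCH_LEN_SHAPE, spec.mean_branch_len / BRANCH_LEN_SHAPE)
        n_steps = max(1, int(round(length / spec.step)))
        nid = par
        truncated = False
        for _ in range(n_steps):
            if len(ids) > 2 * 10**5:
                raise RuntimeError("runaway growth; node budget exceeded")
            if not math.isinf(kappa):
                d = _sample_vmf(rng, d, kappa)
            pos = pos + spec.step * d
            nid = add(DENDRITE_TYPE, pos, rad, nid)
            if float(np.linalg.norm(pos)) > spec.max_extent:
                truncated = True
                break
        if slot in child_slots and not truncated:
            child_rad = max(0.15, 0.8 * rad)
            axis = np.cross(d, rng.standard_normal(3))
            axis /= np.linalg.norm(axis)
            half = math.radians(rng.normal(30.0, 5.0))
            for child, sign in zip(child_slots[slot], (+1, -1)):
                rot = _rotate(d, axis, sign * half)
                queue.append(
                    [pos + spec.step * rot, rot, child_rad, nid, child]
                )
    return NeuronMorphology(
        ids=np.array(ids),
        types=np.array(types),
        xyz=np.vstack(xyz),
        radius=np.array(radius),
        parent=np.array(parent),
    )


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    c, s = math.cos(angle), math.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * float(axis @ v) * (1 - c)
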