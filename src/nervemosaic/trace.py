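"""Automated nerve tracing and nerve fiber length density (CNFL).

Tracing follows the classic curvilinear-structure recipe: enhance nerve
visibility with a bank of log-Gabor filters (maximum response over
orientations and scales), threshold the response with hysteresis to get
candidate string-like segments, skeletonize and split the skeleton into
branchless centerline polylines, then classify each candidate as nerve or
"other" with an RBF support-vector machine on simple geometric and
photometric features.

Densities: mCNFL is the total traced centerline length (mm) divided by the
effective mosaic area (mm²); wCNFL is the same quantity restricted to an
800 μm-diameter disc centered on the expert-identified whorl origin,
counting only covered disc pixels toward the area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.fft import fft2, ifft2
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Point, box
from skimage.filters import apply_hysteresis_threshold
from skimage.morphology import skeletonize
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io_formats import Frame, Tracing, TracingSource
from .mosaic import Mosaic
from .synth import PhantomSpec, generate_scene, polyline_length

FEATURE_NAMES = (
    "length_px", "mean_intensity", "sd_intensity", "local_contrast",
    "mean_curvature", "width_px", "mean_response", "sd_response",
)


class Region(str, Enum):
    WHOLE_MOSAIC = "whole_mosaic"
    WHORL = "whorl"


class Label(str, Enum):
    NERVE = "nerve"
    OTHER = "other"
    UNLABELED = "unlabeled"


@dataclass
class FilterBankConfig:
    """Log-Gabor bank parameters.

    Center wavelengths default to 2–6× the expected 3-px nerve width at
    the native scale; ``sigma_f`` is the radial bandwidth parameter
    (ratio form, ~2 octaves) and the angular spread scales with the
    number of orientations."""

    n_orientations: int = 8
    wavelengths_px: tuple[float, ...] = (6.0, 12.0, 18.0)
    sigma_f_ratio: float = 0.65
    angular_spread: float = 1.2

    def __post_init__(self) -> None:
        if self.n_orientations < 1:
            raise ValueError("filter bank needs at least one orientation")
        if not self.wavelengths_px:
            raise ValueError("filter bank needs at least one wavelength")


@dataclass
class ThresholdConfig:
    """Hysteresis thresholding of the normalized response.

    Thresholds are anchored to a robust response maximum (the
    ``norm_percentile`` percentile of in-coverage response), which makes
    them insensitive to mosaic size and background level."""

    norm_percentile: float = 99.5
    high_frac: float = 0.55
    low_frac: float = 0.35
    min_length_px: float = 12.0


@dataclass
class SVMConfig:
    C: float = 2.0
    gamma: str | float = "scale"


@dataclass
class TraceConfig:
    bank: FilterBankConfig = field(default_factory=FilterBankConfig)
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    tile_size: int = 0       # 0 = no tiling
    tile_overlap: int = 96


@dataclass
class CandidateSegment:
    """A thresholded string-like structure, candidate nerve centerline."""

    polyline: np.ndarray
    mean_response: float
    features: np.ndarray
    label: Label = Label.UNLABELED


# ---------------------------------------------------------------------------
# enhancement
# ---------------------------------------------------------------------------

def _log_gabor_filters(shape: tuple[int, int], config: FilterBankConfig) -> list[np.ndarray]:
    rows, cols = shape
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    radius = np.hypot(fx, fy)
    radius[0, 0] = 1.0  # avoid log(0); DC is zeroed below
    theta = np.arctan2(fy, fx)
    filters = []
    sigma_theta = config.angular_spread * np.pi / config.n_orientations
    for wav in config.wavelengths_px:
        f0 = 1.0 / wav
        radial = np.exp(-(np.log(radius / f0) ** 2)
                        / (2.0 * np.log(config.sigma_f_ratio) ** 2))
        radial[0, 0] = 0.0
        for o in range(config.n_orientations):
            theta0 = o * np.pi / config.n_orientations
            # angular distance folded to the line orientation (period π)
            d = np.angle(np.exp(2j * (theta - theta0))) / 2.0
            angular = np.exp(-(d ** 2) / (2.0 * sigma_theta ** 2))
            filters.append(radial * angular)
    return filters


def enhance_nerves(image: np.ndarray | Mosaic,
                   config: FilterBankConfig | None = None) -> np.ndarray:
    """Per-pixel maximum even-symmetric log-Gabor response.

    Bright ridges produce strong positive responses in the filter
    oriented along them; the response is clipped at zero and zeroed
    outside mosaic coverage."""
    config = config or FilterBankConfig()
    if isinstance(image, Mosaic):
        coverage = image.coverage_mask
        img = np.where(coverage, np.nan_to_num(image.pixels, nan=0.0), 0.0)
    else:
        img = np.nan_to_num(np.asarray(image, dtype=float), nan=0.0)
        coverage = None
    img = img - img.mean()
    F = fft2(img)
    response = np.zeros(img.shape)
    for filt in _log_gabor_filters(img.shape, config):
        even = ifft2(F * filt).real
        np.maximum(response, even, out=response)
    response = np.clip(response, 0.0, None)
    if coverage is not None:
        response[~coverage] = 0.0
    return response


# ---------------------------------------------------------------------------
# candidate extraction
# ---------------------------------------------------------------------------

_NEIGH8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_polylines(skel: np.ndarray) -> list[np.ndarray]:
    """Split a skeleton into branchless (x, y) polylines at junctions.

    Redundant diagonal links (a diagonal step whose two orthogonal
    detours are also skeleton pixels) are pruned so junction degrees are
    not inflated."""
    ys, xs = np.nonzero(skel)
    coords = list(zip(ys.tolist(), xs.tolist()))
    index = {c: k for k, c in enumerate(coords)}
    adj: dict[int, set[int]] = {k: set() for k in range(len(coords))}
    on = set(coords)
    for (y, x) in coords:
        k = index[(y, x)]
        for dy, dx in _NEIGH8:
            n = (y + dy, x + dx)
            if n not in on:
                continue
            if dy and dx and (((y + dy, x) in on) or ((y, x + dx) in on)):
                continue  # redundant diagonal
            adj[k].add(index[n])
            adj[index[n]].add(k)

    deg = {k: len(v) for k, v in adj.items()}
    polylines: list[np.ndarray] = []
    visited_edges: set[tuple[int, int]] = set()

    def walk(start: int, nxt: int) -> list[int]:
        path = [start, nxt]
        prev, cur = start, nxt
        while deg[cur] == 2:
            a, b = tuple(adj[cur])
            nxt2 = b if a == prev else a
            if nxt2 == path[0] and deg[nxt2] == 2:
                break  # pure cycle closes
            path.append(nxt2)
            prev, cur = cur, nxt2
        return path

    nodes = [k for k, d in deg.items() if d != 2]
    for start in nodes:
        for nxt in adj[start]:
            e = (min(start, nxt), max(start, nxt))
            if e in visited_edges:
                continue
            path = walk(start, nxt)
            for a, b in zip(path[:-1], path[1:]):
                visited_edges.add((min(a, b), max(a, b)))
            if len(path) >= 2:
                polylines.append(np.array([(coords[k][1], coords[k][0])
                                           for k in path], dtype=float))
    # remaining pure cycles (every node degree 2)
    seen = {k for poly in polylines for k in ()}
    touched = set()
    for a, b in visited_edges:
        touched.add(a)
        touched.add(b)
    for k in adj:
        if k in touched or deg[k] != 2:
            continue
        path = walk(k, next(iter(adj[k])))
        for a, b in zip(path[:-1], path[1:]):
            visited_edges.add((min(a, b), max(a, b)))
            touched.add(a)
            touched.add(b)
        touched.add(path[-1])
        if len(path) >= 2:
            polylines.append(np.array([(coords[i][1], coords[i][0])
                                       for i in path], dtype=float))
    return polylines


def _segment_features(poly: np.ndarray, intensity: np.ndarray,
                      response: np.ndarray, width_map: np.ndarray) -> np.ndarray:
    xs = np.clip(poly[:, 0].astype(int), 0, intensity.shape[1] - 1)
    ys = np.clip(poly[:, 1].astype(int), 0, intensity.shape[0] - 1)
    ivals = intensity[ys, xs]
    rvals = response[ys, xs]
    wvals = width_map[ys, xs]
    length = polyline_length(poly)
    d = np.diff(poly, axis=0)
    if len(d) >= 2:
        ang = np.arctan2(d[:, 1], d[:, 0])
        turn = np.abs(np.angle(np.exp(1j * np.diff(ang))))
        curvature = float(turn.mean())
    else:
        curvature = 0.0
    y0, y1 = ys.min(), ys.max()
    x0, x1 = xs.min(), xs.max()
    pad = 6
    patch = intensity[max(0, y0 - pad):y1 + pad + 1, max(0, x0 - pad):x1 + pad + 1]
    contrast = float(ivals.mean() - np.median(patch)) if patch.size else 0.0
    return np.array([
        length, float(ivals.mean()), float(ivals.std()), contrast,
        curvature, float(2.0 * wvals.mean()), float(rvals.mean()),
        float(rvals.std()),
    ])


def extract_candidates(response: np.ndarray,
                       threshold_config: ThresholdConfig | None = None,
                       intensity: np.ndarray | None = None
                       ) -> list[CandidateSegment]:
    """Threshold → skeletonize → branchless centerline candidates.

    ``intensity`` (the mosaic pixels) feeds the photometric features; if
    omitted, the response itself is used."""
    cfg = threshold_config or ThresholdConfig()
    response = np.asarray(response, dtype=float)
    pos = response[response > 0]
    if pos.size == 0:
        return []
    norm = np.percentile(pos, cfg.norm_percentile)
    if norm <= 0:
        return []
    binary = apply_hysteresis_threshold(response, cfg.low_frac * norm,
                                        cfg.high_frac * norm)
    if not binary.any():
        return []
    skel = skeletonize(binary)
    width_map = distance_transform_edt(binary)
    if intensity is None:
        intensity = response
    intensity = np.nan_to_num(np.asarray(intensity, dtype=float), nan=0.0)
    candidates = []
    for poly in _skeleton_polylines(skel):
        if polyline_length(poly) < cfg.min_length_px:
            continue
        feats = _segment_features(poly, intensity, response, width_map)
        xs = np.clip(poly[:, 0].astype(int), 0, response.shape[1] - 1)
        ys = np.clip(poly[:, 1].astype(int), 0, response.shape[0] - 1)
        candidates.append(CandidateSegment(
            polyline=poly, mean_response=float(response[ys, xs].mean()),
            features=feats))
    return candidates


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def train_classifier(candidates: list[CandidateSegment],
                     svm_config: SVMConfig | None = None,
                     seed: int = 0) -> Pipeline:
    """Train the nerve/other SVM on labeled candidates.

    Features are standardized inside the returned pipeline; training is
    deterministic for a fixed seed."""
    cfg = svm_config or SVMConfig()
    labeled = [c for c in candidates if c.label != Label.UNLABELED]
    if not labeled:
        raise ValueError("no labeled candidates")
    X = np.vstack([c.features for c in labeled])
    y = np.array([c.label.value for c in labeled])
    if len(set(y)) < 2:
        raise ValueError("training set must contain both classes (nerve and other)")
    model = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel="rbf", C=cfg.C, gamma=cfg.gamma, random_state=seed)),
    ])
    model.fit(X, y)
    return model


def classify_segments(candidates: list[CandidateSegment],
                      model: Pipeline) -> list[CandidateSegment]:
    """Label every candidate nerve/other with a trained model."""
    if model is None:
        raise ValueError("untrained model")
    if not candidates:
        return []
    try:
        X = np.vstack([c.features for c in candidates])
        pred = model.predict(X)
    except Exception as exc:
        raise ValueError(f"model is not a trained classifier: {exc}") from exc
    out = []
    for c, lab in zip(candidates, pred):
        out.append(CandidateSegment(polyline=c.polyline,
                                    mean_response=c.mean_response,
                                    features=c.features, label=Label(lab)))
    return out


def label_candidates_by_truth(candidates: list[CandidateSegment],
                              truth_polylines_px: list[np.ndarray],
                              tol_px: float = 3.0,
                              min_frac: float = 0.8) -> list[CandidateSegment]:
    """Label candidates against known nerve centerlines: nerve iff at
    least ``min_frac`` of a candidate's points lie within ``tol_px`` of a
    true centerline (used to build synthetic training corpora)."""
    pts = []
    for poly in truth_polylines_px:
        poly = np.asarray(poly, float)
        for (x0, y0), (x1, y1) in zip(poly[:-1], poly[1:]):
            n = max(int(np.hypot(x1 - x0, y1 - y0)), 1)
            t = np.linspace(0.0, 1.0, n + 1)
            pts.append(np.column_stack([x0 + t * (x1 - x0), y0 + t * (y1 - y0)]))
    tree = cKDTree(np.vstack(pts)) if pts else None
    out = []
    for c in candidates:
        if tree is None:
            lab = Label.OTHER
        else:
            d, _ = tree.query(c.polyline)
            lab = Label.NERVE if (d <= tol_px).mean() >= min_frac else Label.OTHER
        out.append(CandidateSegment(polyline=c.polyline,
                                    mean_response=c.mean_response,
                                    features=c.features, label=lab))
    return out


def make_training_candidates(seed: int = 1234, n_scenes: int = 2,
                             config: TraceConfig | None = None
                             ) -> list[CandidateSegment]:
    """Generate a labeled training corpus from phantom scenes.

    Scenes are rendered with elevated noise so that thresholding also
    picks up spurious string-like background structures, giving the
    'other' class real members."""
    config = config or TraceConfig()
    lowcfg = ThresholdConfig(
        norm_percentile=config.threshold.norm_percentile,
        high_frac=config.threshold.high_frac * 0.5,
        low_frac=config.threshold.low_frac * 0.5,
        min_length_px=config.threshold.min_length_px,
    )
    rng = np.random.default_rng(seed)
    out: list[CandidateSegment] = []
    for s in range(n_scenes):
        spec = PhantomSpec(frame_grid=(3, 3), n_nerves=10,
                           seed=int(rng.integers(0, 2**31 - 1)))
        scene, truth = generate_scene(spec)
        noisy = np.clip(scene + rng.normal(0.0, 0.05, scene.shape), 0.0, 1.0)
        response = enhance_nerves(noisy, config.bank)
        cands = extract_candidates(response, lowcfg, intensity=noisy)
        truth_px = [np.asarray(p) / spec.microns_per_pixel
                    for p in truth.nerve_polylines]
        out.extend(label_candidates_by_truth(cands, truth_px))
    return out


# ---------------------------------------------------------------------------
# tracing driver
# ---------------------------------------------------------------------------

def _trace_array(img: np.ndarray, model, config: TraceConfig
                 ) -> list[np.ndarray]:
    response = enhance_nerves(img, config.bank)
    cands = extract_candidates(response, config.threshold, intensity=img)
    if model is not None:
        cands = classify_segments(cands, model)
        cands = [c for c in cands if c.label == Label.NERVE]
    return [c.polyline for c in cands]


def auto_trace(mosaic: Mosaic | Frame, model=None,
               config: TraceConfig | None = None) -> Tracing:
    """Fully automatic nerve tracing of a mosaic (or a single frame).

    With ``tile_size`` set, the image is processed in overlapping tiles
    and a segment is kept by the tile owning its midpoint, which keeps
    seams consistent.  ``model=None`` skips classification and keeps all
    candidates (useful for noise-free inputs and for bootstrapping a
    training set)."""
    config = config or TraceConfig()
    if isinstance(mosaic, Mosaic):
        img = np.where(mosaic.coverage_mask,
                       np.nan_to_num(mosaic.pixels, nan=0.0), 0.0)
        scale = mosaic.microns_per_pixel
    else:
        img = np.asarray(mosaic.pixels, dtype=float)
        scale = mosaic.microns_per_pixel

    H, W = img.shape
    ts = config.tile_size
    if ts and (H > ts or W > ts):
        ov = config.tile_overlap
        polylines: list[np.ndarray] = []
        y_starts = list(range(0, max(H - ov, 1), ts - ov))
        x_starts = list(range(0, max(W - ov, 1), ts - ov))
        for ty in y_starts:
            for tx in x_starts:
                y1 = min(ty + ts, H)
                x1 = min(tx + ts, W)
                tile = img[ty:y1, tx:x1]
                if not np.any(tile):
                    continue
                core_y0 = ty + (ov // 2 if ty > 0 else 0)
                core_x0 = tx + (ov // 2 if tx > 0 else 0)
                core_y1 = y1 - (ov // 2 if y1 < H else 0)
                core_x1 = x1 - (ov // 2 if x1 < W else 0)
                for poly in _trace_array(tile, model, config):
                    g = poly + np.array([tx, ty], dtype=float)
                    mid = g[len(g) // 2]
                    if core_x0 <= mid[0] < core_x1 and core_y0 <= mid[1] < core_y1:
                        polylines.append(g)
    else:
        polylines = _trace_array(img, model, config)

    polylines = [p for p in polylines if len(p) >= 2]
    return Tracing(polylines=polylines, microns_per_pixel=scale,
                   source=TracingSource.AUTO)


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

@dataclass
class DensityResult:
    """A nerve fiber length density: total length over analyzed area."""

    total_length_mm: float
    area_mm2: float
    density_mm_per_mm2: float
    region: Region
    tracing_source: TracingSource

    @classmethod
    def build(cls, total_length_mm: float, area_mm2: float, region: Region,
              source: TracingSource) -> "DensityResult":
        if area_mm2 <= 0:
            raise ValueError("area must be > 0")
        return cls(total_length_mm=total_length_mm, area_mm2=area_mm2,
                   density_mm_per_mm2=total_length_mm / area_mm2,
                   region=region, tracing_source=source)


def compute_density(tracing: Tracing, area_mm2: float) -> DensityResult:
    """mCNFL: traced length (mm) over effective area (mm²)."""
    return DensityResult.build(tracing.total_length_mm(), area_mm2,
                               Region.WHOLE_MOSAIC, tracing.source)


def clip_length_to_geometry(tracing: Tracing, geometry) -> float:
    """Total tracing length inside a shapely geometry, in mm."""
    total_px = 0.0
    for poly in tracing.polylines:
        ls = LineString(poly)
        inter = ls.intersection(geometry)
        if not inter.is_empty:
            total_px += inter.length
    return total_px * tracing.microns_per_pixel / 1000.0


WHORL_DIAMETER_UM = 800.0


def compute_whorl_density(tracing: Tracing, mosaic: Mosaic,
                          center_px: tuple[float, float],
                          exclusion_mask: np.ndarray | None = None
                          ) -> DensityResult:
    """wCNFL in the 800 μm-diameter disc around the whorl center.

    Only covered (and non-excluded) disc pixels count toward the area, so
    a partially covered disc is handled explicitly rather than
    underestimating density."""
    cx, cy = center_px
    H, W = mosaic.coverage_mask.shape
    ix, iy = int(round(cx)), int(round(cy))
    if not (0 <= ix < W and 0 <= iy < H) or not mosaic.coverage_mask[iy, ix]:
        raise ValueError("whorl center lies outside mosaic coverage")
    radius_px = (WHORL_DIAMETER_UM / 2.0) / mosaic.microns_per_pixel
    yy, xx = np.ogrid[:H, :W]
    disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px ** 2
    mask = disc & mosaic.coverage_mask
    if exclusion_mask is not None:
        mask &= ~np.asarray(exclusion_mask, dtype=bool)
    area = float(mask.sum()) * mosaic.microns_per_pixel ** 2 / 1e6
    circle = Point(cx, cy).buffer(radius_px, quad_segs=128)
    length = clip_length_to_geometry(tracing, circle)
    return DensityResult.build(length, area, Region.WHORL, tracing.source)


def clip_length_to_box(tracing: Tracing, x0: float, y0: float,
                       side_px: float) -> float:
    """Tracing length (mm) inside an axis-aligned square region."""
    return clip_length_to_geometry(tracing, box(x0, y0, x0 + side_px, y0 + side_px))
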