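"""Synthetic subbasal nerve plexus phantoms with full ground truth.

The generator emulates what the adaptive wide-field acquisition produces:
a scene containing bright curvilinear nerve fibers spiralling toward an
infero-central whorl on a low-contrast cellular background, raster-scanned
into overlapping 384×384 frames.  Each frame carries the acquisition
artifacts the mosaicking pipeline must undo — a smooth per-row horizontal
scan displacement (motion distortion), additive noise, and a subset of
frames blurred and attenuated to emulate lost focus (the consequence of
imaging depth stacks with some slices off the plexus).

Everything is deterministic given ``PhantomSpec.seed``; the truth object
records the exact nerve centerlines, frame positions and per-row
displacements so downstream recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from skimage.draw import line as draw_line

from .io_formats import DEFAULT_MICRONS_PER_PIXEL, FRAME_SIZE, Frame


@dataclass
class PhantomSpec:
    """Parameters of a synthetic acquisition.

    The defaults describe a small but realistic study condition: a 5×5
    raster at 40% overlap over a scene holding 14 nerves converging on a
    whorl, mild motion distortion and low noise.
    """

    canvas_size_um: tuple[float, float] | None = None  # auto: snug to the raster
    n_nerves: int = 14
    whorl_center_um: tuple[float, float] | None = None  # auto: infero-central
    tortuosity: float = 12.0          # μm, sinusoidal perturbation amplitude
    nerve_width_um: float = 3.0
    frame_grid: tuple[int, int] = (5, 5)   # rows × cols of raster positions
    frame_overlap_frac: float = 0.4
    motion_amplitude_px: float = 2.0  # peak per-row horizontal displacement
    noise_sigma: float = 0.02         # additive noise SD, fraction of range
    defocus_frames_frac: float = 0.2
    position_jitter_px: float = 4.0   # raster position jitter (manual scanning)
    defocus_blur_sigma_px: float = 2.5   # blur of the residual nerve signal
    defocus_nerve_gain: float = 0.25     # nerve visibility left out of focus
    seed: int = 0
    nerve_polylines_um: list | None = None  # explicit geometry override
    microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL

    def __post_init__(self) -> None:
        if not (0.0 <= self.frame_overlap_frac < 1.0):
            raise ValueError("frame_overlap_frac must be in [0, 1)")
        if self.frame_grid[0] < 1 or self.frame_grid[1] < 1:
            raise ValueError("frame_grid counts must be >= 1")
        if self.n_nerves < 0:
            raise ValueError("n_nerves must be >= 0")

    # raster geometry, in scene pixels --------------------------------------
    @property
    def step_px(self) -> int:
        return int(round(FRAME_SIZE * (1.0 - self.frame_overlap_frac)))

    @property
    def margin_px(self) -> int:
        return int(np.ceil(self.motion_amplitude_px + self.position_jitter_px)) + 4

    def required_canvas_px(self) -> tuple[int, int]:
        rows, cols = self.frame_grid
        h = (rows - 1) * self.step_px + FRAME_SIZE + 2 * self.margin_px
        w = (cols - 1) * self.step_px + FRAME_SIZE + 2 * self.margin_px
        return h, w

    def canvas_px(self) -> tuple[int, int]:
        req_h, req_w = self.required_canvas_px()
        if self.canvas_size_um is None:
            return req_h, req_w
        w_um, h_um = self.canvas_size_um
        h = int(round(h_um / self.microns_per_pixel))
        w = int(round(w_um / self.microns_per_pixel))
        if h < req_h or w < req_w:
            raise ValueError(
                f"canvas {w}x{h} px too small for a {self.frame_grid} raster at "
                f"{self.frame_overlap_frac:.0%} overlap (needs {req_w}x{req_h} px)"
            )
        return h, w


@dataclass
class PhantomTruth:
    """Ground truth of a phantom acquisition.

    Coordinates are scene microns unless suffixed ``_px`` (scene pixels).
    ``row_displacement_px[i][r]`` is the horizontal scan displacement applied
    to row *r* of frame *i+1* (1-based frame indices elsewhere).
    """

    nerve_polylines: list[np.ndarray]
    total_length_mm: float
    frame_positions_um: list[tuple[float, float]] = field(default_factory=list)
    row_displacement_px: list[np.ndarray] = field(default_factory=list)
    defocused: list[bool] = field(default_factory=list)
    #: (background, nerve-layer) images of the scene; set by generate_scene,
    #: used by acquire_frames to render out-of-focus frames, not serialized
    layers: tuple[np.ndarray, np.ndarray] | None = None
    microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL
    canvas_size_um: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    @property
    def frame_positions_px(self) -> np.ndarray:
        return np.asarray(self.frame_positions_um, dtype=float) / self.microns_per_pixel


def polyline_length(poly: np.ndarray) -> float:
    """Euclidean arc length of an (n, 2) polyline, in its own units."""
    poly = np.asarray(poly, dtype=float)
    if len(poly) < 2:
        return 0.0
    d = np.diff(poly, axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _clip_polyline_to_canvas(poly: np.ndarray, w_um: float, h_um: float) -> np.ndarray:
    inside = (poly[:, 0] >= 0) & (poly[:, 0] <= w_um) & (poly[:, 1] >= 0) & (poly[:, 1] <= h_um)
    if inside.all():
        return poly
    # keep the longest run of in-canvas points (nerves are generated to start
    # at the border, so this trims only numerical overshoot)
    idx = np.flatnonzero(inside)
    if len(idx) < 2:
        return poly[:0]
    splits = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, splits + 1)
    best = max(runs, key=len)
    return poly[best[0]: best[-1] + 1]


def _make_nerve_polylines(spec: PhantomSpec, rng: np.random.Generator,
                          w_um: float, h_um: float) -> list[np.ndarray]:
    """Nerve centerlines in scene-μm coordinates: fibers entering from the
    border and spiralling toward the whorl center, with sinusoidal
    tortuosity perpendicular to the path."""
    if spec.nerve_polylines_um is not None:
        return [np.asarray(p, dtype=float) for p in spec.nerve_polylines_um]
    if spec.n_nerves == 0:
        return []
    cx, cy = spec.whorl_center_um if spec.whorl_center_um is not None else (
        0.5 * w_um, 0.62 * h_um)
    polylines = []
    for k in range(spec.n_nerves):
        theta0 = 2.0 * np.pi * (k + rng.uniform(-0.25, 0.25)) / spec.n_nerves
        # radius at which this direction leaves the canvas
        c, s = np.cos(theta0), np.sin(theta0)
        r_edge = min(
            ((w_um - cx) / c if c > 0 else (-cx) / c) if abs(c) > 1e-9 else np.inf,
            ((h_um - cy) / s if s > 0 else (-cy) / s) if abs(s) > 1e-9 else np.inf,
        )
        r0 = min(r_edge, np.hypot(w_um, h_um))
        r_min = rng.uniform(25.0, 80.0)
        turn = rng.uniform(0.8, 2.2) * rng.choice([-1.0, 1.0])
        n_pts = max(int((r0 - r_min) / 3.0), 8)
        t = np.linspace(0.0, 1.0, n_pts)
        r = r0 + (r_min - r0) * t
        phi = theta0 + turn * t**1.5
        x = cx + r * np.cos(phi)
        y = cy + r * np.sin(phi)
        # tortuosity: perpendicular sinusoid, random phase and frequency
        freq = rng.uniform(2.0, 5.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        wob = spec.tortuosity * np.sin(2.0 * np.pi * freq * t + phase)
        dx = np.gradient(x)
        dy = np.gradient(y)
        norm = np.hypot(dx, dy)
        norm[norm == 0] = 1.0
        x = x + wob * (-dy / norm)
        y = y + wob * (dx / norm)
        poly = _clip_polyline_to_canvas(np.column_stack([x, y]), w_um, h_um)
        if len(poly) >= 2:
            polylines.append(poly)
    return polylines


def generate_scene(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Render the wide-field scene and return it with its ground truth.

    The scene is a float image in [0, 1] at the native frame scale
    (400/384 μm/px); the truth polylines are exactly the rendered
    centerlines, in scene microns.
    """
    rng = np.random.default_rng([spec.seed, 0])
    h_px, w_px = spec.canvas_px()
    scale = spec.microns_per_pixel
    w_um, h_um = w_px * scale, h_px * scale

    polylines = _make_nerve_polylines(spec, rng, w_um, h_um)

    # rasterize centerlines at 1 px, then blur to the nerve width
    ridge = np.zeros((h_px, w_px), dtype=float)
    for poly in polylines:
        gain = rng.uniform(0.7, 1.0)  # per-nerve reflectivity variation
        pts_px = np.round(poly / scale).astype(int)
        pts_px[:, 0] = np.clip(pts_px[:, 0], 0, w_px - 1)
        pts_px[:, 1] = np.clip(pts_px[:, 1], 0, h_px - 1)
        for (x0, y0), (x1, y1) in zip(pts_px[:-1], pts_px[1:]):
            rr, cc = draw_line(y0, x0, y1, x1)
            ridge[rr, cc] = np.maximum(ridge[rr, cc], gain)
    width_sigma = max(spec.nerve_width_um / scale / 2.355, 0.6)
    nerves = gaussian_filter(ridge, width_sigma)
    if nerves.max() > 0:
        nerves = nerves / nerves.max() * 0.75

    # background: low-contrast cell-mosaic texture (basal epithelial cells
    # are visible throughout real SBP images and are what anchors
    # registration in nerve-free regions)
    fine = gaussian_filter(rng.standard_normal((h_px, w_px)), 3.0)
    coarse = gaussian_filter(rng.standard_normal((h_px, w_px)), 8.0)
    bg = 0.12 + 0.05 * fine / max(fine.std(), 1e-12) \
        + 0.03 * coarse / max(coarse.std(), 1e-12)
    scene = np.clip(bg + nerves, 0.0, 1.0)

    total_mm = sum(polyline_length(p) for p in polylines) / 1000.0
    truth = PhantomTruth(
        nerve_polylines=polylines,
        total_length_mm=total_mm,
        layers=(bg, nerves),
        microns_per_pixel=scale,
        canvas_size_um=(w_um, h_um),
        seed=spec.seed,
    )
    return scene, truth


def _row_displacement(rng: np.random.Generator, amplitude: float) -> np.ndarray:
    """Smooth per-row horizontal displacement: a low-pass filtered random
    walk rescaled to the requested peak amplitude.  The smoothing scale
    (30 rows) keeps the curve representable by a spline through 12
    stripe anchors spaced 32 rows apart."""
    if amplitude == 0:
        return np.zeros(FRAME_SIZE)
    walk = np.cumsum(rng.standard_normal(FRAME_SIZE))
    walk = gaussian_filter1d(walk, 30.0, mode="nearest")
    walk -= walk.mean()
    peak = np.abs(walk).max()
    if peak < 1e-12:
        return np.zeros(FRAME_SIZE)
    return walk * (amplitude / peak)


def _sample_frame(src: np.ndarray, px: int, py: int, disp: np.ndarray) -> np.ndarray:
    w_px = src.shape[1]
    xs = np.arange(FRAME_SIZE, dtype=float)
    grid = np.arange(w_px, dtype=float)
    img = np.empty((FRAME_SIZE, FRAME_SIZE), dtype=float)
    for r in range(FRAME_SIZE):
        img[r] = np.interp(px + disp[r] + xs, grid, src[py + r])
    return img


def _defocus_scene(scene: np.ndarray, truth: PhantomTruth,
                   spec: PhantomSpec) -> np.ndarray:
    """What a non-depth-corrected acquisition sees when the focal plane
    misses the thin plexus: the epithelial cell layer stays sharp while
    nerves are reduced to a faint blurred remnant."""
    if truth.layers is not None:
        bg, nerves = truth.layers
        return np.clip(bg + spec.defocus_nerve_gain
                       * gaussian_filter(nerves, spec.defocus_blur_sigma_px),
                       0.0, 1.0)
    return gaussian_filter(scene, spec.defocus_blur_sigma_px) * spec.defocus_nerve_gain


def acquire_frames(scene: np.ndarray, truth: PhantomTruth,
                   spec: PhantomSpec) -> list[Frame]:
    """Raster-scan the scene into the depth-corrected frame sequence.

    These are the frames that feed mosaicking: adaptive depth correction
    found the plexus at every position, so all frames are in focus (as in
    the published workflow, where incorrectly focused images are excluded
    before mosaicking).  *truth* is updated in place with the actual
    frame positions, per-row displacements, and the per-position defocus
    flags that apply to the *raw* (non-depth-corrected) acquisition, see
    :func:`acquire_raw_frames`."""
    rng = np.random.default_rng([spec.seed, 1])
    h_px, w_px = scene.shape
    rows, cols = spec.frame_grid
    step, margin = spec.step_px, spec.margin_px
    scale = spec.microns_per_pixel

    n = rows * cols
    n_defocus = int(round(spec.defocus_frames_frac * n))
    defocus_idx = set(rng.choice(n, size=n_defocus, replace=False).tolist()) if n_defocus else set()

    truth.frame_positions_um = []
    truth.row_displacement_px = []
    truth.defocused = []
    frames: list[Frame] = []
    i = 0
    for gr in range(rows):
        for gc in range(cols):
            jx = rng.uniform(-spec.position_jitter_px, spec.position_jitter_px)
            jy = rng.uniform(-spec.position_jitter_px, spec.position_jitter_px)
            px = int(round(np.clip(margin + gc * step + jx, 0, w_px - FRAME_SIZE)))
            py = int(round(np.clip(margin + gr * step + jy, 0, h_px - FRAME_SIZE)))
            disp = _row_displacement(rng, spec.motion_amplitude_px)
            img = _sample_frame(scene, px, py, disp)
            if spec.noise_sigma > 0:
                img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
            img = np.clip(img, 0.0, 1.0)
            i += 1
            frames.append(Frame(pixels=img, index=i, microns_per_pixel=scale,
                                source_id=f"phantom_{i:03d}"))
            truth.frame_positions_um.append((px * scale, py * scale))
            truth.row_displacement_px.append(disp)
            truth.defocused.append((i - 1) in defocus_idx)
    return frames


def acquire_raw_frames(scene: np.ndarray, truth: PhantomTruth,
                       spec: PhantomSpec) -> list[Frame]:
    """Single raw (non-depth-corrected) images at the acquired positions.

    Without real-time depth correction, ``defocus_frames_frac`` of the
    positions miss the plexus and show the epithelial layer instead
    (flagged in ``truth.defocused``); the rest match the depth-corrected
    frames up to an independent noise draw.  Positions and per-row
    displacements are reused from *truth*, so call
    :func:`acquire_frames` first."""
    if not truth.frame_positions_um:
        raise ValueError("truth carries no positions; run acquire_frames first")
    rng = np.random.default_rng([spec.seed, 2])
    scale = spec.microns_per_pixel
    off_plexus = _defocus_scene(scene, truth, spec)
    frames: list[Frame] = []
    for i, ((px_um, py_um), disp, off) in enumerate(
            zip(truth.frame_positions_um, truth.row_displacement_px,
                truth.defocused), start=1):
        px = int(round(px_um / scale))
        py = int(round(py_um / scale))
        img = _sample_frame(off_plexus if off else scene, px, py, disp)
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
        img = np.clip(img, 0.0, 1.0)
        frames.append(Frame(pixels=img, index=i, microns_per_pixel=scale,
                            source_id=f"phantom_raw_{i:03d}"))
    return frames


def generate_phantom_sequence(spec: PhantomSpec) -> tuple[list[Frame], PhantomTruth, np.ndarray]:
    """Convenience wrapper: scene + acquisition in one call."""
    scene, truth = generate_scene(spec)
    frames = acquire_frames(scene, truth, spec)
    return frames, truth, scene


# ---------------------------------------------------------------------------
# truth (de)serialization
# ---------------------------------------------------------------------------

def save_truth(truth: PhantomTruth, path: str | Path, spec: PhantomSpec | None = None) -> Path:
    path = Path(path)
    payload = {
        "nerve_polylines_um": [p.tolist() for p in truth.nerve_polylines],
        "total_length_mm": truth.total_length_mm,
        "frame_positions_um": [list(p) for p in truth.frame_positions_um],
        "row_displacement_px": [d.tolist() for d in truth.row_displacement_px],
        "defocused": list(truth.defocused),
        "microns_per_pixel": truth.microns_per_pixel,
        "canvas_size_um": list(truth.canvas_size_um),
        "seed": truth.seed,
    }
    if spec is not None:
        spec_d = asdict(spec)
        if spec_d.get("nerve_polylines_um") is not None:
            spec_d["nerve_polylines_um"] = [np.asarray(p).tolist()
                                            for p in spec_d["nerve_polylines_um"]]
        payload["spec"] = spec_d
    path.write_text(json.dumps(payload))
    return path


def load_truth(path: str | Path) -> PhantomTruth:
    d = json.loads(Path(path).read_text())
    return PhantomTruth(
        nerve_polylines=[np.asarray(p, dtype=float) for p in d["nerve_polylines_um"]],
        total_length_mm=d["total_length_mm"],
        frame_positions_um=[tuple(p) for p in d["frame_positions_um"]],
        row_displacement_px=[np.asarray(p, dtype=float) for p in d["row_displacement_px"]],
        defocused=list(d.get("defocused", [])),
        microns_per_pixel=d["microns_per_pixel"],
        canvas_size_um=tuple(d["canvas_size_um"]),
        seed=d.get("seed", 0),
    )
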