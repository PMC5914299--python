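"""Wide-field mosaic assembly with scan-motion distortion correction.

The registration model: each 384-row frame ``I_i`` is cut into 12 equal
horizontal stripes.  Because a raster-scanned confocal image is built row
by row, eye motion during the scan displaces individual rows laterally; a
stripe is narrow enough to be internally near-rigid, so stripe-wise phase
correlation between overlapping frames yields translation measurements
``u = p_(j,n) − p_(i,m)`` between the unknown mosaic positions of stripes.
All measurements are pooled into one sparse linear system and solved by
regularized least squares, with a discrete-curvature smoothness penalty
applied to the 12 stripe positions *within* each frame (never across
frames).  A cubic interpolating spline through the 12 per-frame anchors
then yields a mosaic position for every one of the 384 pixel rows; warping
rows to those positions undoes the motion distortion, and the mosaic is a
weighted average of the warped frames.

Frames whose validated matches do not connect them form separate
components and yield separate mosaics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.sparse as sp
import tifffile
from scipy.fft import fft2, ifft2
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter
from scipy.sparse.linalg import spsolve
from skimage.registration import phase_cross_correlation

from .io_formats import Frame

N_STRIPES = 12


@dataclass
class MosaicConfig:
    """Tunables of the mosaicking pipeline."""

    peak_threshold: float = 0.10      # validation cut on the stripe correlation peak
    regularization_weight: float = 0.1  # within-frame curvature penalty λ
    spacing_weight: float = 0.05      # weak prior toward nominal 32-px stripe spacing
    min_pair_matches: int = 3         # stripe matches needed before a pair links frames
    prefilter: bool = False           # optional coarse skip of non-overlapping pairs
    prefilter_downsample: int = 4
    prefilter_threshold: float = 0.10
    min_col_overlap: int = 64         # minimum shared columns for a stripe correlation
    coarse_ncc_threshold: float = 0.50  # high-pass overlap NCC needed to trust a pair
    trim_thresholds: tuple[float, ...] = (8.0, 3.0, 1.0)  # robust solve outlier passes


@dataclass
class Stripe:
    """One of the 12 equal horizontal bands of a frame (m is 1-based)."""

    frame_index: int
    stripe_index: int
    pixel_rows: np.ndarray


@dataclass
class StripeMatch:
    """A validated translation measurement between two stripes.

    ``u`` is the difference of mosaic positions ``p_b − p_a`` in pixels
    (x, y); ``peak`` is the normalized phase-correlation maximum."""

    a: tuple[int, int]
    b: tuple[int, int]
    u: np.ndarray
    peak: float

    def reversed(self) -> "StripeMatch":
        return StripeMatch(a=self.b, b=self.a, u=-self.u, peak=self.peak)


@dataclass
class StripePositions:
    """Solved mosaic positions of every stripe, plus the frame partition
    into connected alignment components."""

    p: dict[tuple[int, int], np.ndarray]
    component_of: dict[int, int]
    residual_rms: float
    stripe_height: int = 32


@dataclass
class MotionCurve:
    """Mosaic position of every pixel row of one frame.

    ``row_positions[r]`` is the mosaic (x, y) of pixel (row r, col 0);
    pixel (r, c) maps to ``row_positions[r] + (c, 0)``."""

    frame_index: int
    row_positions: np.ndarray


@dataclass
class WarpedFrame:
    """A frame resampled into mosaic coordinates, as a weighted splat."""

    frame_index: int
    weighted_sum: np.ndarray
    weight_map: np.ndarray
    origin: np.ndarray  # mosaic coords of output pixel (0, 0)

    @property
    def valid(self) -> np.ndarray:
        return self.weight_map > 1e-9

    @property
    def image(self) -> np.ndarray:
        out = np.full_like(self.weighted_sum, np.nan)
        v = self.valid
        out[v] = self.weighted_sum[v] / self.weight_map[v]
        return out


@dataclass
class Mosaic:
    """A blended wide-field mosaic (one connected alignment component)."""

    pixels: np.ndarray
    weight_map: np.ndarray
    coverage_mask: np.ndarray
    microns_per_pixel: float
    contributing_frames: list[int]
    component_id: int = 0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(2))
    frame_origins: dict[int, np.ndarray] = field(default_factory=dict)
    residual_rms: float = 0.0

    @property
    def coverage_area_mm2(self) -> float:
        return mosaic_area_mm2(self)


# ---------------------------------------------------------------------------
# stripes and phase correlation
# ---------------------------------------------------------------------------

def decompose_into_stripes(frame: Frame) -> list[Stripe]:
    """Cut a frame into 12 equal horizontal stripes (m = 1..12)."""
    rows = frame.pixels.shape[0]
    if rows % N_STRIPES:
        raise ValueError(f"frame height {rows} not divisible by {N_STRIPES}")
    h = rows // N_STRIPES
    return [Stripe(frame.index, m + 1, frame.pixels[m * h:(m + 1) * h])
            for m in range(N_STRIPES)]


def _wrap(v: np.ndarray, n: int) -> np.ndarray:
    return np.where(v > n / 2, v - n, v)


def _subpixel_1d(r: np.ndarray, p: int, axis_len: int) -> float:
    c0 = r[(p - 1) % axis_len]
    c1 = r[p]
    c2 = r[(p + 1) % axis_len]
    denom = c0 - 2.0 * c1 + c2
    if abs(denom) < 1e-12:
        return 0.0
    d = 0.5 * (c0 - c2) / denom
    return float(np.clip(d, -0.5, 0.5))


def phase_correlate(a: np.ndarray, b: np.ndarray, pad: bool = False
                    ) -> tuple[np.ndarray, float]:
    """Estimate the translation taking *a* onto *b*.

    Returns ``(u, peak)`` with ``u = (u_x, u_y)`` such that the content of
    *a* appears in *b* displaced by ``u`` (``b ≈ roll(a, (u_y, u_x))`` for
    periodic content), refined to sub-pixel precision by a parabolic fit
    around the correlation maximum.  ``peak`` is the normalized
    phase-correlation maximum in [0, 1].  With ``pad=True`` both images
    are zero-padded to twice their size, which removes the ±size/2 wrap
    ambiguity at the cost of a spurious zero-lag component from the
    padded support (used only for the coarse prefilter).

    An all-constant input has no phase information: the result is then
    ``(nan, nan)`` with peak 0, and must not enter the solver.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    a = a - a.mean()
    b = b - b.mean()
    if not (np.any(a) and np.any(b)):
        return np.array([np.nan, np.nan]), 0.0
    if pad:
        M, N = a.shape
        ap = np.zeros((2 * M, 2 * N))
        bp = np.zeros((2 * M, 2 * N))
        ap[:M, :N] = a
        bp[:M, :N] = b
        a, b = ap, bp
    A = fft2(a)
    B = fft2(b)
    R = A.conj() * B
    mag = np.abs(R)
    R = np.where(mag > 1e-15, R / np.maximum(mag, 1e-15), 0.0)
    r = ifft2(R).real
    M, N = r.shape
    iy, ix = np.unravel_index(np.argmax(r), r.shape)
    peak = float(np.clip(r[iy, ix], 0.0, 1.0))
    dy = _subpixel_1d(r[:, ix], iy, M)
    dx = _subpixel_1d(r[iy, :], ix, N)
    uy = float(_wrap(np.array(iy + dy), M))
    ux = float(_wrap(np.array(ix + dx), N))
    return np.array([ux, uy]), peak


def local_ncc_shift(a: np.ndarray, b: np.ndarray, max_shift: int = 6
                    ) -> tuple[np.ndarray, float]:
    """Translation of *a*'s content onto *b* by exhaustive local search.

    Normalized cross-correlation is evaluated at every integer shift
    within ``±max_shift`` and refined by a parabolic fit; unlike FFT
    phase correlation on a small band, this has no circular-wrap
    artifacts, so it is the estimator of choice for small residual
    offsets.  Returns ``(u, score)`` with the same displacement
    convention as :func:`phase_correlate` and score = peak NCC."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    H, W = a.shape
    size = 2 * max_shift + 1
    surf = np.full((size, size), -1.0)
    for ky, dy in enumerate(range(-max_shift, max_shift + 1)):
        ay0, ay1 = max(0, -dy), min(H, H - dy)
        if ay1 - ay0 < 8:
            continue
        for kx, dx in enumerate(range(-max_shift, max_shift + 1)):
            ax0, ax1 = max(0, -dx), min(W, W - dx)
            if ax1 - ax0 < 8:
                continue
            av = a[ay0:ay1, ax0:ax1]
            bv = b[ay0 + dy:ay1 + dy, ax0 + dx:ax1 + dx]
            sa, sb = av.std(), bv.std()
            if sa == 0 or sb == 0:
                continue
            surf[ky, kx] = ((av - av.mean()) * (bv - bv.mean())).mean() / (sa * sb)
    ky, kx = np.unravel_index(np.argmax(surf), surf.shape)
    score = float(surf[ky, kx])
    if score <= -1.0:
        return np.array([np.nan, np.nan]), 0.0

    def para(vals, p):
        if p == 0 or p == size - 1:
            return 0.0
        c0, c1, c2 = vals[p - 1], vals[p], vals[p + 1]
        den = c0 - 2 * c1 + c2
        if abs(den) < 1e-12 or c0 < -1 or c2 < -1:
            return 0.0
        return float(np.clip(0.5 * (c0 - c2) / den, -0.5, 0.5))

    dy = (ky - max_shift) + para(surf[:, kx], ky)
    dx = (kx - max_shift) + para(surf[ky, :], kx)
    return np.array([dx, dy]), float(np.clip(score, 0.0, 1.0))


def select_pairs(n_frames: int) -> list[tuple[int, int]]:
    """All N(N−1)/2 unordered frame pairs (1-based, i < j).

    No acquisition pattern is assumed: every pair is a registration
    candidate."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    return list(combinations(range(1, n_frames + 1), 2))


def _block_mean(img: np.ndarray, k: int) -> np.ndarray:
    h, w = (img.shape[0] // k) * k, (img.shape[1] // k) * k
    return img[:h, :w].reshape(h // k, k, w // k, k).mean(axis=(1, 3))


def register_pair(frame_a: Frame, frame_b: Frame, config: MosaicConfig,
                  coarse: tuple[int, int] | None = None) -> list[StripeMatch]:
    """Stripe-level registration of one frame pair.

    A whole-frame phase correlation (or a caller-supplied estimate, e.g.
    from a previous global solve) supplies the coarse offset that decides
    which stripe of *b* each stripe of *a* overlaps and where to window
    it; each stripe is then correlated against its windowed counterpart,
    and matches whose peak clears the validation threshold become
    translation measurements."""
    A = np.asarray(frame_a.pixels, dtype=float)
    B = np.asarray(frame_b.pixels, dtype=float)
    rows, cols = A.shape
    h = rows // N_STRIPES

    if A.std() == 0 or B.std() == 0:
        return []
    if coarse is None:
        # coarse whole-frame offset; masked real-space scoring resolves the
        # periodic wrap ambiguity of the correlation peak
        shift, _err, _ = phase_cross_correlation(A, B, normalization="phase",
                                                 disambiguate=True)
        tx = int(round(-shift[1]))
        ty = int(round(-shift[0]))
    else:
        tx, ty = int(round(coarse[0])), int(round(coarse[1]))
    if abs(tx) >= cols or abs(ty) >= rows:
        return []

    # shared column range under the coarse horizontal offset
    ci0 = max(0, -tx)
    ci1 = min(cols, cols - tx)
    if ci1 - ci0 < config.min_col_overlap:
        return []
    cj0 = ci0 + tx

    # validate the coarse offset on the actual overlap: unrelated frames can
    # still produce phase peaks above threshold from low-frequency texture,
    # so the consistency check runs on high-pass content (structure, not
    # illumination)
    ri0 = max(0, -ty)
    ri1 = min(rows, rows - ty)
    if ri1 - ri0 < h:
        return []
    Ah = A - gaussian_filter(A, 8.0)
    Bh = B - gaussian_filter(B, 8.0)
    ov_a = Ah[ri0:ri1, ci0:ci1]
    ov_b = Bh[ri0 + ty:ri1 + ty, cj0:cj0 + (ci1 - ci0)]
    sa, sb = ov_a.std(), ov_b.std()
    if sa == 0 or sb == 0:
        return []
    ncc = float(((ov_a - ov_a.mean()) * (ov_b - ov_b.mean())).mean() / (sa * sb))
    if ncc < config.coarse_ncc_threshold:
        return []

    matches: list[StripeMatch] = []
    for m in range(1, N_STRIPES + 1):
        r0 = (m - 1) * h
        target = r0 + ty  # where this stripe's rows sit in frame b
        w0 = int(np.clip(target, 0, rows - h))
        if abs(w0 - target) > 2:  # clipped windows measure a shifted band: skip
            continue
        stripe = Ah[r0:r0 + h, ci0:ci1]
        wx0 = cj0
        width = ci1 - ci0
        # residual measured on high-pass content by local NCC search (no
        # circular-wrap bias); one re-window pass absorbs residuals larger
        # than the search radius allows to localize precisely
        u_r, peak = np.array([np.nan, np.nan]), 0.0
        for _ in range(2):
            window = Bh[w0:w0 + h, wx0:wx0 + width]
            u_r, peak = local_ncc_shift(stripe, window)
            if not np.isfinite(u_r).all():
                break
            ry, rx = int(round(u_r[1])), int(round(u_r[0]))
            if ry == 0 and rx == 0:
                break
            w0_new = int(np.clip(w0 + ry, 0, rows - h))
            wx0_new = int(np.clip(wx0 + rx, 0, cols - width))
            if (w0_new, wx0_new) == (w0, wx0):
                break
            w0, wx0 = w0_new, wx0_new
        if not np.isfinite(u_r).all() or peak < config.peak_threshold:
            continue
        if abs(u_r[1]) > h / 2 - 1:
            continue
        # displacement of the stripe's content in frame-b coordinates
        delta = np.array([(wx0 - ci0) + u_r[0], (w0 - r0) + u_r[1]])
        center_b = r0 + (h - 1) / 2.0 + delta[1]
        n = int(np.clip(center_b // h, 0, N_STRIPES - 1)) + 1
        # p_(j,n) − p_(i,m) from the measured content displacement
        u = np.array([-delta[0], h * (n - m) - delta[1]])
        matches.append(StripeMatch(a=(frame_a.index, m), b=(frame_b.index, n),
                                   u=u, peak=peak))
    return matches


def register_all(frames: list[Frame], config: MosaicConfig | None = None,
                 coarse_offsets: dict[tuple[int, int], tuple[int, int]] | None = None
                 ) -> list[StripeMatch]:
    """Register all frame pairs stripe-wise and return validated matches.

    Pairs contributing fewer than ``min_pair_matches`` validated stripe
    matches are dropped entirely, so a single spurious correlation peak
    cannot link unrelated frames.  ``coarse_offsets`` maps (rank_a,
    rank_b) to a known content displacement and restricts registration to
    those pairs (used for the refinement pass)."""
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to register")
    config = config or MosaicConfig()
    by_rank = {rank: f for rank, f in
               enumerate(sorted(frames, key=lambda f: f.index), start=1)}

    if coarse_offsets is not None:
        pair_list = [(a, b, coarse_offsets[(a, b)]) for a, b in sorted(coarse_offsets)]
    else:
        pairs = select_pairs(len(frames))
        if config.prefilter:
            small = {r: _block_mean(np.asarray(by_rank[r].pixels, float),
                                    config.prefilter_downsample)
                     for r in by_rank}
            pairs = [(a, b) for a, b in pairs
                     if phase_correlate(small[a], small[b],
                                        pad=True)[1] >= config.prefilter_threshold]
        pair_list = [(a, b, None) for a, b in pairs]

    matches: list[StripeMatch] = []
    for ra, rb, coarse in pair_list:
        pair_matches = register_pair(by_rank[ra], by_rank[rb], config,
                                     coarse=coarse)
        if len(pair_matches) >= config.min_pair_matches:
            matches.extend(pair_matches)
    return matches


def frame_offsets_from_positions(positions: StripePositions) -> dict[int, np.ndarray]:
    """Per-frame origin estimate: mean over stripes of
    ``p_(i,m) − (0, 32(m−1))``."""
    h = positions.stripe_height
    frames = sorted({i for (i, _m) in positions.p})
    return {i: np.mean([positions.p[(i, m)] - np.array([0.0, h * (m - 1)])
                        for m in range(1, N_STRIPES + 1)], axis=0)
            for i in frames}


def register_and_solve(frames: list[Frame], config: MosaicConfig | None = None
                       ) -> tuple[list[StripeMatch], StripePositions]:
    """Two-pass registration: detect, solve, then re-register every pair
    whose solved geometry predicts an overlap, and solve again.

    The refinement pass recovers pairs (small-overlap diagonal
    neighbors) whose coarse correlation failed in pass one, adding
    redundancy that tightens the global solution."""
    config = config or MosaicConfig()
    stripe_h = frames[0].pixels.shape[0] // N_STRIPES
    rows, cols = frames[0].pixels.shape

    def solve(mts):
        return solve_positions(mts, len(frames),
                               regularization_weight=config.regularization_weight,
                               spacing_weight=config.spacing_weight,
                               stripe_height=stripe_h,
                               trim_thresholds=config.trim_thresholds)

    matches = register_all(frames, config) if len(frames) > 1 else []
    positions = solve(matches)
    if len(frames) < 2:
        return matches, positions

    offsets = frame_offsets_from_positions(positions)
    coarse: dict[tuple[int, int], tuple[int, int]] = {}
    for a, b in select_pairs(len(frames)):
        if positions.component_of[a] != positions.component_of[b]:
            continue
        d = offsets[a] - offsets[b]  # content displacement a -> b
        if abs(d[0]) <= cols - config.min_col_overlap and abs(d[1]) <= rows - 2 * stripe_h:
            coarse[(a, b)] = (int(round(d[0])), int(round(d[1])))
    if coarse:
        refined = register_all(frames, config, coarse_offsets=coarse)
        # merge per pair: re-measured pairs replace pass-one results, pairs
        # only seen in pass one are kept
        by_pair: dict[tuple[int, int], list[StripeMatch]] = {}
        for mt in matches:
            by_pair.setdefault((mt.a[0], mt.b[0]), []).append(mt)
        refined_pairs: dict[tuple[int, int], list[StripeMatch]] = {}
        for mt in refined:
            refined_pairs.setdefault((mt.a[0], mt.b[0]), []).append(mt)
        by_pair.update(refined_pairs)
        merged = [mt for mts in by_pair.values() for mt in mts]
        if merged:
            positions = solve(merged)
            matches = merged
    return matches, positions


# ---------------------------------------------------------------------------
# global position solve
# ---------------------------------------------------------------------------

def solve_positions(matches: list[StripeMatch], n_frames: int,
                    regularization_weight: float = 1.0,
                    spacing_weight: float = 0.05,
                    stripe_height: int = 32,
                    trim_thresholds: tuple[float, ...] = (8.0, 3.0)
                    ) -> StripePositions:
    """Regularized least-squares solve of all stripe positions.

    Minimizes the match residuals ``‖(p_b − p_a) − u‖²`` together with a
    discrete-curvature penalty ``λ‖p_(i,m+1) − 2p_(i,m) + p_(i,m−1)‖²``
    applied independently within each frame, plus a weak prior toward the
    nominal 32-px vertical stripe spacing that fixes the within-frame
    gauge when a frame has no matches.  Disconnected frames are solved as
    separate components, each anchored with its lowest-index stripe
    (i, 1) at the origin.

    The solve is made robust by trimming: after each pass, matches whose
    residual exceeds the next threshold (px) are discarded and the system
    is re-solved, so a few spurious correlations cannot distort the
    global geometry.  Components are recomputed after trimming, since
    removing a pair's matches can split the graph.
    """
    current = list(matches)
    result = _solve_once(current, n_frames, regularization_weight,
                         spacing_weight, stripe_height)
    for thr in trim_thresholds:
        kept = [mt for mt in current
                if np.linalg.norm((result.p[mt.b] - result.p[mt.a]) - mt.u) <= thr]
        if len(kept) < len(current):
            current = kept
            result = _solve_once(current, n_frames, regularization_weight,
                                 spacing_weight, stripe_height)
    return result


def _solve_once(matches: list[StripeMatch], n_frames: int,
                regularization_weight: float, spacing_weight: float,
                stripe_height: int) -> StripePositions:
    graph = nx.Graph()
    graph.add_nodes_from(range(1, n_frames + 1))
    for match in matches:
        graph.add_edge(match.a[0], match.b[0])

    p: dict[tuple[int, int], np.ndarray] = {}
    component_of: dict[int, int] = {}
    sq_res, n_res = 0.0, 0
    components = sorted(nx.connected_components(graph), key=min)
    for cid, comp in enumerate(components):
        frames_c = sorted(comp)
        for i in frames_c:
            component_of[i] = cid
        idx = {(i, m): k for k, (i, m) in enumerate(
            (i, m) for i in frames_c for m in range(1, N_STRIPES + 1))}
        n_unk = len(idx)
        rows_a, cols_a, vals, rhs = [], [], [], []
        row = 0

        def add_eq(terms, b_vec, w):
            nonlocal row
            for coeff, k in terms:
                rows_a.append(row)
                cols_a.append(k)
                vals.append(coeff * w)
            rhs.append((np.asarray(b_vec, float) * w))
            row += 1

        comp_set = set(frames_c)
        comp_matches = [mt for mt in matches
                        if mt.a[0] in comp_set and mt.b[0] in comp_set]
        for mt in comp_matches:
            add_eq([(-1.0, idx[mt.a]), (1.0, idx[mt.b])], mt.u, 1.0)
        lam = regularization_weight
        mu = spacing_weight
        for i in frames_c:
            for m in range(2, N_STRIPES):
                add_eq([(1.0, idx[(i, m - 1)]), (-2.0, idx[(i, m)]),
                        (1.0, idx[(i, m + 1)])], (0.0, 0.0), lam)
            for m in range(1, N_STRIPES):
                add_eq([(-1.0, idx[(i, m)]), (1.0, idx[(i, m + 1)])],
                       (0.0, float(stripe_height)), mu)
        anchor = (frames_c[0], 1)
        add_eq([(1.0, idx[anchor])], (0.0, 0.0), 1e-3)

        A = sp.csr_matrix((vals, (rows_a, cols_a)), shape=(row, n_unk))
        b = np.vstack(rhs)
        sol = spsolve((A.T @ A).tocsc(), A.T @ b)
        sol = np.atleast_2d(np.asarray(sol))
        if sol.shape != (n_unk, 2):
            sol = sol.reshape(n_unk, 2)
        sol = sol - sol[idx[anchor]]  # exact gauge fix
        for key, k in idx.items():
            p[key] = sol[k].copy()
        for mt in comp_matches:
            r = (p[mt.b] - p[mt.a]) - mt.u
            sq_res += float(r @ r)
            n_res += 1

    rms = float(np.sqrt(sq_res / n_res)) if n_res else 0.0
    return StripePositions(p=p, component_of=component_of, residual_rms=rms,
                           stripe_height=stripe_height)


def _spline_rows(anchor_rows: np.ndarray, anchors: np.ndarray,
                 n_rows: int) -> np.ndarray:
    """Per-coordinate cubic interpolating spline through anchors, linear
    extrapolation beyond the end anchors, evaluated at every pixel row."""
    rows = np.arange(n_rows, dtype=float)
    out = np.empty((n_rows, 2))
    for c in range(2):
        spline = CubicSpline(anchor_rows, anchors[:, c])
        vals = spline(rows)
        d0 = float(spline(anchor_rows[0], 1))
        d1 = float(spline(anchor_rows[-1], 1))
        lo = rows < anchor_rows[0]
        hi = rows > anchor_rows[-1]
        vals[lo] = anchors[0, c] + d0 * (rows[lo] - anchor_rows[0])
        vals[hi] = anchors[-1, c] + d1 * (rows[hi] - anchor_rows[-1])
        out[:, c] = vals
    return out


def fit_motion_curves(positions: StripePositions, n_rows: int = 384
                      ) -> dict[int, MotionCurve]:
    """Cubic interpolating spline through each frame's 12 stripe anchors.

    Anchors sit at stripe-center rows (15.5, 47.5, …, 367.5); the spline
    is fitted separately per coordinate and evaluated at every pixel row,
    with linear extrapolation beyond the end anchors."""
    h = positions.stripe_height
    frames = sorted({i for (i, _m) in positions.p})
    anchor_rows = np.array([(m - 1) * h + (h - 1) / 2.0
                            for m in range(1, N_STRIPES + 1)])
    curves: dict[int, MotionCurve] = {}
    for i in frames:
        # anchor value: mosaic position of pixel (center row, col 0)
        anchors = np.array([positions.p[(i, m)] + np.array([0.0, (h - 1) / 2.0])
                            for m in range(1, N_STRIPES + 1)])
        curves[i] = MotionCurve(frame_index=i,
                                row_positions=_spline_rows(anchor_rows, anchors, n_rows))
    return curves


def refine_motion_curves(frames: list[Frame], curves: dict[int, MotionCurve],
                         config: MosaicConfig | None = None,
                         band_rows: int = 8, search: int = 4,
                         smoothness: float = 0.3, rigidity: float = 0.05,
                         tether: float = 1e-3, min_score: float = 0.25,
                         n_iter: int = 2) -> dict[int, MotionCurve]:
    """Fine-band bundle refinement of the per-frame motion curves.

    The 12-stripe system measures displacement averaged over 32-row
    bands, which blurs the within-frame scan-motion signal.  This pass
    re-measures every overlapping frame pair on ``band_rows``-row bands
    (using the current curves to predict where each band falls in the
    other frame), then re-solves all frame-origin curves jointly on a
    knot grid at band resolution with a second-difference smoothness
    penalty, a per-frame rigidity prior, and a weak tether to the
    current solution.

    The rigidity prior (deviation of each knot from the frame's mean
    position) is the datum that pins an otherwise unobservable gauge
    field: a smooth warp of the whole mosaic applied to every frame's
    curve leaves all pairwise measurements unchanged, and is resolved
    here by the physical assumption that scan displacement is zero-mean
    within a frame.  Frames are keyed by rank, as in
    :func:`register_and_solve`."""
    config = config or MosaicConfig()
    order = sorted(frames, key=lambda f: f.index)
    ranks = list(range(1, len(order) + 1))
    n_rows, n_cols = order[0].pixels.shape
    knot_rows = np.arange(band_rows / 2.0 - 0.5, n_rows, band_rows)
    n_knots = len(knot_rows)
    hp = {r: (lambda img: img - gaussian_filter(img, 8.0))(
        np.asarray(order[r - 1].pixels, dtype=float)) for r in ranks}

    def knot_weights(r: float) -> list[tuple[int, float]]:
        """Linear interpolation weights of row r on the knot grid."""
        if r <= knot_rows[0]:
            return [(0, 1.0)]
        if r >= knot_rows[-1]:
            return [(n_knots - 1, 1.0)]
        k = int(np.searchsorted(knot_rows, r) - 1)
        t = (r - knot_rows[k]) / (knot_rows[k + 1] - knot_rows[k])
        return [(k, 1.0 - t), (k + 1, t)]

    for _ in range(n_iter):
        g = {r: curves[r].row_positions
             - np.column_stack([np.zeros(n_rows), np.arange(n_rows, dtype=float)])
             for r in ranks}  # frame-origin curve q_i(r)
        # collect fine-band measurements for overlapping pairs
        rows_a, cols_a, vals, rhs = [], [], [], []
        neq = 0
        idx = {(r, k): (ranks.index(r) * n_knots + k) for r in ranks
               for k in range(n_knots)}
        n_unk = len(ranks) * n_knots

        def add(terms, b_vec, w):
            nonlocal neq
            for coeff, col in terms:
                rows_a.append(neq)
                cols_a.append(col)
                vals.append(coeff * w)
            rhs.append(np.asarray(b_vec, float) * w)
            neq += 1

        for ra, rb in combinations(ranks, 2):
            qa, qb = g[ra], g[rb]
            d_mean = (qa - qb).mean(axis=0)
            if abs(d_mean[0]) > n_cols - config.min_col_overlap or \
               abs(d_mean[1]) > n_rows - 2 * band_rows:
                continue
            A, B = hp[ra], hp[rb]
            for r0 in range(0, n_rows - band_rows + 1, band_rows):
                r1 = r0 + band_rows
                rc = (r0 + r1 - 1) / 2.0
                # predicted placement of this band inside frame b
                dy = qa[int(rc), 1] + rc - (qb[int(rc), 1] + rc)  # y offset
                rb0 = int(round(r0 + dy))
                if rb0 < 0 or rb0 + band_rows > n_rows:
                    continue
                dx = qa[int(rc), 0] - qb[min(max(rb0, 0), n_rows - 1), 0]
                tx = int(round(dx))
                ci0, ci1 = max(0, -tx), min(n_cols, n_cols - tx)
                if ci1 - ci0 < config.min_col_overlap:
                    continue
                band = A[r0:r1, ci0:ci1]
                win = B[rb0:rb0 + band_rows, ci0 + tx:ci1 + tx]
                u, score = local_ncc_shift(band, win, max_shift=search)
                if not np.isfinite(u).all() or score < min_score:
                    continue
                if abs(u[0]) >= search - 0.01 or abs(u[1]) >= search - 0.01:
                    continue  # peak on the search boundary: unreliable
                delta = np.array([tx + u[0], (rb0 - r0) + u[1]])
                rc_b = rc + delta[1]
                # g_a(rc) - g_b(rc_b) = delta
                terms = [(w, idx[(ra, k)]) for k, w in knot_weights(rc)]
                terms += [(-w, idx[(rb, k)]) for k, w in knot_weights(rc_b)]
                add(terms, delta, 1.0)

        # smoothness, rigidity datum and tether
        for r in ranks:
            for k in range(1, n_knots - 1):
                add([(1.0, idx[(r, k - 1)]), (-2.0, idx[(r, k)]),
                     (1.0, idx[(r, k + 1)])], (0.0, 0.0), smoothness)
            for k in range(n_knots):
                terms = [(1.0 - 1.0 / n_knots, idx[(r, k)])]
                terms += [(-1.0 / n_knots, idx[(r, j)])
                          for j in range(n_knots) if j != k]
                add(terms, (0.0, 0.0), rigidity)
            cur = np.column_stack([
                np.interp(knot_rows, np.arange(n_rows), g[r][:, 0]),
                np.interp(knot_rows, np.arange(n_rows), g[r][:, 1])])
            for k in range(n_knots):
                add([(1.0, idx[(r, k)])], cur[k], tether)

        Amat = sp.csr_matrix((vals, (rows_a, cols_a)), shape=(neq, n_unk))
        bmat = np.vstack(rhs)
        sol = spsolve((Amat.T @ Amat).tocsc(), Amat.T @ bmat)
        sol = np.asarray(sol).reshape(n_unk, 2)

        new_curves = {}
        for r in ranks:
            knots = sol[[idx[(r, k)] for k in range(n_knots)]]
            rp = _spline_rows(knot_rows, knots, n_rows) \
                + np.column_stack([np.zeros(n_rows), np.arange(n_rows, dtype=float)])
            new_curves[r] = MotionCurve(frame_index=curves[r].frame_index,
                                        row_positions=rp)
        curves = new_curves
    return curves


# ---------------------------------------------------------------------------
# warping and blending
# ---------------------------------------------------------------------------

def raised_cosine_window(shape: tuple[int, int], flat_frac: float = 0.5) -> np.ndarray:
    """Separable blend window: full weight over the central ``flat_frac``
    of the frame, cosine² taper to zero at the borders."""
    def w1(n: int) -> np.ndarray:
        u = (np.arange(n) + 0.5) / n
        edge = (1.0 - flat_frac) / 2.0
        w = np.ones(n)
        lo = u < edge
        hi = u > 1.0 - edge
        w[lo] = np.cos(0.5 * np.pi * (edge - u[lo]) / edge) ** 2
        w[hi] = np.cos(0.5 * np.pi * (u[hi] - (1.0 - edge)) / edge) ** 2
        return w
    return np.outer(w1(shape[0]), w1(shape[1]))


def warp_frame(frame: Frame, curve: MotionCurve,
               origin: np.ndarray | None = None,
               out_shape: tuple[int, int] | None = None,
               weights: np.ndarray | None = None) -> WarpedFrame:
    """Resample a frame into mosaic coordinates along its motion curve.

    Each source pixel (r, c) is splatted bilinearly at
    ``row_positions[r] + (c, 0) − origin``; ``weights`` (default all-ones)
    multiply into the splat, so passing a blend window here prepares the
    frame for weighted averaging."""
    img = np.asarray(frame.pixels, dtype=float)
    n_rows, n_cols = img.shape
    rp = curve.row_positions
    if origin is None:
        origin = np.floor(rp.min(axis=0) - np.array([0.0, 0.0])) - 1.0
    origin = np.asarray(origin, dtype=float)
    X = (rp[:, 0] - origin[0])[:, None] + np.arange(n_cols)[None, :]
    Y = (rp[:, 1] - origin[1])[:, None] + np.zeros(n_cols)[None, :]
    if out_shape is None:
        out_shape = (int(np.ceil(Y.max())) + 2, int(np.ceil(X.max())) + 2)
    if weights is None:
        weights = np.ones_like(img)

    H, W = out_shape
    num = np.zeros(out_shape)
    den = np.zeros(out_shape)
    x0 = np.floor(X).astype(int)
    y0 = np.floor(Y).astype(int)
    fx = X - x0
    fy = Y - y0
    for dy, dx, w in ((0, 0, (1 - fy) * (1 - fx)), (0, 1, (1 - fy) * fx),
                      (1, 0, fy * (1 - fx)), (1, 1, fy * fx)):
        yy = (y0 + dy).ravel()
        xx = (x0 + dx).ravel()
        w2 = w * weights
        ww = w2.ravel()
        ok = (yy >= 0) & (yy < H) & (xx >= 0) & (xx < W) & (ww > 0)
        np.add.at(num, (yy[ok], xx[ok]), (w2 * img).ravel()[ok])
        np.add.at(den, (yy[ok], xx[ok]), ww[ok])
    return WarpedFrame(frame_index=frame.index, weighted_sum=num,
                       weight_map=den, origin=origin)


def blend(warped: list[WarpedFrame], microns_per_pixel: float,
          component_id: int = 0) -> Mosaic:
    """Weighted-average blend of warped frames sharing one output grid."""
    if not warped:
        raise ValueError("nothing to blend")
    shape = warped[0].weighted_sum.shape
    origin = warped[0].origin
    num = np.zeros(shape)
    den = np.zeros(shape)
    for w in warped:
        if w.weighted_sum.shape != shape or not np.allclose(w.origin, origin):
            raise ValueError("warped frames must share one output grid")
        num += w.weighted_sum
        den += w.weight_map
    coverage = den > 1e-9
    pixels = np.full(shape, np.nan)
    pixels[coverage] = num[coverage] / den[coverage]
    return Mosaic(pixels=pixels, weight_map=den, coverage_mask=coverage,
                  microns_per_pixel=microns_per_pixel,
                  contributing_frames=[w.frame_index for w in warped],
                  component_id=component_id, origin=origin)


def build_mosaics(frames: list[Frame], config: MosaicConfig | None = None
                  ) -> list[Mosaic]:
    """Run the full pipeline and return one Mosaic per connected
    component of the validated-match graph, largest coverage first."""
    if not frames:
        raise ValueError("empty frame list")
    config = config or MosaicConfig()
    scale = frames[0].microns_per_pixel
    matches, positions = register_and_solve(frames, config)
    curves = fit_motion_curves(positions, n_rows=frames[0].pixels.shape[0])
    by_index = {f.index: f for f in frames}
    order = sorted(by_index)

    components: dict[int, list[int]] = {}
    for rank, i in enumerate(order, start=1):
        components.setdefault(positions.component_of[rank], []).append(rank)

    mosaics: list[Mosaic] = []
    for cid, member_ranks in components.items():
        member_frames = [by_index[order[r - 1]] for r in member_ranks]
        rps = np.vstack([curves[r].row_positions for r in member_ranks])
        n_cols = member_frames[0].pixels.shape[1]
        origin = np.floor(rps.min(axis=0)) - 1.0
        h = int(np.ceil(rps[:, 1].max() - origin[1])) + member_frames[0].pixels.shape[0] + 2
        w = int(np.ceil(rps[:, 0].max() - origin[0])) + n_cols + 2
        window = raised_cosine_window(member_frames[0].pixels.shape)
        warped = [warp_frame(f, curves[r], origin=origin, out_shape=(h, w),
                             weights=window)
                  for f, r in zip(member_frames, member_ranks)]
        mosaic = blend(warped, scale, component_id=cid)
        mosaic.residual_rms = positions.residual_rms
        for f, r in zip(member_frames, member_ranks):
            rp = curves[r].row_positions
            q = rp - np.column_stack([np.zeros(len(rp)), np.arange(len(rp))])
            mosaic.frame_origins[f.index] = q.mean(axis=0) - origin
        mosaics.append(mosaic)

    mosaics.sort(key=lambda m: int(m.coverage_mask.sum()), reverse=True)
    for new_id, m in enumerate(mosaics):
        m.component_id = new_id
    return mosaics


def mosaic_area_mm2(mosaic: Mosaic, exclusion_mask: np.ndarray | None = None) -> float:
    """Effective mosaic area: covered, non-excluded pixels in mm²."""
    mask = mosaic.coverage_mask
    if exclusion_mask is not None:
        exclusion_mask = np.asarray(exclusion_mask, dtype=bool)
        if exclusion_mask.shape != mask.shape:
            raise ValueError("exclusion mask shape mismatch")
        mask = mask & ~exclusion_mask
    return float(mask.sum()) * mosaic.microns_per_pixel ** 2 / 1e6


def save_mosaic(mosaic: Mosaic, path: str | Path) -> Path:
    """Write mosaic TIFF (16-bit, NaN → 0) plus a JSON sidecar."""
    path = Path(path)
    px = np.nan_to_num(mosaic.pixels, nan=0.0)
    lo, hi = px.min(), px.max()
    scaled = ((px - lo) / (hi - lo) if hi > lo else px * 0.0)
    tifffile.imwrite(path, (scaled * 65535 + 0.5).astype(np.uint16))
    sidecar = {
        "component_id": mosaic.component_id,
        "microns_per_pixel": mosaic.microns_per_pixel,
        "contributing_frames": mosaic.contributing_frames,
        "coverage_area_mm2": mosaic.coverage_area_mm2,
        "residual_rms_px": mosaic.residual_rms,
        "origin": mosaic.origin.tolist(),
        "frame_origins": {str(k): v.tolist() for k, v in mosaic.frame_origins.items()},
        "intensity_range": [float(lo), float(hi)],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path
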