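"""Synthetic SHG stacks and force traces with exact ground truth.

Every downstream stage (collagen quantification, lattice morphometry, passive
and active mechanics) is validated against scenes generated here, because the
raw microscope stacks and force traces this kind of study produces are rarely
deposited.  The generator therefore defines the study conditions: striated
single fibers at ~2 um sarcomere spacing, myofibril strips with per-strip
angular jitter, Y-junction verniers rendered as half-period lattice
dislocations, extracellular collagen visible only in the forward SHG channel,
and stress-relaxation traces with an exponential decay from a dynamic peak to
an elastic plateau.

Geometry convention: pixel (row r, col c) maps to physical (x, y) =
(c, r) * pixel_size in um; axial angles are measured from the +x (column)
axis toward +y (rows) and stored modulo 180 degrees, because a striation
orientation has no sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io import ImageStack, MechTrace

__all__ = [
    "FiberScene",
    "GroundTruth",
    "generate_striated_fiber",
    "generate_cross_section",
    "generate_stress_relaxation",
    "generate_twitch_tetanus",
    "auto_vernier_events",
    "auto_collagen_streaks",
    "mean_cos_deviation",
    "fold_axial_deg",
]


def fold_axial_deg(delta_deg: np.ndarray | float) -> np.ndarray | float:
    """Fold an axial angle difference into [-90, 90) degrees."""
    return (np.asarray(delta_deg) + 90.0) % 180.0 - 90.0


def mean_cos_deviation(angle_field_deg: np.ndarray, axis_deg: float) -> float:
    """Brute-force mean cosine of axial deviations over a stored angle field.

    NaN entries (pixels outside the fiber mask) are ignored.  This is the
    analytic CAS oracle: the estimator pipeline is judged against it.
    """
    dev = fold_axial_deg(np.asarray(angle_field_deg, dtype=float) - axis_deg)
    return float(np.nanmean(np.cos(np.deg2rad(dev))))


@dataclass(frozen=True)
class FiberScene:
    """Parameters of a synthetic striated single-fiber scene.

    The fiber is a rotated rectangular region (length x width, centered in the
    frame) split into myofibril strips that run along the fiber axis.  Each
    strip carries its own angular deviation drawn from N(0, angular_jitter_sd),
    and the striation bands are a raised cosine along each strip's own axis.
    Vernier events are half-period axial phase dislocations at strip
    boundaries, each producing one Y-junction in the band pattern.
    """

    fiber_axis_angle_deg: float = 10.0
    sarcomere_spacing_um: float = 2.0
    myofibril_strip_width_um: float = 5.0
    angular_jitter_sd_deg: float = 0.0
    vernier_events: tuple[tuple[int, float, float], ...] = ()  # (slice, x_um, y_um)
    collagen_streaks: tuple[dict, ...] = ()
    noise_gaussian_sd: float = 0.0
    noise_poisson_scale: float | None = None
    pixel_size_um: float = 0.2
    shape: tuple[int, int, int] = (1, 512, 512)
    fiber_length_um: float | None = None
    fiber_width_um: float | None = None
    band_amplitude: float = 1.0
    autofluorescence_level: float = 0.8

    def __post_init__(self):
        if self.sarcomere_spacing_um <= 0:
            raise ValueError("sarcomere spacing must be positive")
        if self.sarcomere_spacing_um / self.pixel_size_um < 2.0:
            raise ValueError(
                "sarcomere spacing below 2 px at this pixel size: aliased lattice"
            )
        if self.myofibril_strip_width_um < self.sarcomere_spacing_um / 2:
            raise ValueError("strip width must be at least half the sarcomere spacing")
        if self.angular_jitter_sd_deg < 0:
            raise ValueError("angular jitter SD must be non-negative")
        if not (0 <= self.fiber_axis_angle_deg < 180):
            raise ValueError("fiber axis angle must lie in [0, 180)")
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError("shape must be (n_slices, n_rows, n_cols) of positive ints")

    # -- derived geometry ---------------------------------------------------

    @property
    def frame_um(self) -> tuple[float, float]:
        return (self.shape[2] * self.pixel_size_um, self.shape[1] * self.pixel_size_um)

    def _extent(self) -> tuple[float, float]:
        fx, fy = self.frame_um
        length = self.fiber_length_um if self.fiber_length_um is not None else 0.85 * min(fx, fy)
        width = self.fiber_width_um if self.fiber_width_um is not None else 0.45 * min(fx, fy)
        return length, width

    def axial_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(s, t) coordinates in um of every pixel, relative to frame center.

        ``s`` runs along the fiber axis, ``t`` across it.
        """
        n_rows, n_cols = self.shape[1], self.shape[2]
        yy, xx = np.mgrid[0:n_rows, 0:n_cols].astype(np.float64)
        x = xx * self.pixel_size_um - 0.5 * (n_cols - 1) * self.pixel_size_um
        y = yy * self.pixel_size_um - 0.5 * (n_rows - 1) * self.pixel_size_um
        th = math.radians(self.fiber_axis_angle_deg)
        s = x * math.cos(th) + y * math.sin(th)
        t = -x * math.sin(th) + y * math.cos(th)
        return s, t

    def fiber_mask(self) -> np.ndarray:
        """Binary fiber region of a single slice (rotated rectangle)."""
        length, width = self._extent()
        s, t = self.axial_coords()
        mask = (np.abs(s) <= length / 2) & (np.abs(t) <= width / 2)
        if not mask.any():
            raise ValueError("empty fiber mask: fiber does not fit in the frame")
        return mask


@dataclass
class GroundTruth:
    """Exact scene truth recorded alongside a generated stack."""

    true_cas: float | None = None
    true_vernier_count: int | None = None
    true_fiber_area_um2: float | None = None
    true_collagen_fraction_pct: float | None = None
    injected_angle_field_deg: np.ndarray | None = None  # NaN outside the mask
    fiber_axis_deg: float | None = None
    vernier_positions: tuple[tuple[int, float, float], ...] = ()
    fiber_mask: np.ndarray | None = None
    muscle_mask: np.ndarray | None = None
    collagen_mask: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.true_cas is not None and not (0.0 <= self.true_cas <= 1.0 + 1e-12):
            raise ValueError("true CAS must lie in [0, 1]")
        if self.true_collagen_fraction_pct is not None and not (
            0.0 <= self.true_collagen_fraction_pct <= 100.0
        ):
            raise ValueError("collagen fraction must lie in [0, 100]")
        if (
            self.true_vernier_count is not None
            and self.vernier_positions
            and self.true_vernier_count != len(self.vernier_positions)
        ):
            raise ValueError("vernier count inconsistent with recorded positions")


# ---------------------------------------------------------------------------
# Striated single fibers
# ---------------------------------------------------------------------------

def generate_striated_fiber(scene: FiberScene, seed: int) -> tuple[ImageStack, GroundTruth]:
    """Render a two-channel striated fiber stack with exact ground truth.

    Channel 1 (forward SHG) carries the raised-cosine band pattern inside the
    fiber mask plus any collagen streaks outside it; channel 2
    (autofluorescence) carries a smooth cell-body signal on the mask only and
    is exactly zero on collagen pixels.  Identical (scene, seed) pairs give
    bit-identical stacks.
    """
    rng = np.random.default_rng(seed)
    n_slices, n_rows, n_cols = scene.shape
    px = scene.pixel_size_um
    lam = scene.sarcomere_spacing_um
    theta0 = scene.fiber_axis_angle_deg

    mask2d = scene.fiber_mask()
    s, t = scene.axial_coords()

    # Strip index per pixel (strips run along the axis, tiled across t).
    w_strip = scene.myofibril_strip_width_um
    k = np.floor(t / w_strip).astype(int)
    k_min, k_max = k[mask2d].min(), k[mask2d].max()
    strip_ids = np.arange(k_min, k_max + 1)

    # Validate vernier positions against the mask.
    origin_x = 0.5 * (n_cols - 1) * px
    origin_y = 0.5 * (n_rows - 1) * px
    for z, ex, ey in scene.vernier_events:
        if not (0 <= z < n_slices):
            raise ValueError(f"vernier slice index {z} outside the stack")
        c = int(round(ex / px))
        r = int(round(ey / px))
        if not (0 <= r < n_rows and 0 <= c < n_cols) or not mask2d[r, c]:
            raise ValueError(f"vernier event at ({ex}, {ey}) um lies outside the fiber mask")

    th0 = math.radians(theta0)
    x_of = lambda ss, tt: ss * math.cos(th0) - tt * math.sin(th0) + origin_x  # noqa: E731
    y_of = lambda ss, tt: ss * math.sin(th0) + tt * math.cos(th0) + origin_y  # noqa: E731

    shg = np.zeros(scene.shape, dtype=np.float64)
    af = np.zeros(scene.shape, dtype=np.float64)
    angle_field = np.full(scene.shape, np.nan, dtype=np.float64)
    realized_events: list[tuple[int, float, float]] = []

    # Smooth cell-body profile: soft-edged interior of the mask, zero outside.
    body = ndimage.gaussian_filter(mask2d.astype(float), sigma=max(2.0, 0.5 * lam / px))
    body *= mask2d

    # Collagen streaks (shared across slices; extracellular, so off the mask).
    collagen = np.zeros((n_rows, n_cols), dtype=np.float64)
    for streak in scene.collagen_streaks:
        collagen = np.maximum(collagen, _rasterize_streak(streak, scene, mask2d))

    for z in range(n_slices):
        # Per-strip angular deviations for this slice.
        dev = rng.normal(0.0, scene.angular_jitter_sd_deg, size=strip_ids.size)
        if scene.angular_jitter_sd_deg == 0:
            dev = np.zeros(strip_ids.size)
        dev_of_k = dict(zip(strip_ids.tolist(), dev.tolist()))

        # Dislocation (vernier) phase offsets, accumulated per strip.
        events_z = [(ex, ey) for (zz, ex, ey) in scene.vernier_events if zz == z]
        # boundary index b sits between strips b and b+1 (at t = (b+1)*w_strip)
        boundary_events: dict[int, list[float]] = {}
        for ex, ey in events_z:
            xs = ex - origin_x
            ys = ey - origin_y
            es = xs * math.cos(th0) + ys * math.sin(th0)
            et = -xs * math.sin(th0) + ys * math.cos(th0)
            b = int(round(et / w_strip)) - 1  # nearest boundary below/above
            # clamp so the boundary separates two strips present in the mask
            b = min(max(b, k_min), k_max - 1)
            boundary_events.setdefault(b, []).append(es)
            t_b = (b + 1) * w_strip
            realized_events.append((z, float(x_of(es, t_b)), float(y_of(es, t_b))))

        img = np.zeros((n_rows, n_cols), dtype=np.float64)
        for kk in strip_ids:
            strip_px = mask2d & (k == kk)
            if not strip_px.any():
                continue
            th_k = math.radians(theta0 + dev_of_k[kk])
            # axial coordinate along this strip's own axis
            s_k = (s[strip_px] * math.cos(th_k - th0) + t[strip_px] * math.sin(th_k - th0))
            phase = 2 * np.pi * s_k / lam
            # accumulate half-period dislocations from boundaries below kk
            for b, s0s in boundary_events.items():
                if kk >= b + 1:
                    for s0 in s0s:
                        phase = phase + np.pi / (
                            1.0 + np.exp(-(s[strip_px] - s0) / (lam / 16.0))
                        )
            img[strip_px] = 0.5 * scene.band_amplitude * (1.0 + np.cos(phase))
            angle_field[z][strip_px] = (theta0 + dev_of_k[kk]) % 180.0

        shg[z] = img + collagen
        af[z] = scene.autofluorescence_level * body

        if scene.noise_poisson_scale:
            sc = scene.noise_poisson_scale
            shg[z] = rng.poisson(np.clip(shg[z], 0, None) * sc) / sc
            af[z] = rng.poisson(np.clip(af[z], 0, None) * sc) / sc
        if scene.noise_gaussian_sd > 0:
            shg[z] = shg[z] + rng.normal(0.0, scene.noise_gaussian_sd, img.shape)
            af[z] = af[z] + rng.normal(0.0, scene.noise_gaussian_sd, img.shape)

    shg = np.clip(shg, 0.0, None)
    af = np.clip(af, 0.0, None)

    area_um2 = float(mask2d.sum()) * px * px
    truth = GroundTruth(
        true_cas=mean_cos_deviation(angle_field, theta0),
        true_vernier_count=len(scene.vernier_events),
        true_fiber_area_um2=area_um2,
        injected_angle_field_deg=angle_field,
        fiber_axis_deg=theta0,
        vernier_positions=tuple(realized_events),
        fiber_mask=np.broadcast_to(mask2d, scene.shape).copy(),
        collagen_mask=np.broadcast_to(collagen > 0, scene.shape).copy(),
        params={"seed": seed, "scene": _scene_params(scene)},
    )
    stack = ImageStack(shg, af, pixel_size_um=px)
    return stack, truth


def _scene_params(scene: FiberScene) -> dict:
    d = {}
    for name in scene.__dataclass_fields__:
        v = getattr(scene, name)
        if isinstance(v, tuple) and v and isinstance(v[0], dict):
            v = list(v)
        d[name] = v
    return d


def _rasterize_streak(streak: dict, scene: FiberScene, fiber_mask: np.ndarray) -> np.ndarray:
    """Draw one collagen streak (a thick wavy line) outside the fiber mask."""
    px = scene.pixel_size_um
    n_rows, n_cols = scene.shape[1], scene.shape[2]
    x0, y0 = streak["start_um"]
    ang = math.radians(streak.get("angle_deg", scene.fiber_axis_angle_deg))
    length = streak.get("length_um", 30.0)
    width = streak.get("width_um", 1.0)
    intensity = streak.get("intensity", 0.8)
    wobble = streak.get("wobble_um", 1.0)
    n_pts = max(2, int(length / (0.5 * px)))
    tt = np.linspace(0, length, n_pts)
    xs = x0 + tt * math.cos(ang)
    ys = y0 + tt * math.sin(ang)
    if wobble > 0:
        ys = ys + wobble * np.sin(2 * np.pi * tt / max(length, 1e-9))
    rr = np.round(ys / px).astype(int)
    cc = np.round(xs / px).astype(int)
    ok = (rr >= 0) & (rr < n_rows) & (cc >= 0) & (cc < n_cols)
    canvas = np.zeros((n_rows, n_cols), dtype=bool)
    canvas[rr[ok], cc[ok]] = True
    r_dil = max(1, int(round(width / (2 * px))))
    canvas = ndimage.binary_dilation(canvas, structure=_disk(r_dil))
    canvas &= ~ndimage.binary_dilation(fiber_mask, structure=_disk(1))
    return np.where(canvas, float(intensity), 0.0)


def _disk(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (yy * yy + xx * xx) <= radius * radius


def auto_vernier_events(
    scene: FiberScene,
    n: int,
    seed: int,
    min_separation_um: float | None = None,
    slice_index: int = 0,
) -> tuple[tuple[int, float, float], ...]:
    """Place ``n`` vernier events on strip boundaries inside the fiber mask.

    Events are spread over the available boundaries with at least
    ``min_separation_um`` (default: two sarcomere spacings) between any two
    events, so each dislocation renders as a distinct Y-junction.
    """
    if min_separation_um is None:
        min_separation_um = 2.0 * scene.sarcomere_spacing_um
    rng = np.random.default_rng(seed)
    length, width = scene._extent()
    w_strip = scene.myofibril_strip_width_um
    # interior strip boundaries: t = (b+1)*w_strip strictly inside the fiber
    bounds_t = []
    b = math.floor(-width / 2 / w_strip)
    while (b + 1) * w_strip < width / 2:
        t_b = (b + 1) * w_strip
        if abs(t_b) < width / 2 - 1.0:  # keep off the fiber edge
            bounds_t.append(t_b)
        b += 1
    if not bounds_t:
        raise ValueError("fiber too narrow for any strip boundary")
    margin = 2.0 * scene.sarcomere_spacing_um
    s_lo, s_hi = -length / 2 + margin, length / 2 - margin
    th0 = math.radians(scene.fiber_axis_angle_deg)
    n_rows, n_cols = scene.shape[1], scene.shape[2]
    origin_x = 0.5 * (n_cols - 1) * scene.pixel_size_um
    origin_y = 0.5 * (n_rows - 1) * scene.pixel_size_um

    # round-robin over boundaries, evenly spaced along the axis with jitter
    span = s_hi - s_lo
    capacity_per_boundary = max(1, int(span // min_separation_um))
    if n > capacity_per_boundary * len(bounds_t):
        raise ValueError("could not place vernier events with the requested separation")
    per_boundary = [n // len(bounds_t)] * len(bounds_t)
    for j in range(n % len(bounds_t)):
        per_boundary[j] += 1
    placed: list[tuple[float, float]] = []  # (s, t)
    for t_b, n_b in zip(bounds_t, per_boundary):
        if n_b == 0:
            continue
        gap = span / n_b
        slots = s_lo + gap * (np.arange(n_b) + 0.5)
        jitter_amp = max(0.0, 0.5 * (gap - min_separation_um))
        for s0 in slots:
            placed.append((float(s0 + rng.uniform(-jitter_amp, jitter_amp)), t_b))
    events = []
    for s0, t_b in placed:
        ex = s0 * math.cos(th0) - t_b * math.sin(th0) + origin_x
        ey = s0 * math.sin(th0) + t_b * math.cos(th0) + origin_y
        events.append((slice_index, float(ex), float(ey)))
    return tuple(events)


def auto_collagen_streaks(
    scene: FiberScene, n: int, seed: int, intensity: float = 0.8
) -> tuple[dict, ...]:
    """Random extracellular collagen streaks running roughly along the fiber."""
    rng = np.random.default_rng(seed)
    length, width = scene._extent()
    fx, fy = scene.frame_um
    th0 = math.radians(scene.fiber_axis_angle_deg)
    streaks = []
    for _ in range(n):
        side = 1 if rng.random() < 0.5 else -1
        t_off = side * (width / 2 + rng.uniform(2.0, 6.0))
        s0 = rng.uniform(-length / 2, 0.0)
        x0 = s0 * math.cos(th0) - t_off * math.sin(th0) + fx / 2
        y0 = s0 * math.sin(th0) + t_off * math.cos(th0) + fy / 2
        streaks.append(
            {
                "start_um": (float(x0), float(y0)),
                "angle_deg": scene.fiber_axis_angle_deg + float(rng.normal(0, 5)),
                "length_um": float(rng.uniform(0.3, 0.6) * length),
                "width_um": float(rng.uniform(0.8, 1.6)),
                "intensity": intensity,
                "wobble_um": float(rng.uniform(0.5, 1.5)),
            }
        )
    return tuple(streaks)


# ---------------------------------------------------------------------------
# Muscle cross-sections with collagen
# ---------------------------------------------------------------------------

def generate_cross_section(
    collagen_fraction_pct: float,
    seed: int,
    shape: tuple[int, int, int] = (1, 512, 512),
    pixel_size_um: float = 0.2,
    noise_gaussian_sd: float = 0.0,
    myosin_level: float = 0.7,
    collagen_level: float = 1.0,
    autofluorescence_level: float = 0.8,
) -> tuple[ImageStack, GroundTruth]:
    """Render a muscle cross-section with a requested collagen fraction.

    The muscle body is a wavy-boundary blob bright in both channels (myosin
    SHG + cell autofluorescence); collagen streaks are laid outside the muscle
    mask, bright in the SHG channel only, until their pixel count reaches
    ``collagen_fraction_pct`` percent of the muscle pixel count (within 0.5
    percentage points; the realized value is recorded in the ground truth).
    """
    if not (0.0 <= collagen_fraction_pct < 100.0):
        raise ValueError("collagen fraction must lie in [0, 100)")
    rng = np.random.default_rng(seed)
    n_slices, n_rows, n_cols = shape
    px = pixel_size_um

    muscle = _blob_mask(n_rows, n_cols, rng)
    n_muscle = int(muscle.sum())

    target_px = int(round(collagen_fraction_pct / 100.0 * n_muscle))
    tol_px = 0.005 * n_muscle  # 0.5 percentage points
    forbidden = ndimage.binary_dilation(muscle, structure=_disk(2))
    collagen = np.zeros((n_rows, n_cols), dtype=bool)
    guard = 0
    # Streaks below ~10 um^2 are kept out: collagen deposits that small are
    # not resolvable as fibrillar streaks at this magnification, and real
    # perimysial accumulations are far larger.
    min_streak_px = 250
    while target_px - collagen.sum() > tol_px:
        guard += 1
        if guard > 5000:
            raise RuntimeError("failed to reach requested collagen budget")
        remaining = target_px - int(collagen.sum())
        if remaining >= min_streak_px or not collagen.any():
            free = ~(forbidden | ndimage.binary_dilation(collagen, structure=_disk(1)))
            streak = _grow_streak(n_rows, n_cols, rng, free, budget_px=remaining)
            if streak.sum() >= min(remaining, min_streak_px):
                collagen |= streak
        else:
            # small remainder: thicken an existing streak instead of laying
            # a new, unresolvably small one
            free = ~(forbidden | collagen)
            boundary = ndimage.binary_dilation(collagen, structure=_disk(1)) & free
            br, bc = np.nonzero(boundary)
            if br.size == 0:
                break
            i = int(rng.integers(br.size))
            streak = _grow_streak(n_rows, n_cols, rng, free, budget_px=remaining,
                                  start=(int(br[i]), int(bc[i])))
            if streak.sum() == 0:
                continue
            collagen |= streak

    realized_pct = 100.0 * collagen.sum() / n_muscle

    body = ndimage.gaussian_filter(muscle.astype(float), sigma=3.0) * muscle
    # mild interior texture so the SHG muscle signal is not perfectly flat
    texture = 1.0 + 0.15 * np.sin(
        2 * np.pi * np.arange(n_cols)[None, :] * px / 2.0
    )
    shg2d = myosin_level * body * texture + collagen_level * collagen
    af2d = autofluorescence_level * body

    shg = np.repeat(shg2d[None], n_slices, axis=0)
    af = np.repeat(af2d[None], n_slices, axis=0)
    if noise_gaussian_sd > 0:
        shg = shg + rng.normal(0.0, noise_gaussian_sd, shg.shape)
        af = af + rng.normal(0.0, noise_gaussian_sd, af.shape)
    shg = np.clip(shg, 0.0, None)
    af = np.clip(af, 0.0, None)

    truth = GroundTruth(
        true_collagen_fraction_pct=float(realized_pct),
        true_fiber_area_um2=float(n_muscle) * px * px,
        muscle_mask=np.broadcast_to(muscle, shape).copy(),
        collagen_mask=np.broadcast_to(collagen, shape).copy(),
        params={
            "seed": seed,
            "requested_fraction_pct": collagen_fraction_pct,
            "pixel_size_um": px,
            "noise_gaussian_sd": noise_gaussian_sd,
        },
    )
    return ImageStack(shg, af, pixel_size_um=px), truth


def _blob_mask(n_rows: int, n_cols: int, rng: np.random.Generator) -> np.ndarray:
    """Elliptical muscle body with a low-order wavy boundary."""
    yy, xx = np.mgrid[0:n_rows, 0:n_cols].astype(float)
    cy, cx = (n_rows - 1) / 2, (n_cols - 1) / 2
    r = np.hypot(yy - cy, xx - cx)
    phi = np.arctan2(yy - cy, xx - cx)
    base = 0.32 * min(n_rows, n_cols)
    wave = np.zeros_like(phi)
    for j in range(2, 6):
        wave += rng.uniform(0.0, 0.06) * np.cos(j * phi + rng.uniform(0, 2 * np.pi))
    return r <= base * (1.0 + wave)


def _grow_streak(
    n_rows: int,
    n_cols: int,
    rng: np.random.Generator,
    free: np.ndarray,
    budget_px: int,
    start: tuple[int, int] | None = None,
) -> np.ndarray:
    """Grow one contiguous thick random-walk streak in free space.

    The walk stamps a disk at each step and stops once the stamped pixel
    count reaches ``budget_px``, so the realized collagen area can land on a
    requested budget without leaving scattered single-pixel crumbs.
    """
    if start is not None:
        r, c = start
    else:
        for _ in range(500):
            r = int(rng.integers(3, n_rows - 3))
            c = int(rng.integers(3, n_cols - 3))
            if free[r, c]:
                break
        else:
            raise RuntimeError("no free space for collagen streak")
    radius = int(rng.integers(2, 4))
    disk = _disk(radius)
    n_steps = int(rng.integers(60, 200))
    ang = rng.uniform(0, 2 * np.pi)
    canvas = np.zeros((n_rows, n_cols), dtype=bool)
    rr, cc = float(r), float(c)
    for _ in range(n_steps):
        ri, ci = int(round(rr)), int(round(cc))
        if not (radius < ri < n_rows - radius - 1 and radius < ci < n_cols - radius - 1):
            break
        stamp = np.zeros_like(canvas)
        stamp[ri - radius : ri + radius + 1, ci - radius : ci + radius + 1] = disk
        stamp &= free
        if int((canvas | stamp).sum()) > budget_px:
            break
        canvas |= stamp
        ang += rng.normal(0, 0.2)
        rr += math.sin(ang)
        cc += math.cos(ang)
    # keep only the connected piece containing the seed (clipping can split)
    labels, n_lab = ndimage.label(canvas, structure=np.ones((3, 3)))
    if n_lab > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n_lab + 1))
        canvas = labels == (1 + int(np.argmax(sizes)))
    return canvas


# ---------------------------------------------------------------------------
# Mechanics traces
# ---------------------------------------------------------------------------

def generate_stress_relaxation(
    a_kpa: float,
    b_kpa: float,
    tau_s: float,
    strains: Sequence[float] = (0.05, 0.075, 0.10, 0.125),
    hold_s: float = 10.0,
    noise_sd_kpa: float = 0.0,
    seed: int = 0,
    a_dyn_kpa: float | None = None,
    b_dyn_kpa: float | None = None,
    sample_rate_hz: float = 100.0,
    pcsa_cm2: float = 0.01,
    pre_s: float = 1.0,
) -> tuple[MechTrace, dict]:
    """Simulate a stepwise stress-relaxation protocol.

    At each strain step the stress jumps to the dynamic value
    ``sigma_dyn = a_d*eps^2 + b_d*eps`` and relaxes exponentially (time
    constant ``tau_s``) toward the elastic plateau ``sigma_el = a*eps^2 +
    b*eps``.  Dynamic coefficients default to twice the elastic ones.  The
    trace is returned in force units (mN) with the PCSA reference attached, so
    downstream stress conversion is exercised, and the generating parameters
    are returned as ground truth.
    """
    strains = [float(e) for e in strains]
    if any(not (0.0 < e <= 0.2) for e in strains):
        raise ValueError("strains must lie in (0, 0.2]")
    if any(e2 <= e1 for e1, e2 in zip(strains, strains[1:])):
        raise ValueError("strain list must be strictly increasing")
    if tau_s <= 0 or hold_s <= 0:
        raise ValueError("tau and hold must be positive")
    a_d = 2.0 * a_kpa if a_dyn_kpa is None else a_dyn_kpa
    b_d = 2.0 * b_kpa if b_dyn_kpa is None else b_dyn_kpa

    rng = np.random.default_rng(seed)
    dt = 1.0 / sample_rate_hz
    total = pre_s + hold_s * len(strains)
    time = np.arange(0.0, total, dt)
    stress = np.zeros_like(time)
    steps = []
    for i, eps in enumerate(strains):
        onset = pre_s + i * hold_s
        steps.append((onset, eps))
        sel = time >= onset
        sig_el = a_kpa * eps**2 + b_kpa * eps
        sig_dyn = a_d * eps**2 + b_d * eps
        # each step supersedes the previous plateau
        stress[sel] = sig_el + (sig_dyn - sig_el) * np.exp(-(time[sel] - onset) / tau_s)
    if noise_sd_kpa > 0:
        stress = stress + rng.normal(0.0, noise_sd_kpa, stress.shape)

    force_mn = stress * 100.0 * pcsa_cm2  # 1 kPa = 100 mN/cm^2
    trace = MechTrace(time, force_mn, steps=tuple(steps), pcsa_cm2=pcsa_cm2)
    truth = {
        "a_kpa": a_kpa,
        "b_kpa": b_kpa,
        "a_dyn_kpa": a_d,
        "b_dyn_kpa": b_d,
        "tau_s": tau_s,
        "strains": strains,
        "hold_s": hold_s,
        "elastic_stiffness_kpa": 2 * a_kpa * 0.10 + b_kpa,
        "dynamic_stiffness_kpa": 2 * a_d * 0.10 + b_d,
        "sigma_el_kpa": [a_kpa * e**2 + b_kpa * e for e in strains],
        "sigma_dyn_kpa": [a_d * e**2 + b_d * e for e in strains],
    }
    return trace, truth


def generate_twitch_tetanus(
    peak_twitch_mn: float,
    peak_tetanus_mn: float,
    seed: int = 0,
    ripple_frac: float = 0.0,
    noise_sd_mn: float = 0.0,
    sample_rate_hz: float = 1000.0,
    twitch_time_to_peak_s: float = 0.02,
    twitch_duration_s: float = 0.3,
    tetanus_rise_s: float = 0.05,
    tetanus_duration_s: float = 0.5,
    stim_rate_hz: float = 150.0,
    pcsa_cm2: float = 0.01,
) -> tuple[MechTrace, MechTrace, dict]:
    """Simulate a single isometric twitch and a fused tetanus.

    The twitch is an alpha-function transient whose maximum equals
    ``peak_twitch_mn`` exactly (time-to-peak lies on the sample grid); the
    tetanus ramps linearly to ``peak_tetanus_mn`` and holds it, with an
    optional non-negative stimulation ripple of relative amplitude
    ``ripple_frac`` on the plateau (max force in
    [peak, peak*(1+ripple_frac)]).
    """
    if peak_twitch_mn <= 0 or peak_tetanus_mn <= 0:
        raise ValueError("peak forces must be positive")
    if twitch_duration_s <= 0 or tetanus_duration_s <= 0:
        raise ValueError("zero-length trace requested")
    rng = np.random.default_rng(seed)
    dt = 1.0 / sample_rate_hz
    # keep time-to-peak on the grid so the sampled maximum is exact
    tp = round(twitch_time_to_peak_s / dt) * dt

    t1 = np.arange(0.0, twitch_duration_s, dt)
    twitch = peak_twitch_mn * (t1 / tp) * np.exp(1.0 - t1 / tp)

    t2 = np.arange(0.0, tetanus_duration_s, dt)
    tet = peak_tetanus_mn * np.minimum(1.0, t2 / tetanus_rise_s)
    if ripple_frac > 0:
        plateau = t2 >= tetanus_rise_s
        tet = tet + plateau * (
            ripple_frac * peak_tetanus_mn * np.sin(2 * np.pi * stim_rate_hz * t2) ** 2
        )
    if noise_sd_mn > 0:
        twitch = twitch + rng.normal(0.0, noise_sd_mn, twitch.shape)
        tet = tet + rng.normal(0.0, noise_sd_mn, tet.shape)

    tr_twitch = MechTrace(t1, twitch, pcsa_cm2=pcsa_cm2)
    tr_tet = MechTrace(t2, tet, pcsa_cm2=pcsa_cm2)
    truth = {
        "peak_twitch_mn": peak_twitch_mn,
        "peak_tetanus_mn": peak_tetanus_mn,
        "ripple_frac": ripple_frac,
        "pcsa_cm2": pcsa_cm2,
    }
    return tr_twitch, tr_tet, truth
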