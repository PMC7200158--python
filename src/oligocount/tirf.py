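"""Single-molecule TIRF spot counting.

The pipeline estimates how many fluorophores (e.g. GFP fusions) sit in
each diffraction-limited spot of a short movie:

1. rolling-ball background subtraction and rolling-window time averaging;
2. per-frame spot detection: candidate local maxima are refined by a
   least-squares 2-D Gaussian fit with the PSF sigma held fixed, and the
   fitted amplitude is tested against the local background noise at a
   significance level alpha;
3. frame-to-frame linking by optimal (minimal total squared displacement)
   assignment with gap closing up to ``max_gap`` missed frames;
4. trajectories at least ``min_length`` detected frames long contribute
   their first-frame integrated intensity (2*pi*sigma**2*amplitude);
5. the pooled intensities are fit with 1..k_max component Gaussian
   mixtures (many replicates, BIC/AIC model selection); the spacing of
   the two smallest component means is the single-fluorophore intensity
   g, and the implied offset b = mu_(1) - g is subtracted before
   normalizing each spot intensity to a copy-number scale.

Field-level mean-gray-value summaries used by the severing/staining
comparisons live here too; the resampling tests are in
:mod:`oligocount.stats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.optimize import least_squares, linear_sum_assignment
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.restoration import rolling_ball
from sklearn.mixture import GaussianMixture

__all__ = [
    "ImageStack",
    "SpotDetection",
    "Trajectory",
    "GmmModel",
    "CalibratedDistribution",
    "rolling_ball_subtract",
    "time_average",
    "detect_spots",
    "link_trajectories",
    "select_trajectories",
    "start_intensities",
    "select_gmm",
    "calibrate",
    "fraction_within",
    "mean_gray_values",
    "center_crop_bounds",
    "run_counting_pipeline",
]


@dataclass(frozen=True)
class ImageStack:
    """A fluorescence movie: (frames, rows, cols) plus acquisition metadata."""

    data: np.ndarray
    pixel_size_nm: float = 65.0
    exposure_ms: float = 100.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3 or arr.shape[0] < 1:
            raise ValueError("stack must be (frames, rows, cols) with >= 1 frame")
        if not np.all(np.isfinite(arr)):
            raise ValueError("stack contains non-finite values")
        object.__setattr__(self, "data", arr)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class SpotDetection:
    """One fitted spot: sub-pixel position (x = column, y = row, 0-based
    pixel-center convention), fitted amplitude and local background in
    counts, the fixed PSF sigma, and the one-sided detection p-value."""

    frame: int
    x: float
    y: float
    amplitude: float
    background: float
    sigma: float
    p_value: float

    @property
    def integrated_intensity(self) -> float:
        """Gaussian volume 2*pi*sigma**2*A above local background."""
        return float(2.0 * np.pi * self.sigma**2 * self.amplitude)


@dataclass
class Trajectory:
    """An ordered sequence of detections of one spot across frames."""

    detections: list[SpotDetection] = field(default_factory=list)

    def __post_init__(self) -> None:
        frames = [d.frame for d in self.detections]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("detection frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def length(self) -> int:
        """Number of frames with a detection (gaps excluded)."""
        return len(self.detections)

    @property
    def gaps(self) -> list[int]:
        frames = [d.frame for d in self.detections]
        return [b - a - 1 for a, b in zip(frames, frames[1:]) if b - a > 1]

    @property
    def start(self) -> SpotDetection:
        return self.detections[0]

    @property
    def end(self) -> SpotDetection:
        return self.detections[-1]


# ---------------------------------------------------------------------------
# preprocessing


def rolling_ball_subtract(stack: ImageStack, diameter_px: int = 5) -> ImageStack:
    """Subtract a rolling-ball background estimate from every frame.

    The background at each pixel is the apex height of a ball of radius
    ``diameter_px``/2 rolled under the intensity surface (a grayscale
    erosion with the ball-profile structuring element); narrow
    diffraction-limited peaks survive while smooth background is removed.
    Output is clipped at zero.
    """
    if diameter_px < 1:
        raise ValueError("diameter_px must be >= 1")
    if diameter_px > min(stack.data.shape[1:]):
        raise ValueError("rolling-ball diameter exceeds the image size")
    radius = diameter_px / 2.0
    out = np.empty_like(stack.data, dtype=float)
    for t in range(stack.n_frames):
        frame = stack.data[t].astype(float)
        bg = rolling_ball(frame, radius=radius)
        out[t] = np.clip(frame - bg, 0.0, None)
    return ImageStack(out, stack.pixel_size_nm, stack.exposure_ms)


def time_average(stack: ImageStack, window: int = 5) -> ImageStack:
    """Centered rolling-window mean over frames (edge-truncated)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > stack.n_frames:
        raise ValueError("window exceeds the number of frames")
    half = window // 2
    data = stack.data.astype(float)
    out = np.empty_like(data)
    for t in range(stack.n_frames):
        lo = max(0, t - half)
        hi = min(stack.n_frames, t + half + 1)
        out[t] = data[lo:hi].mean(axis=0)
    return ImageStack(out, stack.pixel_size_nm, stack.exposure_ms)


# ---------------------------------------------------------------------------
# detection


def _psf_factors(d, sigma):
    """Pixel-integrated 1-D Gaussian factor and its spatial derivative.

    ``d`` are (pixel center - spot center) offsets.  The factor is the
    unit-peak Gaussian integrated across each pixel,
    sqrt(2*pi)*sigma * [Phi(d+1/2) - Phi(d-1/2)], so that a spot of peak
    amplitude A integrates to 2*pi*sigma**2*A over the plane.
    """
    from scipy.special import erf

    s = sigma * np.sqrt(2.0)
    e = np.sqrt(np.pi / 2.0) * sigma * (erf((d + 0.5) / s) - erf((d - 0.5) / s))
    de = np.exp(-((d + 0.5) ** 2) / (2 * sigma**2)) - np.exp(
        -((d - 0.5) ** 2) / (2 * sigma**2)
    )
    return e, -de  # d(e)/d(center) = -de


def _fit_gaussians_batch(frame, peaks, sigma, r, n_iter=14):
    """Damped Gauss-Newton fit of b + A*G(x0,y0; sigma) per candidate.

    G is the pixel-integrated 2-D Gaussian with unit peak (so A is a peak
    amplitude and 2*pi*sigma**2*A the spot's integrated signal); sigma is
    held fixed and all candidate windows are fit simultaneously.  Returns
    per-candidate amplitude, global x/y, local background, amplitude
    standard error (from the Jacobian at the solution), RSS and the
    windowed residual maps.
    """
    h, w = frame.shape
    py = np.clip(peaks[:, 0], r, h - 1 - r)
    px = np.clip(peaks[:, 1], r, w - 1 - r)
    n = len(peaks)
    side = 2 * r + 1
    win = np.empty((n, side, side))
    for i, (y, x) in enumerate(zip(py, px)):
        win[i] = frame[y - r : y + r + 1, x - r : x + r + 1]
    win = win.reshape(n, -1)
    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    yy, xx = yy.ravel(), xx.ravel()
    norm = 2.0 * np.pi * sigma**2  # plane integral of the unit-peak PSF

    b = np.median(win, axis=1)
    x0 = (peaks[:, 1] - (px - r)).astype(float)
    y0 = (peaks[:, 0] - (py - r)).astype(float)
    amp = np.maximum(win[np.arange(n), (y0 * side + x0).astype(int)] - b, 1e-6)

    lam = 1e-3  # Levenberg damping on the normal equations
    eye = np.eye(4)[None]

    def model_and_jac(amp, x0, y0, b):
        ex, dex = _psf_factors(xx[None, :] - x0[:, None], sigma)
        ey, dey = _psf_factors(yy[None, :] - y0[:, None], sigma)
        # unit-peak pixel-integrated PSF: plane-sum of ex*ey is 2*pi*sigma^2
        g = ex * ey
        model = b[:, None] + amp[:, None] * g
        J = np.stack(
            [g, amp[:, None] * dex * ey, amp[:, None] * ex * dey,
             np.ones_like(g)],
            axis=2,
        )
        return model, J

    for _ in range(n_iter):
        model, J = model_and_jac(amp, x0, y0, b)
        res = win - model
        JTJ = np.einsum("npi,npj->nij", J, J)
        JTr = np.einsum("npi,np->ni", J, res)
        diag = np.maximum(JTJ[:, [0, 1, 2, 3], [0, 1, 2, 3]], 1e-12)
        damped = JTJ + lam * diag[:, :, None] * eye
        try:
            step = np.linalg.solve(damped, JTr[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            break
        amp = np.maximum(amp + step[:, 0], 1e-9)
        x0 = np.clip(x0 + step[:, 1], 0.0, side - 1.0)
        y0 = np.clip(y0 + step[:, 2], 0.0, side - 1.0)
        b = b + step[:, 3]

    model, J = model_and_jac(amp, x0, y0, b)
    resid = win - model
    rss = (resid**2).sum(axis=1)
    dof = max(win.shape[1] - 4, 1)
    JTJ = np.einsum("npi,npj->nij", J, J)
    inv = np.linalg.pinv(JTJ)
    amp_se = np.sqrt(np.maximum(inv[:, 0, 0], 1e-300) * rss / dof)
    return (
        amp,
        x0 + px - r,
        y0 + py - r,
        b,
        amp_se,
        rss,
        resid.reshape(n, side, side),
        (py, px),
    )


def _gauss2d(params, yy, xx, sigma):
    a, x0, y0, b = params
    return b + a * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sigma**2))


def _fit_two_spots(window, first_guess, second_guess, sigma):
    """Constrained two-Gaussian least-squares fit on one window."""
    h, w = window.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    bg0 = float(np.median(window))
    (y0, x0), (y1, x1) = first_guess, second_guess
    a0 = max(float(window[int(round(y0)), int(round(x0))]) - bg0, 1e-6)
    a1 = max(float(window[int(round(y1)), int(round(x1))]) - bg0, 1e-6)
    p0 = [a0, x0, y0, a1, x1, y1, bg0]
    lb = [0.0, -0.5, -0.5, 0.0, -0.5, -0.5, -np.inf]
    ub = [np.inf, w - 0.5, h - 0.5, np.inf, w - 0.5, h - 0.5, np.inf]

    def resid(p):
        one = _gauss2d([p[0], p[1], p[2], p[6]], yy, xx, sigma)
        two = _gauss2d([p[3], p[4], p[5], 0.0], yy, xx, sigma)
        return (one + two - window).ravel()

    sol = least_squares(resid, p0, bounds=(lb, ub), method="trf", max_nfev=200)
    rss = float(np.sum(sol.fun**2))
    dof = max(window.size - 7, 1)
    try:
        cov = np.linalg.pinv(sol.jac.T @ sol.jac) * (rss / dof)
        se = (float(np.sqrt(max(cov[0, 0], 1e-300))),
              float(np.sqrt(max(cov[3, 3], 1e-300))))
    except np.linalg.LinAlgError:
        se = (np.inf, np.inf)
    return sol.x, rss, se


def detect_spots(
    frame: np.ndarray,
    alpha: float = 0.05,
    psf_sigma_px: float = 1.0,
    frame_index: int = 0,
    min_distance: int = 2,
    window_radius: int = 3,
    candidate_threshold_sigma: float = 4.0,
) -> list[SpotDetection]:
    """Detect diffraction-limited spots in one preprocessed frame.

    Candidate local maxima (separated by at least ``min_distance`` px and
    brighter than background + ``candidate_threshold_sigma`` robust noise
    sigmas) are refined by a 2-D Gaussian least-squares fit with the PSF
    sigma fixed at ``psf_sigma_px``.  Each fitted amplitude is tested
    one-sided against its standard error (normal reference) and kept when
    p <= alpha.  When a single-spot fit leaves a strong structured
    residual, a two-spot fit on the same window is attempted, so
    partially overlapping pairs can be resolved; pairs much closer than
    the PSF width merge into one detection.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be a 2-D image")
    if np.ptp(frame) == 0:  # constant frame: nothing to detect
        return []

    med = float(np.median(frame))
    noise = 1.4826 * float(np.median(np.abs(frame - med)))
    if noise == 0:
        noise = float(frame.std()) or 1.0

    peaks = peak_local_max(
        frame,
        min_distance=min_distance,
        threshold_abs=med + candidate_threshold_sigma * noise,
        exclude_border=False,
    )
    if len(peaks) == 0:
        return []

    r = window_radius
    amp, gx, gy, bg, amp_se, rss, resid, (py, px) = _fit_gaussians_batch(
        frame, peaks, psf_sigma_px, r
    )

    detections: list[SpotDetection] = []
    for i in range(len(peaks)):
        fits = [(amp[i], gx[i], gy[i], bg[i], amp_se[i])]

        # structured residual -> try resolving two overlapping spots
        if resid[i].max() > 4.0 * noise:
            ry, rx = np.unravel_index(np.argmax(resid[i]), resid[i].shape)
            wy0, wx0 = gy[i] - (py[i] - r), gx[i] - (px[i] - r)
            if np.hypot(ry - wy0, rx - wx0) >= psf_sigma_px:
                window = frame[
                    py[i] - r : py[i] + r + 1, px[i] - r : px[i] + r + 1
                ]
                p2, rss2, (se_a, se_b) = _fit_two_spots(
                    window, (wy0, wx0), (ry, rx), psf_sigma_px
                )
                if rss2 < 0.7 * rss[i]:
                    off_y, off_x = py[i] - r, px[i] - r
                    fits = [
                        (p2[0], p2[1] + off_x, p2[2] + off_y, p2[6], se_a),
                        (p2[3], p2[4] + off_x, p2[5] + off_y, p2[6], se_b),
                    ]

        for a, fx, fy, b, se in fits:
            if a <= 0 or not np.isfinite(se) or se <= 0:
                continue
            p = float(sps.norm.sf(a / se))
            if p > alpha:
                continue
            detections.append(
                SpotDetection(
                    frame=frame_index,
                    x=float(fx),
                    y=float(fy),
                    amplitude=float(a),
                    background=float(b),
                    sigma=float(psf_sigma_px),
                    p_value=p,
                )
            )

    # merge duplicate fits of the same spot (closer than ~1 PSF sigma)
    detections.sort(key=lambda d: -d.amplitude)
    kept: list[SpotDetection] = []
    if detections:
        tree_pts: list[tuple[float, float]] = []
        for det in detections:
            if all(
                (det.x - qx) ** 2 + (det.y - qy) ** 2 > psf_sigma_px**2
                for qx, qy in tree_pts
            ):
                kept.append(det)
                tree_pts.append((det.x, det.y))
    kept.sort(key=lambda d: (d.y, d.x))
    return kept


# ---------------------------------------------------------------------------
# linking


def _assign(prev: list[SpotDetection], cur: list[SpotDetection], max_disp: float):
    """Optimal frame-to-frame matching by total squared displacement."""
    if not prev or not cur:
        return []
    pxy = np.array([[p.x, p.y] for p in prev])
    cxy = np.array([[c.x, c.y] for c in cur])
    d2 = ((pxy[:, None, :] - cxy[None, :, :]) ** 2).sum(axis=2)
    big = 1e12
    cost = np.where(d2 <= max_disp**2, d2, big)
    rows, cols = linear_sum_assignment(cost)
    return [(i, j) for i, j in zip(rows, cols) if cost[i, j] < big]


def link_trajectories(
    detections: list[SpotDetection],
    max_gap: int = 4,
    max_disp_px: float = 2.0,
) -> list[Trajectory]:
    """Link per-frame detections into trajectories.

    Consecutive frames are matched by minimal-total-squared-displacement
    assignment (gated at ``max_disp_px``); track ends are then joined to
    later track starts across gaps of at most ``max_gap`` missed frames,
    greedily by ascending per-frame displacement, with the displacement
    budget scaled by the number of frames bridged.
    """
    if not detections:
        return []
    by_frame: dict[int, list[SpotDetection]] = {}
    for d in detections:
        by_frame.setdefault(d.frame, []).append(d)
    frames = sorted(by_frame)

    segments: list[list[SpotDetection]] = []
    for t in frames:
        cur = by_frame[t]
        linkable = [i for i, s in enumerate(segments) if s[-1].frame == t - 1]
        pairs = _assign([segments[i][-1] for i in linkable], cur, max_disp_px)
        used = set()
        for i, j in pairs:
            segments[linkable[i]].append(cur[j])
            used.add(j)
        for j, det in enumerate(cur):
            if j not in used:
                segments.append([det])

    # gap closing: KD-tree gating keeps the candidate set linear-ish
    starts = np.array([[s[0].x, s[0].y] for s in segments])
    start_frame = np.array([s[0].frame for s in segments])
    tree = cKDTree(starts)
    candidates = []
    for i, seg in enumerate(segments):
        te = seg[-1].frame
        ex, ey = seg[-1].x, seg[-1].y
        for j in tree.query_ball_point([ex, ey], max_disp_px * (max_gap + 1)):
            if j == i:
                continue
            gap = start_frame[j] - te - 1
            if 1 <= gap <= max_gap:
                span = gap + 1
                d2 = (ex - starts[j, 0]) ** 2 + (ey - starts[j, 1]) ** 2
                if d2 <= (max_disp_px * span) ** 2:
                    candidates.append((d2 / span, i, j))
    candidates.sort(key=lambda c: c[0])
    next_of: dict[int, int] = {}
    prev_of: dict[int, int] = {}
    for _, i, j in candidates:
        if i not in next_of and j not in prev_of:
            next_of[i] = j
            prev_of[j] = i

    trajectories = []
    for i in range(len(segments)):
        if i in prev_of:
            continue  # not a chain head
        chain = list(segments[i])
        k = i
        while k in next_of:
            k = next_of[k]
            chain.extend(segments[k])
        trajectories.append(Trajectory(chain))
    trajectories.sort(key=lambda tr: (tr.start.frame, tr.start.y, tr.start.x))
    return trajectories


def select_trajectories(
    trajectories: list[Trajectory], min_length: int = 10
) -> list[Trajectory]:
    """Keep trajectories detected in at least ``min_length`` frames."""
    return [t for t in trajectories if t.length >= min_length]


def start_intensities(
    trajectories: list[Trajectory], mode: str = "integrated"
) -> np.ndarray:
    """First-frame intensity sample per trajectory.

    ``integrated`` (default) uses the fitted Gaussian volume
    2*pi*sigma**2*A; ``peak`` uses the amplitude A itself.
    """
    if mode not in ("integrated", "peak"):
        raise ValueError("mode must be 'integrated' or 'peak'")
    out = []
    for t in trajectories:
        d = t.start
        out.append(d.integrated_intensity if mode == "integrated" else d.amplitude)
    return np.asarray(out, dtype=float)


# ---------------------------------------------------------------------------
# mixture modeling and calibration


@dataclass(frozen=True)
class GmmModel:
    """A selected 1-D Gaussian mixture over spot intensities."""

    k: int
    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    bic: float
    aic: float
    replicates: int
    max_iter: int

    @property
    def sorted_means(self) -> np.ndarray:
        return np.sort(self.means)


@dataclass(frozen=True)
class CalibratedDistribution:
    """Single-fluorophore intensity g, offset b, and normalized samples."""

    single_fluor_intensity: float
    background_offset: float
    normalized: np.ndarray


def select_gmm(
    samples,
    k_max: int,
    criterion: str = "bic",
    replicates: int = 100,
    max_iter: int = 500,
    seed: int | np.random.Generator = 0,
) -> GmmModel:
    """Fit 1..k_max component Gaussian mixtures and select by BIC or AIC.

    Each k is fit with ``replicates`` random EM restarts capped at
    ``max_iter`` iterations; component variances are floored at 1e-6 of
    the sample variance to avoid ill-conditioned fits.  Component counts
    whose fits fail are excluded (effectively reducing k_max).
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if criterion not in ("bic", "aic"):
        raise ValueError("criterion must be 'bic' or 'aic'")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if samples.size < k_max + 1:
        raise ValueError(
            f"need at least k_max + 1 = {k_max + 1} samples, got {samples.size}"
        )
    rng = np.random.default_rng(seed)
    X = samples.reshape(-1, 1)
    reg = 1e-6 * float(np.var(samples))
    if reg == 0:
        reg = 1e-12

    fits = []
    for k in range(1, k_max + 1):
        state = int(rng.integers(0, 2**31 - 1))
        try:
            gm = GaussianMixture(
                n_components=k,
                covariance_type="full",
                n_init=replicates,
                max_iter=max_iter,
                reg_covar=reg,
                init_params="k-means++",
                random_state=state,
            ).fit(X)
        except Exception:
            continue  # ill-conditioned at this k: excluded
        fits.append((k, gm, float(gm.bic(X)), float(gm.aic(X))))
    if not fits:
        raise RuntimeError("every mixture fit failed; intensity pool degenerate")

    key = 2 if criterion == "bic" else 3
    k, gm, bic, aic = min(fits, key=lambda f: f[key])
    return GmmModel(
        k=k,
        means=gm.means_.ravel().copy(),
        variances=gm.covariances_.ravel().copy(),
        weights=gm.weights_.copy(),
        bic=bic,
        aic=aic,
        replicates=replicates,
        max_iter=max_iter,
    )


def calibrate(gmm: GmmModel, samples=None) -> CalibratedDistribution:
    """Single-fluorophore calibration from the two smallest mixture means.

    g = mu_(2) - mu_(1) is the single-fluorophore intensity; the offset
    implied by the smallest component sitting one g above background is
    b = mu_(1) - g.  Raw intensities normalize as (raw - b) / g.
    """
    if gmm.k < 2:
        raise ValueError("calibration needs at least 2 mixture components")
    mu = gmm.sorted_means
    g = float(mu[1] - mu[0])
    if g <= 0:
        raise ValueError("non-positive component-mean spacing; cannot calibrate")
    b = float(mu[0] - g)
    if samples is None:
        normalized = np.empty(0)
    else:
        normalized = (np.asarray(samples, dtype=float).ravel() - b) / g
    return CalibratedDistribution(
        single_fluor_intensity=g, background_offset=b, normalized=normalized
    )


def fraction_within(normalized, multiple: float = 10.0) -> float:
    """Fraction of normalized intensities at or below ``multiple``."""
    arr = np.asarray(normalized, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("no normalized samples")
    return float(np.mean(arr <= multiple))


def mean_gray_values(fields, crop: tuple[int, int, int, int] | None = None):
    """Arithmetic mean intensity (MGV) per field image, over an optional
    (row0, row1, col0, col1) crop."""
    fields = list(fields)
    if not fields:
        raise ValueError("no fields given")
    out = []
    for img in fields:
        img = np.asarray(img, dtype=float)
        if crop is not None:
            r0, r1, c0, c1 = crop
            if not (0 <= r0 < r1 <= img.shape[0] and 0 <= c0 < c1 <= img.shape[1]):
                raise ValueError(f"crop {crop} outside image of shape {img.shape}")
            img = img[r0:r1, c0:c1]
        out.append(float(img.mean()))
    return out


def center_crop_bounds(shape: tuple[int, int], height: int, width: int):
    """(row0, row1, col0, col1) of the centered height-by-width region."""
    r0 = (shape[0] - height) // 2
    c0 = (shape[1] - width) // 2
    if r0 < 0 or c0 < 0:
        raise ValueError("crop larger than image")
    return (r0, r0 + height, c0, c0 + width)


# ---------------------------------------------------------------------------
# end-to-end convenience


def run_counting_pipeline(
    stack: ImageStack,
    alpha: float = 0.05,
    psf_sigma_px: float = 1.0,
    rolling_ball_diameter: int = 5,
    time_window: int = 5,
    max_gap: int = 4,
    max_disp_px: float = 2.0,
    min_length: int = 10,
    k_max: int = 8,
    criterion: str = "bic",
    replicates: int = 100,
    max_iter: int = 500,
    multiple: float = 10.0,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Run the full spot-counting pipeline on a movie.

    Returns a dict with the detections, trajectories, intensity samples,
    selected mixture, calibration (g, b), and the fraction of normalized
    spot intensities within ``multiple`` of a single fluorophore.
    """
    sub = rolling_ball_subtract(stack, diameter_px=rolling_ball_diameter)
    avg = time_average(sub, window=time_window)
    detections: list[SpotDetection] = []
    for t in range(avg.n_frames):
        detections.extend(
            detect_spots(
                avg.data[t], alpha=alpha, psf_sigma_px=psf_sigma_px, frame_index=t
            )
        )
    trajectories = link_trajectories(
        detections, max_gap=max_gap, max_disp_px=max_disp_px
    )
    selected = select_trajectories(trajectories, min_length=min_length)
    samples = start_intensities(selected)
    gmm = select_gmm(
        samples,
        k_max=k_max,
        criterion=criterion,
        replicates=replicates,
        max_iter=max_iter,
        seed=seed,
    )
    cal = calibrate(gmm, samples)
    return {
        "detections": detections,
        "trajectories": trajectories,
        "selected_trajectories": selected,
        "intensities": samples,
        "gmm": gmm,
        "calibration": cal,
        "fraction_within": fraction_within(cal.normalized, multiple),
    }
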