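"""3D spot detection, classification and two-channel codetection.

Detection uses a Laplacian-of-Gaussian filter at the PSF scale (anisotropy
taken from the voxel size), local maxima above a robust threshold, and a
local 3D Gaussian least-squares fit for subpixel position, amplitude and
widths.  Background removal is a per-z-slice grey-scale tophat (rolling-ball
equivalent) with the radius conventions of the source workflow: 5 px for
smFISH channels, 20 px for cell-marker channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from skimage.morphology import disk, opening
from statsmodels.stats.proportion import proportion_confint

from fishscreen.imagestack import ImageStack

SPOT_COLUMNS = [
    "z_um", "y_um", "x_um", "amplitude",
    "sigma_lat_um", "sigma_ax_um", "channel",
    "spot_class", "focus_transcript_estimate", "compartment",
]


@dataclass(frozen=True)
class PSFModel:
    """Expected Gaussian widths of a diffraction-limited spot, in µm."""

    sigma_lateral: float
    sigma_axial: float

    def __post_init__(self) -> None:
        if not self.sigma_axial >= self.sigma_lateral > 0:
            raise ValueError("need sigma_axial >= sigma_lateral > 0")


@dataclass(frozen=True)
class DetectionParams:
    background_radius_smfish: int = 5
    background_radius_marker: int = 20
    detection_threshold_k: float = 7.0
    max_size_factor: float = 2.0
    min_intensity_factor: float = 0.4
    focus_intensity_factor: float = 2.5
    match_radius: float | None = None  # µm; default 2 x lateral PSF sigma

    def __post_init__(self) -> None:
        if self.background_radius_smfish <= 0 or self.background_radius_marker <= 0:
            raise ValueError("background radii must be positive")
        if self.max_size_factor <= 1:
            raise ValueError("max_size_factor must exceed 1")
        if not 0 < self.min_intensity_factor < 1 < self.focus_intensity_factor:
            raise ValueError(
                "need 0 < min_intensity_factor < 1 < focus_intensity_factor"
            )

    def effective_match_radius(self, psf: PSFModel) -> float:
        if self.match_radius is not None:
            return self.match_radius
        return 2.0 * psf.sigma_lateral


@dataclass
class SpotTable:
    """Detected punctae plus a provenance snapshot of how they were made."""

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in SPOT_COLUMNS if c not in self.df.columns]
        for c in missing:
            self.df[c] = np.nan if c != "spot_class" else "candidate"

    def __len__(self) -> int:
        return len(self.df)

    def singles(self) -> pd.DataFrame:
        return self.df[self.df["spot_class"] == "single"]

    _CSV_RENAME = {
        "spot_class": "class",
        "focus_transcript_estimate": "transcript_estimate",
    }

    def to_csv(self, path, image_id: str = "") -> None:
        out = self.df.rename(columns=self._CSV_RENAME)
        out.insert(0, "image_id", image_id or self.provenance.get("image_id", ""))
        out.to_csv(path, index=False, na_rep="NA")

    @classmethod
    def from_csv(cls, path) -> "SpotTable":
        df = pd.read_csv(path, na_values=["NA"])
        df = df.rename(columns={v: k for k, v in cls._CSV_RENAME.items()})
        return cls(df.drop(columns=["image_id"], errors="ignore"))


# --------------------------------------------------------------------------
# background subtraction
# --------------------------------------------------------------------------


def subtract_background(image: ImageStack, radius: int) -> ImageStack:
    """Per-z-slice rolling-ball background removal (grey tophat residual).

    The result is everywhere non-negative, never exceeds the input, and is
    idempotent at fixed radius.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    data = np.asarray(image.voxels, dtype=np.float64)
    squeeze = data.ndim == 3
    if squeeze:
        data = data[None]
    ny, nx = data.shape[-2:]
    if 2 * radius + 1 > min(ny, nx):
        raise ValueError("structuring-element radius exceeds slice extent")
    selem = disk(radius)
    out = np.empty_like(data)
    for c in range(data.shape[0]):
        for z in range(data.shape[1]):
            plane = data[c, z]
            out[c, z] = plane - opening(plane, selem)
    if squeeze:
        out = out[0]
    return ImageStack(out, image.voxel_size, image.channel_names)


def robust_sigma(values: np.ndarray) -> float:
    """MAD-based estimate of the spread of a (mostly background) sample."""
    values = np.asarray(values, dtype=float).ravel()
    med = np.median(values)
    return 1.4826 * float(np.median(np.abs(values - med)))


# --------------------------------------------------------------------------
# detection
# --------------------------------------------------------------------------


def _gaussian3d(coords, amp, z0, y0, x0, sig_ax, sig_lat, offset):
    z, y, x = coords
    return (
        amp
        * np.exp(
            -0.5
            * (
                ((z - z0) / sig_ax) ** 2
                + ((y - y0) / sig_lat) ** 2
                + ((x - x0) / sig_lat) ** 2
            )
        )
        + offset
    )


def _fit_window(img, peak, sigma_vox, voxel_size, scale=1.0):
    """Least-squares 3D Gaussian fit around a candidate peak.

    Window coordinates are physical (µm); ``scale`` widens the window for
    spots broader than the PSF.  Falls back to intensity-weighted moments if
    the fit fails to converge.  Returns (z,y,x) µm, amplitude, sigma_lateral
    µm, sigma_axial µm — or None when the window degenerates.
    """
    shape = img.shape
    half = [max(2, int(math.ceil(2.5 * scale * s))) for s in sigma_vox]
    lo = [max(0, peak[i] - half[i]) for i in range(3)]
    hi = [min(shape[i], peak[i] + half[i] + 1) for i in range(3)]
    win = img[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].astype(float)
    if win.size < 27:
        return None
    axes_um = [
        (np.arange(lo[i], hi[i], dtype=float) + 0.5) * voxel_size[i]
        for i in range(3)
    ]
    zg, yg, xg = np.meshgrid(*axes_um, indexing="ij")
    coords = (zg.ravel(), yg.ravel(), xg.ravel())
    vals = win.ravel()
    offset0 = float(np.percentile(vals, 20))
    amp0 = float(win.max() - offset0)
    if amp0 <= 0:
        return None
    sig_lat0 = sigma_vox[1] * voxel_size[1]
    sig_ax0 = sigma_vox[0] * voxel_size[0]
    p0 = [
        amp0,
        (peak[0] + 0.5) * voxel_size[0],
        (peak[1] + 0.5) * voxel_size[1],
        (peak[2] + 0.5) * voxel_size[2],
        sig_ax0,
        sig_lat0,
        offset0,
    ]
    bounds = (
        [0.0, axes_um[0][0], axes_um[1][0], axes_um[2][0],
         0.2 * sig_ax0, 0.2 * sig_lat0, -np.inf],
        [np.inf, axes_um[0][-1], axes_um[1][-1], axes_um[2][-1],
         5.0 * sig_ax0, 5.0 * sig_lat0, np.inf],
    )
    try:
        popt, _ = optimize.curve_fit(
            _gaussian3d, coords, vals, p0=p0, bounds=bounds, maxfev=200
        )
        amp, z0, y0, x0, sig_ax, sig_lat, _ = popt
    except (RuntimeError, ValueError):
        sub = np.clip(win - offset0, 0, None)
        total = sub.sum()
        if total <= 0:
            return None
        z0 = float((sub * zg).sum() / total)
        y0 = float((sub * yg).sum() / total)
        x0 = float((sub * xg).sum() / total)
        sig_lat = math.sqrt(
            max(
                1e-6,
                float((sub * ((yg - y0) ** 2 + (xg - x0) ** 2)).sum() / (2 * total)),
            )
        )
        sig_ax = math.sqrt(
            max(1e-6, float((sub * (zg - z0) ** 2).sum() / total))
        )
        amp = float(win.max() - offset0)
    return (float(z0), float(y0), float(x0)), float(amp), float(sig_lat), float(sig_ax)


def detect_spots(
    image: ImageStack,
    psf: PSFModel,
    params: DetectionParams | None = None,
    channel: str | None = None,
) -> SpotTable:
    """Scale-matched LoG detection with subpixel Gaussian refinement.

    Candidates are 3D local maxima of the negated Laplacian-of-Gaussian
    response above ``detection_threshold_k`` robust sigmas of the filtered
    image; each candidate is refined by a local 3D Gaussian fit; duplicates
    within one lateral PSF sigma are merged keeping the brighter spot.
    An empty image yields an empty table, not an error.
    """
    params = params or DetectionParams()
    if image.voxel_size is None:
        raise ValueError("voxel_size metadata is required for detection")
    if channel is not None:
        img = image.channel(channel)
        chan_name = channel
    else:
        if image.voxels.ndim == 4:
            raise ValueError("multichannel stack: specify channel=")
        img = image.voxels
        chan_name = image.channel_names[0] if image.channel_names else "ch0"
    img = np.asarray(img, dtype=np.float64)
    vz, vy, vx = image.voxel_size
    sigma_vox = (psf.sigma_axial / vz, psf.sigma_lateral / vy, psf.sigma_lateral / vx)

    response = -ndimage.gaussian_laplace(img, sigma=sigma_vox)
    noise = robust_sigma(response)
    threshold = params.detection_threshold_k * noise
    footprint = np.ones((3, 3, 3), dtype=bool)
    local_max = ndimage.maximum_filter(response, footprint=footprint) == response
    candidates = np.argwhere(local_max & (response > threshold))

    rows = []
    for peak in candidates:
        fit = _fit_window(img, tuple(peak), sigma_vox, image.voxel_size)
        if fit is None:
            continue
        (z0, y0, x0), amp, sig_lat, sig_ax = fit
        # wider-than-PSF spot: refit with an enlarged window so the tails
        # are not truncated and the width estimate is unbiased
        if sig_lat > 1.5 * psf.sigma_lateral:
            refit = _fit_window(
                img, tuple(peak), sigma_vox, image.voxel_size, scale=2.5
            )
            if refit is not None:
                (z0, y0, x0), amp, sig_lat, sig_ax = refit
        if amp <= 0:
            continue
        rows.append(
            dict(
                z_um=z0, y_um=y0, x_um=x0, amplitude=amp,
                sigma_lat_um=sig_lat, sigma_ax_um=sig_ax,
                channel=chan_name, spot_class="candidate",
                focus_transcript_estimate=np.nan, compartment=None,
            )
        )
    df = pd.DataFrame(rows, columns=SPOT_COLUMNS)
    df = _merge_duplicates(df, psf)
    prov = dict(
        psf=asdict(psf), params=asdict(params), channel=chan_name,
        voxel_size=tuple(image.voxel_size), noise_sigma=noise,
    )
    return SpotTable(df.reset_index(drop=True), prov)


def _merge_duplicates(df: pd.DataFrame, psf: PSFModel) -> pd.DataFrame:
    """Drop spots within one lateral PSF sigma of a brighter spot."""
    if len(df) < 2:
        return df
    order = df.sort_values("amplitude", ascending=False)
    coords = _scaled_coords(order, psf)
    keep_idx = []
    kept_coords = []
    for i, row_idx in enumerate(order.index):
        pt = coords[i]
        if kept_coords:
            d = np.sqrt(((np.asarray(kept_coords) - pt) ** 2).sum(axis=1))
            if (d < psf.sigma_lateral).any():
                continue
        keep_idx.append(row_idx)
        kept_coords.append(pt)
    return df.loc[sorted(keep_idx)]


def _scaled_coords(df: pd.DataFrame, psf: PSFModel) -> np.ndarray:
    """Anisotropy-aware coordinates: axial axis compressed by the sigma ratio
    so Euclidean distance is in lateral-µm units."""
    scale = psf.sigma_lateral / psf.sigma_axial
    return np.column_stack(
        [df["z_um"].to_numpy() * scale, df["y_um"].to_numpy(), df["x_um"].to_numpy()]
    )


# --------------------------------------------------------------------------
# unit intensity and classification
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class UnitIntensity:
    value: float
    spread: float
    n_used: int


def estimate_unit_intensity(spots: SpotTable | pd.DataFrame) -> UnitIntensity:
    """Robust single-molecule amplitude: median and scaled MAD of candidate
    amplitudes after excluding the top decile (foci contaminate the tail)."""
    df = spots.df if isinstance(spots, SpotTable) else spots
    amps = np.sort(np.asarray(df["amplitude"], dtype=float))
    amps = amps[~np.isnan(amps)]
    if len(amps) < 10:
        raise ValueError(
            "need at least 10 candidate spots to estimate unit intensity; "
            "pool spots across images"
        )
    cut = int(math.floor(0.9 * len(amps)))
    body = amps[:cut] if cut >= 1 else amps
    return UnitIntensity(
        value=float(np.median(body)),
        spread=robust_sigma(body),
        n_used=len(body),
    )


def classify_spots(
    spots: SpotTable,
    unit: UnitIntensity | float,
    psf: PSFModel,
    params: DetectionParams | None = None,
    nucleus_mask=None,
) -> SpotTable:
    """Partition candidates into single / focus / rejected.

    Foci are called first (amplitude >= focus_intensity_factor x unit and,
    when a nucleus mask is given, position inside the nucleus) so nascent
    transcription clusters are exempt from the size filter.  Remaining spots
    are rejected when wider than max_size_factor x PSF sigma or dimmer than
    min_intensity_factor x unit, and called single otherwise.
    """
    params = params or DetectionParams()
    unit_value = unit.value if isinstance(unit, UnitIntensity) else float(unit)
    df = spots.df.copy()
    amp = df["amplitude"].to_numpy(dtype=float)
    sig = df["sigma_lat_um"].to_numpy(dtype=float)

    in_nucleus = np.ones(len(df), dtype=bool)
    if nucleus_mask is not None:
        mask = nucleus_mask.labels if hasattr(nucleus_mask, "labels") else nucleus_mask
        voxel_size = (
            nucleus_mask.voxel_size
            if hasattr(nucleus_mask, "voxel_size")
            else spots.provenance.get("voxel_size")
        )
        pos = df[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)
        vox = np.floor(pos / np.asarray(voxel_size)).astype(int)
        vox = np.clip(vox, 0, np.asarray(mask.shape) - 1)
        in_nucleus = mask[vox[:, 0], vox[:, 1], vox[:, 2]] > 0

    is_focus = (amp >= params.focus_intensity_factor * unit_value) & in_nucleus
    too_wide = sig > params.max_size_factor * psf.sigma_lateral
    too_dim = amp < params.min_intensity_factor * unit_value
    rejected = ~is_focus & (too_wide | too_dim)

    cls = np.where(is_focus, "focus", np.where(rejected, "rejected", "single"))
    df["spot_class"] = cls
    df["focus_transcript_estimate"] = np.where(
        is_focus, amp / unit_value, np.nan
    )
    prov = dict(spots.provenance)
    prov["classification"] = dict(
        unit_intensity=unit_value,
        focus_intensity_factor=params.focus_intensity_factor,
        max_size_factor=params.max_size_factor,
        min_intensity_factor=params.min_intensity_factor,
        nucleus_mask_used=nucleus_mask is not None,
    )
    return SpotTable(df, prov)


# --------------------------------------------------------------------------
# codetection
# --------------------------------------------------------------------------


@dataclass
class CodetectionResult:
    n_reference: int
    n_other: int
    n_matched: int
    fraction: float  # nan when undefined (empty reference table)
    ci_low: float
    ci_high: float
    pairs: pd.DataFrame  # index_a, index_b, distance_um
    status: str  # "ok" | "undefined"
    method: str = "optimal"


def codetect(
    spots_a: SpotTable | pd.DataFrame,
    spots_b: SpotTable | pd.DataFrame,
    psf: PSFModel,
    match_radius: float | None = None,
    method: str = "auto",
) -> CodetectionResult:
    """One-to-one matching of singles between two channels.

    Uses optimal assignment (minimum total anisotropy-aware distance among
    pairs within ``match_radius``) when the problem is small, or a
    deterministic greedy nearest-neighbour pass (brighter reference spots
    first) otherwise.  The codetection fraction is matched_a / total_a with a
    Wilson binomial interval.  An empty reference table yields fraction nan
    and status "undefined" — distinct from an honest 0.
    """
    a = _singles_frame(spots_a)
    b = _singles_frame(spots_b)
    radius = match_radius if match_radius is not None else 2.0 * psf.sigma_lateral
    if len(a) == 0:
        return CodetectionResult(
            0, len(b), 0, float("nan"), float("nan"), float("nan"),
            pd.DataFrame(columns=["index_a", "index_b", "distance_um"]),
            status="undefined",
        )
    if len(b) == 0:
        lo, hi = proportion_confint(0, len(a), method="wilson")
        return CodetectionResult(
            len(a), 0, 0, 0.0, float(lo), float(hi),
            pd.DataFrame(columns=["index_a", "index_b", "distance_um"]),
            status="ok",
        )
    ca = _scaled_coords(a, psf)
    cb = _scaled_coords(b, psf)
    use_optimal = method == "optimal" or (
        method == "auto" and len(a) * len(b) <= 10**6
    )
    if use_optimal:
        pairs = _optimal_pairs(ca, cb, radius)
        used = "optimal"
    else:
        pairs = _greedy_pairs(a, ca, cb, radius)
        used = "greedy"
    n_matched = len(pairs)
    frac = n_matched / len(a)
    lo, hi = proportion_confint(n_matched, len(a), method="wilson")
    pairs_df = pd.DataFrame(
        [
            dict(index_a=a.index[i], index_b=b.index[j], distance_um=d)
            for i, j, d in pairs
        ],
        columns=["index_a", "index_b", "distance_um"],
    )
    return CodetectionResult(
        len(a), len(b), n_matched, float(frac), float(lo), float(hi),
        pairs_df, status="ok", method=used,
    )


def _singles_frame(spots) -> pd.DataFrame:
    df = spots.df if isinstance(spots, SpotTable) else spots
    if "spot_class" in df.columns:
        sub = df[df["spot_class"].isin(["single", "candidate"])]
    else:
        sub = df
    return sub


def _optimal_pairs(ca, cb, radius):
    d = cdist(ca, cb)
    big = 1e9
    cost = np.where(d <= radius, d, big)
    ri, ci = linear_sum_assignment(cost)
    return [
        (int(i), int(j), float(d[i, j]))
        for i, j in zip(ri, ci)
        if d[i, j] <= radius
    ]


def _greedy_pairs(a, ca, cb, radius):
    """Nearest unmatched neighbour, reference spots by amplitude desc
    (ties broken by lexicographic position) — deterministic."""
    order = np.lexsort(
        (a["x_um"].to_numpy(), a["y_um"].to_numpy(), a["z_um"].to_numpy(),
         -a["amplitude"].to_numpy())
    )
    taken = np.zeros(len(cb), dtype=bool)
    pairs = []
    for i in order:
        d = np.sqrt(((cb - ca[i]) ** 2).sum(axis=1))
        d[taken] = np.inf
        j = int(np.argmin(d))
        if d[j] <= radius:
            taken[j] = True
            pairs.append((int(i), j, float(d[j])))
    return pairs
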