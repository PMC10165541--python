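"""Seeded synthetic microscopy and scoring data with complete ground truth.

Generates multichannel 3D stacks (smFISH probe A, second probe B, compartment
marker, nuclear stain) in which single molecules are diffraction-limited 3D
Gaussians of near-uniform intensity, transcription foci are brighter nuclear
Gaussians whose amplitude is an integer multiple of the single-molecule
amplitude, and background blobs are wider and dimmer.  Probe B shares a
configurable fraction of probe-A positions.  Also simulates multi-annotator
presence/absence scoring tables and per-cell neuroblast-lineage panels.

All randomness flows from a single ``numpy.random.default_rng(seed)`` per
call, so identical configs give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from fishscreen.imagestack import ImageStack
from fishscreen.taxonomy import (
    DEFAULT_TAXONOMY,
    PERIPHERY,
    SOMA,
    CompartmentTaxonomy,
)

SINGLE = "single"
FOCUS = "focus"
BLOB = "blob"

PATTERN_CLASSES = ("concordant", "intercellular", "intracellular", "silent")

NEUROBLAST_CLASSES = (
    "not_detected",
    "homogeneous",
    "cell_specific_transcriptional",
    "cell_specific_posttranscriptional",
)


class ConfigurationError(ValueError):
    """Raised when a simulation config is internally inconsistent."""


# --------------------------------------------------------------------------
# geometry primitives
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid; center and radii in µm, (z, y, x) order."""

    label: str
    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def contains(self, points_um: np.ndarray) -> np.ndarray:
        d = (np.asarray(points_um) - np.asarray(self.center)) / np.asarray(self.radii)
        return (d**2).sum(axis=-1) <= 1.0

    def bounds(self):
        c, r = np.asarray(self.center), np.asarray(self.radii)
        return c - r, c + r


@dataclass(frozen=True)
class Tube:
    """Capped cylinder between two endpoints; coordinates in µm (z, y, x)."""

    label: str
    start: tuple[float, float, float]
    end: tuple[float, float, float]
    radius: float

    def contains(self, points_um: np.ndarray) -> np.ndarray:
        p = np.asarray(points_um, dtype=float)
        a = np.asarray(self.start, dtype=float)
        b = np.asarray(self.end, dtype=float)
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            return ((p - a) ** 2).sum(axis=-1) <= self.radius**2
        t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
        closest = a + t[..., None] * ab
        return ((p - closest) ** 2).sum(axis=-1) <= self.radius**2

    def bounds(self):
        a, b = np.asarray(self.start), np.asarray(self.end)
        lo = np.minimum(a, b) - self.radius
        hi = np.maximum(a, b) + self.radius
        return lo, hi


Primitive = Ellipsoid | Tube


def render_layout_mask(
    layout: tuple[Primitive, ...],
    image_shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
) -> tuple[np.ndarray, dict[int, str]]:
    """Rasterize geometric primitives into a labeled int mask.

    Primitives are drawn in order; later primitives overwrite earlier ones
    (so a nucleus drawn after its soma carves out its own label).
    Returns the mask and an id -> label-name map (0 = outside).
    """
    labels = [p.label for p in layout]
    if len(set(labels)) != len(labels):
        raise ConfigurationError("primitive labels must be unique")
    mask = np.zeros(image_shape, dtype=np.int32)
    names: dict[int, str] = {}
    zc = (np.arange(image_shape[0]) + 0.5) * voxel_size[0]
    yc = (np.arange(image_shape[1]) + 0.5) * voxel_size[1]
    xc = (np.arange(image_shape[2]) + 0.5) * voxel_size[2]
    pts = np.stack(np.meshgrid(zc, yc, xc, indexing="ij"), axis=-1)
    extent = np.asarray(image_shape) * np.asarray(voxel_size)
    for i, prim in enumerate(layout, start=1):
        lo, hi = prim.bounds()
        if (lo < 0).any() or (hi > extent).any():
            raise ConfigurationError(
                f"primitive {prim.label!r} does not fit inside the image"
            )
        inside = prim.contains(pts)
        mask[inside] = i
        names[i] = prim.label
    return mask, names


# --------------------------------------------------------------------------
# image simulation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseModel:
    """Poisson shot noise on (signal + baseline) plus Gaussian read noise."""

    baseline: float = 100.0
    read_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.baseline < 0 or self.read_sd < 0:
            raise ConfigurationError("noise parameters must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    image_shape: tuple[int, int, int] = (32, 128, 128)
    voxel_size: tuple[float, float, float] = (0.3, 0.1, 0.1)
    psf_sigma: tuple[float, float] = (0.13, 0.35)  # (lateral, axial) µm
    n_single_spots: int = 100
    single_amplitude_mean: float = 200.0
    single_amplitude_cv: float = 0.1
    n_foci: int = 0
    focus_transcript_counts: tuple[int, ...] = ()
    n_background_blobs: int = 0
    blob_sigma_factor: float = 2.5
    blob_amplitude_factor: float = 0.3
    codetection_fraction: float = 0.0
    min_separation_um: float | None = None  # reject singles closer than this
    noise_model: NoiseModel | None = field(default_factory=NoiseModel)  # None = noise-free
    compartment_layout: tuple[Primitive, ...] = ()
    nucleus_label_substring: str = "nucleus"
    marker_amplitude: float = 400.0
    focus_sigma_factor: float = 1.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_single_spots, self.n_foci, self.n_background_blobs) < 0:
            raise ConfigurationError("counts must be non-negative")
        if not 0.0 <= self.codetection_fraction <= 1.0:
            raise ConfigurationError("codetection_fraction must be in [0, 1]")
        if self.blob_sigma_factor <= 1.0:
            raise ConfigurationError("blob_sigma_factor must exceed 1")
        if self.blob_amplitude_factor >= 1.0:
            raise ConfigurationError("blob_amplitude_factor must be below 1")
        if self.single_amplitude_mean <= 0:
            raise ConfigurationError("single_amplitude_mean must be positive")
        if self.single_amplitude_cv < 0:
            raise ConfigurationError("single_amplitude_cv must be non-negative")
        if self.psf_sigma[0] <= 0 or self.psf_sigma[1] < self.psf_sigma[0]:
            raise ConfigurationError("need sigma_axial >= sigma_lateral > 0")
        if self.n_foci and len(self.focus_transcript_counts) != self.n_foci:
            raise ConfigurationError(
                "focus_transcript_counts must list one count per focus"
            )
        if any(c < 2 for c in self.focus_transcript_counts):
            raise ConfigurationError("focus transcript counts must be >= 2")

    @property
    def sigma_voxels(self) -> tuple[float, float, float]:
        lat, ax = self.psf_sigma
        vz, vy, vx = self.voxel_size
        return (ax / vz, lat / vy, lat / vx)

    def nucleus_ids(self, label_names: dict[int, str]) -> tuple[int, ...]:
        return tuple(
            i for i, name in label_names.items()
            if self.nucleus_label_substring in name
        )


@dataclass
class GroundTruth:
    """Complete truth for one simulated stack.

    ``spots`` is a DataFrame with columns spot_id, channel, z_um, y_um, x_um,
    amplitude, spot_class, shared_id, compartment.
    """

    spots: pd.DataFrame
    compartment_mask: np.ndarray
    label_names: dict[int, str]
    true_codetection_fraction: float
    per_compartment_counts: dict[str, int]
    seed: int

    def recount_per_compartment(self) -> dict[str, int]:
        sub = self.spots[self.spots["channel"] == "probe_a"]
        counts = sub["compartment"].value_counts().to_dict()
        return {str(k): int(v) for k, v in counts.items()}


_SPOT_COLUMNS = [
    "spot_id", "channel", "z_um", "y_um", "x_um",
    "amplitude", "spot_class", "shared_id", "compartment",
]


def _add_gaussian(image, center_vox, amplitude, sigma_vox, half_width=4.0):
    """Add an analytic 3D Gaussian into ``image`` over a local window."""
    shape = image.shape
    lo, hi, grids = [], [], []
    for ax in range(3):
        w = max(1, int(math.ceil(half_width * sigma_vox[ax])))
        a = max(0, int(math.floor(center_vox[ax])) - w)
        b = min(shape[ax], int(math.ceil(center_vox[ax])) + w + 1)
        if a >= b:
            return
        lo.append(a)
        hi.append(b)
        grids.append(np.arange(a, b, dtype=float) + 0.5)
    dz = (grids[0] - center_vox[0]) / sigma_vox[0]
    dy = (grids[1] - center_vox[1]) / sigma_vox[1]
    dx = (grids[2] - center_vox[2]) / sigma_vox[2]
    g = np.exp(
        -0.5 * (dz[:, None, None] ** 2 + dy[None, :, None] ** 2
                + dx[None, None, :] ** 2)
    )
    image[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amplitude * g


def _sample_positions_in_region(
    rng, region_vox, voxel_size, n, min_sep=None, sep_scale=(1.0, 1.0, 1.0)
):
    """Uniform positions (µm) within a boolean voxel region.

    With ``min_sep`` set, positions closer than that (µm, after axis-wise
    scaling by ``sep_scale``) to an accepted one are rejected and redrawn
    (hard-sphere process); gives benchmarks with individually resolvable
    spots.  ``sep_scale`` compresses the axial coordinate so separation is
    measured in lateral-resolution units.
    """
    idx = np.flatnonzero(region_vox)
    if idx.size == 0:
        raise ConfigurationError("placement region is empty")

    def draw(k):
        chosen = rng.choice(idx, size=k, replace=True)
        zyx = np.column_stack(
            np.unravel_index(chosen, region_vox.shape)
        ).astype(float)
        zyx += rng.uniform(0.0, 1.0, size=zyx.shape)
        return zyx * np.asarray(voxel_size)

    if not min_sep:
        return draw(n)
    scale = np.asarray(sep_scale)
    accepted: list[np.ndarray] = []
    attempts = 0
    while len(accepted) < n:
        attempts += 1
        if attempts > 500 * n:
            raise ConfigurationError(
                "cannot place spots at the requested min_separation_um"
            )
        cand = draw(1)[0]
        if accepted:
            d2 = (((np.asarray(accepted) - cand) * scale) ** 2).sum(axis=1)
            if (d2 < min_sep**2).any():
                continue
        accepted.append(cand)
    return np.asarray(accepted)


def _compartment_at(mask, label_names, pos_um, voxel_size):
    vox = np.floor(np.asarray(pos_um) / np.asarray(voxel_size)).astype(int)
    vox = np.clip(vox, 0, np.asarray(mask.shape) - 1)
    lid = int(mask[tuple(vox)])
    return label_names.get(lid, "outside") if lid else "outside"


def simulate_image_stack(config: SimulationConfig) -> tuple[ImageStack, GroundTruth]:
    """Render a four-channel stack (probe_a, probe_b, marker, nuclear).

    Ground truth lists every rendered spot with its class, channel,
    codetection partner id and compartment label.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.image_shape)
    voxel_size = np.asarray(config.voxel_size, dtype=float)
    sigma_vox = np.asarray(config.sigma_voxels)
    lat_sigma_um = config.psf_sigma[0]

    if config.compartment_layout:
        mask, label_names = render_layout_mask(
            config.compartment_layout, shape, tuple(voxel_size)
        )
    else:
        mask = np.zeros(shape, dtype=np.int32)
        label_names = {}
    nucleus_ids = config.nucleus_ids(label_names)
    nucleus_region = np.isin(mask, nucleus_ids) if nucleus_ids else None

    if config.compartment_layout:
        cyto_region = (mask > 0)
        if nucleus_region is not None:
            cyto_region &= ~nucleus_region
    else:
        cyto_region = np.ones(shape, dtype=bool)

    records: list[dict] = []
    probe_a = np.zeros(shape, dtype=np.float64)
    probe_b = np.zeros(shape, dtype=np.float64)
    next_id = 0

    # -- single molecules (probe A), shared subset echoed in probe B
    n = config.n_single_spots
    if n:
        sep_scale = (config.psf_sigma[0] / config.psf_sigma[1], 1.0, 1.0)
        pos = _sample_positions_in_region(
            rng, cyto_region, voxel_size, n,
            min_sep=config.min_separation_um, sep_scale=sep_scale,
        )
        amps = rng.normal(
            config.single_amplitude_mean,
            config.single_amplitude_cv * config.single_amplitude_mean,
            size=n,
        )
        amps = np.clip(amps, 0.05 * config.single_amplitude_mean, None)
        shared = rng.random(n) < config.codetection_fraction
        jitter = rng.normal(0.0, 0.5 * lat_sigma_um, size=(n, 3))
        for i in range(n):
            sid = next_id
            next_id += 1
            partner_id = None
            if shared[i]:
                partner_id = next_id
                next_id += 1
            _add_gaussian(probe_a, pos[i] / voxel_size, amps[i], sigma_vox)
            records.append(
                dict(
                    spot_id=sid, channel="probe_a",
                    z_um=pos[i, 0], y_um=pos[i, 1], x_um=pos[i, 2],
                    amplitude=amps[i], spot_class=SINGLE, shared_id=partner_id,
                    compartment=_compartment_at(mask, label_names, pos[i], voxel_size),
                )
            )
            if shared[i]:
                extent = np.asarray(shape) * voxel_size
                bpos = np.clip(pos[i] + jitter[i], 0.0, extent - 1e-9)
                _add_gaussian(probe_b, bpos / voxel_size, amps[i], sigma_vox)
                records.append(
                    dict(
                        spot_id=partner_id, channel="probe_b",
                        z_um=bpos[0], y_um=bpos[1], x_um=bpos[2],
                        amplitude=amps[i], spot_class=SINGLE, shared_id=sid,
                        compartment=_compartment_at(
                            mask, label_names, bpos, voxel_size
                        ),
                    )
                )
        true_fraction = float(shared.mean())
    else:
        true_fraction = float("nan")

    # -- nuclear transcription foci: amplitude = count x unit amplitude
    if config.n_foci:
        if nucleus_region is None or not nucleus_region.any():
            raise ConfigurationError("foci requested but layout has no nucleus")
        pos = _sample_positions_in_region(
            rng, nucleus_region, voxel_size, config.n_foci
        )
        focus_sigma = sigma_vox * config.focus_sigma_factor
        for i, count in enumerate(config.focus_transcript_counts):
            amp = count * config.single_amplitude_mean
            _add_gaussian(probe_a, pos[i] / voxel_size, amp, focus_sigma)
            records.append(
                dict(
                    spot_id=next_id, channel="probe_a",
                    z_um=pos[i, 0], y_um=pos[i, 1], x_um=pos[i, 2],
                    amplitude=amp, spot_class=FOCUS, shared_id=None,
                    compartment=_compartment_at(mask, label_names, pos[i], voxel_size),
                )
            )
            next_id += 1

    # -- wider, dimmer background blobs anywhere in the volume
    if config.n_background_blobs:
        pos = _sample_positions_in_region(
            rng, np.ones(shape, dtype=bool), voxel_size, config.n_background_blobs
        )
        blob_sigma = sigma_vox * config.blob_sigma_factor
        amp = config.blob_amplitude_factor * config.single_amplitude_mean
        for i in range(config.n_background_blobs):
            _add_gaussian(probe_a, pos[i] / voxel_size, amp, blob_sigma)
            records.append(
                dict(
                    spot_id=next_id, channel="probe_a",
                    z_um=pos[i, 0], y_um=pos[i, 1], x_um=pos[i, 2],
                    amplitude=amp, spot_class=BLOB, shared_id=None,
                    compartment=_compartment_at(mask, label_names, pos[i], voxel_size),
                )
            )
            next_id += 1

    # -- marker and nuclear channels render the layout geometry
    marker = np.zeros(shape, dtype=np.float64)
    nuclear = np.zeros(shape, dtype=np.float64)
    if config.compartment_layout:
        marker_region = mask > 0
        if nucleus_region is not None:
            marker_region = marker_region & ~nucleus_region
            nuclear[nucleus_region] = config.marker_amplitude
        marker[marker_region] = config.marker_amplitude
        marker = ndimage.gaussian_filter(marker, 1.0)
        nuclear = ndimage.gaussian_filter(nuclear, 1.0)

    channels = np.stack([probe_a, probe_b, marker, nuclear])
    nm = config.noise_model
    if nm is None:
        noisy = channels
    else:
        noisy = np.empty_like(channels)
        for c in range(4):
            lam = np.clip(channels[c] + nm.baseline, 0.0, None)
            noisy[c] = rng.poisson(lam).astype(np.float64)
            if nm.read_sd > 0:
                noisy[c] += rng.normal(0.0, nm.read_sd, size=shape)

    stack = ImageStack(
        noisy,
        tuple(voxel_size),
        ("probe_a", "probe_b", "marker", "nuclear"),
    )
    spots = pd.DataFrame(records, columns=_SPOT_COLUMNS)
    truth = GroundTruth(
        spots=spots,
        compartment_mask=mask,
        label_names=label_names,
        true_codetection_fraction=true_fraction,
        per_compartment_counts={},
        seed=config.seed,
    )
    truth.per_compartment_counts = truth.recount_per_compartment()
    return stack, truth


@dataclass
class ConditionPair:
    """Two simulated arms plus the generating count-reduction truth."""

    arm_a: list[tuple[ImageStack, GroundTruth]]
    arm_b: list[tuple[ImageStack, GroundTruth]]
    reduction_fraction: float

    @property
    def expected_mean_ratio(self) -> float:
        return 1.0 - self.reduction_fraction


def simulate_condition_pair(
    config: SimulationConfig,
    reduction_fraction: float,
    n_replicates_per_arm: int,
) -> ConditionPair:
    """Two arms of replicate stacks; arm B spot counts are Poisson draws
    with mean scaled by ``1 - reduction_fraction``."""
    if not 0.0 <= reduction_fraction <= 1.0:
        raise ConfigurationError("reduction_fraction must be in [0, 1]")
    if n_replicates_per_arm < 2:
        raise ConfigurationError(
            "need at least 2 replicates per arm for a comparison"
        )
    rng = np.random.default_rng(config.seed)
    mean_a = float(config.n_single_spots)
    arms: list[list[tuple[ImageStack, GroundTruth]]] = [[], []]
    for arm, mean in enumerate([mean_a, mean_a * (1.0 - reduction_fraction)]):
        for _ in range(n_replicates_per_arm):
            n = int(rng.poisson(mean))
            sub_seed = int(rng.integers(0, 2**31 - 1))
            sub = replace(config, n_single_spots=n, seed=sub_seed)
            arms[arm].append(simulate_image_stack(sub))
    return ConditionPair(arms[0], arms[1], float(reduction_fraction))


# --------------------------------------------------------------------------
# annotator scoring tables
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationSimConfig:
    n_genes: int = 100
    compartments: tuple[str, ...] = DEFAULT_TAXONOMY.labels
    tissue: str = "cns"
    pattern_priors: dict[str, float] = field(
        default_factory=lambda: {
            "concordant": 0.25,
            "intercellular": 0.25,
            "intracellular": 0.25,
            "silent": 0.25,
        }
    )
    annotator_error_rate: float = 0.05
    na_rate: float = 0.0
    n_annotators: int = 3
    taxonomy: CompartmentTaxonomy = field(default_factory=CompartmentTaxonomy)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_annotators < 3:
            raise ConfigurationError(
                "majority vote needs at least 3 annotators"
            )
        if not 0.0 <= self.annotator_error_rate < 0.5:
            raise ConfigurationError("annotator_error_rate must be in [0, 0.5)")
        if not 0.0 <= self.na_rate < 1.0:
            raise ConfigurationError("na_rate must be in [0, 1)")
        if set(self.pattern_priors) - set(PATTERN_CLASSES):
            raise ConfigurationError("unknown pattern class in priors")
        if abs(sum(self.pattern_priors.values()) - 1.0) > 1e-9:
            raise ConfigurationError("pattern_priors must sum to 1")


@dataclass
class AnnotationTruth:
    gene_classes: dict[str, str]
    true_calls: pd.DataFrame  # gene_id, tissue, compartment, mrna, protein


def _draw_true_pattern(rng, cls, compartments, taxonomy):
    """Per-compartment (mrna, protein) truth realizing a pattern class."""
    mrna = {c: False for c in compartments}
    protein = {c: False for c in compartments}
    classes = [
        cc for cc in taxonomy.cell_classes()
        if any(taxonomy.cell_class_of.get(c) == cc for c in compartments)
    ]

    def concordant_fill(exclude_classes=()):
        for c in compartments:
            if taxonomy.cell_class_of.get(c) in exclude_classes:
                continue
            present = bool(rng.random() < 0.5)
            mrna[c] = protein[c] = present

    if cls == "silent":
        pass
    elif cls == "concordant":
        concordant_fill()
        if not any(mrna.values()):  # force at least one expressed compartment
            c = compartments[int(rng.integers(len(compartments)))]
            mrna[c] = protein[c] = True
    elif cls == "intercellular":
        target = classes[int(rng.integers(len(classes)))]
        members = [c for c in compartments if taxonomy.cell_class_of[c] == target]
        molecule = "mrna" if rng.random() < 0.5 else "protein"
        for c in members:
            if molecule == "mrna":
                mrna[c] = True
            else:
                protein[c] = True
        concordant_fill(exclude_classes=(target,))
    elif cls == "intracellular":
        candidates = [
            cc for cc in classes
            if any(
                taxonomy.subregion_of[c] == SOMA
                for c in compartments
                if taxonomy.cell_class_of[c] == cc
            )
            and any(
                taxonomy.subregion_of[c] == PERIPHERY
                for c in compartments
                if taxonomy.cell_class_of[c] == cc
            )
        ]
        if not candidates:
            raise ConfigurationError(
                "intracellular pattern needs a cell class with soma and "
                "periphery compartments"
            )
        target = candidates[int(rng.integers(len(candidates)))]
        soma = [
            c for c in compartments
            if taxonomy.cell_class_of[c] == target
            and taxonomy.subregion_of[c] == SOMA
        ]
        periph = [
            c for c in compartments
            if taxonomy.cell_class_of[c] == target
            and taxonomy.subregion_of[c] == PERIPHERY
        ]
        # both molecules present in the class, subregion patterns differ:
        # mRNA reaches soma + periphery, protein stays somatic (or swapped)
        if rng.random() < 0.5:
            broad, narrow = mrna, protein
        else:
            broad, narrow = protein, mrna
        for c in soma + periph:
            broad[c] = True
        for c in soma:
            narrow[c] = True
        concordant_fill(exclude_classes=(target,))
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown pattern class {cls!r}")
    return mrna, protein


def simulate_annotation_table(
    config: AnnotationSimConfig,
) -> tuple[pd.DataFrame, AnnotationTruth]:
    """Draw true per-gene calls from pattern classes, then noisy annotators.

    Each annotator's call flips independently with ``annotator_error_rate``;
    NA replaces a call with probability ``na_rate``.  Returns the long-format
    table (gene_id, tissue, compartment, annotator, mrna_present,
    protein_present with values True/False/NA) and the generating truth.
    """
    rng = np.random.default_rng(config.seed)
    class_names = list(config.pattern_priors)
    probs = np.array([config.pattern_priors[c] for c in class_names])
    gene_ids = [f"gene_{i:04d}" for i in range(config.n_genes)]
    gene_classes: dict[str, str] = {}
    truth_rows, table_rows = [], []
    annotators = [f"annotator_{chr(ord('A') + i)}" for i in range(config.n_annotators)]
    eps, na = config.annotator_error_rate, config.na_rate
    for gid in gene_ids:
        cls = class_names[int(rng.choice(len(class_names), p=probs))]
        gene_classes[gid] = cls
        mrna, protein = _draw_true_pattern(
            rng, cls, config.compartments, config.taxonomy
        )
        for comp in config.compartments:
            truth_rows.append(
                dict(
                    gene_id=gid, tissue=config.tissue, compartment=comp,
                    mrna=mrna[comp], protein=protein[comp],
                )
            )
            for ann in annotators:
                m = mrna[comp] ^ (rng.random() < eps)
                p = protein[comp] ^ (rng.random() < eps)
                m_val = pd.NA if (na and rng.random() < na) else bool(m)
                p_val = pd.NA if (na and rng.random() < na) else bool(p)
                table_rows.append(
                    dict(
                        gene_id=gid, tissue=config.tissue, compartment=comp,
                        annotator=ann, mrna_present=m_val, protein_present=p_val,
                    )
                )
    table = pd.DataFrame(table_rows)
    truth = AnnotationTruth(
        gene_classes=gene_classes, true_calls=pd.DataFrame(truth_rows)
    )
    return table, truth


# --------------------------------------------------------------------------
# neuroblast-lineage per-cell panels
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NeuroblastSimConfig:
    n_genes: int = 200
    n_cells: int = 60
    class_priors: dict[str, float] = field(
        default_factory=lambda: {
            "not_detected": 0.215,
            "homogeneous": 0.57,
            "cell_specific_transcriptional": 0.155,
            "cell_specific_posttranscriptional": 0.06,
        }
    )
    presence_flip_rate: float = 0.0
    mrna_high_mean: float = 8.0
    protein_signal_mean: float = 100.0
    protein_signal_sd: float = 10.0
    protein_background_mean: float = 10.0
    protein_background_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 5:
            raise ConfigurationError("need >= 5 cells per lineage")
        if set(self.class_priors) - set(NEUROBLAST_CLASSES):
            raise ConfigurationError("unknown neuroblast class in priors")
        if abs(sum(self.class_priors.values()) - 1.0) > 1e-9:
            raise ConfigurationError("class_priors must sum to 1")
        if not 0.0 <= self.presence_flip_rate < 0.5:
            raise ConfigurationError("presence_flip_rate must be in [0, 0.5)")


def simulate_neuroblast_panel(
    config: NeuroblastSimConfig,
) -> tuple[dict[str, pd.DataFrame], dict[str, str]]:
    """Per-gene per-cell tables (mrna_count, protein_intensity, focus flags).

    ``presence_flip_rate`` flips each cell's per-molecule presence state
    independently, emulating scoring noise.
    """
    rng = np.random.default_rng(config.seed)
    class_names = list(config.class_priors)
    probs = np.array([config.class_priors[c] for c in class_names])
    n = config.n_cells
    cell_types = np.array(
        ["neuroblast"] + ["GMC"] * max(1, n // 6)
        + ["progeny"] * (n - 1 - max(1, n // 6))
    )
    panels: dict[str, pd.DataFrame] = {}
    labels: dict[str, str] = {}
    for g in range(config.n_genes):
        gid = f"gene_{g:04d}"
        cls = class_names[int(rng.choice(len(class_names), p=probs))]
        labels[gid] = cls
        mrna_on = np.zeros(n, dtype=bool)
        prot_on = np.zeros(n, dtype=bool)
        if cls == "homogeneous":
            mrna_on[:] = True
            prot_on[:] = True
        elif cls == "cell_specific_transcriptional":
            frac = rng.uniform(0.25, 0.6)
            k = int(np.clip(round(frac * n), 2, n - 2))
            idx = rng.choice(n, size=k, replace=False)
            mrna_on[idx] = True
            prot_on[idx] = True
        elif cls == "cell_specific_posttranscriptional":
            mrna_on[:] = True
            k = max(2, int(round(0.2 * n)))
            prot_on[rng.choice(n, size=k, replace=False)] = True
        # scoring noise: flip each presence state independently
        if config.presence_flip_rate:
            mrna_on ^= rng.random(n) < config.presence_flip_rate
            prot_on ^= rng.random(n) < config.presence_flip_rate
        mrna_count = np.where(
            mrna_on, rng.poisson(config.mrna_high_mean, size=n) + 2, 0
        )
        protein = np.where(
            prot_on,
            rng.normal(config.protein_signal_mean, config.protein_signal_sd, n),
            rng.normal(
                config.protein_background_mean, config.protein_background_sd, n
            ),
        )
        focus = mrna_on & (rng.random(n) < 0.9)
        panels[gid] = pd.DataFrame(
            dict(
                cell_id=[f"cell_{i:03d}" for i in range(n)],
                cell_type=cell_types,
                mrna_count=mrna_count,
                protein_intensity=protein,
                has_transcription_focus=focus,
            )
        )
    return panels, labels


# --------------------------------------------------------------------------
# convenience layouts
# --------------------------------------------------------------------------


def brain_layout(
    image_shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
) -> tuple[Primitive, ...]:
    """Soma ellipsoid with an inner nucleus plus a neuropil tube."""
    ext = np.asarray(image_shape) * np.asarray(voxel_size)
    soma_center = (ext[0] / 2, ext[1] * 0.32, ext[2] * 0.32)
    soma_radii = (ext[0] * 0.32, ext[1] * 0.24, ext[2] * 0.24)
    nuc_radii = tuple(r * 0.45 for r in soma_radii)
    tube = Tube(
        "mushroom_body_neuropil",
        (ext[0] / 2, ext[1] * 0.72, ext[2] * 0.12),
        (ext[0] / 2, ext[1] * 0.72, ext[2] * 0.88),
        min(ext[0], ext[1]) * 0.14,
    )
    return (
        Ellipsoid("central_brain_soma", soma_center, soma_radii),
        Ellipsoid("muscle_nucleus", soma_center, nuc_radii),
        tube,
    )


def nmj_layout(
    image_shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    n_boutons: int = 0,
) -> tuple[Primitive, ...]:
    """Axon-terminal tube with optional bouton spheres along it."""
    ext = np.asarray(image_shape) * np.asarray(voxel_size)
    start = np.array([ext[0] / 2, ext[1] * 0.5, ext[2] * 0.1])
    end = np.array([ext[0] / 2, ext[1] * 0.5, ext[2] * 0.9])
    radius = min(ext[0], ext[1]) * 0.12
    prims: list[Primitive] = [Tube("nmj_axon_terminal", tuple(start), tuple(end), radius)]
    for i in range(n_boutons):
        t = (i + 1) / (n_boutons + 1)
        center = start + t * (end - start)
        center[1] += radius * 1.4
        prims.append(
            Ellipsoid(
                f"bouton_{i:02d}",
                tuple(center),
                (radius * 0.9, radius * 0.9, radius * 0.9),
            )
        )
    return tuple(prims)
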