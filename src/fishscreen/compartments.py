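"""3D compartment segmentation, spot counting and condition comparison.

Marker channels are segmented by Gaussian smoothing, a global threshold
(Otsu by default), morphological closing and connected components; retained
components are mapped onto taxonomy labels.  Counting aggregates classified
spots per compartment.  Statistical comparisons follow a fixed decision
tree: Shapiro-Wilk for normality, an F test (two groups) or Levene's test
(more) for equal variances, then Student's t / one-way ANOVA with Tukey for
normal data and Wilcoxon rank sum / Kruskal-Wallis with Dunn otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.morphology import ball, closing

from fishscreen.imagestack import ImageStack
from fishscreen.spots import SpotTable

OUTSIDE = "outside"


@dataclass
class CompartmentMask:
    """Labeled 3D volume aligned with an image stack.

    ``labels`` is an int array (0 = outside); ``label_names`` maps each
    positive id injectively to a taxonomy (or object) name.
    """

    labels: np.ndarray
    label_names: dict[int, str]
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        ids = set(np.unique(self.labels)) - {0}
        if not ids <= set(self.label_names):
            raise ValueError("every positive id needs a name")
        names = list(self.label_names.values())
        if len(set(names)) != len(names):
            raise ValueError("label ids must map injectively to names")

    def name_at(self, pos_um) -> str:
        vox = np.floor(np.asarray(pos_um) / np.asarray(self.voxel_size)).astype(int)
        if (vox < 0).any() or (vox >= np.asarray(self.labels.shape)).any():
            return OUTSIDE
        lid = int(self.labels[tuple(vox)])
        return self.label_names.get(lid, OUTSIDE) if lid else OUTSIDE

    def region(self, name: str) -> np.ndarray:
        ids = [i for i, n in self.label_names.items() if n == name]
        return np.isin(self.labels, ids)

    def save(self, tiff_path, json_path) -> None:
        import json

        import tifffile

        tifffile.imwrite(tiff_path, self.labels.astype(np.int32))
        with open(json_path, "w") as fh:
            json.dump(
                {
                    "label_names": {str(k): v for k, v in self.label_names.items()},
                    "voxel_size": list(self.voxel_size),
                },
                fh,
                indent=1,
            )


@dataclass(frozen=True)
class SegmentationParams:
    smooth_sigma: float = 0.5  # voxels
    threshold: float | None = None  # None -> Otsu
    closing_radius: int = 1
    min_volume: int = 30  # voxels
    bouton_min_volume: int = 10


@dataclass
class SegmentationResult:
    mask: CompartmentMask
    status: str  # "ok" | "empty"
    threshold: float


def segment_marker(
    image: ImageStack,
    marker_channel: str | None = None,
    params: SegmentationParams | None = None,
    layout: list[tuple[str, tuple[float, float, float]]] | None = None,
) -> SegmentationResult:
    """Threshold-based 3D segmentation of a marker channel.

    ``layout`` optionally maps taxonomy labels to expected centroids (µm);
    each retained component takes the label of the nearest layout centroid
    (suffixed when several components share a label so ids stay injective).
    Without a layout, components are named region_001, region_002, ... in
    lexicographic centroid order.  If nothing survives filtering an empty
    mask with status "empty" is returned rather than an error.
    """
    params = params or SegmentationParams()
    img = (
        image.channel(marker_channel)
        if marker_channel is not None
        else np.asarray(image.voxels)
    ).astype(np.float64)
    smoothed = ndimage.gaussian_filter(img, params.smooth_sigma)
    thr = params.threshold
    if thr is None:
        thr = float(threshold_otsu(smoothed))
    binary = smoothed > thr
    if params.closing_radius > 0 and binary.any():
        binary = closing(binary, ball(params.closing_radius))
    comp, n = ndimage.label(binary)
    if n == 0:
        return SegmentationResult(
            CompartmentMask(np.zeros(img.shape, np.int32), {}, image.voxel_size),
            status="empty",
            threshold=thr,
        )
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=range(1, n + 1))
    keep = [i + 1 for i, s in enumerate(sizes) if s >= params.min_volume]
    if not keep:
        return SegmentationResult(
            CompartmentMask(np.zeros(img.shape, np.int32), {}, image.voxel_size),
            status="empty",
            threshold=thr,
        )
    centroids = ndimage.center_of_mass(binary, comp, keep)
    centroids_um = [
        tuple(c * v for c, v in zip(cen, image.voxel_size)) for cen in centroids
    ]
    # determinism: relabel in lexicographic centroid order
    order = sorted(range(len(keep)), key=lambda i: centroids_um[i])
    out = np.zeros(img.shape, dtype=np.int32)
    names: dict[int, str] = {}
    used: dict[str, int] = {}
    for new_id, i in enumerate(order, start=1):
        out[comp == keep[i]] = new_id
        if layout:
            dists = [
                sum((a - b) ** 2 for a, b in zip(centroids_um[i], cen))
                for _, cen in layout
            ]
            base = layout[int(np.argmin(dists))][0]
        else:
            base = f"region_{new_id:03d}"
        count = used.get(base, 0)
        used[base] = count + 1
        names[new_id] = base if count == 0 else f"{base}_{count + 1}"
    return SegmentationResult(
        CompartmentMask(out, names, image.voxel_size), status="ok", threshold=thr
    )


def assign_spots(spots: SpotTable, mask: CompartmentMask) -> SpotTable:
    """Label each spot with the compartment at its nearest voxel.

    Spots outside every component get the label "outside".  Raises when the
    spot table's voxel-size provenance disagrees with the mask frame.
    """
    prov_vs = spots.provenance.get("voxel_size")
    if prov_vs is not None and not np.allclose(prov_vs, mask.voxel_size):
        raise ValueError(
            f"coordinate frame mismatch: spots voxel_size {prov_vs} vs "
            f"mask voxel_size {mask.voxel_size}"
        )
    df = spots.df.copy()
    if len(df):
        pos = df[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)
        vox = np.floor(pos / np.asarray(mask.voxel_size)).astype(int)
        shape = np.asarray(mask.labels.shape)
        inb = ((vox >= 0) & (vox < shape)).all(axis=1)
        labels = np.full(len(df), 0, dtype=int)
        labels[inb] = mask.labels[
            vox[inb, 0], vox[inb, 1], vox[inb, 2]
        ]
        df["compartment"] = [
            mask.label_names.get(l, OUTSIDE) if l else OUTSIDE for l in labels
        ]
    return SpotTable(df, dict(spots.provenance))


def per_compartment_counts(
    spots: SpotTable,
    mask: CompartmentMask,
    protein_channel: ImageStack | None = None,
    image_id: str = "",
) -> pd.DataFrame:
    """CountTable rows: one per labeled compartment (plus "outside").

    Singles and foci are counted separately; focus transcript estimates are
    summed; protein mean intensity is taken over each compartment's voxels
    when a protein channel is supplied.
    """
    df = spots.df
    comp_names = sorted(set(mask.label_names.values())) + [OUTSIDE]
    rows = []
    protein = (
        np.asarray(protein_channel.voxels, dtype=float)
        if protein_channel is not None
        else None
    )
    for name in comp_names:
        sub = df[df["compartment"] == name] if len(df) else df
        n_single = int((sub["spot_class"] == "single").sum()) if len(sub) else 0
        foci = sub[sub["spot_class"] == "focus"] if len(sub) else sub
        n_foci = len(foci)
        focus_sum = float(foci["focus_transcript_estimate"].sum()) if n_foci else 0.0
        pmean = np.nan
        if protein is not None and name != OUTSIDE:
            region = mask.region(name)
            if region.any():
                pmean = float(protein[region].mean())
        rows.append(
            dict(
                image_id=image_id, compartment=name,
                n_single_mRNA=n_single, n_foci=n_foci,
                sum_focus_transcripts=focus_sum,
                protein_mean_intensity=pmean,
            )
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# ghost-bouton classification
# --------------------------------------------------------------------------


@dataclass
class BoutonObject:
    object_id: int
    name: str
    centroid_um: tuple[float, float, float]
    volume_um3: float
    presynaptic_marker_mean: float
    psd_marker_mean: float
    maturity: str  # "ghost" | "mature"


def classify_boutons(
    mask: CompartmentMask,
    presyn_channel: ImageStack,
    psd_channel: ImageStack,
    psd_threshold: float | None = None,
    presyn_threshold: float = 0.0,
    bouton_label_prefix: str = "bouton",
) -> list[BoutonObject]:
    """Classify bouton objects as ghost (presynaptic marker without PSD
    marker) or mature.

    The PSD decision threshold defaults to Otsu over the per-object PSD
    means (manual override via ``psd_threshold``).  Returns an empty list
    when the mask holds no bouton-scale objects.
    """
    presyn = np.asarray(presyn_channel.voxels, dtype=float)
    psd = np.asarray(psd_channel.voxels, dtype=float)
    ids = [
        i for i, n in mask.label_names.items() if n.startswith(bouton_label_prefix)
    ]
    if not ids:
        return []
    voxel_vol = float(np.prod(mask.voxel_size))
    objs = []
    psd_means = []
    for oid in sorted(ids):
        region = mask.labels == oid
        nvox = int(region.sum())
        if nvox == 0:
            continue
        centroid = ndimage.center_of_mass(region)
        centroid_um = tuple(
            float(c * v) for c, v in zip(centroid, mask.voxel_size)
        )
        objs.append(
            BoutonObject(
                object_id=oid,
                name=mask.label_names[oid],
                centroid_um=centroid_um,
                volume_um3=nvox * voxel_vol,
                presynaptic_marker_mean=float(presyn[region].mean()),
                psd_marker_mean=float(psd[region].mean()),
                maturity="mature",
            )
        )
        psd_means.append(objs[-1].psd_marker_mean)
    if psd_threshold is None:
        arr = np.asarray(psd_means, dtype=float)
        if len(arr) >= 2 and arr.std() > 0:
            psd_threshold = float(threshold_otsu(arr, nbins=128))
        else:
            psd_threshold = float(arr.mean()) if len(arr) else 0.0
    for obj in objs:
        ghost = (
            obj.psd_marker_mean < psd_threshold
            and obj.presynaptic_marker_mean >= presyn_threshold
        )
        obj.maturity = "ghost" if ghost else "mature"
    return objs


def boutons_to_frame(objs: list[BoutonObject]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                object_id=o.object_id, name=o.name,
                z_um=o.centroid_um[0], y_um=o.centroid_um[1], x_um=o.centroid_um[2],
                volume_um3=o.volume_um3,
                presynaptic_marker_mean=o.presynaptic_marker_mean,
                psd_marker_mean=o.psd_marker_mean,
                maturity=o.maturity,
            )
            for o in objs
        ],
        columns=[
            "object_id", "name", "z_um", "y_um", "x_um", "volume_um3",
            "presynaptic_marker_mean", "psd_marker_mean", "maturity",
        ],
    )


# --------------------------------------------------------------------------
# statistical decision tree and condition comparison
# --------------------------------------------------------------------------


@dataclass
class TestPlan:
    n_groups: int
    shapiro_pvalues: list[float]
    normal: bool
    variance_test: str
    variance_pvalue: float
    equal_variances: bool
    test_name: str
    posthoc: str | None


def _f_test_two_groups(a, b):
    """Two-sided F test for equality of two variances."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.var(a, ddof=1) / np.var(b, ddof=1)
    if not np.isfinite(f):
        return float(f), 0.0
    dfn, dfd = len(a) - 1, len(b) - 1
    p = 2.0 * min(stats.f.cdf(f, dfn, dfd), stats.f.sf(f, dfn, dfd))
    return float(f), float(min(p, 1.0))


def select_test(
    groups: list[np.ndarray],
    paired: bool = False,
    alpha: float = 0.05,
) -> TestPlan:
    """Assumption-driven test selection.

    Normality: Shapiro-Wilk per group (all must pass at ``alpha``).
    Equal variances: F test for two groups, Levene's test for more.
    Normal + equal variances -> Student's t (2 groups) or one-way ANOVA with
    Tukey (>2); normal with unequal variances -> Welch variants; non-normal
    -> Wilcoxon rank sum (2) or Kruskal-Wallis with Dunn (>2).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 3 for g in groups):
        raise ValueError("every group needs n >= 3")
    shapiro_p = [float(stats.shapiro(g).pvalue) for g in groups]
    normal = all(p > alpha for p in shapiro_p)
    if len(groups) == 2:
        _, var_p = _f_test_two_groups(*groups)
        var_test = "f_test"
    else:
        var_p = float(stats.levene(*groups).pvalue)
        var_test = "levene"
    equal_var = var_p > alpha
    if normal:
        if len(groups) == 2:
            name = "student_t" if equal_var else "welch_t"
            posthoc = None
        else:
            name = "anova" if equal_var else "welch_anova"
            posthoc = "tukey" if equal_var else None
    else:
        if len(groups) == 2:
            name = "wilcoxon_rank_sum"
            posthoc = None
        else:
            name = "kruskal_wallis"
            posthoc = "dunn"
    if paired and len(groups) == 2:
        name = "paired_t" if normal else "wilcoxon_signed_rank"
    return TestPlan(
        n_groups=len(groups),
        shapiro_pvalues=shapiro_p,
        normal=normal,
        variance_test=var_test,
        variance_pvalue=var_p,
        equal_variances=equal_var,
        test_name=name,
        posthoc=posthoc,
    )


def run_test(groups, plan: TestPlan, alternative: str = "two-sided"):
    """Execute the planned hypothesis test; returns (statistic, p_value)."""
    name = plan.test_name
    if name == "student_t":
        r = stats.ttest_ind(groups[0], groups[1], alternative=alternative)
    elif name == "welch_t":
        r = stats.ttest_ind(
            groups[0], groups[1], equal_var=False, alternative=alternative
        )
    elif name == "paired_t":
        r = stats.ttest_rel(groups[0], groups[1], alternative=alternative)
    elif name == "wilcoxon_rank_sum":
        r = stats.mannwhitneyu(groups[0], groups[1], alternative=alternative)
    elif name == "wilcoxon_signed_rank":
        r = stats.wilcoxon(groups[0], groups[1], alternative=alternative)
    elif name == "anova":
        r = stats.f_oneway(*groups)
    elif name == "welch_anova":
        from statsmodels.stats.oneway import anova_oneway

        res = anova_oneway(groups, use_var="unequal", welch_correction=True)
        return float(res.statistic), float(res.pvalue)
    elif name == "kruskal_wallis":
        r = stats.kruskal(*groups)
    else:  # pragma: no cover
        raise ValueError(f"unknown test {name!r}")
    return float(r.statistic), float(r.pvalue)


@dataclass
class ComparisonResult:
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    percent_change: float  # 100 * (mean_b - mean_a) / mean_a; nan if undefined
    percent_change_ci: tuple[float, float]
    test_used: str
    statistic: float
    p_value: float
    plan: TestPlan
    status: str = "ok"  # "ok" | "undefined_reference"


def compare_conditions(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    compartment: str,
    value: str = "n_single_mRNA",
    tail: str = "two",
    direction: str = "less",
    force_test: str | None = None,
) -> ComparisonResult:
    """Compare per-image counts of one compartment between two conditions.

    ``tail="one"`` uses the configured ``direction`` (default: arm B lower,
    matching a knockdown design); the test is chosen by :func:`select_test`
    unless ``force_test`` names one explicitly.  Percent change and its
    normal-approximation CI are relative to arm A's mean; a zero reference
    mean is signalled via ``status`` rather than silently propagated.
    """
    a = _extract(counts_a, compartment, value)
    b = _extract(counts_b, compartment, value)
    plan = select_test([a, b])
    if force_test:
        plan.test_name = force_test
    if tail == "two":
        alternative = "two-sided"
    else:
        # direction describes arm B relative to arm A; scipy's alternative
        # describes the first sample relative to the second
        alternative = "greater" if direction == "less" else "less"
    statistic, p = run_test([a, b], plan, alternative=alternative)
    mean_a, mean_b = float(a.mean()), float(b.mean())
    sem_a = float(a.std(ddof=1) / np.sqrt(len(a)))
    sem_b = float(b.std(ddof=1) / np.sqrt(len(b)))
    if mean_a == 0:
        return ComparisonResult(
            len(a), len(b), mean_a, mean_b, sem_a, sem_b,
            float("nan"), (float("nan"), float("nan")),
            plan.test_name, statistic, p, plan, status="undefined_reference",
        )
    ratio = mean_b / mean_a
    # delta-method standard error of the mean ratio
    se_ratio = abs(ratio) * np.sqrt(
        (sem_a / mean_a) ** 2 + ((sem_b / mean_b) ** 2 if mean_b != 0 else 0.0)
    )
    if mean_b == 0:
        se_ratio = sem_b / mean_a
    z = 1.959963984540054
    ci = (
        100.0 * ((ratio - z * se_ratio) - 1.0),
        100.0 * ((ratio + z * se_ratio) - 1.0),
    )
    return ComparisonResult(
        len(a), len(b), mean_a, mean_b, sem_a, sem_b,
        100.0 * (ratio - 1.0), ci,
        plan.test_name, statistic, p, plan,
    )


def _extract(counts: pd.DataFrame, compartment: str, value: str) -> np.ndarray:
    sub = counts[counts["compartment"] == compartment]
    if sub.empty:
        raise ValueError(f"compartment {compartment!r} absent from count table")
    return sub[value].to_numpy(dtype=float)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (optional multiple-testing correction)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
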