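"""Feature extraction from time–energy spectra, and feature processing.

Five feature sets characterise each spot's preprocessed spectrum:

* ``time`` — 15 descriptors of the 1D time projection (central tendency,
  width, shape, entropy, intensity, and the rise/fall-off positions of the
  bunch profile);
* ``ert`` — the same descriptors on the time projection restricted to each
  of the five nuclear-line energy windows (energy-restricted time);
* ``energy`` — window counts, relative intensities and pairwise window
  ratios, for the full time range and for five 230-bin time segments
  (virtual spatial collimation);
* ``image`` — first-order, grey-level co-occurrence texture and Otsu-mask
  shape features of the 2D spectrum, on the full image and each
  energy-window crop;
* ``combined`` — the union of the four.

Feature names follow ``set:window:segment:base``.  Undefined values (zero
projections, zero denominators, degenerate images) are NaN markers and are
removed later by :func:`filter_features`.

Downstream processing: normalisation to the ΔR = 0 reference measurement,
robustness filtering (NaN / near-zero variance / intraclass correlation),
and correlation clustering that passes one representative per cluster to
the model stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from skimage.feature import graycomatrix
from skimage.filters import threshold_otsu

from .spectra import (
    N_SEGMENTS,
    SEGMENT_BINS,
    Spectrum2D,
    TABLE1_WINDOWS,
    ValidationError,
    energy_centers,
    project_time,
    restrict_energy,
    time_centers,
)

__all__ = [
    "TIME_FEATURE_NAMES",
    "IMAGE_FEATURE_NAMES",
    "META_COLUMNS",
    "FEATURE_SET_NAMES",
    "time_features",
    "energy_restricted_time_features",
    "energy_features",
    "image_features",
    "extract_spot_features",
    "assemble_feature_sets",
    "feature_columns",
    "normalize_to_reference",
    "filter_features",
    "icc_1_1",
    "ClusterMap",
    "cluster_features",
]

#: Base names of the time-projection feature catalogue.
TIME_FEATURE_NAMES: tuple[str, ...] = (
    "mean",
    "median",
    "mode",
    "std",
    "rmad_10_90",
    "mad",
    "iqr",
    "skewness",
    "kurtosis",
    "entropy",
    "total",
    "max",
    "falloff",
    "rise",
    "fwhm",
)

#: Base names of the per-image feature catalogue.
IMAGE_FEATURE_NAMES: tuple[str, ...] = (
    # first order
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "energy",
    "entropy",
    "min",
    "max",
    "p10",
    "p90",
    "median",
    "p25",
    "p75",
    "range",
    "rms",
    "uniformity",
    # grey-level co-occurrence texture
    "glcm_contrast",
    "glcm_dissimilarity",
    "glcm_homogeneity",
    "glcm_asm",
    "glcm_correlation",
    "glcm_entropy",
    # Otsu-mask shape
    "foreground_fraction",
    "centroid_time",
    "centroid_energy",
    "axis_ratio",
)

META_COLUMNS: tuple[str, ...] = ("beam_energy", "mode", "dataset", "cavity_mm", "split")

FEATURE_SET_NAMES: tuple[str, ...] = ("time", "ert", "energy", "image", "combined")

_NAN_CATALOGUE = {name: float("nan") for name in TIME_FEATURE_NAMES}


# ---------------------------------------------------------------------------
# time-projection features


def _histogram_quantile(hist: np.ndarray, centers: np.ndarray, q, bin_width: float):
    """Quantile of the binned distribution, mass uniform within each bin."""
    cum = np.cumsum(hist) / hist.sum()
    left = centers[0] - 0.5 * bin_width
    xp = np.concatenate(([0.0], cum))
    fp = np.concatenate(([left], centers + 0.5 * bin_width))
    return np.interp(q, xp, fp)


def time_features(hist: np.ndarray, centers: np.ndarray) -> dict[str, float]:
    """The 15-feature catalogue of a 1D time histogram.

    The histogram is treated as a discrete distribution after normalising
    to unit mass; positional features are in ns.  The rise and fall-off
    positions are the first/last 50 %-of-maximum crossings of the 5-bin
    boxcar-smoothed histogram (linear interpolation); FWHM is their
    difference.  An all-zero histogram yields NaN for every feature.
    """
    hist = np.asarray(hist, dtype=float)
    centers = np.asarray(centers, dtype=float)
    if hist.ndim != 1 or hist.shape != centers.shape:
        raise ValidationError("histogram and bin centres must be matching 1D arrays")
    if np.min(hist, initial=0.0) < 0:
        raise ValidationError("histogram counts must be non-negative")
    total = hist.sum()
    if total == 0 or hist.size == 0:
        return dict(_NAN_CATALOGUE)

    bin_width = float(centers[1] - centers[0]) if centers.size > 1 else 0.0
    p = hist / total
    mean = float(p @ centers)
    dev = centers - mean
    var = float(p @ dev**2)
    std = float(np.sqrt(var))
    if std > 0:
        skewness = float(p @ dev**3) / std**3
        kurtosis = float(p @ dev**4) / std**4 - 3.0
    else:
        skewness = float("nan")
        kurtosis = float("nan")

    if centers.size > 1:
        q10, q25, median, q75, q90 = _histogram_quantile(
            hist, centers, [0.10, 0.25, 0.50, 0.75, 0.90], bin_width
        )
    else:
        q10 = q25 = median = q75 = q90 = float(centers[0])
    sel = (centers >= q10) & (centers <= q90)
    if p[sel].sum() > 0:
        mean_r = float(p[sel] @ centers[sel]) / float(p[sel].sum())
        rmad = float(p[sel] @ np.abs(centers[sel] - mean_r)) / float(p[sel].sum())
    else:
        rmad = float("nan")
    mad = float(p @ np.abs(dev))

    positive = p[p > 0]
    entropy = float(-(positive @ np.log(positive)))

    if centers.size >= 2:
        smoothed = np.convolve(hist, np.full(5, 0.2), mode="same")
    else:
        smoothed = hist
    half = 0.5 * smoothed.max()
    above = smoothed >= half
    i0 = int(np.argmax(above))
    i1 = int(len(above) - 1 - np.argmax(above[::-1]))
    if i0 > 0 and smoothed[i0] > smoothed[i0 - 1]:
        rise = centers[i0 - 1] + (half - smoothed[i0 - 1]) / (
            smoothed[i0] - smoothed[i0 - 1]
        ) * bin_width
    else:
        rise = float(centers[i0])
    if i1 < len(above) - 1 and smoothed[i1] > smoothed[i1 + 1]:
        falloff = centers[i1] + (smoothed[i1] - half) / (
            smoothed[i1] - smoothed[i1 + 1]
        ) * bin_width
    else:
        falloff = float(centers[i1])

    return {
        "mean": mean,
        "median": float(median),
        "mode": float(centers[int(np.argmax(hist))]),
        "std": std,
        "rmad_10_90": rmad,
        "mad": mad,
        "iqr": float(q75 - q25),
        "skewness": skewness,
        "kurtosis": kurtosis,
        "entropy": entropy,
        "total": float(total),
        "max": float(hist.max()),
        "falloff": float(falloff),
        "rise": float(rise),
        "fwhm": float(falloff - rise),
    }


def full_time_features(spec: Spectrum2D) -> dict[str, float]:
    """Time features of the unrestricted time projection."""
    values = time_features(project_time(spec), time_centers(spec))
    return {f"time:all:all:{base}": v for base, v in values.items()}


def energy_restricted_time_features(spec: Spectrum2D) -> dict[str, float]:
    """Time features of each energy-window-restricted time projection."""
    out: dict[str, float] = {}
    for window in TABLE1_WINDOWS:
        sub = restrict_energy(spec, window)
        values = time_features(project_time(sub), time_centers(sub))
        out.update({f"ert:{window.name}:all:{base}": v for base, v in values.items()})
    return out


# ---------------------------------------------------------------------------
# energy-window count features


def _segment_slices(n_time_bins: int) -> list[tuple[str, slice]]:
    slices: list[tuple[str, slice]] = [("all", slice(None))]
    if n_time_bins >= N_SEGMENTS * SEGMENT_BINS:
        slices += [
            (f"t{i}", slice(i * SEGMENT_BINS, (i + 1) * SEGMENT_BINS))
            for i in range(N_SEGMENTS)
        ]
    return slices


def energy_features(spec: Spectrum2D) -> dict[str, float]:
    """Window counts, relative intensities and pairwise window ratios.

    Computed over the full time range and over each of the five 230-bin
    time segments.  Ratios divide the lower-index window by the
    higher-index one; a zero denominator yields NaN.
    """
    edges = spec.binning.energy_edges_MeV
    eps = 1e-9 * spec.binning.energy_bin_width_MeV
    window_masks = [
        (w.name, (edges[:-1] < w.e_max - eps) & (edges[1:] > w.e_min + eps))
        for w in TABLE1_WINDOWS
    ]
    out: dict[str, float] = {}
    for seg_name, sl in _segment_slices(spec.binning.n_time_bins):
        block = spec.counts[sl]
        total = float(block.sum())
        window_counts = {name: float(block[:, mask].sum()) for name, mask in window_masks}
        out[f"energy:all:{seg_name}:total"] = total
        for name, c in window_counts.items():
            out[f"energy:{name}:{seg_name}:counts"] = c
            out[f"energy:{name}:{seg_name}:relative"] = c / total if total > 0 else float("nan")
        names = [w.name for w in TABLE1_WINDOWS]
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                denom = window_counts[names[j]]
                value = window_counts[names[i]] / denom if denom > 0 else float("nan")
                out[f"energy:{names[i]}_{names[j]}:{seg_name}:ratio"] = value
    return out


# ---------------------------------------------------------------------------
# image features


def _requantise(values: np.ndarray, n_levels: int) -> np.ndarray:
    vmin, vmax = float(values.min()), float(values.max())
    if vmax <= vmin:
        return np.zeros(values.shape, dtype=np.uint8)
    levels = np.floor((values - vmin) / (vmax - vmin) * n_levels).astype(np.int64)
    return np.clip(levels, 0, n_levels - 1).astype(np.uint8)


def _glcm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    """Distance-1 co-occurrence features, symmetric, averaged over the four
    standard directions.  Correlation is NaN for a constant image."""
    glcm = graycomatrix(
        levels,
        distances=[1],
        angles=[0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=n_levels,
        symmetric=True,
        normed=True,
    )[:, :, 0, :]
    i_idx, j_idx = np.meshgrid(np.arange(n_levels), np.arange(n_levels), indexing="ij")
    diff = i_idx - j_idx
    acc = {k: [] for k in ("contrast", "dissimilarity", "homogeneity", "asm", "correlation", "entropy")}
    for a in range(glcm.shape[-1]):
        p = glcm[:, :, a]
        acc["contrast"].append(float((p * diff**2).sum()))
        acc["dissimilarity"].append(float((p * np.abs(diff)).sum()))
        acc["homogeneity"].append(float((p / (1.0 + diff**2)).sum()))
        acc["asm"].append(float((p**2).sum()))
        mu_i = float((p * i_idx).sum())
        mu_j = float((p * j_idx).sum())
        var_i = float((p * (i_idx - mu_i) ** 2).sum())
        var_j = float((p * (j_idx - mu_j) ** 2).sum())
        if var_i > 0 and var_j > 0:
            corr = float((p * (i_idx - mu_i) * (j_idx - mu_j)).sum()) / np.sqrt(var_i * var_j)
        else:
            corr = float("nan")
        acc["correlation"].append(corr)
        pos = p[p > 0]
        acc["entropy"].append(float(-(pos * np.log(pos)).sum()))
    return {f"glcm_{k}": float(np.mean(v)) for k, v in acc.items()}


def _single_image_features(spec: Spectrum2D, n_levels: int) -> dict[str, float]:
    img = spec.counts
    values = img.ravel()
    n = values.size
    mean = float(values.mean())
    var = float(values.var())
    out: dict[str, float] = {"mean": mean, "variance": var}
    if var > 0:
        std = np.sqrt(var)
        out["skewness"] = float(np.mean((values - mean) ** 3)) / std**3
        out["kurtosis"] = float(np.mean((values - mean) ** 4)) / std**4 - 3.0
    else:
        out["skewness"] = float("nan")
        out["kurtosis"] = float("nan")
    total = values.sum()
    out["energy"] = float(((values / total) ** 2).sum()) if total > 0 else float("nan")
    levels = _requantise(img, n_levels)
    hist = np.bincount(levels.ravel(), minlength=n_levels) / n
    pos = hist[hist > 0]
    out["entropy"] = float(-(pos * np.log(pos)).sum())
    out["uniformity"] = float((hist**2).sum())
    p10, p25, median, p75, p90 = np.percentile(values, [10, 25, 50, 75, 90])
    out.update(
        {
            "min": float(values.min()),
            "max": float(values.max()),
            "p10": float(p10),
            "p90": float(p90),
            "median": float(median),
            "p25": float(p25),
            "p75": float(p75),
            "range": float(values.max() - values.min()),
            "rms": float(np.sqrt(np.mean(values**2))),
        }
    )
    out.update(_glcm_features(levels, n_levels))

    # Otsu-threshold mask shape
    if values.max() > values.min():
        thr = threshold_otsu(values)
        mask = img > thr
    else:
        mask = np.zeros(img.shape, dtype=bool)
    out["foreground_fraction"] = float(mask.mean())
    if mask.any():
        tt, ee = np.meshgrid(time_centers(spec), energy_centers(spec), indexing="ij")
        coords = np.column_stack([tt[mask], ee[mask]])
        out["centroid_time"] = float(coords[:, 0].mean())
        out["centroid_energy"] = float(coords[:, 1].mean())
        if coords.shape[0] > 1:
            cov = np.cov(coords, rowvar=False, ddof=0)
            eigvals = np.sort(np.linalg.eigvalsh(cov))
            out["axis_ratio"] = (
                float(np.sqrt(eigvals[0] / eigvals[1])) if eigvals[1] > 0 else float("nan")
            )
        else:
            out["axis_ratio"] = float("nan")
    else:
        out["centroid_time"] = float("nan")
        out["centroid_energy"] = float("nan")
        out["axis_ratio"] = float("nan")
    return out


def image_features(spec: Spectrum2D, n_levels: int = 32) -> dict[str, float]:
    """Radiomics-style image features of the full spectrum and each
    energy-window crop (26 features per image, 6 images)."""
    out: dict[str, float] = {}
    for img_name, sub in [("full", spec)] + [
        (w.name, restrict_energy(spec, w)) for w in TABLE1_WINDOWS
    ]:
        values = _single_image_features(sub, n_levels)
        out.update({f"image:{img_name}:all:{base}": v for base, v in values.items()})
    return out


# ---------------------------------------------------------------------------
# assembly


def extract_spot_features(
    spec: Spectrum2D, sets: tuple[str, ...] = ("time", "ert", "energy", "image")
) -> dict[str, float]:
    """All requested feature sets of one preprocessed spectrum."""
    out: dict[str, float] = {}
    if "time" in sets:
        out.update(full_time_features(spec))
    if "ert" in sets:
        out.update(energy_restricted_time_features(spec))
    if "energy" in sets:
        out.update(energy_features(spec))
    if "image" in sets:
        out.update(image_features(spec))
    return out


def _meta_row(meta) -> dict[str, object]:
    return {
        "beam_energy": meta.beam_energy,
        "mode": meta.mode,
        "dataset": meta.dataset,
        "cavity_mm": meta.cavity_mm,
        "split": meta.split,
    }


def assemble_feature_sets(rows: list[tuple[object, dict[str, float]]]) -> dict[str, pd.DataFrame]:
    """Build the five per-set feature tables (spots × features).

    ``rows`` holds ``(SpotMeta, feature dict)`` per spot.  The combined
    table is the union of the four sets; tables share spot ids (the index)
    and the metadata columns, including the ``cavity_mm`` target.
    """
    ids = [meta.spot_id for meta, _ in rows]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate spot_ids in feature assembly")
    combined = pd.DataFrame([values for _, values in rows], index=ids)
    meta_df = pd.DataFrame([_meta_row(meta) for meta, _ in rows], index=ids)
    tables: dict[str, pd.DataFrame] = {}
    for set_name in ("time", "ert", "energy", "image"):
        cols = [c for c in combined.columns if c.startswith(f"{set_name}:")]
        tables[set_name] = pd.concat([meta_df, combined[cols]], axis=1)
    tables["combined"] = pd.concat([meta_df, combined], axis=1)
    return tables


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature columns of a table (everything except the metadata block)."""
    return [c for c in table.columns if c not in META_COLUMNS]


# ---------------------------------------------------------------------------
# normalisation, filtering, clustering


def normalize_to_reference(
    table: pd.DataFrame, group_cols: tuple[str, ...] = ("beam_energy", "dataset")
) -> pd.DataFrame:
    """Divide each feature by the median of the ΔR = 0 reference spots.

    Reference spots per (energy, dataset) group are the train-labelled
    ΔR = 0 spots when the group has any, otherwise all its ΔR = 0 spots
    (scanned data are test-only; their ΔR = 0 acquisition is the
    calibration measurement).  A zero reference median marks the feature
    non-normalisable (NaN everywhere) so the filter removes it.
    """
    feats = feature_columns(table)
    out = table.copy()
    bad_features: set[str] = set()
    for _, group in table.groupby(list(group_cols), sort=False):
        ref = group[(group["cavity_mm"] == 0) & (group["split"] == "train")]
        if ref.empty:
            ref = group[group["cavity_mm"] == 0]
        if ref.empty:
            raise ValidationError(
                "no ΔR = 0 reference spots in group "
                f"{dict(zip(group_cols, group.iloc[0][list(group_cols)]))}"
            )
        med = ref[feats].median()
        zero = med.index[med == 0]
        bad_features.update(zero)
        out.loc[group.index, feats] = group[feats] / med
    if bad_features:
        out[sorted(bad_features)] = np.nan
    return out


def icc_1_1(values: np.ndarray, groups: np.ndarray) -> float:
    """One-way random-effects intraclass correlation ICC(1,1).

    ``groups`` labels repeated measurements of the same condition; the ICC
    compares between-condition to within-condition variance via one-way
    ANOVA mean squares, with the unbalanced-design group-size correction.
    """
    values = np.asarray(values, dtype=float)
    labels, inverse = np.unique(np.asarray(groups), return_inverse=True)
    k = labels.size
    n_total = values.size
    if k < 2 or n_total <= k:
        return float("nan")
    grand = values.mean()
    group_sizes = np.bincount(inverse)
    group_means = np.bincount(inverse, weights=values) / group_sizes
    ssb = float(group_sizes @ (group_means - grand) ** 2)
    ssw = float(((values - group_means[inverse]) ** 2).sum())
    msb = ssb / (k - 1)
    msw = ssw / (n_total - k)
    n0 = (n_total - float(group_sizes @ group_sizes) / n_total) / (k - 1)
    denom = msb + (n0 - 1.0) * msw
    if denom <= 0:
        return 0.0
    return (msb - msw) / denom


def filter_features(
    table: pd.DataFrame,
    variance_floor: float = 1e-8,
    icc_threshold: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Drop unusable or non-robust features, judged on training rows only.

    Removes features with any NaN marker, with sample variance below
    ``variance_floor``, or with intraclass correlation across repeated
    spots of identical (energy, cavity, mode) below ``icc_threshold``.
    Returns the filtered table and a drop log (feature → reason).
    """
    train = table[table["split"] == "train"]
    if train.empty:
        raise ValidationError("filter_features needs training rows")
    groups = (
        train["beam_energy"].astype(str)
        + "|"
        + train["cavity_mm"].astype(str)
        + "|"
        + train["mode"].astype(str)
    ).to_numpy()
    multi_group = np.unique(groups).size >= 2
    log: dict[str, str] = {}
    keep: list[str] = []
    for name in feature_columns(table):
        col = train[name].to_numpy(dtype=float)
        if np.isnan(col).any():
            log[name] = "undefined"
            continue
        if np.var(col, ddof=1) < variance_floor:
            log[name] = "near_zero_variance"
            continue
        if multi_group:
            icc = icc_1_1(col, groups)
            if not icc >= icc_threshold:
                log[name] = "low_icc"
                continue
        keep.append(name)
    if not keep:
        raise ValidationError("all features dropped by filtering")
    return table[list(META_COLUMNS) + keep], log


@dataclass(frozen=True)
class ClusterMap:
    """Partition of the retained features into correlation clusters."""

    clusters: dict[int, tuple[str, ...]]
    representatives: dict[int, str]

    @property
    def representative_names(self) -> list[str]:
        return [self.representatives[cid] for cid in sorted(self.representatives)]

    def __post_init__(self) -> None:
        for cid, rep in self.representatives.items():
            if rep not in self.clusters[cid]:
                raise ValidationError(f"representative {rep!r} not in cluster {cid}")


def cluster_features(table: pd.DataFrame, threshold: float = 0.9) -> ClusterMap:
    """Agglomerative average-linkage clustering on 1 − |Spearman ρ|.

    Features with |ρ| ≥ ``threshold`` (training rows) merge; each cluster
    is represented downstream by the member with the highest mean |ρ| to
    its cluster (ties break lexicographically).
    """
    feats = feature_columns(table)
    train = table[table["split"] == "train"]
    if len(feats) == 1:
        return ClusterMap(clusters={1: (feats[0],)}, representatives={1: feats[0]})
    x = train[feats].to_numpy(dtype=float)
    rho = spearmanr(x).statistic
    rho = np.atleast_2d(np.nan_to_num(rho))
    if rho.shape != (len(feats), len(feats)):  # spearmanr collapses the 2-feature case
        r = float(rho.ravel()[0])
        rho = np.array([[1.0, r], [r, 1.0]])
    dist = np.clip(1.0 - np.abs(rho), 0.0, None)
    np.fill_diagonal(dist, 0.0)
    dist = 0.5 * (dist + dist.T)
    z = linkage(squareform(dist, checks=False), method="average")
    assignment = fcluster(z, t=1.0 - threshold, criterion="distance")
    clusters: dict[int, tuple[str, ...]] = {}
    representatives: dict[int, str] = {}
    for cid in np.unique(assignment):
        members = [feats[i] for i in np.flatnonzero(assignment == cid)]
        clusters[int(cid)] = tuple(members)
        if len(members) == 1:
            representatives[int(cid)] = members[0]
            continue
        idx = [feats.index(m) for m in members]
        sub = np.abs(rho[np.ix_(idx, idx)])
        scores = (sub.sum(axis=1) - 1.0) / (len(members) - 1)  # mean |ρ| to the others
        best = scores.max()
        candidates = [m for m, s in zip(members, scores) if s >= best - 1e-12]
        representatives[int(cid)] = sorted(candidates)[0]
    return ClusterMap(clusters=clusters, representatives=representatives)
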