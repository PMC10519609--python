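"""Synthetic inputs for the whole pipeline.

Three generators, each a pure function of its config (seed included):

* :func:`simulate_image` — multi-channel fluorescent cytology fields with
  ground-truth nucleus/cell label masks and a per-object truth table.
  Cells are randomly oriented ellipses with interior nuclei; atypical
  cells draw a stochastically higher nuclear/cytoplasmic area ratio and
  get boundary-perturbed ("irregular") nuclei; clusters are overlapping
  cells forming one connected region; artefacts are nucleus-free blobs.
* :func:`simulate_cohort` — per-patient marker feature vectors with
  clinical covariates, whose population means rise with disease grade
  (SNA-1 LRL < HGD < OSCC; CD44 nuclear positivity low in LRL; MAA and
  Cyclin D1 highest in carcinoma) and whose CD44 baseline shifts by
  anatomical site × age group.
* :func:`simulate_meta_studies` — meta-analysis study sets drawn around a
  true log odds ratio with between-study variance τ².

All intensities live on a normalised [0, 1] scale; channel order is fixed
as (DAPI, marker1, marker2); pixel coordinates are 0-based row-major.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit, logit

from .metadx import Study2x2

CLASSES = ("NORMAL", "LRL", "HGD", "OSCC")
SITES = ("buccal", "tongue", "gingiva")
MARKERS = ("CD44", "SNA1", "MAA", "CYCD1")
FEATURES = ("SNA1avg", "SNA1max", "CD44max", "CD44Npos", "CD44pct",
            "CYCD1Npos", "MAAavg")

__all__ = [
    "ImageSimConfig",
    "SyntheticImageBundle",
    "CohortSimConfig",
    "MetaSimConfig",
    "simulate_image",
    "simulate_cohort",
    "simulate_meta_studies",
    "simulate_crops",
    "PlacementError",
]


class PlacementError(RuntimeError):
    """Raised when an object cannot be placed without overlap."""


# --------------------------------------------------------------------------
# image simulation
# --------------------------------------------------------------------------

# per-class cytoplasmic marker intensity means (normalised scale) and the
# probability that a cell is nuclear-positive for nuclear-pattern markers
_MARKER_MEAN = {
    "SNA1": {"NORMAL": 0.25, "LRL": 0.30, "HGD": 0.45, "OSCC": 0.60},
    "CD44": {"NORMAL": 0.30, "LRL": 0.30, "HGD": 0.45, "OSCC": 0.50},
    "MAA": {"NORMAL": 0.25, "LRL": 0.30, "HGD": 0.35, "OSCC": 0.50},
    "CYCD1": {"NORMAL": 0.25, "LRL": 0.28, "HGD": 0.32, "OSCC": 0.40},
}
_NUC_POS_PROB = {
    "CD44": {"NORMAL": 0.10, "LRL": 0.10, "HGD": 0.35, "OSCC": 0.45},
    "CYCD1": {"NORMAL": 0.05, "LRL": 0.10, "HGD": 0.15, "OSCC": 0.30},
}
_DAPI_MEAN, _DAPI_SD = 0.80, 0.05
_MARKER_SD = 0.05
_NUC_BOOST = 0.25  # added nuclear marker intensity in nuclear-positive cells

# atypia encoding: N/C area-ratio distributions (truncated normals)
_NC_NORMAL = (0.18, 0.05, 0.05, 0.40)   # mean, sd, lo, hi
_NC_ATYPICAL = (0.45, 0.08, 0.20, 0.90)
_IRREGULARITY_AMP = 0.12  # radial boundary perturbation of atypical nuclei

_MAX_TRIES = 1000


@dataclass(frozen=True)
class ImageSimConfig:
    width: int = 512
    height: int = 512
    n_cells: int = 40
    atypical_fraction: float = 0.3
    cluster_fraction: float = 0.0
    artefact_count: int = 0
    class_label: str = "LRL"
    channel_set: tuple[str, ...] = ("DAPI", "CD44", "SNA1")
    psf_sigma: float = 1.0
    noise_sd: float = 0.02
    cell_radius_range: tuple[float, float] = (14.0, 24.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ValueError("image must be at least 64x64")
        if self.n_cells < 0 or self.artefact_count < 0:
            raise ValueError("object counts must be >= 0")
        for frac in (self.atypical_fraction, self.cluster_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.class_label not in CLASSES:
            raise ValueError(f"class_label must be one of {CLASSES}")
        if self.channel_set[0] != "DAPI":
            raise ValueError("channel_set must start with DAPI")
        if len(self.channel_set) > 3:
            raise ValueError("at most DAPI + two marker channels")
        for ch in self.channel_set[1:]:
            if ch not in MARKERS:
                raise ValueError(f"unknown marker channel {ch!r}")


@dataclass
class SyntheticImageBundle:
    image: np.ndarray            # (n_channels, H, W) float in [0, 1]
    nucleus_labels: np.ndarray   # (H, W) int, 0 = background
    cell_labels: np.ndarray      # (H, W) int, 0 = background
    truth: pd.DataFrame          # one row per labelled object
    channels: tuple[str, ...]
    config: ImageSimConfig


def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return x
    return float(np.clip(mean, lo, hi))


def _ellipse_mask(h, w, cy, cx, a, b, angle, perturb=None, rng=None):
    """Boolean mask of an ellipse (semi-axes a, b at `angle`), optionally
    with a smooth radial boundary perturbation (irregular nucleus)."""
    y0 = max(0, int(cy - max(a, b) * 1.4) - 2)
    y1 = min(h, int(cy + max(a, b) * 1.4) + 3)
    x0 = max(0, int(cx - max(a, b) * 1.4) - 2)
    x1 = min(w, int(cx + max(a, b) * 1.4) + 3)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ca, sa = math.cos(angle), math.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    if perturb is not None:
        amp, k1, p1, k2, p2 = perturb
        theta = np.arctan2(v, u)
        f = 1.0 + amp * (0.6 * np.sin(k1 * theta + p1) + 0.4 * np.sin(k2 * theta + p2))
        inside = rho <= f
    else:
        inside = rho <= 1.0
    mask = np.zeros((h, w), dtype=bool)
    mask[y0:y1, x0:x1] = inside
    return mask


def _draw_cell(rng, radius_range, atypical: bool, center):
    """Geometry for one cell: (cell params, nucleus params)."""
    r_lo, r_hi = radius_range
    a = rng.uniform(r_lo, r_hi)
    b = rng.uniform(r_lo, r_hi)
    angle = rng.uniform(-math.pi / 2, math.pi / 2)
    if atypical:
        nc = _truncated_normal(rng, *_NC_ATYPICAL)
        perturb = (_IRREGULARITY_AMP, rng.integers(3, 6), rng.uniform(0, 2 * math.pi),
                   rng.integers(6, 9), rng.uniform(0, 2 * math.pi))
    else:
        nc = _truncated_normal(rng, *_NC_NORMAL)
        perturb = None
    s = math.sqrt(nc)
    # keep the (possibly perturbed) nucleus fully interior with >=1 px margin
    bulge = 1.0 + (_IRREGULARITY_AMP if perturb else 0.0)
    s = min(s, (min(a, b) - 2.0) / (min(a, b) * bulge))
    an, bn = a * s, b * s
    max_off = max(0.0, min(a, b) * (1.0 - s * bulge) - 1.0)
    off = rng.uniform(-max_off / 2, max_off / 2, size=2)
    return (center, a, b, angle), (center + off, an, bn, angle, perturb), nc


def _place_centers(rng, cfg, occupancy, radius, n_members):
    """Rejection-sample the center(s) of a single cell or a cluster."""
    h, w = cfg.height, cfg.width
    margin = radius * 1.3 + 3
    for _ in range(_MAX_TRIES):
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        centers = [np.array([cy, cx])]
        for _ in range(n_members - 1):
            ang = rng.uniform(0, 2 * math.pi)
            d = radius * rng.uniform(1.0, 1.4)  # overlapping neighbours
            centers.append(np.array([cy + d * math.sin(ang), cx + d * math.cos(ang)]))
        ok = True
        for c in centers:
            y, x = int(c[0]), int(c[1])
            if not (margin / 2 < c[0] < h - margin / 2 and margin / 2 < c[1] < w - margin / 2):
                ok = False
                break
            y0, y1 = max(0, y - int(margin)), min(h, y + int(margin))
            x0, x1 = max(0, x - int(margin)), min(w, x + int(margin))
            if occupancy[y0:y1, x0:x1].any():
                ok = False
                break
        if ok:
            return centers
    raise PlacementError(
        f"could not place an object after {_MAX_TRIES} tries "
        f"({cfg.width}x{cfg.height}, n_cells={cfg.n_cells})"
    )


def simulate_image(cfg: ImageSimConfig) -> SyntheticImageBundle:
    """Render one synthetic fluorescent cytology field with ground truth.

    The truth table records, per labelled object: ``object_id``, ``type``
    (cell/cluster/artefact), ``atypia``, the true N/C area ratio measured
    on the rendered masks, and per-channel mean intensities before blur
    and noise.  Identical configs (same seed) give bit-identical bundles.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height, cfg.width
    n_ch = len(cfg.channel_set)
    ideal = np.zeros((n_ch, h, w), dtype=float)
    nucleus_labels = np.zeros((h, w), dtype=np.uint16)
    cell_labels = np.zeros((h, w), dtype=np.uint16)
    occupancy = np.zeros((h, w), dtype=bool)

    # group cells into clusters
    n_clustered = int(round(cfg.cluster_fraction * cfg.n_cells))
    groups: list[int] = []
    remaining = n_clustered
    while remaining >= 2:
        size = int(min(remaining, rng.integers(2, 4)))
        groups.append(size)
        remaining -= size
    n_single = cfg.n_cells - sum(groups)
    object_plan = [("cell", 1)] * n_single + [("cluster", g) for g in groups]

    truth_rows = []
    next_label = 1
    mean_radius = sum(cfg.cell_radius_range) / 2

    for kind, n_members in object_plan:
        centers = _place_centers(rng, cfg, occupancy, mean_radius, n_members)
        cell_mask_total = np.zeros((h, w), dtype=bool)
        nuc_mask_total = np.zeros((h, w), dtype=bool)
        any_atypical = False
        member_nuc_labels = []
        for c in centers:
            atypical = bool(rng.random() < cfg.atypical_fraction)
            any_atypical |= atypical
            (cc, a, b, ang), (nc_center, an, bn, nang, pert), _ = _draw_cell(
                rng, cfg.cell_radius_range, atypical, c)
            cmask = _ellipse_mask(h, w, cc[0], cc[1], a, b, ang)
            nmask = _ellipse_mask(h, w, nc_center[0], nc_center[1], an, bn, nang,
                                  perturb=pert)
            nmask &= cmask  # safety under discretisation
            cell_mask_total |= cmask
            nuc_mask_total |= nmask
            member_nuc_labels.append(nmask)

        obj_id = next_label
        next_label += 1
        cell_labels[cell_mask_total] = obj_id
        for nmask in member_nuc_labels:
            nuc_id = int(nucleus_labels.max()) + 1
            nucleus_labels[nmask & (nucleus_labels == 0)] = nuc_id
        occupancy |= ndimage.binary_dilation(cell_mask_total, iterations=3)

        # intensities (pre-noise truth)
        intensities = {}
        dapi = float(np.clip(rng.normal(_DAPI_MEAN, _DAPI_SD), 0.15, 0.95))
        for ci, ch in enumerate(cfg.channel_set):
            if ch == "DAPI":
                ideal[ci][nuc_mask_total] = np.maximum(ideal[ci][nuc_mask_total], dapi)
                intensities[ch] = dapi
            else:
                mean = _MARKER_MEAN[ch][cfg.class_label]
                val = float(np.clip(rng.normal(mean, _MARKER_SD), 0.1, 0.95))
                ideal[ci][cell_mask_total] = np.maximum(ideal[ci][cell_mask_total], val)
                npos = ch in _NUC_POS_PROB and rng.random() < _NUC_POS_PROB[ch][cfg.class_label]
                if npos:
                    ideal[ci][nuc_mask_total] = np.maximum(
                        ideal[ci][nuc_mask_total], val + _NUC_BOOST)
                intensities[ch] = val
        nc_ratio = float(nuc_mask_total.sum()) / float(cell_mask_total.sum())
        truth_rows.append({
            "object_id": obj_id, "type": kind,
            "atypia": "atypical" if any_atypical else "normal",
            "nc_ratio": nc_ratio,
            **{f"intensity_{ch}": intensities[ch] for ch in cfg.channel_set},
        })

    for _ in range(cfg.artefact_count):
        centers = _place_centers(rng, cfg, occupancy, mean_radius, 1)
        cy, cx = centers[0]
        a = rng.uniform(*cfg.cell_radius_range)
        b = rng.uniform(*cfg.cell_radius_range)
        ang = rng.uniform(-math.pi / 2, math.pi / 2)
        pert = (0.3, rng.integers(2, 5), rng.uniform(0, 2 * math.pi),
                rng.integers(5, 9), rng.uniform(0, 2 * math.pi))
        mask = _ellipse_mask(h, w, cy, cx, a, b, ang, perturb=pert)
        obj_id = next_label
        next_label += 1
        cell_labels[mask] = obj_id
        occupancy |= ndimage.binary_dilation(mask, iterations=3)
        intensities = {}
        for ci, ch in enumerate(cfg.channel_set):
            if ch == "DAPI":
                intensities[ch] = 0.0
                continue
            val = float(rng.uniform(0.2, 0.5))
            ideal[ci][mask] = np.maximum(ideal[ci][mask], val)
            intensities[ch] = val
        truth_rows.append({
            "object_id": obj_id, "type": "artefact", "atypia": "normal",
            "nc_ratio": 0.0,
            **{f"intensity_{ch}": intensities[ch] for ch in cfg.channel_set},
        })

    image = np.empty_like(ideal)
    for ci in range(n_ch):
        image[ci] = ndimage.gaussian_filter(ideal[ci], cfg.psf_sigma)
    image += rng.normal(0.0, cfg.noise_sd, size=image.shape)
    np.clip(image, 0.0, 1.0, out=image)

    columns = ["object_id", "type", "atypia", "nc_ratio"] + [
        f"intensity_{ch}" for ch in cfg.channel_set]
    truth = pd.DataFrame(truth_rows, columns=columns)
    return SyntheticImageBundle(
        image=image, nucleus_labels=nucleus_labels, cell_labels=cell_labels,
        truth=truth, channels=tuple(cfg.channel_set), config=cfg,
    )


def simulate_crops(
    n: int, size: int = 64, atypical_fraction: float = 0.5, seed: int = 0,
    class_label: str = "HGD",
) -> tuple[np.ndarray, np.ndarray]:
    """Single-cell crops for atypia-classifier training.

    Renders one centred cell per crop on a 2-plane (DAPI, marker) canvas.
    Returns ``(X, y)`` with X of shape (n, 2, size, size) in [0, 1] and
    y ∈ {0 normal, 1 atypical}.  The two classes differ in their N/C
    area-ratio distribution and nuclear irregularity only.
    """
    rng = np.random.default_rng(seed)
    X = np.zeros((n, 2, size, size), dtype=np.float32)
    y = np.zeros(n, dtype=np.int64)
    for i in range(n):
        atypical = bool(rng.random() < atypical_fraction)
        y[i] = int(atypical)
        center = np.array([size / 2, size / 2]) + rng.uniform(-2, 2, size=2)
        (cc, a, b, ang), (ncen, an, bn, nang, pert), _ = _draw_cell(
            rng, (size * 0.18, size * 0.28), atypical, center)
        cmask = _ellipse_mask(size, size, cc[0], cc[1], a, b, ang)
        nmask = _ellipse_mask(size, size, ncen[0], ncen[1], an, bn, nang, perturb=pert)
        nmask &= cmask
        dapi = np.clip(rng.normal(_DAPI_MEAN, _DAPI_SD), 0.15, 0.95)
        mval = np.clip(rng.normal(_MARKER_MEAN["SNA1"][class_label], _MARKER_SD), 0.1, 0.95)
        X[i, 0][nmask] = dapi
        X[i, 1][cmask] = mval
        for ch in range(2):
            X[i, ch] = ndimage.gaussian_filter(X[i, ch], 1.0)
        X[i] += rng.normal(0.0, 0.02, size=(2, size, size))
    np.clip(X, 0.0, 1.0, out=X)
    return X, y


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

# per-feature class means (LRL, HGD, OSCC); grades on the 0-6 scale,
# N+/% features on the percent scale
DEFAULT_EFFECTS = {
    "SNA1avg": (2.0, 3.0, 4.0),
    "SNA1max": (3.0, 4.5, 5.5),
    "CD44max": (3.0, 4.5, 5.0),
    "CD44Npos": (10.0, 35.0, 40.0),
    "CD44pct": (10.0, 30.0, 35.0),
    "CYCD1Npos": (10.0, 15.0, 30.0),
    "MAAavg": (2.0, 2.5, 3.5),
}
# baseline within-class SDs at noise_sd = 1 (grade scale vs percent scale)
_FEATURE_SD = {
    "SNA1avg": 0.6, "SNA1max": 0.7, "CD44max": 0.7, "MAAavg": 0.6,
    "CD44Npos": 9.0, "CD44pct": 9.0, "CYCD1Npos": 8.0,
}
_PERCENT_FEATURES = {"CD44Npos", "CD44pct", "CYCD1Npos"}

# healthy CD44 baseline offsets (grade units) per site x age group: high in
# tongue and gingiva in the >40 age group
DEFAULT_SITE_AGE_BASELINE = {
    ("buccal", "<=40"): 0.0, ("buccal", ">40"): 0.0,
    ("tongue", "<=40"): 0.0, ("tongue", ">40"): 0.8,
    ("gingiva", "<=40"): 0.0, ("gingiva", ">40"): 0.8,
}
_SITE_PROBS = (0.6, 0.25, 0.15)  # buccal-dominated, as in clinic cohorts
_HABIT_PROB = {"LRL": 0.55, "HGD": 0.75, "OSCC": 0.80}


@dataclass(frozen=True)
class CohortSimConfig:
    n_per_class: tuple[int, int, int] = (50, 50, 50)  # LRL, HGD, OSCC
    effect_sizes: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    site_age_baseline: dict = field(
        default_factory=lambda: dict(DEFAULT_SITE_AGE_BASELINE))
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_per_class):
            raise ValueError("need at least one patient per class")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        # reject effect directions that contradict the progression contract;
        # flat (null) settings are legitimate and carry no monotonicity claim
        e = self.effect_sizes
        for f in ("SNA1avg", "SNA1max"):
            lo, hg, os = e[f]
            if lo > hg or hg > os:
                raise ValueError(f"{f} means must not decrease LRL -> HGD -> OSCC")
        lo, hg, os = e["CD44Npos"]
        if lo > hg or lo > os:
            raise ValueError("CD44Npos must not be higher in LRL than HGD/OSCC")
        for f in ("MAAavg", "CYCD1Npos"):
            lo, hg, os = e[f]
            if os < lo or os < hg:
                raise ValueError(f"{f} must not be lower in OSCC")


def simulate_cohort(cfg: CohortSimConfig) -> pd.DataFrame:
    """Per-patient feature table (one row per patient).

    Columns: patient_id, the seven marker features, age, habit, site and
    the class label.  Feature values are class means plus Gaussian noise
    (scaled by ``noise_sd``), clipped to their natural range; CD44
    features additionally carry the site × age healthy-baseline offset.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    pid = 0
    for label, n in zip(("LRL", "HGD", "OSCC"), cfg.n_per_class):
        cls_idx = ("LRL", "HGD", "OSCC").index(label)
        for _ in range(n):
            pid += 1
            age = float(np.clip(rng.normal(44, 13), 19, 80))
            site = SITES[rng.choice(3, p=_SITE_PROBS)]
            habit = int(rng.random() < _HABIT_PROB[label])
            grp = "<=40" if age <= 40 else ">40"
            cd44_shift = float(cfg.site_age_baseline.get((site, grp), 0.0))
            row = {"patient_id": f"P{pid:04d}", "age": age, "habit": habit,
                   "site": site, "label": label}
            for feat, means in cfg.effect_sizes.items():
                mean = means[cls_idx]
                sd = _FEATURE_SD.get(feat, 1.0) * cfg.noise_sd
                val = rng.normal(mean, sd)
                if feat.startswith("CD44"):
                    shift = cd44_shift * (8.0 if feat in _PERCENT_FEATURES else 1.0)
                    val += shift
                if feat in _PERCENT_FEATURES:
                    val = float(np.clip(val, 0.0, 100.0))
                else:
                    val = float(np.clip(val, 0.0, 6.0))
                row[feat] = val
            rows.append(row)
    cols = ["patient_id", *cfg.effect_sizes.keys(), "age", "habit", "site", "label"]
    return pd.DataFrame(rows)[cols]


# --------------------------------------------------------------------------
# meta-analysis study simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MetaSimConfig:
    k_studies: int = 10
    true_log_or: float = math.log(5.0)
    tau2: float = 0.1
    n_range: tuple[int, int] = (30, 200)  # per-arm size bounds
    baseline_rate_range: tuple[float, float] = (0.15, 0.45)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_studies < 1:
            raise ValueError("need at least one study")
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        lo, hi = self.n_range
        if not (2 <= lo <= hi):
            raise ValueError("degenerate n_range")
        rlo, rhi = self.baseline_rate_range
        if not (0.0 < rlo <= rhi < 1.0):
            raise ValueError("degenerate baseline_rate_range")


def simulate_meta_studies(cfg: MetaSimConfig) -> list[Study2x2]:
    """Draw k studies around a true log-OR with heterogeneity τ².

    Per study: θ_i ~ N(true_log_or, τ²); arm sizes uniform in ``n_range``;
    control (non-dysplastic) marker-positivity rate uniform in
    ``baseline_rate_range``; the dysplastic rate is the control rate
    shifted by θ_i on the logit scale; counts are binomial draws.
    """
    rng = np.random.default_rng(cfg.seed)
    studies = []
    for i in range(cfg.k_studies):
        theta = rng.normal(cfg.true_log_or, math.sqrt(cfg.tau2))
        n1 = int(rng.integers(cfg.n_range[0], cfg.n_range[1] + 1))
        n2 = int(rng.integers(cfg.n_range[0], cfg.n_range[1] + 1))
        p_ctrl = rng.uniform(*cfg.baseline_rate_range)
        p_case = float(expit(logit(p_ctrl) + theta))
        a = int(rng.binomial(n1, p_case))
        c = int(rng.binomial(n2, p_ctrl))
        studies.append(Study2x2(study_id=f"S{i + 1:03d}", a=a, b=n1 - a,
                                c=c, d=n2 - c))
    return studies
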