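"""Synthetic ground-truth data: MR lung phantoms, stained-slide images,
qPCR CT tables, and correlated animal cohorts.

Every generator is a pure function of its specification and seed, and
records exact construction-level truth (rasterized voxel volumes, exact
stained-pixel counts, programmed fold inductions, target correlations) so
the quantification pipeline can be validated against known answers.

The MR phantom emulates the appearance of UTE lung stacks: a bright
chest-wall/tissue background, a dark elliptical lung field on every slice,
bright vessels running through the slices, and bright fibrotic lesions —
so that at baseline (no lesions) the segmentation still reports a nonzero
vessel volume, as in real lungs. The noise model is additive Gaussian
clipped at zero; Rician noise is a possible extension but the
intensity-class pipeline under test does not depend on the tail shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import BorderMask, ImageGeometry, LungStack, GEOMETRY_PRESETS

logger = logging.getLogger("fibroquant")

__all__ = [
    "VesselSpec",
    "LesionSpec",
    "PhantomSpec",
    "PhantomTruth",
    "generate_lung_phantom",
    "default_vessels",
    "dispersed_lesions",
    "generate_histology_slide",
    "generate_ct_table",
    "generate_cohort",
]


# ---------------------------------------------------------------------------
# MR lung phantom


@dataclass(frozen=True)
class VesselSpec:
    """A bright tube running along the slice axis.

    ``center_rc`` is the in-plane (row, col) position of the tube axis,
    constant across slices. ``radius_px`` is the in-plane radius.
    """

    center_rc: tuple[float, float]
    radius_px: float
    intensity: float


@dataclass(frozen=True)
class LesionSpec:
    """A bright blob: a disc (or box) of ``radius_px`` repeated over
    ``n_slices`` consecutive slices centred at ``center`` (slice, row, col).

    ``shape="disc"`` rasterizes in-plane pixels whose centre distance to the
    lesion centre is <= radius; ``shape="box"`` rasterizes a square of side
    ``2*radius_px + 1``. ``softness_px > 0`` feathers the intensity edge
    (the rasterized truth stays hard).
    """

    center: tuple[int, int, int]
    radius_px: float
    intensity: float
    n_slices: int = 1
    softness_px: float = 0.0
    shape: str = "disc"


@dataclass
class PhantomSpec:
    """Scene description for a synthetic UTE lung stack.

    Default intensities (arbitrary units) follow the qualitative UTE
    contrast: dark lung parenchyma (20), brighter chest-wall tissue (60),
    bright vessels and lesions (100).
    """

    geometry: ImageGeometry
    lung_intensity: float = 20.0
    tissue_intensity: float = 60.0
    air_intensity: float = 2.0
    vessels: tuple[VesselSpec, ...] = ()
    lesions: tuple[LesionSpec, ...] = ()
    noise_sigma: float = 0.0
    seed: int = 0
    lung_semiaxes_frac: tuple[float, float] = (0.30, 0.38)
    body_semiaxes_frac: tuple[float, float] = (0.44, 0.47)

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for v in self.vessels:
            if v.intensity <= self.lung_intensity:
                raise ValueError("vessel intensity must exceed lung intensity")
        for l in self.lesions:
            if l.intensity <= self.lung_intensity:
                raise ValueError("lesion intensity must exceed lung intensity")


@dataclass
class PhantomTruth:
    """Exact rasterized ground truth of a generated phantom."""

    lesion_volume_ul: float
    vessel_volume_ul: float
    lung_mask: BorderMask
    lesion_mask: np.ndarray = field(repr=False, default=None)
    vessel_mask: np.ndarray = field(repr=False, default=None)


def _ellipse_region(geometry: ImageGeometry,
                    semiaxes_frac: tuple[float, float]) -> np.ndarray:
    n = geometry.matrix_size
    r0 = c0 = (n - 1) / 2.0
    ar = semiaxes_frac[0] * n
    ac = semiaxes_frac[1] * n
    rr, cc = np.mgrid[0:n, 0:n]
    inside = ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0
    return np.broadcast_to(inside, geometry.shape).copy()


def _rasterize_lesion(lesion: LesionSpec, shape: tuple[int, int, int]) -> np.ndarray:
    s0, r0, c0 = lesion.center
    ns = lesion.n_slices
    lo = s0 - (ns - 1) // 2
    hi = lo + ns
    if lo < 0 or hi > shape[0]:
        raise ValueError(f"lesion at slice {s0} extends outside the stack")
    rr, cc = np.mgrid[0:shape[1], 0:shape[2]]
    if lesion.shape == "disc":
        plane = (rr - r0) ** 2 + (cc - c0) ** 2 <= lesion.radius_px ** 2
    elif lesion.shape == "box":
        plane = (np.abs(rr - r0) <= lesion.radius_px) & \
                (np.abs(cc - c0) <= lesion.radius_px)
    else:
        raise ValueError(f"unknown lesion shape {lesion.shape!r}")
    mask = np.zeros(shape, dtype=bool)
    mask[lo:hi] = plane
    return mask


def generate_lung_phantom(spec: PhantomSpec) -> tuple[LungStack, BorderMask, PhantomTruth]:
    """Generate a synthetic UTE lung stack with exact rasterized truth.

    The scene is piecewise constant — dark air outside an elliptical body,
    chest-wall tissue inside it, a dark elliptical lung field per slice,
    bright vessels, bright lesions — plus additive Gaussian noise clipped
    at zero. Lesion and vessel voxel sets are disjoint by construction
    (lesions take precedence). Identical spec + seed yields an identical
    phantom.
    """
    g = spec.geometry
    lung = _ellipse_region(g, spec.lung_semiaxes_frac)
    body = _ellipse_region(g, spec.body_semiaxes_frac)
    scene = np.full(g.shape, spec.air_intensity, dtype=float)
    scene[body] = spec.tissue_intensity
    scene[lung] = spec.lung_intensity

    vessel_mask = np.zeros(g.shape, dtype=bool)
    rr, cc = np.mgrid[0:g.matrix_size, 0:g.matrix_size]
    for v in spec.vessels:
        plane = (rr - v.center_rc[0]) ** 2 + (cc - v.center_rc[1]) ** 2 \
            <= v.radius_px ** 2
        tube = np.broadcast_to(plane, g.shape)
        if np.any(tube & ~lung):
            raise ValueError(f"vessel at {v.center_rc} extends outside the "
                             "lung region")
        vessel_mask |= tube
        scene[tube] = v.intensity

    lesion_mask = np.zeros(g.shape, dtype=bool)
    contrast = np.inf
    for l in spec.lesions:
        m = _rasterize_lesion(l, g.shape)
        if np.any(m & ~lung):
            raise ValueError(f"lesion at {l.center} extends outside the lung "
                             "region")
        lesion_mask |= m
        contrast = min(contrast, l.intensity - spec.lung_intensity)
        if l.softness_px > 0:
            from scipy import ndimage
            soft = ndimage.gaussian_filter(
                m.astype(float), sigma=(0, l.softness_px, l.softness_px))
            scene = scene * (1 - soft) + l.intensity * soft
        else:
            scene[m] = l.intensity
    vessel_mask &= ~lesion_mask

    if spec.lesions and spec.noise_sigma >= contrast:
        logger.warning("noise_sigma %.3g >= lesion contrast %.3g: "
                       "undetectable by design", spec.noise_sigma, contrast)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        scene = scene + rng.normal(0.0, spec.noise_sigma, size=g.shape)
        np.clip(scene, 0.0, None, out=scene)

    vox = g.voxel_volume_ul
    truth = PhantomTruth(
        lesion_volume_ul=float(lesion_mask.sum()) * vox,
        vessel_volume_ul=float(vessel_mask.sum()) * vox,
        lung_mask=BorderMask(mask=lung.copy()),
        lesion_mask=lesion_mask,
        vessel_mask=vessel_mask,
    )
    return LungStack(voxels=scene, geometry=g), BorderMask(mask=lung), truth


def default_vessels(geometry: ImageGeometry,
                    intensity: float = 100.0) -> tuple[VesselSpec, ...]:
    """Two hilar-region vessels inside the lung ellipse (the baseline signal
    source: real baseline stacks contain vessel contributions)."""
    n = geometry.matrix_size
    c = (n - 1) / 2.0
    return (
        VesselSpec(center_rc=(c - 0.10 * n, c - 0.12 * n), radius_px=2.5,
                   intensity=intensity),
        VesselSpec(center_rc=(c + 0.08 * n, c + 0.14 * n), radius_px=2.0,
                   intensity=intensity),
    )


def dispersed_lesions(geometry: ImageGeometry,
                      target_volume_ul: float,
                      intensity: float = 100.0,
                      seed: int = 0,
                      pattern: str = "dispersed",
                      lung_semiaxes_frac: tuple[float, float] = (0.30, 0.38),
                      ) -> tuple[LesionSpec, ...]:
    """Place lesions of approximately ``target_volume_ul`` total volume.

    ``pattern="dispersed"`` scatters blobs across the lung field (the
    homogeneous injury pattern of oropharyngeal aspiration);
    ``pattern="central"`` concentrates them near the lung centre (the
    peri-airway pattern of intranasal administration). The exact rasterized
    volume is reported by :func:`generate_lung_phantom`'s truth, not by
    this helper.
    """
    if pattern not in {"dispersed", "central"}:
        raise ValueError("pattern must be 'dispersed' or 'central'")
    rng = np.random.default_rng(seed)
    n = geometry.matrix_size
    c = (n - 1) / 2.0
    ar = lung_semiaxes_frac[0] * n
    ac = lung_semiaxes_frac[1] * n
    vox = geometry.voxel_volume_ul
    lesions: list[LesionSpec] = []
    placed_ul = 0.0
    spread = 0.22 if pattern == "dispersed" else 0.07
    while placed_ul < target_volume_ul:
        radius = float(rng.uniform(3.0, 7.0))
        ns = int(rng.integers(1, min(3, geometry.n_slices) + 1))
        approx = np.pi * radius ** 2 * ns * vox
        if placed_ul + approx > 1.35 * target_volume_ul and lesions:
            # shrink the last blob instead of overshooting
            radius = max(2.0, radius * np.sqrt(
                max(target_volume_ul - placed_ul, vox) / approx))
            ns = 1
            approx = np.pi * radius ** 2 * vox
        s = int(rng.integers((ns - 1) // 2,
                             geometry.n_slices - (ns - (ns - 1) // 2) + 1))
        # rejection-sample a centre whose whole disc fits inside the ellipse
        margin = radius + 1.0
        for _ in range(1000):
            r = int(round(rng.normal(c, spread * n)))
            cl = int(round(rng.normal(c, spread * n * 1.25)))
            if ((r - c) / max(ar - margin, 1.0)) ** 2 + \
               ((cl - c) / max(ac - margin, 1.0)) ** 2 <= 1.0:
                break
        else:  # pragma: no cover - tiny lungs only
            raise ValueError("could not place lesion inside the lung region")
        lesions.append(LesionSpec(center=(s, r, cl), radius_px=radius,
                                  intensity=intensity, n_slices=ns))
        placed_ul += approx
    return tuple(lesions)


# ---------------------------------------------------------------------------
# Histology phantom

#: Default phantom palette: picrosirius-red collagen, pale counterstained
#: tissue, white background (airspace/glass).
STAIN_RGB = (185, 40, 50)
COUNTERSTAIN_RGB = (235, 215, 160)
BACKGROUND_RGB = (255, 255, 255)


def generate_histology_slide(width: int,
                             height: int,
                             lung_fraction: float = 0.6,
                             collagen_fraction: float = 0.1,
                             seed: int = 0,
                             n_patches: int = 6) -> tuple[np.ndarray, dict]:
    """Generate a synthetic picrosirius-stained slide with exact truth.

    The slide is an 8-bit RGB image: white background, an elliptical lung
    field of counterstained tissue, and exactly
    ``round(collagen_fraction * n_lung_pixels)`` stain-coloured pixels
    grouped into patches around ``n_patches`` seeded centres. No
    anti-aliasing is applied, so pixel counts are exact.

    Returns
    -------
    (image, truth)
        ``truth`` records ``n_lung_px``, ``n_stain_px``, ``stained_fraction``
        and the lung mask.
    """
    if not 0.0 <= collagen_fraction <= 1.0:
        raise ValueError("collagen_fraction must be in [0, 1]")
    if not 0.0 < lung_fraction <= 1.0:
        raise ValueError("lung_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0:height, 0:width]
    r0, c0 = (height - 1) / 2.0, (width - 1) / 2.0
    # ellipse with area ~= lung_fraction of the frame
    scale = np.sqrt(lung_fraction / (np.pi * 0.25))
    ar, ac = scale * height / 2.0, scale * width / 2.0
    lung = ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0
    n_lung = int(lung.sum())
    if n_lung == 0:
        raise ValueError("lung region is empty")
    n_stain = int(round(collagen_fraction * n_lung))

    img = np.empty((height, width, 3), dtype=np.uint8)
    img[...] = BACKGROUND_RGB
    img[lung] = COUNTERSTAIN_RGB

    if n_stain > 0:
        lung_r, lung_c = np.nonzero(lung)
        centers = rng.choice(n_lung, size=min(n_patches, n_lung),
                             replace=False)
        d = np.full(n_lung, np.inf)
        for k in centers:
            d = np.minimum(d, np.hypot(lung_r - lung_r[k],
                                       lung_c - lung_c[k]))
        d = d + rng.normal(0.0, 1.5, size=n_lung)  # ragged patch borders
        order = np.argsort(d, kind="stable")[:n_stain]
        img[lung_r[order], lung_c[order]] = STAIN_RGB

    truth = {
        "n_lung_px": n_lung,
        "n_stain_px": n_stain,
        "stained_fraction": n_stain / n_lung,
        "lung_mask": lung,
    }
    return img, truth


# ---------------------------------------------------------------------------
# qPCR CT tables


def generate_ct_table(genes: Sequence[str],
                      n_control: int,
                      n_treated: int,
                      fold_inductions: dict[str, float],
                      ct_noise_sd: float = 0.0,
                      seed: int = 0,
                      housekeeping: str = "HPRT",
                      n_replicates: int = 2,
                      base_ct: float = 25.0,
                      housekeeping_ct: float = 20.0,
                      control_label: str = "Saline",
                      treated_label: str = "Bleomycin") -> pd.DataFrame:
    """Generate a tidy CT table with programmed fold inductions.

    Housekeeping CTs are constant in expectation across groups; a treated
    animal's target-gene CT is shifted by ``-log2(fold)`` cycles relative to
    control, so the downstream 2^-ΔΔCT analysis recovers the programmed
    fold. Gaussian cycle noise of ``ct_noise_sd`` is added per well.

    Columns: sample_id, group, gene, ct, replicate.
    """
    for gene, fold in fold_inductions.items():
        if fold <= 0:
            raise ValueError(f"fold induction for {gene} must be > 0")
    if ct_noise_sd > 0 and min(n_control, n_treated) < 2:
        raise ValueError("need >= 2 animals per group when noise > 0")
    rng = np.random.default_rng(seed)
    rows = []
    samples = [(f"C{i+1:02d}", control_label) for i in range(n_control)] + \
              [(f"T{i+1:02d}", treated_label) for i in range(n_treated)]
    all_genes = [housekeeping] + [g for g in genes if g != housekeeping]
    for sample_id, group in samples:
        for gene in all_genes:
            if gene == housekeeping:
                mu = housekeeping_ct
            else:
                mu = base_ct
                if group == treated_label:
                    mu -= np.log2(fold_inductions.get(gene, 1.0))
            for rep in range(1, n_replicates + 1):
                ct = mu + (rng.normal(0.0, ct_noise_sd)
                           if ct_noise_sd > 0 else 0.0)
                rows.append((sample_id, group, gene, float(ct), rep))
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct",
                                       "replicate"])


# ---------------------------------------------------------------------------
# Correlated animal cohorts

#: Default per-readout (mean, sd) for a saline-like reference group.
DEFAULT_READOUTS: dict[str, tuple[float, float]] = {
    "picrosirius_factor": (1.0, 0.25),
    "hydroxyproline_ug": (60.0, 12.0),
    "fold_col1a1": (1.0, 0.3),
    "fold_f4_80": (1.0, 0.3),
    "fold_mmp12": (1.0, 0.3),
}


def generate_cohort(n_per_group: int | dict[str, int],
                    group_effects: dict[str, dict[str, float]] | None = None,
                    correlation: float | dict[str, float] | np.ndarray = 0.8,
                    noise_sds: dict[str, float] | None = None,
                    seed: int = 0,
                    readouts: Sequence[str] = tuple(DEFAULT_READOUTS),
                    mri_mean_ul: float = 120.0,
                    mri_sd_ul: float = 40.0) -> pd.DataFrame:
    """Generate a per-animal cohort table with a programmed correlation
    between MRI volume and every other readout.

    Within each group, (MRI, readouts) are jointly Gaussian: readout_j =
    mean_j + sd_j * (R_j * z + sqrt(1 - R_j^2) * eps_j) where z is the
    animal's standardized MRI deviation — so corr(MRI, readout_j) = R_j in
    expectation. A full correlation matrix may be supplied instead and is
    checked for positive semi-definiteness. ``group_effects`` shifts group
    means per readout.

    Columns: animal_id, group, mri_volume_ul, then one column per readout.
    """
    readouts = list(readouts)
    p = len(readouts) + 1
    if isinstance(n_per_group, int):
        groups = {"GroupA": n_per_group}
    else:
        groups = dict(n_per_group)
    rs = None
    if isinstance(correlation, np.ndarray):
        corr = np.asarray(correlation, float)
        if corr.shape != (p, p):
            raise ValueError(f"correlation matrix must be {p}x{p}")
        if not np.allclose(corr, corr.T) or np.any(np.abs(corr) > 1):
            raise ValueError("invalid correlation matrix")
        eig = np.min(np.linalg.eigvalsh(corr))
        if eig < -1e-10:
            raise ValueError("correlation matrix is not positive "
                             "semi-definite")
        L = np.linalg.cholesky(corr + max(0.0, -eig + 1e-12) * np.eye(p))
    else:
        if isinstance(correlation, dict):
            rs = np.array([correlation[r] for r in readouts], float)
        else:
            rs = np.full(len(readouts), float(correlation))
        if np.any(np.abs(rs) > 1):
            raise ValueError("|correlation| must be <= 1")
        L = None  # single-factor construction, exact at |R| = 1

    noise_sds = noise_sds or {}
    sds = np.array([mri_sd_ul] + [
        noise_sds.get(r, DEFAULT_READOUTS.get(r, (0.0, 1.0))[1])
        for r in readouts])
    base_means = np.array([mri_mean_ul] + [
        DEFAULT_READOUTS.get(r, (0.0, 1.0))[0] for r in readouts])

    rng = np.random.default_rng(seed)
    rows = []
    idx = 1
    for group, n in groups.items():
        shift = np.zeros(p)
        if group_effects and group in group_effects:
            eff = group_effects[group]
            shift[0] = eff.get("mri_volume_ul", 0.0)
            for j, r in enumerate(readouts, start=1):
                shift[j] = eff.get(r, 0.0)
        if L is not None:
            z = rng.standard_normal((n, p)) @ L.T
        else:
            raw = rng.standard_normal((n, p))
            z = np.empty((n, p))
            z[:, 0] = raw[:, 0]
            z[:, 1:] = rs * raw[:, :1] + np.sqrt(1.0 - rs ** 2) * raw[:, 1:]
        vals = base_means + shift + z * sds
        for i in range(n):
            rows.append((f"A{idx:03d}", group, *vals[i]))
            idx += 1
    return pd.DataFrame(rows, columns=["animal_id", "group", "mri_volume_ul",
                                       *readouts])
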