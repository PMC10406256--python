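"""Synthetic study generator: histology sections, ROI labels, diffusion volumes.

The generator emulates the study design end-to-end: a cohort of subjects,
each with nine labeled gray-matter regions, a multi-shell diffusion volume
and one digitized Nissl-like section per region.  Cell bodies are dark
ellipses placed by a hard-core process whose local intensity is modulated by
a smooth random field — regions differ in mean cell size, size dispersion,
packing density and, crucially, spatial heterogeneity of packing.  The same
latent-density construction drives the diffusion side through a linear link
between local cell area density and compartment mean diffusivity,

    MD(d) = MD0 * (1 + kappa * (d - d_ref)),

so the statistical coupling between cytoarchitectural heterogeneity and
diffusion heterogeneity is a single tunable coefficient.  Magnitude-MRI
noise is Rician.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np
from scipy import ndimage

from cytodmri.biexp import DEFAULT_D_ISO
from cytodmri.errors import ConfigurationError, PackingError
from cytodmri.io import DiffusionVolume, GradientTable, LabelVolume

#: relative std of local density per unit density_gradient
DENSITY_REL_STD = 0.2


# ---------------------------------------------------------------------------
# Specs


@dataclass
class RegionSpec:
    """Cytoarchitectural parameters of one gray-matter region."""

    name: str
    region_class: str            # 'cortical' or 'subcortical'
    mean_cell_radius_um: float   # median of the lognormal radius law
    radius_cv: float             # coefficient of variation of cell radius
    target_density: float        # cell area fraction in [0, 0.9)
    density_gradient: float      # 0 = uniform placement; larger = patchier

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_density < 0.9:
            raise ConfigurationError("target_density must lie in [0, 0.9)")
        if self.radius_cv < 0 or self.density_gradient < 0:
            raise ConfigurationError("radius_cv and density_gradient must be >= 0")
        if self.region_class not in ("cortical", "subcortical"):
            raise ConfigurationError(f"unknown region class {self.region_class!r}")


@dataclass
class CouplingSpec:
    """Link between local cell density and diffusivity, plus noise level."""

    kappa: float = 3.0           # dimensionless density-diffusivity coupling
    noise_snr: float = 40.0      # Rician SNR at b=0 (inf = noise free)
    md0: float = 0.7e-3          # mm^2/s, fast-compartment MD at d = d_ref
    d_ref: float = 0.26          # reference cell area density
    slow_ratio: float = 0.25     # MD_slow / MD_fast
    w_range: tuple[float, float] = (0.55, 0.65)
    f_iso_range: tuple[float, float] = (0.02, 0.08)
    d_iso: float = DEFAULT_D_ISO
    s0: float = 100.0
    anisotropy: float = 0.0      # 0 = isotropic compartments

    def __post_init__(self) -> None:
        if self.noise_snr <= 0:
            raise ConfigurationError("noise_snr must be positive")

    def md_fast(self, density: np.ndarray) -> np.ndarray:
        md = self.md0 * (1.0 + self.kappa * (np.asarray(density) - self.d_ref))
        if np.any(md <= 0):
            raise ConfigurationError(
                "density-diffusivity link yields non-positive diffusivity; "
                "reduce |kappa| or the density range"
            )
        return md


@dataclass
class RenderConfig:
    """Optical rendering of a section: contrast, blur, pixel noise."""

    background: float = 0.85
    cell_intensity: float = 0.30
    blur_sigma_px: float = 0.6
    noise_sigma: float = 0.04


def default_region_specs() -> list[RegionSpec]:
    """The nine study regions (6 cortical, 3 subcortical).

    Parameter choices follow the qualitative cytoarchitecture of each
    region: the entorhinal cortex is the patchiest, pre/postcentral gyri
    carry large, dispersed cells (Betz cells), the putamen and thalamus are
    the most homogeneous.
    """
    c, s = "cortical", "subcortical"
    return [
        RegionSpec("ACG", c, 10.0, 0.30, 0.25, 1.0),
        RegionSpec("precentral", c, 14.0, 0.50, 0.22, 1.4),
        RegionSpec("postcentral", c, 12.0, 0.40, 0.24, 1.2),
        RegionSpec("STG", c, 10.0, 0.30, 0.26, 0.9),
        RegionSpec("insula", c, 10.0, 0.35, 0.25, 0.8),
        RegionSpec("entorhinal", c, 12.0, 0.50, 0.20, 1.8),
        RegionSpec("caudate", s, 8.0, 0.35, 0.30, 0.7),
        RegionSpec("putamen", s, 8.0, 0.25, 0.30, 0.30),
        RegionSpec("thalamus", s, 10.0, 0.25, 0.28, 0.25),
    ]


# ---------------------------------------------------------------------------
# Acquisition protocol


def _fibonacci_sphere(n: int) -> np.ndarray:
    # hemisphere only: +g and -g are equivalent diffusion directions, so
    # antipodal pairs would waste measurements
    i = np.arange(n)
    z = (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_protocol(n_b0: int, dirs_per_shell: int, shells=(1000.0, 2000.0, 3000.0)) -> GradientTable:
    """Multi-shell protocol with evenly spread (spherical Fibonacci) directions."""
    bvals = [0.0] * n_b0
    bvecs = [np.zeros((n_b0, 3))]
    dirs = _fibonacci_sphere(dirs_per_shell)
    for b in shells:
        bvals.extend([b] * dirs_per_shell)
        bvecs.append(dirs)
    return GradientTable(np.array(bvals), np.vstack(bvecs))


def study_protocol() -> GradientTable:
    """The study acquisition: 11 b=0 plus 60 directions per shell at b=1000/2000/3000."""
    return make_protocol(11, 60)


def reduced_protocol() -> GradientTable:
    """Desk-scale protocol (6 b=0, 20 directions per shell) for replicate studies."""
    return make_protocol(6, 20)


# ---------------------------------------------------------------------------
# Random fields and noise


def smooth_unit_field(shape, corr_sigma, rng) -> np.ndarray:
    """Smoothed white noise standardized to zero mean, unit variance."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=corr_sigma, mode="wrap")
    sd = f.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return (f - f.mean()) / sd


def rician_noise(signal: np.ndarray, sigma: float, rng) -> np.ndarray:
    """Magnitude of the complex Gaussian-perturbed signal |S + e1 + i e2|."""
    s = np.asarray(signal, dtype=float)
    e1 = rng.normal(0.0, sigma, s.shape)
    e2 = rng.normal(0.0, sigma, s.shape)
    return np.hypot(s + e1, e2)


# ---------------------------------------------------------------------------
# Histology sections


@dataclass
class Section:
    """One synthetic digitized section with exact ground truth."""

    image: np.ndarray       # float grayscale in [0, 1]
    roi_mask: np.ndarray    # bool
    cell_mask: np.ndarray   # bool, exact rasterized ground truth
    pixel_size_um: float
    density_true: float     # painted cell fraction of the ROI


def _rasterize_ellipse(mask, cy, cx, a, b_ax, theta) -> int:
    """Paint an ellipse interior; returns number of newly painted pixels."""
    H, W = mask.shape
    r_ext = max(a, b_ax) + 1.0
    y0, y1 = max(0, int(cy - r_ext)), min(H, int(cy + r_ext) + 1)
    x0, x1 = max(0, int(cx - r_ext)), min(W, int(cx + r_ext) + 1)
    if y0 >= y1 or x0 >= x1:
        return 0
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy = yy - cy
    dx = xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b_ax
    inside = u * u + v * v <= 1.0
    block = mask[y0:y1, x0:x1]
    new = int(np.count_nonzero(inside & ~block))
    block |= inside
    return new


def generate_histology_section(
    spec: RegionSpec,
    pixel_size_um: float = 4.0,
    shape: tuple[int, int] = (512, 512),
    seed=None,
    render: RenderConfig | None = None,
    field_corr_px: float | None = None,
    max_attempt_factor: int = 300,
) -> Section:
    """Draw one section: hard-core ellipse placement under a smooth density field.

    Cell radii are lognormal with median ``mean_cell_radius_um`` and sigma set
    by ``radius_cv``; axis ratios are uniform in [0.7, 1] at preserved area;
    centers are accepted with probability proportional to the spatial field
    (uniform when ``density_gradient`` is 0) subject to the hard-core rule
    that two centers keep a distance of at least 0.8 (r_i + r_j).  Placement
    stops when the painted area fraction reaches ``target_density``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rnd = render or RenderConfig()
    H, W = shape
    roi = np.ones(shape, bool)
    cell_mask = np.zeros(shape, bool)

    r_med_px = spec.mean_cell_radius_um / pixel_size_um
    sigma_log = np.sqrt(np.log1p(spec.radius_cv**2))

    if field_corr_px is None:
        field_corr_px = max(8.0, min(H, W) / 3.0)
    if spec.density_gradient > 0:
        f = smooth_unit_field(shape, 0.5 * field_corr_px, rng)
        prob = np.clip(1.0 + spec.density_gradient * DENSITY_REL_STD * f, 0.0, None)
    else:
        prob = np.ones(shape)
    prob_max = prob.max()
    if prob_max <= 0:
        raise ConfigurationError("placement field collapsed to zero everywhere")

    target_pixels = spec.target_density * roi.sum()
    painted = 0
    centers = np.empty((0, 2))
    radii = np.empty(0)
    exp_n = max(1, int(target_pixels / max(np.pi * r_med_px**2, 1.0)))
    attempts_left = max_attempt_factor * (exp_n + 20)

    while painted < target_pixels and attempts_left > 0:
        attempts_left -= 1
        cy = rng.uniform(0, H)
        cx = rng.uniform(0, W)
        if rng.uniform() * prob_max > prob[int(cy), int(cx)]:
            continue
        r = r_med_px * np.exp(sigma_log * rng.standard_normal())
        r = min(r, 3.0 * r_med_px)
        if centers.shape[0]:
            d2 = (centers[:, 0] - cy) ** 2 + (centers[:, 1] - cx) ** 2
            if np.any(d2 < (0.8 * (radii + r)) ** 2):
                continue
        q = rng.uniform(0.7, 1.0)
        a = r / np.sqrt(q)
        b_ax = r * np.sqrt(q)
        theta = rng.uniform(0, np.pi)
        painted += _rasterize_ellipse(cell_mask, cy, cx, a, b_ax, theta)
        centers = np.vstack([centers, [cy, cx]])
        radii = np.append(radii, r)

    if spec.target_density > 0 and painted < 0.9 * target_pixels:
        raise PackingError(
            f"could not reach density {spec.target_density:.3f} "
            f"(achieved {painted / roi.sum():.3f}) within the attempt budget"
        )

    img = rnd.background - (rnd.background - rnd.cell_intensity) * ndimage.gaussian_filter(
        cell_mask.astype(float), rnd.blur_sigma_px
    )
    if rnd.noise_sigma > 0:
        img = img + rng.normal(0.0, rnd.noise_sigma, shape)
    img = np.clip(img, 0.0, 1.0)

    return Section(
        image=img,
        roi_mask=roi,
        cell_mask=cell_mask,
        pixel_size_um=pixel_size_um,
        density_true=painted / roi.sum(),
    )


# ---------------------------------------------------------------------------
# Diffusion signals


def generate_diffusion_region(
    spec: RegionSpec,
    coupling: CouplingSpec,
    gtab: GradientTable,
    shape: tuple[int, int, int] | int,
    seed=None,
    field_corr_vox: float = 1.0,
) -> tuple[np.ndarray, dict]:
    """Diffusion signals for one region's voxel block, with ground truth.

    Each voxel carries a latent cell density drawn from the same smooth-field
    statistics as the section generator; the biexponential forward model maps
    it to signal through the MD(d) link, and Rician noise is applied at the
    configured b=0 SNR.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if isinstance(shape, int):
        shape = (shape, 1, 1)
    z = smooth_unit_field(shape, field_corr_vox, rng) if spec.density_gradient > 0 else np.zeros(shape)
    d = spec.target_density * (1.0 + spec.density_gradient * DENSITY_REL_STD * z)
    d = np.clip(d, 0.005, 0.85).ravel()
    V = d.size

    md_f = coupling.md_fast(d)
    md_s = coupling.slow_ratio * md_f
    w = rng.uniform(*coupling.w_range, V)
    f_iso = rng.uniform(*coupling.f_iso_range, V)
    s0 = coupling.s0

    b = gtab.bvals
    if coupling.anisotropy > 0:
        # axially symmetric tensors at preserved trace, random axis per voxel
        axes = rng.standard_normal((V, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        cos2 = (gtab.bvecs @ axes.T) ** 2  # (M, V)
        a = coupling.anisotropy
        adc_f = md_f * (1.0 - a) + md_f * 3.0 * a * cos2.T  # (V, M)
        adc_s = md_s[:, None] / md_f[:, None] * adc_f
    else:
        adc_f = np.broadcast_to(md_f[:, None], (V, b.size))
        adc_s = np.broadcast_to(md_s[:, None], (V, b.size))

    tissue = w[:, None] * np.exp(-b * adc_f) + (1.0 - w[:, None]) * np.exp(-b * adc_s)
    csf = np.exp(-b * coupling.d_iso)
    clean = s0 * (f_iso[:, None] * csf + (1.0 - f_iso[:, None]) * tissue)

    if np.isfinite(coupling.noise_snr):
        signal = rician_noise(clean, s0 / coupling.noise_snr, rng)
    else:
        signal = clean

    truth = {
        "density": d,
        "md_fast": md_f,
        "md_slow": md_s,
        "w": w,
        "f_iso": f_iso,
        "s0": np.full(V, s0),
        "shape": shape,
        "clean_signal": clean,
    }
    return signal, truth


# ---------------------------------------------------------------------------
# Whole study


@dataclass
class StudyConfig:
    """Shapes and scales of one generated study."""

    n_subjects: int = 4
    block_shape: tuple[int, int, int] = (6, 6, 6)
    voxel_size_mm: float = 0.8
    grid_squares: tuple[int, int] = (3, 3)   # histology grid squares per section
    pixel_size_um: float = 4.0
    grid_size_mm: float | None = None        # defaults to voxel_size_mm
    subject_jitter: float = 0.10             # relative spread of per-subject params
    n_sections: int = 1                      # sections per (subject, region)

    @property
    def grid_mm(self) -> float:
        return self.voxel_size_mm if self.grid_size_mm is None else self.grid_size_mm

    @property
    def section_shape(self) -> tuple[int, int]:
        side = int(round(self.grid_mm * 1000.0 / self.pixel_size_um))
        return (self.grid_squares[0] * side, self.grid_squares[1] * side)


def reduced_study_config() -> StudyConfig:
    """Desk-scale study: 3x3x3 voxel blocks, 0.32 mm histology grid squares."""
    return StudyConfig(block_shape=(3, 3, 3), grid_squares=(3, 3), grid_size_mm=0.32)


@dataclass
class StudyData:
    """In-memory generated study with exact ground truth."""

    subjects: list[str]
    volumes: dict[str, DiffusionVolume]
    labels: dict[str, LabelVolume]
    sections: dict[tuple[str, str], list[Section]]
    truth: dict[tuple[str, str], dict]
    region_specs: list[RegionSpec]
    coupling: CouplingSpec
    config: StudyConfig
    gtab: GradientTable


def _block_layout(n_regions: int, block_shape, gap: int = 1):
    """Place region blocks on a 2D grid of blocks inside one volume."""
    ncol = int(np.ceil(np.sqrt(n_regions)))
    nrow = int(np.ceil(n_regions / ncol))
    bx, by, bz = block_shape
    vol_shape = (
        nrow * bx + (nrow + 1) * gap,
        ncol * by + (ncol + 1) * gap,
        bz + 2 * gap,
    )
    slices = []
    for k in range(n_regions):
        i, j = divmod(k, ncol)
        x0 = gap + i * (bx + gap)
        y0 = gap + j * (by + gap)
        slices.append((slice(x0, x0 + bx), slice(y0, y0 + by), slice(gap, gap + bz)))
    return vol_shape, slices


def generate_study(
    seed,
    region_specs: list[RegionSpec] | None = None,
    coupling: CouplingSpec | None = None,
    gtab: GradientTable | None = None,
    config: StudyConfig | None = None,
) -> StudyData:
    """Generate the full multi-subject study in memory.

    Per-subject parameter jitter (relative, truncated at two sigma) makes
    subjects cluster by region rather than coincide.
    """
    specs = region_specs if region_specs is not None else default_region_specs()
    coup = coupling or CouplingSpec()
    gt = gtab or study_protocol()
    cfg = config or StudyConfig()

    root = np.random.SeedSequence(seed)
    subject_seeds = root.spawn(cfg.n_subjects)
    subjects = [f"sub-{i + 1:02d}" for i in range(cfg.n_subjects)]

    vol_shape, slices = _block_layout(len(specs), cfg.block_shape)
    affine = np.diag([cfg.voxel_size_mm] * 3 + [1.0])
    region_table = {k + 1: (s.name, s.region_class) for k, s in enumerate(specs)}

    volumes: dict[str, DiffusionVolume] = {}
    labels: dict[str, LabelVolume] = {}
    sections: dict[tuple[str, str], list[Section]] = {}
    truth: dict[tuple[str, str], dict] = {}

    for subject, sseq in zip(subjects, subject_seeds):
        rng = np.random.default_rng(sseq)
        signal = np.zeros(vol_shape + (len(gt),))
        # background voxels get pure noise floor so they are clearly non-tissue
        if np.isfinite(coup.noise_snr):
            signal = rician_noise(signal, coup.s0 / coup.noise_snr, rng)
        lab = np.zeros(vol_shape, np.int32)

        for k, spec in enumerate(specs):
            jd = float(np.clip(rng.normal(0.0, cfg.subject_jitter), -2 * cfg.subject_jitter, 2 * cfg.subject_jitter))
            jg = float(np.clip(rng.normal(0.0, cfg.subject_jitter), -2 * cfg.subject_jitter, 2 * cfg.subject_jitter))
            sspec = replace(
                spec,
                target_density=spec.target_density * (1.0 + jd),
                density_gradient=spec.density_gradient * (1.0 + jg),
            )
            sig, tr = generate_diffusion_region(sspec, coup, gt, cfg.block_shape, rng)
            sl = slices[k]
            signal[sl[0], sl[1], sl[2], :] = sig.reshape(cfg.block_shape + (len(gt),))
            lab[sl[0], sl[1], sl[2]] = k + 1
            # latent density field correlation length = one diffusion grid square
            side_px = cfg.grid_mm * 1000.0 / cfg.pixel_size_um
            secs = [
                generate_histology_section(
                    sspec,
                    pixel_size_um=cfg.pixel_size_um,
                    shape=cfg.section_shape,
                    seed=rng,
                    field_corr_px=side_px,
                )
                for _ in range(cfg.n_sections)
            ]
            sections[(subject, spec.name)] = secs
            tr["jittered_spec"] = sspec
            truth[(subject, spec.name)] = tr

        volumes[subject] = DiffusionVolume(signal, affine, gt)
        labels[subject] = LabelVolume(lab, region_table)

    return StudyData(
        subjects=subjects,
        volumes=volumes,
        labels=labels,
        sections=sections,
        truth=truth,
        region_specs=specs,
        coupling=coup,
        config=cfg,
        gtab=gt,
    )


def write_study(study: StudyData, out_dir) -> None:
    """Serialize a generated study: NIfTI volumes/labels, PNG sections/masks,
    CSV ground truth, and a JSON echo of every generator parameter."""
    import imageio.v3 as iio
    import pandas as pd
    from pathlib import Path

    from cytodmri.io import write_gradient_table, write_nifti

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_gradient_table(study.gtab, out / "protocol.bval", out / "protocol.bvec")

    rows = []
    for subject in study.subjects:
        vol = study.volumes[subject]
        write_nifti(vol.signal, vol.affine, out / f"{subject}_dwi.nii.gz")
        write_nifti(study.labels[subject].labels, vol.affine, out / f"{subject}_labels.nii.gz")
        for spec in study.region_specs:
            for i, sec in enumerate(study.sections[(subject, spec.name)]):
                stem = f"{subject}_{spec.name}_sec{i}"
                iio.imwrite(out / f"{stem}.png", (sec.image * 255).astype(np.uint8))
                iio.imwrite(out / f"{stem}_cells.png", sec.cell_mask.astype(np.uint8) * 255)
                rows.append(
                    {
                        "subject": subject,
                        "region": spec.name,
                        "section": i,
                        "density_true": sec.density_true,
                    }
                )
    pd.DataFrame(rows).to_csv(out / "ground_truth_density.csv", index=False)

    region_df = pd.DataFrame(
        [
            {"label": k + 1, "name": s.name, "class": s.region_class}
            for k, s in enumerate(study.region_specs)
        ]
    )
    region_df.to_csv(out / "regions.csv", index=False)

    echo = {
        "config": asdict(study.config),
        "coupling": asdict(study.coupling),
        "region_specs": [asdict(s) for s in study.region_specs],
    }
    with open(out / "generator_config.json", "w") as fh:
        json.dump(echo, fh, indent=2)
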