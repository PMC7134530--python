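"""Synthetic 3D LGE-CMR-like phantoms with known anatomy and scar ground truth.

The phantom emulates the contrast regime of a late-gadolinium-enhanced scan:
a bright blood pool filling the left-atrial (LA) cavity and proximal
pulmonary-vein (PV) lumens, signal-nulled (dark) myocardium and background,
and small high-intensity scar patches confined to a thin atrial wall shell
of fixed physical thickness. Two standard MR degradations are applied on
top of the piecewise-Gaussian tissue model: a Gaussian point-spread blur
(partial-volume effect — the atrial wall is only 2–3 voxels thick, so every
wall voxel is contaminated by its bright neighbours) and a smooth
multiplicative bias field (coil-gain inhomogeneity). These are what make
global-intensity scar detection imperfect, as it is on clinical data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import LabelVolume, Volume


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom.

    The intensity model is piecewise Gaussian per tissue class, in arbitrary
    units on a roughly [0, 1] scale. The constraint
    ``scar_mean > blood_mean + 2 * blood_sd`` keeps the 2-SD thresholding
    baseline well-posed; ``myo_mean < blood_mean`` encodes the nulled
    myocardium of an LGE acquisition.
    """

    grid_edge: int = 48
    spacing_mm: float = 1.25
    la_semi_axes_mm: tuple[float, float, float] = (16.0, 13.0, 11.0)
    wall_thickness_mm: float = 2.25
    n_pv_tubes: int = 4
    pv_radius_mm: float = 3.0
    pv_length_mm: float = 12.0
    n_scar_patches: int = 4
    scar_angular_extent_deg: float = 26.0
    scar_extent_jitter: float = 0.35
    target_scar_fraction: float | None = None
    blood_mean: float = 0.60
    blood_sd: float = 0.05
    myo_mean: float = 0.18
    myo_sd: float = 0.05
    scar_mean: float = 0.85
    scar_sd: float = 0.06
    wall_mean: float = 0.40
    wall_sd: float = 0.18
    wall_corr_mm: float = 4.0
    noise_sd: float = 0.03
    psf_sigma_mm: float = 1.0
    bias_amplitude: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scar_mean <= self.blood_mean + 2.0 * self.blood_sd:
            raise ValueError(
                "scar_mean must exceed blood_mean + 2*blood_sd "
                "(2-SD baseline must be well-posed)"
            )
        if self.myo_mean >= self.blood_mean:
            raise ValueError("myo_mean must be below blood_mean (nulled myocardium)")
        if self.wall_thickness_mm < self.spacing_mm:
            raise ValueError("wall_thickness_mm must be >= spacing_mm")
        if self.grid_edge < 8:
            raise ValueError("grid_edge must be >= 8")
        if self.n_pv_tubes < 0 or self.n_scar_patches < 0:
            raise ValueError("tube and patch counts must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def for_target_scar_fraction(
        cls, fraction: float, n_patches: int = 4, **kwargs
    ) -> "PhantomSpec":
        """Size the scar patches so the realized scar fraction hits `fraction`.

        The angular half-angle alpha is initialized from the spherical-cap
        solid-angle formula (``n`` caps of half-angle alpha cover a fraction
        ``n (1 - cos alpha) / 2`` of the sphere) and then refined against the
        realized shell geometry during generation, so only discretization and
        patch-overlap scatter remain.
        """
        if not 0.0 < fraction < 1.0:
            raise ValueError("target fraction must be in (0, 1)")
        frac_per_patch = fraction / n_patches
        if frac_per_patch >= 0.5:
            raise ValueError("target fraction too large for the patch count")
        alpha = np.degrees(np.arccos(1.0 - 2.0 * frac_per_patch))
        return cls(
            n_scar_patches=n_patches,
            scar_angular_extent_deg=float(alpha),
            target_scar_fraction=fraction,
            scar_extent_jitter=0.0,
            **kwargs,
        )


@dataclass
class PhantomSample:
    """One generated phantom: image, ground-truth masks and known scar burden."""

    image: Volume
    anatomy: LabelVolume
    scar: LabelVolume
    wall: LabelVolume
    true_scar_fraction: float
    spec: PhantomSpec
    class_stats: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def wall_shell(
    anatomy: LabelVolume, spacing: tuple[float, float, float], thickness_mm: float
) -> LabelVolume:
    """Voxels outside the anatomy within `thickness_mm` of its surface.

    Distance is the Euclidean distance (in mm, anisotropy-aware) from each
    exterior voxel centre to the nearest anatomy voxel centre.
    """
    mask = anatomy.as_bool()
    if not mask.any():
        raise ValueError("anatomy mask is empty")
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    shell = (~mask) & (dist <= thickness_mm + 1e-9)
    return LabelVolume(shell.astype(np.uint8), tuple(spacing))


def _physical_grid(edge: int, spacing: float) -> tuple[np.ndarray, ...]:
    """Voxel-centre physical coordinates (z, y, x), centred on the grid."""
    c = (edge - 1) / 2.0 * spacing
    ax = np.arange(edge) * spacing - c
    return np.meshgrid(ax, ax, ax, indexing="ij")


def _sample_directions(rng: np.random.Generator, n: int, min_angle_rad: float,
                       max_tries: int = 200) -> np.ndarray:
    """Uniform unit vectors with pairwise angular separation >= min_angle_rad
    (best effort: separation is relaxed if rejection keeps failing)."""
    dirs: list[np.ndarray] = []
    sep = min_angle_rad
    tries = 0
    while len(dirs) < n:
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        if all(np.arccos(np.clip(np.dot(v, d), -1, 1)) >= sep for d in dirs):
            dirs.append(v)
            tries = 0
        else:
            tries += 1
            if tries > max_tries:
                sep *= 0.8
                tries = 0
    return np.array(dirs)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Generate one phantom, deterministically for a given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    e = spec.grid_edge
    sp = spec.spacing_mm
    zz, yy, xx = _physical_grid(e, sp)

    # LA cavity: ellipsoid with mildly jittered semi-axes and centre.
    semi = np.array(spec.la_semi_axes_mm) * rng.uniform(0.92, 1.08, size=3)
    centre = rng.uniform(-1.5, 1.5, size=3) * sp
    cavity = (
        ((zz - centre[0]) / semi[0]) ** 2
        + ((yy - centre[1]) / semi[1]) ** 2
        + ((xx - centre[2]) / semi[2]) ** 2
    ) <= 1.0

    # PV lumens: cylinders attached near the superior (+z) pole region.
    anatomy = cavity.copy()
    pts = np.stack([zz, yy, xx], axis=-1)  # (e, e, e, 3)
    for i in range(spec.n_pv_tubes):
        theta = rng.uniform(np.radians(20), np.radians(55))  # polar from +z
        phi = 2 * np.pi * i / max(spec.n_pv_tubes, 1) + rng.uniform(-0.4, 0.4)
        u = np.array(
            [np.cos(theta), np.sin(theta) * np.sin(phi), np.sin(theta) * np.cos(phi)]
        )
        # start on the ellipsoid surface along u, run outward for pv_length
        t_surf = 1.0 / np.sqrt(np.sum((u / semi) ** 2))
        p0 = centre + u * t_surf * 0.9  # slight overlap so the lumen connects
        seg = u * spec.pv_length_mm
        rel = pts - p0
        t = np.clip(np.tensordot(rel, seg, axes=([-1], [0])) / np.dot(seg, seg), 0, 1)
        closest = p0 + t[..., None] * seg
        d = np.linalg.norm(pts - closest, axis=-1)
        anatomy |= d <= spec.pv_radius_mm

    anatomy_lv = LabelVolume(anatomy.astype(np.uint8), (sp, sp, sp))
    shell_lv = wall_shell(anatomy_lv, (sp, sp, sp), spec.wall_thickness_mm)
    shell = shell_lv.as_bool()

    # Scar: contiguous angular sectors (spherical caps) of the wall shell.
    n_shell = int(shell.sum())
    scar = np.zeros_like(anatomy)
    if spec.n_scar_patches > 0 and n_shell > 0:
        alpha = np.radians(spec.scar_angular_extent_deg)
        if spec.target_scar_fraction is None and spec.scar_extent_jitter > 0:
            alpha *= rng.uniform(
                1.0 - spec.scar_extent_jitter, 1.0 + spec.scar_extent_jitter
            )
        patch_dirs = _sample_directions(rng, spec.n_scar_patches, 2.2 * alpha)
        rel = pts - centre
        norms = np.linalg.norm(rel, axis=-1)
        norms[norms == 0] = 1.0
        unit = rel / norms[..., None]
        # smallest patch-centre angle for each shell voxel
        shell_cos = np.full(n_shell, -1.0)
        unit_shell = unit[shell]
        for d in patch_dirs:
            shell_cos = np.maximum(shell_cos, unit_shell @ d)
        if spec.target_scar_fraction is not None:
            # refine alpha against the realized shell geometry: pick the
            # angular radius whose covered-voxel count matches the target
            order = np.sort(shell_cos)[::-1]
            n_want = min(n_shell, max(1, int(round(spec.target_scar_fraction * n_shell))))
            cos_cut = order[n_want - 1]
        else:
            cos_cut = np.cos(alpha)
        flags = np.zeros(e**3, dtype=bool).reshape(e, e, e)
        flags[shell] = shell_cos >= cos_cut
        scar = flags
    scar_lv = LabelVolume(scar.astype(np.uint8), (sp, sp, sp))

    true_fraction = float(scar.sum()) / n_shell if n_shell else 0.0

    # Piecewise-Gaussian tissue intensities. Non-scar wall voxels carry a
    # spatially correlated enhancement texture: in a real LGE scan the
    # atrial wall shows a continuum of mild enhancement (diffuse fibrosis,
    # contrast kinetics) rather than a uniformly nulled signal, which is
    # what makes global-intensity scar detection over-segment.
    img = rng.normal(spec.myo_mean, spec.myo_sd, size=(e, e, e))
    blood = anatomy & ~scar
    img[blood] = rng.normal(spec.blood_mean, spec.blood_sd, size=int(blood.sum()))
    wall_plain = shell & ~scar
    if wall_plain.any() and spec.wall_sd > 0:
        texture = ndimage.gaussian_filter(
            rng.normal(size=(e, e, e)), sigma=spec.wall_corr_mm / sp
        )
        texture /= max(texture.std(), 1e-12)
        img[wall_plain] = spec.wall_mean + spec.wall_sd * texture[wall_plain]
    img[scar] = rng.normal(spec.scar_mean, spec.scar_sd, size=int(scar.sum()))
    class_stats = {
        "blood": (float(img[blood].mean()), float(img[blood].std())) if blood.any() else (np.nan, np.nan),
        "scar": (float(img[scar].mean()), float(img[scar].std())) if scar.any() else (np.nan, np.nan),
        "myo": (float(img[~anatomy & ~scar].mean()), float(img[~anatomy & ~scar].std())),
    }

    # Degradations: partial-volume blur, coil-gain bias field, acquisition noise.
    if spec.psf_sigma_mm > 0:
        img = ndimage.gaussian_filter(img, sigma=spec.psf_sigma_mm / sp)
    if spec.bias_amplitude > 0:
        low = rng.normal(size=(3, 3, 3))
        fld = ndimage.zoom(low, e / 3.0, order=3)[:e, :e, :e]
        fld = fld - fld.mean()
        m = np.abs(fld).max()
        if m > 0:
            fld /= m
        img = img * (1.0 + spec.bias_amplitude * fld)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)

    return PhantomSample(
        image=Volume(img, (sp, sp, sp)),
        anatomy=anatomy_lv,
        scar=scar_lv,
        wall=shell_lv,
        true_scar_fraction=true_fraction,
        spec=spec,
        class_stats=class_stats,
    )


def generate_cohort(spec: PhantomSpec, n: int, seed: int | None = None) -> list[PhantomSample]:
    """Generate ``n`` phantoms with per-sample seeds ``root + index``.

    The root seed defaults to ``spec.seed``. Fixed seed arithmetic keeps
    cohorts bit-reproducible across platforms.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    root = spec.seed if seed is None else int(seed)
    return [
        generate_phantom(dataclasses.replace(spec, seed=root + i)) for i in range(n)
    ]
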