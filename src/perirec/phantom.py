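"""Synthetic multiparametric phantoms with known recurrence ground truth.

Each phantom case mimics the geometry of an operated glioblastoma on
postoperative MRI: a spherical resection cavity, a surrounding peritumoral
shell, and — inside the shell — a directional recurrence sector hugging the
cavity wall whose intensities and texture differ from the edematous remainder
by a controllable standardized effect size.  Five coregistered modality
channels (T1w, T1ce, T2w, FLAIR, ADC) share a latent texture field so that
they carry correlated, partially redundant information.

Texture is realized as smoothed Gaussian random fields: white noise blurred
with a Gaussian kernel of a given correlation length and rescaled to unit
variance.  This is not an anatomical brain simulation; it is the minimal
structure that makes first-order and texture features discriminative in a
controlled way.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import MaskVolume, VoxelGrid, read_volume, write_volume

MODALITIES = ("t1w", "t1ce", "t2w", "flair", "adc")

#: Per-modality multiplier on the standardized intensity shift of recurrence
#: voxels.  Contrast enhancement dominates on T1ce; ADC drops (restricted
#: diffusion in cellular tumor).
MODALITY_EFFECT_WEIGHTS = {
    "t1w": 0.3, "t1ce": 1.0, "t2w": 0.3, "flair": 0.5, "adc": -0.7,
}


@dataclass
class PhantomSpec:
    """Geometry, contrast, and texture parameters of one phantom case.

    ``effect_size`` is the standardized mean shift (in units of the marginal
    intensity SD) applied to recurrence voxels in the reference modality
    (T1ce); other modalities are scaled by :data:`MODALITY_EFFECT_WEIGHTS`.
    With ``effect_size=0`` the phantom is an exact null: the class-specific
    texture field is disabled too, so the two classes are statistically
    indistinguishable.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    cavity_radius_mm: float = 10.0
    shell_thickness_mm: float = 12.0
    recurrence_solid_angle_deg: float = 60.0
    recurrence_depth_mm: float = 10.0
    effect_size: float = 2.0
    texture_corr_len_mm: float = 2.0
    recurrence_texture_corr_len_mm: float = 3.5
    texture_mix: float = 0.5
    modality_corr: float = 0.5
    noise_sd: float = 0.5
    brain_margin_mm: float = 8.0
    n_modalities: int = 5
    seed: int = 0
    cavity_center_mm: tuple[float, float, float] | None = None
    recurrence_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def validate(self) -> None:
        for name in ("cavity_radius_mm", "shell_thickness_mm",
                     "recurrence_solid_angle_deg", "recurrence_depth_mm",
                     "texture_corr_len_mm", "recurrence_texture_corr_len_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.recurrence_depth_mm > self.shell_thickness_mm:
            raise ValueError("recurrence depth must not exceed shell thickness")
        if self.n_modalities != len(MODALITIES):
            raise ValueError(f"n_modalities fixed at {len(MODALITIES)}")
        if not 0 <= self.texture_mix <= 1 or not 0 <= self.modality_corr <= 1:
            raise ValueError("texture_mix and modality_corr must lie in [0, 1]")
        extent = np.asarray(self.grid_shape) * np.asarray(self.spacing_mm)
        outer = self.cavity_radius_mm + self.shell_thickness_mm
        if np.any(2 * outer >= extent):
            raise ValueError(
                f"cavity + shell (radius {outer} mm) does not fit in grid extent {tuple(extent)} mm")


@dataclass
class CaseBundle:
    """One coregistered phantom case: five modalities plus the three masks."""

    case_id: str
    modalities: dict[str, VoxelGrid]
    cavity_mask: MaskVolume
    peritumor_mask: MaskVolume
    followup_enhancing_mask: MaskVolume
    brain_mask: MaskVolume
    spec: PhantomSpec | None = None

    def __post_init__(self) -> None:
        ref = self.cavity_mask
        for name, vol in list(self.modalities.items()) + [
                ("peritumor", self.peritumor_mask),
                ("followup", self.followup_enhancing_mask),
                ("brain", self.brain_mask)]:
            if not ref.same_geometry(vol):
                raise ValueError(f"volume {name!r} geometry differs from cavity mask")
        if (self.cavity_mask.data & self.peritumor_mask.data).any():
            raise ValueError("cavity and peritumor masks must be disjoint")


def _gaussian_random_field(rng: np.random.Generator, shape, corr_len_vox) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    white = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(white, sigma=corr_len_vox, mode="wrap")
    return (f - f.mean()) / f.std()


def generate_phantom(spec: PhantomSpec, case_id: str = "case_000") -> CaseBundle:
    """Build one phantom case; bit-identical for a fixed ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    affine = np.diag([*spacing, 1.0])

    center = (np.asarray(shape) - 1) / 2.0 * spacing
    if spec.cavity_center_mm is not None:
        center = np.asarray(spec.cavity_center_mm, dtype=float)
    coords = np.stack(np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                                  indexing="ij"), axis=-1)
    disp = coords - center
    r = np.linalg.norm(disp, axis=-1)

    outer = spec.cavity_radius_mm + spec.shell_thickness_mm
    cavity = r <= spec.cavity_radius_mm
    shell = (r > spec.cavity_radius_mm) & (r <= outer)
    brain = r <= outer + spec.brain_margin_mm
    if not cavity.any() or not shell.any():
        raise ValueError("degenerate geometry: empty cavity or peritumoral shell")

    u = np.asarray(spec.recurrence_direction, dtype=float)
    u = u / np.linalg.norm(u)
    with np.errstate(invalid="ignore"):
        cosang = np.divide((disp * u).sum(-1), r, out=np.ones_like(r), where=r > 0)
    half_angle = np.deg2rad(spec.recurrence_solid_angle_deg) / 2.0
    recurrence = (shell
                  & (r <= spec.cavity_radius_mm + spec.recurrence_depth_mm)
                  & (cosang >= np.cos(half_angle)))

    # Follow-up enhancement = peritumoral recurrence plus a bulge regrowing
    # into the cavity, so downstream clipping to the peritumor is exercised.
    bulge_center = center + u * spec.cavity_radius_mm
    bulge = (np.linalg.norm(coords - bulge_center, axis=-1)
             <= spec.recurrence_depth_mm / 2.0) & cavity
    followup = recurrence | bulge

    corr0 = spec.texture_corr_len_mm / spacing
    corr1 = spec.recurrence_texture_corr_len_mm / spacing
    rho = spec.modality_corr
    latent0 = _gaussian_random_field(rng, shape, corr0)
    latent1 = _gaussian_random_field(rng, shape, corr1)
    # Class-specific texture engages only when an intensity effect is present;
    # effect_size == 0 yields an exact null phantom.
    w = spec.texture_mix if spec.effect_size != 0 else 0.0
    marginal_sd = np.sqrt(1.0 + spec.noise_sd ** 2)

    modalities: dict[str, VoxelGrid] = {}
    for mod in MODALITIES:
        own0 = _gaussian_random_field(rng, shape, corr0)
        own1 = _gaussian_random_field(rng, shape, corr1)
        base = np.sqrt(rho) * latent0 + np.sqrt(1 - rho) * own0
        rec_tex = np.sqrt(rho) * latent1 + np.sqrt(1 - rho) * own1
        img = base.copy()
        img[recurrence] = (np.sqrt(1 - w ** 2) * base[recurrence]
                           + w * rec_tex[recurrence])
        img[recurrence] += (spec.effect_size * MODALITY_EFFECT_WEIGHTS[mod]
                            * marginal_sd)
        img += spec.noise_sd * rng.standard_normal(shape)
        img[~brain] = 0.0
        modalities[mod] = VoxelGrid(data=img.astype(np.float32), affine=affine.copy())

    mk = lambda m: MaskVolume(data=m.astype(np.uint8), affine=affine.copy())
    return CaseBundle(case_id=case_id, modalities=modalities,
                      cavity_mask=mk(cavity), peritumor_mask=mk(shell),
                      followup_enhancing_mask=mk(followup), brain_mask=mk(brain),
                      spec=spec)


def generate_cohort(n_train: int, n_test: int, spec: PhantomSpec,
                    seed: int = 0) -> tuple[list[CaseBundle], list[CaseBundle]]:
    """Generate disjoint train/test cohorts with per-case jittered geometry.

    Each case gets its own subseed, a jittered cavity center (±3 mm per axis)
    and an independent random recurrence direction.
    """
    if n_train < 1 or n_test < 1:
        raise ValueError("cohort sizes must be >= 1")
    spec.validate()
    children = np.random.SeedSequence(seed).spawn(n_train + n_test)
    shape = np.asarray(spec.grid_shape, dtype=float)
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    grid_center = (shape - 1) / 2.0 * spacing

    cases: list[CaseBundle] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        jitter = rng.uniform(-3.0, 3.0, size=3)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        sub = replace(spec,
                      seed=int(rng.integers(2 ** 31)),
                      cavity_center_mm=tuple(grid_center + jitter),
                      recurrence_direction=tuple(direction))
        split = "train" if i < n_train else "test"
        idx = i if i < n_train else i - n_train
        cases.append(generate_phantom(sub, case_id=f"{split}_{idx:03d}"))
    return cases[:n_train], cases[n_train:]


def save_case(bundle: CaseBundle, root) -> Path:
    """Write a case as ``<root>/<case_id>/<role>.nii.gz`` plus a JSON sidecar."""
    case_dir = Path(root) / bundle.case_id
    case_dir.mkdir(parents=True, exist_ok=True)
    for role, grid in bundle.modalities.items():
        write_volume(grid, case_dir / f"{role}.nii.gz")
    for role, mask in [("cavity", bundle.cavity_mask),
                       ("peritumor", bundle.peritumor_mask),
                       ("followup_enhancing", bundle.followup_enhancing_mask),
                       ("brain", bundle.brain_mask)]:
        write_volume(mask, case_dir / f"{role}.nii.gz")
    sidecar = {"case_id": bundle.case_id,
               "spec": asdict(bundle.spec) if bundle.spec else None}
    (case_dir / "case.json").write_text(json.dumps(sidecar, indent=2))
    return case_dir


def load_case(case_dir) -> CaseBundle:
    case_dir = Path(case_dir)
    modalities = {}
    for role in MODALITIES:
        path = case_dir / f"{role}.nii.gz"
        if not path.exists():
            raise FileNotFoundError(
                f"case {case_dir.name!r}: missing modality {role!r} ({path})")
        modalities[role] = read_volume(path)
    masks = {}
    for role in ("cavity", "peritumor", "followup_enhancing", "brain"):
        path = case_dir / f"{role}.nii.gz"
        if not path.exists():
            raise FileNotFoundError(f"case {case_dir.name!r}: missing mask {role!r}")
        masks[role] = read_volume(path, as_mask=True)
    spec = None
    sidecar = case_dir / "case.json"
    if sidecar.exists():
        raw = json.loads(sidecar.read_text()).get("spec")
        if raw is not None:
            for key in ("grid_shape", "spacing_mm", "cavity_center_mm",
                        "recurrence_direction"):
                if raw.get(key) is not None:
                    raw[key] = tuple(raw[key])
            spec = PhantomSpec(**raw)
    return CaseBundle(case_id=case_dir.name, modalities=modalities,
                      cavity_mask=masks["cavity"], peritumor_mask=masks["peritumor"],
                      followup_enhancing_mask=masks["followup_enhancing"],
                      brain_mask=masks["brain"], spec=spec)
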