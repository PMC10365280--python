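"""Digital head-phantom cohort with known ground truth.

Generates a CT-like template, per-subject deformed anatomies, technique-
dependent dose fields and demographics, so the whole analysis chain can be
exercised and validated without patient data.

Geometry is expressed in world mm as fractions of the grid's physical
extent, so the same phantom renders consistently on the full 2 mm template
grid and on small test grids.

Dose model: the planning target is an ellipsoid around a nasopharynx-analog
centre, receiving exactly the prescription inside and an exponential
falloff ``Rx * exp(-d / lambda)`` outside (``d`` = radial mm beyond the
target surface).  Technique asymmetry is injected as an additive +/-
``effect_size/2`` Gy term on an anterior and a posterior intermediate-dose
lobe with opposite signs for IMRT and VMAT, giving an exactly known group
mean difference of ``effect_size`` Gy inside the effect mask.  Noise is
smooth, seeded, technique-independent, and confined to outside the target
plateau (so target coverage is deterministic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from doseatlas.spatial_norm import (
    DeformationField,
    RigidTransform,
    TransformChain,
    invert_displacement,
)
from doseatlas.volume_io import (
    AtlasVolume,
    GridSpec,
    MaskVolume,
    Volume,
    write_atlas,
    write_volume,
)

__all__ = [
    "SubjectRecord",
    "GroundTruth",
    "PhantomParams",
    "Cohort",
    "make_template_phantom",
    "make_atlas_phantom",
    "sample_subject",
    "simulate_dose",
    "sample_record",
    "make_cohort",
    "target_mask",
    "target_coverage",
]

# Cohort-level constants drawn from the emulated population:
# 567 of 803 patients male; median age 53; T-stage counts 81/98/416/207.
MALE_FRACTION = 567 / 803
AGE_MEAN, AGE_SD = 53.0, 10.0
AGE_RANGE = (18.0, 84.0)
PRESCRIPTION_DEFAULT = 70.4
PRESCRIPTION_RANGE = (66.9, 74.2)
T_STAGE_COUNTS = {"T1": 81, "T2": 98, "T3": 416, "T4": 207}
T_STAGE_RADIUS_SCALE = {"T1": 0.85, "T2": 0.92, "T3": 1.0, "T4": 1.1}


@dataclass
class SubjectRecord:
    """One subject's demographics and treatment assignment."""

    id: str
    age: float
    gender: str  # {male, female}
    t_stage: str  # {T1..T4}
    technique: str  # {IMRT, VMAT}
    prescription_dose: float = PRESCRIPTION_DEFAULT

    def __post_init__(self) -> None:
        if self.gender not in ("male", "female"):
            raise ValueError(f"bad gender {self.gender!r}")
        if self.t_stage not in T_STAGE_RADIUS_SCALE:
            raise ValueError(f"bad T stage {self.t_stage!r}")
        if self.technique not in ("IMRT", "VMAT"):
            raise ValueError(f"bad technique {self.technique!r}")
        if not (AGE_RANGE[0] <= self.age <= AGE_RANGE[1]):
            raise ValueError(f"age {self.age} outside {AGE_RANGE}")
        if not (PRESCRIPTION_RANGE[0] <= self.prescription_dose
                <= PRESCRIPTION_RANGE[1]):
            raise ValueError(
                f"prescription {self.prescription_dose} outside "
                f"{PRESCRIPTION_RANGE}")


@dataclass
class PhantomParams:
    """Tunable knobs of the phantom generator (all configurable)."""

    falloff_mm: float = 25.0  # dose falloff length lambda
    target_radius_mm: float | None = None  # None -> 15% of the grid half-extent
    effect_size_gy: float = 3.0  # group mean difference inside effect lobes
    effect_radius_mm: float = 9.0  # lobe radius
    noise_sigma_gy: float = 1.0  # per-subject dose noise (smooth), Gy
    noise_smooth_mm: float = 8.0
    hu_noise: float = 8.0  # additive CT noise, HU
    texture_hu: float = 15.0  # deterministic intra-brain texture amplitude
    deform_smooth_mm: float = 15.0  # smoothness of subject deformations
    age_dose_slope: float = 0.0  # Gy per year of (age - 53), brain-wide


@dataclass
class GroundTruth:
    """Everything the generator knows exactly, for parameter-recovery tests."""

    head_support_mask: MaskVolume
    brain_mask: MaskVolume
    target_center: np.ndarray
    effect_mask: MaskVolume
    effect_size: float
    head_volume_mm3: float
    subject_transform: dict[str, TransformChain] = field(default_factory=dict)
    dose_template: dict[str, Volume] = field(default_factory=dict)
    target_masks: dict[str, MaskVolume] = field(default_factory=dict)


@dataclass
class Cohort:
    """Subject records + per-subject volumes (in memory and/or on disk)."""

    subjects: list[SubjectRecord]
    table: pd.DataFrame
    ct: dict[str, Volume] = field(default_factory=dict)
    dose: dict[str, Volume] = field(default_factory=dict)
    out_dir: Path | None = None


# --------------------------------------------------------------------------
# template phantom
# --------------------------------------------------------------------------

def _ellipsoid_r2(grid: GridSpec, center, radii):
    """Squared normalized ellipsoid coordinate at every voxel."""
    x, y, z = grid.world_coords()
    return (((x - center[0]) / radii[0]) ** 2
            + ((y - center[1]) / radii[1]) ** 2
            + ((z - center[2]) / radii[2]) ** 2)


def _phantom_geometry(grid: GridSpec) -> dict:
    h = grid.extent_mm / 2.0
    c = grid.center_mm
    head_r = 0.80 * h
    skull_t = np.minimum(6.0, 0.08 * h)  # shell thickness, mm
    brain_r = head_r - skull_t - np.minimum(6.0, 0.08 * h)
    target_center = c + np.array([0.0, 0.25 * h[1], -0.50 * h[2]])
    lobe_a = target_center + np.array([0.0, 0.20 * h[1], 0.40 * h[2]])
    lobe_p = target_center + np.array([0.0, -0.45 * h[1], 0.40 * h[2]])
    return {"center": c, "head_r": head_r, "skull_t": skull_t,
            "brain_r": brain_r, "target_center": target_center,
            "lobe_anterior": lobe_a, "lobe_posterior": lobe_p}


def make_template_phantom(grid: GridSpec | None = None, seed: int = 0,
                          params: PhantomParams | None = None,
                          ) -> tuple[Volume, GroundTruth]:
    """CT-like head phantom: air -1000, brain ~+30, skull ~+700 HU.

    Deterministic given ``seed`` (which drives only the intra-brain texture).
    Ground truth records the exact head support, brain mask, effect lobes and
    nasopharynx-analog target centre.
    """
    grid = grid or GridSpec.mni_2mm()
    params = params or PhantomParams()
    g = _phantom_geometry(grid)
    h = grid.extent_mm / 2.0
    r2_head = _ellipsoid_r2(grid, g["center"], g["head_r"])
    # inner skull boundary shifted laterally: the skull shell is thicker on
    # the left, breaking the mirror symmetry registration must resolve
    inner_center = g["center"] + np.array([0.04 * h[0], 0.0, 0.0])
    r2_inner = _ellipsoid_r2(grid, inner_center, g["head_r"] - g["skull_t"])
    r2_brain = _ellipsoid_r2(grid, g["center"], g["brain_r"])

    data = np.full(grid.shape, -1000.0)
    head = r2_head <= 1.0
    data[head] = 700.0  # skull shell default inside head
    inner = r2_inner <= 1.0
    data[inner] = 30.0

    # deterministic two-scale smooth texture so the soft-tissue interior is
    # not featureless (coarse "anatomy" + finer detail); registration
    # accuracy away from boundaries depends on this structure
    rng = np.random.default_rng(seed)
    tex = np.zeros(grid.shape)
    for scale_mm, amp in ((8.0, params.texture_hu),
                          (4.0, 0.8 * params.texture_hu)):
        t = ndimage.gaussian_filter(rng.standard_normal(grid.shape),
                                    scale_mm / np.asarray(grid.spacing))
        sd = t.std()
        if sd > 0:
            tex += t / sd * amp
    data[inner] += tex[inner]

    # ventricle analogs: two low-HU ellipsoids, left larger than right
    for sign, scale, zoff in ((-1.0, 1.25, 0.10), (1.0, 0.8, 0.16)):
        vc = g["center"] + np.array([sign * 0.12 * grid.extent_mm[0] / 2,
                                     0.0, zoff * grid.extent_mm[2] / 2])
        vr = np.maximum(scale * 0.06 * grid.extent_mm / 2, grid.spacing)
        vr[1] *= 2.5  # elongated anterior-posterior
        vent = _ellipsoid_r2(grid, vc, vr) <= 1.0
        data[vent & inner] = 5.0

    template = Volume(data=data, affine=grid.affine, space="template")
    head_mask = MaskVolume(data=head.astype(np.uint8), affine=grid.affine,
                           space="template")
    brain = (r2_brain <= 1.0)
    brain_mask = MaskVolume(data=brain.astype(np.uint8), affine=grid.affine,
                            space="template")
    effect = np.zeros(grid.shape, dtype=bool)
    for key in ("lobe_anterior", "lobe_posterior"):
        lobe = _ellipsoid_r2(grid, g[key],
                             np.full(3, params.effect_radius_mm)) <= 1.0
        effect |= lobe
    effect &= brain
    truth = GroundTruth(
        head_support_mask=head_mask,
        brain_mask=brain_mask,
        target_center=g["target_center"],
        effect_mask=MaskVolume(data=effect.astype(np.uint8),
                               affine=grid.affine, space="template"),
        effect_size=params.effect_size_gy,
        head_volume_mm3=float(head.sum()) * float(np.prod(grid.spacing)),
    )
    return template, truth


def make_atlas_phantom(grid: GridSpec | None = None) -> AtlasVolume:
    """Coarse ~12-region atlas on the phantom brain.

    Regions are defined by hemisphere (world x sign) and anterior/posterior
    and superior/inferior zones, named after the lobes the analysis reports
    (temporal, limbic, frontal, occipital, cerebellum analogs).
    """
    grid = grid or GridSpec.mni_2mm()
    g = _phantom_geometry(grid)
    brain = _ellipsoid_r2(grid, g["center"], g["brain_r"]) <= 1.0
    x, y, z = grid.world_coords()
    x = np.broadcast_to(x, grid.shape)
    y = np.broadcast_to(y, grid.shape)
    z = np.broadcast_to(z, grid.shape)
    c = g["center"]
    h = grid.extent_mm / 2.0

    labels = np.zeros(grid.shape, dtype=np.int32)
    table: dict[int, tuple[str, str]] = {}
    zones = [
        # (name, lobe, predicate) in template world coordinates
        ("Frontal Lobe", "frontal",
         (y > c[1] + 0.25 * h[1]) & (z > c[2])),
        ("Occipital Lobe", "occipital",
         (y < c[1] - 0.25 * h[1]) & (z > c[2])),
        ("Parietal Lobe", "parietal",
         (np.abs(y - c[1]) <= 0.25 * h[1]) & (z > c[2] + 0.25 * h[2])),
        ("Temporal Lobe", "temporal",
         (y > c[1]) & (z <= c[2])),
        ("Limbic Lobe", "limbic",
         (np.abs(y - c[1]) <= 0.25 * h[1]) & (z <= c[2] + 0.25 * h[2])
         & (z > c[2] - 0.35 * h[2]) & (y <= c[1])),
        ("Cerebellum", "cerebellum",
         (y < c[1] - 0.0 * h[1]) & (z <= c[2] - 0.35 * h[2])),
    ]
    label = 0
    for name, lobe, pred in zones:
        for hemi, sign in (("Left", -1.0), ("Right", 1.0)):
            label += 1
            sel = brain & pred & (sign * (x - 0.0) > 0) & (labels == 0)
            labels[sel] = label
            table[label] = (f"{hemi} {name}", lobe)
    # anything left in brain: deep/midline catch-all
    label += 1
    sel = brain & (labels == 0)
    labels[sel] = label
    table[label] = ("Deep Midline", "deep")
    return AtlasVolume(data=labels, affine=grid.affine, space="template",
                       label_table=table)


# --------------------------------------------------------------------------
# subject anatomy
# --------------------------------------------------------------------------

def _smooth_vector_field(grid: GridSpec, rng: np.random.Generator,
                         smooth_mm: float, rms_mm: float,
                         support: np.ndarray) -> np.ndarray:
    """Gaussian-smoothed random displacement with target RMS inside support."""
    disp = rng.standard_normal(tuple(grid.shape) + (3,))
    sigma = smooth_mm / np.asarray(grid.spacing)
    for a in range(3):
        disp[..., a] = ndimage.gaussian_filter(disp[..., a], sigma)
    cur = np.sqrt(np.mean(np.sum(disp[support] ** 2, axis=-1)))
    if cur > 0:
        disp *= rms_mm / cur
    else:
        disp[:] = 0.0
    return disp


def sample_subject(template: Volume, record: SubjectRecord, seed: int,
                   deform_scale: float = 3.0,
                   rigid_max_mm: float = 10.0, rigid_max_deg: float = 6.0,
                   params: PhantomParams | None = None,
                   truth: GroundTruth | None = None,
                   extra_volumes: dict[str, Volume] | None = None,
                   ) -> tuple[Volume, TransformChain]:
    """Warp the template into a subject-space CT with a known transform.

    The subject is ``template(W(y))`` where ``W`` composes a smooth random
    displacement (RMS ``deform_scale`` mm) with a random rigid offset, plus
    additive HU noise.  The returned chain is the exact template->subject
    map ``W^{-1}`` (stored as a dense field), i.e. the transform a perfect
    normalization would recover.  ``extra_volumes`` (e.g. the template-space
    dose) are warped with the identical ``W`` and returned via mutation of
    the dict (synchronization by construction).
    """
    if deform_scale < 0:
        raise ValueError("deform_scale must be >= 0")
    params = params or PhantomParams()
    grid = GridSpec(shape=template.shape,
                    spacing=tuple(template.spacing),
                    origin=tuple(template.affine[:3, 3]))
    rng = np.random.default_rng(seed)
    angles = rng.uniform(-1, 1, 3) * np.deg2rad(rigid_max_deg)
    trans = rng.uniform(-1, 1, 3) * rigid_max_mm
    if rigid_max_mm == 0 and rigid_max_deg == 0:
        angles[:] = 0.0
        trans[:] = 0.0
    center = grid.center_mm
    rigid = RigidTransform(rotation=angles, translation=trans, center=center)

    support = template.data > -500
    if deform_scale > 0:
        disp = _smooth_vector_field(grid, rng, params.deform_smooth_mm,
                                    deform_scale, support)
    else:
        disp = np.zeros(tuple(grid.shape) + (3,))
    field_fwd = DeformationField(disp=disp, affine=grid.affine)

    # forward map W: subject world y -> template world, rigid then warp
    def W(pts: np.ndarray) -> np.ndarray:
        p = rigid.map_points(pts)
        return p + field_fwd.sample(p)

    identity = (deform_scale == 0 and np.all(angles == 0)
                and np.all(trans == 0))
    inv_affine = np.linalg.inv(template.affine)
    if identity:
        subject_data = template.data.astype(float).copy()
    else:
        xs, ys, zs = np.mgrid[[slice(0, s) for s in grid.shape]]
        vox = np.stack([xs, ys, zs], axis=-1).reshape(-1, 3).astype(float)
        world = vox @ np.asarray(grid.affine)[:3, :3].T + grid.origin
        mapped = W(world)
        mvox = (mapped @ inv_affine[:3, :3].T + inv_affine[:3, 3]).T
        subject_data = ndimage.map_coordinates(
            template.data.astype(float), mvox, order=1, mode="constant",
            cval=-1000.0).reshape(grid.shape)
        if extra_volumes:
            for key, vol in list(extra_volumes.items()):
                warped = ndimage.map_coordinates(
                    np.asarray(vol.data, float), mvox, order=1,
                    mode="constant", cval=0.0).reshape(grid.shape)
                extra_volumes[key] = Volume(data=warped, affine=grid.affine,
                                            space="subject")
    if params.hu_noise > 0:
        subject_data = subject_data + rng.standard_normal(grid.shape) \
            * params.hu_noise
    subject = Volume(data=subject_data, affine=grid.affine, space="subject")

    if identity:
        chain = TransformChain()
    else:
        inv_field = invert_displacement(W, grid)
        chain = TransformChain(deformation=inv_field)
    if truth is not None:
        truth.subject_transform[record.id] = chain
    return subject, chain


# --------------------------------------------------------------------------
# dose simulation
# --------------------------------------------------------------------------

def _target_radii(record: SubjectRecord, params: PhantomParams,
                  grid: GridSpec) -> np.ndarray:
    base = params.target_radius_mm
    if base is None:
        base = 0.15 * float(grid.extent_mm.min()) / 2.0
    r = base * T_STAGE_RADIUS_SCALE[record.t_stage]
    return np.array([r, 1.2 * r, 0.8 * r])


def target_mask(record: SubjectRecord, target_center, grid: GridSpec,
                params: PhantomParams | None = None) -> MaskVolume:
    """Planning-target ellipsoid (T-stage-scaled) as a template-grid mask."""
    params = params or PhantomParams()
    r2 = _ellipsoid_r2(grid, np.asarray(target_center),
                       _target_radii(record, params, grid))
    return MaskVolume(data=(r2 <= 1.0).astype(np.uint8), affine=grid.affine,
                      space="template")


def simulate_dose(record: SubjectRecord, subject_support: MaskVolume,
                  target_center, params: PhantomParams | None = None,
                  seed: int = 0,
                  effect_mask: MaskVolume | None = None) -> Volume:
    """Synthesize a dose field (Gy) for one subject on the support grid.

    * exactly the prescription inside the target ellipsoid;
    * ``Rx * exp(-d / lambda)`` falloff outside (d = mm beyond the surface);
    * +/- ``effect_size/2`` Gy on the anterior/posterior lobes with signs
      flipped between IMRT and VMAT (zero net when effect_size is 0);
    * smooth seeded noise outside the target plateau only;
    * clipped to >= 0 and zeroed outside the head support.
    """
    params = params or PhantomParams()
    rx = record.prescription_dose
    if not (60.0 <= rx <= 80.0):
        raise ValueError(f"prescription {rx} Gy outside the accepted "
                         f"[60, 80] Gy range")
    grid = GridSpec(shape=subject_support.shape,
                    spacing=tuple(subject_support.spacing),
                    origin=tuple(subject_support.affine[:3, 3]))
    center = np.asarray(target_center, dtype=float)
    radii = _target_radii(record, params, grid)
    x, y, z = grid.world_coords()
    dx, dy, dz = x - center[0], y - center[1], z - center[2]
    dist = np.sqrt(dx * dx + dy * dy + dz * dz)
    rnorm = np.sqrt((dx / radii[0]) ** 2 + (dy / radii[1]) ** 2
                    + (dz / radii[2]) ** 2)
    inside = rnorm <= 1.0
    # mm beyond the ellipsoid surface along the radial direction
    with np.errstate(divide="ignore", invalid="ignore"):
        d_out = np.where(inside, 0.0, dist * (1.0 - 1.0 / np.maximum(rnorm,
                                                                     1e-12)))
    dose = rx * np.exp(-d_out / params.falloff_mm)
    dose[inside] = rx

    # technique asymmetry: opposite-signed lobes, exact group difference
    if params.effect_size_gy != 0.0:
        g = _phantom_geometry(grid)
        sign = 1.0 if record.technique == "IMRT" else -1.0
        half = params.effect_size_gy / 2.0
        for key, s in (("lobe_anterior", +1.0), ("lobe_posterior", -1.0)):
            lobe = _ellipsoid_r2(grid, g[key],
                                 np.full(3, params.effect_radius_mm)) <= 1.0
            if effect_mask is not None:
                lobe &= effect_mask.data.astype(bool)
            dose[lobe] += sign * s * half

    if params.age_dose_slope != 0.0:
        dose += params.age_dose_slope * (record.age - AGE_MEAN) \
            * (~inside) * np.exp(-d_out / (2 * params.falloff_mm))

    if params.noise_sigma_gy > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(grid.shape)
        noise = ndimage.gaussian_filter(
            noise, params.noise_smooth_mm / np.asarray(grid.spacing))
        sd = noise.std()
        if sd > 0:
            noise = noise / sd * params.noise_sigma_gy
        dose = dose + noise * (~inside)

    dose = np.clip(dose, 0.0, None)
    dose[~subject_support.data.astype(bool)] = 0.0
    return Volume(data=dose, affine=grid.affine, space=subject_support.space)


def target_coverage(dose: Volume, record: SubjectRecord, target_center,
                    params: PhantomParams | None = None) -> float:
    """Fraction of target-ellipsoid voxels at or above the prescription."""
    grid = GridSpec(shape=dose.shape, spacing=tuple(dose.spacing),
                    origin=tuple(dose.affine[:3, 3]))
    tm = target_mask(record, target_center, grid, params).data.astype(bool)
    if not tm.any():
        raise ValueError("target ellipsoid contains no voxels on this grid")
    return float(np.mean(dose.data[tm] >= record.prescription_dose))


# --------------------------------------------------------------------------
# cohort assembly
# --------------------------------------------------------------------------

def sample_record(rng: np.random.Generator, subject_id: str,
                  technique: str) -> SubjectRecord:
    """Draw demographics matching the emulated population margins."""
    age = float(np.clip(rng.normal(AGE_MEAN, AGE_SD), *AGE_RANGE))
    gender = "male" if rng.random() < MALE_FRACTION else "female"
    stages = list(T_STAGE_COUNTS)
    probs = np.array(list(T_STAGE_COUNTS.values()), dtype=float)
    t_stage = rng.choice(stages, p=probs / probs.sum())
    rx = float(np.clip(rng.normal(PRESCRIPTION_DEFAULT, 1.0),
                       *PRESCRIPTION_RANGE))
    return SubjectRecord(id=subject_id, age=age, gender=gender,
                         t_stage=str(t_stage), technique=technique,
                         prescription_dose=rx)


def make_cohort(n_per_group: int, seed: int,
                grid: GridSpec | None = None,
                params: PhantomParams | None = None,
                out_dir: str | Path | None = None,
                deform_scale: float = 0.0,
                rigid_max_mm: float = 0.0, rigid_max_deg: float = 0.0,
                ) -> tuple[Cohort, GroundTruth]:
    """Balanced IMRT/VMAT cohort with full ground truth.

    With the default ``deform_scale=0`` subjects stay on the template grid
    (anatomy identical up to HU noise) -- the fast path for statistical
    testing.  Set ``deform_scale > 0`` (and rigid limits) to exercise the
    normalization pipeline.  When ``out_dir`` is given, all volumes plus
    ``cohort.tsv`` are written there; volumes are always kept in memory too.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    grid = grid or GridSpec.mni_2mm()
    params = params or PhantomParams()
    template, truth = make_template_phantom(grid, seed=seed, params=params)
    atlas = make_atlas_phantom(grid)
    ss = np.random.SeedSequence(seed)
    rec_rng = np.random.default_rng(ss.spawn(1)[0])
    subject_seeds = ss.generate_state(2 * n_per_group * 2).reshape(-1, 2)

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        write_volume(template, out_path / "template.nii")
        write_volume(truth.brain_mask, out_path / "brain_mask.nii")
        write_atlas(atlas, out_path / "atlas.nii", out_path / "atlas.tsv")

    records: list[SubjectRecord] = []
    rows = []
    cohort = Cohort(subjects=records, table=pd.DataFrame(), out_dir=out_path)
    deform = (deform_scale > 0 or rigid_max_mm > 0 or rigid_max_deg > 0)
    for i in range(2 * n_per_group):
        technique = "IMRT" if i % 2 == 0 else "VMAT"
        rec = sample_record(rec_rng, f"sub-{i + 1:03d}", technique)
        records.append(rec)
        dose_seed, anat_seed = (int(subject_seeds[i][0]),
                                int(subject_seeds[i][1]))
        dose_t = simulate_dose(rec, truth.head_support_mask,
                               truth.target_center, params, seed=dose_seed,
                               effect_mask=truth.effect_mask)
        truth.dose_template[rec.id] = dose_t
        truth.target_masks[rec.id] = target_mask(rec, truth.target_center,
                                                 grid, params)
        if deform:
            extra = {"dose": dose_t}
            ct, chain = sample_subject(template, rec, seed=anat_seed,
                                       deform_scale=deform_scale,
                                       rigid_max_mm=rigid_max_mm,
                                       rigid_max_deg=rigid_max_deg,
                                       params=params, truth=truth,
                                       extra_volumes=extra)
            dose_s = extra["dose"]
        else:
            hu = np.random.default_rng(anat_seed).standard_normal(grid.shape) \
                * params.hu_noise
            ct = Volume(data=template.data + hu, affine=grid.affine,
                        space="subject")
            dose_s = dose_t.copy()
            truth.subject_transform[rec.id] = TransformChain()
        cohort.ct[rec.id] = ct
        cohort.dose[rec.id] = dose_s
        ct_path = dose_path = ""
        if out_path is not None:
            ct_path = str(out_path / f"{rec.id}_ct.nii")
            dose_path = str(out_path / f"{rec.id}_dose.nii")
            write_volume(ct, ct_path)
            write_volume(dose_s, dose_path)
        rows.append({"id": rec.id, "age": rec.age, "gender": rec.gender,
                     "t_stage": rec.t_stage, "technique": rec.technique,
                     "prescription_dose": rec.prescription_dose,
                     "ct_path": ct_path, "dose_path": dose_path})
    cohort.table = pd.DataFrame(rows)
    if out_path is not None:
        cohort.table.to_csv(out_path / "cohort.tsv", sep="\t", index=False)
    truth.effect_size = params.effect_size_gy
    return cohort, truth
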