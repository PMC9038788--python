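"""Seeded CT-like torso phantoms with paired ground truth.

Each phantom is an axial stack emulating the statistical structure the
pipeline assumes: a subcutaneous fat ring (SAT), a muscle wall (SM) with
intramuscular fat pixels, a visceral interior with organ tissue and fat blobs
(VAT), and a posterior vertebral column alternating bone vertebrae and soft
intervertebral disks. Exactly one disk is designated the "L3/L4" target; it is
made geometrically identifiable (full column width, at the body "waist") so
that a small network — and an extractor-free geometry oracle — can localize
it. Optional artifact modes mimic metallic implants (high-HU core plus radial
streaks), anasarca (thickened, fluid-infiltrated SAT) and ascites (free fluid
pockets in the visceral compartment).

Intramuscular fat pixels carry adipose HU but keep the SM label, matching the
annotation convention in which intermuscular fat belongs to the muscle class.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .imaging import (BACKGROUND, SAT, SM, VAT, CTVolume, CompartmentMask,
                      DiskAnnotation)

__all__ = [
    "TissueHU",
    "PhantomSpec",
    "PhantomCase",
    "generate_phantom",
    "generate_cohort",
    "oracle_target_z",
]

# internal material codes (not compartment labels)
_AIR, _SAT, _MUSCLE, _ORGAN, _VATM, _BONE, _DISK, _FLUID = range(8)


@dataclass(frozen=True)
class TissueHU:
    """Per-tissue HU mean/SD (Gaussian per-pixel draws)."""

    air: tuple[float, float] = (-1000.0, 5.0)
    fat: tuple[float, float] = (-95.0, 20.0)     # SAT, VAT and intramuscular fat
    muscle: tuple[float, float] = (45.0, 15.0)
    organ: tuple[float, float] = (30.0, 15.0)
    bone: tuple[float, float] = (700.0, 100.0)
    disk: tuple[float, float] = (100.0, 30.0)
    fluid: tuple[float, float] = (10.0, 8.0)
    metal: tuple[float, float] = (3200.0, 100.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one phantom (ranges are sampled per case)."""

    shape: tuple[int, int, int] = (64, 96, 96)          # (z, y, x) voxels
    spacing: tuple[float, float, float] = (3.0, 1.5, 1.5)  # mm
    body_rx_mm: tuple[float, float] = (52.0, 62.0)
    body_ry_mm: tuple[float, float] = (44.0, 52.0)
    slice_jitter_mm: float = 1.5
    sat_thickness_mm: tuple[float, float] = (6.0, 12.0)
    muscle_thickness_mm: tuple[float, float] = (5.0, 9.0)
    waist_depth: tuple[float, float] = (0.06, 0.12)
    waist_sigma_mm: float = 25.0
    vat_blob_count: tuple[int, int] = (4, 10)
    vat_blob_radius_mm: tuple[float, float] = (3.0, 12.0)
    vertebra_slices: int = 8
    disk_slices: int = 2
    column_radius_mm: float = 12.0
    hu: TissueHU = field(default_factory=TissueHU)
    p_imf: float = 0.10
    noise_sd: float = 0.0
    implant: bool = False
    anasarca: bool = False
    ascites: bool = False
    seed: int = 0


@dataclass
class PhantomCase:
    """A generated phantom with its full ground truth."""

    volume: CTVolume
    annotation: DiskAnnotation
    masks: np.ndarray          # (z, y, x) int labels {0..3}, per-slice truth
    metadata: dict

    @property
    def case_id(self) -> str:
        return self.volume.patient_id

    def mask_at(self, z_index: int) -> CompartmentMask:
        return CompartmentMask(
            labels=self.masks[z_index],
            spacing=(self.volume.spacing[1], self.volume.spacing[2]),
        )

    @property
    def target_z(self) -> int:
        return int(self.metadata["target_z_index"])


def _uniform(rng, lo_hi):
    return float(rng.uniform(lo_hi[0], lo_hi[1]))


def generate_phantom(spec: PhantomSpec, case_id: str = "phantom") -> PhantomCase:
    """Generate one phantom deterministically from ``spec.seed``."""
    nz, ny, nx = spec.shape
    dz, dy, dx = spec.spacing
    period = spec.vertebra_slices + spec.disk_slices
    if nz < 3 * period or ny < 32 or nx < 32:
        raise ValueError(f"grid {spec.shape} too small for the requested geometry")

    rng = np.random.default_rng(spec.seed)
    rx = _uniform(rng, spec.body_rx_mm)
    ry = _uniform(rng, spec.body_ry_mm)
    if rx > nx * dx / 2 - 2 or ry > ny * dy / 2 - 2:
        raise ValueError("body ellipse does not fit the in-plane grid")
    t_sat = _uniform(rng, spec.sat_thickness_mm)
    t_sm = _uniform(rng, spec.muscle_thickness_mm)
    if spec.anasarca:
        t_sat *= 1.6
    waist_depth = _uniform(rng, spec.waist_depth)
    jitter_phase = rng.uniform(0, 2 * np.pi)

    # vertebral column layout along z
    z0 = int(rng.integers(0, period))
    disk_starts = [z for z in range(z0 + spec.vertebra_slices, nz - spec.disk_slices, period)]
    if len(disk_starts) < 2:
        raise ValueError("grid too short for an alternating vertebra/disk column")
    target_pref = rng.uniform(nz * 0.40, nz * 0.60)
    centers = [s + (spec.disk_slices - 1) / 2.0 for s in disk_starts]
    target_idx = int(np.argmin([abs(c - target_pref) for c in centers]))
    target_center_z = centers[target_idx]

    yy = (np.arange(ny) - (ny - 1) / 2.0) * dy  # mm from center
    xx = (np.arange(nx) - (nx - 1) / 2.0) * dx
    Y, X = np.meshgrid(yy, xx, indexing="ij")

    inner_ry = ry - t_sat - t_sm
    col_cy = inner_ry * 0.4  # posterior (+y) offset of the column center, mm
    col_cx = 0.0
    col_r = spec.column_radius_mm
    col_region = (Y - col_cy) ** 2 + (X - col_cx) ** 2 <= col_r ** 2

    materials = np.zeros((nz, ny, nx), dtype=np.uint8)  # _AIR
    for z in range(nz):
        z_mm = z * dz
        target_mm = target_center_z * dz
        scale = 1.0 - waist_depth * np.exp(
            -((z_mm - target_mm) ** 2) / (2 * spec.waist_sigma_mm ** 2))
        jit = spec.slice_jitter_mm * np.sin(2 * np.pi * z / nz * 3 + jitter_phase)
        rxs = rx * scale + jit
        rys = ry * scale + jit

        def ellipse(shrink):
            a, b = max(rys - shrink, 1.0), max(rxs - shrink, 1.0)
            return (Y / a) ** 2 + (X / b) ** 2 <= 1.0

        body = ellipse(0.0)
        sat_inner = ellipse(t_sat)
        sm_inner = ellipse(t_sat + t_sm)
        m = materials[z]
        m[body] = _SAT
        m[sat_inner] = _MUSCLE
        m[sm_inner] = _ORGAN

        # column (overrides wall/interior where it overlaps the body)
        in_period = (z - z0) % period
        is_disk = z0 + spec.vertebra_slices <= z and in_period >= spec.vertebra_slices
        col_here = col_region & body
        if not is_disk:
            m[col_here] = _BONE
        else:
            start = z - (in_period - spec.vertebra_slices)
            if start == disk_starts[target_idx]:
                m[col_here] = _DISK  # target disk: full column width
            else:
                inner = (Y - col_cy) ** 2 + (X - col_cx) ** 2 <= (0.6 * col_r) ** 2
                m[col_here] = _BONE
                m[inner & body] = _DISK

    # VAT blobs in the visceral interior
    n_blobs = int(rng.integers(spec.vat_blob_count[0], spec.vat_blob_count[1] + 1))
    organ_zs = np.arange(nz)
    for _ in range(n_blobs):
        bz = int(rng.choice(organ_zs))
        extent_z = int(rng.integers(2, 6))
        by = rng.uniform(-0.6, 0.6) * inner_ry
        bx = rng.uniform(-0.7, 0.7) * (rx - t_sat - t_sm)
        a = _uniform(rng, spec.vat_blob_radius_mm)
        b = _uniform(rng, spec.vat_blob_radius_mm)
        blob = ((Y - by) / a) ** 2 + ((X - bx) / b) ** 2 <= 1.0
        for z in range(max(0, bz - extent_z), min(nz, bz + extent_z + 1)):
            sl = materials[z]
            sl[blob & (sl == _ORGAN)] = _VATM

    if spec.ascites:
        for _ in range(int(rng.integers(1, 4))):
            bz = int(rng.integers(0, nz))
            by = rng.uniform(-0.5, 0.5) * inner_ry
            bx = rng.uniform(-0.6, 0.6) * (rx - t_sat - t_sm)
            a, b = rng.uniform(8, 20), rng.uniform(8, 20)
            pocket = ((Y - by) / a) ** 2 + ((X - bx) / b) ** 2 <= 1.0
            for z in range(max(0, bz - 6), min(nz, bz + 7)):
                sl = materials[z]
                sl[pocket & np.isin(sl, (_ORGAN, _VATM))] = _FLUID

    # labels from materials (intramuscular fat keeps the SM label)
    labels = np.zeros_like(materials, dtype=np.int16)
    labels[materials == _SAT] = SAT
    labels[materials == _MUSCLE] = SM
    labels[materials == _VATM] = VAT

    # HU synthesis
    hu = spec.hu
    params = {
        _AIR: hu.air, _SAT: hu.fat, _MUSCLE: hu.muscle, _ORGAN: hu.organ,
        _VATM: hu.fat, _BONE: hu.bone, _DISK: hu.disk, _FLUID: hu.fluid,
    }
    voxels = np.empty((nz, ny, nx), dtype=np.float32)
    for code, (mu, sd) in params.items():
        sel = materials == code
        voxels[sel] = rng.normal(mu, sd, size=int(sel.sum()))

    # intramuscular fat: adipose HU inside the muscle compartment, label SM
    if spec.p_imf > 0:
        msel = materials == _MUSCLE
        imf = msel & (rng.random(materials.shape) < spec.p_imf)
        voxels[imf] = rng.normal(hu.fat[0], hu.fat[1], size=int(imf.sum()))

    # anasarca: fluid infiltration of the (already thickened) SAT ring
    if spec.anasarca:
        ssel = materials == _SAT
        wet = ssel & (rng.random(materials.shape) < 0.35)
        voxels[wet] = rng.normal(hu.fluid[0], hu.fluid[1], size=int(wet.sum()))

    # metallic implant: high-HU core + hardening streaks around the target
    # level; clinically, streaks at several hundred HU wipe out soft-tissue
    # contrast across much of the slice
    if spec.implant:
        from skimage.draw import line as _line

        my = int(round((col_cy + col_r + 5.0) / dy + (ny - 1) / 2.0))
        mx = nx // 2
        metal = (Y - (my - (ny - 1) / 2.0) * dy) ** 2 + (X - col_cx) ** 2 <= 7.0 ** 2
        zt = int(np.floor(target_center_z + 0.5))
        for z in range(max(0, zt - 2), min(nz, zt + 3)):
            voxels[z][metal] = rng.normal(hu.metal[0], hu.metal[1],
                                          size=int(metal.sum()))
            for k, ang in enumerate(np.linspace(0, 2 * np.pi, 24, endpoint=False)):
                ey = int(np.clip(my + (ny * 2) * np.sin(ang), 0, ny - 1))
                ex = int(np.clip(mx + (nx * 2) * np.cos(ang), 0, nx - 1))
                sign = 1.0 if k % 2 == 0 else -1.0
                for oy in (0, 1):
                    rr, cc = _line(min(my + oy, ny - 1), mx, ey, ex)
                    keep = (rr >= 0) & (rr < ny) & (cc >= 0) & (cc < nx)
                    voxels[z][rr[keep], cc[keep]] += sign * 350.0

    if spec.noise_sd > 0:
        voxels += rng.normal(0.0, spec.noise_sd, size=voxels.shape).astype(np.float32)

    volume = CTVolume(voxels=voxels, spacing=spec.spacing, origin=(0.0, 0.0, 0.0),
                      patient_id=case_id)
    ann_y = col_cy / dy + (ny - 1) / 2.0
    ann_x = col_cx / dx + (nx - 1) / 2.0
    annotation = DiskAnnotation(center=(target_center_z, ann_y, ann_x),
                                frame_shape=spec.shape)

    # ground-truth metrics at the target slice (counting pass on the
    # generated labels and HU, before any model is involved)
    zt = int(np.ceil(target_center_z - 0.5))  # ties toward the inferior slice
    px_area_cm2 = dy * dx / 100.0
    sl_labels = labels[zt]
    sl_hu = voxels[zt]
    areas = {c: float((sl_labels == c).sum() * px_area_cm2) for c in (SM, VAT, SAT)}
    sm_sel = sl_labels == SM
    if sm_sel.any():
        in_fat = (sl_hu >= -190.0) & (sl_hu <= -30.0) & sm_sel
        true_fmf = float(in_fat.sum() / sm_sel.sum())
    else:
        true_fmf = None

    metadata = {
        "seed": spec.seed,
        "implant": spec.implant,
        "anasarca": spec.anasarca,
        "ascites": spec.ascites,
        "target_z_index": zt,
        "target_center_z": float(target_center_z),
        "true_area_sm_cm2": areas[SM],
        "true_area_vat_cm2": areas[VAT],
        "true_area_sat_cm2": areas[SAT],
        "true_fmf": true_fmf,
        "column_center_yx_mm": (float(col_cy), float(col_cx)),
        "column_radius_mm": float(col_r),
        "disk_hu_range": (float(hu.disk[0] - 3 * hu.disk[1]),
                          float(hu.disk[1] * 3 + hu.disk[0])),
    }
    return PhantomCase(volume=volume, annotation=annotation, masks=labels,
                       metadata=metadata)


def oracle_target_z(case: PhantomCase) -> int:
    """Recover the target-disk slice from geometry alone.

    Counts disk-HU voxels inside the column region per slice; the target disk
    is full column width while other disks are narrower, so the count peaks at
    the target level. Independent of any trained model.
    """
    vol = case.volume
    nz, ny, nx = vol.shape
    dy, dx = vol.spacing[1], vol.spacing[2]
    cy_mm, cx_mm = case.metadata["column_center_yx_mm"]
    r = case.metadata["column_radius_mm"]
    lo, hi = case.metadata["disk_hu_range"]
    yy = (np.arange(ny) - (ny - 1) / 2.0) * dy
    xx = (np.arange(nx) - (nx - 1) / 2.0) * dx
    Y, X = np.meshgrid(yy, xx, indexing="ij")
    region = (Y - cy_mm) ** 2 + (X - cx_mm) ** 2 <= r ** 2
    counts = [
        int((((vol.voxels[z] >= lo) & (vol.voxels[z] <= hi)) & region).sum())
        for z in range(nz)
    ]
    return int(np.argmax(counts))


def generate_cohort(n: int, spec: PhantomSpec, seed: int,
                    implant_rate: float = 0.0, anasarca_rate: float = 0.0,
                    ascites_rate: float = 0.0, id_prefix: str = "case"):
    """Generate ``n`` phantoms with per-case seeds derived from ``seed``.

    Artifact flags are Bernoulli draws at the requested rates. Returns the
    cases and a manifest (one dict per case, sufficient to regenerate it).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n)
    flag_rng = np.random.default_rng(ss.spawn(1)[0])
    cases, manifest = [], []
    for i, child in enumerate(children):
        case_seed = int(child.generate_state(1)[0] % (2 ** 31))
        flags = {
            "implant": bool(flag_rng.random() < implant_rate),
            "anasarca": bool(flag_rng.random() < anasarca_rate),
            "ascites": bool(flag_rng.random() < ascites_rate),
        }
        cspec = dataclasses.replace(spec, seed=case_seed, **flags)
        cid = f"{id_prefix}{i:04d}"
        case = generate_phantom(cspec, case_id=cid)
        cases.append(case)
        manifest.append({
            "case_id": cid,
            "seed": case_seed,
            **flags,
            "target_z_index": case.metadata["target_z_index"],
            "true_area_sm_cm2": case.metadata["true_area_sm_cm2"],
            "true_area_vat_cm2": case.metadata["true_area_vat_cm2"],
            "true_area_sat_cm2": case.metadata["true_area_sat_cm2"],
            "true_fmf": case.metadata["true_fmf"],
        })
    return cases, manifest
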