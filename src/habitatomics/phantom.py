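"""Synthetic tumour phantoms with known habitat structure.

Phantoms are ellipsoidal "tumours" partitioned into spatially contiguous
sub-regions (habitats) with distinct intensity means and textures, plus a
binary label whose signal lives in one designated habitat, and a second
"reader" mask obtained by perturbing the tumour boundary. Everything is
seeded and reproducible, so downstream clustering, feature selection and
model evaluation can be scored against ground truth.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "PatientCase",
    "dice",
    "generate_phantom",
    "perturb_mask",
    "generate_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity model of a single phantom tumour.

    The tumour is an ellipsoid centred in the grid, partitioned into
    ``n_habitats`` contiguous compartments whose volume fractions follow
    ``habitat_fractions``. The default geometry stacks the compartments as
    axial slabs (split at z-quantiles of the mask volume), which keeps each
    slice-wise texture window inside a single habitat; concentric
    ellipsoidal shells and in-plane angular sectors are available as
    alternatives. Each habitat draws grayscale values from a Gaussian with
    its own mean and SD — the graded default SDs give the habitats distinct
    local-entropy levels — and the noise field can additionally be smoothed
    per habitat (``habitat_smoothness``, mm) and is then rescaled back to
    the requested SD, so smoothing lowers local entropy without changing
    the marginal SD.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 16)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    tumour_axes: tuple[float, float, float] = (15.0, 13.0, 16.0)
    n_habitats: int = 3
    habitat_fractions: tuple[float, ...] = (0.40, 0.33, 0.27)
    habitat_intensity_means: tuple[float, ...] = (30.0, 128.0, 228.0)
    habitat_intensity_sds: tuple[float, ...] = (8.0, 16.0, 32.0)
    habitat_smoothness: tuple[float, ...] = (0.0, 0.0, 0.0)
    geometry: Literal["slabs", "shells", "sectors"] = "slabs"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_habitats < 1:
            raise ValueError("n_habitats must be >= 1")
        for name in (
            "habitat_fractions",
            "habitat_intensity_means",
            "habitat_intensity_sds",
            "habitat_smoothness",
        ):
            if len(getattr(self, name)) != self.n_habitats:
                raise ValueError(f"{name} must have length n_habitats={self.n_habitats}")
        if abs(sum(self.habitat_fractions) - 1.0) > 1e-9:
            raise ValueError("habitat_fractions must sum to 1")
        if any(s < 0 for s in self.habitat_intensity_sds):
            raise ValueError("habitat_intensity_sds must be >= 0")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level design: sample sizes, label model, reader perturbation.

    ``effect_size`` is the standardised shift (in units of the signal
    habitat's ``between_patient_sd``, the patient-to-patient SD of habitat
    mean intensity) applied to the ``signal_habitat`` mean of
    label-positive patients. ``between_patient_sd`` may be per-habitat:
    the default keeps the extreme-intensity habitats tight, because they
    anchor the per-patient min-max grayscale normalisation — that is also
    why the default signal habitat is the middle-intensity one, whose
    shift survives normalisation intact. ``fraction_jitter`` varies the
    habitat volume proportions per patient; it is the main reason
    whole-tumour histogram features are noisier than within-habitat ones.
    """

    n_train: int = 20
    n_test: int = 10
    label_prevalence: float = 0.5
    signal_habitat: int = 2
    signal_type: Literal["texture", "mean", "both"] = "texture"
    effect_size: float = 2.0
    between_patient_sd: float | tuple[float, ...] = (4.0, 8.0, 4.0)
    size_jitter: float = 0.12
    fraction_jitter: float = 0.15
    texture_jitter: float = 0.15
    mask_jitter_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.label_prevalence < 1.0:
            raise ValueError("label_prevalence must be in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_train < 1 or self.n_test < 0:
            raise ValueError("cohort sizes must be positive")


@dataclass
class PatientCase:
    """One generated patient: image, reader masks, habitat ground truth."""

    patient_id: str
    cohort: str  # "train" | "test"
    label: int
    volume: np.ndarray
    mask: np.ndarray
    mask_r2: np.ndarray
    truth: np.ndarray
    spacing: tuple[float, float, float]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two binary masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        raise ValueError("both masks are empty")
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def _elliptical_radius(spec: PhantomSpec) -> np.ndarray:
    centre = (np.asarray(spec.grid_shape) - 1) / 2.0
    coords = np.meshgrid(*(np.arange(n) for n in spec.grid_shape), indexing="ij")
    r2 = np.zeros(spec.grid_shape, dtype=float)
    for c, ctr, sp, ax in zip(coords, centre, spec.voxel_spacing, spec.tumour_axes):
        r2 += ((c - ctr) * sp / ax) ** 2
    return np.sqrt(r2)


def _habitat_partition(spec: PhantomSpec, radius: np.ndarray, mask: np.ndarray) -> np.ndarray:
    truth = np.zeros(spec.grid_shape, dtype=np.int16)
    if spec.geometry == "slabs":
        # axial slabs: whole slices per habitat, split at the z-quantiles of
        # the mask volume. Matches the slice-wise entropy neighbourhood, so
        # a voxel's texture window never straddles two habitats.
        counts = np.bincount(np.nonzero(mask)[2], minlength=spec.grid_shape[2])
        occupied = np.nonzero(counts)[0]
        if len(occupied) < spec.n_habitats:
            raise ValueError(
                f"tumour spans {len(occupied)} slices < n_habitats={spec.n_habitats}"
            )
        targets = np.cumsum(spec.habitat_fractions) * counts.sum()
        # greedy slice assignment toward the cumulative volume targets,
        # always leaving one slice for each remaining habitat
        slab_of_slice = np.zeros(spec.grid_shape[2], dtype=np.int16)
        h, acc = 0, 0
        for idx, z in enumerate(occupied):
            slab_of_slice[z] = h + 1
            acc += counts[z]
            slices_left = len(occupied) - idx - 1
            habitats_left = spec.n_habitats - h - 1
            if h < spec.n_habitats - 1 and (
                acc >= targets[h] or slices_left <= habitats_left
            ):
                h += 1
        truth[mask] = np.broadcast_to(
            slab_of_slice[None, None, :], spec.grid_shape
        )[mask]
    elif spec.geometry == "shells":
        # concentric shells: cumulative volume fraction of an ellipsoid of
        # normalised radius r is r^3, so shell boundaries are cube roots
        bounds = np.cbrt(np.cumsum(spec.habitat_fractions))
        bounds[-1] = 1.0 + 1e-9
        inner = 0.0
        for h, outer in enumerate(bounds, start=1):
            sel = mask & (radius > inner if h > 1 else mask) & (radius <= outer)
            truth[sel] = h
            inner = outer
    elif spec.geometry == "sectors":
        centre = (np.asarray(spec.grid_shape) - 1) / 2.0
        ii, jj = np.meshgrid(
            np.arange(spec.grid_shape[0]), np.arange(spec.grid_shape[1]), indexing="ij"
        )
        theta = np.arctan2(jj - centre[1], ii - centre[0])  # (-pi, pi]
        frac = (theta + np.pi) / (2 * np.pi)
        bounds = np.cumsum(spec.habitat_fractions)
        labels2d = np.searchsorted(bounds, frac, side="left") + 1
        labels2d = np.clip(labels2d, 1, spec.n_habitats)
        truth[mask] = np.broadcast_to(labels2d[..., None], spec.grid_shape)[mask]
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown geometry {spec.geometry!r}")
    return truth


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate one phantom: (grayscale volume, binary mask, truth habitat map).

    Deterministic given the spec (including its seed). Raises if the
    ellipsoid does not fit inside the grid.
    """
    extent = np.asarray(spec.grid_shape) * np.asarray(spec.voxel_spacing)
    if np.any(2 * np.asarray(spec.tumour_axes) >= extent):
        raise ValueError(
            f"tumour axes {spec.tumour_axes} mm do not fit grid extent {tuple(extent)} mm"
        )
    rng = np.random.default_rng(spec.seed)
    radius = _elliptical_radius(spec)
    mask = radius <= 1.0
    if not mask.any():
        raise ValueError("mask is empty; tumour axes too small for the grid spacing")
    truth = _habitat_partition(spec, radius, mask)

    volume = np.zeros(spec.grid_shape, dtype=float)
    for h in range(1, spec.n_habitats + 1):
        sel = truth == h
        mean = spec.habitat_intensity_means[h - 1]
        sd = spec.habitat_intensity_sds[h - 1]
        if sd == 0:
            volume[sel] = mean
            continue
        noise = rng.normal(0.0, 1.0, size=spec.grid_shape)
        sigma_vox = [
            spec.habitat_smoothness[h - 1] / sp for sp in spec.voxel_spacing
        ]
        if any(s > 0 for s in sigma_vox):
            noise = ndimage.gaussian_filter(noise, sigma=sigma_vox)
            noise_sd = noise.std()
            if noise_sd > 0:
                noise /= noise_sd  # smoothing sets correlation, not marginal SD
        volume[sel] = mean + sd * noise[sel]
    return volume, mask.astype(np.uint8), truth


def perturb_mask(
    mask: np.ndarray,
    jitter_mm: float,
    seed: int,
    spacing: Sequence[float] = (1.0, 1.0, 3.0),
    patch_radius_vox: int = 3,
    n_patches_per_step: int = 6,
) -> np.ndarray:
    """Emulate a second reader by jittering the mask boundary.

    Applies ``round(jitter_mm / min(in-plane spacing))`` rounds of seeded
    one-voxel dilations/erosions restricted to random boundary patches.
    ``jitter_mm == 0`` returns the mask unchanged.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if jitter_mm < 0:
        raise ValueError("jitter_mm must be >= 0")
    n_steps = int(round(jitter_mm / min(spacing[:2])))
    if n_steps == 0:
        return mask.astype(np.uint8)

    rng = np.random.default_rng(seed)
    out = mask.copy()
    structure = ndimage.generate_binary_structure(3, 1)
    for _ in range(n_steps):
        boundary = out & ~ndimage.binary_erosion(out, structure)
        idx = np.argwhere(boundary)
        if len(idx) == 0:
            break
        picks = idx[rng.integers(0, len(idx), size=n_patches_per_step)]
        patch = np.zeros_like(out)
        r = patch_radius_vox
        for p in picks:
            sl = tuple(slice(max(0, c - r), c + r + 1) for c in p)
            patch[sl] = True
        if rng.random() < 0.5:
            grown = ndimage.binary_dilation(out, structure)
            out = np.where(patch, grown, out)
        else:
            shrunk = ndimage.binary_erosion(out, structure)
            out = np.where(patch, shrunk, out)
    if not out.any():
        raise ValueError("perturbation emptied the mask; reduce jitter_mm")
    return out.astype(np.uint8)


def _patient_spec(
    base: PhantomSpec, cohort_spec: CohortSpec, label: int, rng: np.random.Generator
) -> PhantomSpec:
    """Draw one patient's phantom spec: biological variability + label signal."""
    means = np.asarray(base.habitat_intensity_means, float).copy()
    bsd = np.asarray(cohort_spec.between_patient_sd, float)
    if bsd.ndim == 0:
        bsd = np.full(means.shape, float(bsd))
    elif bsd.shape != means.shape:
        raise ValueError(
            f"between_patient_sd has {bsd.size} entries for {base.n_habitats} habitats"
        )
    means += rng.normal(0.0, 1.0, size=means.shape) * bsd
    # per-patient texture variability: log-normal jitter of habitat noise SDs
    sds = np.asarray(base.habitat_intensity_sds, float)
    if cohort_spec.texture_jitter > 0:
        sds = sds * np.exp(rng.normal(0.0, cohort_spec.texture_jitter, size=sds.shape))
    if label == 1 and base.n_habitats >= cohort_spec.signal_habitat >= 1:
        sig = cohort_spec.signal_habitat - 1
        if cohort_spec.signal_type in ("mean", "both"):
            means[sig] += cohort_spec.effect_size * bsd[sig]
        if cohort_spec.signal_type in ("texture", "both"):
            # shift the habitat's noise SD by effect_size between-patient
            # log-SDs: the texture analogue of the standardised mean shift
            sds[sig] = sds[sig] * np.exp(
                cohort_spec.effect_size * max(cohort_spec.texture_jitter, 1e-12)
            )
    scale = 1.0 + rng.uniform(-cohort_spec.size_jitter, cohort_spec.size_jitter)
    axes = tuple(a * scale for a in base.tumour_axes)
    # habitat proportions vary from patient to patient: this is what keeps
    # whole-tumour histogram features noisier than within-habitat ones
    fracs = np.asarray(base.habitat_fractions, float)
    if cohort_spec.fraction_jitter > 0 and base.n_habitats > 1:
        fracs = np.clip(
            fracs + rng.normal(0.0, cohort_spec.fraction_jitter, size=fracs.shape),
            0.08,
            None,
        )
        fracs = fracs / fracs.sum()
    return replace(
        base,
        habitat_intensity_means=tuple(means),
        habitat_intensity_sds=tuple(sds),
        habitat_fractions=tuple(fracs),
        tumour_axes=axes,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_cohort(
    cohort_spec: CohortSpec,
    phantom_spec: PhantomSpec | None = None,
    out_dir: str | Path | None = None,
) -> list[PatientCase]:
    """Generate a two-cohort phantom population with labels and reader masks.

    Returns the cases in memory; if ``out_dir`` is given, additionally
    writes one directory per patient (``img.nii.gz``, ``mask_r1.nii.gz``,
    ``mask_r2.nii.gz``, ``truth.nii.gz``), a cohort ``clinical.csv`` with
    header ``patient_id,cohort,label`` and a JSON sidecar with both specs.
    """
    base = phantom_spec or PhantomSpec()
    rng = np.random.default_rng(cohort_spec.seed)
    cases: list[PatientCase] = []
    n_total = cohort_spec.n_train + cohort_spec.n_test
    labels = (rng.random(n_total) < cohort_spec.label_prevalence).astype(int)
    for i in range(n_total):
        cohort = "train" if i < cohort_spec.n_train else "test"
        spec_i = _patient_spec(base, cohort_spec, int(labels[i]), rng)
        volume, mask, truth = generate_phantom(spec_i)
        mask_r2 = perturb_mask(
            mask,
            cohort_spec.mask_jitter_mm,
            seed=int(rng.integers(0, 2**31 - 1)),
            spacing=base.voxel_spacing,
        )
        cases.append(
            PatientCase(
                patient_id=f"P{i:04d}",
                cohort=cohort,
                label=int(labels[i]),
                volume=volume,
                mask=mask,
                mask_r2=mask_r2,
                truth=truth,
                spacing=base.voxel_spacing,
            )
        )
    if out_dir is not None:
        _write_cohort(Path(out_dir), cases, cohort_spec, base)
    return cases


def _write_cohort(
    out_dir: Path,
    cases: list[PatientCase],
    cohort_spec: CohortSpec,
    phantom_spec: PhantomSpec,
) -> None:
    import nibabel as nib

    out_dir.mkdir(parents=True, exist_ok=True)
    for case in cases:
        pdir = out_dir / case.patient_id
        pdir.mkdir(exist_ok=True)
        affine = np.diag(list(case.spacing) + [1.0])
        try:
            nib.save(nib.Nifti1Image(case.volume.astype(np.float32), affine), pdir / "img.nii.gz")
            nib.save(nib.Nifti1Image(case.mask.astype(np.uint8), affine), pdir / "mask_r1.nii.gz")
            nib.save(nib.Nifti1Image(case.mask_r2.astype(np.uint8), affine), pdir / "mask_r2.nii.gz")
            nib.save(nib.Nifti1Image(case.truth.astype(np.int16), affine), pdir / "truth.nii.gz")
        except OSError as exc:  # re-raise with the offending path
            raise OSError(f"failed writing phantom files under {pdir}: {exc}") from exc
    with open(out_dir / "clinical.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "cohort", "label"])
        for case in cases:
            writer.writerow([case.patient_id, case.cohort, case.label])
    with open(out_dir / "spec.json", "w") as fh:
        json.dump(
            {"cohort_spec": asdict(cohort_spec), "phantom_spec": asdict(phantom_spec)},
            fh,
            indent=2,
        )
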