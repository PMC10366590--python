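"""Deterministic 3D phantom generator.

Stands in for access-gated clinical MRI so the whole pipeline runs with no
download.  Each phantom is an ellipsoidal "brain" of high intensity on a
dark background, containing a central low-intensity cavity whose radius
grows with diagnostic severity (NC < MCI < AD) scaled by ``effect_size`` --
a crude, directionally correct analogue of ventricular enlargement /
atrophy in Alzheimer's disease.  The cavity creates spatially structured
signal (not merely a global intensity shift) that a convolutional extractor
can exploit.  Per-subject anatomy is jittered (ellipsoid axes, cavity
centre and radius) so classes overlap realistically; additive Gaussian
noise is applied on top and intensities clipped to >= 0.

``effect_size = 0`` removes every class difference: AD and NC phantoms with
equal seeds are voxel-identical, which provides the pipeline's null test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import PhantomSpecError
from .preprocess import Volume, save_volume

log = logging.getLogger(__name__)

__all__ = ["PhantomSpec", "SEVERITY", "generate_phantom", "generate_dataset"]

#: Diagnostic class -> severity multiplier of the cavity enlargement.
SEVERITY = {"NC": 0.0, "MCI": 1.0, "AD": 2.0}

# Geometry constants (fractions of the grid / of the smallest semi-axis).
_BRAIN_FRAC = 0.42        # ellipsoid semi-axis as fraction of grid size
_CAVITY_BASE_FRAC = 0.15  # cavity radius at severity*effect = 0
_CAVITY_STEP_FRAC = 0.15  # radius increment per unit severity*effect
_AXIS_JITTER_SD = 0.005   # relative sd of per-subject semi-axis jitter
_RADIUS_JITTER_SD = 0.05  # relative sd of per-subject cavity-radius jitter
_CENTER_JITTER_VOX = 1.5  # half-range of cavity-centre offset (voxels)
_BRAIN_INTENSITY = 1.0
_CAVITY_INTENSITY = 0.0


@dataclass
class PhantomSpec:
    """Parameters of one phantom volume.

    ``seed`` drives the subject anatomy; ``noise_seed`` (default: ``seed``)
    drives the noise draw separately, so repeat "scans" of the same
    synthetic subject share anatomy but not noise.
    """

    shape: tuple = (32, 32, 32)
    spacing_mm: float = 2.0
    class_label: str = "NC"
    effect_size: float = 1.0
    noise_sd: float = 0.05
    seed: int = 0
    noise_seed: int | None = None

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"shape must be three positive integers, got {self.shape}")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be > 0")
        if self.class_label not in SEVERITY:
            raise ValueError(f"class_label must be one of {sorted(SEVERITY)}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_phantom(spec: PhantomSpec) -> Volume:
    """Render one phantom volume; deterministic in ``(seed, noise_seed)``."""
    rng = np.random.default_rng(spec.seed)
    shape = np.array(spec.shape, dtype=float)
    center = (shape - 1) / 2.0

    # Subject jitter is drawn in a fixed order, independent of the class
    # label, so effect_size = 0 makes classes literally identical per seed.
    axis_jitter = 1.0 + _AXIS_JITTER_SD * rng.standard_normal(3)
    cavity_offset = rng.uniform(-_CENTER_JITTER_VOX, _CENTER_JITTER_VOX, size=3)
    radius_jitter = 1.0 + _RADIUS_JITTER_SD * rng.standard_normal()

    semi = _BRAIN_FRAC * shape * axis_jitter
    severity = SEVERITY[spec.class_label]
    cavity_r = (
        (_CAVITY_BASE_FRAC + _CAVITY_STEP_FRAC * severity * spec.effect_size)
        * float(semi.min())
        * radius_jitter
    )
    if cavity_r >= semi.min():
        raise PhantomSpecError(
            f"cavity radius {cavity_r:.2f} vox >= smallest brain semi-axis "
            f"{semi.min():.2f} vox (label={spec.class_label}, "
            f"effect_size={spec.effect_size})"
        )

    ix, iy, iz = np.ogrid[: spec.shape[0], : spec.shape[1], : spec.shape[2]]
    brain = (
        ((ix - center[0]) / semi[0]) ** 2
        + ((iy - center[1]) / semi[1]) ** 2
        + ((iz - center[2]) / semi[2]) ** 2
    ) <= 1.0
    cc = center + cavity_offset
    cavity = (
        (ix - cc[0]) ** 2 + (iy - cc[1]) ** 2 + (iz - cc[2]) ** 2
    ) <= cavity_r**2

    data = np.zeros(spec.shape, dtype=float)
    data[brain] = _BRAIN_INTENSITY
    data[brain & cavity] = _CAVITY_INTENSITY

    if spec.noise_sd > 0:
        noise_rng = np.random.default_rng(
            spec.seed if spec.noise_seed is None else spec.noise_seed
        )
        data = data + noise_rng.normal(0.0, spec.noise_sd, size=spec.shape)
        data = np.clip(data, 0.0, None)

    affine = np.diag([spec.spacing_mm] * 3 + [1.0])
    vol_id = f"{spec.class_label}_s{spec.seed}"
    return Volume(data=data, spacing=(spec.spacing_mm,) * 3, affine=affine, id=vol_id)


def generate_dataset(
    n_per_class: int,
    spec_template: PhantomSpec | None = None,
    out_dir=None,
    classes: tuple = ("AD", "MCI", "NC"),
    scans_per_subject: int = 1,
) -> pd.DataFrame:
    """Write a labelled phantom dataset and its manifest.

    Produces ``len(classes) * n_per_class * scans_per_subject`` NIfTI files
    under ``out_dir`` plus ``manifest.csv`` with columns
    ``path,label,subject``.  Subject seeds are ``template.seed + index`` so
    regeneration is reproducible; repeat scans of a subject share anatomy
    but receive independent noise.  Returns the manifest as a DataFrame.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if scans_per_subject < 1:
        raise ValueError("scans_per_subject must be >= 1")
    template = spec_template or PhantomSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    subject_index = 0
    for label in classes:
        for i in range(n_per_class):
            subject_seed = int(template.seed) + subject_index
            subject = f"{label}_subj{subject_seed:05d}"
            for rep in range(scans_per_subject):
                spec = PhantomSpec(
                    shape=template.shape,
                    spacing_mm=template.spacing_mm,
                    class_label=label,
                    effect_size=template.effect_size,
                    noise_sd=template.noise_sd,
                    seed=subject_seed,
                    noise_seed=subject_seed * 131 + rep,
                )
                vol = generate_phantom(spec)
                fname = f"{subject}_scan{rep}.nii.gz"
                save_volume(vol, out_dir / fname)
                rows.append({"path": str(out_dir / fname), "label": label, "subject": subject})
            subject_index += 1
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    log.info("wrote %d phantoms (%d subjects) to %s", len(rows), subject_index, out_dir)
    return manifest
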