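"""BraTS-convention data handling and a synthetic multimodal phantom generator.

A *case* is four co-registered MRI modalities (T1, T1c, T2, FLAIR) plus an
optional integer label volume with labels drawn from the BraTS set
{0, 1, 2, 4}: 1 = necrotic/non-enhancing core, 2 = peritumoral edema,
4 = enhancing tumor.  The three nested evaluation regions are

    ET = {4},   TC = {1, 4},   WT = {1, 2, 4}     (ET ⊆ TC ⊆ WT).

The phantom generator renders BraTS-shaped volumes with nested ellipsoidal
lesions (necrotic interior, enhancing rim, edema halo), modality-dependent
tissue contrasts, a smooth multiplicative bias field and Gaussian noise —
enough structure for the modalities to be informative, fully reproducible
from a seed, and written in the standard case layout
(``<id>/<id>_t1.nii`` ... ``<id>_seg.nii``) so the whole pipeline can be
exercised without downloading a dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "MODALITIES",
    "LABEL_VALUES",
    "CaseRecord",
    "PhantomSpec",
    "read_case",
    "write_case",
    "find_cases",
    "derive_regions",
    "normalize_modality",
    "extract_slices",
    "labels_to_classes",
    "classes_to_labels",
    "generate_phantom",
]

MODALITIES = ("t1", "t1ce", "t2", "flair")
LABEL_VALUES = (0, 1, 2, 4)

# class-index mapping used by the network head (background, necrotic, edema,
# enhancing) <-> BraTS labels
_LABEL_TO_CLASS = {0: 0, 1: 1, 2: 2, 4: 3}
_CLASS_TO_LABEL = np.array([0, 1, 2, 4], dtype=np.int16)


@dataclass
class CaseRecord:
    """One case: modality volumes sharing a shape and affine, optional labels."""

    case_id: str
    modalities: dict[str, np.ndarray]
    affine: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        missing = [m for m in MODALITIES if m not in self.modalities]
        if missing:
            raise ValueError(f"missing modalities: {missing}")
        shapes = {m: v.shape for m, v in self.modalities.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"inconsistent modality shapes: {shapes}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != next(iter(shapes.values())):
                raise ValueError("label volume shape differs from modalities")
            _check_labels(self.labels)

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.modalities.values())).shape


def _check_labels(labels: np.ndarray) -> None:
    vals = np.unique(labels)
    bad = sorted(set(vals.tolist()) - set(LABEL_VALUES))
    if bad:
        raise ValueError(
            f"unexpected label values {bad}; expected subset of {LABEL_VALUES}"
        )


def labels_to_classes(labels: np.ndarray) -> np.ndarray:
    """Map BraTS labels {0,1,2,4} to contiguous class indices {0,1,2,3}."""
    _check_labels(labels)
    out = np.zeros(labels.shape, dtype=np.int64)
    for lab, cls in _LABEL_TO_CLASS.items():
        out[labels == lab] = cls
    return out


def classes_to_labels(classes: np.ndarray) -> np.ndarray:
    """Inverse of :func:`labels_to_classes`."""
    classes = np.asarray(classes)
    if classes.min() < 0 or classes.max() > 3:
        raise ValueError("class indices must lie in {0,1,2,3}")
    return _CLASS_TO_LABEL[classes]


# ---------------------------------------------------------------------------
# NIfTI case I/O
# ---------------------------------------------------------------------------


def _case_paths(case_dir: Path) -> dict[str, Path]:
    case_id = case_dir.name
    paths = {}
    for m in (*MODALITIES, "seg"):
        for ext in (".nii", ".nii.gz"):
            p = case_dir / f"{case_id}_{m}{ext}"
            if p.exists():
                paths[m] = p
                break
    return paths


def read_case(case_dir: str | Path) -> CaseRecord:
    """Load a BraTS-layout case directory (``<id>_<modality>.nii[.gz]``)."""
    case_dir = Path(case_dir)
    if not case_dir.is_dir():
        raise FileNotFoundError(f"case directory not found: {case_dir}")
    paths = _case_paths(case_dir)
    missing = [m.upper() for m in MODALITIES if m not in paths]
    if missing:
        raise ValueError(f"case {case_dir.name} is missing modalities: {missing}")
    volumes = {}
    affines = {}
    for m in MODALITIES:
        img = nib.load(str(paths[m]))
        volumes[m] = np.asarray(img.dataobj)
        affines[m] = img.affine
    ref = affines[MODALITIES[0]]
    for m, aff in affines.items():
        if not np.allclose(aff, ref, atol=1e-5):
            raise ValueError(f"modality {m.upper()} affine differs from T1 affine")
    shapes = {m: v.shape for m, v in volumes.items()}
    if len(set(shapes.values())) != 1:
        raise ValueError(f"inconsistent modality shapes: {shapes}")
    labels = None
    if "seg" in paths:
        seg_img = nib.load(str(paths["seg"]))
        labels = np.asarray(seg_img.dataobj).astype(np.int16)
        if not np.allclose(seg_img.affine, ref, atol=1e-5):
            raise ValueError("label affine differs from modality affine")
        _check_labels(labels)
    return CaseRecord(case_id=case_dir.name, modalities=volumes, affine=ref,
                      labels=labels)


def write_case(record: CaseRecord, root: str | Path) -> Path:
    """Write a case in the BraTS directory layout (uncompressed NIfTI-1).

    Uncompressed output plus a fixed header policy keeps regeneration
    byte-identical for identical inputs.
    """
    case_dir = Path(root) / record.case_id
    case_dir.mkdir(parents=True, exist_ok=True)
    for m in MODALITIES:
        img = nib.Nifti1Image(
            np.asarray(record.modalities[m], dtype=np.float32), record.affine
        )
        nib.save(img, str(case_dir / f"{record.case_id}_{m}.nii"))
    if record.labels is not None:
        seg = nib.Nifti1Image(record.labels.astype(np.int16), record.affine)
        nib.save(seg, str(case_dir / f"{record.case_id}_seg.nii"))
    return case_dir


def find_cases(root: str | Path) -> list[Path]:
    """Case directories under ``root`` (any directory containing a T1 file)."""
    root = Path(root)
    return sorted(
        d for d in root.iterdir()
        if d.is_dir() and "t1" in _case_paths(d)
    )


# ---------------------------------------------------------------------------
# Regions, normalization, slicing
# ---------------------------------------------------------------------------


def derive_regions(labels: np.ndarray) -> dict[str, np.ndarray]:
    """BraTS evaluation regions: ET = {4}, TC = {1,4}, WT = {1,2,4}."""
    labels = np.asarray(labels)
    _check_labels(labels)
    et = labels == 4
    tc = et | (labels == 1)
    wt = tc | (labels == 2)
    return {"ET": et, "TC": tc, "WT": wt}


def normalize_modality(volume: np.ndarray) -> np.ndarray:
    """Z-score over nonzero (brain) voxels; zero background stays zero."""
    volume = np.asarray(volume, dtype=np.float64)
    if not np.all(np.isfinite(volume)):
        raise ValueError("non-finite intensities")
    mask = volume != 0
    if not mask.any():
        return volume.copy()
    vals = volume[mask]
    std = vals.std()
    if std == 0:
        raise ValueError("constant nonzero region: zero variance, cannot z-score")
    out = np.zeros_like(volume)
    out[mask] = (vals - vals.mean()) / std
    return out


def extract_slices(
    case: CaseRecord,
    min_foreground: int = 0,
    normalize: bool = True,
) -> list[tuple[np.ndarray, np.ndarray | None]]:
    """Axial (last-axis) slices as (4, H, W) stacks plus label slices.

    ``min_foreground`` drops slices with fewer than that many nonzero label
    pixels (0 keeps everything).  Slice order follows the volume index.
    """
    volumes = [
        normalize_modality(case.modalities[m]) if normalize
        else np.asarray(case.modalities[m], dtype=np.float64)
        for m in MODALITIES
    ]
    n_slices = case.shape[-1]
    out = []
    for k in range(n_slices):
        label_slice = case.labels[..., k] if case.labels is not None else None
        if min_foreground > 0:
            if label_slice is None:
                raise ValueError("foreground filtering requires labels")
            if np.count_nonzero(label_slice) < min_foreground:
                continue
        img = np.stack([v[..., k] for v in volumes], axis=0)
        out.append((img, label_slice))
    return out


# ---------------------------------------------------------------------------
# Phantom generator
# ---------------------------------------------------------------------------

# modality intensity multipliers per tissue, relative to normal brain tissue
_TISSUE_CONTRAST = {
    #            t1    t1ce  t2    flair
    "brain":    (1.00, 1.00, 1.00, 1.00),
    "necrotic": (0.60, 0.55, 1.40, 1.10),
    "enhancing": (0.90, 1.80, 1.10, 1.15),
    "edema":    (0.85, 0.90, 1.60, 1.70),
}


@dataclass
class PhantomSpec:
    """Specification of a synthetic multimodal tumor phantom.

    Radii are in voxels; ``enhancing_radius`` is the inner boundary of the
    enhancing rim (i.e. the necrotic core radius), so per lesion the nested
    structure is  necrotic (label 1) for r <= r_enh,  enhancing rim (label 4)
    for r_enh < r <= r_core,  edema halo (label 2) for r_core < r <= r_edema,
    which guarantees ET ⊆ TC ⊆ WT by construction.
    """

    shape: tuple[int, int, int] = (240, 240, 155)
    num_lesions: int = 2
    enhancing_radius: tuple[float, float] = (5.0, 9.0)
    core_radius: tuple[float, float] = (9.0, 15.0)
    edema_radius: tuple[float, float] = (15.0, 24.0)
    base_intensity: float = 100.0
    noise_sigma: float = 5.0
    bias_amplitude: float = 0.2
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 4 for s in self.shape):
            raise ValueError("shape must be three dimensions of at least 4 voxels")
        if self.num_lesions < 0:
            raise ValueError("num_lesions must be >= 0")
        for name, rng_ in (("enhancing_radius", self.enhancing_radius),
                           ("core_radius", self.core_radius),
                           ("edema_radius", self.edema_radius)):
            if len(rng_) != 2 or rng_[0] <= 0 or rng_[1] < rng_[0]:
                raise ValueError(f"{name} must be a positive (lo, hi) range")
        if (self.enhancing_radius[0] > self.core_radius[0]
                or self.enhancing_radius[1] > self.core_radius[1]
                or self.core_radius[0] > self.edema_radius[0]
                or self.core_radius[1] > self.edema_radius[1]):
            raise ValueError(
                "radius ranges must nest: enhancing <= core <= edema"
            )
        if self.noise_sigma < 0 or self.bias_amplitude < 0:
            raise ValueError("noise_sigma and bias_amplitude must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def _brain_mask(shape: tuple[int, int, int]) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                        indexing="ij")
    r2 = sum(((g - (s - 1) / 2.0) / (0.45 * s)) ** 2
             for g, s in zip(grids, shape))
    return r2 <= 1.0


def _bias_field(shape, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * (low-order polynomial)."""
    coords = [np.linspace(-1.0, 1.0, s) for s in shape]
    gx, gy, gz = np.meshgrid(*coords, indexing="ij")
    basis = [np.ones(shape), gx, gy, gz, gx * gy, gx * gz, gy * gz,
             gx**2, gy**2, gz**2]
    coeffs = rng.normal(0.0, 1.0, size=len(basis))
    poly = sum(c * b for c, b in zip(coeffs, basis))
    peak = np.abs(poly).max()
    if peak > 0:
        poly = poly / peak
    return 1.0 + amplitude * poly


def generate_phantom(spec: PhantomSpec, case_id: str | None = None) -> CaseRecord:
    """Render one phantom case; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    brain = _brain_mask(shape)
    labels = np.zeros(shape, dtype=np.int16)
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                        indexing="ij")
    for _ in range(spec.num_lesions):
        center = np.array([
            rng.uniform(0.25 * s, 0.75 * s) for s in shape
        ])
        r_enh = rng.uniform(*spec.enhancing_radius)
        r_core = max(rng.uniform(*spec.core_radius), r_enh)
        r_edema = max(rng.uniform(*spec.edema_radius), r_core)
        # mild anisotropy so lesions are ellipsoidal rather than spherical
        axis_scale = rng.uniform(0.8, 1.25, size=3)
        r = np.sqrt(sum(((g - c) / a) ** 2
                        for g, c, a in zip(grids, center, axis_scale)))
        edema = (r <= r_edema) & brain
        core = (r <= r_core) & brain
        necro = (r <= r_enh) & brain
        labels[edema & (labels == 0)] = 2
        labels[core] = 4
        labels[necro] = 1
    modalities = {}
    tissue_masks = {
        "necrotic": labels == 1,
        "edema": labels == 2,
        "enhancing": labels == 4,
    }
    bias = _bias_field(shape, spec.bias_amplitude, rng)
    for mi, m in enumerate(MODALITIES):
        vol = np.zeros(shape, dtype=np.float64)
        vol[brain] = spec.base_intensity * _TISSUE_CONTRAST["brain"][mi]
        for tissue, mask in tissue_masks.items():
            vol[mask] = spec.base_intensity * _TISSUE_CONTRAST[tissue][mi]
        vol *= bias
        vol += rng.normal(0.0, spec.noise_sigma, size=shape)
        vol[~brain] = 0.0
        modalities[m] = vol.astype(np.float32)
    if case_id is None:
        case_id = f"phantom_{spec.seed:05d}"
    affine = np.eye(4)
    return CaseRecord(case_id=case_id, modalities=modalities, affine=affine,
                      labels=labels)
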