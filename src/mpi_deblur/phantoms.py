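"""Synthetic tumor phantom generation and paired dataset assembly.

Generates 50 x 50 binary phantoms with a configurable number of randomly
shaped lesion blobs, assigns distinct grayscale concentration levels, creates
within-lesion concentration gradients by Gaussian smoothing, expands each
phantom into its eight dihedral (flip/rotation) variants, and renders every
variant through the forward model (PSF blur + spatially varying noise at an
SNR drawn uniformly from the configured range) into phantom/native pairs.

Blob outlines are star-shaped polygons ``r(theta) = R (1 + sum a_k cos(k
theta + phi_k))`` with low-order harmonics, a programmatic stand-in for
hand-drawn lesions that reproduces their qualitative diversity in size, shape
and count.  Whole augmentation families are kept inside a single train/test
split so no phantom and its variants straddle the boundary.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import draw, measure

from .forward_model import (
    PhantomImage,
    PsfKernel,
    SimulationParams,
    add_noise,
    blur,
    build_psf,
    synth_noise_field,
)

__all__ = [
    "PhantomSpec",
    "DatasetManifest",
    "ManifestEntry",
    "GenerationError",
    "PairingError",
    "generate_binary_phantom",
    "assign_concentrations",
    "gradient_grayscale",
    "augment",
    "AUGMENT_TAGS",
    "render_native",
    "build_dataset_arrays",
    "build_dataset",
    "load_manifest",
    "import_image_pairs",
]

AUGMENT_TAGS = (
    "rot0", "rot90", "rot180", "rot270",
    "flip-rot0", "flip-rot90", "flip-rot180", "flip-rot270",
)


class GenerationError(RuntimeError):
    """Raised when the requested blobs cannot be packed into the image."""


class PairingError(RuntimeError):
    """Raised when an external dataset's phantom/native pairing is ambiguous."""


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic phantom.

    ``size_range`` bounds each blob's pixel area; ``concentration_levels`` are
    the grayscale values (in (0, 1]) assigned to the connected components;
    ``gradient_blur_sigma`` > 0 additionally smooths the map into a
    within-lesion concentration gradient.
    """

    n_features: int = 2
    size_range: tuple[int, int] = (30, 200)
    concentration_levels: tuple[float, ...] = (1.0,)
    gradient_blur_sigma: float = 0.0
    image_size: int = 50
    border_gap_px: int = 3
    separation_px: int = 2

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        lo, hi = self.size_range
        if not (0 < lo <= hi):
            raise ValueError("size_range must be ordered and positive")
        for lv in self.concentration_levels:
            if not (0.0 < lv <= 1.0):
                raise ValueError(f"concentration level {lv!r} outside (0, 1]")
        if self.gradient_blur_sigma < 0:
            raise ValueError("gradient_blur_sigma must be nonnegative")


def _random_blob_mask(rng: np.random.Generator, size: int, area_range, max_tries: int = 60):
    """One star-shaped blob mask with pixel area inside ``area_range``."""
    lo, hi = area_range
    for _ in range(max_tries):
        target_area = rng.uniform(lo, hi)
        radius = float(np.sqrt(target_area / np.pi))
        theta = np.linspace(0.0, 2.0 * np.pi, 48, endpoint=False)
        r = np.full_like(theta, radius)
        for k in (2, 3, 4):
            amp = rng.uniform(0.0, 0.30 / k) * radius
            r += amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
        r = np.clip(r, 1.2, None)
        cy = rng.uniform(0, size)
        cx = rng.uniform(0, size)
        rows = cy + r * np.sin(theta)
        cols = cx + r * np.cos(theta)
        rr, cc = draw.polygon(rows, cols, shape=(size, size))
        mask = np.zeros((size, size), dtype=bool)
        mask[rr, cc] = True
        if lo <= mask.sum() <= hi:
            return mask
    raise GenerationError("could not draw a blob within the requested area range")


def generate_binary_phantom(spec: PhantomSpec, rng_seed: int, max_attempts: int = 80) -> np.ndarray:
    """Binary {0,1} phantom with exactly ``spec.n_features`` separated blobs.

    Blobs keep ``spec.border_gap_px`` clearance from the image border and
    ``spec.separation_px`` from each other so connected-component labeling
    (8-connectivity) recovers the requested count.  Reproducible per seed;
    raises :class:`GenerationError` if packing fails after bounded retries.
    """
    rng = np.random.default_rng(rng_seed)
    n = spec.image_size
    for _ in range(max_attempts):
        occupied = np.zeros((n, n), dtype=bool)
        forbidden = np.zeros((n, n), dtype=bool)
        forbidden[: spec.border_gap_px, :] = True
        forbidden[-spec.border_gap_px :, :] = True
        forbidden[:, : spec.border_gap_px] = True
        forbidden[:, -spec.border_gap_px :] = True
        ok = True
        for _feat in range(spec.n_features):
            placed = False
            for _try in range(40):
                try:
                    mask = _random_blob_mask(rng, n, spec.size_range)
                except GenerationError:
                    continue
                if (mask & forbidden).any():
                    continue
                placed = True
                occupied |= mask
                # keep the next blob separated so components never merge
                forbidden |= ndimage.binary_dilation(mask, iterations=spec.separation_px)
                break
            if not placed:
                ok = False
                break
        if not ok:
            continue
        labels = measure.label(occupied, connectivity=2)
        if labels.max() == spec.n_features:
            return occupied.astype(float)
    raise GenerationError(
        f"could not pack {spec.n_features} blobs of area {spec.size_range} "
        f"into a {n}x{n} image"
    )


def assign_concentrations(binary, levels) -> np.ndarray:
    """Assign grayscale concentration levels to the phantom's components.

    Components are ordered deterministically (raster order of first pixel,
    i.e. ``skimage.measure.label`` order) and component ``i`` receives
    ``levels[i % len(levels)]``.  Requires at least as many components as
    levels; every level must lie in (0, 1].
    """
    img = binary.values if isinstance(binary, PhantomImage) else np.asarray(binary, dtype=float)
    levels = list(levels)
    for lv in levels:
        if not (0.0 < lv <= 1.0):
            raise ValueError(f"concentration level {lv!r} outside (0, 1]")
    labels = measure.label(img > 0, connectivity=2)
    n_comp = int(labels.max())
    if n_comp < len(levels):
        raise ValueError(f"{len(levels)} levels requested but only {n_comp} components present")
    out = np.zeros_like(img, dtype=float)
    for i in range(1, n_comp + 1):
        out[labels == i] = levels[(i - 1) % len(levels)]
    return out


def gradient_grayscale(phantom, blur_sigma: float) -> np.ndarray:
    """Gaussian-smooth the concentration map into within-lesion gradients.

    ``blur_sigma = 0`` is the identity.  Smoothing assumes zero concentration
    outside the image (constant padding), so total intensity of interior
    lesions is conserved; output is clipped to [0, 1].
    """
    img = phantom.values if isinstance(phantom, PhantomImage) else np.asarray(phantom, dtype=float)
    if blur_sigma < 0:
        raise ValueError("blur_sigma must be nonnegative")
    if blur_sigma == 0:
        return img.copy()
    out = ndimage.gaussian_filter(img, sigma=blur_sigma, mode="constant", cval=0.0)
    return np.clip(out, 0.0, 1.0)


def augment(image) -> list[np.ndarray]:
    """The 8 dihedral-group variants: 4 rotations x optional horizontal flip.

    Returned in the order of :data:`AUGMENT_TAGS`.  Requires a square image.
    """
    img = image.values if isinstance(image, PhantomImage) else np.asarray(image, dtype=float)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("augmentation requires a square 2-D image")
    variants = [np.rot90(img, k).copy() for k in range(4)]
    flipped = np.fliplr(img)
    variants += [np.rot90(flipped, k).copy() for k in range(4)]
    return variants


def render_native(
    phantom,
    psf: PsfKernel,
    snr_db: float,
    noise_seed: int,
    noise_correlation_px: float = 2.0,
    source_id: str = "",
):
    """Blur a phantom with the PSF and inject noise at the requested SNR."""
    img = phantom.values if isinstance(phantom, PhantomImage) else np.asarray(phantom, dtype=float)
    blurred = blur(img, psf)
    field = synth_noise_field(img.shape, noise_correlation_px, noise_seed)
    return add_noise(blurred, snr_db, field, rng_seed=noise_seed, source_phantom_id=source_id)


@dataclass(frozen=True)
class ManifestEntry:
    phantom_path: str
    native_path: str
    snr_db: float
    augmentation: str
    split: str
    family: int
    variant: str


@dataclass
class DatasetManifest:
    entries: list[ManifestEntry]
    n_train: int
    n_test: int
    seed: int

    def paths(self, split: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.split == split]


_VARIANT_NAMES = ("binary", "graylevel", "gradient")


def _family_images(rng: np.random.Generator, spec: PhantomSpec):
    """All (variant, tag, image) members of one base phantom's family.

    A family is one base phantom expanded into three style variants (binary,
    multi-level grayscale, gradient grayscale) times the eight dihedral
    augmentations: up to 24 images that must share a split.
    """
    base_seed = int(rng.integers(0, 2**31 - 1))
    n_feat = int(rng.integers(1, 4))
    base_spec = PhantomSpec(
        n_features=n_feat,
        size_range=spec.size_range,
        image_size=spec.image_size,
        border_gap_px=spec.border_gap_px,
        separation_px=spec.separation_px,
    )
    binary = generate_binary_phantom(base_spec, base_seed)
    levels = [1.0] + [float(rng.uniform(0.2, 1.0)) for _ in range(n_feat - 1)]
    gray = assign_concentrations(binary, levels)
    sigma = float(rng.uniform(0.8, 1.8))
    gradient = gradient_grayscale(gray, sigma)
    images = []
    for variant, img in zip(_VARIANT_NAMES, (binary, gray, gradient)):
        for tag, aug in zip(AUGMENT_TAGS, augment(img)):
            images.append((variant, tag, aug))
    return images


def build_dataset_arrays(
    n_total: int,
    split: tuple[int, int],
    sim: SimulationParams | None = None,
    rng_seed: int = 0,
    spec: PhantomSpec | None = None,
    fov_mm: float = 40.0,
    psf_kernel_px: int = 25,
    noise_correlation_px: float = 2.0,
):
    """Build the paired dataset in memory.

    Returns ``(phantoms, natives, snrs, families, splits)`` where the image
    arrays are stacked ``(n_total, H, W)`` float64, ``families`` identifies the
    base phantom of each entry (augmentation families never straddle the
    split) and ``splits`` is an array of ``"train"`` / ``"test"`` labels.  The
    test portion is filled first from whole families, then the train portion.
    """
    n_train, n_test = split
    if n_train + n_test != n_total:
        raise ValueError("split must sum to n_total")
    sim = sim or SimulationParams()
    spec = spec or PhantomSpec()
    pixel_mm = fov_mm / spec.image_size
    psf = build_psf(sim, fov_mm=psf_kernel_px * pixel_mm, grid_px=psf_kernel_px)
    rng = np.random.default_rng(rng_seed)

    phantoms, natives, snrs, families, splits, tags, variants = [], [], [], [], [], [], []
    family_id = 0
    lo, hi = sim.snr_db_range
    for split_name, n_needed in (("test", n_test), ("train", n_train)):
        count = 0
        while count < n_needed:
            members = _family_images(rng, spec)
            for variant, tag, img in members:
                if count >= n_needed:
                    break  # truncate the last family; never move it across splits
                snr = float(rng.uniform(lo, hi))
                noise_seed = int(rng.integers(0, 2**31 - 1))
                native = render_native(
                    img, psf, snr, noise_seed,
                    noise_correlation_px=noise_correlation_px,
                    source_id=f"fam{family_id}-{variant}-{tag}",
                )
                phantoms.append(img)
                natives.append(native.values)
                snrs.append(native.realized_snr_db)
                families.append(family_id)
                splits.append(split_name)
                tags.append(tag)
                variants.append(variant)
                count += 1
            family_id += 1

    order = np.arange(n_total)
    return {
        "phantoms": np.stack(phantoms)[order],
        "natives": np.stack(natives)[order],
        "snr_db": np.asarray(snrs),
        "family": np.asarray(families),
        "split": np.asarray(splits),
        "augmentation": np.asarray(tags),
        "variant": np.asarray(variants),
        "psf": psf,
    }


def build_dataset(
    n_total: int,
    split: tuple[int, int],
    sim: SimulationParams | None = None,
    out_dir: str | Path = "dataset",
    rng_seed: int = 0,
    spec: PhantomSpec | None = None,
    fov_mm: float = 40.0,
    write_png: bool = False,
) -> DatasetManifest:
    """Render the dataset to disk as float32 TIFF pairs plus a manifest.

    Fully reproducible: the same seed yields byte-identical images and
    manifests.  Writes ``phantom_NNNNN.tif`` / ``native_NNNNN.tif`` pairs,
    ``manifest.json`` and ``manifest.csv`` under ``out_dir``.
    """
    import tifffile

    data = build_dataset_arrays(n_total, split, sim=sim, rng_seed=rng_seed, spec=spec, fov_mm=fov_mm)
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc

    entries = []
    for i in range(n_total):
        ph_path = out / f"phantom_{i:05d}.tif"
        na_path = out / f"native_{i:05d}.tif"
        tifffile.imwrite(ph_path, data["phantoms"][i].astype(np.float32))
        tifffile.imwrite(na_path, data["natives"][i].astype(np.float32))
        if write_png:
            import imageio.v3 as iio

            iio.imwrite(ph_path.with_suffix(".png"), (np.clip(data["phantoms"][i], 0, 1) * 255).astype(np.uint8))
        entries.append(
            ManifestEntry(
                phantom_path=ph_path.name,
                native_path=na_path.name,
                snr_db=float(data["snr_db"][i]),
                augmentation=str(data["augmentation"][i]),
                split=str(data["split"][i]),
                family=int(data["family"][i]),
                variant=str(data["variant"][i]),
            )
        )
    manifest = DatasetManifest(entries=entries, n_train=split[0], n_test=split[1], seed=rng_seed)
    with open(out / "manifest.json", "w") as fh:
        json.dump(
            {
                "n_train": manifest.n_train,
                "n_test": manifest.n_test,
                "seed": manifest.seed,
                "entries": [e.__dict__ for e in entries],
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(entries[0].__dict__))
        writer.writeheader()
        for e in entries:
            writer.writerow(e.__dict__)
    return manifest


def load_manifest(directory: str | Path) -> tuple[DatasetManifest, np.ndarray, np.ndarray]:
    """Load a dataset written by :func:`build_dataset`.

    Returns ``(manifest, phantoms, natives)`` with images stacked in manifest
    order.  Every referenced file must exist and be shape-consistent.
    """
    import tifffile

    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        payload = json.load(fh)
    entries = [ManifestEntry(**e) for e in payload["entries"]]
    manifest = DatasetManifest(
        entries=entries, n_train=payload["n_train"], n_test=payload["n_test"], seed=payload["seed"]
    )
    phantoms, natives = [], []
    shape = None
    for e in entries:
        ph = tifffile.imread(directory / e.phantom_path)
        na = tifffile.imread(directory / e.native_path)
        if shape is None:
            shape = ph.shape
        if ph.shape != shape or na.shape != shape:
            raise ValueError(f"inconsistent image shapes in manifest near {e.phantom_path}")
        phantoms.append(ph)
        natives.append(na)
    return manifest, np.stack(phantoms).astype(float), np.stack(natives).astype(float)


def import_image_pairs(directory: str | Path):
    """Import an external paired-image dataset into phantom/native arrays.

    Auto-detects one of two layouts and fails loudly otherwise:

    1. Two subdirectories whose names contain ``native`` and one of
       ``phantom``/``gt``/``ground``/``label``, with files matched by stem.
    2. A flat directory of files whose names contain ``native`` paired with
       files whose names contain ``phantom``/``gt``, matched by the remaining
       characters of the stem.
    """
    import imageio.v3 as iio
    import tifffile

    directory = Path(directory)
    if not directory.is_dir():
        raise PairingError(f"{directory} is not a directory")

    def read_any(path: Path) -> np.ndarray:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 3:
            arr = arr.mean(axis=-1)
        if arr.max() > 1.0:
            arr = arr / 255.0
        return arr

    gt_words = ("phantom", "gt", "ground", "label", "clean")
    subdirs = [d for d in sorted(directory.iterdir()) if d.is_dir()]
    native_dir = next((d for d in subdirs if "native" in d.name.lower() or "blur" in d.name.lower()), None)
    gt_dir = next((d for d in subdirs if any(w in d.name.lower() for w in gt_words)), None)
    pairs: list[tuple[Path, Path]] = []
    if native_dir is not None and gt_dir is not None:
        gt_by_stem = {p.stem: p for p in sorted(gt_dir.iterdir()) if p.is_file()}
        for p in sorted(native_dir.iterdir()):
            if not p.is_file():
                continue
            if p.stem not in gt_by_stem:
                raise PairingError(f"no ground-truth file pairs with {p.name}")
            pairs.append((gt_by_stem[p.stem], p))
    else:
        files = [p for p in sorted(directory.iterdir()) if p.is_file()]
        natives = [p for p in files if "native" in p.stem.lower() or "blur" in p.stem.lower()]
        gts = [p for p in files if any(w in p.stem.lower() for w in gt_words)]

        def key(p: Path, words) -> str:
            s = p.stem.lower()
            for w in words:
                s = s.replace(w, "")
            return s.strip("_-")

        gt_by_key = {key(p, gt_words): p for p in gts}
        for p in natives:
            k = key(p, ("native", "blur"))
            if k not in gt_by_key:
                raise PairingError(f"cannot pair {p.name}: no matching ground-truth file")
            pairs.append((gt_by_key[k], p))
    if not pairs:
        raise PairingError(
            f"no phantom/native pairs detected in {directory}; expected 'native'/'phantom' "
            "subdirectories or filename markers"
        )
    phantoms = np.stack([read_any(a) for a, _ in pairs])
    natives = np.stack([read_any(b) for _, b in pairs])
    if phantoms.shape != natives.shape:
        raise PairingError("paired images have inconsistent shapes")
    return phantoms, natives
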