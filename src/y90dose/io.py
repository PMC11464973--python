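"""File I/O and synthetic fixture generation.

Volumes are exchanged as NIfTI (via nibabel) or MetaImage (via SimpleITK);
kernels and cohorts as plain CSV. ``generate_fixtures`` writes everything the
examples and tests need — sphere phantoms, a synthetic two-lesion liver
activity volume with masks, a seed-stamped cohort and the default kernel —
so no external data is ever required.
"""

from __future__ import annotations


import logging
from pathlib import Path

import numpy as np

from .dose_response import simulate_cohort
from .kernels import RadialKernel, load_default_kernel, read_kernel_csv, write_kernel_csv
from .voxel import VoxelGrid, make_sphere_phantom

__all__ = [
    "read_volume", "write_volume", "read_kernel_csv", "write_kernel_csv",
    "read_config", "generate_fixtures",
]

logger = logging.getLogger("y90dose")

_NIFTI_EXT = (".nii", ".nii.gz")
_META_EXT = (".mha", ".mhd")


def _extension(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def read_volume(path: str | Path, semantics: str = "activity_bq") -> VoxelGrid:
    """Read a NIfTI or MetaImage volume into a :class:`VoxelGrid`."""
    path = Path(path)
    ext = _extension(path)
    if ext in _NIFTI_EXT:
        import nibabel as nib

        img = nib.load(str(path))
        values = np.asarray(img.dataobj, dtype=float)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
    elif ext in _META_EXT:
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        # SimpleITK arrays are (z, y, x); transpose to (x, y, z)
        values = sitk.GetArrayFromImage(img).astype(float).transpose(2, 1, 0)
        spacing = tuple(float(s) for s in img.GetSpacing())
        origin = tuple(float(o) for o in img.GetOrigin())
    else:
        raise ValueError(
            f"unsupported volume format {ext!r}; supported: "
            f"{', '.join(_NIFTI_EXT + _META_EXT)}"
        )
    return VoxelGrid(values=values, spacing_mm=spacing, origin_mm=origin,
                     semantics=semantics)


def write_volume(grid: VoxelGrid, path: str | Path) -> None:
    """Write a :class:`VoxelGrid` as NIfTI or MetaImage."""
    path = Path(path)
    ext = _extension(path)
    if ext in _NIFTI_EXT:
        import nibabel as nib

        affine = np.diag(list(grid.spacing_mm) + [1.0])
        affine[:3, 3] = grid.origin_mm
        nib.save(nib.Nifti1Image(grid.values.astype(np.float64), affine), str(path))
    elif ext in _META_EXT:
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(grid.values.transpose(2, 1, 0))
        img.SetSpacing(grid.spacing_mm)
        img.SetOrigin(grid.origin_mm)
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(
            f"unsupported volume format {ext!r}; supported: "
            f"{', '.join(_NIFTI_EXT + _META_EXT)}"
        )


def read_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` text configuration file."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line: {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def synthetic_liver_volume(
    seed: int = 0,
    shape: tuple[int, int, int] = (48, 48, 32),
    voxel_mm: float = 2.0,
    total_activity_gbq: float = 1.5,
) -> tuple[VoxelGrid, VoxelGrid]:
    """Synthetic liver activity volume with two hot lesions, plus label mask.

    An ellipsoidal liver with mildly noisy background uptake and two
    spherical lesions at 5x the background concentration emulates a
    post-therapy activity map. Labels: 1 = normal liver, 2 = lesions.
    """
    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    x, y, z = np.meshgrid(
        np.arange(nx) - nx / 2, np.arange(ny) - ny / 2, np.arange(nz) - nz / 2,
        indexing="ij",
    )
    liver = (x / (nx * 0.42)) ** 2 + (y / (ny * 0.38)) ** 2 + (z / (nz * 0.40)) ** 2 <= 1

    def ball(cx, cy, cz, r_vox):
        return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r_vox**2

    lesions = ball(-6, 4, 2, 4.5) | ball(7, -5, -3, 3.0)
    lesions &= liver
    conc = np.zeros(shape)
    conc[liver] = 1.0 + 0.1 * rng.standard_normal(int(liver.sum()))
    conc[lesions] *= 5.0
    conc = np.clip(conc, 0.0, None)
    conc *= total_activity_gbq * 1e9 / conc.sum()  # Bq per voxel
    labels = np.zeros(shape)
    labels[liver] = 1
    labels[lesions] = 2
    spacing = (voxel_mm,) * 3
    return (
        VoxelGrid(values=conc, spacing_mm=spacing, semantics="activity_bq"),
        VoxelGrid(values=labels, spacing_mm=spacing, semantics="indicator"),
    )


def generate_fixtures(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the standard synthetic fixture set into ``out_dir``.

    Produces sphere phantoms (10 and 30 mm), the synthetic liver activity
    volume and its label mask, a seed-stamped lesion cohort CSV and the
    packaged default kernel CSV. Returns a name -> path mapping.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for d in (10.0, 30.0):
        ph = make_sphere_phantom(d, voxel_size_mm=1.0, padding_mm=6.0)
        p = out / f"sphere_d{int(d)}mm.nii.gz"
        write_volume(ph.grid, p)
        paths[f"sphere_{int(d)}mm"] = p
    activity, labels = synthetic_liver_volume(seed=seed)
    paths["liver_activity"] = out / "liver_activity.nii.gz"
    paths["liver_labels"] = out / "liver_labels.nii.gz"
    write_volume(activity, paths["liver_activity"])
    write_volume(labels, paths["liver_labels"])
    cohort = simulate_cohort(seed=seed)
    paths["cohort"] = out / f"cohort_seed{seed}.csv"
    cohort.to_csv(paths["cohort"])
    paths["kernel"] = out / "y90_dpk_water.csv"
    write_kernel_csv(load_default_kernel(), paths["kernel"])
    logger.info("fixtures written to %s (seed %d)", out, seed)
    return paths
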