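"""Persistence: volumes/stacks as multi-page TIFF, PSFs as HDF5, configs as
YAML, sample directories with a metadata sidecar."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .forward import FLFMViewStack, LightField4D, Volume3D
from .optics import FLFMPSF, LFMPSF, MLAConfig, OpticalConfig
from .phantom import SamplePair

__all__ = [
    "save_volume",
    "load_volume",
    "save_lfm_psf",
    "load_lfm_psf",
    "save_flfm_psf",
    "load_flfm_psf",
    "save_optics_config",
    "load_optics_config",
    "save_yaml",
    "load_yaml",
    "save_sample",
]


def save_volume(path: str | Path, vol: Volume3D | np.ndarray, description: str = ""):
    data = vol.data if isinstance(vol, Volume3D) else np.asarray(vol)
    tifffile.imwrite(str(path), data.astype(np.float32), description=description)


def load_volume(path: str | Path, voxel_size_um=(1.0, 1.0, 1.0)) -> Volume3D:
    data = np.asarray(tifffile.imread(str(path)), dtype=float)
    if data.ndim == 2:
        data = data[None]
    return Volume3D(data, tuple(voxel_size_um))


def save_lfm_psf(path: str | Path, psf: LFMPSF):
    with h5py.File(str(path), "w") as fh:
        fh.create_dataset("data", data=psf.data, compression="gzip")
        fh.create_dataset("depth_grid_um", data=psf.depth_grid_um)
        fh.attrs["offset_spacing_um"] = psf.offset_spacing_um
        fh.attrs["sensor_pixel_pitch_um"] = psf.sensor_pixel_pitch_um
        fh.attrs["kind"] = "lfm"


def load_lfm_psf(path: str | Path) -> LFMPSF:
    with h5py.File(str(path), "r") as fh:
        return LFMPSF(
            data=fh["data"][()],
            depth_grid_um=fh["depth_grid_um"][()],
            offset_spacing_um=float(fh.attrs["offset_spacing_um"]),
            sensor_pixel_pitch_um=float(fh.attrs["sensor_pixel_pitch_um"]),
        )


def save_flfm_psf(path: str | Path, psf: FLFMPSF):
    with h5py.File(str(path), "w") as fh:
        fh.create_dataset("response", data=psf.response, compression="gzip")
        fh.create_dataset("weights", data=psf.weights)
        fh.create_dataset("depth_grid_um", data=psf.depth_grid_um)
        fh.create_dataset("view_offsets", data=psf.view_offsets)
        fh.create_dataset("view_centers_px", data=psf.view_centers_px)
        fh.attrs["disparity_px_per_um"] = psf.disparity_px_per_um
        fh.attrs["spacing_um"] = psf.spacing_um
        fh.attrs["kind"] = "flfm"


def load_flfm_psf(path: str | Path) -> FLFMPSF:
    with h5py.File(str(path), "r") as fh:
        return FLFMPSF(
            response=fh["response"][()],
            weights=fh["weights"][()],
            depth_grid_um=fh["depth_grid_um"][()],
            view_offsets=fh["view_offsets"][()],
            view_centers_px=fh["view_centers_px"][()],
            disparity_px_per_um=float(fh.attrs["disparity_px_per_um"]),
            spacing_um=float(fh.attrs["spacing_um"]),
        )


def save_optics_config(path: str | Path, config: OpticalConfig, mla: MLAConfig):
    """Persist an optical/MLA configuration pair as YAML."""
    save_yaml(
        path,
        {
            "optical": {
                "numerical_aperture": config.numerical_aperture,
                "magnification": config.magnification,
                "wavelength_nm": config.wavelength_nm,
                "refractive_index": config.refractive_index,
                "sensor_pixel_pitch_um": config.sensor_pixel_pitch_um,
                "depth_grid_um": np.asarray(config.depth_grid_um).tolist(),
                "lateral_spacing_um": config.lateral_spacing_um,
                "lateral_extent_px": config.lateral_extent_px,
            },
            "mla": {
                "pitch_um": mla.pitch_um,
                "focal_length_um": mla.focal_length_um,
                "pixels_per_lenslet": mla.pixels_per_lenslet,
                "f_number": mla.f_number,
                "relay_f1_mm": mla.relay_f1_mm,
                "relay_f2_mm": mla.relay_f2_mm,
            },
        },
    )


def load_optics_config(path: str | Path) -> tuple[OpticalConfig, MLAConfig]:
    payload = load_yaml(path)
    opt = dict(payload["optical"])
    opt["depth_grid_um"] = np.asarray(opt["depth_grid_um"], dtype=float)
    return OpticalConfig(**opt), MLAConfig(**payload["mla"])


def save_yaml(path: str | Path, obj: dict):
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_sample(directory: str | Path, sample: SamplePair):
    """Write one sample as a directory: gt/lfm/flfm/epi TIFFs + meta.yaml."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    save_volume(d / "gt.tif", sample.ground_truth)
    tifffile.imwrite(str(d / "lfm.tif"), sample.lfm.data.astype(np.float32))
    tifffile.imwrite(str(d / "flfm.tif"), sample.flfm.data.astype(np.float32))
    for name, stack in (
        ("epi_lfm_uh", sample.epi_lfm_uh),
        ("epi_lfm_vw", sample.epi_lfm_vw),
        ("epi_flfm_cw", sample.epi_flfm_cw),
        ("epi_flfm_ch", sample.epi_flfm_ch),
    ):
        tifffile.imwrite(
            str(d / f"{name}.tif"),
            stack.data.astype(np.float32),
            description=stack.layout,
        )
    save_yaml(
        d / "meta.yaml",
        {
            "sample_id": sample.sample_id,
            "seed": int(sample.seed),
            "lfm_shape": [int(s) for s in sample.lfm.data.shape],
            "flfm_view_offsets": np.asarray(sample.flfm.view_offsets).tolist(),
            "flfm_view_centers_px": np.asarray(sample.flfm.view_centers_px).tolist(),
        },
    )
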