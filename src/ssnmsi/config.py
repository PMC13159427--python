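"""YAML/TSV configuration loaders for the command-line interface.

One structured text config describes the acquisition (timing, inclusion
lists), one the pixel grid, and small YAML/TSV files describe phantoms,
species and noise for the simulator.  The loaders only translate files
into the dataclasses of the library modules.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd
import yaml

from .msi_io import PixelGrid
from .pia_model import AcquisitionConfig
from .synthetic_data import NoiseModel, Phantom, SpeciesSpec, make_phantom

__all__ = [
    "load_acquisition",
    "load_grid",
    "load_phantom",
    "load_noise",
    "load_species",
]


def _read_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    return data


def load_acquisition(path) -> AcquisitionConfig:
    """Acquisition config from YAML; keys mirror AcquisitionConfig fields."""
    data = _read_yaml(path)
    if "inclusion_lists" in data and data["inclusion_lists"] is not None:
        data["inclusion_lists"] = tuple(
            tuple(float(w) for w in lst) for lst in data["inclusion_lists"]
        )
    return AcquisitionConfig(**data)


def load_grid(path) -> tuple[PixelGrid, Optional[int]]:
    """Pixel grid (and MS² scans per pixel, if given) from YAML.

    Accepts either a flat mapping of PixelGrid fields or a mapping with a
    ``grid`` sub-mapping plus ``n_ms2_per_ft``.
    """
    data = _read_yaml(path)
    n_ms2 = data.pop("n_ms2_per_ft", None)
    grid_data = data.pop("grid", None) or data
    grid_fields = {
        k: grid_data[k]
        for k in (
            "n_lines", "pixels_per_line_ms1", "n_lists",
            "ft_pixel_x_um", "ft_pixel_y_um",
        )
        if k in grid_data
    }
    return PixelGrid(**grid_fields), (int(n_ms2) if n_ms2 is not None else None)


def load_phantom(path) -> Phantom:
    """Phantom from YAML: ``shape``, ``seed`` and a list of ``regions``."""
    data = _read_yaml(path)
    return make_phantom(
        shape=tuple(data["shape"]),
        region_specs=data.get("regions", []),
        seed=int(data.get("seed", 0)),
    )


def load_noise(path) -> NoiseModel:
    return NoiseModel(**_read_yaml(path))


def load_species(path) -> list[SpeciesSpec]:
    """Species table from TSV.

    Columns: name, precursor_mz, window_center, region, abundance,
    fragment_mzs and fragment_rels (both semicolon-separated, aligned).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        mzs = [float(x) for x in str(row["fragment_mzs"]).split(";") if x]
        rels = [float(x) for x in str(row["fragment_rels"]).split(";") if x]
        if len(mzs) != len(rels):
            raise ValueError(
                f"species {row['name']}: fragment_mzs and fragment_rels differ in length"
            )
        out.append(
            SpeciesSpec(
                name=row["name"],
                precursor_mz=float(row["precursor_mz"]),
                window_center=float(row["window_center"]),
                region=row["region"],
                abundance=float(row["abundance"]),
                fragments=tuple(zip(mzs, rels)),
            )
        )
    return out
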