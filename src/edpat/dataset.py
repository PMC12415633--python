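"""Dataset manifests, the simulate→label pipeline, and fixture presets.

A dataset is a directory of PNG images plus a CSV manifest (one row per
pattern) and a JSON sidecar holding the full generation configuration, the
cells, and — so that patterns can be relabelled or audited without
re-simulation — the integer hkl set of every pattern.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import (ANISOTROPIC_LENGTH_RANGE, SCREW_21_B, ExtinctionRule,
                       UnitCell, random_unit_cell)
from .simulate import (Pattern, PhysicsConfig, RenderSpec, render_pattern,
                       save_pattern_image, simulate_patterns)
from .zonal import NON_ZONAL, ZONAL, label_pattern

__all__ = ["DatasetManifest", "write_manifest", "read_manifest",
           "simulate_dataset", "make_fixture", "FIXTURE_PRESETS"]

log = logging.getLogger("edpat")

SCHEMA_VERSION = 1

MANIFEST_COLUMNS = [
    "pattern_id", "cell_id", "orientation_id",
    "beam_x", "beam_y", "beam_z", "inplane_angle",
    "n_reflections", "label", "zone_u", "zone_v", "zone_w", "degenerate",
    "predicted_label", "confidence", "image_path",
]


@dataclass
class DatasetManifest:
    """Per-pattern records plus the configuration that generated them."""

    records: pd.DataFrame
    config: dict = field(default_factory=dict)
    reflections: dict[str, list] = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"manifest records missing columns: {missing}")
        ids = self.records["pattern_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate pattern_id {dup!r} in manifest")
        bad = ~self.records["label"].isin([ZONAL, NON_ZONAL, ""])
        if bad.any():
            raise ValueError(
                f"invalid label value {self.records.loc[bad, 'label'].iloc[0]!r}")

    def __len__(self) -> int:
        return len(self.records)

    def validate_images(self) -> list[str]:
        """Return (and warn about) referenced image files that do not exist."""
        missing = []
        for p in self.records["image_path"]:
            if p and not Path(p).exists():
                missing.append(p)
        if missing:
            warnings.warn(f"{len(missing)} manifest image(s) missing, "
                          f"first: {missing[0]}")
        return missing

    def equals(self, other: "DatasetManifest") -> bool:
        if self.schema_version != other.schema_version:
            return False
        if self.config != other.config or self.reflections != other.reflections:
            return False
        try:
            pd.testing.assert_frame_equal(
                self.records.reset_index(drop=True),
                other.records.reset_index(drop=True),
                check_dtype=False)
        except AssertionError:
            return False
        return True


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    """Write the records CSV at ``path`` and the JSON sidecar next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest.records.to_csv(path, index=False, na_rep="")
    sidecar = {
        "schema_version": manifest.schema_version,
        "config": manifest.config,
        "reflections": manifest.reflections,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_manifest(path: str | Path) -> DatasetManifest:
    """Read a manifest written by :func:`write_manifest`.

    Raises on schema mismatch, naming the offending column or version;
    missing image files produce a warning list, not an error.
    """
    path = Path(path)
    records = pd.read_csv(path, keep_default_na=False,
                          dtype={"label": str, "predicted_label": str,
                                 "pattern_id": str, "cell_id": str,
                                 "image_path": str})
    records["confidence"] = pd.to_numeric(records["confidence"], errors="coerce")
    records["degenerate"] = records["degenerate"].map(
        {"True": True, "False": False, True: True, False: False})
    if records["degenerate"].isna().any():
        raise ValueError("manifest column 'degenerate' holds non-boolean values")
    records["degenerate"] = records["degenerate"].astype(bool)
    for col in ("zone_u", "zone_v", "zone_w"):
        records[col] = records[col].astype(str)
    sidecar_path = path.with_suffix(".json")
    config, reflections, version = {}, {}, SCHEMA_VERSION
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        version = sidecar.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported manifest schema_version {version}")
        config = sidecar.get("config", {})
        reflections = sidecar.get("reflections", {})
    manifest = DatasetManifest(records=records, config=config,
                               reflections=reflections, schema_version=version)
    manifest.validate_images()
    return manifest


def _pattern_row(pat: Pattern) -> dict:
    axis = pat.zone_axis or ("", "", "")
    bd = pat.orientation.beam_direction
    return {
        "pattern_id": pat.pattern_id,
        "cell_id": pat.cell_id,
        "orientation_id": pat.orientation.orientation_id,
        "beam_x": float(bd[0]), "beam_y": float(bd[1]), "beam_z": float(bd[2]),
        "inplane_angle": pat.orientation.inplane_angle,
        "n_reflections": len(pat.reflections),
        "label": pat.label or "",
        "zone_u": str(axis[0]), "zone_v": str(axis[1]), "zone_w": str(axis[2]),
        "degenerate": pat.degenerate,
        "predicted_label": "",
        "confidence": np.nan,
        "image_path": pat.image_path or "",
    }


def simulate_dataset(cells: Sequence[UnitCell], n_orientations: int,
                     physics: PhysicsConfig, spec: RenderSpec,
                     output_dir: str | Path | None,
                     extinctions: Mapping[str, Sequence[ExtinctionRule]]
                     | Sequence[ExtinctionRule] = (),
                     seed: int = 0,
                     render: bool = True) -> DatasetManifest:
    """Simulate, label and (optionally) render a full dataset.

    For every cell, ``n_orientations`` patterns are simulated over the
    Fibonacci sphere, labelled with the strict zonal criterion, rendered to
    8-bit PNGs under ``output_dir/images`` and recorded in the manifest.
    The run is fully deterministic given its arguments: in-plane rolls come
    from per-cell substreams of ``seed``.

    ``extinctions`` is either one rule list applied to every cell or a
    mapping from cell_id to rules.  With ``render=False`` the geometric
    dataset (labels, hkl sets, manifest) is produced without images —
    useful when only the labelling statistics are needed.
    """
    if render:
        if output_dir is None:
            raise ValueError("output_dir is required when rendering images")
        image_dir = Path(output_dir) / "images"
        image_dir.mkdir(parents=True, exist_ok=True)
    rows, reflections = [], {}
    cells = list(cells)
    for idx, cell in enumerate(cells):
        rules = (extinctions.get(cell.cell_id, ())
                 if isinstance(extinctions, Mapping) else extinctions)
        rng = np.random.default_rng(np.random.SeedSequence([seed, idx]))
        patterns = simulate_patterns(cell, n_orientations, physics,
                                     extinctions=rules, rng=rng)
        n_zonal = 0
        for pat in patterns:
            assign = label_pattern(pat.hkl_array)
            pat.label = assign.label
            pat.zone_axis = assign.zone_axis
            pat.degenerate = assign.degenerate
            n_zonal += assign.label == ZONAL
            if render:
                img = render_pattern(pat.reflections, spec)
                out = image_dir / f"{pat.pattern_id}.png"
                try:
                    save_pattern_image(img, out)
                except OSError as exc:
                    raise OSError(f"failed to write image {out}: {exc}") from exc
                pat.image_path = str(out)
            rows.append(_pattern_row(pat))
            reflections[pat.pattern_id] = [list(t) for t in pat.hkl_array.tolist()]
        log.info("cell %s: %d patterns, %d zonal", cell.cell_id,
                 len(patterns), n_zonal)
    config = {
        "n_orientations": n_orientations,
        "physics": {"wavelength": physics.wavelength,
                    "g_max": physics.g_max, "s_max": physics.s_max},
        "render": {"image_size": spec.image_size,
                   "gmax_to_edge": spec.gmax_to_edge,
                   "spot_radius": spec.spot_radius,
                   "central_spot_radius": spec.central_spot_radius},
        "seed": seed,
        "cells": [dict(c.to_dict(), extinction_rules=[
            r.rule_kind for r in ((extinctions.get(c.cell_id, ())
                                   if isinstance(extinctions, Mapping)
                                   else extinctions))]) for c in cells],
    }
    records = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return DatasetManifest(records=records, config=config,
                           reflections=reflections)


def relabel_manifest(manifest: DatasetManifest) -> DatasetManifest:
    """Recompute zonal labels from the stored hkl sets (in place)."""
    if not manifest.reflections:
        raise ValueError("manifest carries no reflection lists to relabel from")
    for i, pid in enumerate(manifest.records["pattern_id"]):
        assign = label_pattern(np.array(manifest.reflections[pid],
                                        dtype=np.int64).reshape(-1, 3))
        manifest.records.loc[i, "label"] = assign.label
        manifest.records.loc[i, "degenerate"] = assign.degenerate
        if assign.zone_axis is not None:
            manifest.records.loc[i, ["zone_u", "zone_v", "zone_w"]] = [
                str(x) for x in assign.zone_axis]
    return manifest


# ---------------------------------------------------------------------------
# fixture presets emulating the study datasets

#: Monoclinic cells with a 2₁ screw axis along b (axial extinctions 0k0, k odd).
MONOCLINIC_21_CELLS = [
    dict(a=3.8155, b=10.0452, c=13.7425, beta=107.8717),
    dict(a=3.7061, b=12.0249, c=11.7474, beta=103.1097),
]

FIXTURE_PRESETS = {
    # (volume Å³, n_cells, n_orientations)
    "training_1000A3": dict(volume=1000.0, n_cells=4, n_orientations=1000),
    "smallcell_700A3": dict(volume=700.0, n_cells=2, n_orientations=1000),
    "smallcell_500A3": dict(volume=500.0, n_cells=2, n_orientations=1000),
    "monoclinic_21": dict(n_orientations=1000),
    "tiny_ci": dict(volume=400.0, n_cells=1, n_orientations=50),
}


def make_fixture(preset: str, seed: int = 0,
                 output_dir: str | Path | None = None,
                 n_orientations: int | None = None,
                 render: bool = True,
                 spec: RenderSpec | None = None) -> DatasetManifest:
    """Generate one of the named study datasets.

    ``training_1000A3`` and ``smallcell_*`` presets draw random triclinic
    cells rescaled to the named
    volume, 1000 Fibonacci orientations per cell, at the default physics
    (λ = 0.0251 Å, g_max = 1 Å⁻¹, s_max = 0.01 Å⁻¹).  ``monoclinic_21``
    simulates the two fixed monoclinic cells with the 2₁-screw extinction
    along b.  ``tiny_ci`` is a 1-cell, 50-orientation miniature for fast
    tests.  ``n_orientations`` overrides the preset count; ``render=False``
    skips image output.
    """
    if preset not in FIXTURE_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; "
                         f"choose from {sorted(FIXTURE_PRESETS)}")
    params = FIXTURE_PRESETS[preset]
    n_orient = n_orientations or params["n_orientations"]
    physics = PhysicsConfig()
    spec = spec or RenderSpec()
    extinctions: dict[str, tuple] | tuple = ()
    if preset == "monoclinic_21":
        cells = [UnitCell(d["a"], d["b"], d["c"], 90.0, d["beta"], 90.0,
                          cell_id=f"mono21_{i}", lattice_system="monoclinic")
                 for i, d in enumerate(MONOCLINIC_21_CELLS)]
        extinctions = (SCREW_21_B,)
    else:
        cells = []
        for i in range(params["n_cells"]):
            lengths = (ANISOTROPIC_LENGTH_RANGE if preset == "training_1000A3"
                       and i % 2 else None)
            cells.append(random_unit_cell(
                params["volume"],
                length_ranges=[lengths] * 3 if lengths else None,
                seed=np.random.SeedSequence([seed, 7, i]),
                cell_id=f"{preset}_c{i}"))
    return simulate_dataset(cells, n_orient, physics, spec,
                            output_dir=output_dir, extinctions=extinctions,
                            seed=seed, render=render)
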