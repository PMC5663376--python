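"""TOML configuration loaders (compositions, phantom/plan/detector).

Key names carry explicit units (``distance_mm``, ``energy_keV``, …).  The
reference mouse-head configuration ships with the package as
``data/mousehead_20keV.toml``.
"""

from __future__ import annotations

import tomllib
from importlib import resources
from pathlib import Path

from .materials import ElementalComposition
from .phantom import DetectorModel, Phantom, Region, ScanPlan


def load_composition_toml(path) -> tuple[ElementalComposition, float]:
    """Read ``name``, ``density_g_cm3`` and an ``[elements]`` table of
    weight fractions; returns (composition, density)."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    comp = ElementalComposition(dict(data["elements"]),
                                name=data.get("name", Path(path).stem))
    return comp, float(data["density_g_cm3"])


def _phantom_from_dict(data: dict) -> Phantom:
    regions = tuple(
        Region(r_inner_mm=float(r["r_inner_mm"]),
               r_outer_mm=float(r["r_outer_mm"]),
               material=r["material"], half=r.get("half"),
               label=r.get("label"))
        for r in data["region"])
    return Phantom(regions=regions,
                   slice_thickness_mm=float(
                       data.get("slice_thickness_mm", 1.0)))


def load_scan_config_toml(path=None) -> tuple[Phantom, ScanPlan,
                                              DetectorModel]:
    """Load a phantom + scan plan + detector from TOML; with no path the
    packaged mouse-head default is used."""
    if path is None:
        src = resources.files("saxskit").joinpath(
            "data/mousehead_20keV.toml")
        data = tomllib.loads(src.read_text())
    else:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    phantom = _phantom_from_dict(data["phantom"])
    plan = ScanPlan(**{k: v for k, v in data["plan"].items()})
    detector = DetectorModel(**{k: v for k, v in data["detector"].items()})
    return phantom, plan, detector
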