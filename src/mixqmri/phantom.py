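"""Synthetic knee-like digital phantoms for quantitative MRI simulation.

The phantom is a sagittal slab through a stylized femorotibial joint:
a curved femoral condyle (bone marrow) sits above a femoral cartilage
band, a synovial-fluid joint space with wedge-shaped menisci at its
margins, a flat tibial cartilage plate and tibial marrow below, an
anterior infrapatellar fat pad, and posterior muscle.  Anatomic fidelity
is deliberately minimal — the phantom exists to carry known relaxation
parameters (the simulation ground truth), not to look like a knee.

Cartilage truth maps carry a depth-dependent (zonal) profile: transverse
relaxation times decrease from the articular surface toward the
subchondral bone, as observed in vivo and in situ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "TISSUE_IDS",
    "TissueParams",
    "TissuePhantom",
    "RoiSpec",
    "PhantomConfig",
    "default_tissue_table",
    "build_knee_phantom",
    "cartilage_zonal_profile",
    "roi_from_label",
]

#: Canonical label integers.  0 is background by construction.
TISSUE_IDS: dict[str, int] = {
    "background": 0,
    "femoral_cartilage": 1,
    "tibial_cartilage": 2,
    "synovial_fluid": 3,
    "infrapatellar_fat": 4,
    "bone_marrow": 5,
    "meniscus": 6,
    "muscle": 7,
}

REQUIRED_TISSUES = tuple(n for n in TISSUE_IDS if n != "background")


@dataclass(frozen=True)
class TissueParams:
    """Relaxation and compartment parameters of one tissue class.

    ``fat_fraction`` is the fraction of the voxel signal arising from the
    fat compartment (suppressed by spectral fat saturation); the remainder
    is the water compartment, whose T2/T1rho may be modulated voxel-wise
    by the zonal truth maps.
    """

    name: str
    proton_density: float
    t1_ms: float
    t2_ms: float
    t1rho_ms: float
    fat_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.name != "background":
            if self.proton_density <= 0:
                raise ValueError(f"{self.name}: proton_density must be > 0")
            for attr in ("t1_ms", "t2_ms", "t1rho_ms"):
                if getattr(self, attr) <= 0:
                    raise ValueError(f"{self.name}: {attr} must be > 0")
        if not 0.0 <= self.fat_fraction <= 1.0:
            raise ValueError(f"{self.name}: fat_fraction must be in [0, 1]")


def default_tissue_table() -> dict[int, TissueParams]:
    """Plausible 3 T parameters for the simulated tissue classes.

    Proton densities are relative (arbitrary units).  Fat-dominated
    tissues (fat pad, marrow) carry fat-like relaxation constants and a
    fat fraction of 0.9.
    """
    t = {
        "background": TissueParams("background", 0.0, 1.0, 1.0, 1.0, 0.0),
        "femoral_cartilage": TissueParams("femoral_cartilage", 70.0, 1200.0, 48.0, 45.0),
        "tibial_cartilage": TissueParams("tibial_cartilage", 70.0, 1200.0, 36.0, 38.0),
        "synovial_fluid": TissueParams("synovial_fluid", 100.0, 3600.0, 800.0, 500.0),
        "infrapatellar_fat": TissueParams("infrapatellar_fat", 90.0, 380.0, 130.0, 60.0, 0.9),
        "bone_marrow": TissueParams("bone_marrow", 90.0, 380.0, 130.0, 60.0, 0.9),
        "meniscus": TissueParams("meniscus", 40.0, 1000.0, 12.0, 15.0),
        "muscle": TissueParams("muscle", 60.0, 1400.0, 32.0, 40.0),
    }
    return {TISSUE_IDS[name]: params for name, params in t.items()}


#: Default zonal endpoints (surface -> deep, ms) chosen so that the
#: plate-averaged truth equals the representative segmented means:
#: femoral/tibial T2 48/36 ms, femoral/tibial T1rho 45/38 ms.
DEFAULT_ZONAL = {
    "femoral_cartilage": {"t2": (63.0, 33.0), "t1rho": (60.0, 30.0)},
    "tibial_cartilage": {"t2": (51.0, 21.0), "t1rho": (53.0, 23.0)},
}


@dataclass
class PhantomConfig:
    """Configuration of the synthetic knee slab."""

    shape: tuple[int, int, int] = (160, 160, 7)
    spacing_mm: tuple[float, float, float] = (0.875, 0.875, 3.0)
    tissues: dict[int, TissueParams] = field(default_factory=default_tissue_table)
    zonal: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ZONAL.items()}
    )
    seed: int = 0

    def to_yaml(self) -> str:
        d = {
            "shape": list(self.shape),
            "spacing_mm": list(self.spacing_mm),
            "seed": self.seed,
            "tissues": {p.name: asdict(p) for p in self.tissues.values()},
            "zonal": {k: {m: list(v) for m, v in z.items()} for k, z in self.zonal.items()},
        }
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PhantomConfig":
        d = yaml.safe_load(text)
        tissues = {}
        for name, p in d.get("tissues", {}).items():
            if name not in TISSUE_IDS:
                raise ValueError(f"unknown tissue name in config: {name!r}")
            p = dict(p)
            p.pop("name", None)
            tissues[TISSUE_IDS[name]] = TissueParams(name=name, **p)
        cfg = cls(
            shape=tuple(d.get("shape", (160, 160, 7))),
            spacing_mm=tuple(d.get("spacing_mm", (0.875, 0.875, 3.0))),
            seed=int(d.get("seed", 0)),
        )
        if tissues:
            cfg.tissues = tissues
        if "zonal" in d:
            cfg.zonal = {
                k: {m: tuple(v) for m, v in z.items()} for k, z in d["zonal"].items()
            }
        return cfg


@dataclass
class TissuePhantom:
    """Voxel label grid plus per-tissue parameters and truth maps."""

    labels: np.ndarray  # (nx, ny, nz) int
    spacing_mm: tuple[float, float, float]
    tissue_table: dict[int, TissueParams]
    truth_t2_ms: np.ndarray  # same shape, float; 0 in background
    truth_t1rho_ms: np.ndarray
    config: PhantomConfig | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_area_mm2(self) -> float:
        return self.spacing_mm[0] * self.spacing_mm[1]

    def tissue_id(self, name: str) -> int:
        return TISSUE_IDS[name]

    def mask(self, name: str) -> np.ndarray:
        return self.labels == TISSUE_IDS[name]

    def fat_fraction_map(self) -> np.ndarray:
        ff = np.zeros(self.labels.shape, dtype=float)
        for tid, params in self.tissue_table.items():
            ff[self.labels == tid] = params.fat_fraction
        return ff

    def tissue_table_json(self) -> str:
        return json.dumps(
            {str(tid): asdict(p) for tid, p in self.tissue_table.items()}, indent=2
        )

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        return aff


@dataclass(frozen=True)
class RoiSpec:
    """An explicit voxel set standing in for a circular ROI."""

    center_voxel: tuple[int, int, int]
    voxel_indices: np.ndarray  # (n, 3) int
    area_mm2: float
    tissue_id: int

    def __post_init__(self) -> None:
        if len(self.voxel_indices) < 1:
            raise ValueError("ROI must contain at least one voxel")


def cartilage_zonal_profile(
    depth_fraction, surface_value_ms: float, deep_value_ms: float
):
    """Relaxation time at normalized cartilage depth.

    Linear decrease from ``surface_value_ms`` at the articular surface
    (depth 0) to ``deep_value_ms`` at the osteochondral interface
    (depth 1).  Monotonically non-increasing in depth.

    Parameters
    ----------
    depth_fraction : float or array-like in [0, 1]
    surface_value_ms, deep_value_ms : float, with surface > deep > 0.
    """
    if not surface_value_ms > deep_value_ms > 0:
        raise ValueError("require surface_value_ms > deep_value_ms > 0")
    d = np.asarray(depth_fraction, dtype=float)
    if np.any((d < 0) | (d > 1)):
        raise ValueError("depth_fraction must lie in [0, 1]")
    out = surface_value_ms + d * (deep_value_ms - surface_value_ms)
    return out if out.ndim else float(out)


def _frac(n: int, f: float) -> int:
    return int(round(n * f))


def build_knee_phantom(config: PhantomConfig | None = None) -> TissuePhantom:
    """Construct the stylized sagittal knee slab.

    Geometry is parametric in the grid size: a curved femoral condyle
    band above a femoral cartilage plate, a fluid-filled joint space
    with marginal meniscal wedges, a flat tibial plateau, an anterior
    fat pad, and posterior muscle.  Deterministic for a fixed config
    (the stored seed only tags provenance for downstream noise streams).

    Raises
    ------
    ValueError
        If the grid is smaller than 32 x 32 x 3, a tissue name is
        unknown, or a required tissue cannot be placed.
    """
    cfg = config if config is not None else PhantomConfig()
    nx, ny, nz = cfg.shape
    if nx < 32 or ny < 32 or nz < 3:
        raise ValueError("grid too small: need at least 32 x 32 x 3")
    by_name = {p.name: tid for tid, p in cfg.tissues.items()}
    for name in REQUIRED_TISSUES:
        if name not in by_name:
            raise ValueError(f"config tissue table is missing {name!r}")
    for name in cfg.zonal:
        if name not in TISSUE_IDS:
            raise ValueError(f"unknown tissue name in zonal config: {name!r}")

    L = TISSUE_IDS
    labels2d = np.zeros((nx, ny), dtype=np.int16)
    depth2d = np.full((nx, ny), np.nan)  # cartilage depth fraction

    x0j, x1j = _frac(nx, 0.25), _frac(nx, 0.95)  # joint column
    xc, halfw = 0.5 * (x0j + x1j), 0.5 * (x1j - x0j)
    cart_thick = max(2, _frac(ny, 0.025))
    y_fb_base = _frac(ny, 0.3875)
    curve_amp = max(2, _frac(ny, 0.05))
    tib_top = _frac(ny, 0.525)
    tib_bot = tib_top + cart_thick
    marrow_bot = _frac(ny, 0.7375)

    xs = np.arange(x0j, x1j)
    y_fb = y_fb_base + np.round(curve_amp * ((xs - xc) / halfw) ** 2).astype(int)

    for i, x in enumerate(xs):
        yb = y_fb[i]
        labels2d[x, _frac(ny, 0.05): yb] = L["bone_marrow"]
        labels2d[x, yb: yb + cart_thick] = L["femoral_cartilage"]
        # depth 0 at the fluid-facing surface (bottom row), 1 at bone
        rows = np.arange(yb, yb + cart_thick)
        depth2d[x, rows] = (yb + cart_thick - 1 - rows) / (cart_thick - 1)
        labels2d[x, yb + cart_thick: tib_top] = L["synovial_fluid"]
        labels2d[x, tib_top: tib_bot] = L["tibial_cartilage"]
        rows = np.arange(tib_top, tib_bot)
        depth2d[x, rows] = (rows - tib_top) / (cart_thick - 1)
        labels2d[x, tib_bot: marrow_bot] = L["bone_marrow"]

    # meniscal wedges: triangular, base at the joint margins, apex inward
    men_w = max(4, _frac(nx, 0.125))
    for i, x in enumerate(xs):
        gap_top = y_fb[i] + cart_thick
        gap_h = tib_top - gap_top
        if gap_h <= 0:
            continue
        if x < x0j + men_w:
            t = (x0j + men_w - x) / men_w
        elif x >= x1j - men_w:
            t = (x - (x1j - men_w) + 1) / men_w
        else:
            continue
        h = int(round(gap_h * min(1.0, t)))
        if h > 0:
            labels2d[x, tib_top - h: tib_top] = L["meniscus"]

    # anterior fat pad and posterior muscle
    labels2d[_frac(nx, 0.05): _frac(nx, 0.22), _frac(ny, 0.3125): _frac(ny, 0.6875)] = L[
        "infrapatellar_fat"
    ]
    labels2d[_frac(nx, 0.12): _frac(nx, 0.94), _frac(ny, 0.76): _frac(ny, 0.94)] = L["muscle"]

    labels = np.repeat(labels2d[:, :, None], nz, axis=2)
    depth = np.repeat(depth2d[:, :, None], nz, axis=2)

    counts = {name: int(np.sum(labels == tid)) for name, tid in L.items()}
    missing = [n for n in REQUIRED_TISSUES if counts[n] == 0]
    if missing:
        raise ValueError(f"grid too small to place tissues: {missing}")

    truth_t2 = np.zeros(labels.shape, dtype=float)
    truth_t1rho = np.zeros(labels.shape, dtype=float)
    for tid, params in cfg.tissues.items():
        m = labels == tid
        truth_t2[m] = params.t2_ms
        truth_t1rho[m] = params.t1rho_ms
    for name, prof in cfg.zonal.items():
        m = labels == L[name]
        d = depth[m]
        if "t2" in prof:
            s, dp = prof["t2"]
            truth_t2[m] = cartilage_zonal_profile(d, s, dp)
        if "t1rho" in prof:
            s, dp = prof["t1rho"]
            truth_t1rho[m] = cartilage_zonal_profile(d, s, dp)

    return TissuePhantom(
        labels=labels,
        spacing_mm=cfg.spacing_mm,
        tissue_table=dict(cfg.tissues),
        truth_t2_ms=truth_t2,
        truth_t1rho_ms=truth_t1rho,
        config=cfg,
    )


def roi_from_label(
    phantom: TissuePhantom, tissue_id: int, area_mm2: float, slice_index: int
) -> RoiSpec:
    """Place an approximately disc-shaped ROI of nominal area inside a tissue.

    The ROI contains ``round(area_mm2 / in-plane voxel area)`` voxels
    (minimum 1), selected as the tissue voxels on the slice nearest to the
    in-slice tissue centroid; ties are broken deterministically by index
    order.

    Raises
    ------
    ValueError
        If the tissue is absent from the slice or its extent is smaller
        than the requested area.
    """
    if area_mm2 <= 0:
        raise ValueError("area_mm2 must be positive")
    nx, ny, nz = phantom.shape
    if not 0 <= slice_index < nz:
        raise ValueError("slice_index outside grid")
    plane = phantom.labels[:, :, slice_index]
    xs, ys = np.nonzero(plane == tissue_id)
    if xs.size == 0:
        raise ValueError(f"tissue {tissue_id} absent from slice {slice_index}")
    n_vox = max(1, int(round(area_mm2 / phantom.voxel_area_mm2)))
    if xs.size < n_vox:
        raise ValueError(
            f"requested area needs {n_vox} voxels but tissue {tissue_id} "
            f"has only {xs.size} on slice {slice_index}"
        )
    cx, cy = xs.mean(), ys.mean()
    d2 = (xs - cx) ** 2 + (ys - cy) ** 2
    order = np.lexsort((ys, xs, d2))[:n_vox]
    vox = np.column_stack(
        (xs[order], ys[order], np.full(n_vox, slice_index, dtype=int))
    )
    center = tuple(int(v) for v in vox[0])
    return RoiSpec(
        center_voxel=center, voxel_indices=vox, area_mm2=area_mm2, tissue_id=tissue_id
    )
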