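"""End-to-end pipeline: phantom -> stacks -> maps -> metrics (+ reader sim).

All volumes are written as uncompressed NIfTI (bit-identical across
reruns of the same config and seed), tables as CSV, and fits/manifests
as JSON.  The run manifest records the config, seeds, package version,
and a SHA-256 hash of every artifact so each output is re-derivable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from . import __version__ as _version
from .acquisition import simulate_stack, ImageStack, DEFAULT_FAT_RESIDUAL
from .phantom import PhantomConfig, TissuePhantom, build_knee_phantom, TISSUE_IDS
from .presets import load_sequence_presets, PRESET_WEIGHTING
from .quality import compare_sequences, metrics_table
from .relaxometry import reconstruct_map, summarize_region, ParameterMap

__all__ = ["RunConfig", "run_pipeline", "save_volume", "save_parameter_map"]


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    sequences: tuple[str, ...] = (
        "MIX1",
        "2D TSE PD-w FS",
        "3D TSE PD-w FS",
        "MIX2",
        "2D TSE T1-w",
        "3D TSE T1-w",
    )
    noise_sigma: float = 0.3
    seed: int = 0
    fs_residual: float = DEFAULT_FAT_RESIDUAL
    out_dir: str = "mixqmri_run"

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        cfg = cls()
        if "phantom" in d:
            cfg.phantom = PhantomConfig.from_yaml(yaml.safe_dump(d["phantom"]))
        if "sequences" in d:
            cfg.sequences = tuple(d["sequences"])
        cfg.noise_sigma = float(d.get("noise_sigma", cfg.noise_sigma))
        cfg.seed = int(d.get("seed", cfg.seed))
        cfg.fs_residual = float(d.get("fs_residual", cfg.fs_residual))
        cfg.out_dir = d.get("out_dir", cfg.out_dir)
        return cfg


def _slug(name: str) -> str:
    return name.replace(" ", "_").replace("/", "-")


def save_volume(path: Path, data: np.ndarray, phantom: TissuePhantom, descrip: str = ""):
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), phantom.affine())
    img.header["descrip"] = descrip.encode()[:79]
    nib.save(img, str(path))


def save_parameter_map(out_dir: Path, stem: str, pmap: ParameterMap, phantom: TissuePhantom):
    vals = np.where(pmap.valid, pmap.values_ms, 0.0)
    save_volume(out_dir / f"{stem}_values.nii", vals, phantom, f"{pmap.kind} map [ms]")
    save_volume(
        out_dir / f"{stem}_valid.nii", pmap.valid.astype(np.float64), phantom, "validity mask"
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run phantom -> simulate -> map -> metrics and write all artifacts.

    Returns the manifest (also written to ``manifest.json``).  Any stage
    error propagates with stage-tagged context.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    presets = load_sequence_presets()
    unknown = [s for s in config.sequences if s not in presets]
    if unknown:
        raise ValueError(f"[config] unknown sequence presets: {unknown}")

    try:
        phantom = build_knee_phantom(config.phantom)
    except Exception as e:  # pragma: no cover - rewrap
        raise RuntimeError(f"[phantom] {e}") from e
    save_volume(out / "labels.nii", phantom.labels.astype(np.float64), phantom, "tissue labels")
    save_volume(out / "truth_t2.nii", phantom.truth_t2_ms, phantom, "truth T2 [ms]")
    save_volume(out / "truth_t1rho.nii", phantom.truth_t1rho_ms, phantom, "truth T1rho [ms]")
    (out / "tissues.json").write_text(phantom.tissue_table_json())
    (out / "phantom_config.yaml").write_text(config.phantom.to_yaml())

    stacks: dict[str, ImageStack] = {}
    for i, name in enumerate(config.sequences):
        try:
            stack = simulate_stack(
                phantom,
                presets[name],
                noise_sigma=config.noise_sigma,
                seed=config.seed + i,
                fs_residual=config.fs_residual,
            )
        except Exception as e:
            raise RuntimeError(f"[simulate:{name}] {e}") from e
        stacks[name] = stack
        for b, vol in enumerate(stack.volumes):
            block = stack.sequence.blocks[b]
            save_volume(
                out / f"{_slug(name)}_block{b}.nii",
                vol,
                phantom,
                f"{name} | {block.label}",
            )

    maps = {}
    for name, kind in (("MIX1", "T2"), ("MIX2", "T1rho")):
        if name not in stacks:
            continue
        try:
            pmap = reconstruct_map(stacks[name], kind)
        except Exception as e:
            raise RuntimeError(f"[map:{name}] {e}") from e
        maps[name] = pmap
        save_parameter_map(out, f"{_slug(name)}_{kind}", pmap, phantom)
        summaries = summarize_region(
            pmap,
            phantom.labels,
            [TISSUE_IDS["femoral_cartilage"], TISSUE_IDS["tibial_cartilage"]],
            ["femoral_cartilage", "tibial_cartilage"],
        )
        import pandas as pd

        pd.DataFrame([s.__dict__ for s in summaries]).to_csv(
            out / f"{_slug(name)}_{kind}_regions.csv", index=False
        )

    try:
        frames = []
        roi_audit = {}
        for weighting in ("PD-w FS", "T1-w"):
            group = [
                stacks[n] for n in config.sequences
                if n in stacks and PRESET_WEIGHTING.get(n) == weighting
            ]
            if not group:
                continue
            rows = compare_sequences(group, phantom, weighting)
            frames.append(metrics_table(rows, phantom_id=f"seed{config.seed}"))
            roi_audit[weighting] = rows[0].rois
        if frames:
            import pandas as pd

            pd.concat(frames, ignore_index=True).to_csv(out / "metrics.csv", index=False)
            (out / "roi_audit.json").write_text(json.dumps(roi_audit, indent=2))
    except Exception as e:
        raise RuntimeError(f"[metrics] {e}") from e

    artifacts = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "version": _version,
        "seed": config.seed,
        "noise_sigma": config.noise_sigma,
        "sequences": list(config.sequences),
        "n_volumes": sum(len(s.volumes) for s in stacks.values()),
        "n_maps": len(maps),
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
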