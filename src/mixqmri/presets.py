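"""Packaged acquisition presets for the six compared sequences."""

from __future__ import annotations

from importlib import resources

import yaml

from .acquisition import PrepBlock, SequenceSpec

__all__ = ["load_sequence_presets", "PRESET_WEIGHTING"]

#: Morphologic weighting of each preset (drives ROI pairing downstream).
PRESET_WEIGHTING = {
    "MIX1": "PD-w FS",
    "2D TSE PD-w FS": "PD-w FS",
    "3D TSE PD-w FS": "PD-w FS",
    "MIX2": "T1-w",
    "2D TSE T1-w": "T1-w",
    "3D TSE T1-w": "T1-w",
}


def load_sequence_presets() -> dict[str, SequenceSpec]:
    """Return the packaged sequence presets keyed by name.

    MIX1: two interleaved blocks at TR 1200 ms (T2-prep TE 0 and 50 ms,
    fat saturation on the unprepared block).  MIX2: three interleaved
    blocks at TR 600 ms (spin-lock TSL 0, 25, 50 ms at 500 Hz, fat
    saturation on the prepared blocks).  Plus the 2D/3D TSE references
    of matching weighting.
    """
    text = resources.files("mixqmri").joinpath("data/presets.yaml").read_text()
    raw = yaml.safe_load(text)
    presets: dict[str, SequenceSpec] = {}
    for name, d in raw.items():
        blocks = tuple(
            PrepBlock(
                prep_type=b["prep_type"],
                prep_time_ms=float(b["prep_time_ms"]),
                fat_sat=bool(b["fat_sat"]),
                label=b.get("label", ""),
            )
            for b in d["blocks"]
        )
        presets[name] = SequenceSpec(
            name=name,
            tr_ms=float(d["tr_ms"]),
            te_equiv_ms=float(d["te_equiv_ms"]),
            blocks=blocks,
            spinlock_freq_hz=d.get("spinlock_freq_hz"),
        )
    return presets
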