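"""Desikan-Killiany atlas bookkeeping: region index <-> name and lobe assignment."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

__all__ = ["load_lobe_map", "load_region_names", "LOBES"]

LOBES = ("frontal", "temporal", "parietal", "occipital", "limbic", "insular")


def _read(path: str | Path | None):
    if path is None:
        text = resources.files("adbc").joinpath("dk_lobes.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return {int(k): v for k, v in raw.items()}


def load_lobe_map(path: str | Path | None = None) -> dict[int, str]:
    """Region index (1-based) -> lobe. Default is the shipped standard DK map."""
    out = {}
    for idx, entry in _read(path).items():
        lobe = entry["lobe"] if isinstance(entry, dict) else str(entry)
        if lobe not in LOBES:
            raise ValueError(f"region {idx}: unknown lobe {lobe!r}")
        out[idx] = lobe
    return out


def load_region_names(path: str | Path | None = None) -> dict[int, str]:
    """Region index (1-based) -> anatomical name (e.g. 'lh-entorhinal')."""
    return {
        idx: (entry["name"] if isinstance(entry, dict) else f"region_{idx}")
        for idx, entry in _read(path).items()
    }
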