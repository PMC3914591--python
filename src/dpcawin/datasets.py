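"""Writing synthetic datasets to disk and loading labelled datasets back.

``simulate`` emits a plain-text dataset directory with a ``manifest.yaml``
recording format, sample rate and the file-to-label mapping, so every later
stage can reload the exact same signals without guessing conventions.
Single-channel short-segment presets are written as one ASCII file per
signal; multichannel-style presets are written as one multi-column CSV per
class (columns are replicate signals, standing in for channels).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import yaml

from .io import (read_bonn_ascii, read_multichannel_csv, write_bonn_ascii,
                 write_multichannel_csv)
from .synthetic import DatasetSpec, generate_dataset
from .types import Signal

__all__ = ["write_dataset", "load_dataset", "apply_label_map"]

PathLike = Union[str, Path]

MANIFEST = "manifest.yaml"


def write_dataset(spec: DatasetSpec, out_dir: PathLike,
                  layout: Optional[str] = None) -> Path:
    """Generate the dataset and write it under ``out_dir``; returns the dir.

    ``layout`` is ``"ascii"`` (one file per signal) or ``"csv"`` (one
    multi-column file per class); by default multichannel-style presets
    (sample rate 256) use csv and everything else ascii.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if layout is None:
        layout = "csv" if spec.name == "freiburg_like" else "ascii"
    signals = generate_dataset(spec)
    entries = []
    if layout == "ascii":
        for sig in signals:
            fname = sig.source_id.replace(":", "_") + ".txt"
            write_bonn_ascii(sig, out / fname)
            entries.append({"path": fname, "label": sig.label,
                            "format": "ascii"})
    elif layout == "csv":
        for cls in spec.classes:
            group = [s for s in signals if s.label == cls.label]
            fname = f"{spec.name}_{cls.label}.csv"
            write_multichannel_csv(
                group, out / fname,
                channel_names=[f"rep{j + 1}" for j in range(len(group))])
            entries.append({"path": fname, "label": cls.label,
                            "format": "csv"})
    else:
        raise ValueError(f"unknown layout {layout!r}")
    manifest = {
        "name": spec.name,
        "sample_rate": float(spec.sample_rate),
        "seed": int(spec.seed),
        "files": entries,
    }
    (out / MANIFEST).write_text(yaml.safe_dump(manifest, sort_keys=True))
    return out


def load_dataset(data_dir: PathLike) -> list[Signal]:
    """Load every signal listed in a dataset directory's manifest."""
    data_dir = Path(data_dir)
    manifest_path = data_dir / MANIFEST
    if not manifest_path.exists():
        raise FileNotFoundError(f"no {MANIFEST} in {data_dir}")
    manifest = yaml.safe_load(manifest_path.read_text())
    rate = float(manifest["sample_rate"])
    signals: list[Signal] = []
    for entry in manifest["files"]:
        path = data_dir / entry["path"]
        if entry["format"] == "ascii":
            signals.append(read_bonn_ascii(path, label=entry["label"],
                                           sample_rate=rate))
        elif entry["format"] == "csv":
            signals.extend(read_multichannel_csv(path, sample_rate=rate,
                                                 label=entry["label"]))
        else:
            raise ValueError(f"unknown format {entry['format']!r} in manifest")
    return signals


def apply_label_map(signals: list[Signal], label_map: dict) -> list[Signal]:
    """Relabel signals through an explicit raw-label -> group-label mapping.

    Labels absent from the map are kept as-is; an empty map is the identity.
    Used to express groupings such as ictal-vs-rest without touching data.
    """
    if not label_map:
        return signals
    out = []
    for s in signals:
        new = label_map.get(s.label, s.label)
        out.append(Signal(samples=s.samples, sample_rate=s.sample_rate,
                          label=new, source_id=s.source_id))
    return out
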