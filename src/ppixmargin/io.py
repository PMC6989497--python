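"""On-disk layout for synthetic acquisitions.

One TSV per sample / channel / frame (columns ``wavelength_nm``,
``intensity``) with a JSON sidecar carrying the acquisition metadata, plus a
dataset-level ``manifest.csv``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import ExcitationChannel, SampleAcquisition, WavelengthGrid

__all__ = ["write_dataset", "read_dataset", "read_manifest"]

_MANIFEST = "manifest.csv"


def _frame_name(state: str, index: int) -> str:
    return f"{state}_{index:03d}.tsv"


def write_dataset(samples: list[SampleAcquisition], out_dir: str | Path) -> Path:
    """Write every frame as TSV + JSON sidecar and return the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample in samples:
        sample_dir = out / sample.sample_id
        for ch in sample.channels:
            ch_dir = sample_dir / f"ch{ch.center_nm}"
            ch_dir.mkdir(parents=True, exist_ok=True)
            on, off = sample.frames[ch.center_nm]
            for state, block in (("on", on), ("off", off)):
                for i, frame in enumerate(block):
                    path = ch_dir / _frame_name(state, i)
                    pd.DataFrame(
                        {"wavelength_nm": sample.grid.values, "intensity": frame}
                    ).to_csv(path, sep="\t", index=False)
                    meta = {
                        "sample_id": sample.sample_id,
                        "patient_id": sample.patient_id,
                        "true_class": sample.true_class,
                        "channel_center_nm": ch.center_nm,
                        "channel_fwhm_nm": ch.fwhm_nm,
                        "irradiance": ch.irradiance,
                        "n_frames": ch.n_frames,
                        "frame_ms": ch.frame_ms,
                        "frame_index": i,
                        "led_state": state,
                    }
                    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
        rows.append(
            {
                "sample_id": sample.sample_id,
                "patient_id": sample.patient_id,
                "true_class": sample.true_class,
                "path": sample.sample_id,
            }
        )
    manifest = out / _MANIFEST
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_manifest(dataset_dir: str | Path) -> pd.DataFrame:
    path = Path(dataset_dir) / _MANIFEST
    if not path.exists():
        raise FileNotFoundError(f"no {_MANIFEST} under {dataset_dir}")
    return pd.read_csv(path)


def read_dataset(dataset_dir: str | Path) -> list[SampleAcquisition]:
    """Load a dataset written by :func:`write_dataset` (manifest row order)."""
    root = Path(dataset_dir)
    manifest = read_manifest(root)
    samples: list[SampleAcquisition] = []
    for row in manifest.itertuples():
        sample_dir = root / str(row.path)
        channels = []
        frames: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        grid: WavelengthGrid | None = None
        for ch_dir in sorted(sample_dir.glob("ch*")):
            first_meta = json.loads((ch_dir / "on_000.json").read_text())
            channel = ExcitationChannel(
                center_nm=int(first_meta["channel_center_nm"]),
                fwhm_nm=float(first_meta["channel_fwhm_nm"]),
                irradiance=float(first_meta["irradiance"]),
                n_frames=int(first_meta["n_frames"]),
                frame_ms=float(first_meta["frame_ms"]),
            )
            blocks = {}
            for state in ("on", "off"):
                stack = []
                for i in range(channel.n_frames):
                    table = pd.read_csv(ch_dir / _frame_name(state, i), sep="\t")
                    if grid is None:
                        values = table["wavelength_nm"].to_numpy()
                        values.setflags(write=False)
                        grid = WavelengthGrid(values=values)
                    stack.append(table["intensity"].to_numpy())
                blocks[state] = np.stack(stack)
            channels.append(channel)
            frames[channel.center_nm] = (blocks["on"], blocks["off"])
        assert grid is not None
        samples.append(
            SampleAcquisition(
                sample_id=str(row.sample_id),
                patient_id=str(row.patient_id),
                true_class=str(row.true_class),
                grid=grid,
                channels=tuple(channels),
                frames=frames,
            )
        )
    return samples
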