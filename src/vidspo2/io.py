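"""On-disk layout for synthetic recordings and model checkpoints.

Clips are stored losslessly as 16-bit TIFF frame stacks: the pulsatile
signal is ~1% of the DC level, which lossy codecs and 8-bit quantization
would destroy.  Signals travel as two-column CSV, scene metadata as YAML,
and a dataset manifest links the per-subject directories.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import nn
from .exceptions import DataError
from .preprocess import BoundingBox, VideoClip
from .signalcore import Waveform, waveform_to_csv
from .synthetic import SceneConfig, SyntheticSample

__all__ = [
    "save_clip", "load_clip", "save_sample", "load_sample",
    "write_manifest", "load_manifest", "save_model", "load_model_state",
]

_SCALE = 65535.0


def save_clip(directory, clip: VideoClip):
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(clip.frames):
        arr = np.round(np.clip(frame, 0, 1) * _SCALE).astype(np.uint16)
        tifffile.imwrite(directory / f"frame_{i:05d}.tif", arr)
    (directory / "clip.yaml").write_text(yaml.safe_dump({"rate": float(clip.rate)}))


def load_clip(directory) -> VideoClip:
    directory = Path(directory)
    meta = yaml.safe_load((directory / "clip.yaml").read_text())
    paths = sorted(directory.glob("frame_*.tif"))
    if not paths:
        raise DataError(f"no frames found under {directory}")
    frames = np.stack([tifffile.imread(p) for p in paths]).astype(np.float32) / _SCALE
    return VideoClip(frames, meta["rate"])


def _bbox_dict(b: BoundingBox | None):
    return None if b is None else {"x0": b.x0, "y0": b.y0, "x1": b.x1, "y1": b.y1}


def save_sample(directory, sample: SyntheticSample):
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_clip(directory / "face", sample.face_clip)
    save_clip(directory / "hand", sample.hand_clip)
    waveform_to_csv(sample.ppg, directory / "ppg.csv")
    sec = np.arange(sample.spo2_trace.size)
    np.savetxt(directory / "spo2.csv",
               np.column_stack([sec, sample.spo2_trace]), delimiter=",",
               header="time_s,spo2_percent", comments="")
    meta = dataclasses.asdict(sample.meta)
    meta["spo2_trace"] = np.asarray(meta["spo2_trace"]).tolist()
    doc = {"subject_id": sample.subject_id, "scene": meta,
           "face_bbox": _bbox_dict(sample.face_bbox),
           "hand_bbox": _bbox_dict(sample.hand_bbox)}
    (directory / "scene.yaml").write_text(yaml.safe_dump(doc))


def load_sample(directory) -> SyntheticSample:
    directory = Path(directory)
    doc = yaml.safe_load((directory / "scene.yaml").read_text())
    scene = doc["scene"]
    scene["spo2_trace"] = np.asarray(scene["spo2_trace"], dtype=np.float64)
    cfg = SceneConfig(**scene)
    arr = np.loadtxt(directory / "ppg.csv", delimiter=",", skiprows=1)
    ppg = Waveform(arr[:, 1], cfg.rate)
    fb, hb = doc.get("face_bbox"), doc.get("hand_bbox")
    return SyntheticSample(
        face_clip=load_clip(directory / "face"),
        hand_clip=load_clip(directory / "hand"),
        ppg=ppg,
        spo2_trace=cfg.spo2_trace.copy(),
        meta=cfg,
        face_bbox=BoundingBox(**fb) if fb else None,
        hand_bbox=BoundingBox(**hb) if hb else None,
        subject_id=doc["subject_id"],
    )


def write_manifest(path, subject_dirs: dict[str, str]):
    doc = {"subjects": [{"id": sid, "path": str(p)}
                        for sid, p in subject_dirs.items()]}
    Path(path).write_text(yaml.safe_dump(doc))


def load_manifest(path) -> list[SyntheticSample]:
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not doc or "subjects" not in doc or not doc["subjects"]:
        raise DataError(f"manifest {path} lists no subjects")
    samples = []
    seen = set()
    for rec in doc["subjects"]:
        if rec["id"] in seen:
            raise DataError(f"duplicate subject id {rec['id']!r} in manifest")
        seen.add(rec["id"])
        sub_dir = Path(rec["path"])
        if not sub_dir.is_absolute():
            sub_dir = path.parent / sub_dir
        if not sub_dir.exists():
            raise DataError(f"subject directory {sub_dir} does not exist")
        samples.append(load_sample(sub_dir))
    return samples


def save_model(path, module: nn.Module, meta: dict | None = None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    extras = {}
    mean = getattr(module, "summary_mean", None)
    if mean is not None:
        extras["__summary_mean__"] = np.asarray(mean)
        extras["__summary_sd__"] = np.asarray(module.summary_sd)
    np.savez(path, __meta__=json.dumps(meta or {}),
             **module.state_dict(), **extras)


def load_model_state(path, module: nn.Module) -> dict:
    data = np.load(Path(path), allow_pickle=False)
    special = {"__meta__", "__summary_mean__", "__summary_sd__"}
    module.load_state_dict({k: data[k] for k in data.files if k not in special})
    if "__summary_mean__" in data.files and hasattr(module, "summary_mean"):
        module.summary_mean = data["__summary_mean__"]
        module.summary_sd = data["__summary_sd__"]
    return json.loads(str(data["__meta__"]))
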