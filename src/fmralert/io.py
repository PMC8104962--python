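"""Reading and writing the pipeline's on-disk formats.

Scans and templates go to NIfTI (nibabel); trial tables to BIDS-style
events TSV (onset, duration, trial_type, response_time); EEG and
physiological waveforms to gzipped TSV column files with a JSON sidecar
recording sampling rate and channel names.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import EEGRecording, FMRIScan, PhysioSignals, TrialTable

__all__ = [
    "save_scan", "load_scan", "save_template_volume", "load_volume",
    "save_events", "load_events", "save_eeg", "load_eeg",
    "save_physio", "load_physio", "save_world",
]


def save_scan(scan: FMRIScan, path: str | Path) -> None:
    path = Path(path)
    nib.save(nib.Nifti1Image(scan.data.astype(np.float32), scan.affine), path)
    mask_path = path.with_name(path.name.replace(".nii", "_mask.nii"))
    nib.save(nib.Nifti1Image(scan.mask.astype(np.uint8), scan.affine),
             mask_path)
    sidecar = path.with_suffix("").with_suffix(".json") \
        if path.suffix == ".gz" else path.with_suffix(".json")
    sidecar.write_text(json.dumps({"tr": scan.tr, "scan_id": scan.scan_id}))


def load_scan(path: str | Path) -> FMRIScan:
    path = Path(path)
    img = nib.load(path)
    mask_path = path.with_name(path.name.replace(".nii", "_mask.nii"))
    mask = np.asarray(nib.load(mask_path).dataobj).astype(bool)
    sidecar = path.with_suffix("").with_suffix(".json") \
        if path.suffix == ".gz" else path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    return FMRIScan(data=np.asarray(img.dataobj, dtype=float), tr=meta["tr"],
                    mask=mask, affine=img.affine, scan_id=meta.get("scan_id", ""))


def save_template_volume(values: np.ndarray, path: str | Path,
                         affine: np.ndarray | None = None) -> None:
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32),
                             affine if affine is not None else np.eye(4)),
             Path(path))


def load_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(Path(path)).dataobj, dtype=float)


def save_events(trials: TrialTable, path: str | Path) -> None:
    trials.to_frame().to_csv(Path(path), sep="\t", index=False,
                             na_rep="n/a", float_format="%.4f")


def load_events(path: str | Path, scan_id: str = "") -> TrialTable:
    df = pd.read_csv(Path(path), sep="\t", na_values=["n/a"])
    rt_ms = df["response_time"].to_numpy(dtype=float) * 1000.0
    return TrialTable(onsets=df["onset"].to_numpy(dtype=float),
                      responded=np.isfinite(rt_ms), rt=rt_ms, scan_id=scan_id)


def save_eeg(eeg: EEGRecording, path: str | Path) -> None:
    """Gzipped TSV, one column per channel, with a JSON sidecar."""
    path = Path(path)
    pd.DataFrame(eeg.samples.T, columns=eeg.channel_names).to_csv(
        path, sep="\t", index=False, compression="gzip", float_format="%.5g")
    _sidecar(path).write_text(json.dumps(
        {"sampling_rate_hz": eeg.fs, "channels": eeg.channel_names}))


def load_eeg(path: str | Path) -> EEGRecording:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    df = pd.read_csv(path, sep="\t", compression="gzip")
    return EEGRecording(samples=df.to_numpy(dtype=float).T,
                        fs=meta["sampling_rate_hz"],
                        channel_names=meta["channels"])


def save_physio(physio: PhysioSignals, path: str | Path) -> None:
    path = Path(path)
    n = max(physio.resp.size, physio.ppg.size)
    resp = np.full(n, np.nan)
    ppg = np.full(n, np.nan)
    resp[:physio.resp.size] = physio.resp
    ppg[:physio.ppg.size] = physio.ppg
    pd.DataFrame({"respiration": resp, "ppg": ppg}).to_csv(
        path, sep="\t", index=False, compression="gzip", float_format="%.5g")
    _sidecar(path).write_text(json.dumps(
        {"fs_resp_hz": physio.fs_resp, "fs_ppg_hz": physio.fs_ppg}))


def load_physio(path: str | Path) -> PhysioSignals:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    df = pd.read_csv(path, sep="\t", compression="gzip")
    return PhysioSignals(resp=df["respiration"].dropna().to_numpy(dtype=float),
                         fs_resp=meta["fs_resp_hz"],
                         ppg=df["ppg"].dropna().to_numpy(dtype=float),
                         fs_ppg=meta["fs_ppg_hz"])


def _sidecar(path: Path) -> Path:
    name = path.name
    for ext in (".tsv.gz", ".tsv"):
        if name.endswith(ext):
            return path.with_name(name[:-len(ext)] + ".json")
    return path.with_suffix(".json")


def save_world(world, out_dir: str | Path) -> None:
    """Write all members of a synthetic world under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = world.scan.scan_id or "scan"
    save_scan(world.scan, out / f"{sid}_bold.nii.gz")
    save_template_volume(world.true_template, out / "true_template.nii.gz")
    save_eeg(world.eeg, out / f"{sid}_eeg.tsv.gz")
    if world.trials is not None:
        save_events(world.trials, out / f"{sid}_events.tsv")
    if world.physio is not None:
        save_physio(world.physio, out / f"{sid}_physio.tsv.gz")
    (out / f"{sid}_params.json").write_text(
        json.dumps({k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in world.params.items()}, indent=2))
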