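"""File formats and configuration: EDF recordings, manifests, lead fields,
truth tensors and the validated pipeline configuration.

Recordings are exchanged as plain EDF (written by the minimal 16-bit writer
here, read back through MNE) or as delimited numeric matrices with a JSON
sidecar carrying the sampling rate and channel labels. All tabular outputs
are TSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preproc import SensorRecording
from .synth import LeadField

__all__ = [
    "write_edf",
    "read_recording",
    "write_manifest",
    "read_manifest",
    "save_truth_coeffs",
    "load_truth_coeffs",
    "save_leadfield",
    "load_leadfield",
    "PipelineConfig",
]


def _edf_field(value, width: int) -> bytes:
    b = str(value).encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(path: str | Path, recording: SensorRecording,
              physical_max: float | None = None) -> Path:
    """Write a recording as plain EDF (16-bit, 1 s data records, unit uV).

    The signal is quantized to the symmetric physical range
    [-physical_max, physical_max] (default: max |amplitude| rounded up)
    with the EDF-standard affine digital mapping onto [-32768, 32767]; the
    quantization step is 2*physical_max / 65535 per count.
    """
    path = Path(path)
    data = recording.data
    n_ch, n_samp = data.shape
    fs = recording.fs_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1 s record
    n_rec = int(np.ceil(n_samp / spr))
    if physical_max is None:
        physical_max = float(np.ceil(np.abs(data).max() + 1e-9))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = data
    step = 2.0 * physical_max / 65535.0
    dig = np.clip(np.round((padded + physical_max) / step) - 32768,
                  -32768, 32767).astype("<i2")
    hdr = b""
    hdr += _edf_field("0", 8)
    hdr += _edf_field("X X X X", 80)
    hdr += _edf_field("Startdate 01-JAN-2020 X X X", 80)
    hdr += _edf_field("01.01.20", 8) + _edf_field("00.00.00", 8)
    hdr += _edf_field(256 * (1 + n_ch), 8) + _edf_field("", 44)
    hdr += _edf_field(n_rec, 8) + _edf_field(1, 8) + _edf_field(n_ch, 4)
    for vals, width in (
        (recording.channel_labels, 16),
        ([""] * n_ch, 80),
        (["uV"] * n_ch, 8),
        ([f"{-physical_max:g}"] * n_ch, 8),
        ([f"{physical_max:g}"] * n_ch, 8),
        (["-32768"] * n_ch, 8),
        (["32767"] * n_ch, 8),
        ([""] * n_ch, 80),
        ([spr] * n_ch, 8),
        ([""] * n_ch, 32),
    ):
        hdr += b"".join(_edf_field(v, width) for v in vals)
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            fh.write(dig[:, r * spr : (r + 1) * spr].tobytes())
    return path


def read_recording(path: str | Path) -> SensorRecording:
    """Read an EDF/EDF+ file or a delimited matrix with a JSON sidecar.

    Delimited input ``x.tsv`` expects ``x.json`` beside it with at least
    ``{"fs_hz": ...}`` and optionally ``"channel_labels"``; rows are
    channels. EDF is read through MNE and rescaled to uV.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        data = raw.get_data() * 1e6  # MNE returns Volts for uV-dimension EDF
        return SensorRecording(data=data, fs_hz=float(raw.info["sfreq"]),
                               channel_labels=list(raw.ch_names))
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"delimited recording {path} needs a sidecar {sidecar.name} "
            f"with fs_hz (and optionally channel_labels)"
        )
    meta = json.loads(sidecar.read_text())
    if "fs_hz" not in meta:
        raise ValueError(f"sidecar {sidecar} lacks required key 'fs_hz'")
    data = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    labels = meta.get("channel_labels",
                      [f"E{k + 1:03d}" for k in range(data.shape[0])])
    return SensorRecording(data=data, fs_hz=float(meta["fs_hz"]),
                           channel_labels=list(labels))


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    required = {"patient_id", "group", "soz_region", "recording_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    if df["patient_id"].duplicated().any():
        raise ValueError("manifest patient ids must be unique")
    df.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df["patient_id"].duplicated().any():
        raise ValueError("manifest patient ids must be unique")
    bad = set(df["group"]) - {"seizure_free", "non_seizure_free"}
    if bad:
        raise ValueError(f"unknown group labels in manifest: {sorted(bad)}")
    return df


def save_truth_coeffs(path: str | Path, coeffs: np.ndarray) -> None:
    """Store a (p, n, n) coefficient tensor as delimited text (lag-stacked)."""
    p, n, _ = coeffs.shape
    header = f"order={p} n_channels={n}; rows = lag-stacked coefficient matrices"
    np.savetxt(path, coeffs.reshape(p * n, n), delimiter="\t", header=header)


def load_truth_coeffs(path: str | Path) -> np.ndarray:
    with open(path) as fh:
        header = fh.readline()
    p = int(header.split("order=")[1].split()[0])
    flat = np.loadtxt(path, delimiter="\t")
    n = flat.shape[1]
    return flat.reshape(p, n, n)


def save_leadfield(path: str | Path, lf: LeadField) -> None:
    path = Path(path)
    np.savetxt(path, lf.gain, delimiter="\t")
    side = pd.DataFrame({
        "source_idx": np.arange(lf.gain.shape[1]),
        "macro_region": lf.source_region_map,
        "sign": lf.source_signs,
    })
    side.to_csv(path.with_suffix(".map.tsv"), sep="\t", index=False)


def load_leadfield(path: str | Path) -> LeadField:
    path = Path(path)
    gain = np.loadtxt(path, delimiter="\t")
    side = pd.read_csv(path.with_suffix(".map.tsv"), sep="\t")
    return LeadField(gain=gain,
                     source_region_map=side["macro_region"].to_numpy(),
                     source_signs=side["sign"].to_numpy(dtype=float))


@dataclass
class PipelineConfig:
    """Every tunable of the analysis chain, with the documented defaults."""

    highpass_hz: float = 0.5
    bad_channel_z: float = 4.0
    ica_corr_thresh: float = 0.7
    ica_max_components: int = 20
    n_epochs: int = 10
    epoch_s: float = 5.0
    mvar_order: int = 40
    analysis_fs_hz: float = 250.0  # decimate to this rate before MVAR
    literal_fs: bool = False  # fit at the native rate, as printed
    pdc_variant: str = "pdc"  # pdc | gpdc | sq
    freq_lo: float = 0.5
    freq_hi: float = 45.0
    freq_step: float = 0.5
    graph_density: float = 0.15
    lambda_reg: float | None = None  # None -> SNR-3 default
    depth_gamma: float = 0.5
    seed: int = 0
    bands: dict = field(default_factory=lambda: {
        "delta": [1.0, 4.0], "theta": [5.0, 8.0],
        "alpha": [9.0, 12.0], "beta": [13.0, 30.0]})

    def __post_init__(self) -> None:
        if self.pdc_variant not in ("pdc", "gpdc", "sq"):
            raise ValueError("pdc_variant must be pdc, gpdc or sq")
        if not (0 < self.graph_density <= 1):
            raise ValueError("graph_density must lie in (0, 1]")
        if self.mvar_order < 1:
            raise ValueError("mvar_order must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
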