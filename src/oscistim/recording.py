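"""Multichannel recording container and on-disk trial formats.

The central in-memory object is :class:`RawRecording`, a thin channels x
samples container used for both synthetic and EDF-derived ECoG. Trials are
exchanged on disk as a directory holding one ``.npy`` array per recording
plus a JSON sidecar with sample rate, labels, layout, onsets and any
ground-truth metadata. EDF input is read through :mod:`mne`; EDF output is
optional and requires an mne export backend.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np


@dataclass
class ElectrodeLayout:
    """Planar electrode grid geometry.

    Parameters
    ----------
    positions : (n_channels, 2) array
        Electrode coordinates in millimetres.
    labels : list of str
        Channel identifiers, one per electrode.
    stim_pair : (int, int) or None
        Indices of the two adjacent electrodes used for stimulation;
        ``None`` when the grid is too small to define a pair.
    spacing : float
        Nominal inter-electrode distance in mm.
    """

    positions: np.ndarray
    labels: list[str]
    stim_pair: Optional[tuple[int, int]] = None
    spacing: float = 10.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")
        if len(self.labels) != len(self.positions):
            raise ValueError("labels and positions length mismatch")
        if self.stim_pair is not None:
            i, j = self.stim_pair
            n = len(self.labels)
            if i == j or not (0 <= i < n and 0 <= j < n):
                raise ValueError("stim_pair indices must be distinct and in range")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def stim_midpoint(self) -> np.ndarray:
        """Midpoint of the stimulation pair, in mm."""
        if self.stim_pair is None:
            raise ValueError("layout has no stimulation pair")
        i, j = self.stim_pair
        return 0.5 * (self.positions[i] + self.positions[j])

    def distances_to_stim(self) -> np.ndarray:
        """Euclidean distance of every electrode to the stim-pair midpoint."""
        mid = self.stim_midpoint()
        return np.linalg.norm(self.positions - mid[None, :], axis=1)

    def to_dict(self) -> dict:
        return {
            "positions": self.positions.tolist(),
            "labels": list(self.labels),
            "stim_pair": list(self.stim_pair) if self.stim_pair is not None else None,
            "spacing": self.spacing,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ElectrodeLayout":
        pair = d.get("stim_pair")
        return cls(
            positions=np.asarray(d["positions"], dtype=float),
            labels=list(d["labels"]),
            stim_pair=tuple(pair) if pair is not None else None,
            spacing=float(d.get("spacing", 10.0)),
        )


@dataclass
class RawRecording:
    """Channels x samples recording with stimulation-trial annotations.

    ``data`` is arbitrary-unit field potential, ``trial_onsets`` holds the
    sample index at which each stimulation train starts.
    """

    data: np.ndarray
    sample_rate: float
    channel_labels: list[str] = field(default_factory=list)
    layout: Optional[ElectrodeLayout] = None
    trial_onsets: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:03d}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match channel count")
        self.trial_onsets = np.asarray(self.trial_onsets, dtype=int)
        if self.trial_onsets.size and (
            self.trial_onsets.min() < 0 or self.trial_onsets.max() >= self.n_samples
        ):
            raise ValueError("trial onsets out of range")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def copy_with(self, data: np.ndarray) -> "RawRecording":
        """New recording with the same annotations but different samples."""
        return replace(self, data=np.asarray(data, dtype=float))


def save_trial_dir(
    path: str | Path,
    recordings: dict[str, RawRecording],
    meta: Optional[dict] = None,
) -> Path:
    """Write recordings as ``<name>.npy`` arrays plus a JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ref = next(iter(recordings.values()))
    sidecar: dict = {
        "sample_rate": ref.sample_rate,
        "channel_labels": ref.channel_labels,
        "trial_onsets": ref.trial_onsets.tolist(),
        "layout": ref.layout.to_dict() if ref.layout is not None else None,
        "arrays": sorted(recordings),
        "meta": meta or {},
    }
    for name, rec in recordings.items():
        np.save(path / f"{name}.npy", rec.data)
    (path / "trial.json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_trial_dir(path: str | Path) -> tuple[dict[str, RawRecording], dict]:
    """Inverse of :func:`save_trial_dir`; returns (recordings, meta)."""
    path = Path(path)
    sidecar = json.loads((path / "trial.json").read_text())
    layout = (
        ElectrodeLayout.from_dict(sidecar["layout"])
        if sidecar.get("layout")
        else None
    )
    recs = {}
    for name in sidecar["arrays"]:
        recs[name] = RawRecording(
            data=np.load(path / f"{name}.npy"),
            sample_rate=sidecar["sample_rate"],
            channel_labels=list(sidecar["channel_labels"]),
            layout=layout,
            trial_onsets=np.asarray(sidecar["trial_onsets"], dtype=int),
        )
    return recs, sidecar.get("meta", {})


def read_edf(path: str | Path) -> RawRecording:
    """Read an EDF file into a :class:`RawRecording` via mne.

    Stimulation-onset annotations (any annotation whose description
    contains ``"stim"``, case-insensitive) become ``trial_onsets``.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    sfreq = float(raw.info["sfreq"])
    onsets = [
        int(round(ann["onset"] * sfreq))
        for ann in raw.annotations
        if "stim" in str(ann["description"]).lower()
    ]
    return RawRecording(
        data=raw.get_data(),
        sample_rate=sfreq,
        channel_labels=list(raw.ch_names),
        trial_onsets=np.asarray(onsets, dtype=int),
    )


def write_edf(path: str | Path, rec: RawRecording) -> None:
    """Export a recording to EDF (requires an mne EDF export backend)."""
    import mne

    info = mne.create_info(rec.channel_labels, rec.sample_rate, ch_types="ecog")
    raw = mne.io.RawArray(rec.data, info, verbose="error")
    if rec.trial_onsets.size:
        onsets = rec.trial_onsets / rec.sample_rate
        raw.set_annotations(
            mne.Annotations(onsets, [0.0] * len(onsets), ["stim_onset"] * len(onsets))
        )
    try:
        raw.export(str(path), fmt="edf", overwrite=True)
    except ImportError as exc:  # pragma: no cover - backend-dependent
        raise ImportError(
            "EDF export requires the 'edfio' backend; install it or use "
            "save_trial_dir for the internal array+JSON format"
        ) from exc
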