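"""Data model and I/O for synchronized EEG/EMG recordings.

The central container is :class:`Recording` — a channels × samples matrix in
microvolts with a sampling rate, per-channel metadata, and stimulus-onset
event markers.  Region-of-interest electrode sets (:class:`ROIMap`) follow the
four sensorimotor regions used in task-based corticomuscular coherence work:
premotor cortex (PMC), primary motor cortex (M1), parietal (Pr) and the
midline supplementary motor area (SMA).

Two on-disk formats are supported: EDF (read through MNE; written by a
minimal 16-bit writer with a JSON sidecar for events and subject metadata)
and a generic matrix-plus-JSON-header layout (``.npy`` or TSV matrix).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Modality",
    "Muscle",
    "Side",
    "ChannelInfo",
    "Recording",
    "ROIMap",
    "SubjectCovariates",
    "FormatError",
    "ValidationError",
    "default_exclusion_list",
    "default_adjacency",
    "load_roi_map",
    "read_recording",
    "write_recording",
    "write_cmc_table",
    "read_cmc_table",
    "N_RETAINED_EEG",
    "MUSCLE_ABBREV",
]

#: EEG channels retained after removing the cheek/neck ring from a
#: 256-electrode geodesic net.
N_RETAINED_EEG = 194


class FormatError(ValueError):
    """A file could not be parsed as the declared format."""


class ValidationError(ValueError):
    """Parsed content violates a Recording/ROIMap invariant."""


class Modality(str, Enum):
    EEG = "EEG"
    EMG = "EMG"


class Muscle(str, Enum):
    extensor_digitorum = "extensor_digitorum"
    flexor_digitorum = "flexor_digitorum"
    FDI = "FDI"
    biceps_brachii = "biceps_brachii"


class Side(str, Enum):
    left = "left"
    right = "right"
    midline = "midline"


#: Abbreviations used in default EMG channel labels ``EMG_<abbrev>_<L|R>``.
MUSCLE_ABBREV = {
    Muscle.extensor_digitorum: "ED",
    Muscle.flexor_digitorum: "FD",
    Muscle.FDI: "FDI",
    Muscle.biceps_brachii: "BB",
}
_ABBREV_MUSCLE = {v: k for k, v in MUSCLE_ABBREV.items()}


@dataclass(frozen=True)
class ChannelInfo:
    """Metadata for one channel.

    EEG channels carry only a label (e.g. ``"E51"``); EMG channels carry a
    muscle and a body side and are labelled ``EMG_<abbrev>_<L|R>`` by default.
    """

    label: str
    modality: Modality
    muscle: Muscle | None = None
    side: Side | None = None

    def __post_init__(self) -> None:
        if self.modality is Modality.EMG:
            if self.muscle is None or self.side is None:
                raise ValidationError(
                    f"EMG channel {self.label!r} needs a muscle and a side"
                )
            if self.side is Side.midline:
                raise ValidationError("EMG channels cannot be midline")

    @classmethod
    def eeg(cls, label: str) -> "ChannelInfo":
        return cls(label=label, modality=Modality.EEG, side=Side.midline)

    @classmethod
    def emg(cls, muscle: Muscle, side: Side) -> "ChannelInfo":
        suffix = "L" if side is Side.left else "R"
        return cls(
            label=f"EMG_{MUSCLE_ABBREV[muscle]}_{suffix}",
            modality=Modality.EMG,
            muscle=muscle,
            side=side,
        )

    @classmethod
    def from_label(cls, label: str) -> "ChannelInfo":
        """Reconstruct channel metadata from a conventional label."""
        if label.startswith("EMG_"):
            try:
                _, abbrev, lr = label.split("_")
                muscle = _ABBREV_MUSCLE[abbrev]
                side = Side.left if lr == "L" else Side.right
            except (ValueError, KeyError) as exc:
                raise ValidationError(f"unparseable EMG label {label!r}") from exc
            return cls(label=label, modality=Modality.EMG, muscle=muscle, side=side)
        return cls.eeg(label)


@dataclass
class Recording:
    """A synchronized multichannel EEG+EMG recording.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` array in microvolts.
    fs
        Sampling rate in Hz.
    channels
        One :class:`ChannelInfo` per data row.
    events
        ``(sample_index, label)`` stimulus markers; indices are 0-based.
    """

    data: np.ndarray
    fs: float
    channels: list[ChannelInfo]
    events: list[tuple[int, str]] = field(default_factory=list)
    subject_id: str = "S00"
    lesioned_hemisphere: Side = Side.left

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValidationError("data must be 2-D (channels × samples)")
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channels) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channels)} channel entries for {self.data.shape[0]} rows"
            )
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate channel labels")
        n = self.data.shape[1]
        for idx, lab in self.events:
            if not 0 <= idx < n:
                raise ValidationError(
                    f"event {lab!r} at sample {idx} outside [0, {n})"
                )
        if self.lesioned_hemisphere is Side.midline:
            raise ValidationError("lesioned_hemisphere must be left or right")

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channels]

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError as exc:
            raise KeyError(label) from exc

    def picks(self, modality: Modality) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.channels) if c.modality is modality],
            dtype=int,
        )

    def copy(self) -> "Recording":
        return Recording(
            data=self.data.copy(),
            fs=self.fs,
            channels=list(self.channels),
            events=list(self.events),
            subject_id=self.subject_id,
            lesioned_hemisphere=self.lesioned_hemisphere,
        )


_EXPECTED_ROI_SIZES = {"PMC": 9, "M1": 7, "Pr": 18, "SMA": 10}


@dataclass(frozen=True)
class ROIMap:
    """Named cortical region → electrode-label sets per hemisphere.

    PMC, M1 and Pr have paired left/right lists whose *order* defines the
    left↔right electrode correspondence used by hemisphere flipping; SMA is a
    single midline list that maps to itself.
    """

    regions: Mapping[str, Mapping[str, tuple[str, ...]]]

    REGION_NAMES = ("PMC", "M1", "Pr", "SMA")

    def __post_init__(self) -> None:
        missing = [r for r in self.REGION_NAMES if r not in self.regions]
        if missing:
            raise ValidationError(f"ROI map missing region(s): {', '.join(missing)}")
        unknown = [r for r in self.regions if r not in self.REGION_NAMES]
        if unknown:
            raise ValidationError(f"unknown region name(s): {', '.join(unknown)}")
        for name in ("PMC", "M1", "Pr"):
            sides = self.regions[name]
            if set(sides) != {"left", "right"}:
                raise ValidationError(f"{name} must have left and right lists")
            if len(sides["left"]) != len(sides["right"]):
                raise ValidationError(f"{name} left/right lists differ in length")
            if len(sides["left"]) != _EXPECTED_ROI_SIZES[name]:
                raise ValidationError(
                    f"{name} expects {_EXPECTED_ROI_SIZES[name]} electrodes per side"
                )
        if set(self.regions["SMA"]) != {"midline"}:
            raise ValidationError("SMA must be a single midline list")
        if len(self.regions["SMA"]["midline"]) != _EXPECTED_ROI_SIZES["SMA"]:
            raise ValidationError("SMA expects 10 midline electrodes")

    def electrodes(self, region: str, side: str = "left") -> tuple[str, ...]:
        """Electrode labels for ``region`` on ``side`` (SMA ignores side)."""
        if region not in self.regions:
            raise KeyError(region)
        if region == "SMA":
            return tuple(self.regions["SMA"]["midline"])
        return tuple(self.regions[region][side])

    def all_labels(self) -> set[str]:
        return {
            lab
            for sides in self.regions.values()
            for labs in sides.values()
            for lab in labs
        }

    def flip_pairs(self) -> dict[str, str]:
        """Left↔right label mapping (positional pairing; SMA → identity)."""
        pairs: dict[str, str] = {}
        for name in ("PMC", "M1", "Pr"):
            for l, r in zip(self.regions[name]["left"], self.regions[name]["right"]):
                pairs[l] = r
                pairs[r] = l
        for lab in self.regions["SMA"]["midline"]:
            pairs[lab] = lab
        return pairs


@dataclass(frozen=True)
class SubjectCovariates:
    """Per-subject structural and behavioral scalars.

    cst_injury_pct : percent lesion overlap with a corticospinal-tract
        template, 0–100 (higher = more injury).
    fa_cst : fractional anisotropy of the tract, in [0, 1]; may be missing
        (NaN) — diffusion imaging is not always usable.
    uefm : Upper Extremity Fugl-Meyer score, 0–66.
    arat : Action Research Arm Test score, 0–57.
    """

    subject_id: str
    cst_injury_pct: float
    fa_cst: float = float("nan")
    uefm: int | None = None
    arat: int | None = None
    lesion_volume_cc: float | None = None
    lesioned_hemisphere: Side = Side.left

    def __post_init__(self) -> None:
        if not 0.0 <= self.cst_injury_pct <= 100.0:
            raise ValidationError(
                f"cst_injury_pct {self.cst_injury_pct} outside [0, 100]"
            )
        if not np.isnan(self.fa_cst) and not 0.0 <= self.fa_cst <= 1.0:
            raise ValidationError(f"fa_cst {self.fa_cst} outside [0, 1]")
        if self.uefm is not None and not 0 <= self.uefm <= 66:
            raise ValidationError(f"uefm {self.uefm} outside [0, 66]")
        if self.arat is not None and not 0 <= self.arat <= 57:
            raise ValidationError(f"arat {self.arat} outside [0, 57]")


# ---------------------------------------------------------------------------
# packaged configuration
# ---------------------------------------------------------------------------

def _package_json(name: str) -> dict:
    with resources.files("cmcoh.data").joinpath(name).open() as f:
        return json.load(f)


def default_exclusion_list() -> list[str]:
    """The packaged 62-electrode cheek/neck exclusion list.

    Synthetic stand-in: the 62 most inferior electrodes of the standard GSN
    HydroCel 256 montage geometry.  Only the retained count (194) is a hard
    constraint; users with the true acquisition-specific list should pass
    their own.
    """
    return list(_package_json("exclusion_cheek_neck_synthetic.json")["excluded"])


def retained_eeg_labels(exclusion: Iterable[str] | None = None) -> list[str]:
    """E1..E256 minus the exclusion list (packaged default)."""
    excluded = set(default_exclusion_list() if exclusion is None else exclusion)
    labels = [f"E{i}" for i in range(1, 257) if f"E{i}" not in excluded]
    return labels


def default_adjacency() -> dict[str, list[str]]:
    """Packaged Hjorth neighbor graph over the 194 retained electrodes.

    Synthetic stand-in built from standard montage positions (Delaunay
    triangulation of an azimuthal projection, long rim edges pruned).
    """
    return {
        k: list(v)
        for k, v in _package_json("adjacency_synthetic.json")["neighbors"].items()
    }


def load_roi_map(config: str | Path | None = None) -> ROIMap:
    """Load a region-of-interest map; ``None`` loads the built-in default.

    The built-in map lists, per region and hemisphere, the electrodes
    overlying PMC, M1, Pr and (midline) SMA on the 256-channel net.
    """
    if config is None:
        raw = _package_json("roi_map.json")
    else:
        with open(config) as f:
            raw = json.load(f)
    raw = {k: v for k, v in raw.items() if not k.startswith("_")}
    regions = {
        name: {side: tuple(labs) for side, labs in sides.items()}
        for name, sides in raw.items()
    }
    roi = ROIMap(regions=regions)
    retained = set(retained_eeg_labels())
    stray = sorted(roi.all_labels() - retained)
    if stray:
        raise ValidationError(
            f"ROI electrodes not in the retained set: {', '.join(stray)}"
        )
    return roi


# ---------------------------------------------------------------------------
# recording readers / writers
# ---------------------------------------------------------------------------

def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording from disk.

    Parameters
    ----------
    path
        For ``edf``: the ``.edf`` file (a ``<stem>.events.json`` sidecar is
        picked up when present).  For ``matrix+json``: the JSON header file.
    format
        ``"edf"`` or ``"matrix+json"``; inferred from the suffix if omitted.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix+json"
    if format == "edf":
        return _read_edf(path)
    if format == "matrix+json":
        return _read_matrix_json(path)
    raise FormatError(f"unknown format {format!r}")


def write_recording(rec: Recording, path: str | Path, format: str = "edf") -> Path:
    """Write a recording; see :func:`read_recording` for the layouts."""
    path = Path(path)
    if format == "edf":
        _write_edf(rec, path)
    elif format == "matrix+json":
        _write_matrix_json(rec, path)
    else:
        raise FormatError(f"unknown format {format!r}")
    return path


def _sidecar_path(edf_path: Path) -> Path:
    return edf_path.with_suffix(".events.json")


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal EDF writer: one data record per second, 16-bit samples.

    Events, subject id and lesioned hemisphere go to a JSON sidecar rather
    than an EDF+ annotation channel.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_samp = rec.data.shape
    n_rec = int(np.ceil(n_samp / fs))
    padded = np.zeros((n_ch, n_rec * fs))
    padded[:, :n_samp] = rec.data

    # per-channel physical scaling to the full 16-bit range
    pmin = padded.min(axis=1)
    pmax = padded.max(axis=1)
    span = pmax - pmin
    flat = span <= 0
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767

    def _f(x, width):
        s = f"{x}"[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join(
        [
            _f("0", 8),
            _f(f"subject {rec.subject_id}", 80),
            _f(f"lesion {rec.lesioned_hemisphere.value}", 80),
            _f("01.01.00", 8),
            _f("00.00.00", 8),
            _f(str(256 + 256 * n_ch), 8),
            _f("", 44),
            _f(str(n_rec), 8),
            _f("1", 8),  # record duration, seconds
            _f(str(n_ch), 4),
        ]
    )
    labels = [c.label for c in rec.channels]
    fields: list[tuple[list[str], int]] = [
        (labels, 16),
        (["" for _ in labels], 80),  # transducer
        (["uV" for _ in labels], 8),
        ([f"{v:.6g}" for v in pmin], 8),
        ([f"{v:.6g}" for v in pmax], 8),
        ([str(dmin) for _ in labels], 8),
        ([str(dmax) for _ in labels], 8),
        (["" for _ in labels], 80),  # prefiltering
        ([str(fs) for _ in labels], 8),
        (["" for _ in labels], 32),
    ]
    sig_header = b"".join(
        b"".join(_f(v, width) for v in values) for values, width in fields
    )

    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.rint((padded - pmin[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    with open(path, "wb") as f:
        f.write(header)
        f.write(sig_header)
        # record-major layout: all channels' samples for record k, contiguous
        for k in range(n_rec):
            f.write(digital[:, k * fs : (k + 1) * fs].tobytes())

    sidecar = {
        "subject_id": rec.subject_id,
        "lesioned_hemisphere": rec.lesioned_hemisphere.value,
        "n_samples": int(n_samp),
        "events": [[int(i), lab] for i, lab in rec.events],
        "channels": [
            {
                "label": c.label,
                "modality": c.modality.value,
                "muscle": c.muscle.value if c.muscle else None,
                "side": c.side.value if c.side else None,
            }
            for c in rec.channels
        ],
    }
    with open(_sidecar_path(path), "w") as f:
        json.dump(sidecar, f)


def _read_edf(path: Path) -> Recording:
    import mne

    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - mne error text varies
        raise FormatError(f"could not parse {path} as EDF: {exc}") from exc
    data = raw.get_data() * 1e6  # MNE returns volts for uV-typed channels
    fs = float(raw.info["sfreq"])
    labels = list(raw.ch_names)

    sidecar = _sidecar_path(path)
    events: list[tuple[int, str]] = []
    subject_id, lesioned = "S00", Side.left
    channels: list[ChannelInfo]
    if sidecar.exists():
        with open(sidecar) as f:
            meta = json.load(f)
        events = [(int(i), str(lab)) for i, lab in meta.get("events", [])]
        subject_id = meta.get("subject_id", subject_id)
        lesioned = Side(meta.get("lesioned_hemisphere", "left"))
        data = data[:, : int(meta["n_samples"])]  # strip final-record padding
        by_label = {c["label"]: c for c in meta.get("channels", [])}
        channels = []
        for lab in labels:
            c = by_label.get(lab)
            if c is None:
                channels.append(ChannelInfo.from_label(lab))
            else:
                channels.append(
                    ChannelInfo(
                        label=c["label"],
                        modality=Modality(c["modality"]),
                        muscle=Muscle(c["muscle"]) if c["muscle"] else None,
                        side=Side(c["side"]) if c["side"] else None,
                    )
                )
    else:
        channels = [ChannelInfo.from_label(lab) for lab in labels]
    return Recording(
        data=data,
        fs=fs,
        channels=channels,
        events=events,
        subject_id=subject_id,
        lesioned_hemisphere=lesioned,
    )


def _write_matrix_json(rec: Recording, header_path: Path) -> None:
    data_path = header_path.with_suffix(".npy")
    np.save(data_path, rec.data)
    header = {
        "fs": rec.fs,
        "data_file": data_path.name,
        "data_format": "npy",
        "subject_id": rec.subject_id,
        "lesioned_hemisphere": rec.lesioned_hemisphere.value,
        "events": [[int(i), lab] for i, lab in rec.events],
        "channels": [
            {
                "label": c.label,
                "modality": c.modality.value,
                "muscle": c.muscle.value if c.muscle else None,
                "side": c.side.value if c.side else None,
            }
            for c in rec.channels
        ],
    }
    with open(header_path, "w") as f:
        json.dump(header, f)


def _read_matrix_json(header_path: Path) -> Recording:
    if not header_path.exists():
        raise FileNotFoundError(header_path)
    try:
        with open(header_path) as f:
            header = json.load(f)
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed JSON header {header_path}: {exc}") from exc
    for key in ("fs", "data_file", "channels"):
        if key not in header:
            raise FormatError(f"header missing required key {key!r}")
    data_file = header_path.parent / header["data_file"]
    fmt = header.get("data_format", "npy")
    if fmt == "npy":
        data = np.load(data_file)
    elif fmt == "tsv":
        data = np.loadtxt(data_file, delimiter="\t", ndmin=2)
    else:
        raise FormatError(f"unknown data_format {fmt!r}")
    channels = [
        ChannelInfo(
            label=c["label"],
            modality=Modality(c["modality"]),
            muscle=Muscle(c["muscle"]) if c.get("muscle") else None,
            side=Side(c["side"]) if c.get("side") else None,
        )
        for c in header["channels"]
    ]
    return Recording(
        data=data,
        fs=float(header["fs"]),
        channels=channels,
        events=[(int(i), str(lab)) for i, lab in header.get("events", [])],
        subject_id=header.get("subject_id", "S00"),
        lesioned_hemisphere=Side(header.get("lesioned_hemisphere", "left")),
    )


# ---------------------------------------------------------------------------
# tidy CMC tables
# ---------------------------------------------------------------------------

CMC_COLUMNS = ["subject_id", "region", "muscle", "band", "coherence", "n_segments"]


def write_cmc_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a tidy coherence table (one row per subject×region×muscle×band)."""
    path = Path(path)
    missing = [c for c in CMC_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"CMC table missing column(s): {', '.join(missing)}")
    table[CMC_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_cmc_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in CMC_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"CMC table missing column(s): {', '.join(missing)}")
    return df
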