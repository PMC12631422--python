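"""Cross-spectral estimation and corticomuscular coherence (CMC).

Coherence between an EEG signal S1 and an EMG signal S2 is the
magnitude-squared coherence

    Coh(f) = |P_{S1,S2}(f)|^2 / (P_{S1}(f) · P_{S2}(f)),

with cross- and auto-spectral densities estimated by averaging windowed
(cross-)periodograms over L non-overlapping 1-s segments cut from the
post-onset task window of every usable trial.  With 1-s segments the grid
spacing is Δf = 1 Hz, so the three analysis bands — delta 1–3 Hz, low beta
13–19 Hz, high beta 20–30 Hz (inclusive endpoints) — contain exactly 3, 7
and 11 bins.

A region×muscle CMC value is the mean coherence over all EEG–EMG channel
pairs formed by the region's electrodes with that muscle's EMG channel,
averaged over the in-band bins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import (
    MUSCLE_ABBREV,
    Muscle,
    ROIMap,
    Side,
    ValidationError,
)
from .preprocess import EpochSet

__all__ = [
    "BANDS",
    "REGIONS",
    "MUSCLES",
    "SpectralSet",
    "estimate_spectra",
    "msc",
    "band_cmc",
    "cmc_table",
]

logger = logging.getLogger(__name__)

#: Analysis bands, Hz, inclusive endpoints on the 1-Hz grid.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.0),
    "low_beta": (13.0, 19.0),
    "high_beta": (20.0, 30.0),
}
REGIONS = ("PMC", "M1", "Pr", "SMA")
MUSCLES = tuple(Muscle)


@dataclass
class SpectralSet:
    """Averaged auto- and cross-spectra on a common frequency grid.

    ``auto`` maps channel label → real spectrum; ``cross`` maps an
    (eeg_label, emg_label) pair → complex cross-spectrum.  ``L`` is the
    number of averaged segments.
    """

    freqs: np.ndarray
    auto: dict[str, np.ndarray]
    cross: dict[tuple[str, str], np.ndarray]
    L: int

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValidationError("coherence needs at least 2 averaged segments")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def estimate_spectra(
    epochs: EpochSet,
    pairs: list[tuple[str, str]],
    segment_s: float = 1.0,
    task_window_ms: tuple[float, float] = (0.0, 4000.0),
    window: str = "hann",
) -> SpectralSet:
    """Welch-style averaged spectra over task-window segments of all epochs.

    Each epoch's ``task_window_ms`` (relative to stimulus onset) is cut into
    non-overlapping ``segment_s`` pieces; every piece contributes one tapered
    periodogram / cross-periodogram, and spectra are averaged across all
    pieces of all epochs.
    """
    fs = epochs.fs
    nper = int(round(segment_s * fs))
    if abs(nper - segment_s * fs) > 1e-9:
        raise ValidationError("segment_s × fs must be an integer sample count")
    t0, t1 = task_window_ms
    if t0 < -epochs.pre_ms or t1 > epochs.post_ms or t1 <= t0:
        raise ValidationError("task window outside the epoch window")
    a = int(round((t0 + epochs.pre_ms) * fs / 1000.0))
    b = int(round((t1 + epochs.pre_ms) * fs / 1000.0))
    n_seg_per_epoch = (b - a) // nper
    L = n_seg_per_epoch * epochs.n_epochs
    if L < 2:
        raise ValidationError(f"only {L} segments available; need ≥ 2")

    labels_needed = sorted({lab for p in pairs for lab in p})
    rows = {lab: epochs.channel_index(lab) for lab in labels_needed}

    from scipy.signal import get_window

    win = get_window(window, nper) if window != "boxcar" else np.ones(nper)
    # density scaling as in Welch's method
    scale = 1.0 / (fs * (win**2).sum())
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)

    # gather all segments: (L, n_needed, nper)
    segs = []
    for e in range(epochs.n_epochs):
        for k in range(n_seg_per_epoch):
            s0 = a + k * nper
            segs.append(epochs.data[e][[rows[lab] for lab in labels_needed], s0 : s0 + nper])
    X = np.stack(segs)  # (L, n_ch, nper)
    X = X - X.mean(axis=-1, keepdims=True)  # per-segment detrend (constant)
    F = np.fft.rfft(X * win, axis=-1)

    # one-sided density: double everything except DC (and Nyquist for even n)
    onesided = np.full(freqs.size, 2.0)
    onesided[0] = 1.0
    if nper % 2 == 0:
        onesided[-1] = 1.0

    col = {lab: i for i, lab in enumerate(labels_needed)}
    auto = {
        lab: (np.abs(F[:, col[lab], :]) ** 2).mean(axis=0) * scale * onesided
        for lab in labels_needed
    }
    cross = {
        (s1, s2): (F[:, col[s1], :] * np.conj(F[:, col[s2], :])).mean(axis=0)
        * scale
        * onesided
        for s1, s2 in pairs
    }
    return SpectralSet(freqs=freqs, auto=auto, cross=cross, L=L)


def msc(spec: SpectralSet, pair: tuple[str, str], f: float | None = None):
    """Magnitude-squared coherence for one channel pair.

    Returns the full coherence spectrum, or the single value at frequency
    ``f`` (nearest grid bin).  Bins where either auto-spectrum is zero are
    undefined and returned as NaN with a warning.
    """
    s1, s2 = pair
    p11 = spec.auto[s1]
    p22 = spec.auto[s2]
    p12 = spec.cross[pair] if pair in spec.cross else np.conj(spec.cross[(s2, s1)])
    denom = p11 * p22
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(p12) ** 2 / denom
    bad = denom <= 0
    if bad.any():
        warnings.warn(
            f"coherence undefined at {int(bad.sum())} bins (zero auto-spectrum)",
            RuntimeWarning,
            stacklevel=2,
        )
        coh = np.where(bad, np.nan, coh)
    coh = np.clip(coh, 0.0, 1.0)
    if f is None:
        return coh
    return float(coh[int(np.argmin(np.abs(spec.freqs - f)))])


def band_bins(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    idx = np.nonzero((freqs >= lo - 1e-9) & (freqs <= hi + 1e-9))[0]
    if idx.size == 0:
        raise ValidationError(f"no frequency bins inside band {band}")
    return idx


def band_cmc(
    spec: SpectralSet,
    roi_map: ROIMap,
    region: str,
    muscle: Muscle,
    band: tuple[float, float] | str,
    side: str = "left",
    emg_side: Side = Side.right,
) -> float:
    """ROI-level CMC: mean coherence over (ROI electrode × muscle) pairs,
    then mean over in-band bins (inclusive endpoints).

    ``side`` selects the hemisphere's electrode list (ipsilesional = left
    after flipping); ``emg_side`` selects the arm (affected = right).
    """
    if isinstance(band, str):
        band = BANDS[band]
    emg_label = f"EMG_{MUSCLE_ABBREV[muscle]}_{'L' if emg_side is Side.left else 'R'}"
    idx = band_bins(spec.freqs, band)
    vals = []
    for el in roi_map.electrodes(region, side):
        coh = msc(spec, (el, emg_label))
        vals.append(np.nanmean(coh[idx]))
    return float(np.mean(vals))


def cmc_table(
    epochs: EpochSet,
    roi_map: ROIMap,
    segment_s: float = 1.0,
    task_window_ms: tuple[float, float] = (0.0, 4000.0),
    emg_side: Side = Side.right,
    bands: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Complete tidy CMC table for one subject: 4 regions × 4 muscles × 3
    bands = 48 rows, each the ROI-average in-band coherence.

    Expects epochs already flipped to the ipsilesional convention (left
    hemisphere = ipsilesional, right arm = affected).
    """
    if bands is None:
        bands = BANDS
    suffix = "L" if emg_side is Side.left else "R"
    emg_labels = {m: f"EMG_{MUSCLE_ABBREV[m]}_{suffix}" for m in MUSCLES}
    present = set(epochs.labels)
    missing = [lab for lab in emg_labels.values() if lab not in present]
    if missing:
        raise ValidationError(f"EMG channel(s) missing: {', '.join(missing)}")

    pairs = [
        (el, emg)
        for region in REGIONS
        for el in roi_map.electrodes(region, "left")
        for emg in emg_labels.values()
    ]
    # deduplicate while keeping order
    pairs = list(dict.fromkeys(pairs))
    spec = estimate_spectra(
        epochs, pairs, segment_s=segment_s, task_window_ms=task_window_ms
    )
    logger.info("subject %s: L=%d averaged segments", epochs.subject_id, spec.L)

    rows = []
    for region in REGIONS:
        for muscle in MUSCLES:
            for band_name, band in bands.items():
                rows.append(
                    {
                        "subject_id": epochs.subject_id,
                        "region": region,
                        "muscle": muscle.value,
                        "band": band_name,
                        "coherence": band_cmc(
                            spec, roi_map, region, muscle, band, emg_side=emg_side
                        ),
                        "n_segments": spec.L,
                    }
                )
    return pd.DataFrame(rows)
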