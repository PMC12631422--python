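"""Synthetic trial-structured EEG/EMG with analytically known coherence.

Generative model
----------------
A band-limited Gaussian cortical source ``s(t)`` (white noise through the
same zero-phase Butterworth family used in preprocessing) drives the EMG
with gain ``g`` and a pure integer-sample delay; the EMG additionally
carries an *independent* band-limited component (same filter, so the two
components share an identical spectral shape) and white measurement noise.
EEG channels carry the source plus independent broadband noise:

    eeg(t) = s(t) + e(t),            e white, variance σ_e²
    emg(t) = g·s(t−τ) + b(t) + w(t), b band-limited (σ_b²), w white (σ_n²)

Because ``s`` and ``b`` share one filter, the in-band PSD ratio is flat and
the magnitude-squared coherence has a closed form at every frequency bin:

    γ²(f) = g²·φ_s(f)² / [(φ_s(f)+φ_e)·(g²·φ_s(f)+φ_b(f)+φ_n)]

with φ the one-sided PSDs (white: 2σ²/fs; band-limited: σ²·h(f), h the
normalized squared-magnitude-squared filter response).  With σ_e = σ_n = 0
this collapses to γ² = g²σ_s²/(g²σ_s² + σ_b²) independent of frequency.

Cohorts plant a linear structure–function link: per-subject target in-band
coherence is an affine function of the standardized covariate plus Gaussian
perturbation scaled to hit a requested correlation ρ*.  Percent
corticospinal-tract injury is drawn from a bimodal mixture (a mild-moderate
component on [0, 50] and a severe component on [75, 100]); tract FA from a
truncated normal on [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal

from .core_io import (
    ChannelInfo,
    Muscle,
    Recording,
    ROIMap,
    Side,
    SubjectCovariates,
    ValidationError,
    load_roi_map,
    retained_eeg_labels,
)

__all__ = [
    "CouplingSpec",
    "CohortSpec",
    "generate_trial_pair",
    "generate_subject_recording",
    "generate_cohort",
    "generate_cohort_frame",
]


@lru_cache(maxsize=32)
def _filter_response(band: tuple[float, float], fs: float, order: int):
    """One-sided normalized band-shape h(f) on a dense grid, and its
    equivalent power bandwidth.

    Forward-backward filtering applies |H|² in magnitude, so the PSD shape
    is |H|⁴.  ``h`` is scaled so a unit-variance band-limited process has
    PSD σ²·h(f):  ∫ h df = 1 over [0, fs/2].
    """
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    freqs = np.linspace(0.0, fs / 2, 4097)
    _, H = signal.sosfreqz(sos, worN=freqs, fs=fs)
    shape = np.abs(H) ** 4
    area = np.trapezoid(shape, freqs)
    return freqs, shape / area


def _band_shape_at(f, band, fs, order):
    freqs, h = _filter_response(tuple(band), float(fs), int(order))
    return np.interp(np.atleast_1d(f).astype(float), freqs, h)


@dataclass(frozen=True)
class CouplingSpec:
    """Parameters of one coupled EEG–EMG source.

    band : (low, high) Hz of the coupled rhythm.
    gain : source→EMG gain g ≥ 0 (g = 0 means no coupling).
    delay_ms : corticomuscular conduction delay, integer-sample at fs.
    source_power : σ_s², variance of the band-limited source.
    emg_band_power : σ_b², variance of the independent band-limited EMG
        component (same spectral shape as the source).
    emg_noise_power : σ_n², variance of white EMG measurement noise.
    eeg_noise_power : σ_e², variance of white EEG sensor noise.
    """

    band: tuple[float, float] = (13.0, 19.0)
    gain: float = 1.0
    delay_ms: float = 10.0
    source_power: float = 1.0
    emg_band_power: float = 1.0
    emg_noise_power: float = 0.0
    eeg_noise_power: float = 0.0
    filter_order: int = 4

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValidationError(f"bad band {self.band}")
        if self.gain < 0 or self.delay_ms < 0:
            raise ValidationError("gain and delay must be ≥ 0")
        for name in ("source_power", "emg_band_power", "emg_noise_power", "eeg_noise_power"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be ≥ 0")

    def coherence_at(self, f, fs: float = 1000.0) -> np.ndarray:
        """Closed-form magnitude-squared coherence at frequency ``f``."""
        h = _band_shape_at(f, self.band, fs, self.filter_order)
        phi_s = self.source_power * h
        phi_b = self.emg_band_power * h
        phi_e = 2.0 * self.eeg_noise_power / fs
        phi_n = 2.0 * self.emg_noise_power / fs
        g2 = self.gain**2
        num = g2 * phi_s**2
        den = (phi_s + phi_e) * (g2 * phi_s + phi_b + phi_n)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        return out

    def expected_coherence(self, fs: float = 1000.0, band=None) -> float:
        """Band-average closed-form coherence over the inclusive 1-Hz bins.

        This is the quantity the pipeline's ROI×band CMC estimates.
        """
        lo, hi = self.band if band is None else band
        bins = np.arange(np.ceil(lo - 1e-9), np.floor(hi + 1e-9) + 1)
        return float(np.mean(self.coherence_at(bins, fs=fs)))

    @classmethod
    def for_target_coherence(
        cls,
        gamma2: float,
        band: tuple[float, float] = (13.0, 19.0),
        fs: float = 1000.0,
        delay_ms: float = 10.0,
        emg_noise_power: float = 0.0,
        eeg_noise_power: float = 0.0,
        filter_order: int = 4,
    ) -> "CouplingSpec":
        """Solve for the gain that yields in-band coherence ``gamma2`` at the
        band-shape plateau, given unit source and band-noise powers."""
        if not 0 <= gamma2 < 1:
            raise ValidationError("target coherence must be in [0, 1)")
        if gamma2 == 0:
            return cls(
                band=band,
                gain=0.0,
                delay_ms=delay_ms,
                emg_noise_power=emg_noise_power,
                eeg_noise_power=eeg_noise_power,
                filter_order=filter_order,
            )
        mid = 0.5 * (band[0] + band[1])
        h = float(_band_shape_at(mid, band, fs, filter_order)[0])
        phi_s = 1.0 * h
        phi_b = 1.0 * h
        phi_e = 2.0 * eeg_noise_power / fs
        phi_n = 2.0 * emg_noise_power / fs
        den = phi_s**2 - gamma2 * (phi_s + phi_e) * phi_s
        if den <= 0:
            raise ValidationError(
                f"coherence {gamma2} infeasible with eeg_noise_power={eeg_noise_power}"
            )
        g2 = gamma2 * (phi_s + phi_e) * (phi_b + phi_n) / den
        return cls(
            band=band,
            gain=float(np.sqrt(g2)),
            delay_ms=delay_ms,
            emg_noise_power=emg_noise_power,
            eeg_noise_power=eeg_noise_power,
            filter_order=filter_order,
        )


def _band_noise(rng, n: int, fs: float, band, power: float, order: int) -> np.ndarray:
    """Band-limited Gaussian noise with expected variance ``power``.

    White noise is zero-phase filtered; the deterministic normalization uses
    the filter's power gain so the scaling never adapts to the realization.
    """
    if power == 0:
        return np.zeros(n)
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    freqs, h = _filter_response(tuple(band), float(fs), int(order))
    # variance gain of filtfilt on unit white noise: (2/fs)·∫|H|⁴ df
    area = np.trapezoid(np.abs(signal.sosfreqz(sos, worN=freqs, fs=fs)[1]) ** 4, freqs)
    gain_var = 2.0 * area / fs
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x * np.sqrt(power / gain_var)


def generate_trial_pair(
    spec: CouplingSpec,
    fs: float = 1000.0,
    trial_s: float = 5.0,
    seed: int | np.random.Generator = 0,
):
    """One coupled (eeg, emg) trace pair of length ``trial_s`` seconds."""
    if fs < 2 * spec.band[1]:
        raise ValidationError(
            f"fs={fs} violates Nyquist for band upper edge {spec.band[1]} Hz"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(trial_s * fs))
    if n <= 0:
        raise ValidationError("trial_s must be positive")
    pad = int(round(fs))  # absorb filter transients and the delay
    d = int(round(spec.delay_ms * fs / 1000.0))
    src = _band_noise(
        rng, n + 2 * pad, fs, spec.band, spec.source_power, spec.filter_order
    )
    eeg = src[pad : pad + n].copy()
    if spec.eeg_noise_power > 0:
        eeg += np.sqrt(spec.eeg_noise_power) * rng.standard_normal(n)
    emg = spec.gain * src[pad - d : pad - d + n]
    emg = emg + _band_noise(rng, n, fs, spec.band, spec.emg_band_power, spec.filter_order)
    if spec.emg_noise_power > 0:
        emg = emg + np.sqrt(spec.emg_noise_power) * rng.standard_normal(n)
    return eeg - eeg.mean(), emg - emg.mean()


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generative parameters.

    planted_correlation ρ* is the target correlation between the chosen
    covariate and the subject-level in-band coherence γ².  Percent injury is
    bimodal (no mass between the components, as in early-subacute stroke
    cohorts); FA is truncated normal and missing for a fraction of subjects.
    """

    n_subjects: int = 21
    planted_correlation: float = 0.8
    covariate: str = "injury"  # or "integrity"
    injury_mix_weight: float = 11 / 21  # P(mild-moderate component)
    injury_mild: tuple[float, float, float, float] = (13.6, 19.3, 0.0, 50.0)
    injury_severe: tuple[float, float, float, float] = (86.8, 9.9, 75.0, 100.0)
    fa_mean: float = 0.60
    fa_sd: float = 0.08
    fa_missing_rate: float = 4 / 21
    gamma2_mean: float = 0.35
    gamma2_sd: float = 0.12
    gamma2_range: tuple[float, float] = (0.02, 0.90)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.planted_correlation) > 1:
            raise ValidationError("|planted correlation| must be ≤ 1")
        if self.n_subjects < 4:
            raise ValidationError("need at least 4 subjects")
        if self.covariate not in ("injury", "integrity"):
            raise ValidationError("covariate must be 'injury' or 'integrity'")


def _trunc_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 8)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, size - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def draw_covariates(cspec: CohortSpec, rng) -> pd.DataFrame:
    """Per-subject structural/behavioral covariates (no coupling yet)."""
    n = cspec.n_subjects
    mild = rng.random(n) < cspec.injury_mix_weight
    injury = np.where(
        mild,
        _trunc_normal(rng, *cspec.injury_mild, size=n),
        _trunc_normal(rng, *cspec.injury_severe, size=n),
    )
    fa = _trunc_normal(rng, cspec.fa_mean, cspec.fa_sd, 0.0, 1.0, size=n)
    fa[rng.random(n) < cspec.fa_missing_rate] = np.nan
    # behavioral scores loosely anti-correlated with injury, clipped to range
    uefm = np.clip(np.round(62 - 0.12 * injury + rng.normal(0, 6, n)), 0, 66)
    arat = np.clip(np.round(52 - 0.10 * injury + rng.normal(0, 7, n)), 0, 57)
    lesioned = np.where(rng.random(n) < 13 / 21, "right", "left")
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:02d}" for i in range(n)],
            "cst_injury_pct": injury,
            "fa_cst": fa,
            "uefm": uefm.astype(int),
            "arat": arat.astype(int),
            "lesioned_hemisphere": lesioned,
        }
    )


def planted_gamma2(cspec: CohortSpec, cov: pd.DataFrame, rng) -> np.ndarray:
    """Subject-level target coherence linearly linked to the covariate.

    γ²_i = clip(μ + s·(ρ*·z_i + √(1−ρ*²)·η_i)) with z the standardized
    covariate — corr(covariate, γ²) = ρ* in expectation before clipping.
    """
    key = "cst_injury_pct" if cspec.covariate == "injury" else "fa_cst"
    x = cov[key].to_numpy(dtype=float)
    z = np.zeros_like(x)
    ok = ~np.isnan(x)
    z[ok] = (x[ok] - x[ok].mean()) / max(x[ok].std(), 1e-12)
    rho = cspec.planted_correlation
    eta = rng.standard_normal(x.size)
    raw = cspec.gamma2_mean + cspec.gamma2_sd * (
        rho * z + np.sqrt(max(0.0, 1 - rho**2)) * eta
    )
    return np.clip(raw, *cspec.gamma2_range)


_DEFAULT_EMG_SCALE_UV = 40.0
_DEFAULT_EEG_SCALE_UV = 8.0


def generate_subject_recording(
    spec: CouplingSpec,
    n_trials: int = 40,
    fs: float = 1000.0,
    seed: int | np.random.Generator = 0,
    roi_map: ROIMap | None = None,
    target_region: str = "M1",
    target_muscle: Muscle = Muscle.flexor_digitorum,
    lesioned: Side = Side.left,
    trial_s: float = 5.0,
    iti_range: tuple[float, float] = (7.0, 15.0),
    subject_id: str = "S00",
    eeg_background_uv: float = _DEFAULT_EEG_SCALE_UV,
    emg_carrier_band: tuple[float, float] = (60.0, 100.0),
) -> Recording:
    """Full-length recording: 194 EEG + 8 EMG channels, one event per trial.

    The coupled source is injected into the ``target_region`` electrodes of
    the *ipsilesional* hemisphere with a per-electrode spatial profile (so a
    surface Laplacian attenuates but cannot cancel it).  The affected arm's
    ``target_muscle`` EMG is a broadband carrier amplitude-modulated by the
    delayed source (see below), so the coupling survives the pipeline's
    envelope demodulation.  Trials are ``trial_s`` seconds with inter-trial
    intervals uniform on ``iti_range``; both arms' EMG channels are present,
    the unaffected ones amplitude-modulated by independent signals.
    """
    if n_trials < 1:
        raise ValidationError("n_trials must be ≥ 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if roi_map is None:
        roi_map = load_roi_map()
    if fs < 2 * spec.band[1]:
        raise ValidationError("sampling rate violates Nyquist for the coupling band")

    # trial timeline
    lead = 3.0
    onsets = [lead]
    for _ in range(n_trials - 1):
        onsets.append(onsets[-1] + trial_s + rng.uniform(*iti_range))
    duration = onsets[-1] + trial_s + 2.0
    n = int(round(duration * fs))
    onset_samples = [int(round(t * fs)) for t in onsets]

    roi_side = "left" if lesioned is Side.left else "right"
    emg_side = Side.right if lesioned is Side.left else Side.left
    target_labels = roi_map.electrodes(target_region, roi_side)

    # one continuous coupled source; coherence is measured in task windows
    d = int(round(spec.delay_ms * fs / 1000.0))
    pad = int(round(fs))
    src = _band_noise(
        rng, n + 2 * pad, fs, spec.band, spec.source_power, spec.filter_order
    )
    src_now = src[pad : pad + n]
    src_delayed = src[pad - d : pad - d + n]

    eeg_labels = retained_eeg_labels()
    channels = [ChannelInfo.eeg(lab) for lab in eeg_labels]
    data = rng.standard_normal((len(eeg_labels) + 8, n))
    data[: len(eeg_labels)] *= eeg_background_uv
    sigma_e = np.sqrt(spec.eeg_noise_power) if spec.eeg_noise_power > 0 else 0.0
    profile = rng.uniform(0.6, 1.4, size=len(target_labels))
    for lab, w in zip(target_labels, profile):
        i = eeg_labels.index(lab)
        noise = sigma_e * rng.standard_normal(n) if sigma_e else 0.0
        data[i] += _DEFAULT_EEG_SCALE_UV * (w * src_now + noise)

    # Raw surface EMG is a broadband interference pattern whose *amplitude*
    # carries the corticospinal drive; the conditioning chain (bandpass →
    # Hilbert envelope → rectification) demodulates it.  So EMG channels are
    # amplitude-modulated broadband carriers: the affected target muscle is
    # modulated by the delayed cortical source with depth κ = √γ² (monotone
    # in the planted coupling), every other muscle by its own independent
    # band-limited signal.
    kappa = float(np.sqrt(spec.expected_coherence(fs=fs)))
    src_std = max(np.sqrt(spec.source_power), 1e-12)
    row = len(eeg_labels)
    for side in (Side.left, Side.right):
        for muscle in Muscle:
            ch = ChannelInfo.emg(muscle, side)
            channels.append(ch)
            carrier = _band_noise(rng, n, fs, emg_carrier_band, 1.0, spec.filter_order)
            if side is emg_side and muscle is target_muscle:
                drive = src_delayed / src_std
            else:
                drive = _band_noise(rng, n, fs, spec.band, 1.0, spec.filter_order)
            am = np.clip(1.0 + kappa * drive, 0.05, None)
            data[row] = _DEFAULT_EMG_SCALE_UV * (
                am * carrier + 0.2 * rng.standard_normal(n)
            )
            row += 1

    return Recording(
        data=data,
        fs=fs,
        channels=channels,
        events=[(s, "grip_onset") for s in onset_samples],
        subject_id=subject_id,
        lesioned_hemisphere=lesioned,
    )


def generate_cohort(
    cspec: CohortSpec,
    coupling_base: CouplingSpec | None = None,
    n_trials: int = 40,
    fs: float = 1000.0,
    roi_map: ROIMap | None = None,
    target_region: str = "M1",
    target_muscle: Muscle = Muscle.flexor_digitorum,
):
    """Signal-level cohort: recordings + covariates + ground-truth table.

    Each subject's coupling gain is solved from their planted target γ² (the
    cohort-level link to the covariate); the ground-truth table records that
    γ² per subject so pipeline estimates can be checked cell by cell.
    """
    if coupling_base is None:
        coupling_base = CouplingSpec()
    rng = np.random.default_rng(cspec.seed)
    cov = draw_covariates(cspec, rng)
    g2 = planted_gamma2(cspec, cov, rng)

    recordings: list[Recording] = []
    covariates: list[SubjectCovariates] = []
    truth_rows = []
    for i, r in cov.iterrows():
        sub_spec = CouplingSpec.for_target_coherence(
            float(g2[i]),
            band=coupling_base.band,
            fs=fs,
            delay_ms=coupling_base.delay_ms,
            emg_noise_power=coupling_base.emg_noise_power,
            eeg_noise_power=coupling_base.eeg_noise_power,
            filter_order=coupling_base.filter_order,
        )
        lesioned = Side(r["lesioned_hemisphere"])
        recordings.append(
            generate_subject_recording(
                sub_spec,
                n_trials=n_trials,
                fs=fs,
                seed=rng,
                roi_map=roi_map,
                target_region=target_region,
                target_muscle=target_muscle,
                lesioned=lesioned,
                subject_id=str(r["subject_id"]),
            )
        )
        covariates.append(
            SubjectCovariates(
                subject_id=str(r["subject_id"]),
                cst_injury_pct=float(r["cst_injury_pct"]),
                fa_cst=float(r["fa_cst"]),
                uefm=int(r["uefm"]),
                arat=int(r["arat"]),
                lesioned_hemisphere=lesioned,
            )
        )
        truth_rows.append(
            {
                "subject_id": str(r["subject_id"]),
                "region": target_region,
                "muscle": target_muscle.value,
                "band": "low_beta" if coupling_base.band == (13.0, 19.0) else str(coupling_base.band),
                "true_gamma2": float(g2[i]),
                "modulation_depth": float(np.sqrt(sub_spec.expected_coherence(fs=fs))),
            }
        )
    return recordings, covariates, pd.DataFrame(truth_rows)


def generate_cohort_frame(
    n_subjects: int = 21,
    planted: dict[str, float] | None = None,
    n_segments: int = 160,
    covariate: str = "injury",
    cspec: CohortSpec | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Statistics-level cohort: covariates joined to 48 CMC cells directly.

    A fast path for exercising the inferential layer at replicate counts the
    signal-level generator cannot reach.  Null cells draw lognormal values
    around the coherence-estimator bias floor 1/L; planted cells follow the
    covariate link plus estimation noise.  The noise standard deviation is
    the MSC estimator's asymptotic √(2γ²)·(1−γ²)/√L, further divided by
    √(n_bins) for the cell's band because the pipeline averages over the
    band's frequency bins, which are approximately independent (ROI
    electrode pairs share the EMG channel and are spatially correlated, so
    the pair averaging is not credited).

    ``planted`` maps cell ids ``"region:muscle:band"`` → ρ*.  Returns
    (cohort frame, ground-truth table).
    """
    from .spectral import BANDS, MUSCLES, REGIONS  # local import, no cycle

    rng = np.random.default_rng(seed)
    if cspec is None:
        cspec = CohortSpec(
            n_subjects=n_subjects, covariate=covariate, seed=seed
        )
    else:
        cspec = replace(cspec, n_subjects=n_subjects, covariate=covariate)
    planted = planted or {}
    cov = draw_covariates(cspec, rng)
    frame = cov.copy()
    bias = 1.0 / n_segments
    n_bins = {name: int(hi - lo) + 1 for name, (lo, hi) in BANDS.items()}
    truth_rows = []
    for region in REGIONS:
        for muscle in MUSCLES:
            for band in BANDS:
                cell = f"{region}:{muscle.value}:{band}"
                if cell in planted:
                    sub = replace(cspec, planted_correlation=planted[cell])
                    g2 = planted_gamma2(sub, cov, rng)
                    sd = (
                        np.sqrt(2 * g2)
                        * (1 - g2)
                        / np.sqrt(n_segments * n_bins[band])
                    )
                    vals = np.clip(g2 + sd * rng.standard_normal(n_subjects) + bias, 0, 1)
                    truth_rows.append(
                        {"cell": cell, "planted_rho": planted[cell], "mean_gamma2": g2.mean()}
                    )
                else:
                    vals = np.exp(rng.normal(np.log(bias), 0.4, size=n_subjects))
                    vals = np.clip(vals, 0, 1)
                frame[cell] = vals
    return frame, pd.DataFrame(truth_rows)
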