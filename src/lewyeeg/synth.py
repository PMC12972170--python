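"""Synthetic resting-state EEG cohorts with ground truth.

The generator emulates the three study groups — cognitively unimpaired
elders (Healthy), Parkinson's disease dementia (PDD) and dementia with Lewy
bodies (DLB) — each split into low/high educational-attainment subgroups
(Edu-/Edu+).  Per-subject spectra follow the canonical resting eyes-closed
shape: a 1/f pink background plus band-limited stochastic oscillators whose
delta/theta support ends at the subject's transition frequency TF and whose
alpha component rises from TF to a peak at the individual alpha frequency
IAF, so the landmark definitions (spectral minimum in 3-8 Hz, peak in
6-14 Hz) recover the generating parameters by construction.

Group-level frequency landmarks and demographic/clinical covariates default
to the study cohort's subgroup means and dispersions (Healthy TF 5.6/5.8 Hz,
IAF 8.9/9.0 Hz; PDD TF 4.5/4.7, IAF 7.2/6.7; DLB TF 4.7/4.8, IAF 7.6/7.0;
sample sizes 27/27, 30/45, 21/29; ages, education years, MMSE, LED, UPDRS
III, disease duration, visual-hallucination and RBD rates as published).

Education modulates alpha source amplitude through a single mechanism: a
per-year slope on log amplitude (positive in Healthy, negative in PDD, zero
in DLB).  Combined with the subgroup education-year distributions this
yields both the binary Edu+/Edu- contrast and the continuous
education-trend regressions.  Sources project to the 30-channel 10-10 scalp
montage through the spherical-head leadfield with radially oriented voxel
dipoles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .forward import LeadField, SourceSpace, ROI_NAMES
from .recording import Recording

GROUPS = ("Healthy", "PDD", "DLB")
EDU_LEVELS = ("low", "high")
RHYTHMS = ("delta", "theta", "alpha", "beta")
DOMAINS = ("language", "visuospatial", "attention", "memory")
UNITS = ("unit_a", "unit_b", "unit_c", "unit_d")


@dataclass
class SubjectProfile:
    subject_id: str
    group: str
    edu: str                      # "low" | "high"
    tf_true: float
    iaf_true: float
    roi_band_amplitude: dict      # (roi, rhythm) -> amplitude (arbitrary units)
    age: float
    sex: str                      # "M" | "F"
    mmse: float
    mmsec: float
    unit: str
    edu_years: float
    led_mg: float | None = None
    updrs3: float | None = None
    duration_y: float | None = None
    vh: bool | None = None
    rbd: bool | None = None
    domain_scores: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.edu not in EDU_LEVELS:
            raise ValueError(f"unknown education level {self.edu!r}")
        if not (3.0 <= self.tf_true < self.iaf_true <= 14.0):
            raise ValueError(
                f"need 3 <= tf ({self.tf_true}) < iaf ({self.iaf_true}) <= 14")
        if any(a < 0 for a in self.roi_band_amplitude.values()):
            raise ValueError("amplitudes must be >= 0")
        if not 0 <= self.mmse <= 30:
            raise ValueError("MMSE must lie in [0, 30]")


@dataclass
class SubgroupSpec:
    """Sampling distributions for one (group, education) cell.

    Location/scale pairs are means and SDs; the published tables report the
    standard error of the mean, converted here via SD = SE * sqrt(N).
    """
    n: int
    tf: tuple                     # (mean, sd)
    iaf: tuple
    edu_years: tuple
    edu_years_range: tuple        # truncation consistent with the median split
    age: tuple
    male_fraction: float
    mmse: tuple
    mmsec: tuple
    led: tuple | None = None
    updrs3: tuple | None = None
    duration: tuple | None = None
    vh_rate: float | None = None
    rbd_rate: float | None = None


def _default_subgroups() -> dict:
    return {
        ("Healthy", "low"): SubgroupSpec(
            n=27, tf=(5.6, 1.04), iaf=(8.9, 1.04), edu_years=(7.0, 3.1),
            edu_years_range=(1.0, 10.0), age=(68.3, 7.8), male_fraction=11 / 27,
            mmse=(28.4, 2.1), mmsec=(27.8, 1.6)),
        ("Healthy", "high"): SubgroupSpec(
            n=27, tf=(5.8, 1.04), iaf=(9.0, 1.04), edu_years=(14.0, 2.6),
            edu_years_range=(10.5, 22.0), age=(70.0, 8.8), male_fraction=14 / 27,
            mmse=(28.6, 2.1), mmsec=(27.3, 1.6)),
        ("PDD", "low"): SubgroupSpec(
            n=30, tf=(4.5, 0.55), iaf=(7.2, 1.10), edu_years=(3.6, 2.2),
            edu_years_range=(1.0, 9.5), age=(71.5, 7.7), male_fraction=25 / 30,
            mmse=(18.1, 3.8), mmsec=(18.1, 3.8), led=(608.3, 416.0),
            updrs3=(39.6, 20.8), duration=(8.3, 7.7), vh_rate=0.53,
            rbd_rate=0.53),
        ("PDD", "high"): SubgroupSpec(
            n=45, tf=(4.7, 0.67), iaf=(6.7, 0.67), edu_years=(10.9, 1.3),
            edu_years_range=(10.0, 22.0), age=(73.3, 5.4), male_fraction=37 / 45,
            mmse=(21.0, 4.7), mmsec=(19.8, 4.7), led=(606.3, 324.0),
            updrs3=(41.3, 20.1), duration=(3.6, 5.4), vh_rate=0.56,
            rbd_rate=0.53),
        ("DLB", "low"): SubgroupSpec(
            n=21, tf=(4.7, 0.92), iaf=(7.6, 1.37), edu_years=(5.0, 2.3),
            edu_years_range=(1.0, 9.5), age=(74.0, 8.2), male_fraction=12 / 21,
            mmse=(19.1, 6.0), mmsec=(18.8, 6.0), led=(261.5, 174.0),
            updrs3=(13.5, 7.3), duration=(1.1, 1.8), vh_rate=0.76,
            rbd_rate=0.75),
        ("DLB", "high"): SubgroupSpec(
            n=29, tf=(4.8, 1.08), iaf=(7.0, 1.08), edu_years=(11.5, 4.0),
            edu_years_range=(10.0, 22.0), age=(75.1, 8.6), male_fraction=23 / 29,
            mmse=(21.6, 4.3), mmsec=(20.2, 4.8), led=(153.5, 118.0),
            updrs3=(15.8, 7.5), duration=(2.3, 2.2), vh_rate=0.62,
            rbd_rate=0.57),
    }


# base source amplitudes per (group kind, rhythm) over the six ROIs
# (frontal, central, parietal, occipital, temporal, limbic): posterior alpha
# dominance in Healthy; patients show reduced alpha and elevated delta/theta
_HEALTHY_AMPS = {
    "delta": (0.35, 0.35, 0.35, 0.35, 0.35, 0.35),
    "theta": (0.30, 0.30, 0.30, 0.30, 0.30, 0.30),
    "alpha": (0.40, 0.50, 0.85, 1.00, 0.70, 0.70),
    "beta": (0.25, 0.30, 0.25, 0.20, 0.25, 0.20),
}
_PATIENT_AMPS = {
    "delta": (0.55, 0.55, 0.55, 0.55, 0.55, 0.55),
    "theta": (0.60, 0.60, 0.60, 0.60, 0.60, 0.60),
    "alpha": (0.22, 0.28, 0.47, 0.55, 0.39, 0.39),
    "beta": (0.20, 0.24, 0.20, 0.16, 0.20, 0.16),
}


@dataclass
class EpochPlan:
    n_epochs: int = 150           # 5 min of 2-s epochs
    epoch_length_s: float = 2.0

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_length_s


@dataclass
class ArtifactConfig:
    blink_rate: float = 0.0
    emg_rate: float = 0.0
    blink_amp_uv: float = 150.0
    emg_amp_uv: float = 25.0
    window_s: float = 2.0

    def __post_init__(self):
        for r in (self.blink_rate, self.emg_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("artifact rates must lie in [0, 1]")


@dataclass
class CohortConfig:
    subgroups: dict = field(default_factory=_default_subgroups)
    base_amplitudes: dict = field(default_factory=lambda: {
        "Healthy": _HEALTHY_AMPS, "PDD": _PATIENT_AMPS, "DLB": _PATIENT_AMPS})
    # one mechanism for the education effect on alpha source amplitude:
    # log-amplitude slope per education year (Healthy +, PDD -, DLB 0);
    # ~0.043/year over the ~7-year Edu+/Edu- gap gives an amplitude ratio of
    # ~1.35, consistent with the published subgroup differences being
    # detectable at the published sample sizes
    edu_alpha_slope_per_year: dict = field(default_factory=lambda: {
        "Healthy": 0.043, "PDD": -0.043, "DLB": 0.0})
    # optional binary override: Edu+ alpha amplitude ratio vs Edu-
    edu_alpha_ratio: dict = field(default_factory=dict)
    subject_amp_sigma: float = 0.20    # lognormal sigma per subject x rhythm
    pink_exponent: float = 1.0
    pink_level: float = 0.5            # incoherent diffuse background
    roi_pink_level: float = 0.25       # coherent per-ROI background
    background_rank: int = 64          # carriers for the diffuse background
    fs: float = 256.0
    epoch_plan: EpochPlan = field(default_factory=EpochPlan)
    sensor_noise_uv: float = 1.5
    signal_scale_uv: float = 0.12      # fixed calibration constant, see docs
    artifact: ArtifactConfig = field(default_factory=ArtifactConfig)
    # attention/executive raw score coupling to log10 alpha amplitude,
    # per (group, edu); the published pattern: positive only in PDD-Edu-
    attention_alpha_coupling: dict = field(default_factory=lambda: {
        ("PDD", "low"): 10.0})
    # domain raw scores: Healthy ~ N(0, 5); patients ~2 healthy SD lower
    domain_score_healthy: tuple = (0.0, 5.0)
    domain_score_patient: tuple = (-10.0, 6.0)

    def __post_init__(self):
        for key, sg in self.subgroups.items():
            if sg.n <= 0:
                raise ValueError(f"subgroup {key} has non-positive size")
            if sg.tf[0] >= sg.iaf[0]:
                raise ValueError(
                    f"subgroup {key}: TF mean {sg.tf[0]} >= IAF mean "
                    f"{sg.iaf[0]} violates TF < IAF ordering")
        if self.sensor_noise_uv < 0 or self.signal_scale_uv <= 0:
            raise ValueError("noise must be >= 0 and signal scale > 0")


# ---------------------------------------------------------------------------
# profile sampling

def _trunc_normal(rng, mean, sd, lo, hi, size=None):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


def generate_profiles(config: CohortConfig, seed: int) -> list[SubjectProfile]:
    """Draw all subject profiles (no EEG synthesis)."""
    rng = np.random.default_rng(seed)
    profiles = []
    for (group, edu), sg in config.subgroups.items():
        group_years_ref = np.mean([
            config.subgroups[(group, e)].edu_years[0] for e in EDU_LEVELS
            if (group, e) in config.subgroups])
        for i in range(sg.n):
            sid = f"{group}-{'Edu-' if edu == 'low' else 'Edu+'}-{i:03d}"
            # truncation keeps the landmarks identifiable by the published
            # rules: TF's delta band must reach the 3 Hz search edge and IAF
            # must leave room for an interior 6-14 Hz peak
            tf = float(_trunc_normal(rng, *sg.tf, 3.5, 7.2))
            iaf = float(_trunc_normal(rng, *sg.iaf, 6.6, 12.5))
            if iaf < tf + 1.5:
                iaf = tf + 1.5
            years = float(_trunc_normal(rng, *sg.edu_years,
                                        *sg.edu_years_range))
            # subject-level multiplicative amplitude variation per rhythm
            mult = {r: float(np.exp(rng.normal(0.0, config.subject_amp_sigma)))
                    for r in RHYTHMS}
            # education -> alpha amplitude mechanism
            if group in config.edu_alpha_ratio:
                alpha_edu = (config.edu_alpha_ratio[group]
                             if edu == "high" else 1.0)
            else:
                slope = config.edu_alpha_slope_per_year.get(group, 0.0)
                alpha_edu = float(np.exp(slope * (years - group_years_ref)))
            base = config.base_amplitudes[group]
            amps = {}
            for r in RHYTHMS:
                for roi, a in zip(ROI_NAMES, base[r]):
                    v = a * mult[r]
                    if r == "alpha":
                        v *= alpha_edu
                    amps[(roi, r)] = v

            healthy_mu, healthy_sd = config.domain_score_healthy
            pat_mu, pat_sd = config.domain_score_patient
            mu, sd = ((healthy_mu, healthy_sd) if group == "Healthy"
                      else (pat_mu, pat_sd))
            dscores = {d: float(rng.normal(mu, sd)) for d in DOMAINS}
            coup = config.attention_alpha_coupling.get((group, edu), 0.0)
            if coup:
                dscores["attention"] += coup * np.log10(alpha_edu * mult["alpha"])

            profiles.append(SubjectProfile(
                subject_id=sid, group=group, edu=edu, tf_true=tf, iaf_true=iaf,
                roi_band_amplitude=amps,
                age=float(_trunc_normal(rng, *sg.age, 45, 95)),
                sex="M" if rng.random() < sg.male_fraction else "F",
                mmse=float(_trunc_normal(rng, *sg.mmse, 0, 30)),
                mmsec=float(_trunc_normal(rng, *sg.mmsec, 0, 30)),
                unit=UNITS[rng.integers(len(UNITS))],
                edu_years=years,
                led_mg=(float(_trunc_normal(rng, *sg.led, 0, 3000))
                        if sg.led else None),
                updrs3=(float(_trunc_normal(rng, *sg.updrs3, 0, 108))
                        if sg.updrs3 else None),
                duration_y=(float(_trunc_normal(rng, *sg.duration, 0.2, 30))
                            if sg.duration else None),
                vh=(bool(rng.random() < sg.vh_rate)
                    if sg.vh_rate is not None else None),
                rbd=(bool(rng.random() < sg.rbd_rate)
                     if sg.rbd_rate is not None else None),
                domain_scores=dscores))
    return profiles


# ---------------------------------------------------------------------------
# signal synthesis

def _shaped_noise(rng, mask: np.ndarray, n_samples: int) -> np.ndarray:
    """Real signal with amplitude spectrum ``mask``, unit RMS.

    Gaussian coefficients are drawn only where the mask is non-zero.
    """
    nz = np.flatnonzero(mask)
    spec = np.zeros(mask.shape, dtype=complex)
    spec[nz] = ((rng.standard_normal(len(nz)) +
                 1j * rng.standard_normal(len(nz))) * mask[nz])
    x = np.fft.irfft(spec, n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def _oscillator_mask(freqs, tf, iaf, rhythm):
    """Amplitude response of one rhythm's band-pass shaping.

    delta/theta end exactly at TF-2 / TF; alpha rises from TF to a peak at
    IAF and falls to zero at IAF+2, so the channel-mean spectrum has its
    3-8 Hz minimum at TF and its 6-14 Hz peak at IAF.
    """
    a = np.zeros_like(freqs)
    if rhythm == "delta":
        # flat band [TF-4, TF-2) with a reduced-amplitude floor extending
        # down to 0.4 Hz, as slow activity does in real spectra; without the
        # floor the region below the delta band would undercut the TF valley
        lo, hi = max(tf - 4.0, 0.4), tf - 2.0
        a[(freqs >= 0.4) & (freqs < lo)] = 0.75
        a[(freqs >= lo) & (freqs < hi)] = 1.0
    elif rhythm == "theta":
        # flat band ending just over one grid bin below TF: the cliff plus
        # the ~1-bin Hann leakage of its edge place the 3-8 Hz power minimum
        # in the grid bin containing TF
        m = (freqs >= tf - 2.0) & (freqs < tf - 0.6)
        a[m] = 1.0
    elif rhythm == "alpha":
        # low-alpha shoulder rising from TF (anchors the minimum at TF
        # against the 1/f decline) plus a peak at IAF; the upper flank
        # broadens as IAF slows, as in patient spectra
        m = (freqs >= tf) & (freqs <= iaf)
        frac = (freqs[m] - tf) / max(iaf - tf, 1e-6)
        a[m] = 0.8 * frac ** 0.25
        a[m] += np.exp(-((freqs[m] - iaf) / 0.9) ** 2)
        right = freqs > iaf
        flank = np.exp(-((freqs[right] - iaf) / 1.2) ** 2)
        if iaf < 7.75:
            # slowed rhythms keep substantial power through 8 Hz instead of
            # dying at IAF+2; the gentle rise toward 8 Hz offsets the 1/f
            # background decline so the 3-8 Hz minimum stays at TF
            fr = freqs[right]
            shelf = np.where(
                fr <= 8.25, 0.55 * (1.0 + 0.4 * (fr - iaf)),
                0.55 * (1.0 + 0.4 * (8.25 - iaf))
                * np.exp(-((fr - 8.25) / 1.0) ** 2))
            flank = np.maximum(flank, shelf)
        a[right] += flank
        a[freqs > max(iaf + 5.0, 11.0)] = 0.0
    elif rhythm == "beta":
        lo, hi = 13.0, 30.0
        m = (freqs >= lo) & (freqs <= hi)
        a[m] = np.sin(np.pi * (freqs[m] - lo) / (hi - lo)) ** 2
    else:
        raise ValueError(f"unknown rhythm {rhythm!r}")
    return a


def simulate_subject(profile: SubjectProfile, leadfield: LeadField,
                     space: SourceSpace, config: CohortConfig,
                     seed: int) -> Recording:
    """Synthesize one subject's sensor-space recording.

    Sensor data are the projection of per-voxel source time series (pink
    background plus ROI-coherent band-limited oscillators with the profile's
    amplitudes, radial dipole orientations) through the leadfield, plus
    spatially white sensor noise.
    """
    missing = [roi for roi, _ in profile.roi_band_amplitude
               if roi not in ROI_NAMES]
    if missing:
        raise ValueError(f"profile references unknown ROIs: {sorted(set(missing))}")
    for roi in {r for r, _ in profile.roi_band_amplitude}:
        if not (space.roi_labels == roi).any():
            raise ValueError(f"leadfield source space lacks ROI {roi!r}")
    if not leadfield.gain.any():
        raise ValueError("zero leadfield")

    rng = np.random.default_rng(seed)
    fs = config.fs
    n_samples = int(round(config.epoch_plan.duration_s * fs))
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)

    # effective per-voxel channel gain for radial orientations
    u = space.coords_mm / np.linalg.norm(space.coords_mm, axis=1,
                                         keepdims=True)
    blocks = leadfield.blocks                       # V x M x 3
    geff = np.einsum("vmk,vk->mv", blocks, u)       # M x V

    pink_mask = np.where((freqs >= 0.4) & (freqs <= 48.0),
                         np.maximum(freqs, 0.4) ** (-config.pink_exponent / 2),
                         0.0)
    # scaling is grid-size invariant: ROI-coherent rhythms mix through the
    # mean voxel gain of their ROI, the incoherent pink background through
    # gains scaled by 1/sqrt(n carriers).  The diffuse background rides on a
    # sampled voxel subset (with replacement), an unbiased stand-in for one
    # independent source per voxel.
    V = space.n_voxels
    sensors = np.zeros((geff.shape[0], n_samples))
    nz = np.flatnonzero(pink_mask)
    K = min(config.background_rank, V)
    carriers = (np.arange(V) if K == V
                else rng.integers(0, V, size=K))
    for start in range(0, K, 256):          # chunked to bound memory
        idx = carriers[start: start + 256]
        nb = len(idx)
        spec = np.zeros((nb, len(freqs)), dtype=complex)
        spec[:, nz] = ((rng.standard_normal((nb, len(nz))) +
                        1j * rng.standard_normal((nb, len(nz))))
                       * pink_mask[nz])
        block = np.fft.irfft(spec, n=n_samples, axis=1)
        block /= block.std(axis=1, keepdims=True)
        sensors += geff[:, idx] @ ((config.pink_level / np.sqrt(K)) * block)

    for roi in ROI_NAMES:
        vm = space.roi_mask(roi)
        h = geff[:, vm].mean(axis=1)                # channel mixing vector
        # coherent regional 1/f background keeps the sensor spectra on the
        # canonical resting shape between the oscillator bands
        sig = config.roi_pink_level * _shaped_noise(rng, pink_mask, n_samples)
        for rhythm in RHYTHMS:
            amp = profile.roi_band_amplitude.get((roi, rhythm), 0.0)
            if amp <= 0:
                continue
            mask = _oscillator_mask(freqs, profile.tf_true, profile.iaf_true,
                                    rhythm)
            if not mask.any():
                continue
            sig += amp * _shaped_noise(rng, mask, n_samples)
        sensors += h[:, None] * sig[None, :]

    data = config.signal_scale_uv * sensors
    if config.sensor_noise_uv > 0:
        data = data + rng.normal(0.0, config.sensor_noise_uv, size=data.shape)
    rec = Recording(profile.subject_id, leadfield.channel_labels, fs, data,
                    provenance="synthetic", ground_truth=profile,
                    meta={"epoch_plan": (config.epoch_plan.n_epochs,
                                         config.epoch_plan.epoch_length_s)})
    if config.artifact.blink_rate > 0 or config.artifact.emg_rate > 0:
        rec = inject_artifacts(rec, config.artifact,
                               int(rng.integers(2 ** 31)))
    return rec


def inject_artifacts(recording: Recording, cfg: ArtifactConfig,
                     seed: int) -> Recording:
    """Contaminate a subset of 2-s windows with blink-like frontal transients
    and/or EMG-like 30-70 Hz bursts; the mask is stored in
    ``recording.meta['artifact_mask']`` as ground truth."""
    rng = np.random.default_rng(seed)
    win = int(round(cfg.window_s * recording.fs))
    n_win = recording.data.shape[1] // win
    blink = rng.random(n_win) < cfg.blink_rate
    emg = rng.random(n_win) < cfg.emg_rate
    if not (blink.any() or emg.any()):
        out = Recording(recording.subject_id, recording.channel_labels,
                        recording.fs, recording.data.copy(),
                        recording.provenance, recording.ground_truth,
                        dict(recording.meta,
                             artifact_mask=(blink | emg).tolist()))
        return out

    data = recording.data.copy()
    labels = [c.upper() for c in recording.channel_labels]
    frontal_w = np.array([
        1.0 if c.startswith("FP") else
        0.5 if c.startswith(("F", "AF")) and not c.startswith(("FT", "FC"))
        else 0.25 if c.startswith(("FT", "FC")) else 0.05 for c in labels])
    emg_w = np.array([
        1.0 if c.startswith(("T", "FT", "TP", "F7", "F8")) else 0.3
        for c in labels])

    t = np.arange(win) / recording.fs
    for w in range(n_win):
        sl = slice(w * win, (w + 1) * win)
        if blink[w]:
            t0 = rng.uniform(0.3, cfg.window_s - 0.3)
            pulse = np.exp(-((t - t0) / 0.12) ** 2)
            data[:, sl] += cfg.blink_amp_uv * frontal_w[:, None] * pulse[None, :]
        if emg[w]:
            freqs = np.fft.rfftfreq(win, 1.0 / recording.fs)
            mask = ((freqs >= 30) & (freqs <= 70)).astype(float)
            burst = _shaped_noise(rng, mask, win)
            data[:, sl] += cfg.emg_amp_uv * emg_w[:, None] * burst[None, :]
    return Recording(recording.subject_id, recording.channel_labels,
                     recording.fs, data, recording.provenance,
                     recording.ground_truth,
                     dict(recording.meta,
                          artifact_mask=(blink | emg).tolist()))


def generate_cohort(config: CohortConfig, seed: int, leadfield: LeadField,
                    space: SourceSpace) -> list[tuple[Recording, SubjectProfile]]:
    """Generate the full cohort: profiles plus simulated recordings.

    Deterministic: identical (config, seed) yields identical cohorts.
    """
    ss = np.random.SeedSequence(seed)
    profile_seed, *subject_seeds = [
        int(s.generate_state(1)[0] % (2 ** 31))
        for s in ss.spawn(1 + sum(sg.n for sg in config.subgroups.values()))]
    profiles = generate_profiles(config, profile_seed)
    out = []
    for prof, sseed in zip(profiles, subject_seeds):
        rec = simulate_subject(prof, leadfield, space, config, sseed)
        out.append((rec, prof))
    return out


# ---------------------------------------------------------------------------
# export

def profiles_frame(profiles) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"subject_id": p.subject_id, "group": p.group, "edu": p.edu,
               "tf_true": p.tf_true, "iaf_true": p.iaf_true, "age": p.age,
               "sex": p.sex, "mmse": p.mmse, "mmsec": p.mmsec, "unit": p.unit,
               "edu_years": p.edu_years, "led_mg": p.led_mg,
               "updrs3": p.updrs3, "duration_y": p.duration_y, "vh": p.vh,
               "rbd": p.rbd}
        for d in DOMAINS:
            row[f"score_{d}"] = p.domain_scores.get(d)
        rows.append(row)
    return pd.DataFrame(rows)


def export_cohort(out_dir, cohort, write_edf_files: bool = True) -> None:
    """Write EDF recordings, a cohort metadata CSV and a ground-truth JSON."""
    from .edf import write_edf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profiles = [p for _, p in cohort]
    profiles_frame(profiles).to_csv(out / "cohort_metadata.csv", index=False)
    truth = {}
    for rec, p in cohort:
        truth[p.subject_id] = {
            "tf_true": p.tf_true, "iaf_true": p.iaf_true,
            "roi_band_amplitude": {f"{roi}:{r}": a for (roi, r), a
                                   in p.roi_band_amplitude.items()},
            "artifact_mask": rec.meta.get("artifact_mask")}
        if write_edf_files:
            write_edf(out / f"{p.subject_id}.edf", rec.data, rec.fs,
                      rec.channel_labels, patient_id=p.subject_id)
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
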