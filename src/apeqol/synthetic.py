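"""Synthetic vowel audio and cohort generator.

Every downstream stage of the pipeline (formant extraction, marker
screening, clinical validation, diagnostics) is exercised against data from
this module, so it encodes the statistical structure the analysis assumes:

* gender-dimorphic corner-vowel formant targets,
* formant centralization that grows with tumour stage and surgical extent,
* a logistic link from the formant centralization ratio (FCR) to the
  probability of a deviated consonant articulation (larger FCR -> more
  misarticulation, with alveolo-palatal consonants worst off),
* Speech Handicap Index (SHI) item scores driven by the same latent
  severity, and
* the bookkeeping of a 33-patient pre/post surgical cohort with one
  post-operative dropout (65 sessions, 97% follow-up).

Audio is produced by a Klatt-style source-filter synthesizer: a jittered
glottal pulse train with vibrato, aspiration noise, and a -6 dB/oct
spectral tilt, passed through cascaded second-order resonators at the
target formants.  Because the resonator frequencies are known exactly, the
synthesizer doubles as the ground-truth oracle for the formant-extraction
module.
"""

from __future__ import annotations

import wave
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "VOWELS",
    "GENDERS",
    "RESECTIONS",
    "AudioClip",
    "FormantTargets",
    "SeverityModel",
    "CohortConfig",
    "Cohort",
    "DEFAULT_TARGETS",
    "synthesize_vowel",
    "centralize",
    "simulate_perception",
    "simulate_shi",
    "simulate_cohort",
    "simulate_screening",
    "write_wav",
]

VOWELS = ("A", "I", "U")
GENDERS = ("male", "female")
RESECTIONS = ("PG", "HG", "STG/TG")  # partial / hemi / subtotal-total glossectomy

#: Audio defaults: consumer-tablet recording conditions.
DEFAULT_RATE = 44_100
DEFAULT_BIT_DEPTH = 16

# Fixed upper vocal-tract resonances (Hz, bandwidth Hz).  Kept well below the
# male analysis band edge (5 kHz) so downsampled LPC analysis sees them.
_UPPER_RESONANCES = ((3500.0, 250.0), (4500.0, 300.0))

# Source model constants: ~1% cycle-to-cycle jitter, 1% vibrato at 5 Hz, and
# a glottal tilt pole of 0.9925 at 44.1 kHz (about -6 dB/oct through the
# speech band, which a 0.97 pre-emphasis zero at a 10-11 kHz analysis rate
# undoes almost exactly).
_JITTER_FRAC = 0.01
_VIBRATO_EXTENT = 0.01
_VIBRATO_HZ = 5.0
_TILT_POLE = 0.9925


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AudioClip:
    """A mono sampled waveform normalized to [-1, 1]."""

    samples: np.ndarray
    rate: int
    bit_depth: int = DEFAULT_BIT_DEPTH
    channels: int = 1

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("AudioClip holds mono audio (1-D samples)")
        if samples.size == 0:
            raise ValueError("empty audio clip")
        if not np.all(np.isfinite(samples)):
            raise ValueError("audio contains NaN/inf")
        if np.max(np.abs(samples)) > 1.0 + 1e-9:
            raise ValueError("samples exceed [-1, 1]")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass(frozen=True)
class FormantTargets:
    """Corner-vowel formant targets (Hz) for one gender.

    ``formants`` maps each vowel in {A, I, U} to (F1, F2); ``bandwidths``
    maps it to (B1, B2).
    """

    gender: str
    formants: Mapping[str, tuple[float, float]]
    bandwidths: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {v: (80.0, 120.0) for v in VOWELS}
    )

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}")
        if set(self.formants) != set(VOWELS):
            raise ValueError(f"formants must cover exactly {VOWELS}")
        for v, (f1, f2) in self.formants.items():
            if f1 <= 0 or f2 <= 0:
                raise ValueError(f"non-positive formant for /{v}/")
            if f2 <= f1:
                raise ValueError(f"F2 must exceed F1 for /{v}/")
            b1, b2 = self.bandwidths[v]
            if b1 <= 0 or b2 <= 0:
                raise ValueError(f"non-positive bandwidth for /{v}/")
        # strict inversion is malformed; equality occurs at full centralization
        if self.formants["I"][1] < self.formants["U"][1]:
            raise ValueError("front vowel /i/ cannot have lower F2 than back vowel /u/")

    def f1(self, vowel: str) -> float:
        return self.formants[vowel][0]

    def f2(self, vowel: str) -> float:
        return self.formants[vowel][1]

    def fcr(self) -> float:
        """The formant centralization ratio implied by the targets."""
        return (self.f2("U") + self.f2("A") + self.f1("I") + self.f1("U")) / (
            self.f2("I") + self.f1("A")
        )


def _scaled(base: Mapping[str, tuple[float, float]], k: float):
    return {v: (round(f1 * k, 1), round(f2 * k, 1)) for v, (f1, f2) in base.items()}


# Male targets: Hillenbrand et al. (1995) adult-male means for /ɑ/, /i/, /u/.
# Female targets: the same values under a uniform 1.14x vocal-tract-length
# scaling, which preserves the (scale-invariant) FCR across gender — the
# property that makes FCR a gender-pooled marker in the first place.
_MALE_FORMANTS = {"A": (768.0, 1333.0), "I": (342.0, 2322.0), "U": (469.0, 1122.0)}

DEFAULT_TARGETS: dict[str, FormantTargets] = {
    "male": FormantTargets("male", _MALE_FORMANTS),
    "female": FormantTargets("female", _scaled(_MALE_FORMANTS, 1.14)),
}

#: Typical sustained-phonation fundamental frequencies (Hz).
DEFAULT_F0 = {"male": 120.0, "female": 190.0}


@dataclass(frozen=True)
class SeverityModel:
    """Maps clinical state to centralization and centralization to outcomes.

    ``lambda_t`` gives the pre-operative centralization weight per T class
    (0 = healthy control); ``lambda_surgery`` is the additional weight each
    resection extent contributes post-operatively.  The perceptual link is
    P(deviated) = logistic(b0 + b1*(FCR - fcr_ref) + group offset); b1 >= 0
    so a larger FCR always means more misarticulation.  The SHI link puts a
    latent total score at ``shi_intercept + shi_slope * FCR`` plus subject
    noise and distributes it over 30 items with item noise.
    """

    lambda_t: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.0, 1: 0.04, 2: 0.09, 3: 0.15, 4: 0.22}
    )
    lambda_surgery: Mapping[str, float] = field(
        default_factory=lambda: {"PG": 0.06, "HG": 0.12, "STG/TG": 0.20}
    )
    lambda_subject_sd: float = 0.02
    # logistic perceptual link
    b0: float = -2.0
    b1: float = 40.0
    fcr_ref: float = 1.07
    group_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"alveolar": 0.0, "alveolo-palatal": 0.7, "velar": -0.4}
    )
    # SHI link (item scale 0-4, 30 items, total 0-120)
    shi_slope: float = 120.0
    shi_intercept: float = -110.0
    shi_subject_sd: float = 6.0
    shi_item_sd: float = 0.6
    # speaker idiosyncrasy: vocal-tract scale and per-formant perturbation
    vtl_sd: float = 0.04
    formant_jitter_sd: float = 0.06

    def __post_init__(self) -> None:
        lams = [self.lambda_t[t] for t in sorted(self.lambda_t)]
        if any(b < a for a, b in zip(lams, lams[1:])):
            raise ValueError("lambda_t must be non-decreasing in T class")
        if not all(0.0 <= l <= 1.0 for l in lams):
            raise ValueError("lambda_t values must lie in [0, 1]")
        if self.b1 < 0:
            raise ValueError("b1 must be >= 0 (P(deviated) non-decreasing in FCR)")

    def lam(self, t_class: int, resection: str | None, timepoint: str) -> float:
        """Deterministic centralization weight for a clinical state."""
        lam = float(self.lambda_t[t_class])
        if timepoint == "post":
            if resection is None:
                raise ValueError("post-operative state requires a resection extent")
            lam += float(self.lambda_surgery[resection])
        return min(lam, 1.0)

    def p_deviated(self, fcr: float, consonant_group: str) -> float:
        z = self.b0 + self.b1 * (fcr - self.fcr_ref) + self.group_offsets[consonant_group]
        return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs for the synthetic validation cohort."""

    n_patients: int = 33
    n_controls: int = 20
    n_dropout: int = 1  # patients lost before the post-op session
    timepoints: tuple[str, ...] = ("pre", "post")
    targets: Mapping[str, FormantTargets] = field(
        default_factory=lambda: dict(DEFAULT_TARGETS)
    )
    severity: SeverityModel = field(default_factory=SeverityModel)
    f0: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_F0))
    f0_sd: float = 8.0
    rate: int = DEFAULT_RATE
    duration: float = 1.0
    noise_level: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_dropout >= self.n_patients:
            raise ValueError("dropout count must be below n_patients")
        if self.duration < 1.0:
            raise ValueError("sustained vowels must last at least one second")
        if self.rate != DEFAULT_RATE:
            raise ValueError("cohort audio is recorded at 44100 Hz")


# ---------------------------------------------------------------------------
# vowel synthesis
# ---------------------------------------------------------------------------

def _resonator_coeffs(rate: float, freq: float, bw: float):
    r = np.exp(-np.pi * bw / rate)
    theta = 2.0 * np.pi * freq / rate
    b0 = 1.0 - 2.0 * r * np.cos(theta) + r * r
    return [b0], [1.0, -2.0 * r * np.cos(theta), r * r]


def synthesize_vowel(
    vowel: str,
    targets: FormantTargets,
    f0: float,
    duration: float = 1.0,
    rate: int = DEFAULT_RATE,
    noise_level: float = 0.05,
    seed: int = 0,
) -> AudioClip:
    """Synthesize a sustained corner vowel with known formants.

    Source: impulse train at ``f0`` with 1% period jitter and 1% vibrato,
    plus aspiration noise at ``noise_level`` (relative RMS, injected before
    the tilt filter so voiced and unvoiced components share one spectral
    envelope).  Filter: glottal tilt, then cascaded resonators at
    (F1, B1), (F2, B2) and two fixed upper resonances.
    """
    if vowel not in VOWELS:
        raise ValueError(f"vowel must be one of {VOWELS}")
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    if duration < 0.25:
        raise ValueError("duration below 0.25 s cannot host a 200-ms analysis frame")
    f1, f2 = targets.formants[vowel]
    b1, b2 = targets.bandwidths[vowel]
    if rate < 2.0 * f2:
        raise ValueError(f"rate {rate} Hz aliases F2 = {f2} Hz")

    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    f0_track = f0 * (1.0 + _VIBRATO_EXTENT * np.sin(2.0 * np.pi * _VIBRATO_HZ * t))
    phase = np.cumsum(2.0 * np.pi * f0_track / rate)
    pulses = np.zeros(n)
    onsets = np.where(np.diff(np.floor(phase / (2.0 * np.pi))) > 0)[0] + 1
    jitter = rng.normal(0.0, _JITTER_FRAC * rate / f0, size=onsets.size)
    onsets = np.clip(onsets + np.round(jitter).astype(int), 0, n - 1)
    pulses[onsets] = 1.0

    x = pulses + rng.normal(0.0, noise_level * np.std(pulses), n)
    x = signal.lfilter([1.0], [1.0, -_TILT_POLE], x)
    for freq, bw in [(f1, b1), (f2, b2), *_UPPER_RESONANCES]:
        bc, ac = _resonator_coeffs(rate, freq, bw)
        x = signal.lfilter(bc, ac, x)
    x = 0.9 * x / np.max(np.abs(x))
    return AudioClip(samples=x, rate=rate, bit_depth=DEFAULT_BIT_DEPTH)


def write_wav(clip: AudioClip, path: str | Path) -> Path:
    """Write a clip as a 16-bit PCM mono WAV file."""
    path = Path(path)
    pcm = np.clip(np.round(clip.samples * 32767.0), -32768, 32767).astype("<i2")
    with wave.open(str(path), "wb") as fh:
        fh.setnchannels(1)
        fh.setsampwidth(2)
        fh.setframerate(clip.rate)
        fh.writeframes(pcm.tobytes())
    return path


# ---------------------------------------------------------------------------
# severity: centralization, perception, SHI
# ---------------------------------------------------------------------------

def centralize(targets: FormantTargets, lam: float) -> FormantTargets:
    """Pull every formant toward the vowel-space centroid by weight ``lam``.

    Each formant becomes (1 - lam) * original + lam * centroid, where the
    centroid is the mean over the three vowels taken separately for F1 and
    F2.  lam = 0 is the identity; lam = 1 collapses the triangle to a point
    (downstream FCR = 2 exactly).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("centralization weight must lie in [0, 1]")
    c1 = np.mean([targets.f1(v) for v in VOWELS])
    c2 = np.mean([targets.f2(v) for v in VOWELS])
    newf = {
        v: ((1 - lam) * targets.f1(v) + lam * c1, (1 - lam) * targets.f2(v) + lam * c2)
        for v in VOWELS
    }
    return replace(targets, formants=newf)


def _perturb(targets: FormantTargets, model: SeverityModel, rng) -> FormantTargets:
    """Speaker idiosyncrasy: uniform VTL scale plus per-formant jitter."""
    scale = rng.normal(1.0, model.vtl_sd)
    newf = {}
    for v in VOWELS:
        j1, j2 = rng.normal(1.0, model.formant_jitter_sd, 2)
        f1 = targets.f1(v) * scale * j1
        f2 = targets.f2(v) * scale * j2
        f2 = max(f2, f1 * 1.05)  # keep the F1 < F2 invariant under jitter
        newf[v] = (f1, f2)
    # jitter can re-order front/back F2; restore the ordering invariant
    if newf["I"][1] <= newf["U"][1]:
        newf["I"] = (newf["I"][0], newf["U"][1] * 1.05)
    return replace(targets, formants=newf)


def simulate_perception(
    fcr: float,
    consonant_group: str,
    model: SeverityModel,
    seed: int | np.random.Generator = 0,
    size: int = 1,
) -> np.ndarray:
    """Draw binary articulation outcomes (1 = correct, 0 = deviated)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_dev = model.p_deviated(fcr, consonant_group)
    return (rng.random(size) >= p_dev).astype(int)


def simulate_shi(
    fcr: float,
    model: SeverityModel,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw 30 SHI item scores (0-4) from the latent severity at ``fcr``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    latent = model.shi_intercept + model.shi_slope * fcr
    latent += rng.normal(0.0, model.shi_subject_sd)
    per_item = latent / 30.0
    items = per_item + rng.normal(0.0, model.shi_item_sd, 30)
    return np.clip(np.round(items), 0, 4).astype(int)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

# Clinical layout of the 33-patient validation cohort (20 male, 13 female),
# jointly consistent with the gender-stratified marginals the study design
# prescribes: T distribution, resection extent, reconstruction, flap type.
def _patient_layout() -> list[dict]:
    rows: list[dict] = []

    def block(gender, t_classes, resections, recon_flags, flaps):
        for t, rs, rc, fl in zip(t_classes, resections, recon_flags, flaps):
            rows.append(
                dict(gender=gender, t_class=t, resection=rs, reconstruction=rc, flap=fl)
            )

    # males: T 1x1, 2x7, 3x5, 4x7; PG x6, HG x9, STG/TG x5; 18 reconstructed
    # (15 ALT, 3 other), the two least severe not reconstructed.
    m_t = [1] + [2] * 7 + [3] * 5 + [4] * 7
    m_rs = ["PG"] * 6 + ["HG"] * 9 + ["STG/TG"] * 5
    m_rc = [False, False] + [True] * 18
    m_fl = ["none", "none"] + ["ALT"] * 15 + ["other"] * 3
    block("male", m_t, m_rs, m_rc, m_fl)
    # females: T 1x3, 2x5, 3x1, 4x4; PG x4, HG x7, STG/TG x2; 9 reconstructed
    # (8 ALT, 1 other).
    f_t = [1] * 3 + [2] * 5 + [3] * 1 + [4] * 4
    f_rs = ["PG"] * 4 + ["HG"] * 7 + ["STG/TG"] * 2
    f_rc = [False] * 4 + [True] * 9
    f_fl = ["none"] * 4 + ["ALT"] * 8 + ["other"]
    block("female", f_t, f_rs, f_rc, f_fl)
    return rows


@dataclass
class Cohort:
    """A simulated cohort: session table plus per-session outcome tables.

    ``sessions`` has one row per (subject, timepoint) with clinical
    covariates, the true (noise-free) formants of the speaker's centralized
    vowel targets, and the true FCR those formants imply.  ``outcomes`` is
    session x syllable (0/1); ``shi`` is session x 30 items.  Audio is
    materialized lazily by :meth:`write_audio`.
    """

    sessions: pd.DataFrame
    outcomes: pd.DataFrame
    shi: pd.DataFrame
    config: CohortConfig

    def write_audio(self, out_dir: str | Path) -> list[Path]:
        """Synthesize and write one WAV per vowel per session."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for _, row in self.sessions.iterrows():
            for vowel in VOWELS:
                clip = self.session_clip(row["session_id"], vowel)
                name = f"{row['subject']}_{row['timepoint']}_{vowel}.wav"
                written.append(write_wav(clip, out_dir / name))
        return written

    def session_clip(self, session_id: str, vowel: str) -> AudioClip:
        """Synthesize the audio clip for one session and vowel."""
        row = self.sessions.set_index("session_id").loc[session_id]
        targets = FormantTargets(
            row["gender"],
            {v: (row[f"true_f1_{v}"], row[f"true_f2_{v}"]) for v in VOWELS},
        )
        return synthesize_vowel(
            vowel,
            targets,
            f0=row["f0"],
            duration=self.config.duration,
            rate=self.config.rate,
            noise_level=self.config.noise_level,
            seed=int(row[f"audio_seed_{vowel}"]),
        )


def _make_sessions(states, config: CohortConfig, rng, corpus) -> Cohort:
    """Build session/outcome/SHI tables for a list of speaker-timepoint states."""
    model = config.severity
    sess_rows, out_rows, shi_rows = [], [], []
    for st in states:
        base = config.targets[st["gender"]]
        speaker_targets = st["speaker_targets"]
        lam = model.lam(st["t_class"], st.get("resection"), st["timepoint"])
        lam = float(np.clip(lam + st["lam_noise"], 0.0, 1.0))
        cent = centralize(speaker_targets, lam)
        fcr = cent.fcr()
        session_id = f"{st['subject']}_{st['timepoint']}"
        row = dict(
            session_id=session_id,
            subject=st["subject"],
            timepoint=st["timepoint"],
            cohort=st["cohort"],
            gender=st["gender"],
            age=st["age"],
            t_class=st["t_class"],
            resection=st.get("resection") or "none",
            reconstruction=st.get("reconstruction", False),
            flap=st.get("flap", "none"),
            lam=lam,
            f0=st["f0"],
            true_fcr=fcr,
        )
        for v in VOWELS:
            row[f"true_f1_{v}"] = cent.f1(v)
            row[f"true_f2_{v}"] = cent.f2(v)
            row[f"audio_seed_{v}"] = int(rng.integers(0, 2**31 - 1))
        sess_rows.append(row)

        out = {"session_id": session_id}
        for syl in corpus.itertuples():
            out[syl.syllable_id] = int(
                simulate_perception(fcr, syl.place_group, model, rng)[0]
            )
        out_rows.append(out)

        items = simulate_shi(fcr, model, rng)
        shi_rows.append(
            {"session_id": session_id, **{f"item_{i+1:02d}": s for i, s in enumerate(items)}}
        )
    sessions = pd.DataFrame(sess_rows)
    outcomes = pd.DataFrame(out_rows).set_index("session_id")
    shi = pd.DataFrame(shi_rows).set_index("session_id")
    return Cohort(sessions=sessions, outcomes=outcomes, shi=shi, config=config)


def simulate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Simulate the pre/post validation cohort plus healthy controls.

    With default settings: 33 patients seen pre- and post-operatively minus
    one post-operative dropout gives 65 validation sessions (97% follow-up),
    plus ``n_controls`` healthy-control sessions (T class 0, timepoint
    "pre", cohort flag "control").  Deterministic given ``config.seed``.
    """
    from .perceptual import default_corpus  # local import to avoid a cycle

    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    corpus = default_corpus()
    model = config.severity

    layout = _patient_layout()
    if config.n_patients != len(layout):
        # honour the requested size by cycling the canonical layout
        layout = [layout[i % len(layout)] for i in range(config.n_patients)]

    states = []
    # the dropout is applied deterministically to the last enrolled patients
    dropped = {len(layout) - 1 - k for k in range(config.n_dropout)}
    for i, pat in enumerate(layout):
        subject = f"pat{i+1:02d}"
        speaker_targets = _perturb(config.targets[pat["gender"]], model, rng)
        age = float(np.clip(rng.normal(52.0, 9.0), 25, 75))
        f0 = float(rng.normal(config.f0[pat["gender"]], config.f0_sd))
        lam_noise = rng.normal(0.0, model.lambda_subject_sd)
        for tp in config.timepoints:
            if tp == "post" and i in dropped:
                continue
            states.append(
                dict(
                    subject=subject,
                    timepoint=tp,
                    cohort="patient",
                    age=round(age, 1),
                    f0=round(f0, 1),
                    speaker_targets=speaker_targets,
                    lam_noise=lam_noise,
                    **pat,
                )
            )
    genders = ["male", "female"]
    for i in range(config.n_controls):
        gender = genders[i % 2]
        subject = f"ctl{i+1:02d}"
        speaker_targets = _perturb(config.targets[gender], model, rng)
        states.append(
            dict(
                subject=subject,
                timepoint="pre",
                cohort="control",
                gender=gender,
                age=round(float(np.clip(rng.normal(50.0, 10.0), 25, 75)), 1),
                f0=round(float(rng.normal(config.f0[gender], config.f0_sd)), 1),
                t_class=0,
                speaker_targets=speaker_targets,
                lam_noise=rng.normal(0.0, model.lambda_subject_sd),
            )
        )
    return _make_sessions(states, config, rng, corpus)


def simulate_screening(
    n_male: int = 80,
    n_female: int = 76,
    config: CohortConfig | None = None,
    seed: int = 0,
) -> Cohort:
    """Simulate the cross-sectional marker-screening dataset.

    One session per speaker across the full severity range (healthy controls
    and T1-T4 disease), mirroring the lenient screening recruitment that
    feeds the per-syllable SVMs.
    """
    from .perceptual import default_corpus

    config = config or CohortConfig(seed=seed)
    rng = np.random.default_rng(seed)
    model = config.severity
    t_probs = {0: 0.35, 1: 0.13, 2: 0.16, 3: 0.16, 4: 0.20}
    t_vals = np.array(sorted(t_probs))
    p_vals = np.array([t_probs[t] for t in t_vals])

    states = []
    counts = {"male": n_male, "female": n_female}
    i = 0
    for gender in GENDERS:
        for _ in range(counts[gender]):
            i += 1
            t_class = int(rng.choice(t_vals, p=p_vals))
            states.append(
                dict(
                    subject=f"scr{i:03d}",
                    timepoint="pre",
                    cohort="screening",
                    gender=gender,
                    age=round(float(np.clip(rng.normal(50.0, 12.0), 18, 75)), 1),
                    f0=round(float(rng.normal(config.f0[gender], config.f0_sd)), 1),
                    t_class=t_class,
                    speaker_targets=_perturb(config.targets[gender], model, rng),
                    lam_noise=rng.normal(0.0, 0.025),
                )
            )
    return _make_sessions(states, config, rng, default_corpus())
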