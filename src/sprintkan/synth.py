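"""Synthetic sprint-cohort generator.

Emulates a crossover study: 30 participants x 3 stimulation conditions
(sham, motor-cortex tDCS, dorsolateral-prefrontal tDCS) x 3 sprint phases
(0-30 m, 30-60 m, 60-100 m), with 4-channel surface EMG (RA, BF, TA, GL)
sampled at 1000 Hz and one phase velocity per trial.

Coherent EMG is produced by a common-drive model: for each muscle pair and
frequency band, a shared band-limited Gaussian drive s is mixed into both
channels at a coefficient kappa alongside independent, identically
band-limited noises,

    x = kappa*s + sqrt(1 - kappa^2)*e1,
    y = kappa*s + sqrt(1 - kappa^2)*e2,

which yields expected band coherence kappa^4, so a target coherence t is
hit with kappa = t**(1/4). Channels additionally carry independent
broadband (20-450 Hz) background noise and a small lognormal per-trial
gain jitter. Phase durations derive from phase distance / mean phase
velocity; velocities are drawn either from the configured per-cell
(mean, sd) ("table" mode) or from the packaged closed-form equation plus
Gaussian noise ("formula" mode).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy import signal as _sig

from . import imc as _imc
from . import kan as _kan
from .emg import CHANNELS, EMGRecording

logger = logging.getLogger(__name__)

CONDITIONS: tuple[str, ...] = ("sham", "m1_tdcs", "dlpfc_tdcs")
PHASES: tuple[str, ...] = ("p0_30", "p30_60", "p60_100")


def _default_yaml() -> dict:
    text = resources.files("sprintkan.data").joinpath("default_cohort.yaml").read_text()
    return yaml.safe_load(text)


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort."""

    n_participants: int = 30
    conditions: tuple[str, ...] = CONDITIONS
    phases: tuple[str, ...] = PHASES
    fs: float = 1000.0
    phase_distances_m: dict = field(default_factory=dict)
    velocity_params: dict = field(default_factory=dict)   # condition -> phase -> (mean, sd)
    coherence_targets: dict = field(default_factory=dict) # condition -> phase -> pair -> band -> target
    clamp_coherence_max: float = 0.95
    noise_sd_velocity: float = 0.15
    participant_sd: float = 0.2
    broadband_noise_sd: float = 0.3
    gain_jitter_sigma: float = 0.1
    seed: int = 42

    def __post_init__(self) -> None:
        self.conditions = tuple(self.conditions)
        self.phases = tuple(self.phases)
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        highest = max(high for (_, high) in _imc.BANDS.values())
        if self.fs <= 2 * highest:
            raise ValueError("fs must exceed twice the highest band edge")
        for cond, per_phase in self.velocity_params.items():
            for phase, (mean, sd) in per_phase.items():
                if sd <= 0:
                    raise ValueError(f"velocity sd must be > 0 for {cond}/{phase}")
        for cond, per_phase in self.coherence_targets.items():
            for phase, per_pair in per_phase.items():
                for pair, per_band in per_pair.items():
                    for band, t in per_band.items():
                        if not 0 <= t:
                            raise ValueError(
                                f"coherence target {t} out of range "
                                f"({cond}/{phase}/{pair}/{band})")

    @classmethod
    def default(cls, **overrides) -> "CohortConfig":
        """Configuration mirroring the study's reported cohort structure."""
        d = _default_yaml()
        d.pop("comment", None)
        d.update(overrides)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        base = _default_yaml()
        base.update(d or {})
        return cls(**base)

    def target(self, condition: str, phase: str, pair: str, band: str) -> float:
        t = self.coherence_targets[condition][phase][pair][band]
        return min(float(t), self.clamp_coherence_max)

    def velocity(self, condition: str, phase: str) -> tuple[float, float]:
        mean, sd = self.velocity_params[condition][phase]
        return float(mean), float(sd)

    def duration(self, condition: str, phase: str) -> float:
        """Phase duration (s) = phase distance / condition-phase mean velocity."""
        return self.phase_distances_m[phase] / self.velocity(condition, phase)[0]

    def canonical_json(self) -> str:
        d = {k: v for k, v in self.__dict__.items()}
        return json.dumps(d, sort_keys=True, default=list)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


@dataclass
class TrialRow:
    participant: int
    condition: str
    phase: str
    recording: EMGRecording
    velocity: float


@dataclass
class CohortDataset:
    rows: list[TrialRow]
    seed: int
    config_hash: str

    def __len__(self) -> int:
        return len(self.rows)

    def velocities(self):
        import pandas as pd
        return pd.DataFrame([{"participant": r.participant, "condition": r.condition,
                              "phase": r.phase, "velocity": r.velocity}
                             for r in self.rows])

    def write(self, out_dir) -> None:
        """Write per-trial CSV recordings plus a JSON manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = []
        for r in self.rows:
            name = f"p{r.participant:02d}_{r.condition}_{r.phase}.csv"
            r.recording.to_csv(out / name)
            manifest.append({"participant": r.participant, "condition": r.condition,
                             "phase": r.phase, "file": name,
                             "velocity": r.velocity, "seed": self.seed})
        (out / "manifest.json").write_text(
            json.dumps({"config_hash": self.config_hash, "seed": self.seed,
                        "trials": manifest}, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Signal primitives
# ---------------------------------------------------------------------------

def calibrate_mixing(target_coherence: float) -> float:
    """Mixing coefficient kappa hitting a band-coherence target: t**(1/4)."""
    if not 0 <= target_coherence < 1:
        raise ValueError("target coherence must be in [0, 1); perfect "
                         "coherence is unattainable with independent noise")
    return float(target_coherence) ** 0.25


def band_limited_noise(rng: np.random.Generator, n: int, fs: float,
                       band: tuple[float, float]) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed with a 4th-order Butterworth."""
    sos = _sig.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = _sig.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def coherent_pair(rng: np.random.Generator, n: int, fs: float,
                  band: tuple[float, float], target: float) -> tuple[np.ndarray, np.ndarray]:
    """A pair of band-limited signals with expected band coherence ``target``."""
    kappa = calibrate_mixing(target)
    mix = np.sqrt(1.0 - kappa ** 2)
    s = band_limited_noise(rng, n, fs, band)
    e1 = band_limited_noise(rng, n, fs, band)
    e2 = band_limited_noise(rng, n, fs, band)
    return kappa * s + mix * e1, kappa * s + mix * e2


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _trial_rng(cfg: CohortConfig, participant: int, condition: str, phase: str,
               stream: int = 0) -> np.random.Generator:
    ci = cfg.conditions.index(condition)
    pi = cfg.phases.index(phase)
    return np.random.default_rng([cfg.seed, participant, ci, pi, stream])


def generate_trial(participant: int, condition: str, phase: str,
                   cfg: CohortConfig,
                   rng: np.random.Generator | None = None) -> tuple[EMGRecording, float]:
    """One 4-channel recording plus a table-mode phase velocity."""
    if condition not in cfg.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    if phase not in cfg.phases:
        raise ValueError(f"unknown phase {phase!r}")
    rng = rng or _trial_rng(cfg, participant, condition, phase)
    n = int(round(cfg.duration(condition, phase) * cfg.fs))
    data = np.zeros((n, len(CHANNELS)))
    chan_idx = {c: k for k, c in enumerate(CHANNELS)}
    for pair in _imc.PAIRS:
        pair_key = f"{pair[0]}-{pair[1]}"
        for band_name, band in _imc.BANDS.items():
            t = cfg.target(condition, phase, pair_key, band_name)
            x, y = coherent_pair(rng, n, cfg.fs, band, t)
            data[:, chan_idx[pair[0]]] += x
            data[:, chan_idx[pair[1]]] += y
    for k in range(len(CHANNELS)):
        data[:, k] += cfg.broadband_noise_sd * band_limited_noise(
            rng, n, cfg.fs, (20.0, 450.0))
    gains = np.exp(rng.normal(0.0, cfg.gain_jitter_sigma, size=len(CHANNELS)))
    data *= gains
    mean, sd = cfg.velocity(condition, phase)
    v = float(np.clip(rng.normal(mean, sd), mean - 3 * sd, mean + 3 * sd))
    rec = EMGRecording(fs=cfg.fs, channels=CHANNELS, data=data)
    return rec, v


def generate_cohort(cfg: CohortConfig | None = None) -> CohortDataset:
    """Full cohort: n_participants x |conditions| x |phases| trials.

    Deterministic given (config, seed); a participant-level random
    intercept (sd = cfg.participant_sd) is added to every velocity of a
    participant so that grouped cross-validation is meaningful.
    """
    cfg = cfg or CohortConfig.default()
    rows = []
    for p in range(1, cfg.n_participants + 1):
        eff_rng = np.random.default_rng([cfg.seed, p, 999983])
        p_effect = eff_rng.normal(0.0, cfg.participant_sd) if cfg.participant_sd > 0 else 0.0
        for cond in cfg.conditions:
            for phase in cfg.phases:
                rec, v = generate_trial(p, cond, phase, cfg)
                rows.append(TrialRow(participant=p, condition=cond, phase=phase,
                                     recording=rec, velocity=v + p_effect))
    return CohortDataset(rows=rows, seed=cfg.seed, config_hash=cfg.config_hash())


def generate_velocity_from_formula(features: np.ndarray, noise_sd: float,
                                   rng: np.random.Generator) -> float | np.ndarray:
    """Velocity from the packaged closed-form equation plus Gaussian noise.

    ``features`` is one 9-vector or an (n, 9) matrix in the canonical
    order x1..x9; used as generative ground truth for recovery testing.
    """
    eq = load_formula()
    base = _kan.predict_symbolic(eq, np.asarray(features, dtype=float))
    if np.ndim(base) == 0:
        return float(base + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0))
    noise = rng.normal(0.0, noise_sd, size=np.shape(base)) if noise_sd > 0 else 0.0
    return base + noise


_FORMULA_CACHE: list = []


def load_formula() -> "_kan.SymbolicModel":
    if not _FORMULA_CACHE:
        _FORMULA_CACHE.append(_kan.load_reference_equation())
    return _FORMULA_CACHE[0]
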