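"""Seeded synthetic cough cohorts and waveforms.

Stands in for the (non-deposited) study data: a two-generation cohort whose
demographics match the published group moments, a latent true vital capacity
tied to age/height through the LMS reference, a latent cough peak flow
correlated with vital capacity, and decaying tone-burst "cough" waveforms
whose peak sound pressure encodes that flow via the inverse flow-from-sound
model. Out-of-band contamination exercises the 140-2000 Hz band-pass.

Everything is deterministic given the explicit seeds; all tables carry the
ground truth needed by recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acoustics import MicrophoneModel, Waveform
from .cough_flow import CPSParams, DEFAULT_CPS_PARAMS, invert_cps
from .reference_vc import DEFAULT_LMS_CONFIG, LMSConfig, lln, vc_lms

__all__ = [
    "CohortParams",
    "ContaminationSpec",
    "generate_cohort",
    "synthesize_cough_waveform",
    "synthesize_session_set",
]

GROUPS = ("young", "elderly")


def _default_height_means() -> dict[tuple[str, str], float]:
    # Pooled group means with a documented +/- 4 cm sex offset (the per-sex
    # breakdown within groups is not published; the offset is a free
    # parameter of the generator).
    return {
        ("young", "male"): 164.3 + 4.0,
        ("young", "female"): 164.3 - 4.0,
        ("elderly", "male"): 154.1 + 4.0,
        ("elderly", "female"): 154.1 - 4.0,
    }


def _default_height_sds() -> dict[tuple[str, str], float]:
    return {
        ("young", "male"): 8.4,
        ("young", "female"): 8.4,
        ("elderly", "male"): 8.3,
        ("elderly", "female"): 8.3,
    }


@dataclass(frozen=True)
class CohortParams:
    """Generator settings; demographic defaults are the published group
    moments (ages 21.3 +/- 0.5 and 80.4 +/- 6.1 years, heights 164.3 +/- 8.4
    and 154.1 +/- 8.3 cm, weights 58.0 +/- 11.5 and 55.7 +/- 12.0 kg)."""

    n_young: int = 31
    n_elderly: int = 25
    male_fraction_young: float = 19 / 31
    male_fraction_elderly: float = 11 / 25
    age_mean_young: float = 21.3
    age_sd_young: float = 0.5
    age_mean_elderly: float = 80.4
    age_sd_elderly: float = 6.1
    height_mean_by_group_sex: dict = field(default_factory=_default_height_means)
    height_sd_by_group_sex: dict = field(default_factory=_default_height_sds)
    weight_mean_young: float = 58.0
    weight_sd_young: float = 11.5
    weight_mean_elderly: float = 55.7
    weight_sd_elderly: float = 12.0
    #: SD of the log-deviation of true VC from VC_LMS
    vc_lognoise_sd: float = 0.1
    #: affine cough-peak-flow model: intercept + slope * VC + noise
    cpf_slope: float = 60.0  # (L/min)/L
    cpf_intercept: float = 50.0  # L/min
    cpf_noise_sd: float = 20.0  # L/min
    #: optional extra age effect on cough strength (vocal aging)
    vocal_aging_slope: float = 0.0  # (L/min)/year, applied to (age - 20)
    cpf_floor: float = 10.0  # L/min
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_young < 1 or self.n_elderly < 1:
            raise ValueError("group counts must be >= 1")
        for frac in (self.male_fraction_young, self.male_fraction_elderly):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("male fractions must lie in [0, 1]")
        sds = (
            self.age_sd_young, self.age_sd_elderly, self.vc_lognoise_sd,
            self.cpf_noise_sd, self.weight_sd_young, self.weight_sd_elderly,
        )
        if any(s < 0 for s in sds):
            raise ValueError("standard deviations must be >= 0")
        if self.cpf_floor <= 0:
            raise ValueError("cpf_floor must be > 0")


def generate_cohort(
    params: CohortParams,
    cps_params: CPSParams = DEFAULT_CPS_PARAMS,
    lms_config: LMSConfig = DEFAULT_LMS_CONFIG,
) -> pd.DataFrame:
    """One row per participant: demographics plus the ground-truth record
    (true_vc, true_cpf, target_spl, below_lln).

    true_vc = VC_LMS * exp(eps), eps ~ N(0, vc_lognoise_sd);
    true_cpf = intercept + slope * true_vc + vocal_aging_slope * (age - 20)
    + N(0, cpf_noise_sd), floored at ``cpf_floor``; target_spl inverts the
    flow-from-sound model at the generator's constants.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0x01]))
    rows = []
    idx = 0
    group_spec = {
        "young": (params.n_young, params.male_fraction_young,
                  params.age_mean_young, params.age_sd_young,
                  params.weight_mean_young, params.weight_sd_young),
        "elderly": (params.n_elderly, params.male_fraction_elderly,
                    params.age_mean_elderly, params.age_sd_elderly,
                    params.weight_mean_elderly, params.weight_sd_elderly),
    }
    for group in GROUPS:
        n, male_frac, age_mu, age_sd, wt_mu, wt_sd = group_spec[group]
        n_male = int(round(n * male_frac))
        sexes = ["male"] * n_male + ["female"] * (n - n_male)
        for sex in sexes:
            idx += 1
            pid = f"P{idx:03d}"
            age = float(np.clip(rng.normal(age_mu, age_sd), 18.0, None))
            h_mu = params.height_mean_by_group_sex[(group, sex)]
            h_sd = params.height_sd_by_group_sex[(group, sex)]
            height = float(np.clip(rng.normal(h_mu, h_sd), 130.0, 200.0))
            weight = float(np.clip(rng.normal(wt_mu, wt_sd), 30.0, 150.0))
            ref = vc_lms(sex, height, age, lms_config)
            eps = rng.normal(0.0, params.vc_lognoise_sd) if params.vc_lognoise_sd else 0.0
            true_vc = ref * float(np.exp(eps))
            cpf = (
                params.cpf_intercept
                + params.cpf_slope * true_vc
                + params.vocal_aging_slope * (age - 20.0)
                + (rng.normal(0.0, params.cpf_noise_sd) if params.cpf_noise_sd else 0.0)
            )
            cpf = max(cpf, params.cpf_floor)
            try:
                target_spl = invert_cps(cpf, age, cps_params)
            except ValueError as exc:
                raise ValueError(f"participant {pid}: {exc}") from exc
            rows.append(
                {
                    "participant_id": pid,
                    "group": group,
                    "sex": sex,
                    "age": age,
                    "height": height,
                    "weight": weight,
                    "vc_lms": ref,
                    "measured_vc": true_vc,
                    "true_vc": true_vc,
                    "true_cpf": cpf,
                    "target_spl": target_spl,
                    "below_lln": bool(true_vc < lln(sex, height, age, lms_config)),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ContaminationSpec:
    """Out-of-band additives, amplitudes relative to the burst peak."""

    lf_freq_hz: float = 40.0
    lf_rel_amp: float = 0.0
    hf_freq_hz: float = 4000.0
    hf_rel_amp: float = 0.0

    def validate(self, fs: float) -> None:
        if self.lf_rel_amp and not 0 < self.lf_freq_hz < 140.0:
            raise ValueError("low-frequency contamination must be below 140 Hz")
        if self.hf_rel_amp:
            if self.hf_freq_hz <= 2000.0:
                raise ValueError("high-frequency contamination must be above 2000 Hz")
            if self.hf_freq_hz >= fs / 2:
                raise ValueError("contamination frequency above Nyquist")


NO_CONTAMINATION = ContaminationSpec()

#: burst envelope attack time (s): env = (t/ta) exp(1 - t/ta) peaks at ta
_ATTACK_S = 0.010
#: exponential tail beyond the attack, folded into the same envelope


def _burst(t: np.ndarray, onset: float, attack: float, carrier: float) -> np.ndarray:
    rel = np.maximum(t - onset, 0.0)
    env = (rel / attack) * np.exp(1.0 - rel / attack)
    return env * np.cos(2 * np.pi * carrier * (t - onset - attack))


def synthesize_cough_waveform(
    target_spl: float,
    mic: MicrophoneModel,
    fs: float = 100_000.0,
    n_trials: int = 3,
    trial_jitter_db: float = 0.0,
    contamination: ContaminationSpec = NO_CONTAMINATION,
    seed: int = 0,
    participant_id: str = "",
    carrier_hz: float = 700.0,
    trial_duration: float = 20.0,
) -> list[Waveform]:
    """One session of >= 3 trials; each trial one tone burst.

    Trial i's peak pressure is P0 * 10^((target_spl - |jitter_i|)/20) with
    jitter ~ |N(0, trial_jitter_db)|; trial 0 always gets zero jitter so the
    session maximum equals ``target_spl`` exactly. Pressure is converted to
    microphone voltage; burst onsets are randomized within the trial.
    """
    if fs < 8000:
        raise ValueError("fs must be >= 8000 Hz")
    if n_trials < 3:
        raise ValueError("a session needs at least 3 trials")
    if not np.isfinite(target_spl):
        raise ValueError("target_spl must be finite")
    if not 300.0 <= carrier_hz <= 1500.0:
        raise ValueError(
            "carrier must lie within 300-1500 Hz (inside the analysis passband)"
        )
    contamination.validate(fs)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x02]))
    n_samples = int(round(trial_duration * fs))
    t = np.arange(n_samples) / fs
    # snap the envelope peak onto the sample grid so one sample carries the
    # exact peak pressure
    attack = max(round(_ATTACK_S * fs), 1) / fs

    trials: list[Waveform] = []
    for i in range(n_trials):
        jitter = 0.0 if i == 0 else abs(rng.normal(0.0, trial_jitter_db)) if trial_jitter_db else 0.0
        spl_i = target_spl - jitter
        peak_pressure = mic.reference_pressure * 10.0 ** (spl_i / 20.0)
        onset_max = trial_duration - 10 * attack - 1.0
        onset = round(rng.uniform(0.5, max(onset_max, 0.6)) * fs) / fs
        pressure = peak_pressure * _burst(t, onset, attack, carrier_hz)
        if contamination.lf_rel_amp or contamination.hf_rel_amp:
            # fade the additives in/out so they end at zero; a tone cut
            # mid-cycle at the recording edge would otherwise ring
            # broadband through the zero-phase filter's signal extension
            ramp = np.ones_like(t)
            n_ramp = min(int(0.1 * fs), t.size // 4)
            window = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
            ramp[:n_ramp] = window
            ramp[-n_ramp:] = window[::-1]
            if contamination.lf_rel_amp:
                pressure += ramp * (
                    contamination.lf_rel_amp * peak_pressure
                    * np.sin(2 * np.pi * contamination.lf_freq_hz * t)
                )
            if contamination.hf_rel_amp:
                pressure += ramp * (
                    contamination.hf_rel_amp * peak_pressure
                    * np.sin(2 * np.pi * contamination.hf_freq_hz * t)
                )
        trials.append(
            Waveform(
                samples=mic.pressure_to_voltage(pressure),
                fs=fs,
                participant_id=participant_id,
                trial_index=i,
            )
        )
    return trials


def synthesize_session_set(
    cohort: pd.DataFrame,
    mic: MicrophoneModel,
    fs: float = 100_000.0,
    n_trials: int = 3,
    trial_jitter_db: float = 1.0,
    contamination: ContaminationSpec = NO_CONTAMINATION,
    seed: int = 0,
    trial_duration: float = 20.0,
) -> dict[str, list[Waveform]]:
    """Sessions for every cohort row, each with its own derived seed."""
    sessions: dict[str, list[Waveform]] = {}
    child_seeds = np.random.SeedSequence([seed, 0x03]).generate_state(len(cohort))
    for child, (_, row) in zip(child_seeds, cohort.iterrows()):
        sessions[row["participant_id"]] = synthesize_cough_waveform(
            target_spl=float(row["target_spl"]),
            mic=mic,
            fs=fs,
            n_trials=n_trials,
            trial_jitter_db=trial_jitter_db,
            contamination=contamination,
            seed=int(child),
            participant_id=row["participant_id"],
            trial_duration=trial_duration,
        )
    return sessions
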