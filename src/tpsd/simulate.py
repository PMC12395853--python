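"""Synthetic lick-behavior generator for TPSD-style go/no-go cohorts.

The generator is a two-level model.  At the trial level a Bernoulli draw
decides whether the mouse responds (probability p_hit on preferred trials,
p_fa on nonpreferred trials); conditional on responding, a renewal lick train
with gamma inter-lick intervals is laid down from a uniform anticipatory
latency until reward offset (rewarded trials) or a false-alarm stop time
(nonpreferred trials).  Sparse baseline licks are superimposed over the whole
trial epoch, all times are quantized to the 4 ms (250 Hz) recording grid, and
a 50 ms refractory floor is enforced.  Because the Bernoulli draw *is* the
response model, baseline licks are censored from the response window on
withholding trials, so the scored hit/false-alarm fractions recover
(p_hit, p_fa) exactly as binomial proportions.

Across sessions, p_hit relaxes exponentially toward its asymptote while p_fa
declines along a logistic in session number — the false-alarm suppression
that carries learning in this task.  Genotype presets differ mainly in the
midpoint and shallowness of that decline (knockout-like presets suppress
false alarms later and less completely) and in prolonged licking on
false-alarm trials.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .records import SessionRecord, TrialRecord
from .task import SessionConfig, build_schedule, pretrial_config

__all__ = [
    "BehaviorPreset",
    "SimulatedMouse",
    "wt_like",
    "ko_expert_like",
    "ko_nonexpert_like",
    "naive_preset",
    "learning_curve",
    "modality_adjusted_probabilities",
    "simulate_trial",
    "simulate_session",
    "simulate_cohort",
    "default_config_sequence",
]

#: Quantization grid of the lick-port recording (250 Hz).
LICK_GRID_S = 1.0 / 250.0
#: Physiological refractory floor between licks (licking tops out near 10 Hz).
REFRACTORY_S = 0.05
#: Trial epoch over which baseline licks are laid down, [0, end) seconds.
TRIAL_EPOCH_END_S = 3.0


@dataclass(frozen=True)
class BehaviorPreset:
    """Generative parameters for one simulated mouse phenotype.

    Response-probability learning curves are parameterized by initial/final
    hit and false-alarm probabilities, an exponential time constant for the
    hit curve and a logistic midpoint/scale (in sessions) for the
    false-alarm curve.  Lick trains use a gamma renewal process with mean
    rate ``lick_rate`` (Hz) and shape ``lick_isi_shape``.
    ``modality_dprime_scaling`` multiplies the logit-scale discrimination
    (logit p_hit - logit p_fa) about its midpoint for unimodal probes.
    """

    genotype_label: str
    p_hit_initial: float
    p_hit_final: float
    p_fa_initial: float
    p_fa_final: float
    fa_curve_midpoint: float
    fa_curve_scale: float
    hit_curve_tau: float
    lick_rate: float = 7.0
    lick_isi_shape: float = 4.0
    response_latency_range: tuple[float, float] = (0.3, 0.9)
    fa_stop_time_range: tuple[float, float] = (1.2, 1.6)
    reward_consumption_rate: float = 7.0
    baseline_lick_rate: float = 0.2
    modality_dprime_scaling: dict = field(
        default_factory=lambda: {"multimodal": 1.0, "audio_only": 1.0, "visual_only": 1.0}
    )

    def __post_init__(self) -> None:
        for name in ("p_hit_initial", "p_hit_final", "p_fa_initial", "p_fa_final"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.p_fa_final > self.p_fa_initial:
            raise ValueError("p_fa_final must not exceed p_fa_initial")
        if self.lick_rate <= 0 or self.reward_consumption_rate <= 0:
            raise ValueError("lick rates must be > 0")
        if self.lick_isi_shape <= 0:
            raise ValueError("lick_isi_shape must be > 0")
        if self.baseline_lick_rate < 0:
            raise ValueError("baseline_lick_rate must be >= 0")


def wt_like() -> BehaviorPreset:
    """Wild-type-like preset: rapid false-alarm suppression (endpoint FA ~24%)."""
    return BehaviorPreset(
        genotype_label="WT_like",
        p_hit_initial=0.97, p_hit_final=0.995, hit_curve_tau=2.0,
        p_fa_initial=0.915, p_fa_final=0.236, fa_curve_midpoint=4.5, fa_curve_scale=0.8,
        fa_stop_time_range=(1.2, 1.6),
        modality_dprime_scaling={"multimodal": 1.0, "audio_only": 0.45, "visual_only": 0.35},
    )


def ko_expert_like() -> BehaviorPreset:
    """Knockout-like preset that eventually learns: late FA suppression.

    False-alarm decline is centred near session 12 so that the true
    intermediate-threshold (d' > 1) crossing lands around session 10 and the
    expert (d' > 2) crossing in the mid-teens, with an endpoint FA near 30%
    and hit rate near 97.5%.
    """
    return BehaviorPreset(
        genotype_label="KO_expert_like",
        p_hit_initial=0.96, p_hit_final=0.975, hit_curve_tau=4.0,
        p_fa_initial=0.915, p_fa_final=0.30, fa_curve_midpoint=12.0, fa_curve_scale=2.0,
        fa_stop_time_range=(1.6, 2.4),
        modality_dprime_scaling={"multimodal": 1.0, "audio_only": 0.30, "visual_only": 0.80},
    )


def ko_nonexpert_like() -> BehaviorPreset:
    """Knockout-like preset that never suppresses false alarms below ~55%,
    so asymptotic d' stays below the expert threshold."""
    return BehaviorPreset(
        genotype_label="KO_nonexpert_like",
        p_hit_initial=0.96, p_hit_final=0.975, hit_curve_tau=4.0,
        p_fa_initial=0.915, p_fa_final=0.55, fa_curve_midpoint=13.0, fa_curve_scale=3.0,
        fa_stop_time_range=(1.6, 2.4),
        modality_dprime_scaling={"multimodal": 1.0, "audio_only": 0.30, "visual_only": 0.80},
    )


def naive_preset() -> BehaviorPreset:
    """Session-constant naive preset, (p_hit, p_fa) = (0.97, 0.915).

    Expected full-session discriminability is the analytic
    ``Phi^-1(0.97) - Phi^-1(0.915) ~= 0.51``, matching first-session
    performance after pretrial training.
    """
    return BehaviorPreset(
        genotype_label="naive",
        p_hit_initial=0.97, p_hit_final=0.97, hit_curve_tau=1.0,
        p_fa_initial=0.915, p_fa_final=0.915, fa_curve_midpoint=1.0, fa_curve_scale=1.0,
    )


def learning_curve(preset: BehaviorPreset, session: int) -> tuple[float, float]:
    """Response probabilities (p_hit, p_fa) for a 1-based session index.

    p_hit relaxes exponentially from initial to final with time constant
    ``hit_curve_tau``; p_fa follows a declining logistic with midpoint
    ``fa_curve_midpoint`` and scale ``fa_curve_scale``.  Both are clipped to
    (0.001, 0.999).
    """
    if session < 1:
        raise ValueError("session must be >= 1")
    p_hit = preset.p_hit_final + (preset.p_hit_initial - preset.p_hit_final) * np.exp(
        -(session - 1) / preset.hit_curve_tau
    )
    p_fa = preset.p_fa_final + (preset.p_fa_initial - preset.p_fa_final) * expit(
        (preset.fa_curve_midpoint - session) / preset.fa_curve_scale
    )
    return (float(np.clip(p_hit, 0.001, 0.999)), float(np.clip(p_fa, 0.001, 0.999)))


def modality_adjusted_probabilities(
    p_hit: float, p_fa: float, multiplier: float
) -> tuple[float, float]:
    """Scale the logit-scale discrimination about its midpoint.

    The gap (logit p_hit - logit p_fa) is multiplied by ``multiplier`` while
    the midpoint is preserved, shrinking (or stretching) discriminability
    without moving overall response bias.
    """
    zh, zf = logit(p_hit), logit(p_fa)
    mid, half_gap = 0.5 * (zh + zf), 0.5 * (zh - zf)
    return (
        float(np.clip(expit(mid + multiplier * half_gap), 0.001, 0.999)),
        float(np.clip(expit(mid - multiplier * half_gap), 0.001, 0.999)),
    )


def _renewal_train(
    start: float, stop: float, rate: float, shape: float, rng: np.random.Generator
) -> np.ndarray:
    if stop <= start:
        return np.empty(0)
    n_max = int((stop - start) * rate * 3) + 10
    isis = rng.gamma(shape, 1.0 / (rate * shape), n_max)
    times = start + np.concatenate(([0.0], np.cumsum(isis)))
    return times[times < stop]


def _enforce_grid_and_refractory(times: np.ndarray) -> np.ndarray:
    # Quantize to the 250 Hz grid, then greedily drop events violating the
    # 50 ms refractory floor (earlier event wins).
    if times.size == 0:
        return times
    t = np.sort(np.round(times / LICK_GRID_S)) * LICK_GRID_S
    kept = [t[0]]
    for x in t[1:]:
        if x - kept[-1] >= REFRACTORY_S - 1e-9:
            kept.append(x)
    return np.asarray(kept)


def simulate_trial(
    stimulus_type: str,
    p_hit: float,
    p_fa: float,
    preset: BehaviorPreset,
    config: SessionConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample one trial's lick times (sorted, grid-quantized, refractory-clean).

    Responding trials are guaranteed at least one lick inside the response
    window; withholding trials carry no licks there (anticipatory/baseline
    licking outside the window is allowed on any trial).
    """
    preferred = stimulus_type == "preferred"
    p = p_hit if preferred else p_fa
    respond = rng.random() < p
    w_lo, w_hi = config.response_window

    parts = []
    stop = None
    if respond:
        start = rng.uniform(*preset.response_latency_range)
        if preferred:
            stop = config.reward_end
        else:
            stop = rng.uniform(*preset.fa_stop_time_range)
        parts.append(
            _renewal_train(start, stop, preset.lick_rate, preset.lick_isi_shape, rng)
        )
    if preset.baseline_lick_rate > 0:
        n_base = rng.poisson(preset.baseline_lick_rate * TRIAL_EPOCH_END_S)
        if n_base:
            parts.append(rng.uniform(0.0, TRIAL_EPOCH_END_S, n_base))
    times = np.concatenate(parts) if parts else np.empty(0)
    times = _enforce_grid_and_refractory(times)

    in_window = (times >= w_lo) & (times < w_hi)
    if not respond:
        # The Bernoulli draw defines the response: censor window licks.
        times = times[~in_window]
    elif not in_window.any():
        # Rare: train/quantization left the window empty; insert a grid lick.
        cap = min(stop if stop is not None else w_hi, w_hi)
        lo_grid = int(np.ceil(w_lo / LICK_GRID_S))
        hi_grid = max(int(np.floor((cap - 1e-9) / LICK_GRID_S)), lo_grid)
        extra = rng.integers(lo_grid, hi_grid + 1) * LICK_GRID_S
        times = np.sort(np.append(times, extra))
        # Re-enforce the refractory floor around the inserted lick, keeping it.
        times = times[
            (np.abs(times - extra) < 1e-9)
            | (np.abs(times - extra) >= REFRACTORY_S - 1e-9)
        ]
    return times


def simulate_session(
    mouse_id: str,
    preset: BehaviorPreset,
    session: int,
    config: SessionConfig,
    rng: np.random.Generator,
) -> SessionRecord:
    """Simulate one session: schedule, per-trial Bernoulli draws, lick trains."""
    schedule = build_schedule(config, rng)
    p_hit, p_fa = learning_curve(preset, session)
    mult = preset.modality_dprime_scaling.get(config.modality_condition, 1.0)
    if config.modality_condition == "control_no_stimulus":
        # No stimulus: no discrimination; respond at the bias midpoint.
        p_hit, p_fa = modality_adjusted_probabilities(p_hit, p_fa, 0.0)
    elif mult != 1.0:
        p_hit, p_fa = modality_adjusted_probabilities(p_hit, p_fa, mult)
    trials = [
        TrialRecord(
            index=i + 1,
            stimulus_type=stype,
            lick_times=simulate_trial(stype, p_hit, p_fa, preset, config, rng),
        )
        for i, stype in enumerate(schedule.trial_types)
    ]
    return SessionRecord(
        mouse_id=mouse_id,
        genotype=preset.genotype_label,
        session=session,
        trials=trials,
        config=config,
    )


def _mouse_seed_sequence(master_seed: int, mouse_index: int) -> np.random.SeedSequence:
    """Stable per-mouse seed split: SeedSequence(master, spawn_key=(index,))."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(mouse_index,))


@dataclass
class SimulatedMouse:
    """A simulated mouse: identifier, behavioral preset, fixed seed."""

    mouse_id: str
    preset: BehaviorPreset
    seed: np.random.SeedSequence | int

    def simulate(self, configs: list[SessionConfig]) -> list[SessionRecord]:
        """Simulate one session per config (sessions numbered from 1)."""
        rng = np.random.default_rng(self.seed)
        return [
            simulate_session(self.mouse_id, self.preset, s + 1, cfg, rng)
            for s, cfg in enumerate(configs)
        ]


def default_config_sequence(
    n_sessions: int, modality_condition: str = "multimodal", preferred_fraction: float = 0.7
) -> list[SessionConfig]:
    """Standard main-task sequence: 250 trials on session 1, 350 after."""
    return [
        SessionConfig(
            n_trials=250 if s == 0 else 350,
            preferred_fraction=preferred_fraction,
            modality_condition=modality_condition,
        )
        for s in range(n_sessions)
    ]


def simulate_cohort(
    presets: list[BehaviorPreset] | dict[str, tuple[BehaviorPreset, int]],
    n_mice_per_preset: int | None = None,
    n_sessions: int = 14,
    config_sequence: list[SessionConfig] | None = None,
    master_seed: int = 0,
) -> list[SessionRecord]:
    """Simulate a full cohort, deterministic given ``master_seed``.

    ``presets`` is either a list (each simulated for ``n_mice_per_preset``
    mice) or a mapping label -> (preset, n_mice).  Per-mouse seeds are split
    from the master seed by a stable spawning rule, so cohorts are
    reproducible mouse-by-mouse.
    """
    if isinstance(presets, dict):
        groups = [(label, p, n) for label, (p, n) in presets.items()]
    else:
        if not presets:
            raise ValueError("presets must be nonempty")
        if n_mice_per_preset is None or n_mice_per_preset < 1:
            raise ValueError("n_mice_per_preset must be >= 1")
        groups = [(p.genotype_label, p, n_mice_per_preset) for p in presets]
    if not groups:
        raise ValueError("presets must be nonempty")
    if config_sequence is None:
        config_sequence = default_config_sequence(n_sessions)
    else:
        config_sequence = list(config_sequence)

    sessions: list[SessionRecord] = []
    mouse_index = 0
    for label, preset, n_mice in groups:
        for i in range(n_mice):
            mouse = SimulatedMouse(
                mouse_id=f"{label}_{i + 1:02d}",
                preset=preset,
                seed=_mouse_seed_sequence(master_seed, mouse_index),
            )
            sessions.extend(mouse.simulate(config_sequence))
            mouse_index += 1
    return sessions
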