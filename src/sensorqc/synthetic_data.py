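"""Seeded generators for synthetic clinimetric test recordings.

Emulates the structure of short smartphone test recordings: a tri-axial
accelerometer trace is the sum of a piecewise-linear gravitational
orientation trend (norm ~9.81 m/s^2 with occasional slope changes) and a
behavior-dependent dynamic component; a voice recording alternates
sustained phonation with silence and cough bursts.  Every test starts
with a short high-frequency buzzer (the phone announcing the test).
Ground-truth adherence/violation labels and behavior tags are emitted at
raw-sample resolution, aligned exactly with the segment plan.

Behavior repertoire
-------------------
walking test: ``buzzer`` | ``walking`` (adherence) | ``phone_stationary``
| ``irregular``; balance test: ``buzzer`` | ``standing`` (adherence) |
``walking`` | ``transient``; voice test: ``phonation`` (adherence) |
``silence`` | ``cough``.

Walking dynamics are a harmonic gait pattern (fundamental 1.5-2.5 Hz
plus three harmonics, so band-limited well below 15 Hz); the buzzer is a
40 Hz burst, which the walking preset's 15 Hz low-pass removes -- the
segment is then recognisable as a violation by its near-zero residual.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from sensorqc.core_io import (
    ADHERENCE,
    VIOLATION,
    BehaviorSeries,
    DataError,
    LabelSeries,
    SensorRecording,
)

GRAVITY = 9.81
BUZZER_HZ = 40.0

ADHERENT_BEHAVIOR = {"walking": "walking", "balance": "standing",
                     "voice": "phonation"}

DEFAULT_PLANS = {
    "walking": [("buzzer", 0.5), ("walking", 12.0),
                ("phone_stationary", 5.0), ("walking", 9.5),
                ("irregular", 3.0)],
    "balance": [("buzzer", 0.5), ("standing", 14.5), ("walking", 5.0),
                ("standing", 8.0), ("transient", 2.0)],
    "voice": [("silence", 2.0), ("phonation", 10.0), ("cough", 1.0),
              ("silence", 2.0), ("phonation", 5.0)],
}


@dataclasses.dataclass(frozen=True)
class ScenarioConfig:
    """One synthetic clinimetric test scenario.

    duration_s defaults to ~30 s for accelerometer tests and ~20 s for
    voice tests; rate_hz to 100 Hz (accel) / 44,100 Hz (audio).  The
    segment plan is an ordered list of (behavior, duration_s) whose
    durations sum to duration_s.  ``jitter_std`` adds zero-mean Gaussian
    jitter (seconds) to accelerometer timestamps to emulate irregular
    phone sampling.
    """

    test_type: str
    duration_s: Optional[float] = None
    rate_hz: Optional[float] = None
    segment_plan: Optional[Sequence[tuple]] = None
    n_gravity_changepoints: int = 2
    gravity_slope_std: float = 0.05   # m/s^2 per second
    noise_std: float = 0.02           # accel sensor noise, m/s^2
    jitter_std: float = 0.0

    def resolved(self) -> "ScenarioConfig":
        if self.test_type not in DEFAULT_PLANS:
            raise DataError(f"unknown test_type {self.test_type!r}")
        plan = list(self.segment_plan or DEFAULT_PLANS[self.test_type])
        dur = float(sum(d for _, d in plan))
        if self.duration_s is not None and \
                abs(dur - self.duration_s) > 1e-9:
            raise DataError("segment plan durations must sum to duration_s")
        rate = self.rate_hz
        if rate is None:
            rate = 44100.0 if self.test_type == "voice" else 100.0
        return dataclasses.replace(self, duration_s=dur, rate_hz=rate,
                                   segment_plan=tuple(plan))


def _segment_edges(plan, rate: float) -> np.ndarray:
    """Sample index of each segment boundary (exact plan alignment)."""
    times = np.concatenate([[0.0], np.cumsum([d for _, d in plan])])
    return np.round(times * rate).astype(int)


def _behavior_array(plan, edges: np.ndarray) -> np.ndarray:
    b = np.empty(edges[-1], dtype=object)
    for (name, _), a, z in zip(plan, edges, edges[1:]):
        b[a:z] = name
    return b


def _piecewise_linear_gravity(T: int, rate: float, n_changes: int,
                              slope_std: float, rng) -> np.ndarray:
    """Exactly piecewise-linear per-axis trend with norm ~9.81 at t=0."""
    direction = rng.normal(size=3)
    g0 = GRAVITY * direction / np.linalg.norm(direction)
    t = np.arange(T) / rate
    cps = np.sort(rng.uniform(0.1 * t[-1], 0.9 * t[-1], size=n_changes)) \
        if n_changes else np.empty(0)
    trend = np.empty((T, 3))
    for ax in range(3):
        slopes = rng.normal(0.0, slope_std, size=n_changes + 1)
        y = np.full(T, g0[ax]) + slopes[0] * t
        for i, cp in enumerate(cps):
            y += (slopes[i + 1] - slopes[i]) * np.maximum(t - cp, 0.0)
        trend[:, ax] = y
    return trend


def _gait_component(n: int, rate: float, rng) -> np.ndarray:
    """Harmonic gait: fundamental 1.5-2.5 Hz plus three harmonics."""
    t = np.arange(n) / rate
    f0 = rng.uniform(1.5, 2.5)
    out = np.zeros((n, 3))
    for ax in range(3):
        amp0 = rng.uniform(1.0, 3.0)
        for h in range(4):
            amp = amp0 / (h + 1.0)
            phase = rng.uniform(0, 2 * np.pi)
            out[:, ax] += amp * np.sin(2 * np.pi * f0 * (h + 1) * t + phase)
    return out


def _buzzer_component(n: int, rate: float, rng) -> np.ndarray:
    t = np.arange(n) / rate
    tone = 2.0 * np.sin(2 * np.pi * BUZZER_HZ * t)
    return np.tile(tone[:, None], (1, 3)) * rng.uniform(0.6, 1.0, size=3)


def _smoothed_noise(n: int, rng, scale: float, smooth: int) -> np.ndarray:
    raw = rng.normal(0.0, scale, size=(n + smooth, 3))
    kernel = np.ones(smooth) / smooth
    out = np.column_stack([np.convolve(raw[:, ax], kernel, mode="same")
                           for ax in range(3)])
    return out[:n]


def _accel_dynamic(behavior: str, n: int, rate: float, rng) -> np.ndarray:
    if behavior == "walking":
        return _gait_component(n, rate, rng)
    if behavior == "buzzer":
        return _buzzer_component(n, rate, rng)
    if behavior == "phone_stationary":
        return np.zeros((n, 3))
    if behavior == "irregular":
        # aperiodic large movements: a handful of random low-frequency
        # tones (0.8-4 Hz, above the orientation-drift band) with random
        # phases, plus broadband noise
        t = np.arange(n) / rate
        out = np.zeros((n, 3))
        for ax in range(3):
            for _ in range(4):
                f = rng.uniform(0.8, 4.0)
                out[:, ax] += rng.uniform(0.3, 1.2) * np.sin(
                    2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        return out + rng.normal(0.0, 0.3, size=(n, 3))
    if behavior == "standing":
        # low-amplitude broadband postural sway (< 0.3 m/s^2)
        sway = _smoothed_noise(n, rng, 0.25, 5)
        return np.clip(sway, -0.29, 0.29)
    if behavior == "transient":
        out = np.zeros((n, 3))
        n_spikes = max(1, n // int(rate))
        for _ in range(n_spikes):
            i = rng.integers(0, max(1, n - 10))
            out[i:i + 10] += rng.normal(0.0, 4.0, size=3)
        return out
    raise DataError(f"unknown accelerometer behavior {behavior!r}")


def _timestamps(n: int, rate: float, jitter_std: float, rng) -> np.ndarray:
    t = np.arange(n) / rate
    if jitter_std > 0:
        jit = rng.normal(0.0, jitter_std, size=n)
        jit = np.clip(jit, -0.45 / rate, 0.45 / rate)
        t = t + jit
        t[0] = 0.0
    return t


def _gen_accel_test(cfg: ScenarioConfig, seed: int):
    cfg = cfg.resolved()
    if cfg.rate_hz < 2.0 * BUZZER_HZ:
        raise DataError(
            f"rate {cfg.rate_hz} Hz too low to represent the "
            f"{BUZZER_HZ} Hz buzzer tone")
    rng = np.random.default_rng(seed)
    edges = _segment_edges(cfg.segment_plan, cfg.rate_hz)
    T = int(edges[-1])
    b = _behavior_array(cfg.segment_plan, edges)
    dynamic = np.vstack([
        _accel_dynamic(name, z - a, cfg.rate_hz, rng)
        for (name, _), a, z in zip(cfg.segment_plan, edges, edges[1:])])
    gravity = _piecewise_linear_gravity(T, cfg.rate_hz,
                                        cfg.n_gravity_changepoints,
                                        cfg.gravity_slope_std, rng)
    noise = rng.normal(0.0, cfg.noise_std, size=(T, 3))
    samples = gravity + dynamic + noise
    t = _timestamps(T, cfg.rate_hz, cfg.jitter_std, rng)
    rec = SensorRecording(t, samples, nominal_rate=cfg.rate_hz,
                          modality="accel",
                          meta={"test_type": cfg.test_type, "seed": seed,
                                "true_gravity": gravity,
                                "true_dynamic": dynamic})
    adherent = ADHERENT_BEHAVIOR[cfg.test_type]
    u = np.where(b == adherent, ADHERENCE, VIOLATION)
    return rec, LabelSeries(u), BehaviorSeries(b)


def gen_walking_test(cfg: Optional[ScenarioConfig] = None, seed: int = 0):
    """Synthetic walking test: gravity drift + gait / buzzer / violations.

    Returns (recording, raw-sample labels, raw-sample behaviors); only
    ``walking`` samples carry the adherence label.
    """
    cfg = cfg or ScenarioConfig("walking")
    if cfg.test_type != "walking":
        raise DataError("config is not a walking scenario")
    return _gen_accel_test(cfg, seed)


def gen_balance_test(cfg: Optional[ScenarioConfig] = None, seed: int = 0):
    """Synthetic balance test: low-amplitude sway is adherence; walking,
    transient movements and the start buzzer are violations."""
    cfg = cfg or ScenarioConfig("balance")
    if cfg.test_type != "balance":
        raise DataError("config is not a balance scenario")
    return _gen_accel_test(cfg, seed)


def _audio_segment(behavior: str, n: int, rate: float, rng) -> np.ndarray:
    t = np.arange(n) / rate
    background = rng.normal(0.0, 0.003, size=n)
    if behavior == "silence":
        return background
    if behavior == "phonation":
        f0 = rng.uniform(120.0, 220.0)
        x = np.zeros(n)
        for h in range(5):
            amp = 0.3 / (h + 1.0)
            x += amp * np.sin(2 * np.pi * f0 * (h + 1) * t
                              + rng.uniform(0, 2 * np.pi))
        # short onset/offset ramps so transitions are realistic but sharp
        ramp = min(n // 2, int(0.02 * rate))
        env = np.ones(n)
        env[:ramp] = np.linspace(0, 1, ramp)
        env[-ramp:] = np.linspace(1, 0, ramp)
        return x * env + background
    if behavior == "cough":
        burst = rng.normal(0.0, 0.2, size=n)
        env = np.exp(-5.0 * t / max(t[-1], 1e-9))
        return burst * env + background
    raise DataError(f"unknown audio behavior {behavior!r}")


def gen_voice_test(cfg: Optional[ScenarioConfig] = None, seed: int = 0,
                   frame_ms: float = 10.0):
    """Synthetic voice test at 44,100 Hz.

    Returns (audio recording, frame-aligned labels, frame-aligned
    behaviors); labels are per 10-ms frame (441 samples at the default
    rate), majority-voted within each frame with ties going to
    violation.
    """
    cfg = (cfg or ScenarioConfig("voice")).resolved()
    if cfg.test_type != "voice":
        raise DataError("config is not a voice scenario")
    rng = np.random.default_rng(seed)
    edges = _segment_edges(cfg.segment_plan, cfg.rate_hz)
    T = int(edges[-1])
    b = _behavior_array(cfg.segment_plan, edges)
    x = np.concatenate([
        _audio_segment(name, z - a, cfg.rate_hz, rng)
        for (name, _), a, z in zip(cfg.segment_plan, edges, edges[1:])])
    x = np.clip(x, -1.0, 1.0)
    t = np.arange(T) / cfg.rate_hz
    rec = SensorRecording(t, x[:, None], nominal_rate=cfg.rate_hz,
                          modality="audio",
                          meta={"test_type": "voice", "seed": seed})
    u_raw = np.where(b == "phonation", ADHERENCE, VIOLATION)
    n = int(round(cfg.rate_hz * frame_ms / 1000.0))
    n_frames = T // n
    u_frames = np.empty(n_frames, dtype=int)
    b_frames = np.empty(n_frames, dtype=object)
    for k in range(n_frames):
        blk_u = u_raw[k * n:(k + 1) * n]
        adh = int(np.sum(blk_u == ADHERENCE))
        u_frames[k] = ADHERENCE if adh > n - adh else VIOLATION
        blk_b = b[k * n:(k + 1) * n]
        names, counts = np.unique(blk_b.astype(str), return_counts=True)
        b_frames[k] = sorted(names[counts == counts.max()])[0]
    return rec, LabelSeries(u_frames), BehaviorSeries(b_frames)


def _random_plan(test_type: str, rng) -> list:
    """Randomised segment plan covering the behavior repertoire."""
    if test_type == "voice":
        plan = [("silence", float(rng.uniform(1.0, 3.0)))]
        for _ in range(rng.integers(2, 4)):
            plan.append(("phonation", float(rng.uniform(3.0, 7.0))))
            plan.append((str(rng.choice(["silence", "cough"])),
                         float(rng.uniform(0.5, 2.5))))
        return plan
    adherent = ADHERENT_BEHAVIOR[test_type]
    violations = (["phone_stationary", "irregular"] if test_type == "walking"
                  else ["walking", "transient"])
    plan = [("buzzer", 0.5)]
    for _ in range(rng.integers(2, 4)):
        plan.append((adherent, float(rng.uniform(5.0, 10.0))))
        plan.append((str(rng.choice(violations)),
                     float(rng.uniform(1.5, 5.0))))
    return plan


def gen_controlled_suite(n_per_type: int = 32, seed: int = 0,
                         test_types: Sequence[str] = ("walking", "balance",
                                                      "voice")) -> dict:
    """A suite of controlled tests with randomised segment plans.

    Returns {test_type: [(recording, labels, behaviors), ...]} with
    n_per_type tests per type.  Per-test seeds are derived from ``seed``
    by counter so the suite is reproducible element-wise; the plans are
    constrained so that every behavior in the repertoire appears in at
    least one test of each type.
    """
    gens = {"walking": gen_walking_test, "balance": gen_balance_test,
            "voice": gen_voice_test}
    plan_rng = np.random.default_rng(seed)
    suite: dict = {}
    counter = 0
    for tt in test_types:
        tests = []
        for i in range(n_per_type):
            counter += 1
            test_seed = int((seed * 100003 + counter) % (2 ** 31))
            if i == 0:
                plan = DEFAULT_PLANS[tt]   # covers the full repertoire
            else:
                plan = _random_plan(tt, plan_rng)
            cfg = ScenarioConfig(tt, segment_plan=plan)
            tests.append(gens[tt](cfg, seed=test_seed))
        suite[tt] = tests
    return suite
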