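"""Seeded synthetic TMS-EEG sessions with known ground truth.

Every downstream stage of the pipeline is testable without real data: this
module generates continuous EEG as a time-varying vector-autoregressive (VAR)
background process with a known directed-coupling schedule, superposes
Gaussian ERP templates time-locked to the second stimulus, injects an
exponentially decaying pulse artifact on real-stimulation trials, and emits a
fully consistent behavioral trial table.

Trial timeline (emulating a dual-feature delayed matching task under
single-pulse stimulation): S1 for 500 ms, a 500 ms interstimulus interval with
the pulse 300 ms before S2, S2 for 500 ms, and 5 s from the end of S2 to the
next S1.  Four equiprobable stimulus-pair types cross with task (color/shape)
and condition (sham/real) into 16 cells.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import Recording
from .montage import MONTAGE_21

__all__ = [
    "CoeffSchedule",
    "ErpTemplate",
    "simulate_tvmvar",
    "simulate_session",
    "simulate_behavior",
    "default_background",
    "default_templates",
    "REPORTED_RT_MS",
    "REPORTED_ACC",
    "CONDITIONS",
    "TASKS",
    "STIM_TYPES",
    "TRIAL_COLUMNS",
]

CONDITIONS = ("sham", "real")
TASKS = ("color", "shape")
STIM_TYPES = ("match", "task_relevant", "task_irrelevant", "conjunction")

TRIAL_COLUMNS = [
    "trial", "task", "condition", "stim_type", "correct", "rt_ms",
    "s1_sample", "tms_sample", "s2_sample",
]

# Reported group-mean reaction times (ms) per (condition, task, stim type);
# these are the generator's default RT cell means.
REPORTED_RT_MS: dict[tuple[str, str, str], float] = {
    ("sham", "color", "match"): 573.8, ("sham", "shape", "match"): 555.6,
    ("real", "color", "match"): 527.4, ("real", "shape", "match"): 524.4,
    ("sham", "color", "task_relevant"): 616.4, ("sham", "shape", "task_relevant"): 638.9,
    ("real", "color", "task_relevant"): 572.9, ("real", "shape", "task_relevant"): 602.8,
    ("sham", "color", "task_irrelevant"): 559.3, ("sham", "shape", "task_irrelevant"): 574.5,
    ("real", "color", "task_irrelevant"): 533.8, ("real", "shape", "task_irrelevant"): 547.4,
    ("sham", "color", "conjunction"): 623.6, ("sham", "shape", "conjunction"): 614.7,
    ("real", "color", "conjunction"): 578.2, ("real", "shape", "conjunction"): 599.3,
}

# Default per-cell correct-response probabilities (reported correct rates / 100).
REPORTED_ACC: dict[tuple[str, str, str], float] = {
    ("sham", "color", "match"): 0.983, ("sham", "shape", "match"): 0.993,
    ("real", "color", "match"): 0.990, ("real", "shape", "match"): 0.992,
    ("sham", "color", "task_relevant"): 0.992, ("sham", "shape", "task_relevant"): 0.986,
    ("real", "color", "task_relevant"): 0.990, ("real", "shape", "task_relevant"): 0.986,
    ("sham", "color", "task_irrelevant"): 0.990, ("sham", "shape", "task_irrelevant"): 0.991,
    ("real", "color", "task_irrelevant"): 0.991, ("real", "shape", "task_irrelevant"): 0.981,
    ("sham", "color", "conjunction"): 0.984, ("sham", "shape", "conjunction"): 0.992,
    ("real", "color", "conjunction"): 0.993, ("real", "shape", "conjunction"): 0.983,
}

# Trial timing (seconds). S2 - S1 = 1.0 s and S2 - pulse = 0.3 s by construction.
S1_DURATION = 0.5
ISI = 0.5
TMS_BEFORE_S2 = 0.3
S2_DURATION = 0.5
INTER_TRIAL = 5.0  # end of S2 to next S1 onset
LEAD_IN = 2.0  # fixation before the first S1

RT_SHIFT_MS = 150.0  # shift of the shifted-lognormal RT distribution


def _companion(coeffs: np.ndarray) -> np.ndarray:
    """Companion matrix of a VAR(p) coefficient stack (p, n, n)."""
    p, n, _ = coeffs.shape
    top = np.concatenate([coeffs[i] for i in range(p)], axis=1)
    if p == 1:
        return top
    eye = np.eye(n * (p - 1))
    bottom = np.concatenate([eye, np.zeros((n * (p - 1), n))], axis=1)
    return np.concatenate([top, bottom], axis=0)


def spectral_radius(coeffs: np.ndarray) -> float:
    """Spectral radius of the companion matrix of a VAR coefficient stack."""
    return float(np.max(np.abs(np.linalg.eigvals(_companion(np.asarray(coeffs, float))))))


@dataclass
class CoeffSchedule:
    """Piecewise schedule of time-varying VAR coefficients (the ground truth).

    ``breakpoints`` maps onset times (s) to coefficient stacks of shape
    (order, n, n); before the first breakpoint the first stack applies.  Each
    stack must define a stable stationary VAR (companion spectral radius < 1).
    ``interpolation`` is ``"step"`` (piecewise constant) or ``"linear"``.
    """

    breakpoints: list[tuple[float, np.ndarray]]
    interpolation: str = "step"

    def __post_init__(self) -> None:
        if not self.breakpoints:
            raise ValueError("schedule needs at least one breakpoint")
        if self.interpolation not in ("step", "linear"):
            raise ValueError("interpolation must be 'step' or 'linear'")
        self.breakpoints = [(float(t), np.asarray(a, dtype=float))
                            for t, a in self.breakpoints]
        times = [t for t, _ in self.breakpoints]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("breakpoint times must be strictly increasing")
        shape = self.breakpoints[0][1].shape
        if len(shape) != 3 or shape[1] != shape[2]:
            raise ValueError("coefficient tensors must be (order, n, n)")
        for t, a in self.breakpoints:
            if a.shape != shape:
                raise ValueError("all coefficient tensors must share one shape")
            rho = spectral_radius(a)
            if rho >= 1.0:
                raise ValueError(
                    f"unstable VAR at breakpoint t={t:g}s (spectral radius {rho:.3f})"
                )

    @property
    def order(self) -> int:
        return self.breakpoints[0][1].shape[0]

    @property
    def n_channels(self) -> int:
        return self.breakpoints[0][1].shape[1]

    def coeffs_at(self, t: float) -> np.ndarray:
        """Coefficient stack in effect at time ``t`` (seconds)."""
        times = [bt for bt, _ in self.breakpoints]
        if t <= times[0]:
            return self.breakpoints[0][1]
        if t >= times[-1]:
            return self.breakpoints[-1][1]
        k = int(np.searchsorted(times, t, side="right")) - 1
        if self.interpolation == "step":
            return self.breakpoints[k][1]
        t0, a0 = self.breakpoints[k]
        t1, a1 = self.breakpoints[k + 1]
        w = (t - t0) / (t1 - t0)
        return (1.0 - w) * a0 + w * a1


@dataclass
class ErpTemplate:
    """A Gaussian-in-time ERP component superposed on the background EEG.

    Peak latency is relative to S2 onset; ``gains`` scales the waveform per
    channel (channels absent from the map receive zero); ``modulation`` scales
    the amplitude per (condition, task, stim_type) cell, defaulting to 1.
    Gaussians keep window means analytic, so planted amplitudes can be checked
    in closed form.
    """

    name: str
    latency_ms: float
    amplitude_uv: float
    width_ms: float
    gains: dict[str, float] = field(default_factory=dict)
    modulation: dict[tuple[str, str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")

    def cell_factor(self, condition: str, task: str, stim_type: str) -> float:
        return self.modulation.get((condition, task, stim_type), 1.0)

    def waveform(self, times_s: np.ndarray) -> np.ndarray:
        """Unit-gain waveform on a time axis (s) relative to S2 onset."""
        mu = self.latency_ms / 1000.0
        sigma = self.width_ms / 1000.0
        return self.amplitude_uv * np.exp(-0.5 * ((times_s - mu) / sigma) ** 2)


def simulate_tvmvar(
    schedule: CoeffSchedule,
    noise_cov: np.ndarray,
    duration: float,
    fs: float,
    seed: int,
    channels: list[str] | None = None,
) -> Recording:
    """Simulate a time-varying VAR process X(t) = Σ_i A(i,t) X(t−i) + E(t).

    E(t) is multivariate Gaussian with covariance ``noise_cov``.  A burn-in of
    10·order samples is generated under the t=0 coefficients and discarded, so
    the returned series starts near the stationary regime of the initial
    coefficient stack.  Identical arguments and seed give identical output.
    """
    n = schedule.n_channels
    p = schedule.order
    noise_cov = np.asarray(noise_cov, dtype=float)
    if noise_cov.shape != (n, n):
        raise ValueError(f"noise_cov must be {n}x{n}")
    if not np.allclose(noise_cov, noise_cov.T):
        raise ValueError("noise_cov must be symmetric")
    try:
        chol = np.linalg.cholesky(noise_cov)
    except np.linalg.LinAlgError:
        raise ValueError("noise_cov must be positive definite") from None
    n_samples = int(round(duration * fs))
    if n_samples < 10 * p:
        raise ValueError("duration*fs must be at least 10*order samples")
    burn = 10 * p
    rng = np.random.default_rng(seed)
    innov = rng.standard_normal((burn + n_samples, n)) @ chol.T
    x = np.zeros((burn + n_samples, n))
    # precompute per-sample coefficient stacks (burn-in uses the t=0 stack)
    for t in range(burn + n_samples):
        a = schedule.coeffs_at(max(t - burn, 0) / fs)
        acc = innov[t].copy()
        for i in range(1, min(p, t) + 1):
            acc += a[i - 1] @ x[t - i]
        x[t] = acc
    if channels is None:
        channels = [f"ch{i}" for i in range(n)]
    return Recording(signal=x[burn:].T, fs=fs, channels=list(channels), events=[])


def _cell_iter() -> list[tuple[str, str, str]]:
    return list(itertools.product(CONDITIONS, TASKS, STIM_TYPES))


def simulate_behavior(
    n_trials_per_cell: int,
    rt_means: dict[tuple[str, str, str], float] | None = None,
    rt_sigma: float = 0.175,
    accuracy: dict[tuple[str, str, str], float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-cell reaction times and correctness.

    RTs follow a shifted lognormal (shift 150 ms) whose mean equals the
    requested cell mean; ``rt_sigma`` is the lognormal shape parameter
    (``rt_sigma == 0`` degenerates to every RT equal to the cell mean).  The
    default 0.175 yields cell SDs near the reported ±70-90 ms spread.
    Correctness is Bernoulli with the per-cell probability.
    """
    if n_trials_per_cell < 1:
        raise ValueError("n_trials_per_cell must be >= 1")
    rt_means = dict(REPORTED_RT_MS) if rt_means is None else dict(rt_means)
    accuracy = dict(REPORTED_ACC) if accuracy is None else dict(accuracy)
    cells = _cell_iter()
    for key in rt_means:
        if key not in cells:
            raise KeyError(f"unknown cell key {key!r}")
    for key, acc in accuracy.items():
        if key not in cells:
            raise KeyError(f"unknown cell key {key!r}")
        if not 0.0 <= acc <= 1.0:
            raise ValueError(f"accuracy for {key!r} outside [0, 1]")
    if any(v <= RT_SHIFT_MS for v in rt_means.values()):
        raise ValueError(f"rt_means must exceed the {RT_SHIFT_MS:g} ms shift")
    rng = np.random.default_rng(seed)
    rows = []
    for cond, task, stype in cells:
        mean = rt_means[(cond, task, stype)]
        acc = accuracy[(cond, task, stype)]
        if rt_sigma > 0:
            mu = np.log(mean - RT_SHIFT_MS) - 0.5 * rt_sigma**2
            rts = RT_SHIFT_MS + rng.lognormal(mu, rt_sigma, size=n_trials_per_cell)
        else:
            rts = np.full(n_trials_per_cell, mean)
        correct = rng.random(n_trials_per_cell) < acc
        for rt, ok in zip(rts, correct):
            rows.append((task, cond, stype, bool(ok), float(rt)))
    df = pd.DataFrame(rows, columns=["task", "condition", "stim_type", "correct", "rt_ms"])
    # randomized presentation order, seeded
    df = df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    df.insert(0, "trial", np.arange(len(df)))
    return df


def default_background(
    n_channels: int = 21,
    order: int = 2,
    seed: int = 0,
    coupling: float = 0.25,
    radius: float = 0.7,
) -> CoeffSchedule:
    """A random stable sparse VAR(order) schedule for background activity.

    Diagonal lag-1 terms give each channel alpha-band-free 1/f-ish smoothness;
    a sparse random off-diagonal coupling (density ~10%) is rescaled so the
    companion spectral radius equals ``radius``.
    """
    rng = np.random.default_rng(seed)
    a = np.zeros((order, n_channels, n_channels))
    a[0] = np.diag(np.full(n_channels, 0.5))
    mask = rng.random((n_channels, n_channels)) < 0.1
    np.fill_diagonal(mask, False)
    a[0] += coupling * mask * rng.standard_normal((n_channels, n_channels))
    if order > 1:
        a[1] = np.diag(np.full(n_channels, 0.2))
    rho = spectral_radius(a)
    if rho > 0:
        # rescaling lags by s^k scales the companion spectrum by s
        s = radius / rho
        for k in range(order):
            a[k] *= s ** (k + 1)
    return CoeffSchedule(breakpoints=[(0.0, a)])


def default_templates() -> list[ErpTemplate]:
    """Default ERP component set reproducing the study's qualitative pattern.

    P1/N1 load on posterior electrodes, N270/P3 centro-parietally.  The N270
    is present only for mismatch pairs and attenuated (less negative) under
    real stimulation — the planted conflict effect; P1 is enhanced under real
    stimulation; P3 is condition-insensitive.
    """
    posterior = {"P3": 1.0, "P4": 1.0, "O1": 1.0, "O2": 1.0, "Pz": 0.8,
                 "T5": 0.6, "T6": 0.6, "Oz": 0.9}
    centroparietal = {"C3": 1.0, "C4": 1.0, "P3": 1.0, "P4": 1.0,
                      "Cz": 0.9, "Pz": 0.9}
    mismatch = [t for t in STIM_TYPES if t != "match"]
    p1_mod = {("real", task, st): 1.6 for task in TASKS for st in STIM_TYPES}
    n270_mod: dict[tuple[str, str, str], float] = {}
    for task in TASKS:
        n270_mod[("sham", task, "match")] = 0.0
        n270_mod[("real", task, "match")] = 0.0
        for st in mismatch:
            n270_mod[("sham", task, st)] = 1.0
            n270_mod[("real", task, st)] = 0.45  # attenuated conflict response
    return [
        ErpTemplate("P1", 85.0, 3.0, 20.0, posterior, p1_mod),
        ErpTemplate("N1", 150.0, -8.0, 30.0, posterior),
        ErpTemplate("N270", 270.0, -6.0, 25.0, centroparietal, n270_mod),
        ErpTemplate("P3", 400.0, 9.0, 60.0, centroparietal),
    ]


def simulate_session(
    n_trials_per_cell: int,
    montage: list[str] | None = None,
    templates: list[ErpTemplate] | None = None,
    artifact_spec: tuple[float, float] = (300.0, 15.0),
    background: CoeffSchedule | None = None,
    fs: float = 1024.0,
    seed: int = 0,
    noise_scale: float = 5.0,
    rt_sigma: float = 0.175,
) -> tuple[Recording, pd.DataFrame]:
    """Generate one continuous session: EEG recording plus trial table.

    The recording is background tv-VAR activity plus per-trial ERP templates
    time-locked to S2 and, on real-condition trials, a signed exponentially
    decaying artifact of ``artifact_spec = (amplitude µV, decay ms)`` starting
    at the pulse sample.  Events ``S1``/``TMS``/``S2`` are emitted per trial;
    the trial table records their sample indices together with the behavioral
    draw.  Identical arguments and seed give bit-identical output.
    """
    if n_trials_per_cell < 1:
        raise ValueError("n_trials_per_cell must be >= 1")
    montage = list(MONTAGE_21) if montage is None else list(montage)
    if not montage:
        raise ValueError("montage must be non-empty")
    if templates is None:
        # default components adapt to the montage at hand
        templates = []
        for tpl in default_templates():
            gains = {ch: g for ch, g in tpl.gains.items() if ch in montage}
            templates.append(ErpTemplate(tpl.name, tpl.latency_ms, tpl.amplitude_uv,
                                         tpl.width_ms, gains, tpl.modulation))
    for tpl in templates:
        unknown = set(tpl.gains) - set(montage)
        if unknown:
            raise ValueError(
                f"template {tpl.name!r} references channels not in montage: {sorted(unknown)}"
            )
    if background is None:
        background = default_background(len(montage), seed=seed)
    if background.n_channels != len(montage):
        raise ValueError("background schedule channel count must match montage")

    rng = np.random.default_rng(seed)
    trials = simulate_behavior(
        n_trials_per_cell, rt_sigma=rt_sigma, seed=int(rng.integers(2**31))
    )
    n_trials = len(trials)

    trial_span = S1_DURATION + ISI + S2_DURATION + INTER_TRIAL  # S1 to next S1
    duration = LEAD_IN + n_trials * trial_span + 1.0
    bg_seed = int(rng.integers(2**31))
    if noise_scale > 0:
        noise_cov = (noise_scale**2) * np.eye(len(montage))
        rec = simulate_tvmvar(background, noise_cov, duration, fs, seed=bg_seed,
                              channels=montage)
    else:  # noise off: pure template superposition, background identically zero
        rec = Recording(
            signal=np.zeros((len(montage), int(round(duration * fs)))),
            fs=fs, channels=montage, events=[],
        )
    signal = rec.signal
    n_samples = signal.shape[1]

    s1 = (LEAD_IN + np.arange(n_trials) * trial_span) * fs
    s1_samples = np.round(s1).astype(int)
    s2_samples = s1_samples + int(round((S1_DURATION + ISI) * fs))  # S1 + 1.0 s
    tms_samples = s2_samples - int(round(TMS_BEFORE_S2 * fs))

    trials = trials.copy()
    trials["s1_sample"] = s1_samples
    trials["tms_sample"] = tms_samples
    trials["s2_sample"] = s2_samples
    trials = trials[TRIAL_COLUMNS]

    # ERP superposition, time-locked to S2
    erp_window = int(round(0.8 * fs))  # components live within S2..S2+800 ms
    t_axis = np.arange(erp_window) / fs
    gain_vec = {tpl.name: np.array([tpl.gains.get(ch, 0.0) for ch in montage])
                for tpl in templates}
    wave = {tpl.name: tpl.waveform(t_axis) for tpl in templates}
    amp_uv, decay_ms = artifact_spec
    art_len = int(round(min(8.0 * decay_ms / 1000.0, 0.3) * fs)) if decay_ms > 0 else 0
    art = amp_uv * np.exp(-np.arange(art_len) / (decay_ms / 1000.0 * fs)) \
        if art_len else np.zeros(0)

    events: list[tuple[str, int]] = []
    for row in trials.itertuples(index=False):
        events.append(("S1", int(row.s1_sample)))
        events.append(("TMS", int(row.tms_sample)))
        events.append(("S2", int(row.s2_sample)))
        s2 = int(row.s2_sample)
        stop = min(s2 + erp_window, n_samples)
        for tpl in templates:
            f = tpl.cell_factor(row.condition, row.task, row.stim_type)
            if f == 0.0:
                continue
            signal[:, s2:stop] += f * np.outer(gain_vec[tpl.name], wave[tpl.name][: stop - s2])
        if row.condition == "real" and art_len:
            ts = int(row.tms_sample)
            stop_a = min(ts + art_len, n_samples)
            signal[:, ts:stop_a] += art[: stop_a - ts]
    rec.events = events
    return rec, trials
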