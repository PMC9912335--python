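"""Synthetic nanopore current traces: state kinetics, noise, filtering.

The generator emulates the three-level phenomenology of an origami-docked
nanopore recording: an open-pore level I0, a docked level I_d (fraction of
I0) after the origami sphere lands on the pore, and a deeper trapped level
while a protein is held in the pore by the electro-osmotic flow.  State
dynamics are a continuous-time Markov chain with bias-dependent rates:

* docking (open -> docked) requires positive bias (electrophoretic landing);
* spontaneous undocking (docked -> open) at positive bias, zero for a
  cholesterol-locked sphere;
* ejection (docked -> open) at negative bias — fast for a bare sphere,
  zero when cholesterol anchors lock the sphere to the lipid coat;
* capture (docked -> trapped) requires positive bias (EOF on); escape
  (trapped -> docked) is always active.

Rendering scales the state levels linearly with the protocol voltage
(levels are defined at the +100 mV reference), adds Gaussian white noise
plus 1/f^alpha pink noise synthesized in the frequency domain, and applies
a causal low-pass filter (4-pole Bessel, 10 kHz by default) as the
acquisition electronics would.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import scipy.signal

__all__ = [
    "STATE_OPEN",
    "STATE_DOCKED",
    "STATE_TRAPPED",
    "KineticScheme",
    "NoiseModel",
    "AcquisitionSpec",
    "VoltageProtocol",
    "StatePath",
    "CurrentTrace",
    "simulate_state_path",
    "render_trace",
    "make_fixture",
    "PRESETS",
    "bessel_sos",
    "filter_band_integral",
    "filter_enbw",
]

STATE_OPEN = 0
STATE_DOCKED = 1
STATE_TRAPPED = 2

REFERENCE_VOLTAGE_MV = 100.0


@dataclass(frozen=True)
class KineticScheme:
    """State levels and transition rates of the docking/trapping chain.

    Levels are fractions: ``docked_level`` of the open-pore current I0,
    ``attempt_level`` (optional, rendering only) of I0, ``trapped_level``
    of the *docked* current.  Rates are per second; see the module
    docstring for which rates act at which bias polarity.
    """

    open_current_pA: float = 1529.4
    docked_level: float = 0.83
    trapped_level: float = 0.8
    attempt_level: float | None = None
    docking_rate: float = 0.0
    undocking_rate: float = 0.0
    eject_rate: float = 0.0
    capture_rate: float = 0.0
    escape_rate: float = 0.0
    initial_state: int = STATE_DOCKED

    def __post_init__(self) -> None:
        for name in ("docking_rate", "undocking_rate", "eject_rate", "capture_rate", "escape_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 < self.docked_level <= 1.0):
            raise ValueError("docked_level must lie in (0, 1]")
        if not (0.0 < self.trapped_level < 1.0):
            raise ValueError("trapped_level must lie in (0, 1): trapping deepens the blockade")
        if self.attempt_level is not None and not (0.0 < self.attempt_level <= 1.0):
            raise ValueError("attempt_level must lie in (0, 1]")
        if self.initial_state not in (STATE_OPEN, STATE_DOCKED, STATE_TRAPPED):
            raise ValueError("unknown initial state")

    def level_fraction(self, state: int) -> float:
        """Current level of a state as a fraction of the open-pore level."""
        if state == STATE_OPEN:
            return 1.0
        if state == STATE_DOCKED:
            return self.docked_level
        return self.docked_level * self.trapped_level


@dataclass(frozen=True)
class NoiseModel:
    """Additive noise: white floor plus 1/f^alpha low-frequency excess.

    ``white_psd`` is the one-sided white level in pA^2/Hz; the pink PSD is
    ``pink_A / f**alpha`` (pA^2/Hz with ``pink_A`` in pA^2 at alpha = 1).
    """

    white_psd: float = 0.0
    pink_A: float = 0.0
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.white_psd < 0 or self.pink_A < 0:
            raise ValueError("noise coefficients must be non-negative")
        if not (0.5 <= self.alpha <= 1.5):
            raise ValueError("pink exponent alpha must lie in [0.5, 1.5]")

    @classmethod
    def from_sigma(
        cls, sigma_pA: float, acq: "AcquisitionSpec", pink_A: float = 0.0, alpha: float = 1.0
    ) -> "NoiseModel":
        """White level chosen so the filtered trace has RMS ``sigma_pA``
        when measured in the acquisition bandwidth (brick-wall at the
        filter cutoff), plus an optional pink component."""
        band = filter_band_integral(acq, acq.cutoff_hz)
        return cls(white_psd=sigma_pA**2 / band, pink_A=pink_A, alpha=alpha)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Sampling and anti-alias filtering of the recording chain."""

    sample_rate_hz: float = 125e3
    cutoff_hz: float = 10e3
    filter_order: int = 4
    duration_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cutoff_hz >= 0.5 * self.sample_rate_hz:
            raise ValueError("filter cutoff must lie below the Nyquist frequency")
        if self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("duration and sample rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate_hz))


@dataclass(frozen=True)
class VoltageProtocol:
    """Piecewise-constant applied-voltage protocol: (duration s, voltage mV)."""

    segments: tuple[tuple[float, float], ...] = ((np.inf, 100.0),)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        for dur, _ in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be positive")

    @classmethod
    def constant(cls, voltage_mV: float = 100.0) -> "VoltageProtocol":
        return cls(((np.inf, voltage_mV),))

    @classmethod
    def alternating(cls, period_s: float, n_cycles: int,
                    high_mV: float = 100.0, low_mV: float = -100.0) -> "VoltageProtocol":
        segs = []
        for _ in range(n_cycles):
            segs.append((period_s, high_mV))
            segs.append((period_s, low_mV))
        return cls(tuple(segs))

    def boundaries(self) -> np.ndarray:
        """Cumulative segment end times (s)."""
        return np.cumsum([d for d, _ in self.segments])

    def voltage_at(self, t: np.ndarray) -> np.ndarray:
        edges = self.boundaries()
        volts = np.array([v for _, v in self.segments])
        idx = np.minimum(np.searchsorted(edges, t, side="right"), len(volts) - 1)
        return volts[idx]


@dataclass(frozen=True)
class StatePath:
    """Piecewise-constant state path: transition times and the state
    entered at each; ``times[0]`` is 0 with the initial state."""

    times: np.ndarray
    states: np.ndarray
    duration: float

    def state_at(self, t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return self.states[np.maximum(idx, 0)]

    def dwell_times(self, state: int, drop_last: bool = True) -> np.ndarray:
        """Completed sojourn durations in ``state``; the final (censored)
        sojourn is dropped unless ``drop_last`` is False."""
        edges = np.append(self.times, self.duration)
        durations = np.diff(edges)
        mask = self.states == state
        if drop_last and len(self.states) and mask[-1]:
            mask = mask.copy()
            mask[-1] = False
        return durations[mask]


@dataclass
class CurrentTrace:
    """Uniformly sampled current (pA) with full acquisition provenance."""

    samples: np.ndarray
    acquisition: AcquisitionSpec
    protocol: VoltageProtocol
    params: dict = field(default_factory=dict)

    @property
    def sample_rate(self) -> float:
        return self.acquisition.sample_rate_hz

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate

    def metadata_json(self) -> str:
        meta = {
            "acquisition": asdict(self.acquisition),
            "protocol": [[d if np.isfinite(d) else "inf", v] for d, v in self.protocol.segments],
            "params": self.params,
        }
        return json.dumps(meta)


# --------------------------------------------------------------------- #
# filtering helpers
# --------------------------------------------------------------------- #

def bessel_sos(acq: AcquisitionSpec):
    """Causal low-pass Bessel filter (magnitude-matched -3 dB at cutoff)."""
    return scipy.signal.bessel(
        acq.filter_order, acq.cutoff_hz, btype="low", output="sos",
        fs=acq.sample_rate_hz, norm="mag",
    )

def _filter_response(acq: AcquisitionSpec, n: int = 4096):
    sos = bessel_sos(acq)
    w, h = scipy.signal.sosfreqz(sos, worN=n, fs=acq.sample_rate_hz)
    return w, np.abs(h) ** 2


def filter_band_integral(acq: AcquisitionSpec, upper_hz: float) -> float:
    """integral_0^upper |H(f)|^2 df of the acquisition filter (Hz)."""
    w, h2 = _filter_response(acq)
    m = w <= upper_hz
    return float(np.trapezoid(h2[m], w[m]))


def filter_enbw(acq: AcquisitionSpec) -> float:
    """Equivalent noise bandwidth of the acquisition filter (Hz)."""
    w, h2 = _filter_response(acq)
    return float(np.trapezoid(h2, w))


# --------------------------------------------------------------------- #
# state-path simulation
# --------------------------------------------------------------------- #

def _rate_matrix(scheme: KineticScheme, voltage_mV: float) -> dict[int, list[tuple[int, float]]]:
    """Outgoing (target, rate) lists per state at the given bias."""
    positive = voltage_mV > 0
    out: dict[int, list[tuple[int, float]]] = {STATE_OPEN: [], STATE_DOCKED: [], STATE_TRAPPED: []}
    if positive and scheme.docking_rate > 0:
        out[STATE_OPEN].append((STATE_DOCKED, scheme.docking_rate))
    if positive and scheme.undocking_rate > 0:
        out[STATE_DOCKED].append((STATE_OPEN, scheme.undocking_rate))
    if not positive and scheme.eject_rate > 0:
        out[STATE_DOCKED].append((STATE_OPEN, scheme.eject_rate))
    if positive and scheme.capture_rate > 0:
        out[STATE_DOCKED].append((STATE_TRAPPED, scheme.capture_rate))
    if scheme.escape_rate > 0:
        out[STATE_TRAPPED].append((STATE_DOCKED, scheme.escape_rate))
    return out


def simulate_state_path(
    scheme: KineticScheme,
    duration: float,
    seed: int | np.random.Generator,
    protocol: VoltageProtocol | None = None,
) -> StatePath:
    """Exact stochastic (Gillespie) simulation of the state chain.

    Exponential waiting times are drawn per state from the total outgoing
    rate at the current bias polarity; at protocol segment boundaries the
    clock is advanced and waiting times redrawn (valid by memorylessness).
    A state with no outgoing rate simply persists.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    protocol = protocol or VoltageProtocol.constant()
    edges = protocol.boundaries()
    volts = [v for _, v in protocol.segments]

    times = [0.0]
    states = [scheme.initial_state]
    t = 0.0
    state = scheme.initial_state
    seg = 0
    rates = _rate_matrix(scheme, volts[seg])
    while t < duration:
        seg_end = min(edges[seg] if seg < len(edges) else np.inf, duration)
        outgoing = rates[state]
        total = sum(r for _, r in outgoing)
        if total <= 0:
            t = seg_end
        else:
            wait = rng.exponential(1.0 / total)
            if t + wait >= seg_end:
                t = seg_end
            else:
                t += wait
                u = rng.uniform(0.0, total)
                acc = 0.0
                for target, r in outgoing:
                    acc += r
                    if u <= acc:
                        state = target
                        break
                times.append(t)
                states.append(state)
                continue
        if t >= duration:
            break
        if seg < len(edges) and t >= edges[seg] - 1e-15:
            seg += 1
            if seg >= len(volts):
                break
            rates = _rate_matrix(scheme, volts[seg])
    return StatePath(np.asarray(times), np.asarray(states, dtype=np.int8), duration)


# --------------------------------------------------------------------- #
# trace rendering
# --------------------------------------------------------------------- #

def _pink_noise(n: int, fs: float, A: float, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with one-sided PSD A/f^alpha, via spectral synthesis."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = np.sqrt(A / freqs[1:] ** alpha * fs * n / 2.0)
    re = rng.standard_normal(len(freqs))
    im = rng.standard_normal(len(freqs))
    spec = amp * (re + 1j * im) / np.sqrt(2.0)
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = amp[-1] * re[-1]
    return np.fft.irfft(spec, n=n)


def render_trace(
    path: StatePath,
    scheme: KineticScheme,
    noise: NoiseModel,
    acq: AcquisitionSpec,
    protocol: VoltageProtocol | None = None,
    seed: int | np.random.Generator | None = None,
    apply_filter: bool = True,
) -> CurrentTrace:
    """Render a state path into a sampled, noisy, filtered current trace.

    The clean level is the state's fractional level times I0, scaled by
    the instantaneous protocol voltage relative to +100 mV (sign and
    magnitude).  Pink noise is synthesized in the frequency domain with
    seed-deterministic phases, white noise in the time domain; the causal
    acquisition filter is applied last.
    """
    protocol = protocol or VoltageProtocol.constant()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        acq.seed if seed is None else seed
    )
    n = int(round(path.duration * acq.sample_rate_hz))
    t = np.arange(n) / acq.sample_rate_hz
    state = path.state_at(t)
    levels = np.array([scheme.level_fraction(s) for s in (STATE_OPEN, STATE_DOCKED, STATE_TRAPPED)])
    x = levels[state] * scheme.open_current_pA
    x = x * (protocol.voltage_at(t) / REFERENCE_VOLTAGE_MV)

    if noise.white_psd > 0:
        sigma_raw = np.sqrt(noise.white_psd * acq.sample_rate_hz / 2.0)
        x = x + rng.normal(0.0, sigma_raw, size=n)
    if noise.pink_A > 0:
        x = x + _pink_noise(n, acq.sample_rate_hz, noise.pink_A, noise.alpha, rng)

    if apply_filter:
        x = scipy.signal.sosfilt(bessel_sos(acq), x)

    params = {
        "scheme": asdict(scheme),
        "noise": asdict(noise),
    }
    acq_n = replace(acq, duration_s=n / acq.sample_rate_hz)
    return CurrentTrace(samples=np.asarray(x, dtype=np.float64), acquisition=acq_n,
                        protocol=protocol, params=params)


# --------------------------------------------------------------------- #
# presets parameterized from the study's printed numbers
# --------------------------------------------------------------------- #

# Open-pore current chosen so that sigma = 8 pA and SNR = <dI>/sigma = 32.5
# give dI = 260 pA, which is 17% of I0 for the vertical docked level.
_I0_PA = 260.0 / 0.17

# Pink coefficients: locked spheres have ~10x less 1/f noise than bare ones;
# with a white floor at the open-pore sigma ~7.3 pA these reproduce the
# reported total sigma of 8 pA (locked) and 13 pA (bare) in a 10 kHz band.
_PINK_LOCKED = 1.5
_PINK_BARE = 15.0


def _sigma_white_for_total(total_sigma: float, pink_A: float, acq: AcquisitionSpec) -> float:
    """White-component sigma such that white + pink integrate to the total
    in the acquisition band (pink integrated over 1 Hz .. cutoff)."""
    pink_var = pink_A * np.log(acq.cutoff_hz / 1.0)
    white_var = total_sigma**2 - pink_var
    if white_var <= 0:
        raise ValueError("pink component alone exceeds the requested total sigma")
    return float(np.sqrt(white_var))


def _preset_table(acq: AcquisitionSpec) -> dict[str, tuple[KineticScheme, NoiseModel, VoltageProtocol]]:
    locked_white = _sigma_white_for_total(8.0, _PINK_LOCKED, acq)
    bare_white = _sigma_white_for_total(13.0, _PINK_BARE, acq)
    noise_locked = NoiseModel.from_sigma(locked_white, acq, pink_A=_PINK_LOCKED)
    noise_bare = NoiseModel.from_sigma(bare_white, acq, pink_A=_PINK_BARE)
    const = VoltageProtocol.constant(100.0)
    alternating = VoltageProtocol.alternating(1.0, 5)

    # Vertical: capture 7.7/s, escape 11/s; horizontal: half the capture
    # rate and a 270-fold faster escape; blockades 17% / 14.5% of I0.
    vertical = KineticScheme(
        open_current_pA=_I0_PA, docked_level=1.0 - 0.17, capture_rate=7.7, escape_rate=11.0,
        initial_state=STATE_DOCKED,
    )
    horizontal = KineticScheme(
        open_current_pA=_I0_PA, docked_level=1.0 - 0.145, capture_rate=7.7 / 2.0,
        escape_rate=11.0 * 270.0, initial_state=STATE_DOCKED,
    )
    vertical_docking = KineticScheme(
        open_current_pA=_I0_PA, docked_level=1.0 - 0.17, attempt_level=1.0 - 0.12,
        docking_rate=6.0, undocking_rate=3.0, initial_state=STATE_OPEN,
    )
    horizontal_docking = replace(vertical_docking, docked_level=1.0 - 0.145)
    bare = KineticScheme(
        open_current_pA=_I0_PA, docked_level=1.0 - 0.17, docking_rate=5.0,
        eject_rate=200.0, initial_state=STATE_OPEN,
    )
    cholesterol = KineticScheme(
        open_current_pA=_I0_PA, docked_level=1.0 - 0.17, docking_rate=5.0,
        eject_rate=0.0, initial_state=STATE_OPEN,
    )
    return {
        "vertical_avidin": (vertical, noise_locked, const),
        "horizontal_avidin": (horizontal, noise_locked, const),
        "vertical_docking": (vertical_docking, noise_locked, const),
        "horizontal_docking": (horizontal_docking, noise_locked, const),
        "bare_docking": (bare, noise_bare, alternating),
        "cholesterol_docking": (cholesterol, noise_locked, alternating),
    }


PRESETS = tuple(_preset_table(AcquisitionSpec()).keys())


def make_fixture(
    preset: str,
    seed: int,
    duration_s: float = 60.0,
    sample_rate_hz: float = 125e3,
    cutoff_hz: float = 10e3,
) -> CurrentTrace:
    """Generate a preset trace parameterized from the study's printed values.

    Presets: vertical_avidin / horizontal_avidin (trapping kinetics on a
    docked baseline), vertical_docking / horizontal_docking (two-level
    open/docked traces), bare_docking / cholesterol_docking (voltage
    inversions; the bare sphere ejects at negative bias, the locked one
    stays docked).
    """
    acq = AcquisitionSpec(sample_rate_hz=sample_rate_hz, cutoff_hz=cutoff_hz,
                          duration_s=duration_s, seed=seed)
    table = _preset_table(acq)
    if preset not in table:
        raise KeyError(f"unknown preset {preset!r}; choose from {sorted(table)}")
    scheme, noise, protocol = table[preset]
    rng = np.random.default_rng(seed)
    path = simulate_state_path(scheme, duration_s, rng, protocol)
    trace = render_trace(path, scheme, noise, acq, protocol, seed=rng)
    trace.params["preset"] = preset
    trace.params["seed"] = seed
    return trace
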