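"""Synthetic multichannel EEG with known directed phase-lag ground truth.

The generator emulates the features of anesthesia EEG that the analysis
chain measures, with every parameter controlled:

* alpha-band (8–13 Hz) oscillations carrying a directed per-pair
  phase-lead/lag graph, realized as phase-shifted copies of a shared
  narrowband process per coupled pair (the analytic-signal rotation makes
  the expected dPLI of a pair exact);
* additive 1/f-shaped broadband background noise at a controlled in-band
  signal-to-noise ratio;
* zero-lag common-source mixing as a volume-conduction stand-in;
* binary-Markov amplitude modulation controlling signal compressibility.

`gen_case_pair` bundles these into paired baseline/anesthesia recordings
for six named scenarios covering the canonical and paradoxical directions
of change in frontoparietal feedback, hub topography and complexity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal
from scipy.signal import hilbert

from .preprocessing import ALPHA_BAND, _butter_sos
from .recording import Montage, Recording

logger = logging.getLogger(__name__)

CARRIER_HZ = 10.0  # center of the 8-13 Hz band: maximal in-band energy

SCENARIOS = (
    "feedback_increase", "feedback_decrease",
    "hub_posteriorize", "hub_anteriorize",
    "complexity_up", "complexity_down",
)

#: Metrics with a controlled expected direction of change per scenario.
#: +1 = anesthesia larger, -1 = smaller, None = not controlled.
SCENARIO_EXPECTATIONS: dict[str, dict[str, int | None]] = {
    "feedback_increase": {"fp_dpli": +1, "hub_index": None, "lzc": None},
    "feedback_decrease": {"fp_dpli": -1, "hub_index": None, "lzc": None},
    "hub_posteriorize": {"fp_dpli": None, "hub_index": -1, "lzc": None},
    "hub_anteriorize": {"fp_dpli": None, "hub_index": +1, "lzc": None},
    "complexity_up": {"fp_dpli": None, "hub_index": None, "lzc": +1},
    "complexity_down": {"fp_dpli": None, "hub_index": None, "lzc": -1},
}


# ---------------------------------------------------------------------------
# domain types


@dataclass
class LagGraph:
    """Directed phase-lead graph: (i, j) means channel i leads channel j.

    ``pairs`` maps ordered index pairs to (lag_radians, coupling); the lag
    must lie strictly inside (0, π) and the coupling weight in [0, 1].  A
    pair may not appear in both directions.
    """

    n_channels: int
    pairs: dict[tuple[int, int], tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be positive")
        for (i, j), (lag, coupling) in self.pairs.items():
            if not (0 <= i < self.n_channels and 0 <= j < self.n_channels):
                raise ValueError(f"pair ({i},{j}) outside channel range")
            if i == j:
                raise ValueError("self-pairs are not allowed")
            if (j, i) in self.pairs:
                raise ValueError(f"pair ({i},{j}) appears in both directions")
            if not 0.0 < lag < math.pi:
                raise ValueError(f"lag for ({i},{j}) must be in (0, pi), got {lag}")
            if not 0.0 <= coupling <= 1.0:
                raise ValueError(f"coupling for ({i},{j}) must be in [0,1]")


@dataclass
class ScenarioSpec:
    """Named baseline/anesthesia contrast with generation parameters."""

    name: str
    fs_hz: float = 250.0
    duration_s: float = 40.0
    snr_db: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}; one of {SCENARIOS}")
        if self.duration_s < 30:
            raise ValueError("duration_s must be >= 30 s (at least 3 windows)")
        if self.fs_hz < 100:
            raise ValueError("fs_hz must be >= 100 Hz to resolve the alpha band")


@dataclass
class CasePair:
    """Paired recordings plus the ground-truth expected directions."""

    baseline: Recording
    anesthesia: Recording
    montage: Montage
    expected_changes: dict[str, int | None]


# ---------------------------------------------------------------------------
# montage


_REGION_Y = {"F": 0.8, "C": 0.3, "T": 0.0, "P": -0.4, "O": -0.8}
_HEMI_X = {"L": -0.5, "R": 0.5, "Z": 0.0}
_SLOT_ORDER = [(r, h) for r in ("F", "C", "P", "T", "O") for h in ("L", "R")]


def make_montage(n_channels: int) -> Montage:
    """Evenly populated reduced montage: 5 regions × 2 lateral hemispheres.

    Channels are distributed round-robin over the ten region/hemisphere
    slots, so ``n_channels`` must be even and at least 10 (one channel per
    slot guarantees frontal and parietal coverage in both hemispheres).
    Within a slot, extra channels get small coordinate offsets; frontal
    channels always have y > 0 and occipital y < 0.
    """
    if n_channels < 10:
        raise ValueError(
            f"n_channels={n_channels} cannot cover all five regions in both "
            "hemispheres; need at least 10"
        )
    if n_channels % 2 != 0:
        raise ValueError(f"n_channels must be even, got {n_channels}")
    mapping: dict[str, tuple[str, str, float, float]] = {}
    per_slot = n_channels // len(_SLOT_ORDER)
    extra = n_channels % len(_SLOT_ORDER)
    counts = [per_slot + (1 if k < extra else 0) for k in range(len(_SLOT_ORDER))]
    for (region, hemi), count in zip(_SLOT_ORDER, counts):
        for dup in range(count):
            label = f"{region}{hemi}{dup + 1}"
            # stagger duplicates without crossing the y = 0 line
            dy = 0.08 * dup * (-1 if _REGION_Y[region] > 0 else 1)
            dx = 0.08 * dup * (1 if hemi == "R" else -1)
            mapping[label] = (region, hemi,
                              _HEMI_X[hemi] + dx, _REGION_Y[region] + dy)
    return Montage.from_mapping(mapping)


# ---------------------------------------------------------------------------
# signal building blocks


def _narrowband_analytic(n: int, fs_hz: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS analytic alpha-band noise process."""
    sos = _butter_sos(fs_hz, *ALPHA_BAND)
    x = _signal.sosfiltfilt(sos, rng.standard_normal(n))
    z = hilbert(x)
    rms = np.sqrt(np.mean(x ** 2))
    return z / rms if rms > 0 else z


def _pink_noise(shape: tuple[int, ...], fs_hz: float,
                rng: np.random.Generator) -> np.ndarray:
    """1/f-power-shaped Gaussian noise, unit variance per channel."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1], d=1.0 / fs_hz)
    scale = 1.0 / np.sqrt(np.maximum(freqs, 1.0))  # flat below 1 Hz
    spec *= scale
    x = np.fft.irfft(spec, n=shape[-1], axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def _inband_power(x: np.ndarray, fs_hz: float) -> np.ndarray:
    """Alpha-band (8–13 Hz) power per channel."""
    sos = _butter_sos(fs_hz, *ALPHA_BAND)
    return _signal.sosfiltfilt(sos, x, axis=-1).var(axis=-1)


def _default_labels(n: int) -> tuple[str, ...]:
    return tuple(f"ch{i:02d}" for i in range(n))


def gen_lagged_oscillators(graph: LagGraph, fs_hz: float, duration_s: float,
                           snr_db: float, seed: int,
                           labels: tuple[str, ...] | None = None,
                           state: str = "synthetic") -> Recording:
    """Alpha-band recording realizing a directed phase-lag graph.

    Each coupled pair shares one narrowband analytic process z(t): the
    leading channel receives coupling·Re{z} and the lagging channel
    coupling·Re{z·e^{-i·lag}} — an exact phase rotation at every in-band
    frequency, so the expected dPLI of the pair is exactly 1 before noise.
    Independent 1/f noise is added to every channel, scaled so the in-band
    (8–13 Hz) signal-to-noise ratio of the coupled channels is ``snr_db``.
    Channels in no pair carry noise only.
    """
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    n = int(round(duration_s * fs_hz))
    rng = np.random.default_rng(seed)
    sig = np.zeros((graph.n_channels, n))
    for (i, j), (lag, coupling) in sorted(graph.pairs.items()):
        z = _narrowband_analytic(n, fs_hz, rng)
        sig[i] += coupling * z.real
        sig[j] += coupling * (z * np.exp(-1j * lag)).real

    noise = _pink_noise((graph.n_channels, n), fs_hz, rng)
    sig_band = _inband_power(sig, fs_hz)
    coupled = sig_band > 0
    if coupled.any():
        ref_power = float(sig_band[coupled].mean())
        noise_band = float(_inband_power(noise, fs_hz).mean())
        noise_scale = math.sqrt(ref_power / (noise_band * 10 ** (snr_db / 10.0)))
    else:
        noise_scale = 1.0
    data = sig + noise_scale * noise
    return Recording(labels or _default_labels(graph.n_channels),
                     fs_hz, data, state)


def gen_common_source(n_channels: int, fs_hz: float, duration_s: float,
                      seed: int, gains: np.ndarray | None = None,
                      jitter_scale: float = 1e-12,
                      labels: tuple[str, ...] | None = None) -> Recording:
    """Zero-lag volume-conduction fixture: scaled copies of one source.

    Every channel is a positive scalar multiple of a single shared
    alpha-band process, plus negligible independent jitter
    (``jitter_scale`` relative RMS; 0 gives the analytically exact case
    where the imaginary cross-spectrum of every pair is identically zero).
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels for a common-source fixture")
    rng = np.random.default_rng(seed)
    if gains is None:
        gains = rng.uniform(0.5, 2.0, size=n_channels)
    gains = np.asarray(gains, dtype=float)
    if gains.shape != (n_channels,) or np.any(gains <= 0):
        raise ValueError("gains must be positive, one per channel")
    n = int(round(duration_s * fs_hz))
    source = _narrowband_analytic(n, fs_hz, rng).real
    data = gains[:, None] * source[None, :]
    if jitter_scale > 0:
        data = data + jitter_scale * data.std() * rng.standard_normal(data.shape)
    return Recording(labels or _default_labels(n_channels), fs_hz, data,
                     "synthetic")


def gen_complexity_signal(n_channels: int, p_flip: float, fs_hz: float,
                          duration_s: float, seed: int,
                          symbol_rate_hz: float = 8.0,
                          env_low: float = 0.25, env_high: float = 1.0,
                          noise_scale: float = 0.0,
                          share_chain: bool = False,
                          labels: tuple[str, ...] | None = None,
                          state: str = "synthetic") -> Recording:
    """Carrier amplitude-modulated by a binary Markov chain.

    Each channel's 10-Hz carrier envelope switches between ``env_low`` and
    ``env_high`` following a two-state Markov chain that flips with
    probability ``p_flip`` at each symbol (``symbol_rate_hz`` symbols/s).
    Higher flip probability produces a less compressible envelope and hence
    a higher expected Lempel-Ziv complexity; p_flip = 0 gives a constant
    envelope, the minimal-complexity case.  ``share_chain`` puts the same
    chain on every channel (maximal inter-channel redundancy).
    """
    if not 0.0 <= p_flip <= 0.5:
        raise ValueError(f"p_flip must be in [0, 0.5], got {p_flip}")
    if n_channels < 1:
        raise ValueError("n_channels must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    samples_per_symbol = max(1, int(round(fs_hz / symbol_rate_hz)))
    n_symbols = n // samples_per_symbol + 1
    n_chains = 1 if share_chain else n_channels

    flips = rng.random((n_chains, n_symbols)) < p_flip
    flips[:, 0] = False  # start in the high state so p_flip=0 is constant-high
    chains = 1 - np.cumsum(flips, axis=1) % 2  # 1 = high, 0 = low

    t = np.arange(n) / fs_hz
    data = np.empty((n_channels, n))
    shared_phase = rng.uniform(0, 2 * np.pi)
    for c in range(n_channels):
        chain = chains[0] if share_chain else chains[c]
        env = np.where(chain == 1, env_high, env_low)
        env_t = np.repeat(env, samples_per_symbol)[:n]
        # a shared chain shares the carrier too: channels are identical
        phase0 = shared_phase if share_chain else rng.uniform(0, 2 * np.pi)
        data[c] = env_t * np.cos(2 * np.pi * CARRIER_HZ * t + phase0)
    if noise_scale > 0:
        data = data + noise_scale * data.std() * rng.standard_normal(data.shape)
    return Recording(labels or _default_labels(n_channels), fs_hz, data, state)


# ---------------------------------------------------------------------------
# paired baseline/anesthesia scenarios


def _hemi_pair_graph(mont: Montage, labels: tuple[str, ...],
                     lead_region: str, lag_region: str,
                     lag: float = math.pi / 2,
                     coupling: float = 1.0) -> LagGraph:
    """One lead pair per lateral hemisphere between two regions."""
    index = {l: k for k, l in enumerate(labels)}
    pairs = {}
    for hemi in ("L", "R"):
        leads = mont.select(labels, region=lead_region, hemisphere=hemi)
        lags_ = mont.select(labels, region=lag_region, hemisphere=hemi)
        for a, b in zip(leads, lags_):
            pairs[(index[a], index[b])] = (lag, coupling)
    return LagGraph(len(labels), pairs)


def _star_graph(mont: Montage, labels: tuple[str, ...], hub_label: str,
                n_spokes: int = 4, lag: float = math.pi / 2,
                coupling: float = 1.0) -> LagGraph:
    """Hub channel phase-leading ``n_spokes`` other channels."""
    index = {l: k for k, l in enumerate(labels)}
    hub = index[hub_label]
    others = [l for l in labels if l != hub_label]
    # spread spokes over regions for a spatially distributed periphery
    spokes = others[:: max(1, len(others) // n_spokes)][:n_spokes]
    pairs = {(hub, index[s]): (lag, coupling) for s in spokes}
    return LagGraph(len(labels), pairs)


def gen_case_pair(spec: ScenarioSpec, n_channels: int = 10) -> CasePair:
    """Baseline/anesthesia pair for one named scenario.

    Both recordings share one montage; ``expected_changes`` records the
    ground-truth sign of the anesthesia−baseline change for the metric the
    scenario controls (frontoparietal dPLI, anterior–posterior hub index,
    or the LZC variants) and None for metrics the scenario leaves free.
    """
    mont = make_montage(n_channels)
    labels = mont.labels
    ss = np.random.SeedSequence(spec.seed)
    seed_b, seed_a = (int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2))
    fs, dur, snr = spec.fs_hz, spec.duration_s, spec.snr_db
    name = spec.name

    def lagged(graph: LagGraph, seed: int, state: str) -> Recording:
        return gen_lagged_oscillators(graph, fs, dur, snr, seed,
                                      labels=labels, state=state)

    empty = LagGraph(len(labels), {})
    fp = _hemi_pair_graph(mont, labels, "F", "P")

    if name == "feedback_increase":
        base = lagged(empty, seed_b, "baseline")
        anes = lagged(fp, seed_a, "anesthesia")
    elif name == "feedback_decrease":
        base = lagged(fp, seed_b, "baseline")
        anes = lagged(empty, seed_a, "anesthesia")
    elif name in ("hub_posteriorize", "hub_anteriorize"):
        frontal_star = _star_graph(mont, labels, "FL1")
        posterior_star = _star_graph(mont, labels, "OL1")
        if name == "hub_posteriorize":
            base = lagged(frontal_star, seed_b, "baseline")
            anes = lagged(posterior_star, seed_a, "anesthesia")
        else:
            base = lagged(posterior_star, seed_b, "baseline")
            anes = lagged(frontal_star, seed_a, "anesthesia")
    else:  # complexity scenarios
        # both endpoints sit in the regime where surrogate-normalized LZC
        # rises monotonically with the flip probability
        if name == "complexity_up":
            p_base, p_anes = 0.1, 0.45
        else:
            p_base, p_anes = 0.45, 0.1

        def modulated(p: float, seed: int, state: str) -> Recording:
            return gen_complexity_signal(len(labels), p, fs, dur, seed,
                                         noise_scale=0.05, labels=labels,
                                         state=state)

        base = modulated(p_base, seed_b, "baseline")
        anes = modulated(p_anes, seed_a, "anesthesia")

    return CasePair(base, anes, mont, dict(SCENARIO_EXPECTATIONS[name]))
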