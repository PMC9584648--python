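"""Lempel-Ziv complexity of binarized EEG windows, raw and surrogate-normalized.

Three estimators are computed on each non-overlapping window after
binarization against the within-window mean Hilbert envelope:

* **median univariate** — LZ76 of each channel's bit string, median over
  channels (mean available as an option);
* **concatenated** — LZ76 of all channel bit strings joined end-to-end in a
  fixed, logged channel order;
* **joint** — LZ76 over the time-ordered sequence of per-sample channel
  bit-vectors, each vector treated as one symbol.  This is directly
  multivariate: identical channels collapse to a two-symbol alphabet, so the
  joint value of k copies of one channel equals the single-channel value.

LZ76 here is the exhaustive-history production complexity: the number of
phrases in the parsing where each phrase is the shortest extension not
copyable from the preceding sequence (trailing incomplete phrase counts).

To separate complexity changes from spectral changes, raw phrase counts are
normalized by the mean count over phase-randomized surrogates of the same
window (identical power spectrum, uniformly random Fourier phases).
Gaussian linear signals then score ≈ 1; signals with envelope or other
nonlinear temporal structure score below 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.signal import hilbert

from .recording import Epochs

logger = logging.getLogger(__name__)

VARIANTS = ("univariate_median", "concatenated", "joint")


# ---------------------------------------------------------------------------
# LZ76 core


@njit(cache=False)
def _lz76_count(s: np.ndarray) -> int:
    """Phrase count of the LZ76 exhaustive-history parsing of ``s``."""
    n = s.size
    c = 1
    i = 0
    u = 1
    v = 1
    vmax = 1
    while u + v <= n:
        if s[i + v - 1] == s[u + v - 1]:
            v += 1
        else:
            if v > vmax:
                vmax = v
            i += 1
            if i == u:
                c += 1
                u += vmax
                i = 0
                v = 1
                vmax = 1
            else:
                v = 1
    if v != 1:
        c += 1
    return c


@njit(cache=False)
def _lz76_sam(s: np.ndarray, sigma: int) -> int:
    """LZ76 phrase count via a suffix automaton, O(n·sigma).

    Builds the automaton of the whole sequence once, recording for every
    state the end position of its first occurrence; a phrase extension
    s[m:e] is reproducible from the preceding sequence exactly when its
    first occurrence ends before e.  Equivalent to the quadratic scan in
    `_lz76_count` (cross-checked in the test suite) but linear-time, which
    matters for the concatenated variant's long sequences.
    """
    n = s.size
    cap = 2 * n + 5
    nxt = np.full((cap, sigma), -1, np.int32)
    link = np.empty(cap, np.int32)
    length = np.empty(cap, np.int32)
    firstpos = np.empty(cap, np.int32)
    link[0] = -1
    length[0] = 0
    size = 1
    last = 0
    for pos in range(n):
        c = s[pos]
        cur = size
        size += 1
        length[cur] = length[last] + 1
        firstpos[cur] = length[cur]
        link[cur] = 0
        p = last
        while p != -1 and nxt[p, c] == -1:
            nxt[p, c] = cur
            p = link[p]
        if p != -1:
            q = nxt[p, c]
            if length[p] + 1 == length[q]:
                link[cur] = q
            else:
                clone = size
                size += 1
                length[clone] = length[p] + 1
                link[clone] = link[q]
                firstpos[clone] = firstpos[q]
                for a in range(sigma):
                    nxt[clone, a] = nxt[q, a]
                while p != -1 and nxt[p, c] == q:
                    nxt[p, c] = clone
                    p = link[p]
                link[q] = clone
                link[cur] = clone
        last = cur

    count = 0
    st = 0
    pending = False
    for e in range(1, n + 1):
        st = nxt[st, s[e - 1]]
        if firstpos[st] < e:
            pending = True
        else:
            count += 1
            st = 0
            pending = False
    if pending:
        count += 1
    return count


_SAM_MAX_ALPHABET = 4


def _lz76_dispatch(arr: np.ndarray) -> int:
    """Linear-time path for small alphabets, quadratic scan otherwise."""
    if arr.size == 0:
        raise ValueError("empty sequence has no defined complexity")
    hi = int(arr.max())
    if int(arr.min()) >= 0 and hi < _SAM_MAX_ALPHABET:
        return int(_lz76_sam(arr, hi + 1))
    return int(_lz76_count(arr))


def lz76(seq) -> int:
    """LZ76 phrase count of a finite symbol sequence.

    Accepts any 1-D sequence over a finite alphabet (bits, integers,
    characters); symbols are compared for equality only.
    """
    arr = np.asarray(list(seq) if isinstance(seq, str) else seq)
    if arr.ndim != 1:
        raise ValueError("sequence must be one-dimensional")
    if arr.size == 0:
        raise ValueError("empty sequence has no defined complexity")
    if arr.dtype.kind not in "iub":
        _, codes = np.unique(arr, return_inverse=True)
        arr = codes
    return _lz76_dispatch(np.ascontiguousarray(arr, dtype=np.int64))


# ---------------------------------------------------------------------------
# binarization


@dataclass
class BinaryWindows:
    """Binarized windows plus the per-channel thresholds used."""

    windows: list[np.ndarray]        # uint8, channels × samples
    thresholds: list[np.ndarray]     # per-window, per-channel envelope mean
    labels: tuple[str, ...]

    @property
    def n_windows(self) -> int:
        return len(self.windows)


#: Envelope excursions below this fraction of the mean envelope are treated
#: as numerically constant: a flat envelope equals its mean analytically and
#: must binarize to all zeros, not to rounding noise around the threshold.
ENVELOPE_REL_TOL = 1e-9


def _binarize_window(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    envelope = np.abs(hilbert(w, axis=-1))
    thresh = envelope.mean(axis=-1, keepdims=True)
    bits = (envelope > thresh * (1.0 + ENVELOPE_REL_TOL)).astype(np.uint8)
    return bits, thresh[:, 0]


def binarize(ep: Epochs) -> BinaryWindows:
    """Binarize each channel of each window against its mean envelope.

    The instantaneous amplitude is the Hilbert envelope of the broadband
    signal; a sample maps to 1 when the envelope exceeds the within-window,
    within-channel mean envelope.  A constant channel has envelope equal to
    its mean everywhere and binarizes to all zeros (logged).
    """
    windows, thresholds = [], []
    constant = set()
    for w in ep.windows:
        bits, thresh = _binarize_window(w)
        for c in range(w.shape[0]):
            if np.ptp(w[c]) == 0:
                constant.add(ep.labels[c])
        windows.append(bits)
        thresholds.append(thresh)
    if constant:
        logger.warning("constant channels binarize to all zeros: %s",
                       sorted(constant))
    return BinaryWindows(windows, thresholds, ep.labels)


# ---------------------------------------------------------------------------
# the three variants


@dataclass
class ComplexityResult:
    """Raw (and optionally normalized) LZC per window and averaged."""

    labels: tuple[str, ...]
    per_window: dict[str, np.ndarray]
    normalized_per_window: dict[str, np.ndarray] | None = None
    n_norm_surrogates: int = 0
    channel_stat: str = "median"

    @property
    def mean(self) -> dict[str, float]:
        return {k: float(np.mean(v)) for k, v in self.per_window.items()}

    @property
    def normalized_mean(self) -> dict[str, float] | None:
        if self.normalized_per_window is None:
            return None
        return {
            k: float(np.nanmean(v))
            for k, v in self.normalized_per_window.items()
        }


def _joint_symbols(bits: np.ndarray) -> np.ndarray:
    """Encode per-sample channel bit-vectors as one integer symbol each."""
    C = bits.shape[0]
    if C <= 62:
        weights = (1 << np.arange(C, dtype=np.int64))
        return weights @ bits.astype(np.int64)
    _, codes = np.unique(bits.T, axis=0, return_inverse=True)
    return codes.astype(np.int64)


def _variants_window(bits: np.ndarray, channel_stat: str) -> dict[str, int | float]:
    rows = np.ascontiguousarray(bits, dtype=np.int64)
    per_channel = [_lz76_dispatch(rows[c]) for c in range(rows.shape[0])]
    stat = np.median if channel_stat == "median" else np.mean
    return {
        "univariate_median": float(stat(per_channel)),
        "concatenated": _lz76_dispatch(rows.reshape(-1)),
        "joint": _lz76_dispatch(np.ascontiguousarray(_joint_symbols(bits))),
    }


def lzc_variants(bw: BinaryWindows, channel_stat: str = "median") -> ComplexityResult:
    """Raw LZC per window for the three variants, then means over windows.

    Channel concatenation order is the (fixed) label order of ``bw`` and is
    logged, since the concatenated variant is the only order-dependent one.
    """
    if channel_stat not in ("median", "mean"):
        raise ValueError("channel_stat must be 'median' or 'mean'")
    logger.info("concatenation order: %s", list(bw.labels))
    per_window: dict[str, list] = {v: [] for v in VARIANTS}
    for bits in bw.windows:
        vals = _variants_window(bits, channel_stat)
        for v in VARIANTS:
            per_window[v].append(vals[v])
    return ComplexityResult(
        bw.labels,
        {v: np.asarray(a, dtype=float) for v, a in per_window.items()},
        channel_stat=channel_stat,
    )


# ---------------------------------------------------------------------------
# phase-randomized normalization


def phase_randomize(window: np.ndarray, seed=None) -> np.ndarray:
    """Phase-randomized surrogate of a channels × samples window.

    The magnitude spectrum of every channel is preserved exactly; the phases
    of the positive-frequency bins are replaced by i.i.d. uniform draws
    (independently per channel), with Hermitian symmetry enforced by
    construction through the real inverse FFT.  DC and Nyquist bins are
    left untouched so the output is real.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    window = np.asarray(window, dtype=float)
    squeeze = window.ndim == 1
    if squeeze:
        window = window[None, :]
    n = window.shape[-1]
    spec = np.fft.rfft(window, axis=-1)
    n_bins = spec.shape[-1]
    lo, hi = 1, n_bins - 1 if n % 2 == 0 else n_bins
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(window.shape[0], hi - lo))
    spec[:, lo:hi] = np.abs(spec[:, lo:hi]) * np.exp(1j * phases)
    out = np.fft.irfft(spec, n=n, axis=-1)
    return out[0] if squeeze else out


def normalized_lzc(ep: Epochs, n_norm_surrogates: int = 10, seed: int = 0,
                   channel_stat: str = "median") -> ComplexityResult:
    """Raw and surrogate-normalized LZC per window and averaged.

    For each window and variant, the normalized value is the raw phrase
    count divided by the mean count over ``n_norm_surrogates``
    phase-randomized versions of that window.  A degenerate window whose
    surrogates have zero mean count yields NaN with a warning.
    """
    bw = binarize(ep)
    raw = lzc_variants(bw, channel_stat=channel_stat)
    rng = np.random.default_rng(seed)
    normalized: dict[str, list] = {v: [] for v in VARIANTS}
    for k, w in enumerate(ep.windows):
        surr_vals = {v: [] for v in VARIANTS}
        for _ in range(n_norm_surrogates):
            s_bits, _ = _binarize_window(phase_randomize(w, rng))
            vals = _variants_window(s_bits, channel_stat)
            for v in VARIANTS:
                surr_vals[v].append(vals[v])
        for v in VARIANTS:
            denom = float(np.mean(surr_vals[v]))
            if denom == 0:
                logger.warning(
                    "window %d: surrogate %s count is 0; normalized value NaN",
                    k, v,
                )
                normalized[v].append(np.nan)
            else:
                normalized[v].append(raw.per_window[v][k] / denom)
    return ComplexityResult(
        ep.labels,
        raw.per_window,
        {v: np.asarray(a, dtype=float) for v, a in normalized.items()},
        n_norm_surrogates=n_norm_surrogates,
        channel_stat=channel_stat,
    )
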