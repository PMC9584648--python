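"""Phase-lag connectivity: wPLI, dPLI, surrogate correction and hub measures.

The weighted phase lag index (wPLI) of channels i and j is

    wPLI_ij = |E{Im(C_ij)}| / E{|Im(C_ij)|}

where C_ij is the cross-spectrum of the analytic signals and E{·} the mean
over within-window samples.  Weighting by the magnitude of the imaginary
cross-spectrum makes the index insensitive to zero-lag (volume-conducted)
coupling: instantaneous mixing has a purely real cross-spectrum.

The directed phase lag index (dPLI) is the fraction of samples at which
channel i's instantaneous phase leads channel j's,

    dPLI_ij = (1/N) Σ_t H(Δφ_ij(t)),    Δφ_ij = φ_i − φ_j  (wrapped)

with the Heaviside convention H(x>0)=1, H(0)=0.5, H(x<0)=0.  dPLI = 0.5
means no consistent phase relationship; > 0.5 means i leads j.  Note that
sign(Δφ wrapped to (−π, π]) equals sign(Im C_ij), so both indices derive
from the imaginary cross-spectrum alone.

Spurious connections are removed by a surrogate test: for each pair and
window the time course of one channel is circularly shifted (which preserves
its spectrum and autocorrelation but destroys the phase relation), the index
recomputed, the observed value bias-corrected by the surrogate mean, and
retained only when it falls outside the surrogate distribution at the chosen
significance level — otherwise it is set to 0 (wPLI) / 0.5 (dPLI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .recording import Epochs, Montage

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers


@dataclass
class ConnMatrices:
    """Per-window and time-averaged wPLI / dPLI matrices.

    ``wpli[t]`` is symmetric with zero diagonal and entries in [0, 1];
    ``dpli[t]`` satisfies dpli[i, j] + dpli[j, i] = 1 with diagonal 0.5.
    """

    labels: tuple[str, ...]
    wpli: np.ndarray  # (n_windows, C, C)
    dpli: np.ndarray  # (n_windows, C, C)
    corrected: bool = False

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.wpli = np.asarray(self.wpli, dtype=float)
        self.dpli = np.asarray(self.dpli, dtype=float)
        C = len(self.labels)
        if self.wpli.shape[1:] != (C, C) or self.dpli.shape != self.wpli.shape:
            raise ValueError("matrix shapes inconsistent with labels")

    @property
    def n_windows(self) -> int:
        return self.wpli.shape[0]

    @property
    def wpli_avg(self) -> np.ndarray:
        return self.wpli.mean(axis=0)

    @property
    def dpli_avg(self) -> np.ndarray:
        return self.dpli.mean(axis=0)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class SurrogateConfig:
    """Settings of the surrogate significance test.

    ``n_surrogates`` must give an attainable empirical p below ``alpha``:
    the smallest rank-based p is 1/(n_surrogates + 1).
    """

    n_surrogates: int = 20
    alpha: float = 0.05
    method: str = "circular_shift"
    min_shift_s: float = 1.0
    seed: int = 0
    dpli_two_sided: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("circular_shift", "sample_shuffle"):
            raise ValueError(f"unknown surrogate method {self.method!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if 1.0 / (self.n_surrogates + 1) > self.alpha:
            raise ValueError(
                f"{self.n_surrogates} surrogates cannot resolve p < {self.alpha}: "
                f"minimum attainable p is 1/{self.n_surrogates + 1}"
            )


# ---------------------------------------------------------------------------
# core estimators


def analytic_signals(ep: Epochs) -> np.ndarray:
    """FFT-based analytic signal per channel per window.

    Returns a complex array of shape (n_windows, n_channels, n_samples).
    Because the Hilbert transform is computed through the DFT, it commutes
    exactly with circular shifts — the property the surrogate step relies on.
    """
    return np.stack([hilbert(w, axis=-1) for w in ep.windows])


#: Pairs whose mean |Im C| falls below this fraction of the mean
#: cross-spectrum magnitude carry no phase-lag information (the imaginary
#: part is numerically zero, as for exact zero-lag mixtures): they get
#: wPLI 0 and dPLI 0.5 rather than a ratio of rounding noise.
IMAG_REL_TOL = 1e-9


def _indices_from_imag(im: np.ndarray,
                       scale: np.ndarray | float = 0.0) -> tuple[float, float]:
    """(wPLI, dPLI) from the imaginary cross-spectrum samples of one pair.

    ``scale`` is the mean cross-spectrum magnitude E{|C_ij|}, used to detect
    a degenerate (numerically zero) imaginary part.
    """
    denom = np.abs(im).mean(axis=-1)
    degenerate = denom <= IMAG_REL_TOL * np.asarray(scale)
    num = np.abs(im.mean(axis=-1))
    wpli = np.divide(num, denom,
                     out=np.zeros_like(num), where=~degenerate & (denom > 0))
    dpli = (im > 0).mean(axis=-1) + 0.5 * (im == 0).mean(axis=-1)
    dpli = np.where(degenerate, 0.5, dpli)
    return wpli, dpli


def phase_lag_indices(ep: Epochs) -> ConnMatrices:
    """Uncorrected per-window wPLI and dPLI for every channel pair.

    Expects alpha-band-filtered epochs of at least 2 s.  An all-zero channel
    yields wPLI 0 / dPLI 0.5 against every partner, with a logged warning.
    """
    if ep.window_s < 2.0:
        raise ValueError("windows must be at least 2 s for phase estimation")
    A = analytic_signals(ep)
    n_win, C, _ = A.shape

    silent = [ep.labels[c] for c in range(C)
              if not np.any(np.abs(ep.as_array()[:, c, :]) > 0)]
    if silent:
        logger.warning("all-zero channels (pairs get wPLI 0 / dPLI 0.5): %s",
                       silent)

    wpli = np.zeros((n_win, C, C))
    dpli = np.full((n_win, C, C), 0.5)
    for i in range(C):
        for j in range(i + 1, C):
            cross = A[:, i, :] * np.conj(A[:, j, :])  # (n_win, N)
            w, d = _indices_from_imag(cross.imag,
                                      np.abs(cross).mean(axis=-1))
            wpli[:, i, j] = wpli[:, j, i] = w
            dpli[:, i, j] = d
            dpli[:, j, i] = 1.0 - d
    return ConnMatrices(ep.labels, wpli, dpli, corrected=False)


def _surrogate_cross(a_i: np.ndarray, a_j: np.ndarray, cfg: SurrogateConfig,
                     rng: np.random.Generator, fs_hz: float) -> np.ndarray:
    """Cross-spectra of channel i against scrambled copies of j.

    Returns a complex array of shape (n_surrogates, N).
    """
    N = a_i.shape[0]
    if cfg.method == "circular_shift":
        min_shift = max(1, int(round(cfg.min_shift_s * fs_hz)))
        if 2 * min_shift >= N:
            raise ValueError("min_shift_s too large for the window length")
        offsets = rng.integers(min_shift, N - min_shift, size=cfg.n_surrogates)
        idx = (np.arange(N)[None, :] - offsets[:, None]) % N
        scrambled = a_j[idx]
    else:  # sample_shuffle
        scrambled = np.stack(
            [a_j[rng.permutation(N)] for _ in range(cfg.n_surrogates)]
        )
    return a_i[None, :] * np.conj(scrambled)


def surrogate_correct(ep: Epochs, raw: ConnMatrices,
                      cfg: SurrogateConfig | None = None) -> ConnMatrices:
    """Bias-correct and threshold raw connectivity with pairwise surrogates.

    For each pair and window, ``cfg.n_surrogates`` surrogate index values are
    obtained by scrambling the second channel.  Observed values are corrected
    by the surrogate mean (wPLI: subtraction, clipped at 0; dPLI: recentred
    about 0.5, which preserves antisymmetry) and retained only when the
    rank-based empirical p-value (1 + #{surrogate as extreme}) /
    (n_surrogates + 1) is below ``cfg.alpha`` — one-sided for wPLI,
    two-sided on |dPLI − 0.5| by default.  Non-significant entries are set
    to exactly 0 (wPLI) and 0.5 (dPLI).
    """
    if cfg is None:
        cfg = SurrogateConfig()
    if raw.corrected:
        raise ValueError("matrices are already surrogate-corrected")
    A = analytic_signals(ep)
    n_win, C, N = A.shape
    rng = np.random.default_rng(cfg.seed)

    wpli = np.zeros_like(raw.wpli)
    dpli = np.full_like(raw.dpli, 0.5)
    n_s = cfg.n_surrogates
    for t in range(n_win):
        for i in range(C):
            for j in range(i + 1, C):
                cr_s = _surrogate_cross(A[t, i], A[t, j], cfg, rng, ep.fs_hz)
                w_s, d_s = _indices_from_imag(cr_s.imag,
                                              np.abs(cr_s).mean(axis=-1))
                w_obs = raw.wpli[t, i, j]
                d_obs = raw.dpli[t, i, j]

                # one-sided upper-tail test for wPLI
                p_w = (1 + np.count_nonzero(w_s >= w_obs)) / (n_s + 1)
                if p_w < cfg.alpha:
                    wpli[t, i, j] = wpli[t, j, i] = max(0.0, w_obs - w_s.mean())

                # dPLI: deviation from 0.5
                if cfg.dpli_two_sided:
                    extreme = np.abs(d_s - 0.5) >= abs(d_obs - 0.5)
                else:
                    extreme = (d_s >= d_obs) if d_obs >= 0.5 else (d_s <= d_obs)
                p_d = (1 + np.count_nonzero(extreme)) / (n_s + 1)
                if p_d < cfg.alpha:
                    d_corr = 0.5 + (d_obs - d_s.mean())
                    d_corr = float(np.clip(d_corr, 0.0, 1.0))
                    dpli[t, i, j] = d_corr
                    dpli[t, j, i] = 1.0 - d_corr
    return ConnMatrices(raw.labels, wpli, dpli, corrected=True)


# ---------------------------------------------------------------------------
# network summaries


def node_degree(m: ConnMatrices) -> np.ndarray:
    """Node degree: summed wPLI from each channel to all others.

    Computed on the time-averaged (and normally surrogate-corrected) wPLI
    matrix; returns one nonnegative value per channel in label order.
    """
    return m.wpli_avg.sum(axis=1)


def frontoparietal_summary(m: ConnMatrices, mont: Montage) -> dict:
    """Per-hemisphere frontal→parietal dPLI pairs and their mean.

    For each lateral hemisphere, collects dpli_avg[f, p] over frontal
    channels f and parietal channels p of that hemisphere.  A mean above 0.5
    indicates feedback-dominant (anterior-leads-posterior) connectivity.
    A hemisphere without both frontal and parietal coverage is reported as
    missing (``mean`` and ``pairs`` None), not raised.
    """
    mont.require(m.labels)
    dpli = m.dpli_avg
    out = {}
    for hemi in ("L", "R"):
        frontal = mont.select(m.labels, region="F", hemisphere=hemi)
        parietal = mont.select(m.labels, region="P", hemisphere=hemi)
        if not frontal or not parietal:
            logger.warning("hemisphere %s lacks frontal or parietal coverage",
                           hemi)
            out[hemi] = {"mean": None, "pairs": None}
            continue
        pairs = [
            (f, p, float(dpli[m.index_of(f), m.index_of(p)]))
            for f in frontal for p in parietal
        ]
        out[hemi] = {
            "mean": float(np.mean([v for _, _, v in pairs])),
            "pairs": pairs,
        }
    return out


def hub_index(deg: np.ndarray, mont: Montage,
              labels: tuple[str, ...]) -> tuple[float | None, str | None]:
    """Degree-weighted anterior–posterior hub score and the hub channel.

    The score is Σ_i deg_i · y_i / Σ_i deg_i, the degree-weighted mean of
    the posterior→anterior coordinate: +1 fully anterior, −1 fully
    posterior.  The hub channel is the argmax of degree (ties broken by
    label order).  An all-zero degree vector yields (None, None).
    """
    deg = np.asarray(deg, dtype=float)
    if deg.shape != (len(labels),):
        raise ValueError("degree vector does not match labels")
    total = deg.sum()
    if total <= 0:
        logger.warning("all-zero node degree: hub index undefined")
        return None, None
    y = np.array([mont.y_of(l) for l in labels])
    score = float((deg * y).sum() / total)
    hub = labels[int(np.argmax(deg))]
    return score, hub


def hub_directionality(m: ConnMatrices) -> np.ndarray:
    """Mean dPLI of each channel against all others.

    Values above 0.5 mark a channel as a source (it phase-leads the rest of
    the network), below 0.5 a target.
    """
    dpli = m.dpli_avg
    C = dpli.shape[0]
    off_diag = dpli.sum(axis=1) - np.diag(dpli)
    return off_diag / (C - 1)
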