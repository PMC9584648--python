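"""Per-case orchestration: baseline vs anesthesia metrics, deltas, labels.

For each recording state the chain is

    preprocess → epoch (10 s) → alpha band → wPLI/dPLI + surrogate test
                              → broadband   → normalized Lempel-Ziv complexity

and the case report compares anesthesia against baseline.  The anesthetic
is expected to weaken markers of consciousness, so each delta is labelled
*canonical* when it moves that way, *paradoxical* when it moves the other
way, and *null* when it stays inside a configured tolerance:

* frontoparietal dPLI — canonical is a decrease (feedback neutralized),
  paradoxical an increase;
* anterior–posterior hub index — canonical is an increase
  (anteriorization), paradoxical a decrease (posteriorization);
* normalized LZC — canonical is a decrease, paradoxical an increase.

An optional post-anesthesia recording yields a reversibility block: post
metrics within tolerance of baseline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from . import complexity as cx
from . import connectivity as conn
from . import preprocessing as pp
from .recording import Montage, Recording, epoch

logger = logging.getLogger(__name__)

LZC_METRICS = tuple(f"lzc_{v}" for v in cx.VARIANTS)
CRSR_SUBSCALES = ("Auditory", "Visual", "Motor", "Oromotor", "Communication",
                  "Arousal")


@dataclass
class AnalysisConfig:
    """All tunables of a case run, logged with every report."""

    window_s: float = 10.0
    band: tuple[float, float] = pp.ALPHA_BAND
    n_surrogates: int = 20
    alpha: float = 0.05
    surrogate_method: str = "circular_shift"
    min_shift_s: float = 1.0
    n_norm_surrogates: int = 10
    channel_stat: str = "median"
    artifact_threshold_uv: float | None = None
    tol_fp_dpli: float = 0.01
    tol_hub_index: float = 0.05
    tol_lzc: float = 0.01
    seed: int = 0

    def surrogate_config(self, seed: int) -> conn.SurrogateConfig:
        return conn.SurrogateConfig(
            n_surrogates=self.n_surrogates, alpha=self.alpha,
            method=self.surrogate_method, min_shift_s=self.min_shift_s,
            seed=seed,
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class StateMetrics:
    """All metrics of one recording state."""

    state: str
    n_windows: int
    fp_dpli: dict
    hub_index: float | None
    hub_channel: str | None
    hub_directionality: dict[str, float]
    degree: dict[str, float]
    lzc_raw: dict[str, float]
    lzc_normalized: dict[str, float]
    alpha_power: dict[str, float]
    conn_matrices: conn.ConnMatrices | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("conn_matrices")
        return d


@dataclass
class CaseReport:
    """Per-case result: per-state metrics, deltas and classifications."""

    config: dict
    states: dict[str, StateMetrics]
    deltas: dict[str, float | None] = field(default_factory=dict)
    classification: dict[str, str] = field(default_factory=dict)
    reversibility: dict[str, bool | None] | None = None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "config": self.config,
            "states": {k: v.to_dict() for k, v in self.states.items()},
            "deltas": self.deltas,
            "classification": self.classification,
            "reversibility": self.reversibility,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


def _state_seed(base_seed: int, rec: Recording, purpose: str) -> int:
    """Deterministic per-state seed keyed on the data content.

    Keying on content (not the state name) makes identical recordings yield
    bit-identical metrics regardless of which state slot they occupy — so a
    perfectly reversed post state reproduces the baseline metrics exactly.
    zlib.crc32 is stable across processes (str.__hash__ is salted).
    """
    import zlib

    ss = np.random.SeedSequence(
        [base_seed, zlib.crc32(np.ascontiguousarray(rec.data).tobytes()),
         zlib.crc32(purpose.encode())]
    )
    return int(ss.generate_state(1)[0] % (2 ** 31))


def analyze_state(rec: Recording, mont: Montage, config: AnalysisConfig,
                  drop_labels: Sequence[str] = ()) -> StateMetrics:
    """Run the full metric chain on one recording state."""
    clean = pp.preprocess(rec, drop_labels)
    mont.require(clean.labels)
    ep = epoch(clean, config.window_s)
    if config.artifact_threshold_uv is not None:
        ep = pp.reject_artifact_windows(ep, config.artifact_threshold_uv)
    if ep.n_windows < 3:
        raise ValueError(
            f"state {rec.state!r}: only {ep.n_windows} usable windows (< 3)"
        )

    alpha_ep = pp.bandpass_alpha(ep, config.band)
    raw = conn.phase_lag_indices(alpha_ep)
    corrected = conn.surrogate_correct(
        alpha_ep, raw,
        config.surrogate_config(_state_seed(config.seed, rec, "surr")),
    )
    degree = conn.node_degree(corrected)
    fp = conn.frontoparietal_summary(corrected, mont)
    hub_score, hub_channel = conn.hub_index(degree, mont, corrected.labels)
    directionality = conn.hub_directionality(corrected)

    lzc = cx.normalized_lzc(
        ep, n_norm_surrogates=config.n_norm_surrogates,
        seed=_state_seed(config.seed, rec, "lzc"),
        channel_stat=config.channel_stat,
    )
    power = pp.band_power(ep, *config.band)

    labels = corrected.labels
    return StateMetrics(
        state=rec.state,
        n_windows=ep.n_windows,
        fp_dpli=fp,
        hub_index=hub_score,
        hub_channel=hub_channel,
        hub_directionality={l: float(v) for l, v in zip(labels, directionality)},
        degree={l: float(v) for l, v in zip(labels, degree)},
        lzc_raw=lzc.mean,
        lzc_normalized=lzc.normalized_mean,
        alpha_power={l: float(v) for l, v in zip(labels, power)},
        conn_matrices=corrected,
    )


def _fp_mean(metrics: StateMetrics) -> float | None:
    means = [h["mean"] for h in metrics.fp_dpli.values() if h["mean"] is not None]
    return float(np.mean(means)) if means else None


def _delta(a: float | None, b: float | None) -> float | None:
    if a is None or b is None:
        return None
    return float(a - b)


def compute_deltas(base: StateMetrics, anes: StateMetrics) -> dict:
    """Anesthesia − baseline changes for every scalar metric."""
    deltas: dict[str, float | None] = {
        "fp_dpli": _delta(_fp_mean(anes), _fp_mean(base)),
        "hub_index": _delta(anes.hub_index, base.hub_index),
    }
    for variant in cx.VARIANTS:
        deltas[f"lzc_{variant}"] = _delta(
            anes.lzc_normalized.get(variant), base.lzc_normalized.get(variant)
        )
    return deltas


def classify_deltas(deltas: Mapping[str, float | None],
                    config: AnalysisConfig) -> dict[str, str]:
    """Label each delta canonical / paradoxical / null.

    Canonical direction under anesthesia: frontoparietal feedback decreases,
    hubs anteriorize (hub index increases), complexity decreases.
    """
    out: dict[str, str] = {}

    def label(value, tol, paradoxical_sign):
        if value is None:
            return "null"
        if abs(value) < tol:
            return "null"
        return "paradoxical" if np.sign(value) == paradoxical_sign else "canonical"

    out["fp_dpli"] = label(deltas.get("fp_dpli"), config.tol_fp_dpli, +1)
    out["hub_index"] = label(deltas.get("hub_index"), config.tol_hub_index, -1)
    for m in LZC_METRICS:
        out[m] = label(deltas.get(m), config.tol_lzc, +1)
    return out


def _reversibility(base: StateMetrics, post: StateMetrics,
                   config: AnalysisConfig) -> dict[str, bool | None]:
    deltas = compute_deltas(post, base)  # post − baseline
    tol = {"fp_dpli": config.tol_fp_dpli, "hub_index": config.tol_hub_index}
    tol.update({m: config.tol_lzc for m in LZC_METRICS})
    return {
        k: (None if v is None else bool(abs(v) <= tol[k]))
        for k, v in deltas.items()
    }


def run_case(baseline: Recording, anesthesia: Recording, mont: Montage,
             config: AnalysisConfig | None = None,
             post: Recording | None = None,
             drop_labels: Sequence[str] = (),
             metadata: Mapping | None = None) -> CaseReport:
    """Analyze a baseline/anesthesia(/post) triplet into a case report.

    The recordings must share channel labels after the drop list is applied,
    and the montage must resolve every retained label.
    """
    if config is None:
        config = AnalysisConfig()
    recs = {"baseline": baseline, "anesthesia": anesthesia}
    if post is not None:
        recs["post"] = post
    keep = [l for l in baseline.labels if l not in set(drop_labels)]
    for name, rec in recs.items():
        retained = [l for l in rec.labels if l not in set(drop_labels)]
        if retained != keep:
            raise ValueError(
                f"{name} channels differ from baseline after drop list"
            )
    mont.require(keep)

    states = {
        name: analyze_state(rec, mont, config, drop_labels)
        for name, rec in recs.items()
    }
    deltas = compute_deltas(states["baseline"], states["anesthesia"])
    classification = classify_deltas(deltas, config)
    reversibility = (
        _reversibility(states["baseline"], states["post"], config)
        if post is not None else None
    )
    return CaseReport(
        config=config.to_dict(),
        states=states,
        deltas=deltas,
        classification=classification,
        reversibility=reversibility,
        metadata=dict(metadata or {}),
    )


# ---------------------------------------------------------------------------
# cross-metric checks and clinical metadata


def alpha_power_degree_check(delta_power: Sequence[float],
                             delta_degree: Sequence[float],
                             n_permutations: int = 10_000,
                             seed: int = 0) -> tuple[float | None, float | None]:
    """Rank correlation of per-channel alpha-power change vs degree change.

    Returns (Spearman rho, permutation p-value over ``n_permutations``
    channel-label permutations).  Requires at least 5 channels; a constant
    input makes the correlation undefined and yields (None, None) with a
    warning.
    """
    dp = np.asarray(delta_power, dtype=float)
    dd = np.asarray(delta_degree, dtype=float)
    if dp.shape != dd.shape or dp.ndim != 1:
        raise ValueError("delta vectors must be 1-D and equal length")
    if dp.size < 5:
        raise ValueError(f"need at least 5 channels, got {dp.size}")
    if np.ptp(dp) == 0 or np.ptp(dd) == 0:
        logger.warning("constant delta vector: correlation undefined")
        return None, None
    rho = float(stats.spearmanr(dp, dd).statistic)
    rng = np.random.default_rng(seed)
    count = 0
    rp = stats.rankdata(dp)
    rd = stats.rankdata(dd)
    for _ in range(n_permutations):
        perm = rng.permutation(rd)
        r = np.corrcoef(rp, perm)[0, 1]
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return rho, float(p)


def validate_crsr(table) -> None:
    """Check CRS-R rows: total must equal the sum of the six subscales.

    ``table`` is a DataFrame with the subscale columns and ``Total``.
    Raises ValueError listing every inconsistent row.
    """
    missing = [c for c in (*CRSR_SUBSCALES, "Total") if c not in table.columns]
    if missing:
        raise ValueError(f"clinical table lacks columns: {missing}")
    sums = table[list(CRSR_SUBSCALES)].sum(axis=1)
    bad = table.index[sums != table["Total"]]
    if len(bad):
        detail = [
            f"row {i}: subscales sum to {int(sums[i])}, Total says "
            f"{int(table['Total'][i])}"
            for i in bad
        ]
        raise ValueError("CRS-R totals inconsistent: " + "; ".join(detail))


def load_clinical_table(path) -> "pd.DataFrame":
    """Read and validate a CRS-R clinical metadata CSV."""
    import pandas as pd

    df = pd.read_csv(path)
    validate_crsr(df)
    return df
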