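"""Core containers: labeled multichannel recordings, fixed-length epochs, montages.

A :class:`Recording` is a channels × samples matrix with unique channel labels,
a sampling rate and a state tag (baseline / anesthesia / post / synthetic).
All estimation downstream operates on :class:`Epochs` — non-overlapping
fixed-length windows cut from a recording.  A :class:`Montage` maps channel
labels to a scalp region (F, C, P, T, O), a hemisphere (L, R, Z) and a 2-D
coordinate whose y axis increases from posterior to anterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

VALID_STATES = ("baseline", "anesthesia", "post", "synthetic")
REGIONS = ("F", "C", "P", "T", "O")
HEMISPHERES = ("L", "R", "Z")

#: Display/concatenation order of regions, matching the convention of ordering
#: electrodes frontal → central → parietal → temporal → occipital.
REGION_ORDER = {r: i for i, r in enumerate(REGIONS)}


@dataclass
class Recording:
    """Labeled multichannel time series.

    Parameters
    ----------
    labels : sequence of str
        Unique channel names, one per data row.
    fs_hz : float
        Sampling rate in Hz (> 0).
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts (synthetic signals use arbitrary units).
    state : str
        One of ``baseline``, ``anesthesia``, ``post``, ``synthetic``.
    """

    labels: tuple[str, ...]
    fs_hz: float
    data: np.ndarray
    state: str = "synthetic"

    def __post_init__(self) -> None:
        self.labels = tuple(str(l) for l in self.labels)
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise ValueError(f"duplicate channel labels: {dupes}")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels × samples)")
        if self.data.shape[0] != len(self.labels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but {len(self.labels)} labels"
            )
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite samples")
        if self.state not in VALID_STATES:
            raise ValueError(f"state must be one of {VALID_STATES}, got {self.state!r}")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def pick(self, labels: Sequence[str]) -> "Recording":
        """Return a copy restricted to ``labels``, in the order given."""
        index = {l: i for i, l in enumerate(self.labels)}
        missing = [l for l in labels if l not in index]
        if missing:
            raise KeyError(f"labels not in recording: {missing}")
        rows = [index[l] for l in labels]
        return replace(self, labels=tuple(labels), data=self.data[rows].copy())

    def drop(self, labels: Iterable[str]) -> "Recording":
        drop_set = set(labels)
        unknown = sorted(drop_set - set(self.labels))
        if unknown:
            raise KeyError(f"cannot drop unknown channels: {unknown}")
        keep = [l for l in self.labels if l not in drop_set]
        if len(keep) < 2:
            raise ValueError("dropping channels would leave fewer than 2 channels")
        return self.pick(keep)


@dataclass
class Epochs:
    """Non-overlapping equal-length windows of a recording."""

    windows: list[np.ndarray]
    window_s: float
    fs_hz: float
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        if not self.windows:
            raise ValueError("Epochs requires at least one window")
        shape = self.windows[0].shape
        n_expected = int(round(self.window_s * self.fs_hz))
        for w in self.windows:
            if w.shape != shape:
                raise ValueError("all windows must share one shape")
        if shape != (len(self.labels), n_expected):
            raise ValueError(
                f"window shape {shape} != (n_labels={len(self.labels)}, "
                f"window_s*fs={n_expected})"
            )

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    @property
    def n_samples(self) -> int:
        return self.windows[0].shape[1]

    def as_array(self) -> np.ndarray:
        """Stack windows into (n_windows, n_channels, n_samples)."""
        return np.stack(self.windows)

    def map_windows(self, fn) -> "Epochs":
        """Apply ``fn`` (channels × samples → same shape) to every window."""
        out = [np.asarray(fn(w), dtype=float) for w in self.windows]
        return Epochs(out, self.window_s, self.fs_hz, self.labels)


def epoch(rec: Recording, window_s: float = 10.0) -> Epochs:
    """Cut a recording into non-overlapping windows of ``window_s`` seconds.

    The trailing remainder shorter than one window is discarded.  Raises if
    the recording is shorter than a single window.
    """
    n_win_samples = int(round(window_s * rec.fs_hz))
    n_windows = rec.n_samples // n_win_samples
    if n_windows < 1:
        raise ValueError(
            f"recording of {rec.duration_s:.3f} s is shorter than one "
            f"{window_s} s window"
        )
    windows = [
        rec.data[:, k * n_win_samples : (k + 1) * n_win_samples].copy()
        for k in range(n_windows)
    ]
    return Epochs(windows, window_s, rec.fs_hz, rec.labels)


@dataclass(frozen=True)
class ChannelInfo:
    region: str
    hemisphere: str
    x: float
    y: float


@dataclass
class Montage:
    """Channel label → (region, hemisphere, x, y) map.

    ``y`` increases from posterior to anterior (occipital < 0 < frontal), the
    axis along which hub anteriorization/posteriorization is scored.
    """

    channels: dict[str, ChannelInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, info in self.channels.items():
            if info.region not in REGIONS:
                raise ValueError(f"{label}: region {info.region!r} not in {REGIONS}")
            if info.hemisphere not in HEMISPHERES:
                raise ValueError(
                    f"{label}: hemisphere {info.hemisphere!r} not in {HEMISPHERES}"
                )

    def __contains__(self, label: str) -> bool:
        return label in self.channels

    def __getitem__(self, label: str) -> ChannelInfo:
        return self.channels[label]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def require(self, labels: Iterable[str]) -> None:
        """Raise listing every label the montage cannot resolve."""
        missing = sorted(set(labels) - set(self.channels))
        if missing:
            raise KeyError(f"montage does not resolve channels: {missing}")

    def region_of(self, label: str) -> str:
        return self.channels[label].region

    def hemisphere_of(self, label: str) -> str:
        return self.channels[label].hemisphere

    def y_of(self, label: str) -> float:
        return self.channels[label].y

    def select(self, labels: Sequence[str], region: str | None = None,
               hemisphere: str | None = None) -> list[str]:
        """Subset of ``labels`` matching region and/or hemisphere."""
        out = []
        for l in labels:
            info = self.channels[l]
            if region is not None and info.region != region:
                continue
            if hemisphere is not None and info.hemisphere != hemisphere:
                continue
            out.append(l)
        return out

    def display_order(self, labels: Sequence[str]) -> list[str]:
        """Order labels hemisphere-major then F, C, P, T, O within hemisphere."""
        hemi_order = {h: i for i, h in enumerate(HEMISPHERES)}
        return sorted(
            labels,
            key=lambda l: (
                hemi_order[self.channels[l].hemisphere],
                REGION_ORDER[self.channels[l].region],
                l,
            ),
        )

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[str, tuple[str, str, float, float]]
    ) -> "Montage":
        return cls(
            {
                label: ChannelInfo(region, hemisphere, float(x), float(y))
                for label, (region, hemisphere, x, y) in mapping.items()
            }
        )
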