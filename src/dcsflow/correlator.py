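"""Multi-tau photon-count autocorrelation.

Photon arrival events are binned into uniform time bins (1 us by default, the
native resolution of a hardware photon counter).  The normalized intensity
autocorrelation g2 is then estimated on a quasi-logarithmic lag schedule by
the multi-tau scheme: a first stage of ``first_stage_delays`` lags at the base
bin width, followed by ``n_stages`` stages of ``stage_delays`` lags each, the
counts being coarsened by pairwise summation (factor ``coarsening_factor``)
between stages so that each stage's lag indices continue contiguously after
the previous stage's maximum lag.

With the defaults (16-delay first stage, 8 delays per stage, factor 2) the
two standard presets are 80 total delays (8 multi-tau stages, max lag
16 * 2^8 base bins) for physiological measurements and liquid phantoms, and
120 total delays (13 stages, max lag 16 * 2^13 base bins) for the slow decays
of solid phantoms.

Normalization is symmetric: for lag k within a stage whose coarsened series
has Ns usable samples (pairs i = 0..Ns-k-1, no wraparound or padding),

    G(k)    = sum_i n_i * n_{i+k}        raw accumulator
    Md(k)   = sum_i n_i                  direct monitor
    Mdel(k) = sum_i n_{i+k}              delayed monitor
    g2(k)   = G(k) * Ms / (Md(k) * Mdel(k)),   Ms = Ns - k

which is exactly 1 for any constant input and invariant under integer
rescaling of the counts.

:func:`brute_force_correlate` recomputes the identical quantity by direct
summation over the full series at each scheduled lag; it is the reference
oracle for the streaming multi-tau accumulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .model import CorrelationCurve

__all__ = [
    "PhotonCountSeries",
    "CorrelatorConfig",
    "CorrelationCurve",
    "bin_events",
    "delay_schedule",
    "multitau_correlate",
    "brute_force_correlate",
    "min_series_length",
    "MultiTauAccumulator",
]


@dataclass(frozen=True)
class PhotonCountSeries:
    """Photon counts in uniform time bins."""

    counts: np.ndarray
    bin_width: float = 1e-6
    t0: float = 0.0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or len(counts) < 1:
            raise ValueError("counts must be a nonempty 1-D sequence")
        if not np.issubdtype(counts.dtype, np.integer):
            if np.any(counts != np.floor(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts)
        if not (np.isfinite(self.bin_width) and self.bin_width > 0):
            raise ValueError(f"bin_width must be positive, got {self.bin_width}")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def duration(self) -> float:
        return len(self.counts) * self.bin_width

    @property
    def mean_rate(self) -> float:
        """Mean count rate, counts/s."""
        return float(self.counts.sum()) / self.duration


@dataclass(frozen=True)
class CorrelatorConfig:
    """Multi-tau lag-schedule configuration.

    ``n_stages = 8`` gives the 80-delay preset, ``n_stages = 13`` the
    120-delay preset (with the default 16 + 8-per-stage layout).
    """

    base_bin: float = 1e-6
    first_stage_delays: int = 16
    stage_delays: int = 8
    n_stages: int = 8
    coarsening_factor: int = 2

    def __post_init__(self) -> None:
        if self.base_bin <= 0:
            raise ValueError("base_bin must be positive")
        if self.first_stage_delays < 1 or self.stage_delays < 1:
            raise ValueError("delay counts must be >= 1")
        if self.n_stages < 0:
            raise ValueError("n_stages must be >= 0")
        if self.coarsening_factor < 2:
            raise ValueError("coarsening_factor must be >= 2")

    @property
    def total_delays(self) -> int:
        return self.first_stage_delays + self.n_stages * self.stage_delays

    @classmethod
    def preset_80(cls, base_bin: float = 1e-6) -> "CorrelatorConfig":
        return cls(base_bin=base_bin, n_stages=8)

    @classmethod
    def preset_120(cls, base_bin: float = 1e-6) -> "CorrelatorConfig":
        return cls(base_bin=base_bin, n_stages=13)

    @classmethod
    def preset(cls, name: str, base_bin: float = 1e-6) -> "CorrelatorConfig":
        presets = {"80": cls.preset_80, "120": cls.preset_120}
        try:
            return presets[str(name)](base_bin)
        except KeyError:
            raise ValueError(
                f"unknown correlator preset {name!r}; choose from {sorted(presets)}"
            ) from None


def bin_events(
    timestamps: Sequence[float], bin_width: float, duration: float
) -> PhotonCountSeries:
    """Bin sorted photon arrival times (s) into uniform counts.

    Events fall in half-open bins [k*bin_width, (k+1)*bin_width); an event
    exactly at a bin edge belongs to the higher bin.  Timestamps must be
    sorted and lie in [0, duration).
    """
    if bin_width <= 0 or duration <= 0:
        raise ValueError("bin_width and duration must be positive")
    ts = np.asarray(timestamps, dtype=float)
    n_bins = int(np.ceil(duration / bin_width - 1e-9))
    if len(ts) == 0:
        return PhotonCountSeries(np.zeros(n_bins, dtype=np.int64), bin_width)
    if np.any(np.diff(ts) < 0):
        raise ValueError("timestamps must be sorted in nondecreasing order")
    if ts[0] < 0 or ts[-1] >= duration:
        raise ValueError("timestamps must lie in [0, duration)")
    idx = np.floor(ts / bin_width).astype(np.int64)
    # guard against float round-up at the last edge
    idx = np.minimum(idx, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return PhotonCountSeries(counts.astype(np.int64), bin_width)


def _stage_layout(config: CorrelatorConfig) -> List[Tuple[int, np.ndarray]]:
    """Per-stage lag indices: list of (stage, array of lag indices k).

    Stage 0 runs k = 1..first_stage_delays at the base bin width.  Stage
    s >= 1 uses bins coarsened by factor^s and continues contiguously: its
    first lag index is (previous stage's max lag in base bins) // width + 1.
    """
    layout = [(0, np.arange(1, config.first_stage_delays + 1))]
    prev_max_base = config.first_stage_delays  # max lag so far, in base bins
    m = config.coarsening_factor
    for s in range(1, config.n_stages + 1):
        width = m**s
        start = prev_max_base // width + 1
        ks = np.arange(start, start + config.stage_delays)
        layout.append((s, ks))
        prev_max_base = int(ks[-1]) * width
    return layout


def delay_schedule(config: CorrelatorConfig) -> np.ndarray:
    """Lag times (s) of the multi-tau schedule, strictly increasing."""
    taus = []
    m = config.coarsening_factor
    for s, ks in _stage_layout(config):
        taus.append(ks * (m**s) * config.base_bin)
    return np.concatenate(taus)


def min_series_length(config: CorrelatorConfig) -> int:
    """Minimum series length (base bins) the schedule requires.

    The coarsest stage must have at least 8 sample pairs beyond its largest
    lag index.
    """
    s, ks = _stage_layout(config)[-1]
    return (int(ks[-1]) + 8) * config.coarsening_factor**s


class MultiTauAccumulator:
    """Streaming multi-tau correlator: feed count chunks, then finalize.

    Mirrors a hardware cascade: each stage holds running accumulators
    (G, Md, Mdel per lag), a short history of its most recent coarse samples
    for products across chunk boundaries, and a carry buffer of unpaired
    samples awaiting coarsening for the next stage.  Accumulators reset only
    by constructing a new instance (one instance per measurement window).
    """

    def __init__(self, config: CorrelatorConfig, bin_width: Optional[float] = None):
        self.config = config
        self.bin_width = config.base_bin if bin_width is None else bin_width
        self._layout = _stage_layout(config)
        n_st = len(self._layout)
        self._G = [np.zeros(len(ks)) for _, ks in self._layout]
        self._Md = [np.zeros(len(ks)) for _, ks in self._layout]
        self._Mdel = [np.zeros(len(ks)) for _, ks in self._layout]
        self._hist = [np.empty(0) for _ in range(n_st)]
        self._carry = [np.empty(0) for _ in range(n_st)]
        self._n_proc = [0] * n_st
        self._n_base = 0
        self._total_counts = 0.0

    def update(self, counts: np.ndarray) -> None:
        """Process one chunk of base-resolution counts."""
        x = np.asarray(counts, dtype=float)
        if x.ndim != 1:
            raise ValueError("chunk must be 1-D")
        if len(x) == 0:
            return
        self._n_base += len(x)
        self._total_counts += float(x.sum())
        m = self.config.coarsening_factor
        for j, (_, ks) in enumerate(self._layout):
            if len(x) == 0:
                break
            t = self._n_proc[j]
            hist = self._hist[j]
            ext = np.concatenate([hist, x])
            off = len(hist)
            kmax = int(ks[-1])
            new_sum = None
            for i, k in enumerate(ks):
                k = int(k)
                skip = max(0, k - t)
                if skip >= len(x):
                    continue
                seg_new = x[skip:]
                seg_old = ext[off + skip - k : off + len(x) - k]
                self._G[j][i] += seg_old @ seg_new
                self._Md[j][i] += seg_old.sum()
                if new_sum is None:
                    new_sum = x.sum()
                self._Mdel[j][i] += seg_new.sum() if skip else new_sum
            self._hist[j] = ext[-kmax:] if len(ext) > kmax else ext
            self._n_proc[j] = t + len(x)
            # coarsen for the next stage
            y = np.concatenate([self._carry[j], x]) if len(self._carry[j]) else x
            r = len(y) % m
            if r:
                self._carry[j] = y[len(y) - r :]
                y = y[: len(y) - r]
            else:
                self._carry[j] = np.empty(0)
            x = y.reshape(-1, m).sum(axis=1) if len(y) else np.empty(0)

    @property
    def n_base_samples(self) -> int:
        return self._n_base

    def result(self) -> CorrelationCurve:
        """Finalize into a normalized correlation curve."""
        need = min_series_length(self.config)
        if self._n_base < need:
            raise ValueError(
                f"series too short for the configured schedule: got "
                f"{self._n_base} base bins, need at least {need}"
            )
        g2_parts = []
        for j, (_, ks) in enumerate(self._layout):
            Ms = self._n_proc[j] - ks.astype(float)
            denom = self._Md[j] * self._Mdel[j]
            with np.errstate(divide="ignore", invalid="ignore"):
                g2 = np.where(denom > 0, self._G[j] * Ms / denom, np.nan)
            g2_parts.append(g2)
        duration = self._n_base * self.bin_width
        return CorrelationCurve(
            taus=delay_schedule(self.config),
            g2=np.concatenate(g2_parts),
            n_samples=self._n_base,
            mean_rate=self._total_counts / duration,
        )


def _check_series(series: PhotonCountSeries, config: CorrelatorConfig) -> None:
    if not np.isclose(series.bin_width, config.base_bin, rtol=1e-9, atol=0.0):
        raise ValueError(
            f"series bin_width {series.bin_width} != correlator base_bin "
            f"{config.base_bin}"
        )
    need = min_series_length(config)
    if len(series) < need:
        raise ValueError(
            f"series too short for the configured schedule: got {len(series)} "
            f"base bins, need at least {need}"
        )


def multitau_correlate(
    series: PhotonCountSeries, config: CorrelatorConfig
) -> CorrelationCurve:
    """Multi-tau autocorrelation of a count series on the full schedule."""
    _check_series(series, config)
    acc = MultiTauAccumulator(config, bin_width=series.bin_width)
    acc.update(series.counts)
    return acc.result()


def brute_force_correlate(
    series: PhotonCountSeries, config: CorrelatorConfig
) -> CorrelationCurve:
    """Reference correlator: direct summation at every scheduled lag.

    For each lag the full base series is explicitly coarsened to the lag's
    stage resolution (pairwise sums, trailing remainder dropped) and the
    symmetric-normalized estimate is computed by direct products.  O(N*L);
    used as the oracle for :func:`multitau_correlate`.
    """
    _check_series(series, config)
    base = series.counts.astype(float)
    m = config.coarsening_factor
    taus, g2 = [], []
    for s, ks in _stage_layout(config):
        width = m**s
        n_coarse = len(base) // width
        coarse = base[: n_coarse * width].reshape(n_coarse, width).sum(axis=1)
        for k in ks:
            k = int(k)
            n_pairs = n_coarse - k
            taus.append(k * width * config.base_bin)
            if n_pairs <= 0:
                g2.append(np.nan)
                continue
            direct = coarse[:n_pairs]
            delayed = coarse[k : k + n_pairs]
            G = float(np.sum(direct * delayed))
            Md = float(direct.sum())
            Mdel = float(delayed.sum())
            g2.append(G * n_pairs / (Md * Mdel) if Md > 0 and Mdel > 0 else np.nan)
    return CorrelationCurve(
        taus=np.asarray(taus),
        g2=np.asarray(g2),
        n_samples=len(base),
        mean_rate=series.mean_rate,
    )
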