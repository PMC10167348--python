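"""Single-channel and whole-cell current analysis.

Covers the standard bilayer/patch workflow: all-points amplitude
histograms, Gaussian-mixture level fitting, half-amplitude threshold
idealization into open/closed dwells, open-probability aggregation
across recordings, and voltage-ramp I-V metrics normalised to cell
capacitance (pA/pF).

Sign convention: at negative holding potentials inward unitary current
is negative, so the open level is the more negative mixture component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CurrentTrace",
    "AmplitudeHistogram",
    "GaussianMixtureFit",
    "Dwell",
    "IdealizedTrace",
    "OpenProbability",
    "RampIV",
    "MultiChannelError",
    "all_points_histogram",
    "fit_gaussian_mixture",
    "idealize_half_amplitude",
    "aggregate_po",
    "ramp_iv_metrics",
]


class MultiChannelError(RuntimeError):
    """Raised when a trace shows stacked openings beyond one channel."""


@dataclass
class CurrentTrace:
    """Sampled current in pA at a fixed sampling rate."""

    samples_pA: np.ndarray
    sampling_rate_Hz: float
    holding_mV: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples_pA = np.asarray(self.samples_pA, dtype=float)
        if self.sampling_rate_Hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples_pA.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples_pA)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples_pA.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_Hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_Hz

    def to_csv(self, path) -> None:
        """Two-column CSV (time_s, current_pA) with '#' metadata header."""
        with open(path, "w") as fh:
            fh.write(f"# sampling_rate_Hz={self.sampling_rate_Hz}\n")
            if self.holding_mV is not None:
                fh.write(f"# holding_mV={self.holding_mV}\n")
            for k, v in self.metadata.items():
                fh.write(f"# {k}={v}\n")
            fh.write("time_s,current_pA\n")
            for t, i in zip(self.times_s, self.samples_pA):
                fh.write(f"{t:.9g},{i:.9g}\n")

    @classmethod
    def from_csv(cls, path) -> "CurrentTrace":
        meta: dict = {}
        samples = []
        rate = None
        with open(path) as fh:
            for ln in fh:
                ln = ln.strip()
                if not ln:
                    continue
                if ln.startswith("#"):
                    k, _, v = ln[1:].strip().partition("=")
                    meta[k.strip()] = v.strip()
                    continue
                if ln.startswith("time_s"):
                    continue
                _, cur = ln.split(",")
                samples.append(float(cur))
        rate = float(meta.pop("sampling_rate_Hz", 0)) or None
        if rate is None:
            raise ValueError(f"{path}: missing sampling_rate_Hz header")
        holding = meta.pop("holding_mV", None)
        return cls(np.array(samples), rate,
                   float(holding) if holding is not None else None, meta)


@dataclass
class AmplitudeHistogram:
    bin_edges_pA: np.ndarray
    counts: np.ndarray

    @property
    def bin_centers_pA(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_pA[:-1] + self.bin_edges_pA[1:])


@dataclass
class GaussianMixtureFit:
    means_pA: np.ndarray        # sorted ascending
    sds_pA: np.ndarray
    weights: np.ndarray
    converged: bool
    log_likelihood: float


@dataclass(frozen=True)
class Dwell:
    state: str        # "open" | "closed"
    duration_s: float

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("dwell duration must be positive")
        if self.state not in ("open", "closed"):
            raise ValueError(f"bad dwell state {self.state!r}")


@dataclass
class IdealizedTrace:
    dwells: list[Dwell]
    sampling_rate_Hz: float

    @property
    def duration_s(self) -> float:
        return sum(d.duration_s for d in self.dwells)

    @property
    def open_time_s(self) -> float:
        return sum(d.duration_s for d in self.dwells if d.state == "open")

    @property
    def po(self) -> float:
        dur = self.duration_s
        return self.open_time_s / dur if dur > 0 else 0.0

    @property
    def n_events(self) -> int:
        """Number of state transitions in the idealized record."""
        return max(len(self.dwells) - 1, 0)


@dataclass
class OpenProbability:
    per_trace: np.ndarray
    mean: float
    sem: float            # nan when only one trace (flagged below)
    n_traces: int
    total_events: int
    sem_defined: bool


@dataclass
class RampIV:
    v_start_mV: float
    v_end_mV: float
    duration_ms: float
    current_at_minus80_pA: float
    current_at_plus80_pA: float
    capacitance_pF: float
    density_at_minus80_pA_per_pF: float
    density_at_plus80_pA_per_pF: float


def all_points_histogram(trace: CurrentTrace, bin_width_pA: float) -> AmplitudeHistogram:
    """Histogram of every current sample (an 'all-points' histogram).

    Bin edges are deterministic: aligned to multiples of the bin width
    spanning the data range, so equal traces give equal histograms.
    """
    if bin_width_pA <= 0:
        raise ValueError("bin width must be positive")
    x = trace.samples_pA
    if x.size == 0:
        raise ValueError("empty trace")
    lo = np.floor(x.min() / bin_width_pA) * bin_width_pA
    hi = np.ceil(x.max() / bin_width_pA) * bin_width_pA
    if hi <= lo:
        hi = lo + bin_width_pA
    edges = np.arange(lo, hi + 0.5 * bin_width_pA, bin_width_pA)
    counts, edges = np.histogram(x, bins=edges)
    return AmplitudeHistogram(edges, counts)


def fit_gaussian_mixture(data, n_components: int = 2, *,
                         random_state: int = 0,
                         max_samples: int = 200_000) -> GaussianMixtureFit:
    """Maximum-likelihood 1-D Gaussian mixture of the current amplitudes.

    ``data`` may be a :class:`CurrentTrace` or a plain sample array.
    Components are reported sorted by mean.  Large traces are thinned
    deterministically (every k-th sample) to bound the EM cost; the
    subsample is order-independent for stationary traces.
    """
    if not (1 <= n_components <= 5):
        raise ValueError("n_components must be between 1 and 5")
    x = data.samples_pA if isinstance(data, CurrentTrace) else np.asarray(data, float)
    x = x.ravel()
    if x.size <= n_components * 10:
        raise ValueError("too few samples for a mixture fit")
    if x.size > max_samples:
        step = int(np.ceil(x.size / max_samples))
        x = x[::step]

    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(n_components=n_components, covariance_type="full",
                         n_init=3, random_state=random_state)
    gm.fit(x.reshape(-1, 1))
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    weights = gm.weights_.ravel()[order]
    return GaussianMixtureFit(means, sds, weights, bool(gm.converged_),
                              float(gm.score(x.reshape(-1, 1)) * x.size))


def check_single_channel(trace: CurrentTrace, closed_level_pA: float,
                         open_level_pA: float, factor: float = 1.5,
                         min_samples: int = 4) -> None:
    """Reject traces with stacked (multi-channel) openings.

    A run of ``min_samples`` consecutive samples whose deviation from the
    closed level exceeds ``factor`` times the unitary amplitude indicates
    a second conducting channel; such recordings are discarded from
    single-channel analysis.
    """
    unitary = abs(open_level_pA - closed_level_pA)
    dev = np.abs(trace.samples_pA - closed_level_pA) > factor * unitary
    if dev.size < min_samples:
        return
    run = np.convolve(dev.astype(int), np.ones(min_samples, dtype=int), "valid")
    if np.any(run == min_samples):
        raise MultiChannelError(
            "trace shows sustained amplitudes beyond 1.5x the unitary "
            "current: more than one channel in the bilayer")


def idealize_half_amplitude(trace: CurrentTrace, closed_level_pA: float,
                            open_level_pA: float, min_event_samples: int = 2,
                            *, reject_multichannel: bool = True) -> IdealizedTrace:
    """Half-amplitude threshold idealization into open/closed dwells.

    The threshold is the midpoint of the two levels; a state change must
    be sustained for at least ``min_event_samples`` samples, which
    suppresses single-sample noise spikes.  Dwell durations sum exactly
    to the trace duration.
    """
    if open_level_pA == closed_level_pA:
        raise ValueError("open and closed levels must differ")
    if min_event_samples < 1:
        raise ValueError("min_event_samples must be >= 1")
    if trace.n_samples == 0:
        raise ValueError("empty trace")
    if reject_multichannel:
        check_single_channel(trace, closed_level_pA, open_level_pA)

    threshold = 0.5 * (open_level_pA + closed_level_pA)
    if open_level_pA > closed_level_pA:
        is_open = trace.samples_pA > threshold
    else:
        is_open = trace.samples_pA < threshold

    # run-length encode, then absorb runs shorter than the minimum event
    # duration into the preceding dwell
    change = np.flatnonzero(np.diff(is_open.astype(np.int8))) + 1
    bounds = np.concatenate([[0], change, [is_open.size]])
    runs = [(bool(is_open[b]), int(e - b)) for b, e in zip(bounds[:-1], bounds[1:])]

    cleaned: list[list] = []
    for state, length in runs:
        if cleaned and (length < min_event_samples or cleaned[-1][0] == state):
            cleaned[-1][1] += length
        else:
            cleaned.append([state, length])

    dt = 1.0 / trace.sampling_rate_Hz
    dwells = [Dwell("open" if s else "closed", n * dt) for s, n in cleaned]
    return IdealizedTrace(dwells, trace.sampling_rate_Hz)


def aggregate_po(idealized: list[IdealizedTrace]) -> OpenProbability:
    """Open probability across recordings: per-trace Po, mean and SEM.

    Po per trace is open time over total time; SEM uses the sample SD
    (ddof=1) over n traces and is undefined (NaN, flagged) for n = 1.
    """
    if not idealized:
        raise ValueError("need at least one idealized trace")
    per = np.array([tr.po for tr in idealized])
    n = per.size
    mean = float(per.mean())
    if n > 1:
        sem = float(per.std(ddof=1) / np.sqrt(n))
        defined = True
    else:
        sem, defined = float("nan"), False
    events = int(sum(tr.n_events for tr in idealized))
    return OpenProbability(per, mean, sem, n, events, defined)


def ramp_iv_metrics(trace: CurrentTrace, capacitance_pF: float,
                    v_start_mV: float = -100.0, v_end_mV: float = 100.0,
                    duration_ms: float = 50.0) -> RampIV:
    """Currents at -80 and +80 mV on a linear voltage ramp, as pA/pF.

    The ramp maps sample index linearly onto voltage; the current is read
    at the samples corresponding to the two probe voltages and divided by
    the cell capacitance.
    """
    if capacitance_pF <= 0:
        raise ValueError("capacitance must be positive")
    n = trace.n_samples
    expected = trace.sampling_rate_Hz * duration_ms * 1e-3
    if abs(n - expected) > max(1.0, 0.01 * expected):
        raise ValueError(
            f"trace length {n} inconsistent with a {duration_ms} ms ramp at "
            f"{trace.sampling_rate_Hz} Hz (expected ~{expected:.0f} samples)")

    def current_at(v: float) -> float:
        frac = (v - v_start_mV) / (v_end_mV - v_start_mV)
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{v} mV outside the ramp range")
        return float(trace.samples_pA[round(frac * (n - 1))])

    i_m80 = current_at(-80.0)
    i_p80 = current_at(80.0)
    return RampIV(v_start_mV, v_end_mV, duration_ms, i_m80, i_p80,
                  capacitance_pF, i_m80 / capacitance_pF, i_p80 / capacitance_pF)
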