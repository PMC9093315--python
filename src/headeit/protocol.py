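"""Measurement protocol of the 100 fps scalp EIT instrument.

A frame consists of 20 current patterns (CPs) applied for 500 microseconds
each; during every CP the voltages between all numerically adjacent pairs of
non-injecting electrodes (k, k+1), k = 1..31, are acquired simultaneously.
Numeric adjacency does not wrap from electrode 32 to 1 -- that is the unique
convention under which the default patterns yield 546 measurements per frame.
A configurable rejection list removes adjacent pairs that are not spatially
neighbouring, leaving 509 accepted measurements by default.

All voltages are rms values of the 10 kHz sinusoid; currents are quoted
peak-to-peak as on the instrument.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, replace

import numpy as np

from . import layouts


@dataclass(frozen=True)
class CurrentPattern:
    """One injection pair: ``amplitude`` is in amperes peak-to-peak."""

    source: int
    sink: int
    amplitude: float = layouts.DEFAULT_AMPLITUDE_PKPK

    def __post_init__(self):
        if self.source == self.sink:
            raise ValueError("source and sink electrodes must differ")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")

    @property
    def rms_current(self) -> float:
        """Drive current as rms of the sinusoid (pk-pk / 2*sqrt(2))."""
        return self.amplitude / (2.0 * math.sqrt(2.0))


@dataclass(frozen=True)
class MeasurementProtocol:
    """Ordered current patterns with their ordered voltage pairs.

    ``measurements`` is the flattened frame layout: (pattern index,
    (k, k+1)) in acquisition order.  ``cp_duration`` is the dwell per
    current pattern in seconds.
    """

    patterns: tuple[CurrentPattern, ...]
    measurements: tuple[tuple[int, tuple[int, int]], ...]
    n_electrodes: int = 32
    cp_duration: float = 500e-6

    def __post_init__(self):
        for p_idx, (lo, hi) in self.measurements:
            pat = self.patterns[p_idx]
            if lo in (pat.source, pat.sink) or hi in (pat.source, pat.sink):
                raise ValueError(
                    f"measurement pair ({lo},{hi}) uses an injection electrode "
                    f"of pattern {p_idx}"
                )
            if hi != lo + 1:
                raise ValueError(f"pair ({lo},{hi}) is not numerically adjacent")

    def __len__(self) -> int:
        return len(self.measurements)

    @property
    def frame_rate(self) -> float:
        return frame_rate(len(self.patterns), self.cp_duration)

    def labels(self) -> list[str]:
        return [measurement_label(self.patterns[p], pair)
                for p, pair in self.measurements]

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for p in self.patterns:
            h.update(f"{p.source},{p.sink},{p.amplitude:.9e};".encode())
        for p_idx, (lo, hi) in self.measurements:
            h.update(f"{p_idx}:{lo}-{hi};".encode())
        return h.hexdigest()[:16]

    def to_table(self) -> str:
        """Columnar text, one row per measurement."""
        lines = ["cp_index\tsrc\tsink\tmeas_hi\tmeas_lo"]
        for p_idx, (lo, hi) in self.measurements:
            pat = self.patterns[p_idx]
            lines.append(f"{p_idx + 1}\t{pat.source}\t{pat.sink}\t{lo}\t{hi}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class VoltageFrame:
    """One frame's voltage vector (volts rms) in protocol order."""

    values: np.ndarray
    index: int = 0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("voltage frame contains non-finite values")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


def default_current_patterns(amplitude: float = layouts.DEFAULT_AMPLITUDE_PKPK
                             ) -> list[CurrentPattern]:
    """The 20 shipped injection pairs, in frame order."""
    return [CurrentPattern(a, b, amplitude) for a, b in layouts.TABLE1_PATTERNS]


def enumerate_frame(patterns: list[CurrentPattern] | None = None,
                    n_electrodes: int = 32) -> MeasurementProtocol:
    """Assemble the full frame layout for the given current patterns.

    For each pattern, all numerically adjacent pairs (k, k+1), k = 1..n-1,
    excluding pairs touching either injection electrode, in ascending k
    order.  With the default 20 patterns and 32 electrodes this yields 546
    measurements.
    """
    if patterns is None:
        patterns = default_current_patterns()
    if n_electrodes < 2:
        raise ValueError("need at least two electrodes")
    for p in patterns:
        if not (1 <= p.source <= n_electrodes and 1 <= p.sink <= n_electrodes):
            raise ValueError(f"pattern {p.source}-{p.sink} out of range")
    meas = []
    for p_idx, p in enumerate(patterns):
        for k in range(1, n_electrodes):
            if k in (p.source, p.sink) or k + 1 in (p.source, p.sink):
                continue
            meas.append((p_idx, (k, k + 1)))
    return MeasurementProtocol(tuple(patterns), tuple(meas),
                               n_electrodes=n_electrodes)


def apply_rejection(protocol: MeasurementProtocol,
                    rejected: list[tuple[int, tuple[int, int]]]
                    ) -> MeasurementProtocol:
    """Remove the listed (pattern index, pair) measurements, order preserved."""
    remaining = list(protocol.measurements)
    for entry in rejected:
        p_idx, pair = entry[0], (entry[1][0], entry[1][1])
        try:
            remaining.remove((p_idx, pair))
        except ValueError:
            raise KeyError(f"rejection entry {entry!r} not in protocol") from None
    return replace(protocol, measurements=tuple(remaining))


def default_protocol(amplitude: float = layouts.DEFAULT_AMPLITUDE_PKPK,
                     reject: bool = True) -> MeasurementProtocol:
    """546-measurement frame, reduced to 509 by the default rejection list."""
    proto = enumerate_frame(default_current_patterns(amplitude))
    if reject:
        proto = apply_rejection(proto, layouts.default_rejection_entries())
    return proto


def measurement_label(pattern: CurrentPattern, pair: tuple[int, int]) -> str:
    """Tetrapolar label "a-b-c-d": injection a-b, measurement c-d."""
    return f"{pattern.source}-{pattern.sink}-{pair[0]}-{pair[1]}"


def parse_label(label: str) -> tuple[tuple[int, int], tuple[int, int]]:
    a, b, c, d = (int(s) for s in label.split("-"))
    return (a, b), (c, d)


def frame_rate(n_patterns: int, cp_duration: float) -> float:
    """Frames per second: 1 / (n_patterns * cp_duration)."""
    if n_patterns <= 0 or cp_duration <= 0:
        raise ValueError("pattern count and dwell time must be positive")
    return 1.0 / (n_patterns * cp_duration)


def snr_db(full_scale_rms: float, noise_rms: float) -> float:
    """Signal-to-noise ratio 20*log10(full_scale / noise), in dB."""
    if full_scale_rms <= 0 or noise_rms <= 0:
        raise ValueError("voltages must be positive")
    return 20.0 * math.log10(full_scale_rms / noise_rms)


def add_noise(frame: VoltageFrame, snr: float, seed: int,
              mode: str = "per_channel",
              full_scale: float | None = None) -> VoltageFrame:
    """Add zero-mean Gaussian measurement noise at the requested SNR.

    ``mode="per_channel"`` scales the noise standard deviation to each
    measurement's own magnitude, sigma_i = |v_i| * 10^(-snr/20), matching how
    instrument channel SNRs are quoted.  ``mode="full_scale"`` references all
    channels to a common full-scale voltage instead.  ``snr=inf`` returns the
    frame unchanged.  Deterministic for a fixed seed.
    """
    if math.isinf(snr):
        return frame
    rng = np.random.default_rng(seed)
    factor = 10.0 ** (-snr / 20.0)
    if mode == "per_channel":
        sd = np.abs(frame.values) * factor
    elif mode == "full_scale":
        fs = full_scale if full_scale is not None else np.max(np.abs(frame.values))
        sd = np.full(len(frame), fs * factor)
    else:
        raise ValueError(f"unknown noise mode {mode!r}")
    return VoltageFrame(frame.values + rng.normal(0.0, 1.0, len(frame)) * sd,
                        index=frame.index)
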