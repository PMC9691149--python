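"""Power-spectrum entropy (PSE) and wavelet-packet entropy (WPE).

Both indices share one construction: the energy of a signal segment is
split over ``z`` frequency sub-bands (unequal widths allowed), the
sub-band energies ``Ex`` are normalised to a probability distribution
``Px = Ex / E`` with ``E = sum(Ex)``, and the Shannon entropy

    H = -sum_x Px * log_z(Px)

is taken with logarithm base ``z`` so that a uniform distribution scores
1 and a one-band distribution scores 0. PSE obtains ``Ex`` from the FFT
periodogram; WPE obtains it from an orthonormal wavelet-packet
decomposition whose terminal-node energies are pooled per sub-band
(coefficient energy equals reconstructed-signal energy for orthogonal
wavelets, so no explicit reconstruction is needed).

As a muscle fatigues, sEMG power migrates into fewer low-frequency
sub-bands, so both entropies fall with movement number; ``trend_stats``
quantifies that decline (Pearson r, p, least-squares slope).

The wavelet-packet transform is implemented here directly (orthonormal
Daubechies filter bank, periodic boundary handling, frequency-ordered
terminal nodes) rather than through an external wavelet library.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import normalize_mvc

if TYPE_CHECKING:
    from .synthetic_semg import Recording

__all__ = [
    "BandScheme",
    "BandEnergies",
    "EntropyTrace",
    "TrendStats",
    "EmptyBandError",
    "band_energies_fft",
    "band_energies_wavelet",
    "wavelet_packet_energies",
    "pse",
    "wpe",
    "entropy_trace",
    "trend_stats",
    "feature_table",
    "feature_matrix",
    "trend_report",
]


class EmptyBandError(ValueError):
    """A sub-band contains no spectral estimate."""


# Orthonormal Daubechies scaling filters (sum = sqrt(2), unit energy).
_WAVELET_FILTERS: dict[str, np.ndarray] = {
    "haar": np.array([0.7071067811865476, 0.7071067811865476]),
    "db2": np.array(
        [
            0.48296291314469025,
            0.8365163037378079,
            0.22414386804185735,
            -0.12940952255092145,
        ]
    ),
    "db4": np.array(
        [
            0.23037781330885523,
            0.7148465705525415,
            0.6308807679295904,
            -0.02798376941698385,
            -0.18703481171888114,
            0.030841381835986965,
            0.032883011666982945,
            -0.010597401784997278,
        ]
    ),
}


@dataclass(frozen=True)
class BandScheme:
    """Shared sub-band layout for PSE and WPE.

    ``edges`` are strictly increasing frequency boundaries in Hz defining
    ``z = len(edges) - 1`` sub-bands. The default follows common sEMG
    practice: eight unequal bands over 10-250 Hz, narrower at low
    frequencies where fatigue concentrates the power.

    ``wp_depth`` is the extra wavelet-packet refinement below the depth
    needed to resolve the narrowest sub-band.
    """

    edges: tuple[float, ...] = (10, 20, 35, 55, 80, 110, 150, 200, 250)
    wavelet_name: str = "db4"
    wp_depth: int = 3
    log_base: str = "z"  # "z" (normalised to [0,1]) or "natural"

    @property
    def z(self) -> int:
        return len(self.edges) - 1

    def validate(self, sampling_rate: float | None = None) -> None:
        edges = np.asarray(self.edges, dtype=float)
        if len(edges) < 3 or np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be strictly increasing with >= 2 bands")
        if self.wp_depth < 1:
            raise ValueError("wp_depth must be >= 1")
        if self.wavelet_name not in _WAVELET_FILTERS:
            raise ValueError(
                f"unknown wavelet {self.wavelet_name!r}; "
                f"available: {sorted(_WAVELET_FILTERS)}"
            )
        if sampling_rate is not None and edges[-1] > sampling_rate / 2 + 1e-9:
            raise ValueError("band edges must lie within [0, sampling_rate/2]")


@dataclass
class BandEnergies:
    """Per-sub-band energies and their probability distribution."""

    Ex: np.ndarray
    E: float
    Px: np.ndarray

    @property
    def z(self) -> int:
        return len(self.Ex)

    @classmethod
    def from_energies(cls, Ex: np.ndarray) -> "BandEnergies":
        Ex = np.asarray(Ex, dtype=float)
        if np.any(Ex < 0):
            raise ValueError("band energies must be non-negative")
        E = float(Ex.sum())
        if E <= 0:
            raise ValueError("total band energy must be positive")
        return cls(Ex=Ex, E=E, Px=Ex / E)


@dataclass
class EntropyTrace:
    """One entropy value per movement cycle for one muscle channel."""

    values: np.ndarray
    kind: str  # "PSE" or "WPE"
    channel: int
    subject_id: str = ""
    speed: int = 0

    @property
    def cycle_index(self) -> np.ndarray:
        """1-based movement number."""
        return np.arange(1, len(self.values) + 1)


@dataclass
class TrendStats:
    pearson_r: float
    p_value: float
    slope: float
    intercept: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# FFT band energies
# ---------------------------------------------------------------------------

def band_energies_fft(
    segment: np.ndarray, scheme: BandScheme, sampling_rate: float
) -> BandEnergies:
    """Sub-band energies from the FFT periodogram.

    ``Ex`` sums the squared spectral magnitudes of the bins falling in
    each sub-band (half-open [lo, hi), last band closed); bins outside
    the scheme's range are excluded.
    """
    segment = np.asarray(segment, dtype=float).ravel()
    if segment.size < 2:
        raise ValueError("segment must contain at least 2 samples")
    scheme.validate(sampling_rate)

    spec = np.abs(np.fft.rfft(segment)) ** 2
    freqs = np.fft.rfftfreq(segment.size, 1.0 / sampling_rate)
    edges = np.asarray(scheme.edges, dtype=float)

    Ex = np.empty(scheme.z)
    for x in range(scheme.z):
        lo, hi = edges[x], edges[x + 1]
        if x == scheme.z - 1:
            mask = (freqs >= lo) & (freqs <= hi)
        else:
            mask = (freqs >= lo) & (freqs < hi)
        if not mask.any():
            raise EmptyBandError(
                f"no FFT bin falls inside sub-band {x + 1} ({lo}-{hi} Hz); "
                "use a longer segment or wider bands"
            )
        Ex[x] = spec[mask].sum()
    return BandEnergies.from_energies(Ex)


# ---------------------------------------------------------------------------
# Wavelet-packet transform (orthonormal, periodic, frequency-ordered)
# ---------------------------------------------------------------------------

def _analysis_step(x: np.ndarray, h: np.ndarray, g: np.ndarray):
    """One periodic filter-bank split; energy-preserving for even len(x)."""
    n = x.size
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(h.size)[None, :]) % n
    windows = x[idx]
    return windows @ h, windows @ g


def wavelet_packet_energies(
    segment: np.ndarray, depth: int, wavelet_name: str = "db4"
) -> tuple[np.ndarray, float]:
    """Terminal-node energies of a depth-``depth`` wavelet packet tree.

    The segment is symmetrically padded to a multiple of ``2**depth``;
    filtering uses periodic boundaries, so the transform is unitary and
    the node energies sum exactly to the padded segment's energy (the
    second return value). Nodes are returned in frequency order: node ``i``
    nominally covers ``[i, i+1] * (fs/2) / 2**depth``.
    """
    h = _WAVELET_FILTERS[wavelet_name]
    L = h.size
    g = ((-1) ** np.arange(L)) * h[::-1]

    x = np.asarray(segment, dtype=float).ravel()
    block = 2 ** depth
    if x.size < L * block:
        raise ValueError(
            f"segment of {x.size} samples is too short for depth {depth} "
            f"with a {L}-tap filter (needs >= {L * block})"
        )
    if x.size % block:
        pad = block - x.size % block
        x = np.pad(x, (0, pad), mode="symmetric")
    total_energy = float(np.sum(x ** 2))

    # frequency-ordered recursion: at an odd-position node the low/high
    # children swap (standard sequency ordering of the packet tree)
    nodes = [x]
    for _ in range(depth):
        nxt: list[np.ndarray] = []
        for pos, node in enumerate(nodes):
            lo, hi = _analysis_step(node, h, g)
            nxt.extend([lo, hi] if pos % 2 == 0 else [hi, lo])
        nodes = nxt
    energies = np.array([float(np.sum(n ** 2)) for n in nodes])
    return energies, total_energy


def _wp_total_depth(scheme: BandScheme, sampling_rate: float, n_samples: int) -> int:
    """Depth resolving the narrowest band, plus wp_depth refinement,
    capped by what the segment length supports."""
    L = _WAVELET_FILTERS[scheme.wavelet_name].size
    min_width = float(np.min(np.diff(np.asarray(scheme.edges))))
    nyquist = sampling_rate / 2.0
    d_band = max(0, math.ceil(math.log2(nyquist / min_width))) if min_width < nyquist else 0
    d_cap = int(math.floor(math.log2(n_samples / L))) if n_samples >= 2 * L else 0
    if d_cap < 1:
        raise ValueError(
            f"segment of {n_samples} samples is too short for wavelet analysis"
        )
    return min(d_band + scheme.wp_depth, d_cap)


def band_energies_wavelet(
    segment: np.ndarray, scheme: BandScheme, sampling_rate: float
) -> BandEnergies:
    """Sub-band energies pooled from wavelet-packet terminal nodes.

    Each terminal node is assigned to the sub-band containing its centre
    frequency; nodes below the first or above the last edge are pooled
    into the first/last band, so the total ``E`` equals the (padded)
    segment energy exactly (Parseval).
    """
    segment = np.asarray(segment, dtype=float).ravel()
    scheme.validate(sampling_rate)
    depth = _wp_total_depth(scheme, sampling_rate, segment.size)
    node_E, _total = wavelet_packet_energies(segment, depth, scheme.wavelet_name)

    width = (sampling_rate / 2.0) / node_E.size
    centers = (np.arange(node_E.size) + 0.5) * width
    edges = np.asarray(scheme.edges, dtype=float)
    band_idx = np.clip(np.searchsorted(edges, centers, side="right") - 1, 0, scheme.z - 1)

    Ex = np.zeros(scheme.z)
    np.add.at(Ex, band_idx, node_E)
    interior = np.flatnonzero(
        np.array([np.sum(band_idx == b) for b in range(scheme.z)]) == 0
    )
    if interior.size:
        b = int(interior[0])
        raise EmptyBandError(
            f"no wavelet-packet node falls inside sub-band {b + 1} "
            f"({edges[b]}-{edges[b + 1]} Hz); the segment is too short to "
            "resolve it"
        )
    return BandEnergies.from_energies(Ex)


# ---------------------------------------------------------------------------
# Entropy functionals
# ---------------------------------------------------------------------------

def _band_entropy(P: BandEnergies, log_base: str) -> float:
    p = P.Px[P.Px > 0]  # 0 * log 0 := 0
    h = -np.sum(p * np.log(p))
    if log_base == "z":
        h /= np.log(P.z)
    elif log_base != "natural":
        raise ValueError("log_base must be 'z' or 'natural'")
    return float(h)


def pse(P: BandEnergies, log_base: str = "z") -> float:
    """Power-spectrum entropy of a band-energy distribution.

    With the default base-``z`` logarithm the value lies in [0, 1]:
    1 for a uniform distribution, 0 when all energy sits in one band.
    """
    return _band_entropy(P, log_base)


def wpe(P: BandEnergies, log_base: str = "z") -> float:
    """Wavelet-packet entropy; same functional as :func:`pse`."""
    return _band_entropy(P, log_base)


# ---------------------------------------------------------------------------
# Per-cycle traces and fatigue trends
# ---------------------------------------------------------------------------

def entropy_trace(
    rec: "Recording",
    channel: int,
    kind: str = "PSE",
    scheme: BandScheme | None = None,
) -> EntropyTrace:
    """Per-cycle entropy of one muscle channel of a %MVC-normalised session."""
    scheme = scheme or BandScheme()
    kind = kind.upper()
    if kind not in ("PSE", "WPE"):
        raise ValueError("kind must be 'PSE' or 'WPE'")
    pct = normalize_mvc(rec.signal, rec.mvc_reference)
    values = []
    for start, end in rec.cycle_bounds:
        seg = pct[channel, start:end]
        if kind == "PSE":
            P = band_energies_fft(seg, scheme, rec.sampling_rate)
        else:
            P = band_energies_wavelet(seg, scheme, rec.sampling_rate)
        values.append(_band_entropy(P, scheme.log_base))
    return EntropyTrace(
        values=np.asarray(values),
        kind=kind,
        channel=channel,
        subject_id=rec.subject_id,
        speed=rec.speed,
    )


def trend_stats(trace: EntropyTrace | np.ndarray) -> TrendStats:
    """Pearson correlation and least-squares line of entropy vs movement number."""
    values = trace.values if isinstance(trace, EntropyTrace) else np.asarray(trace, float)
    if values.size < 3:
        raise ValueError("need at least 3 cycles for a trend")
    x = np.arange(1, values.size + 1, dtype=float)
    if np.allclose(values, values[0]):
        return TrendStats(0.0, 1.0, 0.0, float(values.mean()), degenerate=True)
    r, p = stats.pearsonr(x, values)
    fit = stats.linregress(x, values)
    return TrendStats(float(r), float(p), float(fit.slope), float(fit.intercept))


# ---------------------------------------------------------------------------
# Feature tables for the classical classifiers
# ---------------------------------------------------------------------------

def feature_table(
    recordings: Iterable["Recording"], scheme: BandScheme | None = None
) -> pd.DataFrame:
    """Long-format per-cycle entropy features.

    Columns: subject, speed, channel, cycle, rpe, PSE, WPE — one row per
    (recording, channel, cycle).
    """
    scheme = scheme or BandScheme()
    rows = []
    for rec in recordings:
        pct = normalize_mvc(rec.signal, rec.mvc_reference)
        for ch in range(rec.signal.shape[0]):
            for cyc, (start, end) in enumerate(rec.cycle_bounds):
                seg = pct[ch, start:end]
                p_fft = band_energies_fft(seg, scheme, rec.sampling_rate)
                p_wav = band_energies_wavelet(seg, scheme, rec.sampling_rate)
                rows.append(
                    {
                        "subject": rec.subject_id,
                        "speed": rec.speed,
                        "channel": ch,
                        "cycle": cyc,
                        "rpe": rec.rpe_per_cycle[cyc],
                        "PSE": pse(p_fft, scheme.log_base),
                        "WPE": wpe(p_wav, scheme.log_base),
                    }
                )
    return pd.DataFrame(rows)


def feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Pivot the long table into one 12-vector per (subject, speed, cycle).

    Feature order: PSE of channels 0..5 then WPE of channels 0..5.
    Returns the matrix and an index frame (subject, speed, cycle, rpe)
    aligned with its rows.
    """
    wide = table.pivot_table(
        index=["subject", "speed", "cycle", "rpe"],
        columns="channel",
        values=["PSE", "WPE"],
    )
    wide = wide.reindex(columns=pd.MultiIndex.from_product(
        [["PSE", "WPE"], sorted(table["channel"].unique())]
    ))
    X = wide.to_numpy(dtype=float)
    keys = wide.index.to_frame(index=False)
    return X, keys


def trend_report(table: pd.DataFrame) -> pd.DataFrame:
    """Per (channel, speed, index) fatigue-trend statistics.

    Mirrors a channel x speed correlation table: traces are averaged over
    subjects before the trend fit, plus the mean per-subject r.
    """
    rows = []
    for (speed, ch), grp in table.groupby(["speed", "channel"]):
        for kind in ("PSE", "WPE"):
            mean_trace = grp.groupby("cycle")[kind].mean().sort_index().to_numpy()
            ts = trend_stats(mean_trace)
            per_subj = [
                trend_stats(g.sort_values("cycle")[kind].to_numpy()).pearson_r
                for _, g in grp.groupby("subject")
            ]
            rows.append(
                {
                    "speed": speed,
                    "channel": ch,
                    "index": kind,
                    "pearson_r": ts.pearson_r,
                    "p_value": ts.p_value,
                    "slope": ts.slope,
                    "mean_subject_r": float(np.mean(per_subj)),
                }
            )
    return pd.DataFrame(rows)
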