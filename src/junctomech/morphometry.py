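"""Junction morphometrics from digitized geometry and intensity tables.

Implements the image-derived junction statistics downstream of manual
tracing: the zigzag index of the tight-junction membrane, relative
fluorescence intensity, Gaussian linescan peak distances across the
junction, puncta density and spacing along adherens junctions, proximity
ligation ROI arithmetic, and filament dimension summaries.  Inputs are
continuous-coordinate tables (µm / nm); segmentation and spot detection
are upstream of this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats
from skimage.filters import threshold_otsu

__all__ = [
    "JunctionTrace",
    "LinescanProfile",
    "PunctaTrain",
    "RegionIntensity",
    "ROICounts",
    "GaussianPeakFit",
    "PunctaMetrics",
    "zigzag_index",
    "relative_intensity",
    "linescan_peak_positions",
    "puncta_metrics",
    "pla_junctional_count",
    "filament_dimensions",
    "puncta_from_profile",
]


@dataclass
class JunctionTrace:
    """Ordered 2D polyline (µm) along one bicellular junction."""

    points: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if self.points.shape[0] < 2:
            raise ValueError("a trace needs at least 2 points")
        if np.any(np.all(np.diff(self.points, axis=0) == 0, axis=1)):
            raise ValueError("consecutive trace points must be distinct")

    @property
    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        return self.points[0], self.points[-1]


@dataclass
class LinescanProfile:
    """Intensity profiles along a ~1-µm line crossing the junction."""

    positions: np.ndarray               # nm, strictly increasing
    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        self.channels = {
            k: np.asarray(v, dtype=float) for k, v in self.channels.items()
        }
        for name, arr in self.channels.items():
            if arr.shape != self.positions.shape:
                raise ValueError(f"channel {name!r} length mismatch")


@dataclass
class PunctaTrain:
    """Punctum intervals (µm) along a junction of known length."""

    junction_length: float
    puncta: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.junction_length <= 0:
            raise ValueError("junction_length must be > 0")
        self.puncta = sorted((float(a), float(b)) for a, b in self.puncta)
        prev_end = 0.0
        for start, end in self.puncta:
            if not (0.0 <= start < end <= self.junction_length):
                raise ValueError(f"punctum ({start}, {end}) outside junction")
            if start < prev_end:
                raise ValueError("puncta intervals must not overlap")
            prev_end = end


@dataclass(frozen=True)
class RegionIntensity:
    mean_signal: float
    mean_reference: float
    mean_background: float

    def __post_init__(self) -> None:
        if min(self.mean_signal, self.mean_reference, self.mean_background) < 0:
            raise ValueError("intensities must be >= 0")


@dataclass(frozen=True)
class ROICounts:
    cell_count: int
    cyto_count: int

    def __post_init__(self) -> None:
        if self.cell_count < 0 or self.cyto_count < 0:
            raise ValueError("ROI dot counts must be >= 0 integers")


@dataclass(frozen=True)
class GaussianPeakFit:
    channel: str
    mean: float          # nm
    sigma: float
    amplitude: float
    offset: float
    ok: bool
    note: str = ""


@dataclass(frozen=True)
class PunctaMetrics:
    count_per_10um: float
    inter_puncta_distances: np.ndarray  # center-to-center, µm
    gaps: np.ndarray                    # edge-to-edge, µm
    punctum_lengths: np.ndarray


def zigzag_index(trace: JunctionTrace) -> float:
    """Tortuosity of the junction: arc length / endpoint chord.

    ZI = L(junction) / L(straight); 1 for a straight junction, larger
    the more the tight-junction membrane zigzags.
    """
    seglens = np.linalg.norm(np.diff(trace.points, axis=0), axis=1)
    p0, p1 = trace.endpoints
    chord = float(np.linalg.norm(p1 - p0))
    if chord == 0:
        raise ZeroDivisionError("trace endpoints coincide: zigzag index undefined")
    return float(seglens.sum() / chord)


def relative_intensity(region: RegionIntensity) -> tuple[float, bool]:
    """Background-subtracted signal ratioed to a junctional reference.

    RFI = (signal - background) / (reference - background).  Both signal
    and reference are corrected by the same image-level mean background,
    which makes the ratio invariant to intensity rescaling.  A negative
    numerator is clipped to 0 and flagged.
    """
    num = region.mean_signal - region.mean_background
    den = region.mean_reference - region.mean_background
    if den <= 0:
        raise ValueError("reference must exceed background")
    clipped = num < 0
    return (max(num, 0.0) / den, clipped)


def _gaussian(x, amp, mu, sigma, off):
    return off + amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _two_gaussian(x, a1, m1, s1, a2, m2, s2, off):
    return (
        off
        + a1 * np.exp(-0.5 * ((x - m1) / s1) ** 2)
        + a2 * np.exp(-0.5 * ((x - m2) / s2) ** 2)
    )


def _fit_single_gaussian(pos: np.ndarray, y: np.ndarray, channel: str) -> GaussianPeakFit:
    if np.ptp(y) <= 0:
        return GaussianPeakFit(channel, np.nan, np.nan, np.nan, np.nan, False, "flat channel")
    i_max = int(np.argmax(y))
    if i_max in (0, len(y) - 1):
        return GaussianPeakFit(channel, np.nan, np.nan, np.nan, np.nan, False, "peak at scan edge")
    span = float(pos[-1] - pos[0])
    step = float(np.median(np.diff(pos)))
    off0 = float(np.median(y))  # the peak occupies a small part of the scan
    amp0 = float(y[i_max] - off0)
    # half-width at half maximum around the empirical peak
    half = off0 + 0.5 * amp0
    left = i_max
    while left > 0 and y[left] > half:
        left -= 1
    right = i_max
    while right < len(y) - 1 and y[right] > half:
        right += 1
    hwhm = 0.5 * float(pos[right] - pos[left])
    sigma0 = max(hwhm / 1.1774, step)  # HWHM = sigma * sqrt(2 ln 2)
    try:
        popt, _ = optimize.curve_fit(
            _gaussian, pos, y,
            p0=[amp0, float(pos[i_max]), sigma0, off0],
            bounds=(
                [0.0, float(pos[0]), step / 2.0, -np.inf],
                [np.inf, float(pos[-1]), span, np.inf],
            ),
            maxfev=10000,
        )
    except RuntimeError:
        return GaussianPeakFit(channel, np.nan, np.nan, np.nan, np.nan, False, "fit did not converge")
    amp, mu, sigma, off = (float(v) for v in popt)
    if not (pos[0] <= mu <= pos[-1]):
        return GaussianPeakFit(channel, mu, abs(sigma), amp, off, False, "fitted peak outside scan")
    return GaussianPeakFit(channel, mu, abs(sigma), amp, off, True)


def _fit_two_gaussian_offset(
    pos: np.ndarray, y: np.ndarray, channel: str, midline: float
) -> GaussianPeakFit:
    """Mean absolute offset of two flanking peaks from the midline."""
    if np.ptp(y) <= 0:
        return GaussianPeakFit(channel, np.nan, np.nan, np.nan, np.nan, False, "flat channel")
    off0 = float(np.min(y))
    peaks, props = signal.find_peaks(y, prominence=0.1 * np.ptp(y))
    if peaks.size >= 2:
        top2 = peaks[np.argsort(props["prominences"])[-2:]]
        m1, m2 = float(pos[top2.min()]), float(pos[top2.max()])
    else:
        span = 0.25 * (pos[-1] - pos[0])
        m1, m2 = midline - span, midline + span
    amp0 = float(np.max(y) - off0)
    s0 = 0.1 * (pos[-1] - pos[0])
    try:
        popt, _ = optimize.curve_fit(
            _two_gaussian, pos, y,
            p0=[amp0, m1, s0, amp0, m2, s0, off0],
            maxfev=20000,
        )
    except RuntimeError:
        return GaussianPeakFit(channel, np.nan, np.nan, np.nan, np.nan, False, "fit did not converge")
    _, mu1, s1, _, mu2, s2, off = (float(v) for v in popt)
    mean_abs = 0.5 * (abs(mu1 - midline) + abs(mu2 - midline))
    return GaussianPeakFit(
        channel, midline + mean_abs, 0.5 * (abs(s1) + abs(s2)),
        float(np.max(y) - off), off, True, "two-peak fit: mean absolute offset",
    )


def linescan_peak_positions(
    profile: LinescanProfile,
    midline_channel: str,
    two_peak_channels: tuple[str, ...] = (),
) -> tuple[dict[str, GaussianPeakFit], dict[str, float]]:
    """Gaussian peak position per channel and distances from the midline.

    Each channel is fitted with a single Gaussian (amplitude, mean,
    width, offset); the reported distance of a channel is the absolute
    difference between its fitted mean and the midline channel's fitted
    mean.  Channels named in ``two_peak_channels`` (markers flanking the
    junction on both sides) are fitted with a two-Gaussian model and
    report the mean absolute offset of the two peaks.
    """
    if midline_channel not in profile.channels:
        raise KeyError(f"midline channel {midline_channel!r} not in profile")
    fits: dict[str, GaussianPeakFit] = {}
    mid_fit = _fit_single_gaussian(
        profile.positions, profile.channels[midline_channel], midline_channel
    )
    fits[midline_channel] = mid_fit
    distances: dict[str, float] = {}
    for name, y in profile.channels.items():
        if name == midline_channel:
            continue
        if name in two_peak_channels and mid_fit.ok:
            fit = _fit_two_gaussian_offset(profile.positions, y, name, mid_fit.mean)
        else:
            fit = _fit_single_gaussian(profile.positions, y, name)
        fits[name] = fit
        if fit.ok and mid_fit.ok:
            distances[name] = abs(fit.mean - mid_fit.mean)
        else:
            distances[name] = float("nan")
    return fits, distances


def puncta_metrics(train: PunctaTrain) -> PunctaMetrics:
    """Density and spacing statistics of a punctum train.

    Density is the punctum count per 10 µm of junction.  Lengths are
    end - start; gaps are edge-to-edge between consecutive puncta;
    inter-puncta distances are center-to-center (punctum length + gap
    for a periodic train).
    """
    starts = np.array([p[0] for p in train.puncta])
    ends = np.array([p[1] for p in train.puncta])
    count_per_10 = len(train.puncta) / (train.junction_length / 10.0)
    lengths = ends - starts
    gaps = starts[1:] - ends[:-1] if len(starts) > 1 else np.array([])
    centers = 0.5 * (starts + ends)
    inter = np.diff(centers) if len(centers) > 1 else np.array([])
    return PunctaMetrics(
        count_per_10um=float(count_per_10),
        inter_puncta_distances=inter,
        gaps=gaps,
        punctum_lengths=lengths,
    )


def pla_junctional_count(counts: ROICounts) -> tuple[int, bool]:
    """Junctional PLA dots: whole-cell ROI count minus cytoplasmic ROI count.

    A negative difference (more dots in the cytoplasmic ROI) is reported
    as-is with a quality flag.
    """
    diff = counts.cell_count - counts.cyto_count
    return diff, diff < 0


def filament_dimensions(
    measurements: dict[str, pd.DataFrame],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Filament length/width summaries with a two-group Mann-Whitney test.

    ``measurements`` maps group name to a table with ``length_nm`` and
    ``width_nm`` columns.  With exactly two groups, a two-sided
    Mann-Whitney U test is run per dimension; identical zero-variance
    groups are reported as p = 1 (no table more extreme than observed).
    """
    if not measurements:
        raise ValueError("no measurement groups")
    for name, df in measurements.items():
        if len(df) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 measurements")
    rows = []
    for name, df in measurements.items():
        for col in ("length_nm", "width_nm"):
            rows.append(
                {
                    "group": name,
                    "dimension": col,
                    "mean": float(df[col].mean()),
                    "sd": float(df[col].std(ddof=1)),
                    "n": len(df),
                }
            )
    summary = pd.DataFrame(rows)
    pvalues: dict[str, float] = {}
    names = list(measurements)
    if len(names) == 2:
        g1, g2 = measurements[names[0]], measurements[names[1]]
        for col in ("length_nm", "width_nm"):
            a, b = np.asarray(g1[col], float), np.asarray(g2[col], float)
            if np.ptp(np.concatenate([a, b])) == 0:
                pvalues[col] = 1.0
            else:
                _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                pvalues[col] = float(p)
    return summary, pvalues


def puncta_from_profile(
    positions_um: np.ndarray,
    intensity: np.ndarray,
    threshold: float | None = None,
) -> PunctaTrain:
    """Extract a punctum train from a 1D intensity profile by thresholding.

    Contiguous above-threshold runs become puncta; the threshold defaults
    to Otsu's.  A convenience for synthetic profiles — real spot
    detection is upstream of this package.
    """
    pos = np.asarray(positions_um, float)
    y = np.asarray(intensity, float)
    if pos.shape != y.shape:
        raise ValueError("positions and intensity must have equal length")
    thr = float(threshold_otsu(y)) if threshold is None else threshold
    above = y > thr
    puncta = []
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(y))
    for s, e in zip(starts, ends):
        puncta.append((float(pos[s]), float(pos[e - 1])))
    length = float(pos[-1])
    puncta = [(a, b) for a, b in puncta if b > a]
    return PunctaTrain(junction_length=length, puncta=puncta)
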