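"""Axial-stagger interaction scanning for coiled-coil rod domains.

Predicts the most likely parallel/antiparallel assembly modes of two
alpha-fibrous rod domains by counting potential inter-chain apolar and
ionic interactions as a function of the axial stagger between the two
molecules, in the tradition of classical myosin/intermediate-filament
axial-assembly analyses.

The model is deliberately one-dimensional: each residue of the coiled-coil
span occupies one axial unit (the supercoil pitch is ignored), and an
interaction is a pairwise condition on the axial separation of two
residues — apolar/apolar within +/-1 residue, oppositely charged within
+/-2 residues.  The total count, normalised by the overlap length, is a
per-residue interaction density whose peaks over stagger are the candidate
assembly modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "ResidueChain",
    "ResidueClassScheme",
    "InteractionProfile",
    "AssemblyMode",
    "ScanConfig",
    "ScanResult",
    "Periodogram",
    "classify_residue",
    "axial_positions",
    "count_interactions",
    "stagger_scan",
    "overlap_label",
    "combine_species",
    "fft_periodicity",
]

#: The 20 standard one-letter codes plus 'X' (unknown, treated as neutral).
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWYX")

PARALLEL = "parallel"
ANTIPARALLEL = "antiparallel"
_ORIENTATIONS = (PARALLEL, ANTIPARALLEL)


class InvalidResidueError(ValueError):
    """A character outside the accepted amino-acid alphabet."""


@dataclass(frozen=True)
class ResidueChain:
    """A rod-domain sequence with its coiled-coil span.

    ``cc_span`` is a pair of 1-based inclusive indices delimiting the
    region assumed to be in coiled-coil conformation; only this span
    participates in the stagger scan.
    """

    id: str
    sequence: str
    cc_span: tuple[int, int]
    species: str = ""
    role: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - AMINO_ACIDS
        if bad:
            raise InvalidResidueError(
                f"chain {self.id!r}: invalid residue code(s) {sorted(bad)}"
            )
        lo, hi = self.cc_span
        if not (1 <= lo <= hi <= len(self.sequence)):
            raise ValueError(
                f"chain {self.id!r}: cc_span {self.cc_span} outside "
                f"[1, {len(self.sequence)}]"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def cc_sequence(self) -> str:
        """The coiled-coil subsequence (the unit slid in the scan)."""
        lo, hi = self.cc_span
        return self.sequence[lo - 1 : hi]

    @property
    def cc_length(self) -> int:
        lo, hi = self.cc_span
        return hi - lo + 1


@dataclass(frozen=True)
class ResidueClassScheme:
    """Residue classification and axial interaction windows.

    The charged sets follow the classical definition (D, E acidic;
    R, K basic; histidine neutral).  The apolar set defaults to the
    standard hydrophobic-core alphabet used in coiled-coil analyses and
    is configurable because different traditions include or exclude A/Y.
    """

    apolar_set: frozenset = frozenset("AFILMVWY")
    basic_set: frozenset = frozenset("RK")
    acidic_set: frozenset = frozenset("DE")
    apolar_window: int = 1
    ionic_window: int = 2

    def __post_init__(self) -> None:
        sets = [self.apolar_set, self.basic_set, self.acidic_set]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("residue class sets must be pairwise disjoint")
        if self.apolar_window < 0 or self.ionic_window < 0:
            raise ValueError("interaction windows must be >= 0")


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of the stagger scan and peak significance rules."""

    score_cutoff: float = 0.23
    min_overlap: int = 32
    stagger_range: tuple[int, int] | str = "auto"
    smooth_window: int = 3
    scheme: ResidueClassScheme = field(default_factory=ResidueClassScheme)

    def __post_init__(self) -> None:
        if self.score_cutoff <= 0:
            raise ValueError("score_cutoff must be > 0")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be an odd integer >= 1")


@dataclass
class InteractionProfile:
    """Interaction counts and scores over all scanned staggers."""

    orientation: str
    staggers: np.ndarray     # integer residues
    n_apolar: np.ndarray
    n_ionic: np.ndarray
    overlap_len: np.ndarray
    score: np.ndarray        # (n_apolar + n_ionic) / overlap_len; NaN if overlap 0

    def row(self, stagger: int) -> tuple[int, int, int, float]:
        i = int(np.flatnonzero(self.staggers == stagger)[0])
        return (
            int(self.n_apolar[i]),
            int(self.n_ionic[i]),
            int(self.overlap_len[i]),
            float(self.score[i]),
        )


@dataclass(frozen=True)
class AssemblyMode:
    """One candidate assembly mode (a Table-style output row)."""

    orientation: str
    stagger: float
    score: float
    overlap_label: str
    status: str  # "significant" | "NS" | "ND"
    n_apolar: int = 0
    n_ionic: int = 0
    overlap_len: int = 0


@dataclass
class ScanResult:
    parallel: InteractionProfile
    antiparallel: InteractionProfile
    modes: list  # AssemblyMode, sorted by descending score; may be ND placeholders


@dataclass
class Periodogram:
    property_name: str
    frequencies: np.ndarray  # cycles/residue
    power: np.ndarray
    dominant_period: float   # residues/cycle; NaN when no periodicity

    @property
    def no_periodicity(self) -> bool:
        return not np.isfinite(self.dominant_period)


def classify_residue(aa: str, scheme: ResidueClassScheme | None = None) -> str:
    """Classify a one-letter code as apolar, basic, acidic or neutral."""
    scheme = scheme or ResidueClassScheme()
    if len(aa) != 1 or aa.upper() not in AMINO_ACIDS:
        raise InvalidResidueError(f"invalid residue code {aa!r}")
    aa = aa.upper()
    if aa in scheme.acidic_set:
        return "acidic"
    if aa in scheme.basic_set:
        return "basic"
    if aa in scheme.apolar_set:
        return "apolar"
    return "neutral"


def _check_orientation(orientation: str) -> None:
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}")


def axial_positions(
    chain_a: ResidueChain,
    chain_b: ResidueChain,
    orientation: str,
    stagger: int,
):
    """Axial coordinate of every cc-span residue of both chains.

    Chain A residue i (1-based within its cc_span) sits at axial i-1.
    Parallel: chain B residue j sits at (j-1) + stagger, i.e. the stagger
    separates the two N-termini.  Antiparallel: B residue j sits at
    stagger + (LB - j), so B's C-terminal residue sits at axial = stagger
    and B runs C->N toward higher axial coordinates.

    Returns ``(pos_a, pos_b, overlap_len)`` where the positions are dicts
    from 1-based cc-span residue index to integer axial coordinate.
    """
    _check_orientation(orientation)
    la, lb = chain_a.cc_length, chain_b.cc_length
    pos_a = {i: i - 1 for i in range(1, la + 1)}
    if orientation == PARALLEL:
        pos_b = {j: (j - 1) + stagger for j in range(1, lb + 1)}
    else:
        pos_b = {j: stagger + (lb - j) for j in range(1, lb + 1)}
    overlap = _overlap_len(la, lb, stagger)
    return pos_a, pos_b, overlap


def _overlap_len(la: int, lb: int, stagger: int) -> int:
    # both orientations occupy axial interval [stagger, stagger + lb - 1]
    return max(0, min(la - 1, stagger + lb - 1) - max(0, stagger) + 1)


def _class_indicators(chain: ResidueChain, scheme: ResidueClassScheme):
    seq = chain.cc_sequence
    apolar = np.array([c in scheme.apolar_set for c in seq], dtype=float)
    basic = np.array([c in scheme.basic_set for c in seq], dtype=float)
    acidic = np.array([c in scheme.acidic_set for c in seq], dtype=float)
    return apolar, basic, acidic


def _windowed(counts: np.ndarray, window: int) -> np.ndarray:
    """Sum of ``counts`` over lags within +/-window of each lag."""
    kernel = np.ones(2 * window + 1)
    return np.convolve(counts, kernel, mode="same")


def count_interactions(
    chain_a: ResidueChain,
    chain_b: ResidueChain,
    orientation: str,
    stagger: int,
    scheme: ResidueClassScheme | None = None,
) -> tuple[int, int, int]:
    """Count apolar and ionic residue pairs at one stagger.

    A pair (i in A, j in B) counts as apolar when both residues are
    apolar and their axial separation is at most ``scheme.apolar_window``;
    as ionic when the residues carry opposite charges and the separation
    is at most ``scheme.ionic_window``.  Each qualifying pair is counted
    exactly once.  Returns ``(n_apolar, n_ionic, overlap_len)``.
    """
    scheme = scheme or ResidueClassScheme()
    _check_orientation(orientation)
    prof_p, prof_a = _scan_profiles(chain_a, chain_b, scheme)
    prof = prof_p if orientation == PARALLEL else prof_a
    idx = stagger - int(prof.staggers[0])
    if idx < 0 or idx >= len(prof.staggers):
        return 0, 0, 0  # no axial overlap at this stagger
    return int(prof.n_apolar[idx]), int(prof.n_ionic[idx]), int(prof.overlap_len[idx])


def _scan_profiles(
    chain_a: ResidueChain,
    chain_b: ResidueChain,
    scheme: ResidueClassScheme,
    stagger_range: tuple[int, int] | str = "auto",
) -> tuple[InteractionProfile, InteractionProfile]:
    """Interaction counts for every stagger with nonzero overlap.

    Pair counts for all staggers at once: with one residue per axial
    unit, the number of pairs at a given axial separation is a
    cross-correlation (parallel) or convolution (antiparallel) of the
    per-chain class indicator arrays, and the windowed pair count is a
    moving sum over separations.
    """
    la, lb = chain_a.cc_length, chain_b.cc_length
    ap_a, ba_a, ac_a = _class_indicators(chain_a, scheme)
    ap_b, ba_b, ac_b = _class_indicators(chain_b, scheme)

    # Staggers with overlap >= 1, padded by the interaction window: residues
    # just outside the axial overlap can still pair across the gap.
    pad = max(scheme.apolar_window, scheme.ionic_window)
    staggers = np.arange(-(lb - 1) - pad, la + pad)
    overlap = np.array([_overlap_len(la, lb, int(s)) for s in staggers])

    # Parallel: A residue p (0-based) at axial p, B residue q at q + s.
    # Pairs at separation t: sum over p - q = s + t, i.e. correlate.
    def corr(u, v):  # pairs at lag k = p - q, ascending k = -(lb-1) .. la-1
        return np.correlate(u, v, mode="full")

    # Antiparallel: B residue q at axial s + (lb - 1) - q; separation
    # t = p + q - (s + lb - 1).  Pairs over p + q = m: convolve.
    def conv(u, v):
        return np.convolve(u, v, mode="full")  # index m = 0 .. la+lb-2

    profiles = []
    for combine in (corr, conv):
        # pair-count arrays over lag -(lb-1) .. la-1; pad to the stagger axis
        pairs_ap = np.pad(combine(ap_a, ap_b), pad)
        pairs_ion = np.pad(combine(ac_a, ba_b) + combine(ba_a, ac_b), pad)
        n_ap_all = _windowed(pairs_ap, scheme.apolar_window)
        n_ion_all = _windowed(pairs_ion, scheme.ionic_window)
        # correlate index k corresponds to stagger k (separation 0);
        # convolve index m corresponds to stagger m - (lb - 1).
        n_ap = np.rint(n_ap_all).astype(int)
        n_ion = np.rint(n_ion_all).astype(int)
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(overlap > 0, (n_ap + n_ion) / overlap, np.nan)
        orientation = PARALLEL if combine is corr else ANTIPARALLEL
        profiles.append(
            InteractionProfile(
                orientation=orientation,
                staggers=staggers.copy(),
                n_apolar=n_ap,
                n_ionic=n_ion,
                overlap_len=overlap.copy(),
                score=score,
            )
        )

    if stagger_range != "auto":
        lo, hi = stagger_range
        for i, p in enumerate(profiles):
            keep = (p.staggers >= lo) & (p.staggers <= hi)
            profiles[i] = InteractionProfile(
                p.orientation,
                p.staggers[keep],
                p.n_apolar[keep],
                p.n_ionic[keep],
                p.overlap_len[keep],
                p.score[keep],
            )
    return profiles[0], profiles[1]


def _find_peaks(
    profile: InteractionProfile, config: ScanConfig
) -> list[AssemblyMode]:
    score = profile.score.copy()
    valid = np.isfinite(score)
    score[~valid] = 0.0
    w = config.smooth_window
    if w > 1:
        kernel = np.ones(w)
        norm = np.convolve(np.ones_like(score), kernel, mode="same")
        smoothed = np.convolve(score, kernel, mode="same") / norm
    else:
        smoothed = score
    modes = []
    seen: set[int] = set()
    half = w // 2
    for i in range(1, len(smoothed) - 1):
        if not (smoothed[i] > smoothed[i - 1] and smoothed[i] > smoothed[i + 1]):
            continue
        if profile.overlap_len[i] < config.min_overlap:
            continue
        # localize the mode at the raw-score maximum inside the smoothing
        # window (the moving average finds the peak, the raw profile places it)
        lo = max(0, i - half)
        window = score[lo : i + half + 1]
        i = lo + int(np.argmax(window))
        if profile.overlap_len[i] < config.min_overlap or i in seen:
            continue
        seen.add(i)
        raw = float(profile.score[i])
        status = "significant" if raw >= config.score_cutoff else "NS"
        modes.append(
            AssemblyMode(
                orientation=profile.orientation,
                stagger=int(profile.staggers[i]),
                score=raw,
                overlap_label="",
                status=status,
                n_apolar=int(profile.n_apolar[i]),
                n_ionic=int(profile.n_ionic[i]),
                overlap_len=int(profile.overlap_len[i]),
            )
        )
    return modes


def stagger_scan(
    chain_a: ResidueChain,
    chain_b: ResidueChain,
    config: ScanConfig | None = None,
) -> ScanResult:
    """Slide chain B past chain A in both orientations and score staggers.

    Returns the full interaction profiles plus the list of assembly-mode
    peaks (strict local maxima of the smoothed score with overlap at
    least ``config.min_overlap``), each labelled significant or NS by the
    normalised-score cutoff; an orientation with no admissible peak
    contributes a single ND placeholder mode.  Modes are sorted by
    descending score.
    """
    config = config or ScanConfig()
    if min(chain_a.cc_length, chain_b.cc_length) < config.min_overlap:
        warnings.warn(
            "coiled-coil span shorter than min_overlap: all modes will be ND/NS",
            stacklevel=2,
        )
    prof_p, prof_a = _scan_profiles(
        chain_a, chain_b, config.scheme, config.stagger_range
    )
    modes: list[AssemblyMode] = []
    for prof in (prof_p, prof_a):
        peaks = _find_peaks(prof, config)
        for m in peaks:
            label = overlap_label(chain_a, chain_b, m.orientation, int(m.stagger))
            modes.append(replace(m, overlap_label=label))
        if not peaks:
            modes.append(
                AssemblyMode(
                    orientation=prof.orientation,
                    stagger=float("nan"),
                    score=float("nan"),
                    overlap_label="ND",
                    status="ND",
                )
            )
    modes.sort(key=lambda m: (-(m.score if np.isfinite(m.score) else -np.inf)))
    return ScanResult(parallel=prof_p, antiparallel=prof_a, modes=modes)


class NoOverlapError(ValueError):
    """Requested a label for a stagger with zero axial overlap."""


def overlap_label(
    chain_a: ResidueChain,
    chain_b: ResidueChain,
    orientation: str,
    stagger: int,
) -> str:
    """Encode which ends of the two chains lie in the overlap region.

    First letter: the end of chain A inside the overlap (C or N); second
    letter: the end (or region) of chain B.  "CC50" means the C-terminal
    50 residues of both coiled-coil domains overlap; "CN46" means the
    C-terminus of A lies over an N-terminal region of B.  When either
    chain lies entirely inside the other's span the label is "FULL" plus
    the overlap length.
    """
    _check_orientation(orientation)
    la, lb = chain_a.cc_length, chain_b.cc_length
    ov = _overlap_len(la, lb, stagger)
    if ov == 0:
        raise NoOverlapError(f"zero overlap at stagger {stagger}")
    if ov == la or ov == lb:
        return f"FULL{ov}"
    lo = max(0, stagger)
    hi = min(la - 1, stagger + lb - 1)
    # chain A: N-terminus at axial 0, C-terminus at la - 1
    end_a = "C" if hi == la - 1 else "N"
    # chain B ends: parallel N at stagger / C at stagger+lb-1; antiparallel swapped
    if orientation == PARALLEL:
        b_n, b_c = stagger, stagger + lb - 1
    else:
        b_c, b_n = stagger, stagger + lb - 1
    if lo <= b_c <= hi:
        end_b = "C"
    elif lo <= b_n <= hi:
        end_b = "N"
    else:  # overlap interior to B: name the nearer end's region
        end_b = "N" if abs(lo - b_n) <= abs(b_c - hi) else "C"
    return f"{end_a}{end_b}{ov}"


def combine_species(
    modes_by_species: dict[str, list[AssemblyMode]],
    stagger_tolerance: int = 5,
) -> tuple[list[AssemblyMode], list[tuple[str, AssemblyMode]]]:
    """Merge per-species assembly modes into consensus modes.

    Peaks of the same orientation are matched across species when their
    staggers agree within ``stagger_tolerance`` residues; a matched set
    spanning every species is combined by arithmetic mean of stagger and
    score (status significant only if significant in every species).
    Modes not matched in all species are returned separately, flagged by
    species.  A single-species input is returned unchanged.
    """
    if not modes_by_species:
        raise ValueError("combine_species requires at least one species")
    species = list(modes_by_species)
    if len(species) == 1:
        return list(modes_by_species[species[0]]), []

    anchor, *others = species
    combined: list[AssemblyMode] = []
    used = {sp: set() for sp in species}
    real = lambda m: m.status != "ND" and np.isfinite(m.stagger)

    for i, mode in enumerate(modes_by_species[anchor]):
        if not real(mode):
            continue
        group = [mode]
        picks = {}
        for sp in others:
            best = None
            for j, cand in enumerate(modes_by_species[sp]):
                if j in used[sp] or not real(cand):
                    continue
                if cand.orientation != mode.orientation:
                    continue
                d = abs(cand.stagger - mode.stagger)
                if d <= stagger_tolerance and (best is None or d < best[0]):
                    best = (d, j, cand)
            if best is None:
                break
            picks[sp] = best
        if len(picks) == len(others):
            used[anchor].add(i)
            for sp, (_, j, cand) in picks.items():
                used[sp].add(j)
                group.append(cand)
            status = (
                "significant"
                if all(g.status == "significant" for g in group)
                else "NS"
            )
            combined.append(
                AssemblyMode(
                    orientation=mode.orientation,
                    stagger=float(np.mean([g.stagger for g in group])),
                    score=float(np.mean([g.score for g in group])),
                    overlap_label=mode.overlap_label,
                    status=status,
                    n_apolar=mode.n_apolar,
                    n_ionic=mode.n_ionic,
                    overlap_len=mode.overlap_len,
                )
            )
    unmatched = [
        (sp, m)
        for sp in species
        for k, m in enumerate(modes_by_species[sp])
        if k not in used[sp] and real(m)
    ]
    combined.sort(key=lambda m: -m.score)
    return combined, unmatched


def fft_periodicity(
    property_profile: np.ndarray,
    property_name: str = "profile",
) -> Periodogram:
    """Discrete-Fourier periodogram of a per-residue property profile.

    The profile is mean-subtracted before transformation; the dominant
    period is the reciprocal of the nonzero frequency with maximal power.
    A constant profile has no off-origin power and is flagged (NaN
    dominant period).
    """
    x = np.asarray(property_profile, dtype=float)
    if x.size < 8:
        raise ValueError("profile must have length >= 8")
    x = x - x.mean()
    spectrum = np.fft.rfft(x)
    power = np.abs(spectrum) ** 2
    freqs = np.fft.rfftfreq(x.size)
    if np.allclose(power[1:], 0.0):
        return Periodogram(property_name, freqs, power, float("nan"))
    k = 1 + int(np.argmax(power[1:]))
    return Periodogram(property_name, freqs, power, 1.0 / freqs[k])
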