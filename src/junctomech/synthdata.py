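"""Seeded generators of synthetic inputs with ground-truth metadata.

Each generator is a pure function of (seed, parameters): the same call
yields bit-identical data.  Generated objects mimic the statistical
structure the corresponding analysis stage assumes — heptad-patterned
coiled-coil pairs with a planted interaction-rich stagger, Hertz-law AFM
force curves with baseline and contact offsets, multi-channel junction
linescans, periodic puncta trains, and 1:1 binding titrations — and each
dataset carries a :class:`GroundTruth` record of every planted quantity.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .coilscan import ResidueChain
from .mechanofit import BindingSeries, ForceCurve, binding_fraction, hertz_force
from .morphometry import LinescanProfile, PunctaTrain

__all__ = [
    "GroundTruth",
    "gen_coiled_coil_pair",
    "gen_afm_curves",
    "gen_linescans",
    "gen_puncta_trains",
    "gen_binding_series",
]


@dataclass(frozen=True)
class GroundTruth:
    """Provenance record of one generated dataset."""

    generator_name: str
    seed: int
    parameters: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


_APOLAR_CORE = "LIVMAF"   # residues planted at heptad a/d positions
_NEUTRAL = "QNSTG"        # uncharged, non-apolar background


def gen_coiled_coil_pair(
    seed: int,
    len_a: int = 150,
    len_b: int = 150,
    orientation: str = "antiparallel",
    planted_stagger: int = 100,
    interaction_density: float = 0.5,
) -> tuple[ResidueChain, ResidueChain, GroundTruth]:
    """A coiled-coil pair with ionic interactions planted at one stagger.

    Both chains carry a heptad background (apolar residues at the a/d
    core positions, neutral residues elsewhere, no charges).  Interacting
    pairs — acidic on chain A with basic on chain B, or apolar with
    apolar — are then planted at axially matched positions of the planted
    stagger/orientation, with partners sitting at the boundary of their
    interaction window, so the windowed count has a strict, sharp maximum
    at the planted stagger.  ``interaction_density`` is the planting
    probability per overlap position (0 = pure background).
    """
    rng = np.random.default_rng(seed)
    if not 0.0 <= interaction_density <= 1.0:
        raise ValueError("interaction_density must lie in [0, 1]")
    overlap = max(0, min(len_a - 1, planted_stagger + len_b - 1)
                  - max(0, planted_stagger) + 1)
    if overlap < 32:
        raise ValueError(
            f"planted stagger {planted_stagger} gives overlap {overlap} < 32 "
            f"for lengths ({len_a}, {len_b})"
        )

    def background(n: int) -> list[str]:
        seq = []
        for i in range(n):
            if i % 7 in (0, 3):  # heptad positions a and d
                seq.append(_APOLAR_CORE[rng.integers(len(_APOLAR_CORE))])
            else:
                seq.append(_NEUTRAL[rng.integers(len(_NEUTRAL))])
        return seq

    seq_a, seq_b = background(len_a), background(len_b)

    # axial coordinate of B residue index q (0-based) at the planted stagger
    if orientation == "parallel":
        b_index_at = lambda axial: axial - planted_stagger
    else:
        b_index_at = lambda axial: planted_stagger + len_b - 1 - axial

    # Pairs are planted at the boundary of their interaction window
    # (ionic at +/-2, apolar at +/-1): every planted pair is counted at the
    # planted stagger but half of them fall out of the window one stagger
    # away, so the interaction count has a strict, sharp maximum at the
    # planted alignment instead of a window-wide plateau.
    lo = max(0, planted_stagger)
    hi = min(len_a - 1, planted_stagger + len_b - 1)
    for p in range(lo, hi + 1):
        if p % 7 in (0, 3) or rng.random() >= interaction_density:
            continue
        ionic = rng.random() < 0.5
        w = 2 if ionic else 1
        for t in (-w, w):  # partners at both window boundaries
            q = b_index_at(p - t)
            if 0 <= q < len_b and q % 7 not in (0, 3):
                if ionic:
                    seq_a[p] = "DE"[rng.integers(2)]
                    seq_b[q] = "KR"[rng.integers(2)]
                else:
                    seq_a[p] = _APOLAR_CORE[rng.integers(len(_APOLAR_CORE))]
                    seq_b[q] = _APOLAR_CORE[rng.integers(len(_APOLAR_CORE))]

    chain_a = ResidueChain(
        id="synthA", sequence="".join(seq_a), cc_span=(1, len_a),
        species="synthetic", role="planted pair A",
    )
    chain_b = ResidueChain(
        id="synthB", sequence="".join(seq_b), cc_span=(1, len_b),
        species="synthetic", role="planted pair B",
    )
    truth = GroundTruth(
        "gen_coiled_coil_pair", seed,
        {
            "len_a": len_a, "len_b": len_b, "orientation": orientation,
            "planted_stagger": planted_stagger,
            "interaction_density": interaction_density,
        },
    )
    return chain_a, chain_b, truth


def gen_afm_curves(
    seed: int,
    n: int = 200,
    young_modulus: float = 0.0037,   # MPa; WT apical stiffness scale
    probe_radius: float = 5.0,       # µm
    poisson_ratio: float = 0.5,
    noise_sd: float = 0.1,           # nN
    baseline: float = 0.2,           # nN offset before correction
    contact_shift: float = 0.3,      # µm of pre-contact travel
    max_force: float = 5.0,          # nN
    n_points: int = 400,
    condition: str = "synthetic",
) -> tuple[list[ForceCurve], GroundTruth]:
    """Hertz-law approach curves with pre-contact segment and noise.

    Each curve follows the spherical Hertz law beyond a flat pre-contact
    segment of length ``contact_shift``, offset by ``baseline`` and with
    additive Gaussian force noise.  The indentation axis spans the
    pre-contact region plus the depth at which the noise-free force
    reaches ``max_force``.
    """
    if young_modulus <= 0 or probe_radius <= 0:
        raise ValueError("young_modulus and probe_radius must be > 0")
    rng = np.random.default_rng(seed)
    f_unit = hertz_force(1.0, young_modulus, probe_radius, poisson_ratio)
    x_max = (max_force / f_unit) ** (2.0 / 3.0)
    curves = []
    for _ in range(n):
        x = np.linspace(0.0, contact_shift + x_max, n_points)
        depth = np.clip(x - contact_shift, 0.0, None)
        f = baseline + hertz_force(depth, young_modulus, probe_radius, poisson_ratio)
        f = f + rng.normal(0.0, noise_sd, size=x.size) if noise_sd > 0 else f
        curves.append(
            ForceCurve(
                indentation=x, force=f,
                probe_radius=probe_radius, poisson_ratio=poisson_ratio,
                condition=condition,
            )
        )
    truth = GroundTruth(
        "gen_afm_curves", seed,
        {
            "n": n, "young_modulus": young_modulus,
            "probe_radius": probe_radius, "poisson_ratio": poisson_ratio,
            "noise_sd": noise_sd, "baseline": baseline,
            "contact_shift": contact_shift, "max_force": max_force,
            "n_points": n_points,
        },
    )
    return curves, truth


def gen_linescans(
    seed: int,
    n: int = 25,
    offsets_nm: dict[str, float] | None = None,
    midline_channel: str = "ZO1",
    fwhm_nm: float = 80.0,
    noise_sd: float = 0.05,          # fraction of peak amplitude
    span_nm: float = 1000.0,
    step_nm: float = 10.0,
) -> tuple[list[LinescanProfile], GroundTruth]:
    """Multi-channel 1-µm junction linescans with planted peak offsets.

    The midline channel peaks at 0; each other channel peaks at its
    planted offset from the midline.  Default offsets are the measured
    junctional architecture (CGN 64.6 nm, NM2B 117.13 nm from the ZO-1
    midline); peak FWHM defaults to 80 nm, STED-like.
    """
    offsets = dict(offsets_nm) if offsets_nm is not None else {
        "CGN": 64.6, "NM2B": 117.13,
    }
    half = span_nm / 2.0
    for name, off in offsets.items():
        if abs(off) >= half:
            raise ValueError(f"offset of channel {name!r} outside the scan window")
    rng = np.random.default_rng(seed)
    sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    positions = np.arange(-half, half + step_nm / 2, step_nm)
    profiles = []
    for _ in range(n):
        channels = {}
        for name, off in {midline_channel: 0.0, **offsets}.items():
            y = np.exp(-0.5 * ((positions - off) / sigma) ** 2)
            if noise_sd > 0:
                y = y + rng.normal(0.0, noise_sd, size=y.size)
            channels[name] = y
        profiles.append(LinescanProfile(positions=positions.copy(), channels=channels))
    truth = GroundTruth(
        "gen_linescans", seed,
        {
            "n": n, "offsets_nm": offsets, "midline_channel": midline_channel,
            "fwhm_nm": fwhm_nm, "noise_sd": noise_sd,
            "span_nm": span_nm, "step_nm": step_nm,
        },
    )
    return profiles, truth


def gen_puncta_trains(
    seed: int,
    n: int = 100,
    junction_length: float = 20.0,   # µm
    punctum_length: float = 0.27,    # µm
    gap: float = 0.66,               # µm
    jitter_sd: float = 0.05,         # µm, per punctum edge
) -> tuple[list[PunctaTrain], GroundTruth]:
    """Periodic puncta trains with jittered edges along a junction.

    Defaults reproduce the fragmented adherens-junction geometry
    (punctum ≈0.27 µm, empty gap ≈0.66 µm, so center-to-center spacing
    ≈0.93 µm).  Edge jitter is Gaussian and independent; intervals are
    clipped to the junction and forced non-overlapping.
    """
    period = punctum_length + gap
    if punctum_length <= 0 or gap <= 0:
        raise ValueError("punctum_length and gap must be > 0")
    if punctum_length >= period:
        raise ValueError("punctum length must be smaller than the period")
    rng = np.random.default_rng(seed)
    trains = []
    for _ in range(n):
        phase = rng.uniform(0, period)
        starts0 = np.arange(phase, junction_length - punctum_length, period)
        intervals = []
        prev_end = 0.0
        for s0 in starts0:
            a = s0 + rng.normal(0.0, jitter_sd)
            b = s0 + punctum_length + rng.normal(0.0, jitter_sd)
            a = max(a, prev_end, 0.0)
            b = min(b, junction_length)
            if b - a <= 1e-9:
                continue
            intervals.append((a, b))
            prev_end = b
        trains.append(PunctaTrain(junction_length=junction_length, puncta=intervals))
    truth = GroundTruth(
        "gen_puncta_trains", seed,
        {
            "n": n, "junction_length": junction_length,
            "punctum_length": punctum_length, "gap": gap,
            "jitter_sd": jitter_sd,
        },
    )
    return trains, truth


def gen_binding_series(
    seed: int,
    n: int = 7,
    kd: float = 346.0,               # nM
    target_conc: float = 200.0,      # nM
    ligand_max: float = 10000.0,     # nM
    ligand_min: float = 0.0,
    n_points: int = 16,
    noise_sd: float = 0.02,          # absolute, on fraction bound
) -> tuple[list[BindingSeries], GroundTruth]:
    """1:1 titration series from the exact quadratic isotherm plus noise.

    With ``ligand_min`` = 0 the grid is a two-fold dilution series from
    ``ligand_max`` plus a zero point (MST capillary convention); with a
    positive ``ligand_min`` the points are spaced geometrically over
    [ligand_min, ligand_max].  Defaults mirror a 200 nM target titrated
    to 10 µM.
    """
    if kd <= 0 or target_conc <= 0:
        raise ValueError("kd and target_conc must be > 0")
    rng = np.random.default_rng(seed)
    if ligand_min > 0:
        ligand = np.geomspace(ligand_min, ligand_max, n_points)
    else:
        grid = ligand_max / (2.0 ** np.arange(n_points - 1))[::-1]
        ligand = np.concatenate([[0.0], grid])
    series = []
    for k in range(n):
        f = binding_fraction(ligand, kd, target_conc, model="quadratic")
        resp = f + rng.normal(0.0, noise_sd, size=ligand.size) if noise_sd > 0 else f
        series.append(
            BindingSeries(
                ligand_conc=ligand.copy(), response=resp,
                target_conc=target_conc, label=f"synthetic-{k}",
            )
        )
    truth = GroundTruth(
        "gen_binding_series", seed,
        {
            "n": n, "kd": kd, "target_conc": target_conc,
            "ligand_max": ligand_max, "ligand_min": ligand_min,
            "n_points": n_points, "noise_sd": noise_sd,
        },
    )
    return series, truth
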