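"""Mechanical and binding model fitting.

Three small fitting problems around junction mechanobiology:

* Hertz spherical contact mechanics for AFM force-indentation curves of
  epithelial monolayers, F = 4 E sqrt(r) x^(3/2) / (3 (1 - v^2)), yielding
  the apparent Young's modulus E of the apical surface;
* the exact 1:1 binding isotherm for microscale-thermophoresis titrations,
  yielding a dissociation constant K_d;
* soluble-fraction arithmetic for filament pelleting assays.

Interface units follow lab conventions: indentation in µm, force in nN,
Young's modulus in MPa, concentrations in nM.  The Hertz prefactor is
computed in SI internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ForceCurve",
    "HertzFitResult",
    "BindingSeries",
    "KdFitResult",
    "DensitometryPair",
    "hertz_force",
    "indentation_from_piezo",
    "preprocess_curve",
    "fit_hertz",
    "aggregate_stiffness",
    "dunn_test",
    "binding_fraction",
    "fit_kd",
    "solubility_fraction",
]


class PreprocessingError(ValueError):
    """No usable pre-contact region could be identified."""


class InsufficientDataError(ValueError):
    """Too few samples inside the fit window."""


@dataclass
class ForceCurve:
    """One AFM approach curve: indentation (µm) vs force (nN)."""

    indentation: np.ndarray
    force: np.ndarray
    probe_radius: float = 5.0      # µm
    poisson_ratio: float = 0.5
    spring_constant: float | None = None  # N/m, metadata only
    condition: str = ""

    def __post_init__(self) -> None:
        self.indentation = np.asarray(self.indentation, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.indentation.shape != self.force.shape:
            raise ValueError("indentation and force must have equal length")
        if self.indentation.size < 10:
            raise ValueError("force curve needs >= 10 samples")
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be > 0")
        if not (0.0 <= self.poisson_ratio < 0.5 + 1e-9):
            raise ValueError("poisson_ratio must lie in [0, 0.5]")


@dataclass(frozen=True)
class HertzFitResult:
    young_modulus: float          # MPa
    contact_point: float          # µm, relative to the preprocessed zero
    fit_force_range: tuple[float, float] = (0.5, 4.5)  # nN
    rmse: float = float("nan")    # nN
    n_points_used: int = 0
    condition: str = ""


@dataclass
class BindingSeries:
    """An MST-style titration: ligand concentration (nM) vs response."""

    ligand_conc: np.ndarray
    response: np.ndarray
    target_conc: float            # nM (labelled species, held constant)
    label: str = ""

    def __post_init__(self) -> None:
        self.ligand_conc = np.asarray(self.ligand_conc, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.ligand_conc.shape != self.response.shape:
            raise ValueError("ligand_conc and response must have equal length")
        if np.any(self.ligand_conc < 0):
            raise ValueError("ligand concentrations must be >= 0")
        if self.target_conc <= 0:
            raise ValueError("target_conc must be > 0")


@dataclass(frozen=True)
class KdFitResult:
    kd: float                     # nM
    response_scale: float
    baseline: float
    rmse: float
    well_constrained: bool = True
    label: str = ""


@dataclass(frozen=True)
class DensitometryPair:
    supernatant_intensity: float
    pellet_intensity: float

    def __post_init__(self) -> None:
        s, p = self.supernatant_intensity, self.pellet_intensity
        if s < 0 or p < 0:
            raise ValueError("band intensities must be >= 0")
        if s + p == 0:
            raise ValueError("supernatant and pellet intensities are both zero")


# --- Hertz contact mechanics -------------------------------------------------

#: nN per (MPa * sqrt(µm) * µm^1.5): 1e6 Pa * sqrt(1e-6 m) * (1e-6 m)^1.5 / 1e-9 N
_HERTZ_UNIT = 1e6 * 1e-3 * 1e-9 / 1e-9


def hertz_force(
    x: np.ndarray | float,
    young_modulus: float,
    probe_radius: float = 5.0,
    poisson_ratio: float = 0.5,
) -> np.ndarray | float:
    """Hertz spherical indentation force.

    F = 4 E sqrt(r) x^(3/2) / (3 (1 - v^2)), with x in µm, E in MPa and
    r in µm, returned in nN.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise ValueError("indentation must be >= 0")
    if young_modulus <= 0 or probe_radius <= 0:
        raise ValueError("young_modulus and probe_radius must be > 0")
    if not (0.0 <= poisson_ratio < 1.0):
        raise ValueError("poisson_ratio must lie in [0, 1)")
    f = (
        (4.0 / 3.0)
        * young_modulus
        * np.sqrt(probe_radius)
        * x_arr ** 1.5
        / (1.0 - poisson_ratio**2)
        * _HERTZ_UNIT
    )
    return float(f) if np.isscalar(x) else f


def indentation_from_piezo(
    piezo_um: np.ndarray, deflection_um: np.ndarray
) -> np.ndarray:
    """Tip-sample separation from piezo extension and cantilever deflection.

    Indentation = piezo travel minus cantilever deflection; the force is
    deflection times the spring constant, which the caller applies.
    """
    return np.asarray(piezo_um, float) - np.asarray(deflection_um, float)


def preprocess_curve(
    raw: ForceCurve, noise_k: float = 3.0, min_precontact: int = 10
) -> tuple[ForceCurve, float]:
    """Baseline-correct a raw approach curve and zero it at contact.

    The pre-contact baseline is the mean force over the flat segment
    before contact; the contact point is the first sample whose force
    exceeds the baseline by ``noise_k`` pre-contact noise SDs and stays
    above it.  Returns the corrected curve (force minus baseline,
    indentation re-zeroed at contact) and the contact position on the
    raw axis.
    """
    x, f = raw.indentation, raw.force
    n0 = max(min_precontact, x.size // 20)
    if n0 >= x.size:
        raise PreprocessingError("curve too short for baseline estimation")
    base = float(np.mean(f[:n0]))
    sd = float(np.std(f[:n0]))
    thresh = base + noise_k * max(sd, 1e-12)
    above = f > thresh
    # require the exceedance to persist (5 consecutive samples) so noise
    # excursions are not taken for contact even when the pre-contact SD
    # estimate runs low
    persist = 5
    run = above.copy()
    for k in range(1, persist):
        shifted = np.roll(above, -k)
        shifted[-k:] = True
        run &= shifted
    idx = np.flatnonzero(run)
    idx = idx[idx >= n0 // 2]
    if idx.size == 0:
        raise PreprocessingError(
            "no contact detected: force never rises above the baseline "
            f"(baseline {base:.3g} nN, threshold {thresh:.3g} nN)"
        )
    contact_i = int(idx[0])
    # refine the baseline over everything clearly before contact
    pre = slice(0, max(min_precontact, contact_i - 2))
    base = float(np.mean(f[pre]))
    contact_x = float(x[contact_i])
    # Hertz force is linear in x when raised to the 2/3 power, so the
    # contact point is refined as the abscissa intercept of a regression
    # of f^(2/3) over the early post-contact rise; the threshold crossing
    # alone is biased late because the force grows as x^(3/2).
    fc = f - base
    fmax = float(fc.max())
    lo = max(noise_k * max(sd, 1e-12), 0.02 * fmax)
    sel = (fc >= lo) & (fc <= 0.5 * fmax) & (np.arange(f.size) >= contact_i - 2)
    if sel.sum() >= 5:
        slope, intercept = np.polyfit(x[sel], fc[sel] ** (2.0 / 3.0), 1)
        if slope > 0:
            x0 = -intercept / slope
            if x[0] <= x0 <= x[contact_i]:
                contact_x = float(x0)
    corrected = replace(
        raw, indentation=x - contact_x, force=f - base
    )
    return corrected, contact_x


def _hertz_model_factory(radius: float, poisson: float):
    def model(x, young_modulus, contact_offset):
        xx = np.clip(x - contact_offset, 0.0, None)
        return hertz_force(xx, young_modulus, radius, poisson)

    return model


def fit_hertz(
    curve: ForceCurve,
    fit_force_range: tuple[float, float] = (0.5, 4.5),
    refine_contact: bool = True,
    min_points: int = 10,
) -> HertzFitResult:
    """Least-squares Hertz fit over a contact-force window.

    Fits E (and, optionally, a small contact-point refinement) to the
    samples whose force lies inside ``fit_force_range`` (nN) of a
    preprocessed curve.  Restricting the window avoids the noisy contact
    region at low force and substrate effects at high force.
    """
    fmin, fmax = fit_force_range
    mask = (curve.force >= fmin) & (curve.force <= fmax) & (curve.indentation > 0)
    n = int(mask.sum())
    if n < min_points:
        raise InsufficientDataError(
            f"only {n} samples inside the {fmin}-{fmax} nN window (need {min_points})"
        )
    x, f = curve.indentation[mask], curve.force[mask]
    model = _hertz_model_factory(curve.probe_radius, curve.poisson_ratio)
    # initial E from the closed form at the median in-window sample
    xm, fm = float(np.median(x)), float(np.median(f))
    e0 = fm / hertz_force(xm, 1.0, curve.probe_radius, curve.poisson_ratio)
    if refine_contact:
        span = float(x.max())
        popt, _ = optimize.curve_fit(
            model,
            x,
            f,
            p0=[e0, 0.0],
            bounds=([1e-12, -0.5 * span], [np.inf, 0.9 * float(x.min())]),
            maxfev=10000,
        )
        e_fit, x0 = float(popt[0]), float(popt[1])
    else:
        popt, _ = optimize.curve_fit(
            lambda xx, e: model(xx, e, 0.0), x, f, p0=[e0], maxfev=10000
        )
        e_fit, x0 = float(popt[0]), 0.0
    resid = f - model(x, e_fit, x0)
    return HertzFitResult(
        young_modulus=e_fit,
        contact_point=x0,
        fit_force_range=(fmin, fmax),
        rmse=float(np.sqrt(np.mean(resid**2))),
        n_points_used=n,
        condition=curve.condition,
    )


def dunn_test(
    groups: dict[str, np.ndarray], adjust: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's post-hoc rank comparison after a Kruskal-Wallis test.

    z_ij = (mean rank_i - mean rank_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))
    with the standard tie correction T = sum(t^3 - t) / (12 (N - 1));
    two-sided normal p values, Bonferroni-adjusted by default.
    """
    names = list(groups)
    values = np.concatenate([np.asarray(groups[g], float) for g in names])
    sizes = [len(groups[g]) for g in names]
    ranks = stats.rankdata(values)
    n_total = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks, start = {}, 0
    for g, sz in zip(names, sizes):
        mean_ranks[g] = float(np.mean(ranks[start : start + sz]))
        start += sz
    rows = []
    m = len(names) * (len(names) - 1) // 2
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            gi, gj = names[i], names[j]
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            if se == 0:
                z, p = 0.0, 1.0
            else:
                z = (mean_ranks[gi] - mean_ranks[gj]) / se
                p = 2.0 * stats.norm.sf(abs(z))
            p_adj = min(1.0, p * m) if adjust == "bonferroni" else p
            rows.append({"group1": gi, "group2": gj, "z": z, "p": p, "p_adj": p_adj})
    return pd.DataFrame(rows)


def aggregate_stiffness(
    fits: list[HertzFitResult],
) -> tuple[pd.DataFrame, dict]:
    """Per-condition stiffness summary plus nonparametric comparisons.

    Returns a (condition, mean_mpa, sd_mpa, n) table and, when more than
    one condition is present, a Kruskal-Wallis test with Dunn's pairwise
    post-hoc comparisons.
    """
    if not fits:
        raise ValueError("no fits to aggregate")
    by_cond: dict[str, list[float]] = {}
    for f in fits:
        by_cond.setdefault(f.condition, []).append(f.young_modulus)
    for cond, vals in by_cond.items():
        if len(vals) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 fits")
    summary = pd.DataFrame(
        {
            "condition": list(by_cond),
            "mean_mpa": [float(np.mean(v)) for v in by_cond.values()],
            "sd_mpa": [float(np.std(v, ddof=1)) for v in by_cond.values()],
            "n": [len(v) for v in by_cond.values()],
        }
    )
    tests: dict = {}
    if len(by_cond) > 1:
        arrays = [np.asarray(v) for v in by_cond.values()]
        h, p = stats.kruskal(*arrays)
        tests["kruskal"] = {"H": float(h), "p": float(p)}
        tests["dunn"] = dunn_test({k: np.asarray(v) for k, v in by_cond.items()})
    return summary, tests


# --- Binding isotherms -------------------------------------------------------


def binding_fraction(
    ligand: np.ndarray | float,
    kd: float,
    target_conc: float | None = None,
    model: str = "quadratic",
) -> np.ndarray | float:
    """Fraction of target bound at a given ligand concentration (1:1).

    The quadratic form is exact when the target concentration is not
    negligible relative to K_d (ligand depletion):
    f = ((T + L + Kd) - sqrt((T + L + Kd)^2 - 4 T L)) / (2 T).
    The hyperbolic form f = L / (Kd + L) applies when T << Kd.
    """
    l_arr = np.asarray(ligand, dtype=float)
    if np.any(l_arr < 0) or kd < 0:
        raise ValueError("ligand concentrations and kd must be >= 0")
    if model == "hyperbolic":
        f = l_arr / (kd + l_arr)
    elif model == "quadratic":
        if target_conc is None or target_conc <= 0:
            raise ValueError("quadratic isotherm requires target_conc > 0")
        t = target_conc
        s = t + l_arr + kd
        f = (s - np.sqrt(s**2 - 4.0 * t * l_arr)) / (2.0 * t)
    else:
        raise ValueError(f"unknown isotherm model {model!r}")
    return float(f) if np.isscalar(ligand) else f


def fit_kd(
    series: BindingSeries,
    model: str = "quadratic",
    min_points: int = 6,
) -> KdFitResult:
    """Fit a 1:1 isotherm to a titration, with free scale and baseline.

    response = baseline + scale * f(L; Kd, T).  The result is flagged as
    poorly constrained (with a warning) when the fitted K_d exceeds the
    largest ligand concentration, i.e. the titration never approaches
    saturation.
    """
    l_conc, resp = series.ligand_conc, series.response
    if l_conc.size < min_points:
        raise InsufficientDataError(
            f"titration has {l_conc.size} points (need {min_points})"
        )

    def curve(l, kd, scale, base):
        return base + scale * binding_fraction(l, kd, series.target_conc, model)

    base0 = float(np.min(resp))
    scale0 = float(np.max(resp) - base0) or 1.0
    half = base0 + 0.5 * scale0
    above = np.flatnonzero(resp >= half)
    kd0 = float(l_conc[above[0]]) if above.size else float(np.max(l_conc))
    kd0 = max(kd0, 1e-6)
    popt, _ = optimize.curve_fit(
        curve,
        l_conc,
        resp,
        p0=[kd0, scale0, base0],
        bounds=([1e-12, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    kd, scale, base = (float(v) for v in popt)
    resid = resp - curve(l_conc, kd, scale, base)
    constrained = kd <= float(np.max(l_conc))
    if not constrained:
        warnings.warn(
            f"fitted Kd ({kd:.3g} nM) exceeds the largest ligand concentration "
            f"({np.max(l_conc):.3g} nM): Kd is poorly constrained",
            stacklevel=2,
        )
    return KdFitResult(
        kd=kd,
        response_scale=scale,
        baseline=base,
        rmse=float(np.sqrt(np.mean(resid**2))),
        well_constrained=constrained,
        label=series.label,
    )


def solubility_fraction(pair: DensitometryPair) -> float:
    """Soluble percentage: 100 * S / (S + P) from band densitometry."""
    s, p = pair.supernatant_intensity, pair.pellet_intensity
    return 100.0 * s / (s + p)
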