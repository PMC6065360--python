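"""Primer-concentration calibration and EvaGreen duplex design.

With a single intercalating dye (EvaGreen) every amplicon fluoresces in the
same spectrum, so a duplex assay must separate the two single-positive
droplet populations by *intensity*.  End-point droplet intensity rises with
primer concentration along a saturating exponential

    intensity = plateau * (1 - exp(-k * [primer]))

and the rate constant follows a square law in amplicon length L, moderated
by primer efficiency E and an instrument/dye constant a:

    k = (L / (a * E))**2

Fitting four-point calibration curves per primer pair therefore yields both
a diagnostic efficiency estimate and a way to pick primer concentrations
that place the two positive populations at well-separated mean intensities
below the plateau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from lmfit import Model

from .errors import DesignInfeasibleError, FitError

#: Detector/dye constant derived empirically for the QX200 + EvaGreen setup.
DEFAULT_DETECTOR_CONSTANT = 1235.0
#: Plateau intensity (fluorescence units) used when the plateau is constrained.
DEFAULT_PLATEAU = 30000.0

__all__ = [
    "DEFAULT_DETECTOR_CONSTANT",
    "DEFAULT_PLATEAU",
    "PrimerAssay",
    "CalibrationCurve",
    "predict_intensity",
    "k_from_length",
    "efficiency_from_k",
    "curve_from_assay",
    "fit_calibration",
    "choose_duplex_concentrations",
]


@dataclass
class PrimerAssay:
    """A primer pair characterised by amplicon length and efficiency."""

    name: str
    amplicon_length_bp: float
    efficiency: float = 1.0
    detector_constant: float = DEFAULT_DETECTOR_CONSTANT

    def __post_init__(self) -> None:
        if self.amplicon_length_bp <= 0:
            raise ValueError("amplicon length must be positive")
        if self.efficiency <= 0 or self.detector_constant <= 0:
            raise ValueError("efficiency and detector constant must be positive")

    @property
    def k(self) -> float:
        return k_from_length(
            self.amplicon_length_bp, self.detector_constant, self.efficiency
        )


@dataclass
class CalibrationCurve:
    """Fitted primer-concentration -> droplet-intensity curve (through origin)."""

    plateau: float
    k: float
    source_points: list[tuple[float, float]] = field(default_factory=list)
    rss: float = 0.0

    def __post_init__(self) -> None:
        if self.plateau <= 0 or self.k <= 0:
            raise ValueError("plateau and k must be positive")


def predict_intensity(primer_conc_nm: float, curve: CalibrationCurve) -> float:
    """Mean positive-droplet intensity at a primer concentration (nM)."""
    if primer_conc_nm < 0:
        raise ValueError("primer concentration must be non-negative")
    return curve.plateau * (1.0 - math.exp(-curve.k * primer_conc_nm))


def _invert_intensity(intensity: float, curve: CalibrationCurve) -> float:
    """Primer concentration producing a target mean intensity."""
    if not 0.0 <= intensity < curve.plateau:
        raise ValueError("intensity must lie in [0, plateau)")
    return -math.log(1.0 - intensity / curve.plateau) / curve.k


def k_from_length(length_bp: float, a: float, efficiency: float) -> float:
    """Rate constant from amplicon length: ``k = (L / (a*E))**2`` (per nM)."""
    if length_bp <= 0 or a <= 0 or efficiency <= 0:
        raise ValueError("length, detector constant and efficiency must be > 0")
    return (length_bp / (a * efficiency)) ** 2


def efficiency_from_k(k: float, length_bp: float, a: float) -> float:
    """Primer efficiency implied by a fitted rate constant: ``E = L/(a*sqrt(k))``."""
    if k <= 0:
        raise ValueError("k must be positive")
    if length_bp <= 0 or a <= 0:
        raise ValueError("length and detector constant must be positive")
    return length_bp / (a * math.sqrt(k))


def curve_from_assay(
    assay: PrimerAssay, plateau: float = DEFAULT_PLATEAU
) -> CalibrationCurve:
    """Predicted calibration curve for an assay of known length/efficiency."""
    return CalibrationCurve(plateau=plateau, k=assay.k)


def _model_fn(x, plateau, k):
    return plateau * (1.0 - np.exp(-k * x))


def fit_calibration(
    points: list[tuple[float, float]],
    plateau: float | None = DEFAULT_PLATEAU,
) -> CalibrationCurve:
    """Least-squares fit of the saturating-exponential calibration curve.

    The curve is constrained through the origin.  With ``plateau`` given
    (the conventional 30,000-unit constraint) only ``k`` is fitted and a
    single point suffices — it is solved algebraically and then polished.
    With ``plateau=None`` both parameters are free and at least three
    distinct concentrations are required.

    Parameters
    ----------
    points : list of (primer concentration nM, mean positive-droplet intensity)
    plateau : float or None
        Fixed plateau intensity, or None to fit it.
    """
    pts = [(float(c), float(i)) for c, i in points]
    conc = np.array([p[0] for p in pts])
    inten = np.array([p[1] for p in pts])
    n_distinct = len(set(conc.tolist()))
    free_plateau = plateau is None
    if (not free_plateau and n_distinct < 1) or (free_plateau and n_distinct < 3):
        raise FitError("insufficient distinct concentrations for calibration fit")
    if np.all(inten <= 0):
        raise FitError("all intensities are zero or negative")
    if np.any(conc < 0):
        raise FitError("negative primer concentrations")

    plateau0 = plateau if plateau is not None else 1.1 * inten.max()
    # Algebraic k from the most informative (highest-concentration) point.
    idx = int(np.argmax(conc))
    frac = min(inten[idx] / plateau0, 0.999)
    if frac <= 0:
        raise FitError("degenerate calibration point at highest concentration")
    k0 = -math.log(1.0 - frac) / conc[idx] if conc[idx] > 0 else 1e-3

    if not free_plateau and n_distinct == 1 and len(pts) == 1:
        return CalibrationCurve(plateau=plateau0, k=k0, source_points=pts, rss=0.0)

    model = Model(_model_fn)
    params = model.make_params(plateau=plateau0, k=k0)
    params["k"].set(min=1e-12)
    params["plateau"].set(min=1e-6, vary=free_plateau)
    result = model.fit(inten, params, x=conc)
    if not result.success:
        raise FitError(f"calibration fit failed: {result.message}")
    return CalibrationCurve(
        plateau=float(result.params["plateau"].value),
        k=float(result.params["k"].value),
        source_points=pts,
        rss=float(np.sum(result.residual**2)),
    )


def choose_duplex_concentrations(
    curve_a: CalibrationCurve,
    curve_b: CalibrationCurve,
    sd_a: float,
    sd_b: float,
    separation_multiple: float = 2.0,
    conc_range: tuple[float, float] = (10.0, 500.0),
    step: float = 1.0,
) -> tuple[float, float]:
    """Pick duplex primer concentrations with minimal sufficient separation.

    Optimal separation is the *minimal* separation of the two single-positive
    mean intensities that still avoids population overlap — keeping the
    brighter single positives clear of the double-positive band.  The gap is
    required to be at least ``separation_multiple * (sd_a + sd_b)``; among
    feasible pairs the gap is minimised, with ties broken toward lower total
    primer.  A dense grid search (the objective is cheap and non-convex in
    the constrained region) is followed by an exact local refinement that
    lands the gap on the constraint boundary.

    Returns ``(conc_a, conc_b)`` in nM.
    """
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("population SDs must be positive")
    if separation_multiple < 0:
        raise ValueError("separation_multiple must be non-negative")
    lo, hi = conc_range
    if not 0 < lo < hi:
        raise ValueError("invalid concentration range")
    gap_req = separation_multiple * (sd_a + sd_b)

    grid = np.arange(lo, hi + 0.5 * step, step)
    mu_a = curve_a.plateau * (1.0 - np.exp(-curve_a.k * grid))
    mu_b = curve_b.plateau * (1.0 - np.exp(-curve_b.k * grid))

    gaps = np.abs(mu_a[:, None] - mu_b[None, :])
    feasible = gaps >= gap_req
    if not feasible.any():
        raise DesignInfeasibleError(
            f"no concentration pair in {conc_range} nM achieves a mean-intensity "
            f"gap of {gap_req:.0f} units below the plateau"
        )
    totals = grid[:, None] + grid[None, :]
    # Lexicographic: minimal gap, then minimal total primer.
    score = np.where(feasible, gaps, np.inf)
    best_gap = score.min()
    tie = np.isclose(score, best_gap)
    masked_totals = np.where(tie, totals, np.inf)
    ia, ib = np.unravel_index(int(np.argmin(masked_totals)), totals.shape)
    conc_a, conc_b = float(grid[ia]), float(grid[ib])

    if gap_req > 0:
        # Refine: fix the dimmer target's concentration and solve the
        # brighter target's concentration so the gap sits exactly on the
        # constraint boundary (lower total primer than any larger gap).
        mu_ai = predict_intensity(conc_a, curve_a)
        mu_bi = predict_intensity(conc_b, curve_b)
        try:
            if mu_ai >= mu_bi:
                target = mu_bi + gap_req
                if target < curve_a.plateau:
                    cand = _invert_intensity(target, curve_a)
                    if lo <= cand <= hi:
                        conc_a = cand
            else:
                target = mu_ai + gap_req
                if target < curve_b.plateau:
                    cand = _invert_intensity(target, curve_b)
                    if lo <= cand <= hi:
                        conc_b = cand
        except ValueError:
            pass
    return conc_a, conc_b
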