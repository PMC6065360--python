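"""Seeded generators for droplet, puncta and titration data.

Every analysis stage in this package can be exercised without instrument
exports: these generators produce duplex droplet amplitude tables with
Poisson occupancy and calibration-model intensities, per-cell nucleoid
puncta with quantal structure, and mCN titration series with pipetting and
partition-sampling noise.  All generators are bit-reproducible for a fixed
seed and return the ground truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gating import AmplitudeTable
from .poisson_core import DEFAULT_DROPLET_VOLUME_NL, DropletCounts
from .quantal import CellPuncta

__all__ = [
    "DuplexSimConfig",
    "PunctaSimConfig",
    "simulate_duplex_droplets",
    "simulate_puncta_cells",
    "simulate_titration",
]


@dataclass
class DuplexSimConfig:
    """Conditions for one simulated duplex (or singleplex) well.

    Intensity geometry emulates a QX200 EvaGreen duplex: a fail band, a
    dimmer single-positive band (target B), a brighter one (target A) and a
    double-positive band at the brighter single-positive mean plus a fixed
    increment (droplet end-point intensity is not additive across targets;
    co-amplification saturates).  Channel 2 reads the same dye through the
    HEX filter at a fixed gain.  Set ``conc_b=0`` for a singleplex well.
    """

    conc_a: float  # copies/ul of target A (brighter population)
    conc_b: float = 0.0  # copies/ul of target B
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
    n_droplets: int = 16000
    fail_mean: float = 2000.0
    fail_sd: float = 250.0
    pos_a_mean: float = 18000.0
    pos_a_sd: float = 600.0
    pos_b_mean: float = 10000.0
    pos_b_sd: float = 600.0
    double_increment: float = 6000.0
    double_sd: float = 700.0
    ch2_gain: float = 0.55
    ch2_noise_sd: float = 150.0
    rain_fraction: float = 0.0
    seed: int = 0
    well_id: str = "A01"

    def __post_init__(self) -> None:
        if self.conc_a < 0 or self.conc_b < 0:
            raise ValueError("concentrations must be non-negative")
        if not 0 <= self.rain_fraction < 1:
            raise ValueError("rain_fraction must be in [0, 1)")
        for sd in (self.fail_sd, self.pos_a_sd, self.pos_b_sd, self.double_sd):
            if sd <= 0:
                raise ValueError("population SDs must be positive")


def simulate_duplex_droplets(
    config: DuplexSimConfig,
) -> tuple[AmplitudeTable, np.ndarray, DropletCounts]:
    """Simulate one well of droplet amplitudes with known truth.

    Each droplet receives an independent Poisson number of copies of each
    target (``lambda_i = conc_i * droplet_volume``); any occupancy beyond
    one copy leaves the amplitude class unchanged (end-point saturation).
    Rain replaces a random ``rain_fraction`` of droplets with uniform
    amplitudes between the fail ceiling and the dimmest positive floor.

    Returns ``(table, truth_labels, truth_counts)`` where ``truth_labels``
    includes ``"rain"`` for rained-out droplets and ``truth_counts`` is the
    pre-rain gated tally.
    """
    rng = np.random.default_rng(config.seed)
    vd_ul = config.droplet_volume_nl * 1e-3
    n = config.n_droplets
    occ_a = rng.poisson(config.conc_a * vd_ul, n)
    occ_b = rng.poisson(config.conc_b * vd_ul, n)

    labels = np.full(n, "fail", dtype=object)
    labels[(occ_a > 0) & (occ_b == 0)] = "posA"
    labels[(occ_a == 0) & (occ_b > 0)] = "posB"
    labels[(occ_a > 0) & (occ_b > 0)] = "double"

    double_mean = max(config.pos_a_mean, config.pos_b_mean) + config.double_increment
    mean_by = {
        "fail": config.fail_mean,
        "posA": config.pos_a_mean,
        "posB": config.pos_b_mean,
        "double": double_mean,
    }
    sd_by = {
        "fail": config.fail_sd,
        "posA": config.pos_a_sd,
        "posB": config.pos_b_sd,
        "double": config.double_sd,
    }
    ch1 = np.empty(n)
    for lab in ("fail", "posA", "posB", "double"):
        mask = labels == lab
        ch1[mask] = rng.normal(mean_by[lab], sd_by[lab], int(mask.sum()))

    if config.rain_fraction > 0:
        n_rain = int(round(config.rain_fraction * n))
        idx = rng.choice(n, size=n_rain, replace=False)
        ceiling = config.fail_mean + 4.0 * config.fail_sd
        floor = (
            min(config.pos_a_mean, config.pos_b_mean if config.conc_b > 0 else np.inf)
            - 4.0 * (config.pos_b_sd if config.conc_b > 0 else config.pos_a_sd)
        )
        ch1[idx] = rng.uniform(ceiling, floor, n_rain)
        labels[idx] = "rain"

    ch2 = config.ch2_gain * ch1 + rng.normal(0.0, config.ch2_noise_sd, n)
    table = AmplitudeTable(well_id=config.well_id, ch1=ch1, ch2=ch2)

    gated = labels[labels != "rain"]
    positives = {
        lab: int(np.sum(gated == lab))
        for lab in ("posB", "posA", "double")
        if np.any(gated == lab)
    }
    counts = DropletCounts(
        well_id=config.well_id,
        n_total=int(gated.size),
        n_negative=int(np.sum(gated == "fail")),
        positives_by_target=positives,
        n_rain=int(np.sum(labels == "rain")),
    )
    return table, labels, counts


@dataclass
class PunctaSimConfig:
    """Conditions for a simulated imaging batch.

    Defaults emulate the benchmark culture batch: 36 cells averaging ~970
    genomes/cell (SD 280 between cells), nucleoids carrying 1-10 genomes
    with a truncated-geometric multiplicity (mean ~3.5 genomes/nucleoid,
    hence ~275 puncta/cell), quantal intensity 1000 with unitary SD 150.
    """

    n_cells: int = 36
    mcn_mean: float = 970.0
    mcn_sd: float = 280.0
    multiplicity_p: float = 0.24  # truncated-geometric success probability
    n_max: int = 10
    q: float = 1000.0
    sigma1: float = 150.0
    seed: int = 0
    batch_id: str = "batch1"

    def __post_init__(self) -> None:
        if self.q <= 0 or self.sigma1 < 0:
            raise ValueError("q must be positive and sigma1 non-negative")
        if not 0 < self.multiplicity_p < 1:
            raise ValueError("multiplicity_p must be in (0, 1)")
        if self.mcn_mean <= 0 or self.n_cells < 1:
            raise ValueError("need positive mean mCN and at least one cell")


def simulate_puncta_cells(
    config: PunctaSimConfig,
) -> tuple[list[CellPuncta], dict[str, int]]:
    """Simulate per-cell puncta intensities with known genome counts.

    Each cell draws a target genome count from a truncated normal, then
    accumulates nucleoid multiplicities (truncated geometric on
    ``1..n_max``) until the running total reaches the target; the realised
    total is the cell's true mCN.  A punctum of multiplicity n has intensity
    ``Normal(n*q, sigma1*sqrt(n))``, floored just above zero.

    Returns ``(cells, true_mcn)`` with ``true_mcn[cell_id]`` equal to the
    sum of that cell's multiplicities.
    """
    rng = np.random.default_rng(config.seed)
    support = np.arange(1, config.n_max + 1)
    pmf = config.multiplicity_p * (1.0 - config.multiplicity_p) ** (support - 1)
    pmf /= pmf.sum()

    cells: list[CellPuncta] = []
    truth: dict[str, int] = {}
    for i in range(config.n_cells):
        target = max(1.0, rng.normal(config.mcn_mean, config.mcn_sd))
        mults: list[int] = []
        total = 0
        while total < target:
            m = int(rng.choice(support, p=pmf))
            mults.append(m)
            total += m
        mult_arr = np.array(mults)
        noise = rng.normal(0.0, 1.0, mult_arr.size)
        intensities = mult_arr * config.q + config.sigma1 * np.sqrt(mult_arr) * noise
        intensities = np.maximum(intensities, 1e-9)
        cell_id = f"{config.batch_id}-cell{i:03d}"
        cells.append(
            CellPuncta(cell_id=cell_id, batch_id=config.batch_id,
                       intensities=intensities)
        )
        truth[cell_id] = total
    return cells, truth


def simulate_titration(
    base_ratio: float,
    depleted_ratio: float,
    fractions: "list[float] | np.ndarray",
    pipetting_cv: float = 0.02,
    replicates: int = 4,
    seed: int = 0,
    denom_conc: float | None = None,
    n_droplets: int = 16000,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
) -> dict[float, np.ndarray]:
    """Simulate an mCN depletion titration measured as a target ratio.

    A depleted DNA stock is mixed into the untreated stock at each fraction
    ``f``, so the expected ratio interpolates linearly:
    ``(1-f)*base_ratio + f*depleted_ratio``.  Each technical replicate is
    perturbed by multiplicative pipetting noise (CV ``pipetting_cv`` on the
    mixing step).  If ``denom_conc`` is given, droplet-partition sampling
    noise is added by simulating binomial negative-droplet counts for both
    targets at that reference concentration and re-estimating the ratio;
    with ``denom_conc=None`` (default) partition noise is omitted, the
    merged-well regime in which pipetting dominates the replicate variance.

    Returns ``{fraction: array of replicate ratios}``.
    """
    if replicates < 2:
        raise ValueError("need at least two replicates")
    if pipetting_cv < 0:
        raise ValueError("pipetting_cv must be non-negative")
    fractions = np.asarray(fractions, dtype=float)
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("fractions must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    vd_ul = droplet_volume_nl * 1e-3
    out: dict[float, np.ndarray] = {}
    for f in fractions:
        expected = (1.0 - f) * base_ratio + f * depleted_ratio
        ratios = np.empty(replicates)
        for r in range(replicates):
            value = expected * (1.0 + pipetting_cv * rng.standard_normal())
            if denom_conc is not None:
                # value is a ratio; numerator concentration = ratio * denom.
                lam_den = denom_conc * vd_ul
                lam_num = denom_conc * max(value, 0.0) * vd_ul
                neg_den = rng.binomial(n_droplets, np.exp(-lam_den))
                neg_num = rng.binomial(n_droplets, np.exp(-lam_num))
                neg_den = max(neg_den, 1)
                neg_num = max(neg_num, 1)
                lam_den_hat = -np.log(neg_den / n_droplets)
                lam_num_hat = -np.log(neg_num / n_droplets)
                value = lam_num_hat / lam_den_hat if lam_den_hat > 0 else np.nan
            ratios[r] = value
        out[float(f)] = ratios
    return out
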