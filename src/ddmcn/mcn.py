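"""Mitochondrial copy-number arithmetic and sensitivity statistics.

The central quantity is mitochondrial genome copies per cell:

    mCN = (mt copies/ul) / (reference copies/ul) * ploidy * (1 + pseudogenes)

i.e. the measured mt:reference concentration ratio scaled by nuclear genomes
per cell and by the reference's per-genome copy number.  A reference locus
amplifying N targets per genome (gene + N-1 pseudogenes) runs at N-fold the
concentration of a single-copy locus, which both tightens the denominator's
coefficient of variation and extends the usable dynamic range.

Also here: inference of a reference's per-genome copy number from its ratio
to a known single-copy assay, deletion heteroplasmy from length-normalised
gel band intensities, and the one-way ANOVA + Scheffe post-hoc machinery
used to ask which mCN depletion levels a titration can statistically
distinguish.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AmbiguousCopyNumberError
from .poisson_core import RatioEstimate

__all__ = [
    "MCNResult",
    "mcn_per_cell",
    "mcn_from_ratio",
    "infer_reference_copy_number",
    "heteroplasmy_from_bands",
    "depletion_detection",
]


@dataclass
class MCNResult:
    """Copies of mitochondrial genome per cell with provenance."""

    mcn: float
    mt_ref_ratio: float
    pseudogene_count: int
    ploidy: int
    ci_low: float = float("nan")
    ci_high: float = float("nan")


def mcn_per_cell(
    mt_ref_ratio: float,
    pseudogene_count: int = 0,
    ploidy: int = 2,
    ratio_ci: tuple[float, float] | None = None,
) -> MCNResult:
    """Copies per cell from an mt:reference concentration ratio.

    ``mcn = ratio * ploidy * (1 + pseudogene_count)``.  A supplied ratio CI
    is scaled by the same constant.  For the A7r5 benchmark, an mt:EIF2C1
    ratio of 400 with a single-copy diploid reference gives 800 copies/cell;
    the same sample read against beta-actin (ratio 135, two pseudogenes)
    gives 810.
    """
    if mt_ref_ratio < 0:
        raise ValueError("ratio must be non-negative")
    if ploidy < 1 or pseudogene_count < 0:
        raise ValueError("ploidy must be >= 1 and pseudogene_count >= 0")
    scale = ploidy * (1 + pseudogene_count)
    ci_low = ci_high = float("nan")
    if ratio_ci is not None:
        ci_low, ci_high = ratio_ci[0] * scale, ratio_ci[1] * scale
    return MCNResult(
        mcn=mt_ref_ratio * scale,
        mt_ref_ratio=mt_ref_ratio,
        pseudogene_count=pseudogene_count,
        ploidy=ploidy,
        ci_low=ci_low,
        ci_high=ci_high,
    )


def mcn_from_ratio(
    ratio: RatioEstimate, pseudogene_count: int = 0, ploidy: int = 2
) -> MCNResult:
    """Convenience wrapper taking a :class:`RatioEstimate`."""
    return mcn_per_cell(
        ratio.ratio,
        pseudogene_count=pseudogene_count,
        ploidy=ploidy,
        ratio_ci=(ratio.ci_low, ratio.ci_high),
    )


def infer_reference_copy_number(
    multi_to_single_ratio: float, tolerance: float = 0.2
) -> tuple[int, int]:
    """Per-genome copy number of a reference from its ratio to a single-copy assay.

    ddPCR's absolute concentrations make this a division: a candidate
    reference run against a validated single-copy locus should give an
    integer ratio (beta-actin : EIF2C1 of 3.0 implies three targets per
    genome, i.e. two pseudogenes).  Returns
    ``(copies_per_genome, pseudogene_count)``.

    Raises
    ------
    AmbiguousCopyNumberError
        If the ratio is farther than ``tolerance`` from any positive integer.
    """
    if multi_to_single_ratio <= 0:
        raise ValueError("ratio must be positive")
    nearest = max(1, round(multi_to_single_ratio))
    if abs(multi_to_single_ratio - nearest) > tolerance:
        raise AmbiguousCopyNumberError(
            f"ratio {multi_to_single_ratio:.3f} is not within {tolerance} "
            f"of an integer copy number"
        )
    return nearest, nearest - 1


def heteroplasmy_from_bands(
    i_del: float, len_del: float, i_full: float, len_full: float
) -> float:
    """Deletion heteroplasmy from end-point PCR gel band fluorescence.

    Intercalating-dye band intensity scales with both molarity and amplicon
    length, so each band is length-normalised before taking the molar
    fraction: ``(i_del/len_del) / (i_del/len_del + i_full/len_full)``.
    """
    if i_del < 0 or i_full < 0:
        raise ValueError("band intensities must be non-negative")
    if len_del <= 0 or len_full <= 0:
        raise ValueError("amplicon lengths must be positive")
    if i_del == 0 and i_full == 0:
        raise ValueError("both band intensities are zero")
    m_del = i_del / len_del
    m_full = i_full / len_full
    return m_del / (m_del + m_full)


def depletion_detection(
    groups: dict[object, "np.ndarray | list[float]"], alpha: float = 0.05
) -> pd.DataFrame:
    """Which pairs of depletion levels are statistically distinguishable.

    One-way ANOVA across all groups followed by Scheffe pairwise contrasts
    at group-wise level ``alpha``: pair (i, j) is detected when

        (mean_i - mean_j)^2 / (MSE * (1/n_i + 1/n_j)) > (k-1) * F_crit

    with ``F_crit`` the upper-``alpha`` quantile of F(k-1, N-k).  Scheffe
    controls the family-wise error over *all* contrasts, so it is
    conservative for many groups.  Groups are assumed homoscedastic.

    Returns a symmetric boolean DataFrame (detected / not) indexed by group
    label, with the overall F statistic and p-value in ``df.attrs``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    labels = list(groups.keys())
    data = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(v.size < 2 for v in data.values()):
        raise ValueError("every group needs at least two replicates")

    k = len(labels)
    ns = {g: data[g].size for g in labels}
    n_total = sum(ns.values())
    means = {g: data[g].mean() for g in labels}
    sse = sum(float(np.sum((data[g] - means[g]) ** 2)) for g in labels)
    df_err = n_total - k
    mse = sse / df_err
    f_stat, p_value = stats.f_oneway(*(data[g] for g in labels))
    f_crit = stats.f.ppf(1.0 - alpha, k - 1, df_err)
    scheffe_crit = (k - 1) * f_crit

    detected = pd.DataFrame(False, index=labels, columns=labels, dtype=bool)
    for i, gi in enumerate(labels):
        for gj in labels[i + 1 :]:
            if mse == 0:
                hit = means[gi] != means[gj]
            else:
                t2 = (means[gi] - means[gj]) ** 2 / (
                    mse * (1.0 / ns[gi] + 1.0 / ns[gj])
                )
                hit = bool(t2 > scheffe_crit)
            detected.loc[gi, gj] = detected.loc[gj, gi] = hit
    detected.attrs["f_statistic"] = float(f_stat)
    detected.attrs["p_value"] = float(p_value)
    detected.attrs["alpha"] = alpha
    detected.attrs["scheffe_critical"] = float(scheffe_crit)
    return detected
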