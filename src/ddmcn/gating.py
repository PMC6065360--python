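"""Droplet amplitude gating: clustering, manual thresholds and rain.

EvaGreen droplets form discrete intensity bands — fails (no template), one
band per single-positive target and, in duplex wells, a double-positive
band.  QuantaSoft exports per-droplet amplitudes in two channels (the FAM
and HEX filter sets see the same dye), and gating assigns each droplet to a
population.  This module automates that step with a seeded Gaussian-mixture
clustering, supports explicit 1-D threshold gates, and quantifies "rain":
droplets of intermediate intensity (typically partial amplification) that
fall between the fail ceiling and the lowest positive gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .errors import EmptyWellError, GateConfigError
from .poisson_core import DropletCounts

__all__ = [
    "AmplitudeTable",
    "GateSet",
    "POPULATION_ORDER",
    "cluster_droplets",
    "apply_manual_gates",
    "rain_metric",
]

#: Population labels from dimmest to brightest.
POPULATION_ORDER = ("fail", "posB", "posA", "double")


@dataclass
class AmplitudeTable:
    """Per-droplet fluorescence amplitudes for one well."""

    well_id: str
    ch1: np.ndarray
    ch2: np.ndarray
    cluster: np.ndarray | None = None  # optional prior assignments

    def __post_init__(self) -> None:
        self.ch1 = np.asarray(self.ch1, dtype=float)
        self.ch2 = np.asarray(self.ch2, dtype=float)
        if self.ch1.shape != self.ch2.shape or self.ch1.ndim != 1:
            raise ValueError("ch1 and ch2 must be 1-D arrays of equal length")
        if not (np.isfinite(self.ch1).all() and np.isfinite(self.ch2).all()):
            raise ValueError("amplitudes must be finite")

    def __len__(self) -> int:
        return self.ch1.size


@dataclass
class GateSet:
    """Gate definitions for one well.

    ``thresholds`` maps population labels to half-open ch1 intervals
    ``(lo, hi)``; populations must not overlap.  ``mode`` records whether
    the intervals came from explicit thresholds or were summarised from a
    mixture-model clustering (for audit and for the rain metric).
    """

    mode: str  # "thresholds" | "clusters"
    thresholds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ivs = sorted(self.thresholds.items(), key=lambda kv: kv[1][0])
        for (la, (lo_a, hi_a)), (lb, (lo_b, hi_b)) in zip(ivs, ivs[1:]):
            if hi_a > lo_b:
                raise GateConfigError(
                    f"gates {la!r} and {lb!r} overlap ({hi_a} > {lo_b})"
                )
        for label, (lo, hi) in self.thresholds.items():
            if not lo < hi:
                raise GateConfigError(f"gate {label!r} has non-positive width")

    def assign(self, ch1: np.ndarray) -> np.ndarray:
        """Label each droplet by gate, or 'rain' if outside every gate."""
        labels = np.full(ch1.shape, "rain", dtype=object)
        for label, (lo, hi) in self.thresholds.items():
            labels[(ch1 >= lo) & (ch1 < hi)] = label
        return labels


def _counts_from_labels(
    well_id: str, labels: np.ndarray, rain_to: str = "exclude"
) -> DropletCounts:
    n_rain = int(np.sum(labels == "rain"))
    n_fail = int(np.sum(labels == "fail"))
    positives = {
        lab: int(np.sum(labels == lab))
        for lab in POPULATION_ORDER[1:]
        if np.any(labels == lab)
    }
    if rain_to == "negative":
        n_fail += n_rain
        n_rain = 0
    elif rain_to != "exclude":
        raise ValueError("rain_to must be 'exclude' or 'negative'")
    n_total = n_fail + sum(positives.values())
    return DropletCounts(
        well_id=well_id,
        n_total=n_total,
        n_negative=n_fail,
        positives_by_target=positives,
        n_rain=n_rain,
    )


def _gap_segments(ch1: np.ndarray, n_populations: int) -> list[np.ndarray]:
    """Split droplets into bands at the ``n_populations - 1`` largest gaps."""
    order = np.argsort(ch1)
    sorted_vals = ch1[order]
    diffs = np.diff(sorted_vals)
    cut_positions = np.sort(np.argsort(diffs)[-(n_populations - 1):])
    segments = []
    start = 0
    for cut in cut_positions:
        segments.append(order[start : cut + 1])
        start = cut + 1
    segments.append(order[start:])
    return segments


def cluster_droplets(
    table: AmplitudeTable,
    n_populations: int,
    seed: int = 0,
    rain_to: str = "exclude",
    gate_halfwidth_sd: float = 5.0,
) -> tuple[GateSet, DropletCounts]:
    """Model-based gating of a well into 2-4 droplet populations.

    Fits a seeded Gaussian mixture in (ch1, ch2), with component means
    initialised at the bands delimited by the largest amplitude gaps — ddPCR
    populations are wildly unequal in size (a low-concentration reference
    band may hold tens of droplets against tens of thousands of positives),
    and an uninformed mixture fit tends to split the dominant band rather
    than find the sparse one.  Components are ordered by mean intensity and
    labelled (dimmest to brightest) from ``fail < posB < posA < double``
    according to ``n_populations``.

    The returned :class:`GateSet` summarises each population as a ch1
    interval of +/- ``gate_halfwidth_sd`` component SDs truncated at
    midpoints between neighbouring means; counts are derived from those
    intervals, so droplets falling between gates are handled as rain exactly
    as under :func:`apply_manual_gates`.  Deterministic for a fixed seed.
    """
    if not 2 <= n_populations <= 4:
        raise ValueError("n_populations must be in 2..4")
    if len(table) == 0:
        raise EmptyWellError(f"well {table.well_id} has no droplets")
    if len(table) < 10 * n_populations:
        raise ValueError("too few droplets for reliable clustering")

    X = np.column_stack([table.ch1, table.ch2])
    if np.allclose(X, X[0]):
        warnings.warn(
            f"well {table.well_id}: all amplitudes identical; "
            "falling back to a single population",
            stacklevel=2,
        )
        labels = np.full(len(table), "fail", dtype=object)
        lo, hi = table.ch1[0] - 1.0, table.ch1[0] + 1.0
        gates = GateSet(mode="clusters", thresholds={"fail": (lo, hi)})
        return gates, _counts_from_labels(table.well_id, labels, rain_to)

    means_init = np.array(
        [X[seg].mean(axis=0) for seg in _gap_segments(table.ch1, n_populations)]
    )
    gmm = GaussianMixture(
        n_components=n_populations,
        covariance_type="diag",
        random_state=seed,
        means_init=means_init,
    )
    gmm.fit(X)
    order = np.argsort(gmm.means_.sum(axis=1))
    if n_populations == 2:
        label_names = ("fail", "posA")
    elif n_populations == 3:
        label_names = ("fail", "posB", "posA")
    else:
        label_names = POPULATION_ORDER

    # 1-D interval summary per population, clipped at midpoints between
    # neighbouring means; degenerate (zero-width) populations are dropped.
    means = gmm.means_[order, 0]
    sds = np.sqrt(gmm.covariances_[order, 0])
    thresholds: dict[str, tuple[float, float]] = {}
    for r, name in enumerate(label_names):
        lo = means[r] - gate_halfwidth_sd * sds[r]
        hi = means[r] + gate_halfwidth_sd * sds[r]
        if r > 0:
            lo = max(lo, 0.5 * (means[r - 1] + means[r]))
        if r < len(label_names) - 1:
            hi = min(hi, 0.5 * (means[r] + means[r + 1]))
        if hi > lo:
            thresholds[name] = (float(lo), float(hi))
    gates = GateSet(mode="clusters", thresholds=thresholds)
    labels = gates.assign(table.ch1)
    return gates, _counts_from_labels(table.well_id, labels, rain_to)


def apply_manual_gates(
    table: AmplitudeTable, gates: GateSet, rain_to: str = "exclude"
) -> DropletCounts:
    """Count droplets per population under explicit gates.

    Droplets outside every gate are counted as rain; by default they are
    excluded from both the negative and positive tallies (conservative),
    or folded into the negatives with ``rain_to='negative'``.
    """
    if len(table) == 0:
        raise EmptyWellError(f"well {table.well_id} has no droplets")
    labels = gates.assign(table.ch1)
    return _counts_from_labels(table.well_id, labels, rain_to)


def rain_metric(table: AmplitudeTable, gates: GateSet) -> float:
    """Fraction of droplets between the fail ceiling and lowest positive floor."""
    if len(table) == 0:
        raise EmptyWellError(f"well {table.well_id} has no droplets")
    if "fail" not in gates.thresholds:
        raise GateConfigError("gates must include a 'fail' population")
    fail_hi = gates.thresholds["fail"][1]
    pos_lows = [lo for lab, (lo, _) in gates.thresholds.items() if lab != "fail"]
    if not pos_lows:
        return 0.0
    floor = min(pos_lows)
    if floor <= fail_hi:
        return 0.0
    in_band = (table.ch1 >= fail_hi) & (table.ch1 < floor)
    return float(np.mean(in_band))
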