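"""File readers/writers, run configuration and the end-to-end pipeline.

Amplitude input follows the QuantaSoft CSV export dialect ("Ch1 Amplitude",
"Ch2 Amplitude", optional "Cluster" and "Well" columns; the well falls back
to the file name).  All result tables are tidy long-format CSV (one row per
well x target) and carry the configuration hash so reruns are auditable.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gating, mcn as mcn_mod, poisson_core, synthetic_data
from .gating import AmplitudeTable

logger = logging.getLogger("ddmcn")

__all__ = [
    "RunConfig",
    "read_amplitude_csv",
    "write_amplitude_csv",
    "read_counts_csv",
    "estimates_to_frame",
    "run_pipeline",
]

CH1 = "Ch1 Amplitude"
CH2 = "Ch2 Amplitude"


def read_amplitude_csv(path: "str | Path") -> dict[str, AmplitudeTable]:
    """Read a QuantaSoft-style amplitude CSV into per-well tables.

    Requires "Ch1 Amplitude" and "Ch2 Amplitude" columns; a "Cluster"
    column, if present, is preserved as prior assignments.  Wells come from
    a "Well" column or, failing that, the file stem.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no droplet rows")
    for col in (CH1, CH2):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"{path}: column {col!r} is not numeric")
    well_col = df["Well"] if "Well" in df.columns else pd.Series([path.stem] * len(df))
    tables: dict[str, AmplitudeTable] = {}
    for well, sub in df.groupby(well_col, sort=True):
        cluster = sub["Cluster"].to_numpy() if "Cluster" in sub.columns else None
        tables[str(well)] = AmplitudeTable(
            well_id=str(well),
            ch1=sub[CH1].to_numpy(float),
            ch2=sub[CH2].to_numpy(float),
            cluster=cluster,
        )
    logger.info("read %d droplets in %d wells from %s", len(df), len(tables), path)
    return tables


def write_amplitude_csv(path: "str | Path", tables: dict[str, AmplitudeTable]) -> None:
    """Write per-well amplitude tables in the same dialect the reader consumes."""
    frames = []
    for well, t in tables.items():
        frame = pd.DataFrame({"Well": well, CH1: t.ch1, CH2: t.ch2})
        if t.cluster is not None:
            frame["Cluster"] = t.cluster
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_counts_csv(path: "str | Path") -> list[poisson_core.DropletCounts]:
    """Read pre-gated per-well counts (well, target columns, n_total, n_negative)."""
    df = pd.read_csv(path)
    required = {"well", "n_total", "n_negative"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    pos_cols = [c for c in df.columns if c not in required]
    out = []
    for _, row in df.iterrows():
        positives = {c: int(row[c]) for c in pos_cols if not pd.isna(row[c])}
        out.append(
            poisson_core.DropletCounts(
                well_id=str(row["well"]),
                n_total=int(row["n_total"]),
                n_negative=int(row["n_negative"]),
                positives_by_target=positives,
            )
        )
    return out


def estimates_to_frame(estimates: list[poisson_core.PoissonEstimate]) -> pd.DataFrame:
    """Tidy results table: one row per well x target."""
    return pd.DataFrame(
        [
            {
                "well": e.well_id,
                "target": e.target,
                "lambda": e.lam,
                "concentration": e.concentration,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "n_total": e.n_total,
                "n_negative": e.n_negative,
                "saturated": e.saturated,
            }
            for e in estimates
        ]
    )


@dataclass
class RunConfig:
    """Configuration for an end-to-end simulate/gate/quantify/mcn run."""

    # input: either an amplitude CSV or simulation settings
    amplitude_csv: str | None = None
    simulate: bool = False
    conc_a: float = 2700.0
    conc_b: float = 20.0
    n_droplets: int = 16000
    n_wells: int = 3
    # analysis parameters
    droplet_volume_nl: float = poisson_core.DEFAULT_DROPLET_VOLUME_NL
    confidence: float = 0.95
    dilution_factor: float = 1.0
    n_populations: int = 4
    ploidy: int = 2
    pseudogene_count: int = 0
    seed: int = 0
    out_dir: str = "results"

    def to_yaml(self, path: "str | Path") -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    @property
    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (output location excluded)."""
        settings = asdict(self)
        settings.pop("out_dir")
        canonical = yaml.safe_dump(settings, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]

    def validate(self) -> None:
        if self.droplet_volume_nl <= 0:
            raise ValueError("droplet volume must be positive")
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must be in (0, 1)")
        if self.ploidy < 1 or self.pseudogene_count < 0:
            raise ValueError("invalid ploidy/pseudogene settings")
        if not self.simulate and self.amplitude_csv is None:
            raise ValueError("either simulate=True or an amplitude CSV is required")


def run_pipeline(config: RunConfig) -> dict:
    """Gate -> quantify -> ratio -> mCN over simulated or file input.

    Returns a bundle with the per-well estimate table, the per-well mCN
    table and the gate sets, and writes both tables (stamped with the
    config hash) plus the resolved configuration into ``config.out_dir``.
    Deterministic for a fixed config and seed.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        tables = {}
        for w in range(config.n_wells):
            sim = synthetic_data.DuplexSimConfig(
                conc_a=config.conc_a,
                conc_b=config.conc_b,
                droplet_volume_nl=config.droplet_volume_nl,
                n_droplets=config.n_droplets,
                seed=config.seed + w,
                well_id=f"S{w + 1:02d}",
            )
            tables[sim.well_id], _, _ = synthetic_data.simulate_duplex_droplets(sim)
    else:
        tables = read_amplitude_csv(config.amplitude_csv)

    if not tables:
        logger.warning("no wells to process; nothing to do")
        return {"estimates": pd.DataFrame(), "mcn": pd.DataFrame(), "gates": {}}

    estimates: list[poisson_core.PoissonEstimate] = []
    mcn_rows = []
    gate_sets: dict[str, gating.GateSet] = {}
    for well_id in sorted(tables):
        table = tables[well_id]
        try:
            gates, counts = gating.cluster_droplets(
                table, config.n_populations, seed=config.seed
            )
        except Exception as exc:  # noqa: BLE001 - annotate stage/well and re-raise
            raise RuntimeError(f"gating failed for well {well_id}: {exc}") from exc
        gate_sets[well_id] = gates
        logger.info(
            "well %s: gated %d droplets (gates: %s)",
            well_id,
            counts.n_total,
            {k: tuple(round(v, 1) for v in iv) for k, iv in gates.thresholds.items()},
        )
        per_target = {}
        for target in ("posA", "posB"):
            if target not in counts.positives_by_target:
                continue
            est = poisson_core.quantify(
                counts.negatives_for_target(target),
                counts.n_total,
                droplet_volume_nl=config.droplet_volume_nl,
                confidence=config.confidence,
                dilution_factor=config.dilution_factor,
                target=target,
                well_id=well_id,
            )
            estimates.append(est)
            per_target[target] = est
        if "posA" in per_target and "posB" in per_target:
            ratio = poisson_core.ratio_estimate(
                per_target["posA"], per_target["posB"]
            )
            result = mcn_mod.mcn_from_ratio(
                ratio,
                pseudogene_count=config.pseudogene_count,
                ploidy=config.ploidy,
            )
            mcn_rows.append(
                {
                    "well": well_id,
                    "ratio": ratio.ratio,
                    "pseudogene_count": result.pseudogene_count,
                    "ploidy": result.ploidy,
                    "mcn": result.mcn,
                    "ci_low": result.ci_low,
                    "ci_high": result.ci_high,
                }
            )

    est_frame = estimates_to_frame(estimates)
    mcn_frame = pd.DataFrame(mcn_rows)
    for frame in (est_frame, mcn_frame):
        if not frame.empty:
            frame["config_hash"] = config.config_hash
    est_frame.to_csv(out_dir / "estimates.csv", index=False)
    mcn_frame.to_csv(out_dir / "mcn.csv", index=False)
    config.to_yaml(out_dir / "config.yaml")
    return {"estimates": est_frame, "mcn": mcn_frame, "gates": gate_sets}
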