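"""End-to-end study orchestration: synthesize inputs, backtrack, cluster, test, report.

``run_study`` mirrors the field study's workflow: one 100-particle, 365-day
backtrack per collection date from the beach launch point; reduction to
trajectory metrics; K-means partition into sub-origins A/B; the
date-nested PERMANOVA of morphotype composition between sub-origins with a
dispersion check; box-averaged SST/chl at origins and midpoints with the
two-factor environmental PERMANOVA; and a forward-dispersal experiment from
the bloom-region box.  Every random stage draws its seed deterministically
from the global seed, so a rerun with the same config reproduces the report
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field, replace
from datetime import date as _date
from pathlib import Path

import numpy as np
import pandas as pd

from . import compstats, envstats, origins
from .currents import VelocityGrid, WindGrid
from .synthetic_data import (
    CompositionParams,
    FieldConfig,
    RegimeCalendar,
    generate_current_field,
    generate_env_fields,
    generate_morphotype_samples,
    samples_to_dataframe,
)
from .tracker import TrackConfig, backtrack_sample, forward_dispersal

__all__ = ["StudyConfig", "StudyReport", "run_study", "default_collection_dates"]


def default_collection_dates(year: int = 2021) -> list[_date]:
    """Two collection dates per month over one synthetic year (24 total).

    Dates default to the 10th and 24th; in March and August — the weeks when
    the circulation hands over between pathways and a launch has genuinely
    mixed provenance — sampling falls later in the month, mirroring the
    opportunistic scheduling of beach sampling around transition periods.
    """
    days = {m: (10, 24) for m in range(1, 13)}
    days[3] = (20, 27)
    days[8] = (24, 29)
    return [_date(year, m, d) for m in range(1, 13) for d in days[m]]


@dataclass(frozen=True)
class StudyConfig:
    """Complete configuration of one synthetic (or file-driven) study."""

    field: FieldConfig = FieldConfig()
    calendar: RegimeCalendar = RegimeCalendar()
    composition: CompositionParams = CompositionParams()
    track: TrackConfig = TrackConfig()
    collection_dates: tuple = tuple(default_collection_dates())
    launch_lon: float = -59.56345
    launch_lat: float = 13.26802
    n_perm: int = 9999
    dispersal_box: tuple = (-45.6, -35.6, -1.0, 3.0)
    dispersal_particles: int = 200
    seed: int = 0
    # optional file inputs overriding the synthetic generators
    currents_path: str | None = None
    wind_path: str | None = None
    env_path: str | None = None
    samples_path: str | None = None

    def __post_init__(self) -> None:
        if len(self.collection_dates) == 0:
            raise ValueError("study needs at least one collection date")

    def seed_for(self, stage: str) -> int:
        """Stable per-stage seed derived from the global seed (< 2^31)."""
        return zlib.crc32(f"{self.seed}:{stage}".encode()) & 0x7FFFFFFF

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(dataclasses.asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, _date):
        return obj.isoformat()
    return obj


@dataclass
class StudyReport:
    """All per-date and study-level results plus a provenance block."""

    metrics: pd.DataFrame
    labels: dict
    planted_regime: dict
    monthly_composition: pd.DataFrame
    composition_permanova: object
    dispersion: object
    env_records: pd.DataFrame
    env_permanova: object
    sst_pooled_mean: dict
    dispersal_fraction_at_end: float
    dispersal_day_below_10pct: int | None
    provenance: dict

    @property
    def regime_recovery(self) -> float:
        """Fraction of dates whose K-means pathway label matches the planted regime."""
        hits = [self.labels[s] == self.planted_regime[s] for s in self.labels]
        return float(np.mean(hits))

    def to_dict(self) -> dict:
        return _jsonable(
            {
                "metrics": self.metrics.to_dict(orient="records"),
                "labels": self.labels,
                "planted_regime": self.planted_regime,
                "regime_recovery": self.regime_recovery,
                "monthly_composition": {str(k): list(v) for k, v in self.monthly_composition.iterrows()},
                "composition_permanova": self.composition_permanova.to_dict(),
                "dispersion": vars(self.dispersion),
                "env_permanova": self.env_permanova.to_dict(),
                "sst_pooled_mean": self.sst_pooled_mean,
                "dispersal_fraction_at_end": self.dispersal_fraction_at_end,
                "dispersal_day_below_10pct": self.dispersal_day_below_10pct,
                "provenance": self.provenance,
            }
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def run_study(config: StudyConfig, outdir=None, backtracks_out: list | None = None) -> StudyReport:
    """Execute the full study; see module docstring.

    ``backtracks_out``, if given, collects the per-date BacktrackResult
    objects for reuse by the caller.  With ``outdir`` the intermediate
    artifacts (grids, samples, metrics, report) are written there.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- inputs ---------------------------------------------------------
    if config.currents_path:
        currents = VelocityGrid.from_netcdf(config.currents_path)
        wind = WindGrid.from_netcdf(config.wind_path) if config.wind_path else None
    else:
        fcfg = replace(config.field, seed=config.seed_for("field"))
        currents, wind = generate_current_field(fcfg, config.calendar)

    if config.samples_path:
        df = pd.read_csv(config.samples_path, parse_dates=["date"])
        df["date"] = df["date"].dt.date
        samples = df
    else:
        samples = samples_to_dataframe(
            generate_morphotype_samples(
                config.collection_dates, config.calendar, config.composition, config.seed_for("samples")
            )
        )

    # --- backtracking and sub-origins -----------------------------------
    results = []
    for date in config.collection_dates:
        cfg = replace(config.track, seed=config.seed_for(f"track:{date.isoformat()}"), direction="backward")
        res = backtrack_sample(
            config.launch_lon, config.launch_lat, date, currents, wind, cfg, simulation_id=date.isoformat()
        )
        results.append(res)
    if backtracks_out is not None:
        backtracks_out.extend(results)

    metrics = [origins.compute_track_metrics(r) for r in results]
    assignment = origins.partition_kmeans(metrics, k=2, seed=config.seed_for("kmeans"))
    assignment = origins.label_suborigins(assignment, metrics)
    planted = {d.isoformat(): config.calendar.regime_of_date(d) for d in config.collection_dates}

    # --- morphotype composition between sub-origins ----------------------
    comp = compstats.compositions_from_samples(samples)
    date_key = comp["date"].astype(str).to_numpy()
    suborigin = np.array([assignment.labels[d] for d in date_key])
    response = compstats.ilr_bivariate(comp[["p_sni", "p_snviii", "p_sfiii"]].to_numpy())
    comp_test = compstats.permanova_nested(
        response, suborigin, date_key, n_perm=config.n_perm, seed=config.seed_for("permanova")
    )
    disp = compstats.dispersion_homogeneity(
        response, suborigin, n_perm=min(config.n_perm, 999), seed=config.seed_for("betadisper")
    )
    monthly = compstats.aggregate_date_then_month(samples)

    # --- environmental conditions ----------------------------------------
    if config.env_path:
        env = envstats.EnvGrid.from_netcdf(config.env_path)
    else:
        env = generate_env_fields(config.field, config.seed_for("env"))
    env_records = envstats.extract_env_records(results, assignment, env)
    env_test = envstats.env_permanova(env_records, n_perm=config.n_perm, seed=config.seed_for("env-permanova"))
    pooled = env_records.dropna(subset=["sst_mean"]).groupby("suborigin")["sst_mean"].mean()
    sst_pooled = {k: float(v) for k, v in pooled.items()}

    # --- forward dispersal ------------------------------------------------
    disp_cfg = replace(config.track, seed=config.seed_for("dispersal"))
    retention = forward_dispersal(
        config.dispersal_box, config.dispersal_particles, config.track.horizon_days, currents, wind, disp_cfg
    )

    import sargasso

    report = StudyReport(
        metrics=origins.metrics_to_dataframe(metrics),
        labels=dict(assignment.labels),
        planted_regime=planted,
        monthly_composition=monthly,
        composition_permanova=comp_test,
        dispersion=disp,
        env_records=env_records,
        env_permanova=env_test,
        sst_pooled_mean=sst_pooled,
        dispersal_fraction_at_end=float(retention.fraction[-1]),
        dispersal_day_below_10pct=retention.first_day_below(0.1),
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "versions": {"sargasso": sargasso.__version__, "numpy": np.__version__, "pandas": pd.__version__},
        },
    )

    if out is not None:
        currents.to_netcdf(out / "currents.nc")
        if wind is not None:
            wind.to_netcdf(out / "wind.nc")
        env.to_netcdf(out / "env.nc")
        samples.to_csv(out / "samples.csv", index=False)
        report.metrics.to_csv(out / "track_metrics.csv", index=False)
        env_records.to_csv(out / "env_records.csv", index=False)
        report.save(out / "report.json")
    return report
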