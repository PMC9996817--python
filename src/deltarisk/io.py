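"""CSV and NetCDF entry/exit points for the pipeline's tables and grids.

Real-data runs enter through the same schemas the synthetic generators
write, so a field campaign's spreadsheets drop in without code changes.

Schemas (CSV, one header row):

* cosolvent:  ``methanol_mole_fraction, log_kpw_obs``
* PRC:        ``compound, fraction_retained, deployment_days``
* absorbed:   ``station, depth_band, distance_to_pen, absorbed_ng``
* outcomes:   ``treatment, tank, n, dead, swimming_observed, day``
* sediment:   ``station, distance, depth, concentration, lod, censored``
"""

from __future__ import annotations

import pandas as pd

from .effects import ExposureOutcome
from .impact import SedimentSample
from .pas import CosolventMeasurement, Measurement, PrcObservation

__all__ = [
    "read_cosolvent_csv",
    "read_prc_csv",
    "read_absorbed_csv",
    "read_outcomes_csv",
    "write_outcomes_csv",
    "read_sediment_csv",
    "write_sediment_csv",
    "write_history_netcdf",
    "write_flow_netcdf",
]


def read_cosolvent_csv(path) -> list[CosolventMeasurement]:
    df = pd.read_csv(path)
    return [
        CosolventMeasurement(float(r.methanol_mole_fraction), float(r.log_kpw_obs))
        for r in df.itertuples()
    ]


def read_prc_csv(path) -> list[PrcObservation]:
    df = pd.read_csv(path)
    return [
        PrcObservation(str(r.compound), float(r.fraction_retained), float(r.deployment_days))
        for r in df.itertuples()
    ]


def read_absorbed_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"station", "depth_band", "distance_to_pen", "absorbed_ng"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"absorbed-amounts table missing columns: {sorted(missing)}")
    return df


def read_outcomes_csv(path) -> list[ExposureOutcome]:
    df = pd.read_csv(path)
    return [
        ExposureOutcome(
            treatment=float(r.treatment),
            tank=str(r.tank),
            n=int(r.n),
            dead=int(r.dead),
            swimming_observed=int(getattr(r, "swimming_observed", 0)),
            day=int(getattr(r, "day", 4)),
        )
        for r in df.itertuples()
    ]


def write_outcomes_csv(outcomes, path) -> None:
    pd.DataFrame(
        [
            {
                "treatment": o.treatment,
                "tank": o.tank,
                "n": o.n,
                "dead": o.dead,
                "swimming_observed": o.swimming_observed,
                "day": o.day,
            }
            for o in outcomes
        ]
    ).to_csv(path, index=False)


def read_sediment_csv(path) -> list[SedimentSample]:
    df = pd.read_csv(path)
    return [
        SedimentSample(
            station=str(r.station),
            distance=float(r.distance),
            depth=float(r.depth),
            concentration=Measurement(
                value=float(r.concentration),
                lod=float(r.lod),
                censored=bool(r.censored),
            ),
        )
        for r in df.itertuples()
    ]


def write_sediment_csv(samples, path) -> None:
    pd.DataFrame(
        [
            {
                "station": s.station,
                "distance": s.distance,
                "depth": s.depth,
                "concentration": s.concentration.value,
                "lod": s.concentration.lod,
                "censored": s.concentration.censored,
            }
            for s in samples
        ]
    ).to_csv(path, index=False)


def write_history_netcdf(history, path) -> None:
    """ConcentrationHistory to NetCDF3 (CF-style time/y/x, ng L-1)."""
    history.to_xarray().to_netcdf(path, engine="scipy")


def write_flow_netcdf(flow, path) -> None:
    flow.to_xarray().to_netcdf(path, engine="scipy")
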