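"""CSV/YAML/JSON codecs for series, curves, schemes and reports.

Formats:

* bound-fraction series — CSV with columns ``time_s, p`` plus a YAML
  sidecar (same stem, ``.yaml``) holding CS, CE (molar) and the series kind;
* ACF curves — CSV with columns ``lag_s, G[, sigma]``;
* coupled experiments — a directory of series CSVs plus ``manifest.yaml``
  mapping each file to its incubation time and the shared pre-dilution
  condition;
* linear schemes — YAML/JSON list of {from_state, to_state, rate_per_s};
* trajectories — CSV with ``time_s`` then one column per state;
* reports — JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binding_fits import BoundFractionSeries
from .coupled_kinetics import CoupledExperiment
from .errors import ParseError
from .fcs_model import FcsCurve
from .reaction_scheme import LinearScheme

__all__ = [
    "read_series", "write_series",
    "read_acf_curve", "write_acf_curve",
    "read_coupled_experiment", "write_coupled_experiment",
    "read_scheme", "write_scheme",
    "write_trajectories", "write_report", "read_report",
]


def _read_csv(path: Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
    for col in required:
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    for col in df.columns:
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ParseError(f"{path}: NaN in column {col!r} at row {bad[0] + 2}")
    return df


def _check_monotone(path: Path, t: np.ndarray, column: str) -> None:
    steps = np.diff(t)
    if np.any(steps <= 0):
        row = int(np.argmax(steps <= 0)) + 3  # header + 1-based + offset
        raise ParseError(f"{path}: column {column!r} not strictly increasing at row {row}")


def write_series(series: BoundFractionSeries, path) -> None:
    path = Path(path)
    pd.DataFrame({"time_s": series.times, "p": series.p}).to_csv(path, index=False)
    sidecar = {"CS_M": float(series.CS), "CE_M": float(series.CE), "kind": series.kind}
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))


def read_series(path) -> BoundFractionSeries:
    path = Path(path)
    df = _read_csv(path, ["time_s", "p"])
    t = df["time_s"].to_numpy(float)
    _check_monotone(path, t, "time_s")
    meta = {"CS_M": 0.0, "CE_M": 0.0, "kind": "association"}
    sidecar = path.with_suffix(".yaml")
    if sidecar.exists():
        loaded = yaml.safe_load(sidecar.read_text()) or {}
        meta.update(loaded)
    return BoundFractionSeries(
        times=t, p=df["p"].to_numpy(float),
        CS=meta["CS_M"], CE=meta["CE_M"], kind=meta["kind"],
    )


def write_acf_curve(curve: FcsCurve, path) -> None:
    data = {"lag_s": curve.lags, "G": curve.G}
    if curve.sigma is not None:
        data["sigma"] = curve.sigma
    pd.DataFrame(data).to_csv(path, index=False)


def read_acf_curve(path) -> FcsCurve:
    path = Path(path)
    df = _read_csv(path, ["lag_s", "G"])
    lags = df["lag_s"].to_numpy(float)
    _check_monotone(path, lags, "lag_s")
    return FcsCurve(
        lags=lags, G=df["G"].to_numpy(float),
        sigma=df["sigma"].to_numpy(float) if "sigma" in df.columns else None,
    )


def write_coupled_experiment(exp: CoupledExperiment, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "CS_M": float(exp.CS), "CE_M": float(exp.CE),
        "dilution": float(exp.dilution), "series": [],
    }
    for i, (T, s) in enumerate(zip(exp.T, exp.series)):
        name = f"chase_{i:02d}.csv"
        write_series(s, directory / name)
        manifest["series"].append({"file": name, "T_s": float(T)})
    (directory / "manifest.yaml").write_text(yaml.safe_dump(manifest))


def read_coupled_experiment(directory) -> CoupledExperiment:
    directory = Path(directory)
    manifest_path = directory / "manifest.yaml"
    if not manifest_path.exists():
        raise ParseError(f"{directory}: missing manifest.yaml")
    manifest = yaml.safe_load(manifest_path.read_text())
    T, series = [], []
    for entry in manifest.get("series", []):
        T.append(float(entry["T_s"]))
        s = read_series(directory / entry["file"])
        s.kind = "dissociation"
        series.append(s)
    return CoupledExperiment(
        T=T, series=series,
        CS=float(manifest["CS_M"]), CE=float(manifest["CE_M"]),
        dilution=float(manifest.get("dilution", 4000.0)),
    )


def write_scheme(scheme: LinearScheme, path) -> None:
    doc = {
        "states": scheme.states,
        "initial": {k: float(v) for k, v in scheme.initial.items()},
        "transitions": [
            {"from_state": a, "to_state": b, "rate_per_s": float(k)}
            for (a, b), k in scheme.rates.items()
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc))


def read_scheme(path) -> LinearScheme:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        rates = {
            (tr["from_state"], tr["to_state"]): float(tr["rate_per_s"])
            for tr in doc["transitions"]
        }
        return LinearScheme(states=list(doc["states"]), rates=rates,
                            initial=dict(doc.get("initial", {})))
    except KeyError as exc:
        raise ParseError(f"{path}: missing key {exc}") from exc


def write_trajectories(times, trajectories: dict, path) -> None:
    """CSV with a time_s column followed by one column per state."""
    df = pd.DataFrame({"time_s": np.asarray(times, float)})
    for state, values in trajectories.items():
        df[state] = np.asarray(values, float)
    df.to_csv(path, index=False)


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
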