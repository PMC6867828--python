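"""CSV/YAML readers and writers for the assay formats the package consumes.

Concentration columns carry their unit in the header (``titrant_M`` /
``titrant_nM`` / ``titrant_uM``; ``conc_uM``); everything is converted to
molar on entry.  Trajectory files carry their simulation parameters as
``# key=value`` comment lines so a run can be reproduced from the file
alone.
"""

from __future__ import annotations

import ast
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .elongation import FilamentTrajectory, VelocityCurve, END_FREE
from .equilibria import AffinityConstant, CompetitionMixture, TitrationSeries
from .errors import InvalidInputError
from .kinetics import StoppedFlowTrace
from .units import parse_concentration

__all__ = [
    "read_titration_csv",
    "read_trace_csv",
    "read_velocity_curve_csv",
    "write_velocity_curve_csv",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "load_mixture_yaml",
    "write_truth_json",
]

_TITRANT_UNITS = {"titrant_M": 1.0, "titrant_mM": 1e-3, "titrant_uM": 1e-6,
                  "titrant_nM": 1e-9}


def read_titration_csv(path) -> TitrationSeries:
    """Read a titration (``titrant_<unit>``, ``signal``[, ``signal_err``])."""
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c in _TITRANT_UNITS]
    if len(cols) != 1:
        raise InvalidInputError(
            f"expected exactly one titrant column among {sorted(_TITRANT_UNITS)}"
        )
    titrant = df[cols[0]].to_numpy(dtype=float) * _TITRANT_UNITS[cols[0]]
    err = df["signal_err"].to_numpy(dtype=float) if "signal_err" in df else None
    return TitrationSeries(titrant, df["signal"].to_numpy(dtype=float), err)


def read_trace_csv(path, profilin_total=None) -> StoppedFlowTrace:
    """Read a stopped-flow trace (``time_s``, ``intensity``).

    The concentration comes from ``profilin_total`` (molar or a string
    like ``"10 uM"``) or, failing that, a ``trace_<conc>nM.csv`` filename.
    """
    df = pd.read_csv(path)
    if profilin_total is None:
        stem = Path(path).stem
        if stem.startswith("trace_") and stem.endswith("nM"):
            profilin_total = float(stem[len("trace_"):-2]) * 1e-9
        else:
            raise InvalidInputError(
                "profilin_total not given and filename does not follow "
                "trace_<conc_nM>nM.csv"
            )
    else:
        profilin_total = parse_concentration(profilin_total)
    return StoppedFlowTrace(
        time=df["time_s"].to_numpy(dtype=float),
        intensity=df["intensity"].to_numpy(dtype=float),
        profilin_total=profilin_total,
    )


def read_velocity_curve_csv(path) -> VelocityCurve:
    """Read ``conc_uM``, ``v_mean_sub_per_s``, ``v_sd``, ``n``."""
    df = pd.read_csv(path)
    return VelocityCurve(
        conc=df["conc_uM"].to_numpy(dtype=float) * 1e-6,
        v_mean=df["v_mean_sub_per_s"].to_numpy(dtype=float),
        v_sd=df["v_sd"].to_numpy(dtype=float),
        n=df["n"].to_numpy(dtype=int),
    )


def write_velocity_curve_csv(curve: VelocityCurve, path) -> None:
    pd.DataFrame(
        {
            "conc_uM": curve.conc * 1e6,
            "v_mean_sub_per_s": curve.v_mean,
            "v_sd": curve.v_sd,
            "n": curve.n,
        }
    ).to_csv(path, index=False)


def write_trajectory_csv(traj: FilamentTrajectory, path) -> None:
    """Write events plus ``# key=value`` metadata lines."""
    with open(path, "w") as fh:
        fh.write(f"# seed={traj.seed}\n")
        for key, val in sorted(traj.params.items()):
            if key == "conc":
                fh.write(f"# conc_uM={val * 1e6!r}\n")
            else:
                fh.write(f"# {key}={val!r}\n")
        pd.DataFrame(
            {
                "time_s": traj.times,
                "length_subunits": traj.lengths,
                "end_state": traj.end_state,
            }
        ).to_csv(fh, index=False)


def read_trajectory_csv(path) -> FilamentTrajectory:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    params = {}
    for key, val in meta.items():
        if key == "seed":
            continue
        try:
            parsed = ast.literal_eval(val)
        except (ValueError, SyntaxError):
            parsed = val
        if key == "conc_uM":
            params["conc"] = float(parsed) * 1e-6
        else:
            params[key] = parsed
    seed = meta.get("seed")
    try:
        seed = int(seed)
    except (TypeError, ValueError):
        pass
    return FilamentTrajectory(
        times=df["time_s"].to_numpy(dtype=float),
        lengths=df["length_subunits"].to_numpy(dtype=np.int64),
        end_state=df["end_state"].to_numpy(dtype=np.int8),
        seed=seed,
        params=params,
    )


def load_mixture_yaml(path) -> CompetitionMixture:
    """Load an assay mix: ``a_total``/``p_total``/``w_total``/``kp``/``kw``.

    Values are numbers (molar) or ``"value unit"`` strings (``"18 nM"``).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return CompetitionMixture(
            a_total=parse_concentration(raw["a_total"]),
            p_total=parse_concentration(raw["p_total"]),
            w_total=parse_concentration(raw["w_total"]),
            kp=AffinityConstant(parse_concentration(raw["kp"])),
            kw=AffinityConstant(parse_concentration(raw["kw"])),
        )
    except KeyError as exc:
        raise InvalidInputError(f"mixture YAML missing key {exc}") from None


def write_truth_json(truth: dict, path) -> None:
    """Sidecar ground-truth record for a generated dataset."""

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return repr(o)

    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=default)
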