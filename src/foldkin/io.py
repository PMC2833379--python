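"""CSV / JSON input-output for datasets, constraints and fit reports.

Column names are fixed and matched case-insensitively; unknown columns
are ignored with a warning. All CSV output is RFC-4180 (pandas default);
readers accept LF and CRLF line endings. Denaturant concentrations are
molar floats with a decimal point — decimal commas are rejected.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .chevron import FitConstraints, FitResult
from .datasets import REFOLDING, UNFOLDING, ChevronDataset, EquilibriumCurve, KineticTrace

__all__ = [
    "read_chevron_csv",
    "write_chevron_csv",
    "read_equilibrium_csv",
    "write_equilibrium_csv",
    "read_trace_csv",
    "read_constraints_json",
    "fit_result_to_dict",
    "write_fit_report",
]

_CHEVRON_COLUMNS = {
    "variant": "variant",
    "urea_m": "urea_M",
    "branch": "branch",
    "kobs_s1": "kobs_s1",
    "kobs_sigma": "kobs_sigma",
    "initial_fluor": "initial_fluor",
    "final_fluor": "final_fluor",
}


def _read_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.columns.size == 0:
        raise ValueError(f"{path}: no header row found")
    return df


def _canonicalise(df: pd.DataFrame, known: dict[str, str], path) -> pd.DataFrame:
    renames, drops = {}, []
    for col in df.columns:
        key = col.strip().lower()
        if key in known:
            renames[col] = known[key]
        else:
            drops.append(col)
    if drops:
        warnings.warn(f"{path}: ignoring unknown columns {drops}")
    return df.rename(columns=renames).drop(columns=drops)


def _require_numeric(df: pd.DataFrame, cols, path) -> None:
    for col in cols:
        if col in df and not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(
                f"{path}: column {col!r} is not numeric "
                "(decimal commas are not supported; use a decimal point)"
            )


def read_chevron_csv(path) -> dict[str, ChevronDataset]:
    """Read chevron observations, one :class:`ChevronDataset` per variant.

    Mandatory columns: ``urea_M``, ``kobs_s1``. Optional: ``variant``,
    ``branch``, ``kobs_sigma``, ``initial_fluor``, ``final_fluor``. When
    the branch column is absent, observations below the empirical rate
    minimum are labelled refolding.
    """
    df = _canonicalise(_read_csv(path), _CHEVRON_COLUMNS, path)
    missing = [c for c in ("urea_M", "kobs_s1") if c not in df]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    _require_numeric(df, ["urea_M", "kobs_s1", "kobs_sigma", "initial_fluor", "final_fluor"], path)
    bad = df.index[~(df["kobs_s1"] > 0)]
    if len(bad):
        # +2: one for the header line, one for 1-based numbering
        raise ValueError(f"{path}: non-positive kobs_s1 in row {bad[0] + 2}")
    if "variant" not in df:
        df["variant"] = "unknown"
    out = {}
    for variant, sub in df.groupby("variant", sort=False):
        sub = sub.reset_index(drop=True)
        if "branch" not in sub:
            i_min = int(sub["kobs_s1"].idxmin())
            D_min = float(sub.loc[i_min, "urea_M"])
            sub["branch"] = np.where(sub["urea_M"] < D_min, REFOLDING, UNFOLDING)
            warnings.warn(f"{path}: no branch column; assigned by the empirical rate minimum")
        out[str(variant)] = ChevronDataset.from_dataframe(sub, variant=str(variant))
    return out


def write_chevron_csv(dataset: ChevronDataset, path) -> None:
    dataset.to_dataframe().to_csv(path, index=False)


def read_equilibrium_csv(path) -> EquilibriumCurve:
    """Read an equilibrium curve: columns ``urea_M``, ``signal`` [, ``probe``]."""
    known = {"urea_m": "urea_M", "signal": "signal", "probe": "probe"}
    df = _canonicalise(_read_csv(path), known, path)
    missing = [c for c in ("urea_M", "signal") if c not in df]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    _require_numeric(df, ["urea_M", "signal"], path)
    probe = str(df["probe"].iloc[0]) if "probe" in df else "fluorescence"
    return EquilibriumCurve(
        denaturant=df["urea_M"].to_numpy(float),
        signal=df["signal"].to_numpy(float),
        probe=probe,
    )


def write_equilibrium_csv(curve: EquilibriumCurve, path) -> None:
    curve.to_dataframe().to_csv(path, index=False)


def read_trace_csv(path, denaturant: float = 0.0, direction: str = REFOLDING) -> KineticTrace:
    """Read a kinetic trace: columns ``time_s``, ``signal``."""
    known = {"time_s": "time_s", "signal": "signal"}
    df = _canonicalise(_read_csv(path), known, path)
    missing = [c for c in ("time_s", "signal") if c not in df]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    _require_numeric(df, ["time_s", "signal"], path)
    return KineticTrace(
        times=df["time_s"].to_numpy(float),
        signal=df["signal"].to_numpy(float),
        denaturant=denaturant,
        direction=direction,
    )


def read_constraints_json(path) -> FitConstraints:
    """Read a constraint set: {"fixed": {...}, "bounds": {...}, "M_UN_range": [lo, hi]}."""
    raw = json.loads(Path(path).read_text())
    return FitConstraints(
        fixed={k: float(v) for k, v in raw.get("fixed", {}).items()},
        bounds={k: (float(lo), float(hi)) for k, (lo, hi) in raw.get("bounds", {}).items()},
        M_UN_range=tuple(raw["M_UN_range"]) if raw.get("M_UN_range") else None,
    )


def fit_result_to_dict(result: FitResult, variant: str = "") -> dict:
    """JSON-serialisable summary of a chevron fit (params, errors, thermo)."""
    thermo = {
        k: v
        for k, v in vars(result.thermo).items()
        if v is not None
    }
    return {
        "variant": variant,
        "model": "three_state" if result.scheme.n_states == 3 else "two_state",
        "success": result.success,
        "params": {k: float(v) for k, v in result.params.items()},
        "sigma": {k: float(v) for k, v in result.sigma.items()},
        "fixed": {k: float(v) for k, v in result.fixed.items()},
        "thermo": {k: float(v) for k, v in thermo.items()},
        "thermo_sigma": {k: float(v) for k, v in result.thermo_sigma.items()},
        "residual_rms": result.residual_rms,
        "unidentifiable": result.unidentifiable,
        "at_bounds": result.at_bounds,
        "n_starts": result.n_starts,
        "seed": result.seed,
    }


def write_fit_report(result: FitResult, path, variant: str = "") -> None:
    Path(path).write_text(json.dumps(fit_result_to_dict(result, variant), indent=2) + "\n")
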