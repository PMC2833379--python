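"""In-memory containers for kinetic and equilibrium observations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REFOLDING = "refolding"
UNFOLDING = "unfolding"

__all__ = ["KineticTrace", "ChevronDataset", "EquilibriumCurve", "REFOLDING", "UNFOLDING"]


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if np.any(~np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class KineticTrace:
    """One averaged stopped-flow trace: fluorescence vs time at fixed urea."""

    times: np.ndarray
    signal: np.ndarray
    denaturant: float
    direction: str = REFOLDING

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times, "times")
        self.signal = _as_float_array(self.signal, "signal")
        if self.times.size != self.signal.size:
            raise ValueError("times and signal must have equal length")
        if self.times.size < 2:
            raise ValueError("a trace needs at least 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.denaturant < 0:
            raise ValueError("denaturant must be >= 0")
        if self.direction not in (REFOLDING, UNFOLDING):
            raise ValueError(f"direction must be refolding/unfolding, got {self.direction!r}")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class ChevronDataset:
    """Observed rates and normalised amplitude signals vs urea for one variant.

    ``initial_signal``/``final_signal`` are the burst-phase and endpoint
    fluorescence of each mixing experiment, normalised so the 7.75 M urea
    reference is 1; they may be absent (None) for rate-only datasets.
    """

    denaturant: np.ndarray
    kobs: np.ndarray
    branch: np.ndarray
    kobs_sigma: np.ndarray | None = None
    initial_signal: np.ndarray | None = None
    final_signal: np.ndarray | None = None
    variant: str = ""

    def __post_init__(self) -> None:
        self.denaturant = _as_float_array(self.denaturant, "denaturant")
        self.kobs = _as_float_array(self.kobs, "kobs")
        self.branch = np.asarray(self.branch, dtype=object)
        n = self.denaturant.size
        if self.kobs.size != n or self.branch.size != n:
            raise ValueError("denaturant, kobs and branch must have equal length")
        if np.any(self.kobs <= 0):
            bad = int(np.flatnonzero(self.kobs <= 0)[0])
            raise ValueError(f"kobs must be > 0 (first offending observation index {bad})")
        unknown = set(self.branch) - {REFOLDING, UNFOLDING}
        if unknown:
            raise ValueError(f"unknown branch labels {sorted(unknown)}")
        for name in ("kobs_sigma", "initial_signal", "final_signal"):
            arr = getattr(self, name)
            if arr is not None:
                arr = _as_float_array(arr, name)
                if arr.size != n:
                    raise ValueError(f"{name} must have length {n}")
                setattr(self, name, arr)
        refold_D = np.unique(self.denaturant[self.branch == REFOLDING])
        if refold_D.size < 3:
            raise ValueError("need refolding observations at >= 3 distinct urea concentrations")

    def __len__(self) -> int:
        return self.denaturant.size

    @property
    def has_signals(self) -> bool:
        return self.initial_signal is not None and self.final_signal is not None

    def to_dataframe(self) -> pd.DataFrame:
        cols = {
            "variant": self.variant or "unknown",
            "urea_M": self.denaturant,
            "branch": self.branch,
            "kobs_s1": self.kobs,
        }
        if self.kobs_sigma is not None:
            cols["kobs_sigma"] = self.kobs_sigma
        if self.initial_signal is not None:
            cols["initial_fluor"] = self.initial_signal
        if self.final_signal is not None:
            cols["final_fluor"] = self.final_signal
        return pd.DataFrame(cols)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, variant: str = "") -> "ChevronDataset":
        return cls(
            denaturant=df["urea_M"].to_numpy(float),
            kobs=df["kobs_s1"].to_numpy(float),
            branch=df["branch"].to_numpy(object),
            kobs_sigma=df["kobs_sigma"].to_numpy(float) if "kobs_sigma" in df else None,
            initial_signal=df["initial_fluor"].to_numpy(float) if "initial_fluor" in df else None,
            final_signal=df["final_fluor"].to_numpy(float) if "final_fluor" in df else None,
            variant=variant,
        )


@dataclass
class EquilibriumCurve:
    """An equilibrium denaturation curve: signal vs urea for one probe."""

    denaturant: np.ndarray
    signal: np.ndarray
    probe: str = "fluorescence"

    def __post_init__(self) -> None:
        self.denaturant = _as_float_array(self.denaturant, "denaturant")
        self.signal = _as_float_array(self.signal, "signal")
        if self.denaturant.size != self.signal.size:
            raise ValueError("denaturant and signal must have equal length")
        if self.denaturant.size < 10:
            raise ValueError("an equilibrium curve needs >= 10 points")

    def __len__(self) -> int:
        return self.denaturant.size

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"urea_M": self.denaturant, "signal": self.signal, "probe": self.probe}
        )
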