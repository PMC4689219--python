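"""Parameter containers for the mutual-repression fate-switch model.

The circuit couples two transcriptional programs — NANOG (epiblast, Epi) and
GATA (primitive endoderm, PrE) — through mutual Hill repression, driven by a
pulse of exogenous GATA whose per-cell maximum production rate ``D`` ("dose")
is the only source of cell-to-cell variability.  FGF/MAPK signaling enters
through a dimensionless level ``s`` that either inhibits NANOG production
(the preferred coupling) or promotes endogenous GATA production.

All concentrations are in arbitrary units scaled so that steady-state levels
are O(1); time is in hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np

#: Allowed signaling coupling modes.
SIGNALING_MODES = ("none", "promotes_gata", "inhibits_nanog")

#: Allowed dose-distribution families.
DOSE_FAMILIES = ("lognormal", "uniform", "fixed")


class ParameterError(ValueError):
    """Raised when a parameter container violates its invariants."""


def _require(cond: bool, key: str, message: str) -> None:
    if not cond:
        raise ParameterError(f"{key}: {message}")


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants and signaling coupling of the three-variable circuit.

    Parameters
    ----------
    alpha_N, alpha_G
        Maximal NANOG / endogenous-GATA production rates [conc/h].
    K_GN, K_NG
        Repression thresholds: total GATA on NANOG, and NANOG on GATA [conc].
    h_N, h_G
        Hill exponents of the two repressive links (>= 1).
    gamma_N, gamma_G, gamma_X
        First-order degradation rates of N, G and exogenous GATA G_X [1/h].
    s
        FGF/MAPK signaling level; 0 = fully inhibited, 1 = saturated.
    K_s, m
        Half-effect constant and Hill exponent of the signaling input.
    mode
        How signaling couples to the circuit: ``"none"``,
        ``"promotes_gata"`` or ``"inhibits_nanog"``.
    """

    alpha_N: float = 5.0
    alpha_G: float = 1.0
    K_GN: float = 0.3
    K_NG: float = 0.3
    h_N: float = 4.0
    h_G: float = 4.0
    gamma_N: float = 0.5
    gamma_G: float = 0.5
    gamma_X: float = 0.5
    s: float = 1.0
    K_s: float = 0.5
    m: float = 2.0
    mode: str = "inhibits_nanog"

    def __post_init__(self) -> None:
        # production rates may be zero (a silenced node is a useful limit
        # with closed-form behaviour); thresholds and degradation rates
        # must be strictly positive
        for key in ("alpha_N", "alpha_G"):
            _require(getattr(self, key) >= 0, key, "must be non-negative")
        for key in ("K_GN", "K_NG", "gamma_N", "gamma_G", "gamma_X", "K_s"):
            _require(getattr(self, key) > 0, key, "must be strictly positive")
        for key in ("h_N", "h_G", "m"):
            _require(getattr(self, key) >= 1, key, "Hill exponent must be >= 1")
        _require(self.s >= 0, "s", "signaling level must be non-negative")
        _require(self.mode in SIGNALING_MODES, "mode",
                 f"must be one of {SIGNALING_MODES}")

    # -- signaling transfer functions -------------------------------------
    def signaling_factor_nanog(self) -> float:
        """Multiplier on NANOG production, ``1/(1+(s/K_s)^m)`` under
        ``inhibits_nanog``, else 1."""
        if self.mode == "inhibits_nanog":
            return 1.0 / (1.0 + (self.s / self.K_s) ** self.m)
        return 1.0

    def signaling_factor_gata(self) -> float:
        """Multiplier on GATA production, ``s^m/(K_s^m+s^m)`` under
        ``promotes_gata``, else 1."""
        if self.mode == "promotes_gata":
            sm = self.s ** self.m
            return sm / (self.K_s ** self.m + sm)
        return 1.0

    def with_signaling(self, s: float) -> "ModelParameters":
        """Copy with a different signaling level."""
        return replace(self, s=s)

    def replace(self, **kwargs) -> "ModelParameters":
        """Copy with selected fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class PulseProtocol:
    """Doxycycline pulse-chase timing: exogenous GATA is produced on the
    half-open interval ``[t_start, t_end)``; integration runs to ``t_final``."""

    t_start: float = 0.0
    t_end: float = 6.0
    t_final: float = 30.0

    def __post_init__(self) -> None:
        _require(self.t_start < self.t_end, "t_end",
                 "pulse must have positive duration (t_start < t_end)")
        _require(self.t_end <= self.t_final, "t_final",
                 "simulation must extend to at least the pulse end")

    def pulse_active(self, t: float) -> bool:
        return self.t_start <= t < self.t_end

    def replace(self, **kwargs) -> "PulseProtocol":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class CellState:
    """Instantaneous circuit state (NANOG, endogenous GATA, exogenous GATA)."""

    N: float
    G: float
    G_X: float = 0.0

    def __post_init__(self) -> None:
        for key in ("N", "G", "G_X"):
            _require(getattr(self, key) >= 0, key,
                     "concentrations must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.N, self.G, self.G_X], dtype=float)


@dataclass(frozen=True)
class DoseDistribution:
    """Distribution of the per-cell maximum exogenous production rate D.

    ``lognormal`` uses ``location`` = mean of log D and ``scale`` = sd of
    log D; ``uniform`` uses midpoint/half-width; ``fixed`` ignores scale.
    """

    family: str = "lognormal"
    location: float = -1.05
    scale: float = 0.8

    def __post_init__(self) -> None:
        _require(self.family in DOSE_FAMILIES, "family",
                 f"must be one of {DOSE_FAMILIES}")
        _require(self.scale >= 0, "scale", "must be non-negative")
        if self.family == "uniform":
            _require(self.location - self.scale >= 0, "location",
                     "uniform support must be non-negative")
        if self.family == "fixed":
            _require(self.location >= 0, "location",
                     "fixed dose must be non-negative")

    def replace(self, **kwargs) -> "DoseDistribution":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise model for synthetic fluorescence readouts.

    Intensities are corrupted multiplicatively, ``x * exp(eps)`` with
    ``eps ~ Normal(0, sigma_mult)``, then offset by an additive background
    draw ``Normal(background, background_sd)``.  End-point fate labels are
    flipped independently with probability ``label_flip``.
    """

    sigma_mult: float = 0.2
    background: float = 0.5
    background_sd: float = 0.05
    label_flip: float = 0.0

    def __post_init__(self) -> None:
        _require(self.sigma_mult >= 0, "sigma_mult", "must be non-negative")
        _require(self.background_sd >= 0, "background_sd",
                 "must be non-negative")
        _require(0 <= self.label_flip < 0.5, "label_flip",
                 "must lie in [0, 0.5)")

    @property
    def is_zero(self) -> bool:
        return (self.sigma_mult == 0 and self.background == 0
                and self.background_sd == 0 and self.label_flip == 0)

    def replace(self, **kwargs) -> "NoiseModel":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class Trace:
    """A single cell's simulated timecourse.

    ``states`` has shape (len(times), 3) with columns (N, G, G_X); ``dose``
    is the cell's maximum exogenous production rate D [conc/h].
    """

    times: np.ndarray
    states: np.ndarray
    dose: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 2 or self.states.shape != (self.times.size, 3):
            raise ParameterError(
                "states: expected shape (len(times), 3), got "
                f"{self.states.shape}")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ParameterError("times: must be strictly increasing")
        if self.dose < 0:
            raise ParameterError("dose: must be non-negative")

    @property
    def N(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def G(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def G_X(self) -> np.ndarray:
        return self.states[:, 2]

    def final_state(self) -> CellState:
        N, G, G_X = np.clip(self.states[-1], 0.0, None)
        return CellState(N=N, G=G, G_X=G_X)
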