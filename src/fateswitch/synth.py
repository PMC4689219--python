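"""Synthetic stand-ins for single-cell time-lapse and flow-cytometry data.

Generates noisy measurement tables from the circuit model so every analysis
stage can be exercised end to end: per-cell reporter traces through a
pulse-chase protocol, single-timepoint intensity snapshots, and simple
two-class toy samples for the ROC stack.  Measurement noise is
multiplicative log-normal plus an additive background; end-point fate
labels can be flipped with a configurable error rate.  Each generator also
returns the noise-free counterpart for oracle-style testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .analysis import LabeledSample
from .params import (DoseDistribution, ModelParameters, NoiseModel,
                     PulseProtocol)
from .population import (FATE_GATA, PopulationResult, sample_doses,
                         simulate_population)

__all__ = [
    "TimelapseData",
    "generate_timelapse",
    "generate_flow_snapshot",
    "generate_labeled_toy",
]

CHANNELS = ("N", "G", "G_X")


@dataclass
class TimelapseData:
    """Synthetic time-lapse dataset.

    ``traces`` / ``traces_clean`` are tidy tables with columns
    (cell_id, time_h, channel, intensity); ``labels`` has (cell_id, fate)
    with the recorded (possibly flipped) fate and ``fate_true`` the
    noise-free one.  ``population`` keeps the underlying simulation.
    """

    traces: pd.DataFrame
    traces_clean: pd.DataFrame
    labels: pd.DataFrame
    population: PopulationResult
    seed: int | None

    @property
    def times(self) -> np.ndarray:
        return self.population.times

    def channel_matrix(self, channel: str, clean: bool = False) -> np.ndarray:
        """(cells × frames) noisy (or clean) matrix of one channel, rows in
        cell-id order."""
        table = self.traces_clean if clean else self.traces
        sub = table[table["channel"] == channel]
        wide = sub.pivot(index="cell_id", columns="time_h",
                         values="intensity").sort_index()
        return wide.to_numpy()

    def label_vector(self, true: bool = False) -> np.ndarray:
        col = "fate_true" if true else "fate"
        lab = self.labels.sort_values("cell_id")[col]
        return (lab == FATE_GATA).astype(int).to_numpy()


def _apply_noise(values: np.ndarray, noise: NoiseModel,
                 rng: np.random.Generator) -> np.ndarray:
    eps = rng.normal(0.0, noise.sigma_mult, size=values.shape) \
        if noise.sigma_mult > 0 else 0.0
    bg = rng.normal(noise.background, noise.background_sd,
                    size=values.shape) \
        if (noise.background != 0 or noise.background_sd > 0) else 0.0
    return values * np.exp(eps) + bg


def _tidy(times: np.ndarray, matrices: Dict[str, np.ndarray]) -> pd.DataFrame:
    frames = []
    for channel, mat in matrices.items():
        n_cells = mat.shape[0]
        frames.append(pd.DataFrame({
            "cell_id": np.repeat(np.arange(n_cells), times.size),
            "time_h": np.tile(times, n_cells),
            "channel": channel,
            "intensity": mat.ravel(),
        }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["cell_id", "channel", "time_h"],
                           ignore_index=True)


def generate_timelapse(params: ModelParameters, protocol: PulseProtocol,
                       dist: DoseDistribution, n: int,
                       noise: NoiseModel | None = None,
                       frame_interval: float = 0.25,
                       seed: int | None = None,
                       doses: np.ndarray | None = None) -> TimelapseData:
    """Simulate a filmed population and return noisy + clean trace tables.

    Cells are simulated through the pulse-chase protocol, sampled at frame
    boundaries in every channel, corrupted by the measurement-noise model,
    and labelled with their end-point fate (flipped independently with
    probability ``noise.label_flip``).  Passing explicit ``doses`` pairs
    the underlying population across datasets that differ only in their
    noise draws.
    """
    if n < 2:
        raise ValueError("need at least 2 cells")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    if noise is None:
        noise = NoiseModel()
    times = np.arange(0.0, protocol.t_final + 1e-9, frame_interval)
    if times.size == 0:
        raise ValueError("zero frames: t_final shorter than one frame")

    ss = np.random.SeedSequence(seed)
    seed_doses, seed_noise, seed_flip = [s.generate_state(1)[0] % (2**31)
                                         for s in ss.spawn(3)]
    pop = simulate_population(params, protocol, dist, n,
                              seed=int(seed_doses), times=times,
                              doses=doses)

    clean = {ch: pop.channel_matrix(ch) for ch in CHANNELS}
    rng = np.random.default_rng(int(seed_noise))
    noisy = {ch: _apply_noise(mat, noise, rng)
             for ch, mat in clean.items()}

    fates_true = list(pop.fates)
    rng_flip = np.random.default_rng(int(seed_flip))
    fates_rec = []
    for f in fates_true:
        if f is None:
            fates_rec.append(None)
        elif noise.label_flip > 0 and rng_flip.random() < noise.label_flip:
            fates_rec.append("NANOG_high" if f == FATE_GATA else FATE_GATA)
        else:
            fates_rec.append(f)

    labels = pd.DataFrame({"cell_id": np.arange(n),
                           "fate": fates_rec,
                           "fate_true": fates_true,
                           "dose": pop.doses})
    return TimelapseData(traces=_tidy(times, noisy),
                         traces_clean=_tidy(times, clean),
                         labels=labels, population=pop, seed=seed)


def generate_flow_snapshot(params: ModelParameters, protocol: PulseProtocol,
                           dist: DoseDistribution, n: int,
                           t_sample: float | None = None,
                           noise: NoiseModel | None = None,
                           seed: int | None = None
                           ) -> Dict[str, np.ndarray]:
    """Single-timepoint noisy intensity sample per channel for ``n`` cells,
    emulating a flow-cytometry measurement at ``t_sample`` (default: end of
    the chase)."""
    if noise is None:
        noise = NoiseModel()
    if t_sample is None:
        t_sample = protocol.t_final
    if t_sample > protocol.t_final:
        raise ValueError("t_sample must not exceed t_final")
    ss = np.random.SeedSequence(seed)
    seed_doses, seed_noise = [s.generate_state(1)[0] % (2**31)
                              for s in ss.spawn(2)]
    # integrate the full protocol (fates are defined by the full pulse-chase)
    # but record channel values at the snapshot time
    times = np.unique(np.array([0.0, t_sample, protocol.t_final]))
    col = int(np.searchsorted(times, t_sample))
    pop = simulate_population(params, protocol, dist, n,
                              seed=int(seed_doses), times=times)
    rng = np.random.default_rng(int(seed_noise))
    out = {}
    for ch in CHANNELS:
        vals = pop.channel_matrix(ch)[:, col]
        out[ch] = _apply_noise(vals, noise, rng)
    out["fate"] = pop.fate_labels()
    return out


def generate_labeled_toy(n_pos: int, n_neg: int, separation: float,
                         seed: int | None = None) -> LabeledSample:
    """Two unit-variance normal classes whose means differ by
    ``separation`` — the textbook binormal ROC setting with
    AUC = Phi(separation / sqrt(2))."""
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one sample per class")
    rng = np.random.default_rng(seed)
    neg = rng.normal(0.0, 1.0, size=n_neg)
    pos = rng.normal(separation, 1.0, size=n_pos)
    return LabeledSample(values=np.concatenate([neg, pos]),
                         labels=np.concatenate([np.zeros(n_neg, int),
                                                np.ones(n_pos, int)]))
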