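"""Synthetic two-channel single-cell expression datasets.

Emulates parallel live-cell imaging of co-transfected reporter mRNAs
(eGFP construct under study + CayRFP reference in every cell): a regular
10-minute sampling grid over 30 h, per-cell expression onset, correlated
initial expression between channels and independent degradation rates.

The delivery model drives the cross-channel correlation structure: each
cell receives a shared number of lipoplexes ``N ~ Poisson(lipoplex_mean)``
(zero re-drawn), and each channel independently unpacks
``m0 ~ Poisson(N * mrna_per_lipoplex)`` molecules (conditioned >= 1).  The
shared N induces a positive correlation of the initial expression rates
``m0 * k_tl`` across channels, while degradation rates are drawn
independently per channel (lognormal around the condition's multiplier) and
are therefore uncorrelated — the structure seen in dual-reporter data.

Measurement model: ``model_fluorescence(truth) * LogNormal(1, noise_cv)
+ Normal(0, baseline_sd)``.  A configurable fraction of cells is
non-expressing (baseline noise only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import KineticParams, model_fluorescence

__all__ = ["CellSimConfig", "Condition", "SyntheticDataset",
           "sample_cell_params", "simulate_dataset"]

CHANNELS = ("eGFP", "CayRFP")


@dataclass(frozen=True)
class CellSimConfig:
    """Study conditions for the synthetic microscope.

    Times in hours; degradation and translation rates per hour.
    """

    n_cells: int = 200
    duration: float = 30.0
    dt: float = 1.0 / 6.0            # 10-minute sampling
    lipoplex_mean: float = 3.0
    mrna_per_lipoplex: float = 150.0
    ktl_mean: float = 50.0           # proteins per mRNA per hour
    cv_ktl: float = 0.4
    delta_egfp: float = 0.15         # base eGFP-mRNA degradation rate (1/h)
    delta_rfp: float = 0.12          # base CayRFP-mRNA degradation rate (1/h)
    cv_delta: float = 0.4
    noise_cv: float = 0.05
    baseline_sd: float = 1.0
    nonexpressing_frac: float = 0.05
    t0_min: float = 0.25             # expression-onset window (h)
    t0_max: float = 2.0
    k_m: float = 1.2                 # fixed maturation rate (1/h)
    beta: float = 0.03               # fixed protein degradation rate (1/h)
    scale: float = 1e-3              # fluorescence units per mature protein
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.dt <= 0:
            raise ValueError("need n_cells >= 1 and dt > 0")
        if min(self.cv_ktl, self.cv_delta, self.noise_cv, self.baseline_sd) < 0:
            raise ValueError("noise parameters must be >= 0")

    @property
    def times(self) -> np.ndarray:
        n = int(round(self.duration / self.dt)) + 1
        return np.arange(n) * self.dt


@dataclass(frozen=True)
class Condition:
    """One experimental condition; ``delta_mult``/``ktl_mult`` act on the
    eGFP channel only (the construct under study), never on the CayRFP
    reference."""

    construct: str = "eGFP"
    sirna: str = "none"              # none | siCtrl | siRNA1 | siRNA2
    cell_line: str = "A549"
    experiment: str = "exp1"
    delta_mult: float = 1.0
    ktl_mult: float = 1.0
    n_cells: int | None = None

    def __post_init__(self) -> None:
        if self.delta_mult <= 0 or self.ktl_mult <= 0:
            raise ValueError("condition multipliers must be > 0")

    @property
    def label(self) -> str:
        return f"{self.construct}|{self.sirna}|{self.cell_line}|{self.experiment}"


@dataclass
class SyntheticDataset:
    trajectories: pd.DataFrame   # cell_id, channel, time_h, fluorescence
    truth: pd.DataFrame          # per cell x channel ground-truth parameters
    config: CellSimConfig = field(repr=False, default=None)  # type: ignore[assignment]


def _lognormal_cv(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Lognormal draw with the given arithmetic mean and coefficient of
    variation (degenerates to the mean at cv = 0)."""
    if cv == 0:
        return mean
    s2 = np.log1p(cv**2)
    return float(rng.lognormal(np.log(mean) - s2 / 2.0, np.sqrt(s2)))


def sample_cell_params(
    config: CellSimConfig, condition: Condition, rng: np.random.Generator
) -> tuple[KineticParams, KineticParams]:
    """Ground-truth parameters for one cell: (eGFP, CayRFP)."""
    n_lipo = 0
    while n_lipo == 0:
        n_lipo = int(rng.poisson(config.lipoplex_mean))
    t0 = float(rng.uniform(config.t0_min, config.t0_max))
    out = []
    for channel in CHANNELS:
        m0 = 0
        while m0 == 0:
            m0 = int(rng.poisson(n_lipo * config.mrna_per_lipoplex))
        ktl = _lognormal_cv(rng, config.ktl_mean, config.cv_ktl)
        if channel == "eGFP":
            ktl *= condition.ktl_mult
            delta = _lognormal_cv(
                rng, config.delta_egfp * condition.delta_mult, config.cv_delta
            )
        else:
            delta = _lognormal_cv(rng, config.delta_rfp, config.cv_delta)
        out.append(
            KineticParams(
                delta=delta, k_tl=ktl, k_m=config.k_m, beta=config.beta,
                m0=float(m0), t0=t0, scale=config.scale,
            )
        )
    return out[0], out[1]


def simulate_dataset(
    config: CellSimConfig, conditions: list[Condition]
) -> SyntheticDataset:
    """Bit-reproducible synthetic dataset for a list of conditions."""
    rng = np.random.default_rng(config.rng_seed)
    times = config.times
    traj_rows = []
    truth_rows = []
    for cond in conditions:
        n_cells = cond.n_cells if cond.n_cells is not None else config.n_cells
        for i in range(n_cells):
            cell_id = f"{cond.label}|c{i:04d}"
            non_expr = bool(rng.random() < config.nonexpressing_frac)
            params = sample_cell_params(config, cond, rng)
            for channel, p in zip(CHANNELS, params):
                if non_expr:
                    values = np.zeros_like(times)
                else:
                    values = model_fluorescence(p, times)
                if config.noise_cv > 0:
                    s2 = np.log1p(config.noise_cv**2)
                    values = values * rng.lognormal(
                        -s2 / 2.0, np.sqrt(s2), times.size
                    )
                if config.baseline_sd > 0:
                    values = values + rng.normal(0.0, config.baseline_sd, times.size)
                traj_rows.append(
                    pd.DataFrame(
                        {"cell_id": cell_id, "channel": channel,
                         "time_h": times, "fluorescence": values}
                    )
                )
                truth_rows.append(
                    {
                        "cell_id": cell_id, "channel": channel,
                        "construct": cond.construct, "sirna": cond.sirna,
                        "cell_line": cond.cell_line,
                        "experiment": cond.experiment,
                        "delta": p.delta, "k_tl": p.k_tl, "m0": p.m0,
                        "t0": p.t0, "m0ktl": p.m0ktl * p.scale,
                        "tau": p.tau, "non_expressing": non_expr,
                    }
                )
    trajectories = pd.concat(traj_rows, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return SyntheticDataset(trajectories=trajectories, truth=truth, config=config)
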