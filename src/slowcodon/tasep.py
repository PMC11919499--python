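"""Stochastic ribosome-traffic simulation along an ORF.

The model is a totally asymmetric exclusion process with extended particles:
ribosomes occupy ``footprint`` codons, initiate at the 5' end with rate
``alpha_on``, advance codon by codon at the codon-specific elongation rate,
detach prematurely at rate ``gamma`` and terminate from the last codon at
``alpha_off``.  The Gillespie direct method yields time-averaged per-codon
occupancy (A-site convention, with a coverage profile also exported) and the
protein-completion flux J, with batch-means Monte-Carlo standard errors.

``exact_density_small`` solves the same Markov process exactly by building
its full generator matrix; it is the verification oracle for small lattices.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .orf import ElongationRateTable, Orf, SlowWindowVariant

__all__ = [
    "SimParams",
    "DensityProfile",
    "simulate_density",
    "exact_density_small",
    "select_flux_matched",
    "density_at",
    "write_profiles_tsv",
    "read_profiles_tsv",
]


@dataclass(frozen=True)
class SimParams:
    """Rates are per second.  ``omega_scale`` converts the (mean-1) rate
    table into absolute elongation rates, default mean 5 codons/s.
    ``burn_in = None`` uses 10x the expected empty-lattice traversal time."""

    alpha_on: float = 0.1
    alpha_off: float = 2.0
    gamma: float = 2e-4
    footprint: int = 10
    omega_scale: float = 5.0
    burn_in: float | None = None
    sample_time: float = 10_000.0
    n_batches: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha_on < 0 or self.alpha_off <= 0 or self.gamma < 0:
            raise ValueError("rates must be >= 0 with alpha_off > 0")
        if self.footprint < 1:
            raise ValueError("footprint must be >= 1")
        if self.sample_time <= 0:
            raise ValueError("sample_time must be > 0")

    def resolved_burn_in(self, omega: np.ndarray) -> float:
        if self.burn_in is not None:
            return self.burn_in
        traversal = float(np.sum(1.0 / omega)) + 1.0 / self.alpha_off
        return 10.0 * traversal


@dataclass
class DensityProfile:
    """Steady-state per-codon ribosome occupancy and completion flux."""

    orf_id: str
    rho: np.ndarray                 # A-site occupancy per codon
    mc_stderr: np.ndarray
    flux: float                     # completed terminations per second
    flux_stderr: float = 0.0
    rho_cover: np.ndarray | None = None  # footprint-coverage occupancy
    window_start: int | None = None
    rho_batches: np.ndarray | None = None  # batch-means matrix (B x L)
    meta: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return int(self.rho.shape[0])

    def region_mean(self, start: int, end: int) -> tuple[float, float]:
        """Mean occupancy over codons ``start..end`` (1-based, closed) with
        a standard error that respects the correlation of Monte-Carlo noise
        along the lattice (computed from batch means when available)."""
        a, b = start - 1, end
        if not 0 <= a < b <= self.length:
            raise ValueError(f"region {start}..{end} outside profile")
        m = float(self.rho[a:b].mean())
        if self.rho_batches is not None and self.rho_batches.shape[0] > 1:
            batch = self.rho_batches[:, a:b].mean(axis=1)
            se = float(batch.std(ddof=1) / math.sqrt(batch.shape[0]))
        else:
            se = float(np.sqrt(np.sum(self.mc_stderr[a:b] ** 2)) / (b - a))
        return m, se


def _omega_array(orf: Orf, rates: ElongationRateTable, params: SimParams) -> np.ndarray:
    return np.asarray(rates.omega(orf), dtype=float) * params.omega_scale


def simulate_density(
    orf: Orf | SlowWindowVariant,
    rates: ElongationRateTable,
    params: SimParams,
) -> DensityProfile:
    """Gillespie simulation of the exclusion process; deterministic given
    ``params.rng_seed``."""
    from ._kernel import gillespie_tasep

    window_start = None
    if isinstance(orf, SlowWindowVariant):
        window_start = orf.window_start
        orf = orf.to_orf()
    if orf.length < params.footprint:
        raise ValueError(
            f"ORF length {orf.length} shorter than footprint {params.footprint}"
        )
    omega = _omega_array(orf, rates, params)
    burn_in = params.resolved_burn_in(omega)
    batch_time = params.sample_time / params.n_batches
    rho_a, rho_c, term, n_events = gillespie_tasep(
        omega, params.alpha_on, params.alpha_off, params.gamma,
        params.footprint, burn_in, batch_time, params.n_batches,
        int(params.rng_seed) & 0x7FFFFFFF,
    )
    b = params.n_batches
    rho = rho_a.mean(axis=0)
    stderr = rho_a.std(axis=0, ddof=1) / math.sqrt(b)
    flux = float(term.mean())
    flux_stderr = float(term.std(ddof=1) / math.sqrt(b))
    return DensityProfile(
        orf_id=orf.id, rho=rho, mc_stderr=stderr, flux=flux,
        flux_stderr=flux_stderr, rho_cover=rho_c.mean(axis=0),
        window_start=window_start, rho_batches=rho_a,
        meta={"n_events": int(n_events), "burn_in": burn_in,
              "params": params.__dict__.copy()},
    )


# ---------------------------------------------------------------------------
# Exact oracle

def _enumerate_states(L: int, footprint: int, max_states: int) -> list[tuple[int, ...]]:
    """All configurations of A-sites in 1..L with pairwise gaps >= footprint."""
    states: list[tuple[int, ...]] = []

    def extend(prefix: tuple[int, ...], min_pos: int) -> None:
        states.append(prefix)
        if len(states) > max_states:
            raise ValueError(
                f"state space exceeds {max_states} configurations; "
                "use simulate_density instead"
            )
        for p in range(min_pos, L + 1):
            extend(prefix + (p,), p + footprint)

    extend((), 1)
    return states


def exact_density_small(
    orf: Orf,
    rates: ElongationRateTable,
    params: SimParams,
    max_states: int = 100_000,
) -> DensityProfile:
    """Stationary distribution of the full configuration-space generator.

    Mirrors the Gillespie dynamics exactly; feasible for short lattices only
    (the reachable-configuration count is capped at ``max_states``).
    """
    L = orf.length
    f = params.footprint
    if L < f:
        raise ValueError(f"ORF length {L} shorter than footprint {f}")
    omega = _omega_array(orf, rates, params)
    states = _enumerate_states(L, f, max_states)
    index = {s: i for i, s in enumerate(states)}
    n = len(states)

    rows, cols, vals = [], [], []

    def add(i: int, j: int, rate: float) -> None:
        rows.append(j)  # transposed: columns of Q become rows of Q^T
        cols.append(i)
        vals.append(rate)
        rows.append(i)
        cols.append(i)
        vals.append(-rate)

    for s, i in index.items():
        # state tuples are ascending A-site positions (rear to front)
        if not s or s[0] > f:
            add(i, index[(1,) + s], params.alpha_on)
        for k, p in enumerate(s):
            ahead = s[k + 1] if k + 1 < len(s) else None
            if p == L:
                add(i, index[s[:k]], params.alpha_off)  # frontmost terminates
            elif ahead is None or ahead - p > f:
                t = s[:k] + (p + 1,) + s[k + 1 :]
                add(i, index[t], omega[p])
            if params.gamma > 0:
                add(i, index[s[:k] + s[k + 1 :]], params.gamma)

    A = sp.csr_matrix(
        sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    ).tolil()
    A[-1, :] = 1.0  # replace one balance equation with normalization
    b = np.zeros(n)
    b[-1] = 1.0
    pi = spla.spsolve(sp.csr_matrix(A), b)
    pi = np.maximum(pi, 0.0)
    pi /= pi.sum()

    rho = np.zeros(L)
    rho_cover = np.zeros(L)
    p_front_last = 0.0
    for s, i in index.items():
        for p in s:
            rho[p - 1] += pi[i]
            rho_cover[p - 1 : min(p - 1 + f, L)] += pi[i]
        if s and s[-1] == L:
            p_front_last += pi[i]
    flux = params.alpha_off * p_front_last
    return DensityProfile(
        orf_id=orf.id, rho=rho, mc_stderr=np.zeros(L), flux=float(flux),
        flux_stderr=0.0, rho_cover=rho_cover,
        meta={"n_states": n, "exact": True},
    )


# ---------------------------------------------------------------------------
# Selection and lookup

def select_flux_matched(
    profiles: list[DensityProfile],
    reference: DensityProfile,
    k: int = 5,
) -> list[tuple[str, float]]:
    """The k variants whose flux deviates least (relatively) from the
    reference; ties break by window position ascending.  Returns
    ``(orf_id, relative_deviation)`` pairs sorted by deviation."""
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds number of profiles ({len(profiles)})")
    if reference.flux <= 0:
        raise ValueError("reference flux must be > 0")

    def sort_key(p: DensityProfile):
        dev = abs(p.flux - reference.flux) / reference.flux
        wpos = p.window_start if p.window_start is not None else 10**9
        return (dev, wpos, p.orf_id)

    ranked = sorted(profiles, key=sort_key)
    return [
        (p.orf_id, abs(p.flux - reference.flux) / reference.flux)
        for p in ranked[:k]
    ]


def density_at(
    profile: DensityProfile, codon: int | None = None, nt: int | None = None
) -> float:
    """Occupancy at a codon, or at the codon containing nucleotide ``nt``
    (codon = ceil(nt / 3))."""
    if (codon is None) == (nt is None):
        raise ValueError("give exactly one of codon= or nt=")
    if nt is not None:
        if not 1 <= nt <= 3 * profile.length:
            raise ValueError(f"nt position {nt} outside ORF")
        codon = -(-nt // 3)
    assert codon is not None
    if not 1 <= codon <= profile.length:
        raise ValueError(f"codon {codon} outside profile of length {profile.length}")
    return float(profile.rho[codon - 1])


# ---------------------------------------------------------------------------
# I/O

def write_profiles_tsv(profiles: list[DensityProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        for i in range(p.length):
            rows.append(
                {"orf_id": p.orf_id, "codon": i + 1, "rho": p.rho[i],
                 "stderr": p.mc_stderr[i]}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_profiles_tsv(path: str | Path) -> dict[str, DensityProfile]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for orf_id, g in df.groupby("orf_id", sort=False):
        g = g.sort_values("codon")
        out[str(orf_id)] = DensityProfile(
            orf_id=str(orf_id), rho=g["rho"].to_numpy(),
            mc_stderr=g["stderr"].to_numpy(), flux=float("nan"),
        )
    return out


def write_flux_summary(
    profiles: list[DensityProfile], params: SimParams, path: str | Path
) -> None:
    payload = {
        "params": params.__dict__.copy(),
        "fluxes": {
            p.orf_id: {"flux": p.flux, "flux_stderr": p.flux_stderr,
                       "window_start": p.window_start}
            for p in profiles
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))
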