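"""Monte-Carlo phase-plane sweeps and the cooperation index Ω.

The central observable is x_ffc, the average final fraction of cooperators:
each fixation run ends monomorphic (all-C or all-D, contributing 1 or 0) and
x_ffc is the mean over many runs on independently grown scale-free networks.
Sweeping x_ffc over the (T, S) rectangle yields a phase grid; Ω is the
fraction of that rectangle on which x_ffc exceeds one half (strictly), i.e.
a Riemann estimate of the area where cooperators win the evolutionary race.

Because punishment only translates the effective payoffs (T → T − p,
S → S − q), the Ω landscape over the (p, q) plane can be computed from a
single punishment-free sweep on an extended rectangle and re-windowed — the
translation mode of :func:`scan_pq_plane` — which is exact, not an
approximation, provided the per-run seeds are keyed to the extended-grid
point so that translated and direct simulations consume identical random
streams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from .engine import C, GameParams, default_max_steps
from .networks import Network, generate_ba_network

__all__ = [
    "SweepConfig", "PhaseGrid", "PQScan",
    "estimate_xffc", "sweep_ts_plane", "compute_omega", "scan_pq_plane",
]

_M64 = 0xFFFFFFFFFFFFFFFF


def mix_seed(*parts: int) -> int:
    """Deterministic splitmix64-style hash of integers onto [0, 2^31).

    Keys every run's RNG stream by (root_seed, grid indices, run index) so
    sweeps are order-independent and reproducible point by point.
    """
    h = 0x243F6A8885A308D3
    for v in parts:
        h ^= int(v) & _M64
        h = (h + 0x9E3779B97F4A7C15) & _M64
        h = ((h ^ (h >> 30)) * 0xBF58476D1CE4E5B9) & _M64
        h = ((h ^ (h >> 27)) * 0x94D049BB133111EB) & _M64
        h = h ^ (h >> 31)
    return h & 0x7FFFFFFF

_NET_TAG = 0x6E657473  # distinguishes network seeds from run seeds


@dataclass(frozen=True)
class SweepConfig:
    """Protocol for a phase-plane sweep.

    Defaults are the desk-scale protocol: 500-node Barabási–Albert networks
    (m = 2, so mean degree ≈ 4), 10 networks shared across grid points,
    200 fixation runs per point, selection intensity β = 0.25, and a 0.05
    grid step over 0 ≤ T ≤ 2, −1 ≤ S ≤ 0.
    """

    t_range: tuple[float, float] = (0.0, 2.0)
    s_range: tuple[float, float] = (-1.0, 0.0)
    grid_step: float = 0.05
    n_networks: int = 10
    runs_per_point: int = 200
    network_size: int = 500
    m_links: int = 2
    p: float = 0.0
    q: float = 0.0
    beta: float = 0.25
    root_seed: int = 0
    reuse_networks: bool = True
    max_steps: int | None = None

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.n_networks < 1 or self.runs_per_point < 1:
            raise ValueError("n_networks and runs_per_point must be positive")
        for lo, hi in (self.t_range, self.s_range):
            if hi <= lo:
                raise ValueError("ranges must be nondegenerate (lo < hi)")

    def axis(self, which: str) -> np.ndarray:
        lo, hi = self.t_range if which == "t" else self.s_range
        n = (hi - lo) / self.grid_step
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"{which}_range must be an integer multiple of grid_step")
        return lo + self.grid_step * np.arange(round(n) + 1)

    def game_params(self, T: float, S: float) -> GameParams:
        return GameParams(T=T, S=S, p=self.p, q=self.q, beta=self.beta)

    @property
    def effective_max_steps(self) -> int:
        return self.max_steps if self.max_steps is not None else default_max_steps(self.network_size)


@dataclass
class PhaseGrid:
    """x_ffc estimates on a rectangular (T, S) lattice.

    ``x_ffc[i, j]`` is the mean fixation outcome at ``(t_values[i],
    s_values[j])`` over the absorbed runs; ``n_unabsorbed`` counts runs that
    hit the step cap (excluded from the mean, since the observable is only
    defined at fixation).
    """

    t_values: np.ndarray
    s_values: np.ndarray
    x_ffc: np.ndarray
    n_runs: np.ndarray
    n_unabsorbed: np.ndarray
    config: SweepConfig | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        shape = (len(self.t_values), len(self.s_values))
        for name in ("x_ffc", "n_runs", "n_unabsorbed"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} must have shape {shape}")

    @property
    def grid_step(self) -> float:
        return float(self.t_values[1] - self.t_values[0]) if len(self.t_values) > 1 else 0.0

    def to_csv(self, path) -> None:
        tt, ss = np.meshgrid(self.t_values, self.s_values, indexing="ij")
        pd.DataFrame(
            {
                "T": tt.ravel(),
                "S": ss.ravel(),
                "x_ffc": self.x_ffc.ravel(),
                "n_runs": self.n_runs.ravel(),
                "n_unabsorbed": self.n_unabsorbed.ravel(),
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PhaseGrid":
        df = pd.read_csv(path)
        t_values = np.unique(df["T"].to_numpy())
        s_values = np.unique(df["S"].to_numpy())
        shape = (len(t_values), len(s_values))
        if len(df) != shape[0] * shape[1]:
            raise ValueError("CSV does not describe a full rectangular grid")
        df = df.sort_values(["T", "S"])
        return cls(
            t_values=t_values,
            s_values=s_values,
            x_ffc=df["x_ffc"].to_numpy().reshape(shape),
            n_runs=df["n_runs"].to_numpy().reshape(shape),
            n_unabsorbed=df["n_unabsorbed"].to_numpy().reshape(shape),
        )


def _networks_for(config: SweepConfig, i: int = 0, j: int = 0) -> list[Network]:
    """The batch of BA networks a grid point runs on.

    With ``reuse_networks`` (default) the same batch serves every point;
    otherwise each point grows its own batch from point-keyed seeds.
    """
    key = (config.root_seed, _NET_TAG) if config.reuse_networks else (config.root_seed, _NET_TAG, i, j)
    return [
        generate_ba_network(config.network_size, config.m_links, mix_seed(*key, k))
        for k in range(config.n_networks)
    ]


def _point_xffc(eff_T: float, eff_S: float, config: SweepConfig, i: int, j: int,
                networks: list[Network]) -> tuple[float, int]:
    """x_ffc and unabsorbed count at one grid point.

    ``eff_T, eff_S`` are the *effective* payoffs (fine and cost already
    subtracted). Runs are distributed round-robin over the network batch;
    run ``r`` is seeded by ``mix_seed(root_seed, i, j, r)`` so results are
    independent of execution order.
    """
    m = np.array([[1.0, eff_S], [eff_T, 0.0]])
    n = config.network_size
    template = np.repeat(np.array([0, 1], dtype=np.int8), [n // 2, n - n // 2])
    run_seeds = np.array(
        [mix_seed(config.root_seed, i, j, r) for r in range(config.runs_per_point)],
        dtype=np.uint32,
    )
    coop = 0
    absorbed_total = 0
    for k, net in enumerate(networks):
        sel = run_seeds[k :: len(networks)]
        if sel.size == 0:
            continue
        winners, absorbed = _kernels.batch_fixation(
            net.indptr, net.indices, template, m, config.beta,
            config.effective_max_steps, sel,
        )
        coop += int(np.sum((winners == C) & (absorbed == 1)))
        absorbed_total += int(absorbed.sum())
    n_unabs = config.runs_per_point - absorbed_total
    xffc = coop / absorbed_total if absorbed_total else np.nan
    return xffc, n_unabs


def estimate_xffc(T: float, S: float, config: SweepConfig,
                  point_index: tuple[int, int] = (0, 0)) -> float:
    """Estimate the average final fraction of cooperators at one (T, S) point.

    Deterministic given ``config.root_seed`` and ``point_index`` (the grid
    coordinates used to key the random streams). Warns if more than 1% of
    runs failed to absorb within the step cap.
    """
    i, j = point_index
    networks = _networks_for(config, i, j)
    xffc, n_unabs = _point_xffc(T - config.p, S - config.q, config, i, j, networks)
    if n_unabs > 0.01 * config.runs_per_point:
        warnings.warn(
            f"point (T={T}, S={S}): {n_unabs}/{config.runs_per_point} runs unabsorbed",
            stacklevel=2,
        )
    return xffc


def sweep_ts_plane(config: SweepConfig, progress=None) -> PhaseGrid:
    """Estimate x_ffc on the whole (T, S) lattice of ``config``.

    A pure function of the config: per-point seeds derive from the root seed
    and the grid indices, so the result is identical regardless of the order
    in which points are evaluated.
    """
    t_values = config.axis("t")
    s_values = config.axis("s")
    shape = (len(t_values), len(s_values))
    x_ffc = np.empty(shape)
    n_unabs = np.zeros(shape, dtype=np.int64)
    shared = _networks_for(config) if config.reuse_networks else None
    for i, T in enumerate(t_values):
        for j, S in enumerate(s_values):
            networks = shared if shared is not None else _networks_for(config, i, j)
            x_ffc[i, j], n_unabs[i, j] = _point_xffc(
                float(T) - config.p, float(S) - config.q, config, i, j, networks
            )
            if progress is not None:
                progress(i, j, float(T), float(S), x_ffc[i, j], int(n_unabs[i, j]))
    n_runs = np.full(shape, config.runs_per_point, dtype=np.int64)
    return PhaseGrid(t_values, s_values, x_ffc, n_runs, n_unabs, config=config)


def compute_omega(grid: PhaseGrid) -> float:
    """Cooperation index: fraction of grid points with x_ffc strictly > 0.5.

    Ties (exactly 0.5) and points with no absorbed runs count as
    non-cooperative.
    """
    if grid.x_ffc.size == 0:
        raise ValueError("empty grid")
    with np.errstate(invalid="ignore"):
        return float(np.mean(grid.x_ffc > 0.5))


def _offsets(values: np.ndarray, step: float, name: str) -> np.ndarray:
    off = np.asarray(values, dtype=float) / step
    if np.any(np.abs(off - np.round(off)) > 1e-9):
        raise ValueError(f"{name} values must be multiples of the grid step {step}")
    if np.any(np.asarray(values) < 0):
        raise ValueError(f"{name} values must be nonnegative")
    return np.round(off).astype(int)


@dataclass
class PQScan:
    """Ω landscape over the punishment (p) / cost (q) plane."""

    p_values: np.ndarray
    q_values: np.ndarray
    omega: np.ndarray
    omega_baseline: float
    base_grid: PhaseGrid | None = None

    def to_csv(self, path) -> None:
        pp, qq = np.meshgrid(self.p_values, self.q_values, indexing="ij")
        pd.DataFrame({"p": pp.ravel(), "q": qq.ravel(), "omega": self.omega.ravel()}).to_csv(
            path, index=False
        )


def scan_pq_plane(p_values, q_values, config: SweepConfig, mode: str = "translate",
                  base_grid: PhaseGrid | None = None, progress=None) -> PQScan:
    """Compute Ω(p, q) over a lattice of fine/cost pairs.

    Translation mode (default) exploits the exact payoff equivalence
    (T, S, p, q) ≡ (T − p, S − q, 0, 0): a single punishment-free sweep on
    the rectangle extended to T ∈ [t_min − max(p), t_max],
    S ∈ [s_min − max(q), s_max] is re-windowed for every (p, q). Direct mode
    re-simulates each (p, q) with seeds matched to the corresponding
    extended-grid points; it exists as a cross-check and must agree exactly.

    p and q values must be nonnegative multiples of the grid step.
    """
    p_values = np.atleast_1d(np.asarray(p_values, dtype=float))
    q_values = np.atleast_1d(np.asarray(q_values, dtype=float))
    step = config.grid_step
    p_off = _offsets(p_values, step, "p")
    q_off = _offsets(q_values, step, "q")

    ext = replace(
        config,
        p=0.0,
        q=0.0,
        t_range=(config.t_range[0] - float(p_values.max()), config.t_range[1]),
        s_range=(config.s_range[0] - float(q_values.max()), config.s_range[1]),
    )
    nt_win = len(config.axis("t"))
    ns_win = len(config.axis("s"))
    i0 = int(p_off.max())  # extended-grid index of the window origin
    j0 = int(q_off.max())

    if mode == "translate":
        if base_grid is None:
            base_grid = sweep_ts_plane(ext, progress=progress)
        else:
            if len(base_grid.t_values) < i0 + nt_win or len(base_grid.s_values) < j0 + ns_win:
                raise ValueError("base_grid does not cover the required extended region")
            if not (np.isclose(base_grid.t_values[i0], config.t_range[0])
                    and np.isclose(base_grid.s_values[j0], config.s_range[0])):
                raise ValueError("base_grid lattice does not align with the scan window")
        omega = np.empty((len(p_values), len(q_values)))
        with np.errstate(invalid="ignore"):
            coop = base_grid.x_ffc > 0.5
        for a, di in enumerate(p_off):
            for b, dj in enumerate(q_off):
                win = coop[i0 - di : i0 - di + nt_win, j0 - dj : j0 - dj + ns_win]
                omega[a, b] = float(np.mean(win))
    elif mode == "direct":
        # re-simulates every window point of every (p, q); the effective
        # payoffs are evaluated at the canonical extended-grid coordinates so
        # the comparison with translation mode is float-exact
        base_grid = None
        omega = np.empty((len(p_values), len(q_values)))
        t_ext = ext.axis("t")
        s_ext = ext.axis("s")
        shared = _networks_for(ext) if ext.reuse_networks else None
        for a, di in enumerate(p_off):
            for b, dj in enumerate(q_off):
                coop = 0
                for i in range(nt_win):
                    for j in range(ns_win):
                        ib, jb = i0 - di + i, j0 - dj + j  # matched extended-grid index
                        nets = shared if shared is not None else _networks_for(ext, ib, jb)
                        xffc, _ = _point_xffc(
                            float(t_ext[ib]), float(s_ext[jb]), ext, ib, jb, nets
                        )
                        coop += xffc > 0.5
                omega[a, b] = coop / (nt_win * ns_win)
    else:
        raise ValueError("mode must be 'translate' or 'direct'")

    zero = np.flatnonzero((p_off == 0))
    zeroq = np.flatnonzero((q_off == 0))
    if zero.size and zeroq.size:
        baseline = float(omega[zero[0], zeroq[0]])
    elif mode == "translate":
        win = (base_grid.x_ffc[i0 : i0 + nt_win, j0 : j0 + ns_win] > 0.5)
        baseline = float(np.mean(win))
    else:
        raise ValueError("direct mode requires (0, 0) in the scanned lattice for the baseline")
    return PQScan(p_values, q_values, omega, baseline, base_grid=base_grid)
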