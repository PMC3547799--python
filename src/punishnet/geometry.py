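"""Phase-plane geometry: the 50% edge-curve, its slope, and punishment regimes.

The boundary between cooperator- and defector-dominated regions of the
(T, S) plane is the x_ffc = 0.5 level set ("edge-curve" λ).  Because
punishment translates the plane by the vector (p, q), the local slope
σ = dS/dT of λ decides whether a given fine/cost pair helps or harms:
moving the plane along a direction shallower than the shallowest tangent
(q/p < σ₁) enlarges the cooperative region everywhere, steeper than the
steepest tangent (but still with q < p) shrinks it, and in between the
effect depends on where in the plane the population sits.

Contours are extracted with marching squares (bilinear interpolation on the
grid) via scikit-image; slopes by sliding-window least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .sweep import PhaseGrid, PQScan

__all__ = [
    "EdgeCurve", "extract_edge_curve", "slope_along_curve", "choose_slope_window",
    "classify_regime", "fit_separation_line", "SeparationFit",
]

LEVEL = 0.5


@dataclass
class EdgeCurve:
    """Ordered points of the x_ffc = 0.5 level set with local slope estimates.

    ``points`` is (n, 2) with columns (T, S), ordered by increasing T;
    ``slope`` holds the local dS/dT where a full fitting window exists and
    NaN at the truncated ends.
    """

    points: np.ndarray
    slope: np.ndarray | None = None

    @property
    def is_empty(self) -> bool:
        return self.points.shape[0] == 0

    @property
    def sigma_bounds(self) -> tuple[float, float]:
        """(min, max) of the slope over the curve interior."""
        if self.slope is None:
            raise ValueError("slopes not computed; call slope_along_curve first")
        valid = self.slope[np.isfinite(self.slope)]
        if valid.size == 0:
            raise ValueError("no valid slope estimates")
        return float(valid.min()), float(valid.max())

    def to_csv(self, path) -> None:
        import pandas as pd

        slope = self.slope if self.slope is not None else np.full(len(self.points), np.nan)
        pd.DataFrame({"T": self.points[:, 0], "S": self.points[:, 1], "slope": slope}).to_csv(
            path, index=False
        )


def extract_edge_curve(grid: PhaseGrid) -> EdgeCurve:
    """Extract the x_ffc = 0.5 contour from a phase grid.

    Marching squares with linear interpolation along cell edges; of the
    connected contour components the longest (most points) is returned,
    ordered by increasing T.  Grid values exactly at 0.5 are treated as
    below the level, consistent with the strict inequality in Ω.  An empty
    curve signals that the grid never crosses 0.5.
    """
    field = np.asarray(grid.x_ffc, dtype=float)
    # ties at the level count as "below": nudge them off the contour
    field = np.where(field == LEVEL, LEVEL - 1e-12, field)
    field = np.nan_to_num(field, nan=0.0)
    contours = measure.find_contours(field, LEVEL)
    if not contours:
        return EdgeCurve(points=np.empty((0, 2)))
    best = max(contours, key=len)
    t0 = grid.t_values[0]
    s0 = grid.s_values[0]
    dt = grid.t_values[1] - grid.t_values[0] if len(grid.t_values) > 1 else 1.0
    ds = grid.s_values[1] - grid.s_values[0] if len(grid.s_values) > 1 else 1.0
    pts = np.column_stack([t0 + best[:, 0] * dt, s0 + best[:, 1] * ds])
    if pts[-1, 0] < pts[0, 0]:
        pts = pts[::-1]
    return EdgeCurve(points=pts)


def slope_along_curve(curve: EdgeCurve, window: int = 5) -> EdgeCurve:
    """Local slope dS/dT of the edge-curve by sliding-window least squares.

    At each point with a full centered window of ``window`` contour points,
    a straight line S = a·T + b is fitted by ordinary least squares and its
    slope recorded; the truncated ends are left NaN and excluded from the
    (σ_min, σ_max) bounds.  Windows with no spread in T (vertical runs of
    contour points) yield NaN as well.

    Returns a new EdgeCurve with the slope array filled in.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    n = len(curve.points)
    if n < window:
        raise ValueError(f"curve has {n} points, need at least window={window}")
    half = window // 2
    slope = np.full(n, np.nan)
    T = curve.points[:, 0]
    S = curve.points[:, 1]
    for i in range(half, n - half):
        t = T[i - half : i + half + 1]
        s = S[i - half : i + half + 1]
        tc = t - t.mean()
        denom = float(tc @ tc)
        if denom < 1e-20:
            continue
        slope[i] = float(tc @ (s - s.mean())) / denom
    return EdgeCurve(points=curve.points.copy(), slope=slope)


def choose_slope_window(grid: PhaseGrid, curve: EdgeCurve, target_se: float = 0.05,
                        min_window: int = 5) -> int:
    """Slope-fit window sized so Monte-Carlo noise does not masquerade as slope.

    Contour points on a Monte-Carlo phase grid scatter around the true
    edge-curve by roughly δS = δx / |∂x/∂S|, where δx is the binomial
    standard error of a grid value at the 0.5 level and the gradient is
    measured from the grid itself near the contour.  An OLS slope over a
    window spanning w grid columns of width Δt then carries a standard error
    of about (δS/Δt)·sqrt(12 / (w(w²−1))) — adjacent contour points share
    grid vertices, so the column, not the point, is the unit of independent
    information.  This returns the smallest odd point-window pushing that
    propagated SE below ``target_se``, capped at a quarter of the curve so
    genuine curvature is not smoothed away.  On clean grids (many runs or a
    steep transition) it falls back to ``min_window``.
    """
    n = len(curve.points)
    if n < min_window:
        raise ValueError(f"curve has {n} points, need at least {min_window}")
    if len(grid.s_values) < 2 or len(grid.t_values) < 2:
        raise ValueError("grid too small to estimate the transition gradient")
    n_runs = max(float(np.median(grid.n_runs)), 1.0)
    delta_x = 0.5 / np.sqrt(n_runs)  # binomial SE at the 0.5 level
    ds = float(grid.s_values[1] - grid.s_values[0])
    grad_s = np.gradient(np.nan_to_num(grid.x_ffc, nan=0.0), ds, axis=1)
    near = np.abs(np.nan_to_num(grid.x_ffc, nan=0.0) - LEVEL) < 0.25
    if not near.any():
        return min_window
    grad = float(np.median(np.abs(grad_s[near])))
    if grad <= 0:
        return min_window
    delta_s = delta_x / grad
    step_t = grid.grid_step
    t_span = float(curve.points[:, 0].max() - curve.points[:, 0].min())
    if step_t <= 0 or t_span <= 0:
        return min_window
    w_cols = 3
    while (delta_s / step_t) * np.sqrt(12.0 / (w_cols * (w_cols**2 - 1))) > target_se:
        w_cols += 2
    pts_per_col = n / (t_span / step_t)
    window = int(round(w_cols * pts_per_col))
    window += (window + 1) % 2  # make odd
    cap = max(min_window, 2 * (n // 8) + 1)
    return int(np.clip(window, min_window, cap))


def classify_regime(p: float, q: float, sigma_lo: float, sigma_hi: float) -> str:
    """Classify a fine/cost pair by its overall effect on cooperation.

    With σ₁ (σ₂) the smallest (largest) slope of the edge-curve:

    - ``q/p < σ₁`` → ``"beneficial_everywhere"``: the translation enlarges
      the cooperative region at every point of the plane;
    - ``σ₂ < q/p < 1`` → ``"detrimental"``: cooperation is set back even
      though the punishment is still altruistic;
    - ``σ₁ ≤ q/p ≤ σ₂`` → ``"mixed"``: helps in some regions, harms others;
    - ``q ≥ p`` → ``"not_altruistic"``: outside the altruistic-punishment
      regime p > q.
    """
    if p < 0 or q < 0:
        raise ValueError("p and q must be nonnegative")
    if not (0 <= sigma_lo <= sigma_hi):
        raise ValueError("need 0 <= sigma_lo <= sigma_hi")
    if q >= p:
        return "not_altruistic"
    ratio = q / p
    if ratio < sigma_lo:
        return "beneficial_everywhere"
    if ratio > sigma_hi:
        return "detrimental"
    return "mixed"


@dataclass
class SeparationFit:
    """Through-origin line fit q = slope · p to the Ω-neutral contour."""

    slope: float
    points: np.ndarray
    rms_residual: float


def fit_separation_line(scan: PQScan, omega_baseline: float | None = None) -> SeparationFit:
    """Fit the Ω(p, q) = Ω(0, 0) contour with a line through the origin.

    The level set separates fine/cost pairs that enhance overall cooperation
    from those that diminish it; since (p, q) = (0, 0) is exactly neutral,
    the separating line is constrained through the origin, and its slope is
    the critical cost-over-fine ratio.

    Residual diagnostics: RMS of the perpendicular-free residual q − s·p over
    the contour points.
    """
    omega0 = scan.omega_baseline if omega_baseline is None else float(omega_baseline)
    om = np.asarray(scan.omega, dtype=float)
    if not (om.max() > omega0 and om.min() < omega0):
        raise ValueError("omega matrix does not cross the baseline level")
    contours = measure.find_contours(om, omega0)
    if not contours:
        raise ValueError("no separation contour found")
    best = max(contours, key=len)
    p0, q0 = scan.p_values[0], scan.q_values[0]
    dp = scan.p_values[1] - scan.p_values[0] if len(scan.p_values) > 1 else 1.0
    dq = scan.q_values[1] - scan.q_values[0] if len(scan.q_values) > 1 else 1.0
    pts = np.column_stack([p0 + best[:, 0] * dp, q0 + best[:, 1] * dq])
    pp = pts[:, 0]
    qq = pts[:, 1]
    denom = float(pp @ pp)
    if denom <= 0:
        raise ValueError("degenerate contour (all points at p = 0)")
    slope = float(pp @ qq) / denom
    resid = qq - slope * pp
    return SeparationFit(slope=slope, points=pts, rms_residual=float(np.sqrt(np.mean(resid**2))))
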