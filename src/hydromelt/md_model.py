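"""Segmented model of the melting diagram and its differential form.

The melting diagram of a protein solution has three regimes on the
normalized fundamental-temperature axis:

1. a sharp onset step at the "melting point" of protein-bound water,
   where the almost identically bound first-shell molecules start to
   rotate within a very narrow energy range;
2. a plateau [T_fno, T_fne] where no new water mobilizes — evidence of
   a homogeneous (equipotential) first hydration shell;
3. a heterogeneous rise above T_fne described by a short power series

       n = A + B·(T_fn − T_fn1) + C·(T_fn − T_fn2)² + …

   whose differential form

       Δn/ΔT_fn = B + 2C·(T_fn − T_fn2) + …

   is the distribution of potential-energy barriers opposing the motion
   of protein-bound water (the DMD).

A linear term's intercept folds into the plateau level A, so (B, T_fn1)
and A are not jointly identifiable; the fit is parameterized with both
anchors at T_fne (n = A + B·u + C·u², u = T_fn − T_fne), which makes
continuity n(T_fne) = A exact by construction and is reported back in
the power-series convention with T_fn1 = T_fn2 = T_fne.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar, nnls

from .errors import InvalidInputError, NoMeltingError, NoOnsetError
from .melting_diagram import MeltingDiagram
from .units_scales import CELSIUS_OFFSET

__all__ = [
    "MdFit",
    "DmdCurve",
    "OnsetDetection",
    "PlateauDetection",
    "estimate_noise_sd",
    "detect_onset",
    "detect_plateau",
    "fit_melting_model",
    "fit_md",
    "model_n",
    "dmd_analytic",
    "dmd_numeric",
    "integrate_dmd",
]

_EPS = 1e-12


@dataclass(frozen=True)
class MdFit:
    """Fitted onset + plateau + power-series melting-diagram model."""

    onset_t_fn: float
    A: float
    t_fno: float
    t_fne: float
    B: float
    C: float
    t_fn1: float
    t_fn2: float
    D: float = 0.0  # cubic coefficient, 0 unless a cubic was selected
    param_errors: dict = field(default_factory=dict)
    fit_window: tuple[float, float] = (0.0, 1.0)
    rss: float = np.nan
    order: int = 2
    plateau_mean: float = np.nan  # literal unweighted plateau average
    n_plateau_points: int = 0
    n_rise_points: int = 0
    warnings: tuple[str, ...] = ()

    def __post_init__(self):
        if not (self.onset_t_fn <= self.t_fno + 1e-9 <= self.t_fne + 2e-9):
            raise InvalidInputError("require onset_t_fn <= t_fno <= t_fne")
        if self.t_fne >= 1.0:
            raise InvalidInputError("t_fne must be < 1")
        if self.A < 0:
            raise InvalidInputError("plateau level A must be >= 0")

    def to_json_dict(self) -> dict:
        return {
            "onset_t_fn": self.onset_t_fn,
            "onset_celsius": self.onset_t_fn * CELSIUS_OFFSET - CELSIUS_OFFSET,
            "A": self.A,
            "t_fno": self.t_fno,
            "t_fne": self.t_fne,
            "B": self.B,
            "C": self.C,
            "D": self.D,
            "t_fn1": self.t_fn1,
            "t_fn2": self.t_fn2,
            "order": self.order,
            "param_errors": self.param_errors,
            "fit_window": list(self.fit_window),
            "rss": self.rss,
            "plateau_mean": self.plateau_mean,
            "n_plateau_points": self.n_plateau_points,
            "n_rise_points": self.n_rise_points,
            "warnings": list(self.warnings),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "MdFit":
        return cls(
            onset_t_fn=d["onset_t_fn"],
            A=d["A"],
            t_fno=d["t_fno"],
            t_fne=d["t_fne"],
            B=d["B"],
            C=d["C"],
            D=d.get("D", 0.0),
            t_fn1=d["t_fn1"],
            t_fn2=d["t_fn2"],
            param_errors=d.get("param_errors", {}),
            fit_window=tuple(d.get("fit_window", (0.0, 1.0))),
            rss=d.get("rss", np.nan),
            order=d.get("order", 2),
            plateau_mean=d.get("plateau_mean", np.nan),
            n_plateau_points=d.get("n_plateau_points", 0),
            n_rise_points=d.get("n_rise_points", 0),
            warnings=tuple(d.get("warnings", ())),
        )


@dataclass
class DmdCurve:
    """Differential melting diagram Δn/ΔT_fn on a T_fn grid.

    ``kind`` is ``"analytic"`` (derivative of a fitted model; carries
    the fit so integrals can be taken in closed form) or ``"numeric"``
    (model-free centered finite differences of the data).
    """

    t_fn: np.ndarray
    dn_dtfn: np.ndarray
    kind: str
    segments: list[dict] = field(default_factory=list)
    fit: MdFit | None = None
    onset_bin_width: float | None = None


@dataclass(frozen=True)
class OnsetDetection:
    t_fn: float
    celsius: float
    index_above: int  # index of the first point above threshold
    threshold: float
    noise_sd: float


@dataclass(frozen=True)
class PlateauDetection:
    t_fno: float
    t_fne: float
    start_index: int  # into the MD arrays
    end_index: int
    degenerate: bool
    onset: OnsetDetection
    slope_tol: float

    def as_tuple(self) -> tuple[float, float]:
        return (self.t_fno, self.t_fne)


def estimate_noise_sd(md: MeltingDiagram) -> float:
    """Point noise s.d. of n: stated errors if present, otherwise a
    robust estimate from consecutive differences (MAD/√2), which the
    onset step and the slow rise barely perturb."""
    if md.n_err is not None and np.any(md.n_err > 0):
        return float(np.median(md.n_err[md.n_err > 0]))
    d = np.diff(md.n[md.reliable_mask()])
    if len(d) == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def detect_onset(md: MeltingDiagram, threshold: float | None = None) -> OnsetDetection:
    """Locate the melting onset of protein-bound water.

    The threshold (default 3× the point noise above zero) selects the
    first crossing interval; the reported onset is the linear
    interpolation to the half-rise level of that interval, which
    localizes a sharp step at its center instead of at the lower
    bracketing point.
    """
    mask = md.reliable_mask()
    t = md.t_fn[mask]
    n = md.n[mask]
    idx_map = np.flatnonzero(mask)
    noise = estimate_noise_sd(md)
    if threshold is None:
        # floor: fractions below 1e-6 are physically zero (numerical
        # residue of the decomposition, not mobile water)
        threshold = max(3.0 * noise, 1e-6)
    above = n > threshold
    if not np.any(above):
        raise NoMeltingError(f"no point exceeds the onset threshold {threshold:.4g}")
    i = int(np.argmax(above))
    if i == 0:
        raise NoOnsetError("all points already above the onset threshold")
    level = max(threshold, 0.5 * (n[i - 1] + n[i]))
    denom = n[i] - n[i - 1]
    if denom <= 0:
        onset_t = t[i]
    else:
        onset_t = t[i - 1] + (level - n[i - 1]) / denom * (t[i] - t[i - 1])
        onset_t = float(np.clip(onset_t, t[i - 1], t[i]))
    return OnsetDetection(
        t_fn=float(onset_t),
        celsius=float(onset_t * CELSIUS_OFFSET - CELSIUS_OFFSET),
        index_above=int(idx_map[i]),
        threshold=float(threshold),
        noise_sd=noise,
    )


def _segmented_rss(t, n, tb, rise_mask):
    """RSS of (plateau mean) + (nonnegative linear+quadratic rise
    anchored at tb), with membership given by ``rise_mask``."""
    plateau = ~rise_mask
    n_plat = n[plateau]
    a = float(np.mean(n_plat))
    rss = float(np.sum((n_plat - a) ** 2))
    if np.any(rise_mask):
        u = t[rise_mask] - tb
        y = np.ascontiguousarray(n[rise_mask] - a)
        basis = np.column_stack([u, u * u])
        coef, _ = nnls(basis, y)
        resid = y - basis @ coef
        rss += float(resid @ resid)
    return rss


def detect_plateau(
    md: MeltingDiagram,
    slope_tol: float | None = None,
    min_span: float = 0.02,
    onset: OnsetDetection | None = None,
    refine: bool = True,
) -> PlateauDetection:
    """Find the plateau [T_fno, T_fne] of a melting diagram.

    Two stages.  (1) Run-based slope thresholding: the longest
    contiguous run of points after the onset whose local
    finite-difference slope magnitude stays within ``slope_tol``
    (default 3× the noise-propagated slope, 3·√2·σ_n/Δt).  If no run
    spans at least ``min_span``, the plateau is degenerate —
    T_fno = T_fne = onset, the no-plateau IDP limit, a valid result.
    (2) Refinement of T_fne (the weak start of the heterogeneous rise
    sits far below the slope threshold on realistic grids): the
    continuity-constrained segmented model — plateau mean plus a
    nonnegative linear+quadratic rise anchored at the candidate
    boundary — is profiled over grid candidates inside the run, then
    the boundary is optimized continuously between neighboring grid
    points by minimizing the same residual sum of squares.
    """
    if onset is None:
        onset = detect_onset(md)
    mask = md.reliable_mask()
    mask &= np.arange(len(md)) >= onset.index_above
    t = md.t_fn[mask]
    n = md.n[mask]
    idx_map = np.flatnonzero(mask)
    m = len(t)
    if m < 3:
        raise InvalidInputError("need at least 3 points above the onset")

    noise = onset.noise_sd
    h = float(np.median(np.diff(t)))
    if slope_tol is None:
        slope_tol = max(3.0 * np.sqrt(2.0) * noise / h, _EPS / h)

    slopes = np.diff(n) / np.diff(t)
    ok = np.abs(slopes) <= slope_tol
    degenerate = PlateauDetection(
        t_fno=onset.t_fn,
        t_fne=onset.t_fn,
        start_index=onset.index_above,
        end_index=onset.index_above,
        degenerate=True,
        onset=onset,
        slope_tol=float(slope_tol),
    )

    # longest qualifying run, by span in t_fn
    best = None  # (span, i_start_pt, i_end_pt)
    i = 0
    while i < len(ok):
        if ok[i]:
            j = i
            while j + 1 < len(ok) and ok[j + 1]:
                j += 1
            span = t[j + 1] - t[i]
            if best is None or span > best[0]:
                best = (span, i, j + 1)
            i = j + 1
        i += 1
    if best is None or best[0] < min_span:
        return degenerate
    _, i0, e0 = best

    if not refine:
        return PlateauDetection(
            t_fno=float(t[i0]),
            t_fne=float(t[e0]),
            start_index=int(idx_map[i0]),
            end_index=int(idx_map[e0]),
            degenerate=False,
            onset=onset,
            slope_tol=float(slope_tol),
        )

    # stage 2: profile the segmented-model RSS over candidate boundaries
    tt, nn = t[i0:], n[i0:]
    mm = len(tt)
    j_hi = min(e0 - i0 + 1, mm - 1)
    candidates = range(1, j_hi + 1)
    rss_grid = []
    for j in candidates:
        rise = np.zeros(mm, dtype=bool)
        rise[j + 1 :] = True
        rss_grid.append(_segmented_rss(tt, nn, tt[j], rise))
    rss_grid = np.asarray(rss_grid)
    rss_min = rss_grid.min()
    # deterministic tie-break toward the longest plateau
    tied = np.flatnonzero(rss_grid <= rss_min * (1 + 1e-9) + 1e-300)
    jbest = list(candidates)[tied[-1]]
    best_tb = float(tt[jbest])
    best_rss = float(rss_grid[tied[-1]])

    # continuous refinement in the two neighboring inter-point intervals
    for k in (jbest - 1, jbest):
        if k < 1 or k + 1 >= mm:
            continue
        rise = np.zeros(mm, dtype=bool)
        rise[k + 1 :] = True

        def rss_of(tb, rise=rise):
            return _segmented_rss(tt, nn, tb, rise)

        res = minimize_scalar(
            rss_of,
            bounds=(float(tt[k]), float(tt[k + 1])),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if res.fun < best_rss - 1e-300 or (res.fun <= best_rss * (1 + 1e-9) and res.x > best_tb):
            best_rss = float(res.fun)
            best_tb = float(res.x)

    end_pt = int(np.searchsorted(tt, best_tb + 1e-12, side="right") - 1)
    end_pt = max(end_pt, 1)
    return PlateauDetection(
        t_fno=float(tt[0]),
        t_fne=float(best_tb),
        start_index=int(idx_map[i0]),
        end_index=int(idx_map[i0 + end_pt]),
        degenerate=False,
        onset=onset,
        slope_tol=float(slope_tol),
    )


def fit_melting_model(
    md: MeltingDiagram,
    plateau: PlateauDetection | tuple[float, float],
    max_order: int = 2,
    onset: OnsetDetection | float | None = None,
    plateau_stat: str = "mean",
    bic_margin: float = 6.0,
) -> MdFit:
    """Fit the plateau + power-series model to a melting diagram.

    The plateau level A is the unweighted average of the plateau points
    (``plateau_stat="mean"``, the default) and the rise coefficients are
    fitted by least squares against it with the continuity constraint
    n(T_fne) = A built into the parameterization.
    ``plateau_stat="joint"`` instead estimates A as the shared intercept
    of plateau and rise rows in one least-squares system; with realistic
    rise curvature the two estimators are statistically equivalent (the
    rise rows extrapolate weakly to the boundary), so the simpler
    plateau average is the default.  The quadratic order suffices in
    practice; a cubic is admitted only when it improves the BIC by
    ``bic_margin``.
    """
    if plateau_stat not in ("joint", "mean"):
        raise InvalidInputError("plateau_stat must be 'joint' or 'mean'")
    if isinstance(plateau, PlateauDetection):
        t_fno, t_fne = plateau.t_fno, plateau.t_fne
        if onset is None:
            onset = plateau.onset
        degenerate = plateau.degenerate
    else:
        t_fno, t_fne = plateau
        degenerate = t_fne <= t_fno + _EPS
    if onset is None:
        onset = detect_onset(md)
    onset_t = onset.t_fn if isinstance(onset, OnsetDetection) else float(onset)

    notes: list[str] = []
    mask = md.reliable_mask()
    t = md.t_fn[mask]
    n = md.n[mask]

    if degenerate:
        # IDP limit: no plateau; anchor the rise at the onset-step top
        plat_mask = (t >= onset_t - _EPS) & (t <= t[t >= onset_t - _EPS][0] + _EPS)
        notes.append("degenerate plateau: A taken at the onset-step top")
        t_fne_eff = max(t_fno, onset_t)
    else:
        plat_mask = (t >= t_fno - _EPS) & (t <= t_fne + _EPS)
        t_fne_eff = t_fne
    rise_mask = t > t_fne_eff + _EPS

    n_plat = n[plat_mask]
    if len(n_plat) == 0:
        raise InvalidInputError("no points on the plateau")
    plateau_mean = float(np.mean(n_plat))
    plateau_sem = float(np.std(n_plat, ddof=1) / np.sqrt(len(n_plat))) if len(n_plat) > 1 else 0.0

    u = t[rise_mask] - t_fne_eff
    y = n[rise_mask]
    r = len(u)

    def solve(order: int, stat: str):
        """Returns (A, coeffs, rss, cov, n_params)."""
        if stat == "mean":
            a = plateau_mean
            basis = np.column_stack([u**k for k in range(1, order + 1)])
            coef, *_ = np.linalg.lstsq(basis, y - a, rcond=None)
            resid_r = (y - a) - basis @ coef
            rss = float(np.sum((n_plat - a) ** 2) + resid_r @ resid_r)
            dof = max(len(n_plat) + r - (1 + order), 1)
            sigma2 = rss / dof
            try:
                cov = sigma2 * np.linalg.inv(basis.T @ basis)
            except np.linalg.LinAlgError:
                cov = np.full((order, order), np.nan)
            errs = {"A": plateau_sem}
            for k in range(order):
                errs["BCD"[k]] = float(np.sqrt(max(cov[k, k], 0.0)))
            return a, coef, rss, errs, 1 + order
        # joint: A is a shared intercept for plateau and rise rows
        rows = len(n_plat) + r
        X = np.zeros((rows, 1 + order))
        X[:, 0] = 1.0
        for k in range(1, order + 1):
            X[len(n_plat) :, k] = u**k
        yy = np.concatenate([n_plat, y])
        coef, *_ = np.linalg.lstsq(X, yy, rcond=None)
        resid = yy - X @ coef
        rss = float(resid @ resid)
        dof = max(rows - (1 + order), 1)
        sigma2 = rss / dof
        try:
            cov = sigma2 * np.linalg.inv(X.T @ X)
        except np.linalg.LinAlgError:
            cov = np.full((1 + order, 1 + order), np.nan)
        errs = {"A": float(np.sqrt(max(cov[0, 0], 0.0)))}
        for k in range(order):
            errs["BCD"[k]] = float(np.sqrt(max(cov[k + 1, k + 1], 0.0)))
        return float(coef[0]), coef[1:], rss, errs, 1 + order

    if r == 0:
        A, coeffs = plateau_mean, np.zeros(2)
        rss = float(np.sum((n_plat - A) ** 2))
        errs = {"A": plateau_sem, "B": 0.0, "C": 0.0}
        order = 0
        notes.append("no rise points above the plateau: B = C = 0")
    else:
        order = min(max_order, 2)
        if r < order:
            order = max(r, 1)
            notes.append(f"under-determined rise segment: falling back to order {order}")
        A, coeffs, rss, errs, p = solve(order, plateau_stat)
        if max_order >= 3 and r >= 4:
            A3, coeffs3, rss3, errs3, p3 = solve(3, plateau_stat)
            N = len(n_plat) + r
            bic2 = N * np.log(max(rss, 1e-300) / N) + p * np.log(N)
            bic3 = N * np.log(max(rss3, 1e-300) / N) + p3 * np.log(N)
            if bic3 < bic2 - bic_margin:
                A, coeffs, rss, errs, order = A3, coeffs3, rss3, errs3, 3
                notes.append("cubic term admitted by BIC")

    coeffs = np.atleast_1d(np.asarray(coeffs, dtype=float))
    B = float(coeffs[0]) if len(coeffs) >= 1 else 0.0
    C = float(coeffs[1]) if len(coeffs) >= 2 else 0.0
    D = float(coeffs[2]) if len(coeffs) >= 3 else 0.0

    # plateau boundaries are localized to about half the grid spacing
    h_half = float(np.median(np.diff(t))) / 2.0 if len(t) > 1 else 0.0
    errs.setdefault("t_fno", h_half)
    errs.setdefault("t_fne", h_half)

    window_hi = float(t[rise_mask].max()) if r else t_fne_eff
    # monotonicity check of the fitted rise on the window
    if r:
        ugrid = np.linspace(0, window_hi - t_fne_eff, 64)
        deriv = B + 2 * C * ugrid + 3 * D * ugrid**2
        if np.any(deriv < -_EPS):
            notes.append("model-validity warning: fitted rise is not monotone nondecreasing")
            warnings.warn(notes[-1], stacklevel=2)

    return MdFit(
        onset_t_fn=float(min(onset_t, t_fno)),
        A=float(max(A, 0.0)),
        t_fno=float(t_fno),
        t_fne=float(t_fne_eff),
        B=B,
        C=C,
        D=D,
        t_fn1=float(t_fne_eff),
        t_fn2=float(t_fne_eff),
        param_errors=errs,
        fit_window=(float(t_fno), window_hi),
        rss=rss,
        order=order if r else 2,
        plateau_mean=plateau_mean,
        n_plateau_points=int(len(n_plat)),
        n_rise_points=int(r),
        warnings=tuple(notes),
    )


def fit_md(
    md: MeltingDiagram,
    slope_tol: float | None = None,
    min_span: float = 0.02,
    onset_threshold: float | None = None,
    max_order: int = 2,
    plateau_stat: str = "mean",
) -> MdFit:
    """Convenience pipeline: detect onset → detect plateau → fit."""
    onset = detect_onset(md, threshold=onset_threshold)
    plateau = detect_plateau(md, slope_tol=slope_tol, min_span=min_span, onset=onset)
    return fit_melting_model(
        md, plateau, max_order=max_order, onset=onset, plateau_stat=plateau_stat
    )


def model_n(fit: MdFit, t_fn) -> np.ndarray:
    """Evaluate the fitted melting-diagram model n(T_fn).

    The onset step is treated as instantaneous at ``onset_t_fn`` (its
    finite rendering lives in the DMD's onset bar)."""
    t = np.asarray(t_fn, dtype=float)
    u = t - fit.t_fn2
    rise = fit.A + fit.B * (t - fit.t_fn1) + fit.C * u**2 + fit.D * u**3
    out = np.where(t < fit.onset_t_fn, 0.0, np.where(t <= fit.t_fne, fit.A, rise))
    return float(out) if np.ndim(t_fn) == 0 else out


def dmd_analytic(fit: MdFit, grid, onset_bin_width: float | None = None) -> DmdCurve:
    """Analytic differential melting diagram of a fitted model.

    The onset delta is rendered as a finite bar of width one grid bin
    with area A; the plateau contributes 0; above T_fne the curve is
    B + 2C·(T_fn − T_fn2) (+ 3D·u² if a cubic was admitted).
    """
    grid = np.asarray(grid, dtype=float)
    if len(grid) < 2 or not np.all(np.diff(grid) > 0):
        raise InvalidInputError("grid must be strictly increasing with >= 2 points")
    if onset_bin_width is None:
        onset_bin_width = float(np.median(np.diff(grid)))
    w = float(onset_bin_width)
    lo, hi = fit.fit_window
    if grid[0] < fit.onset_t_fn - w or grid[-1] > max(hi, 1.0) + _EPS:
        warnings.warn(
            "grid extends beyond the fit window; values outside are model extrapolation",
            stacklevel=2,
        )
    u = grid - fit.t_fn2
    vals = np.where(
        grid < fit.onset_t_fn,
        0.0,
        np.where(
            grid < fit.onset_t_fn + w,
            fit.A / w,
            np.where(grid <= fit.t_fne, 0.0, fit.B + 2 * fit.C * u + 3 * fit.D * u**2),
        ),
    )
    top = float(grid[-1])
    ue = max(top - fit.t_fne, 0.0)
    segments = [
        {"name": "onset", "lo": fit.onset_t_fn, "hi": fit.onset_t_fn + w, "area": fit.A},
        {"name": "plateau", "lo": fit.onset_t_fn + w, "hi": fit.t_fne, "area": 0.0},
        {
            "name": "heterogeneous",
            "lo": fit.t_fne,
            "hi": top,
            "area": fit.B * ue + fit.C * ue**2 + fit.D * ue**3,
        },
    ]
    return DmdCurve(
        t_fn=grid, dn_dtfn=vals, kind="analytic", segments=segments, fit=fit, onset_bin_width=w
    )


def dmd_numeric(md: MeltingDiagram) -> DmdCurve:
    """Model-free DMD: centered finite differences at interior points.

    Serves as the independent oracle for :func:`dmd_analytic`."""
    if len(md) < 3:
        raise InvalidInputError("need at least 3 points for centered differences")
    t, n = md.t_fn, md.n
    deriv = (n[2:] - n[:-2]) / (t[2:] - t[:-2])
    return DmdCurve(t_fn=t[1:-1].copy(), dn_dtfn=deriv, kind="numeric")


def _analytic_integral(fit: MdFit, w: float, a: float, b: float) -> float:
    """Closed-form integral of the analytic DMD (bar + polynomial)."""
    total = 0.0
    bar_lo, bar_hi = fit.onset_t_fn, fit.onset_t_fn + w
    overlap = max(0.0, min(b, bar_hi) - max(a, bar_lo))
    total += fit.A / w * overlap
    lo = max(a, fit.t_fne)
    if b > lo:

        def anti(x):
            u = x - fit.t_fn2
            return fit.B * u + fit.C * u**2 + fit.D * u**3

        total += anti(b) - anti(lo)
    return total


def integrate_dmd(dmd: DmdCurve, a: float, b: float) -> float:
    """Area under the DMD between T_fn = a and b.

    Closed form for analytic curves; trapezoidal rule (with endpoint
    interpolation) for numeric ones.  The area over [T_fne, ≈1] is the
    heterogeneous-region water fraction n_he.
    """
    if not a < b:
        raise InvalidInputError("require a < b")
    if dmd.kind == "analytic" and dmd.fit is not None:
        return _analytic_integral(dmd.fit, dmd.onset_bin_width, a, b)
    t, v = dmd.t_fn, dmd.dn_dtfn
    lo = max(a, float(t[0]))
    hi = min(b, float(t[-1]))
    if hi <= lo:
        return 0.0
    inside = (t > lo) & (t < hi)
    xs = np.concatenate([[lo], t[inside], [hi]])
    ys = np.concatenate([[np.interp(lo, t, v)], v[inside], [np.interp(hi, t, v)]])
    return float(np.trapezoid(ys, xs))
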