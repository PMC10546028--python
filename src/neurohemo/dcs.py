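"""Diffuse correlation spectroscopy (DCS): blood-flow-index extraction.

DCS measures microvascular blood flow from the temporal decorrelation of
multiply scattered coherent near-infrared light. The measured normalized
intensity autocorrelation g2(tau) is linked to the normalized field
autocorrelation g1(tau) by the Siegert relation::

    g2(tau) = 1 + beta * g1(tau)**2

and g1 follows the semi-infinite Green's-function solution of the
correlation-diffusion equation with Brownian scatterer dynamics
(mean-square displacement ``<dr^2> = 6 * alpha_Db * tau``)::

    G1(tau) = exp(-K(tau) r1)/r1 - exp(-K(tau) rb)/rb
    K(tau)  = sqrt(3 mua musp + 6 musp^2 k0^2 alpha_Db tau)
    g1(tau) = G1(tau) / G1(0)

with ``r1 = sqrt(rho^2 + z0^2)``, ``rb = sqrt(rho^2 + (z0 + 2 zb)^2)``,
``z0 = 1/musp`` and the extrapolated boundary
``zb = (2 / 3 musp) (1 + Reff) / (1 - Reff)``.

The blood flow index ``alpha_Db`` (cm^2/s; dynamic-scatterer fraction times
an effective Brownian diffusion coefficient) and the coherence factor
``beta`` are estimated per g2 curve either by trust-region nonlinear least
squares (`G2Model.fit`) or by a closed-form linearized early-lag estimator
(`G2Model.fit_linear`). Per-frame fits assemble into a `FlowSeries`;
relative CBF is the flow index as percent of a baseline-window mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DcsOpticalModel",
    "G2Frame",
    "FlowFit",
    "FlowSeries",
    "G2Model",
    "effective_reflection_coefficient",
    "g1_semiinfinite",
    "g2_siegert",
    "siegert_invert",
    "fit_g2",
    "fit_g2_linear",
    "flow_series",
    "rcbf",
    "default_tau_grid",
]


class NoDecayError(ValueError):
    """g2 curve carries no decaying signal to fit."""


class FitConvergenceError(RuntimeError):
    """Nonlinear fit failed to converge."""


def effective_reflection_coefficient(n: float) -> float:
    """Effective Fresnel reflection coefficient R_eff(n).

    Standard polynomial approximation in the relative refractive index
    (tissue/air) used for the extrapolated-boundary condition.
    """
    return -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n


@dataclass(frozen=True)
class DcsOpticalModel:
    """Tissue optical properties and probe geometry for the diffusion model.

    Defaults are conventional adult-head values at 785 nm with a 2.5 cm
    source–detector separation; all are configuration, not measurements.

    Attributes
    ----------
    mua : absorption coefficient, cm^-1
    musp : reduced scattering coefficient, cm^-1
    n : tissue refractive index (relative to air)
    wavelength_nm : laser wavelength, nm
    rho : source–detector separation, cm
    """

    mua: float = 0.1
    musp: float = 10.0
    n: float = 1.37
    wavelength_nm: float = 785.0
    rho: float = 2.5

    def __post_init__(self) -> None:
        for name in ("mua", "musp", "n", "wavelength_nm", "rho"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.musp / self.mua < 5:
            warnings.warn(
                f"musp/mua = {self.musp / self.mua:.2f} < 5: diffusion "
                "approximation is questionable",
                stacklevel=2,
            )

    @property
    def k0(self) -> float:
        """Optical wavenumber in tissue, cm^-1."""
        return 2.0 * np.pi * self.n / (self.wavelength_nm * 1e-7)

    @property
    def z0(self) -> float:
        """Effective depth of the isotropic source, cm."""
        return 1.0 / self.musp

    @property
    def reff(self) -> float:
        return effective_reflection_coefficient(self.n)

    @property
    def zb(self) -> float:
        """Extrapolated boundary distance, cm."""
        return (2.0 / (3.0 * self.musp)) * (1.0 + self.reff) / (1.0 - self.reff)

    @property
    def r1(self) -> float:
        return float(np.hypot(self.rho, self.z0))

    @property
    def rb(self) -> float:
        return float(np.hypot(self.rho, self.z0 + 2.0 * self.zb))

    @property
    def k_tau0(self) -> float:
        """Static decay wavevector K(0) = sqrt(3 mua musp), cm^-1."""
        return float(np.sqrt(3.0 * self.mua * self.musp))

    def to_dict(self) -> dict:
        return {
            "mua": self.mua,
            "musp": self.musp,
            "n": self.n,
            "wavelength_nm": self.wavelength_nm,
            "rho": self.rho,
        }


def default_tau_grid(
    n_lags: int = 50, tau_min: float = 1e-7, tau_max: float = 1e-1
) -> np.ndarray:
    """Multi-tau-style log-spaced lag grid (s)."""
    return np.logspace(np.log10(tau_min), np.log10(tau_max), n_lags)


def g1_semiinfinite(
    model: DcsOpticalModel, alpha_db: float, tau: np.ndarray
) -> np.ndarray:
    """Normalized field autocorrelation g1(tau) for the semi-infinite medium.

    g1(0) = 1 exactly; strictly decreasing in tau for alpha_db > 0.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("lags must be nonnegative")
    if alpha_db <= 0:
        raise ValueError("alpha_db must be positive")
    ksq = 3.0 * model.mua * model.musp + 6.0 * model.musp**2 * model.k0**2 * alpha_db * tau
    k = np.sqrt(ksq)
    r1, rb = model.r1, model.rb
    k0s = model.k_tau0
    # factored form: exp(-(K-K0) r1) * [1 - (r1/rb) e^{-K dr}] / [1 - (r1/rb) e^{-K0 dr}]
    # gives g1(0) = 1 exactly and avoids cancellation of two tiny exponentials
    dr = rb - r1
    lead = np.exp(np.maximum(-(k - k0s) * r1, -745.0))
    num = 1.0 - (r1 / rb) * np.exp(-k * dr)
    den = 1.0 - (r1 / rb) * np.exp(-k0s * dr)
    return lead * num / den


def g2_siegert(g1: np.ndarray, beta: float) -> np.ndarray:
    """Siegert relation: g2 = 1 + beta * g1^2 (0 < beta <= 1)."""
    if not 0 < beta <= 1:
        raise ValueError(f"beta must lie in (0, 1], got {beta}")
    return 1.0 + beta * np.asarray(g1, dtype=float) ** 2


def siegert_invert(g2: np.ndarray, beta: float) -> np.ndarray:
    """Recover g1 = sqrt((g2 - 1)/beta); negative excursions clipped to 0."""
    if not 0 < beta <= 1:
        raise ValueError(f"beta must lie in (0, 1], got {beta}")
    return np.sqrt(np.clip((np.asarray(g2, dtype=float) - 1.0) / beta, 0.0, None))


@dataclass
class G2Frame:
    """One autocorrelation measurement: lag grid, g2 values, timestamp (s)."""

    tau: np.ndarray
    g2: np.ndarray
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.g2 = np.asarray(self.g2, dtype=float)
        if self.tau.shape != self.g2.shape or self.tau.ndim != 1:
            raise ValueError("tau and g2 must be 1-D arrays of equal length")
        if np.any(self.tau <= 0) or np.any(np.diff(self.tau) <= 0):
            raise ValueError("tau must be positive and strictly increasing")
        if not np.all(np.isfinite(self.g2)):
            raise ValueError("g2 values must be finite")


@dataclass
class FlowFit:
    """Result of fitting one g2 curve (Results object of `G2Model`).

    ``alpha_db`` in cm^2/s, ``beta`` dimensionless; ``residual`` is the sum
    of squared g2 misfits. Standard errors (when available) come from the
    Gauss–Newton covariance at the optimum.
    """

    alpha_db: float
    beta: float
    residual: float
    converged: bool
    method: str = "nls"
    n_lags: int = 0
    n_excluded: int = 0
    alpha_db_se: float | None = None
    beta_se: float | None = None
    model: "G2Model | None" = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [
            "DCS g2 fit" + f" ({self.method})",
            "-" * 46,
            f"{'blood flow index alpha_Db':<30}{self.alpha_db:.4e} cm^2/s",
            f"{'coherence factor beta':<30}{self.beta:.4f}",
            f"{'sum squared residual':<30}{self.residual:.3e}",
            f"{'lags used':<30}{self.n_lags}",
            f"{'lags excluded':<30}{self.n_excluded}",
            f"{'converged':<30}{self.converged}",
        ]
        if self.alpha_db_se is not None:
            lines.insert(3, f"{'s.e.(alpha_Db)':<30}{self.alpha_db_se:.2e} cm^2/s")
        if self.beta_se is not None:
            lines.insert(5, f"{'s.e.(beta)':<30}{self.beta_se:.2e}")
        return "\n".join(lines)


class G2Model:
    """Correlation-diffusion model for one measured g2 curve.

    statsmodels-style usage::

        fit = G2Model(frame, optics).fit()
        print(fit.summary())
    """

    def __init__(self, frame: G2Frame, optics: DcsOpticalModel | None = None):
        self.frame = frame
        self.optics = optics or DcsOpticalModel()

    def predict(self, alpha_db: float, beta: float, tau: np.ndarray | None = None):
        tau = self.frame.tau if tau is None else np.asarray(tau, dtype=float)
        return g2_siegert(g1_semiinfinite(self.optics, alpha_db, tau), beta)

    # ---------------------------------------------------------------- nls
    def fit(
        self,
        x0: tuple[float, float] | None = None,
        bounds_alpha: tuple[float, float] = (1e-12, 1e-4),
        fix_beta: float | None = None,
        min_lags: int = 10,
        signal_floor: float = 0.02,
    ) -> FlowFit:
        """Trust-region least squares over (log10 alpha_Db, beta).

        alpha_Db is log-parameterized so positivity holds by construction;
        initialization comes from the linearized estimator unless ``x0``
        is given. ``fix_beta`` freezes beta (e.g. from the earliest lags).
        """
        frame, optics = self.frame, self.optics
        if frame.tau.size < min_lags:
            raise ValueError(f"need >= {min_lags} lags, got {frame.tau.size}")
        span = float(np.max(frame.g2) - np.min(frame.g2))
        if float(np.max(frame.g2)) - 1.0 < signal_floor or span < signal_floor / 2:
            raise NoDecayError(
                f"g2 curve is flat (max excess {np.max(frame.g2) - 1:.4f}, "
                f"span {span:.4f}); no decay to fit"
            )
        if x0 is None:
            try:
                lin = self.fit_linear()
                a0 = float(np.clip(lin.alpha_db, *bounds_alpha))
                b0 = float(np.clip(lin.beta, 1e-3, 1.0))
            except (ValueError, NoDecayError):
                a0, b0 = 1e-8, float(np.clip(np.max(frame.g2) - 1.0, 1e-3, 1.0))
        else:
            a0, b0 = x0
        la, lb = np.log10(bounds_alpha[0]), np.log10(bounds_alpha[1])

        if fix_beta is None:
            def resid(p):
                return self.predict(10.0 ** p[0], p[1]) - frame.g2
            p0 = [np.clip(np.log10(a0), la, lb), b0]
            lo, hi = [la, 1e-6], [lb, 1.0]
        else:
            if not 0 < fix_beta <= 1:
                raise ValueError("fix_beta must lie in (0, 1]")
            def resid(p):
                return self.predict(10.0 ** p[0], fix_beta) - frame.g2
            p0 = [np.clip(np.log10(a0), la, lb)]
            lo, hi = [la], [lb]

        res = least_squares(
            resid, p0, bounds=(lo, hi), method="trf",
            ftol=1e-12, xtol=1e-12, gtol=1e-12,
        )
        alpha = float(10.0 ** res.x[0])
        beta = float(fix_beta if fix_beta is not None else res.x[1])
        ssr = float(2.0 * res.cost)
        converged = bool(res.success)
        alpha_se = beta_se = None
        dof = frame.tau.size - res.x.size
        if converged and dof > 0:
            try:
                jtj = res.jac.T @ res.jac
                cov = np.linalg.inv(jtj) * (ssr / dof)
                # delta method: d alpha / d log10(alpha) = alpha ln 10
                alpha_se = float(np.sqrt(cov[0, 0]) * alpha * np.log(10.0))
                if fix_beta is None:
                    beta_se = float(np.sqrt(cov[1, 1]))
            except np.linalg.LinAlgError:
                pass
        return FlowFit(
            alpha_db=alpha, beta=beta, residual=ssr, converged=converged,
            method="nls", n_lags=int(frame.tau.size), alpha_db_se=alpha_se,
            beta_se=beta_se, model=self,
        )

    # ------------------------------------------------------------- linear
    def estimate_beta(self, n_earliest: int = 5) -> float:
        """beta from linear extrapolation of g2 - 1 to tau = 0 (earliest lags)."""
        tau, g2 = self.frame.tau, self.frame.g2
        if tau.size < n_earliest:
            raise ValueError("not enough lags to estimate beta")
        coef = np.polynomial.polynomial.polyfit(
            tau[:n_earliest], g2[:n_earliest] - 1.0, 1
        )
        return float(np.clip(coef[0], 1e-6, 1.0))

    def fit_linear(
        self,
        order: int = 2,
        early_lag_window: tuple[float, float] | None = None,
        decay_cut: float = 0.3,
        min_lags: int = 5,
    ) -> FlowFit:
        """Closed-form Nth-order linearized estimator (no iterative optimizer).

        beta is extrapolated from the earliest lags; g2 is converted to g1 by
        the Siegert relation; ln g1 over the early-lag window is fitted with a
        degree-``order`` polynomial by linear least squares, and the initial
        slope ``S = -d ln g1/d tau |_0`` is mapped to alpha_Db through the
        analytic derivative of the semi-infinite solution at tau = 0::

            S = [(exp(-K0 r1) - exp(-K0 rb)) / G1(0)] * 3 musp^2 k0^2 alpha_Db / K0
        """
        frame, optics = self.frame, self.optics
        beta = self.estimate_beta()
        excess = (frame.g2 - 1.0) / beta
        if early_lag_window is not None:
            t0, t1 = early_lag_window
            sel = (frame.tau >= t0) & (frame.tau <= t1)
        else:
            # contiguous earliest lags with appreciable signal above the floor
            above = excess >= decay_cut
            first_below = int(np.argmax(~above)) if (~above).any() else above.size
            sel = np.zeros_like(above)
            sel[:first_below] = True
        n_neg = int(np.sum(excess[sel] <= 0))
        sel = sel & (excess > 0)
        if sel.sum() < min_lags:
            raise ValueError(
                f"early-lag window holds {int(sel.sum())} usable lags "
                f"(need >= {min_lags}); {n_neg} nonpositive excess values excluded"
            )
        tau_w = frame.tau[sel]
        ln_g1 = 0.5 * np.log(excess[sel])
        coef = np.polynomial.polynomial.polyfit(tau_w, ln_g1, order)
        slope = -float(coef[1])  # S = -d ln g1/d tau at tau = 0
        k0s = optics.k_tau0
        r1, rb = optics.r1, optics.rb
        g1_0 = np.exp(-k0s * r1) / r1 - np.exp(-k0s * rb) / rb
        c_map = (
            (np.exp(-k0s * r1) - np.exp(-k0s * rb))
            / g1_0
            * 3.0
            * optics.musp**2
            * optics.k0**2
            / k0s
        )
        alpha = slope / c_map
        if alpha <= 0:
            raise NoDecayError(
                f"linearized slope {slope:.3g} implies nonpositive flow index"
            )
        pred = self.predict(alpha, beta)
        ssr = float(np.sum((pred - frame.g2) ** 2))
        return FlowFit(
            alpha_db=float(alpha), beta=beta, residual=ssr, converged=True,
            method=f"linear-{order}", n_lags=int(sel.sum()), n_excluded=n_neg,
            model=self,
        )


# ------------------------------------------------------------------ wrappers

def fit_g2(
    frame: G2Frame, model: DcsOpticalModel | None = None, **opts
) -> FlowFit:
    """Nonlinear least-squares fit of one g2 curve (see `G2Model.fit`)."""
    return G2Model(frame, model).fit(**opts)


def fit_g2_linear(
    frame: G2Frame,
    model: DcsOpticalModel | None = None,
    order: int = 2,
    early_lag_window: tuple[float, float] | None = None,
    **opts,
) -> FlowFit:
    """Linearized early-lag fit of one g2 curve (see `G2Model.fit_linear`)."""
    return G2Model(frame, model).fit_linear(
        order=order, early_lag_window=early_lag_window, **opts
    )


@dataclass
class FlowSeries:
    """Blood-flow-index time course; rCBF is percent of a baseline mean."""

    time: np.ndarray
    alpha_db: np.ndarray
    rcbf: np.ndarray | None = None
    converged: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.alpha_db = np.asarray(self.alpha_db, dtype=float)
        if self.time.shape != self.alpha_db.shape:
            raise ValueError("time and alpha_db must have equal shapes")
        if self.converged is None:
            self.converged = np.isfinite(self.alpha_db)
        self.converged = np.asarray(self.converged, dtype=bool)
        if self.rcbf is not None:
            self.rcbf = np.asarray(self.rcbf, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "alpha_db_cm2s": self.alpha_db,
                "rcbf_pct": self.rcbf if self.rcbf is not None else np.nan,
                "converged": self.converged,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FlowSeries":
        df = pd.read_csv(path)
        rcbf_col = df["rcbf_pct"].to_numpy(dtype=float)
        return cls(
            df["time_s"].to_numpy(dtype=float),
            df["alpha_db_cm2s"].to_numpy(dtype=float),
            None if np.all(np.isnan(rcbf_col)) else rcbf_col,
            df["converged"].to_numpy(dtype=bool),
        )

    def plot(self, ax=None, which: str = "rcbf"):
        """Quick-look plot of the flow time course."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if which == "rcbf" and self.rcbf is not None:
            ax.plot(self.time, self.rcbf)
            ax.set_ylabel("rCBF (% baseline)")
        else:
            ax.plot(self.time, self.alpha_db)
            ax.set_ylabel(r"$\alpha D_B$ (cm$^2$/s)")
        ax.set_xlabel("time (s)")
        return ax


def flow_series(
    frames: Sequence[G2Frame],
    model: DcsOpticalModel | None = None,
    method: str = "nls",
    order: int = 2,
    warm_start: bool = True,
    **opts,
) -> FlowSeries:
    """Fit every frame independently and assemble a FlowSeries.

    Frames whose fit fails are marked missing (NaN, converged=False) rather
    than interpolated. Raises if every frame fails.
    """
    if not frames:
        raise ValueError("no frames supplied")
    times = np.array([f.timestamp for f in frames], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("frame timestamps must be strictly increasing")
    model = model or DcsOpticalModel()
    alphas = np.full(len(frames), np.nan)
    ok = np.zeros(len(frames), dtype=bool)
    prev: FlowFit | None = None
    for i, frame in enumerate(frames):
        g2m = G2Model(frame, model)
        try:
            if method == "nls":
                x0 = (prev.alpha_db, prev.beta) if (warm_start and prev) else None
                fit = g2m.fit(x0=x0, **opts)
            elif method == "linear":
                fit = g2m.fit_linear(order=order, **opts)
            else:
                raise ValueError(f"unknown method {method!r}")
            if fit.converged:
                alphas[i] = fit.alpha_db
                ok[i] = True
                prev = fit
        except (ValueError, NoDecayError, FitConvergenceError):
            pass
    if not ok.any():
        raise FitConvergenceError("all frames failed to fit")
    return FlowSeries(times, alphas, converged=ok)


def rcbf(series: FlowSeries, baseline_window: tuple[float, float]) -> FlowSeries:
    """Populate rCBF = 100 * alpha_Db(t) / mean(alpha_Db over baseline window)."""
    t0, t1 = baseline_window
    mask = (series.time >= t0) & (series.time < t1) & series.converged
    mask &= np.isfinite(series.alpha_db)
    if not mask.any():
        raise ValueError(f"baseline window ({t0}, {t1}) holds no usable samples")
    base = float(series.alpha_db[mask].mean())
    if base <= 0:
        raise ValueError("baseline mean flow index must be positive")
    return FlowSeries(
        series.time.copy(),
        series.alpha_db.copy(),
        100.0 * series.alpha_db / base,
        series.converged.copy(),
    )


# ---------------------------------------------------------------------- io

def write_g2_frames(frames: Sequence[G2Frame], path: str | Path) -> None:
    """CSV with header timestamp_s,tau_s,g2; frames delimited by timestamp."""
    rows = [
        {"timestamp_s": f.timestamp, "tau_s": t, "g2": g}
        for f in frames
        for t, g in zip(f.tau, f.g2)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_g2_frames(path: str | Path) -> list[G2Frame]:
    df = pd.read_csv(path)
    required = {"timestamp_s", "tau_s", "g2"}
    if missing := required - set(df.columns):
        raise ValueError(f"g2 CSV missing columns {sorted(missing)}")
    frames = []
    for ts, grp in df.groupby("timestamp_s", sort=True):
        grp = grp.sort_values("tau_s")
        frames.append(
            G2Frame(grp["tau_s"].to_numpy(), grp["g2"].to_numpy(), float(ts))
        )
    return frames
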