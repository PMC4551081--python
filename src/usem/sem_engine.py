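"""Block-Toeplitz lagged covariance construction and ML covariance-structure
estimation: the shared numerical core for the whole uSEM model family.

A structural VAR with contemporaneous matrix ``A`` and lagged matrices
``Phi_q`` is fitted as a covariance-structure model on the block-Toeplitz
arrangement of the lag-0..a cross-covariance blocks.  The first ``p``
variables of that arrangement are the current observations (endogenous);
the remaining variables (lagged copies and, for models with task input,
HRF-convolved input columns and bilinear product regressors) form a
saturated exogenous block whose covariance is free.

The estimator minimizes the Gaussian ML discrepancy

    F(theta) = ln det Sigma(theta) + tr(S Sigma(theta)^-1) - ln det S - m

with ``chi2 = (n_eff - 1) * F`` at the optimum.  Because the likelihood
factors into an exogenous marginal and an endogenous conditional, the
saturated exogenous covariance is profiled out exactly at its sample
value; it still counts as free parameters in the degrees of freedom and
enters the expected (Fisher) information used for standard errors,
modification indices (Lagrange-multiplier tests), and Wald tests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2 as _chi2_dist
from scipy.stats import norm as _norm_dist

from .data_model import InputSeries, RoiTimeSeries

__all__ = [
    "EngineConfig",
    "LaggedCovariance",
    "ModelSpec",
    "ParamMatrixSet",
    "FitResult",
    "ModIndexTable",
    "ModIndexRow",
    "block_toeplitz_cov",
    "implied_sigma",
    "fit_ml",
    "model_df",
    "fit_indices",
    "modification_indices",
    "wald_prune",
    "MI_CRIT_05",
]

ParamId = tuple
#: chi^2(1) critical value at alpha = 0.05, the default threshold for a
#: single modification index to count as significant.
MI_CRIT_05 = float(_chi2_dist.ppf(0.95, 1))
_Z95 = float(_norm_dist.ppf(0.975))


@dataclass(frozen=True)
class EngineConfig:
    """Numerical knobs of the ML engine (defaults used throughout)."""

    grad_tol: float = 1e-6       # converged iff ||grad F||_2 below this
    max_iter: int = 500
    psi_floor: float = 1e-10     # lower bound for innovation variances
    heywood_tol: float = 1e-8    # warn when a variance hits this
    mi_alpha: float = 0.05
    wald_alpha: float = 0.05


# ---------------------------------------------------------------------------
# Lagged covariance construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LaggedCovariance:
    """Block-Toeplitz second-moment matrix of order ``a``.

    Variables are ordered [y(t), y(t-1), ..., y(t-a), inputs, products].
    Lag-l cross-covariance blocks are estimated as
    ``C(l) = (1/(T-l)) sum_t y(t) y(t-l)'`` and tiled, so equal-offset
    blocks are identical by construction.
    """

    S: np.ndarray
    order: int
    n_eff: int
    p: int
    var_names: tuple[str, ...]
    block_labels: tuple[str, ...]
    f: int | None = None          # direct-input lag bound (columns u(t-r), r=0..f)
    g: int = 0                    # bilinear lag bounds (products y(t-q)u(t-r))
    h: int = 0
    singular: bool = False

    @property
    def m(self) -> int:
        return self.S.shape[0]

    @property
    def n_exog_extra(self) -> int:
        return self.m - self.p * (self.order + 1)

    def exog_position(self, pid: ParamId) -> tuple[int, int]:
        """(row, column) in the m-dim arrangement for a regression parameter."""
        kind = pid[0]
        p, a = self.p, self.order
        if kind == "A":
            _, k, j = pid
            return k, j
        if kind == "Phi":
            _, q, k, j = pid
            if not 1 <= q <= a:
                raise KeyError(f"lag {q} outside modelled order {a}: {pid}")
            return k, q * p + j
        base = p * (a + 1)
        if kind == "gamma":
            _, r, k = pid
            if self.f is None or not 0 <= r <= self.f:
                raise KeyError(f"no input column for {pid}")
            return k, base + r
        if kind == "tau":
            _, q, r, k, j = pid
            if not (1 <= q <= self.g and 1 <= r <= self.h):
                raise KeyError(f"no product column for {pid}")
            off = base + (0 if self.f is None else self.f + 1)
            return k, off + ((q - 1) * self.h + (r - 1)) * p + j
        raise KeyError(f"unknown parameter kind: {pid}")

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("\t".join(self.var_names) + "\n")
            for row in self.S:
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def block_toeplitz_cov(
    ts: RoiTimeSeries,
    order: int,
    inputs: InputSeries | None = None,
    bilinear: bool = False,
    f: int = 1,
    g: int = 1,
    h: int = 1,
) -> LaggedCovariance:
    """Build the block-Toeplitz lagged covariance of ``ts`` up to ``order``.

    With ``inputs``, lagged input columns u(t-r), r=0..f are appended;
    with ``bilinear`` additionally the centered product regressors
    y_j(t-q)u(t-r) for q=1..g, r=1..h.
    """
    if not ts.centered:
        raise ValueError("time series must be centered before covariance construction")
    if order < 0:
        raise ValueError("order must be >= 0")
    p, T = ts.p, ts.T
    if T <= p * (order + 1):
        raise ValueError(f"T={T} too short for p={p}, order={order}")
    Y = ts.values
    C = [Y[:, l:] @ Y[:, : T - l].T / (T - l) for l in range(order + 1)]

    m_y = p * (order + 1)
    names = list(ts.labels)
    labels = ["lag0"] * p
    for q in range(1, order + 1):
        names += [f"{lab}[t-{q}]" for lab in ts.labels]
        labels += [f"lag{q}"] * p

    extras: list[np.ndarray] = []
    f_out: int | None = None
    g_out = h_out = 0
    if inputs is not None:
        if inputs.n_u != 1:
            raise ValueError("a single external input vector is supported")
        u = inputs.effective[0]
        if u.shape[0] != T:
            raise ValueError("input length must match the time series")
        f_out = f
        t0 = max(order, f, h if bilinear else 0, g if bilinear else 0)
        idx = np.arange(t0, T)
        for r in range(f + 1):
            extras.append(u[idx - r])
            names.append(f"u[t-{r}]")
            labels.append("input")
        if bilinear:
            g_out, h_out = g, h
            for q in range(1, g + 1):
                for r in range(1, h + 1):
                    for j in range(p):
                        w = Y[j, idx - q] * u[idx - r]
                        extras.append(w - w.mean())
                        names.append(f"{ts.labels[j]}[t-{q}]*u[t-{r}]")
                        labels.append("prod")
        y_rows = [Y[j, idx - q] for q in range(order + 1) for j in range(p)]
    m = m_y + len(extras)

    S = np.empty((m, m))
    for i in range(order + 1):
        for j in range(order + 1):
            l = j - i
            blk = C[l] if l >= 0 else C[-l].T
            S[i * p : (i + 1) * p, j * p : (j + 1) * p] = blk
    if extras:
        Z = np.vstack(extras)
        n_al = Z.shape[1]
        Yal = np.vstack(y_rows)
        S[m_y:, :m_y] = Z @ Yal.T / n_al
        S[:m_y, m_y:] = S[m_y:, :m_y].T
        S[m_y:, m_y:] = Z @ Z.T / n_al
    S = (S + S.T) / 2.0

    singular = bool(np.linalg.matrix_rank(S, tol=1e-10 * np.abs(S).max()) < m)
    if singular:
        warnings.warn("lagged covariance matrix is singular; estimation may still proceed")
    return LaggedCovariance(
        S=S,
        order=order,
        n_eff=T - order,
        p=p,
        var_names=tuple(names),
        block_labels=tuple(labels),
        f=f_out,
        g=g_out,
        h=h_out,
        singular=singular,
    )


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Free/fixed masks of a uSEM-family model.

    ``a_free`` is the p x p mask of contemporaneous regressions (diagonal
    structurally fixed at zero), ``phi_free`` the (a, p, p) mask of lagged
    regressions.  ``gamma_free``/``tau_free`` are present only for models
    with external input.
    """

    p: int
    order: int
    a_free: np.ndarray = None  # type: ignore[assignment]
    phi_free: np.ndarray = None  # type: ignore[assignment]
    f: int | None = None
    g: int = 0
    h: int = 0
    gamma_free: np.ndarray | None = None  # (f+1, p)
    tau_free: np.ndarray | None = None    # (g, h, p, p)

    def __post_init__(self) -> None:
        a = np.zeros((self.p, self.p), dtype=bool) if self.a_free is None else np.asarray(self.a_free, dtype=bool)
        phi = (
            np.zeros((self.order, self.p, self.p), dtype=bool)
            if self.phi_free is None
            else np.asarray(self.phi_free, dtype=bool)
        )
        if a.shape != (self.p, self.p):
            raise ValueError("a_free has wrong shape")
        if phi.shape != (self.order, self.p, self.p):
            raise ValueError("phi_free has wrong shape")
        if np.any(np.diag(a)):
            raise ValueError("the diagonal of A is structurally fixed at zero")
        object.__setattr__(self, "a_free", a)
        object.__setattr__(self, "phi_free", phi)
        if self.f is not None:
            gam = (
                np.zeros((self.f + 1, self.p), dtype=bool)
                if self.gamma_free is None
                else np.asarray(self.gamma_free, dtype=bool)
            )
            if gam.shape != (self.f + 1, self.p):
                raise ValueError("gamma_free has wrong shape")
            object.__setattr__(self, "gamma_free", gam)
        if self.g and self.h:
            tau = (
                np.zeros((self.g, self.h, self.p, self.p), dtype=bool)
                if self.tau_free is None
                else np.asarray(self.tau_free, dtype=bool)
            )
            if tau.shape != (self.g, self.h, self.p, self.p):
                raise ValueError("tau_free has wrong shape")
            object.__setattr__(self, "tau_free", tau)

    @classmethod
    def null(cls, p: int, order: int, f: int | None = None, g: int = 0, h: int = 0) -> "ModelSpec":
        """The null model: empty A and Phi (and gamma/tau) matrices."""
        return cls(p=p, order=order, f=f, g=g, h=h)

    def free_params(self) -> list[ParamId]:
        """Freed regression parameters, in deterministic (lag, target, source) order."""
        out: list[ParamId] = []
        for k in range(self.p):
            for j in range(self.p):
                if self.a_free[k, j]:
                    out.append(("A", k, j))
        for q in range(1, self.order + 1):
            for k in range(self.p):
                for j in range(self.p):
                    if self.phi_free[q - 1, k, j]:
                        out.append(("Phi", q, k, j))
        if self.f is not None and self.gamma_free is not None:
            for r in range(self.f + 1):
                for k in range(self.p):
                    if self.gamma_free[r, k]:
                        out.append(("gamma", r, k))
        if self.tau_free is not None:
            for q in range(1, self.g + 1):
                for r in range(1, self.h + 1):
                    for k in range(self.p):
                        for j in range(self.p):
                            if self.tau_free[q - 1, r - 1, k, j]:
                                out.append(("tau", q, r, k, j))
        return out

    @property
    def k_free(self) -> int:
        return len(self.free_params())

    def is_free(self, pid: ParamId) -> bool:
        return pid in set(self.free_params())

    def _mutate(self, pid: ParamId, value: bool) -> "ModelSpec":
        a = self.a_free.copy()
        phi = self.phi_free.copy()
        gam = None if self.gamma_free is None else self.gamma_free.copy()
        tau = None if self.tau_free is None else self.tau_free.copy()
        kind = pid[0]
        if kind == "A":
            _, k, j = pid
            if k == j:
                raise ValueError("the diagonal of A cannot be freed")
            a[k, j] = value
        elif kind == "Phi":
            _, q, k, j = pid
            if not 1 <= q <= self.order:
                raise ValueError(f"lag {q} outside model order {self.order}")
            phi[q - 1, k, j] = value
        elif kind == "gamma":
            _, r, k = pid
            if gam is None:
                raise ValueError("model has no input terms")
            gam[r, k] = value
        elif kind == "tau":
            _, q, r, k, j = pid
            if tau is None:
                raise ValueError("model has no bilinear terms")
            tau[q - 1, r - 1, k, j] = value
        else:
            raise ValueError(f"unknown parameter id {pid}")
        return replace(self, a_free=a, phi_free=phi, gamma_free=gam, tau_free=tau)

    def with_freed(self, pid: ParamId) -> "ModelSpec":
        return self._mutate(pid, True)

    def with_fixed(self, pid: ParamId) -> "ModelSpec":
        return self._mutate(pid, False)

    def expanded_to_order(self, order: int) -> "ModelSpec":
        """Embed this spec in a higher-order model (new lags start empty)."""
        if order < self.order:
            raise ValueError("cannot shrink the model order")
        if order == self.order:
            return self
        phi = np.zeros((order, self.p, self.p), dtype=bool)
        phi[: self.order] = self.phi_free
        return replace(self, order=order, phi_free=phi)

    def key(self) -> tuple:
        """Hashable identity of (order, freed set), for revisit detection."""
        return (self.order, frozenset(self.free_params()))

    def permuted(self, perm: Sequence[int]) -> "ModelSpec":
        """Spec under a relabeling of the ROIs (perm maps new index -> old)."""
        idx = np.asarray(perm)
        a = self.a_free[np.ix_(idx, idx)]
        phi = self.phi_free[:, idx][:, :, idx]
        gam = None if self.gamma_free is None else self.gamma_free[:, idx]
        tau = None if self.tau_free is None else self.tau_free[:, :, idx][:, :, :, idx]
        return replace(self, a_free=a, phi_free=phi, gamma_free=gam, tau_free=tau)

    def to_json_dict(self) -> dict:
        return {
            "p": self.p,
            "order": self.order,
            "f": self.f,
            "g": self.g,
            "h": self.h,
            "free": [list(pid) for pid in self.free_params()],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "ModelSpec":
        spec = cls.null(d["p"], d["order"], f=d.get("f"), g=d.get("g", 0), h=d.get("h", 0))
        for pid in d["free"]:
            spec = spec.with_freed(tuple(pid))
        return spec


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitResult:
    chi2: float
    df: int
    p_value: float
    rmsea: float
    srmr: float
    cfi: float
    nnfi: float | None
    baseline_chi2: float
    baseline_df: int
    converged: bool
    n_eff: int

    def indices(self) -> dict:
        return {
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
            "rmsea": self.rmsea,
            "srmr": self.srmr,
            "cfi": self.cfi,
            "nnfi": self.nnfi,
        }


@dataclass(frozen=True)
class ParamMatrixSet:
    """Estimates, SEs and 95% CIs of a fitted uSEM-family model."""

    spec: ModelSpec
    A: np.ndarray
    phi: np.ndarray
    psi: np.ndarray
    gamma: np.ndarray | None = None
    tau: np.ndarray | None = None
    se: dict = field(default_factory=dict)

    def estimate(self, pid: ParamId) -> float:
        kind = pid[0]
        if kind == "A":
            return float(self.A[pid[1], pid[2]])
        if kind == "Phi":
            return float(self.phi[pid[1] - 1, pid[2], pid[3]])
        if kind == "gamma":
            return float(self.gamma[pid[1], pid[2]])
        if kind == "tau":
            return float(self.tau[pid[1] - 1, pid[2] - 1, pid[3], pid[4]])
        if kind == "Psi":
            return float(self.psi[pid[1]])
        raise KeyError(pid)

    def ci(self, pid: ParamId) -> tuple[float, float]:
        est, s = self.estimate(pid), self.se[pid]
        return est - _Z95 * s, est + _Z95 * s

    def wald_z(self, pid: ParamId) -> float:
        s = self.se.get(pid, np.nan)
        return self.estimate(pid) / s if s and np.isfinite(s) and s > 0 else np.nan

    def wald_p(self, pid: ParamId) -> float:
        z = self.wald_z(pid)
        return float(2.0 * _norm_dist.sf(abs(z))) if np.isfinite(z) else 1.0

    def to_json_dict(self) -> dict:
        rows = []
        for pid in self.spec.free_params() + [("Psi", i) for i in range(self.spec.p)]:
            est = self.estimate(pid)
            s = self.se.get(pid)
            lo, hi = self.ci(pid) if pid in self.se else (None, None)
            rows.append(
                {
                    "param": list(pid),
                    "free": True,
                    "estimate": est,
                    "se": s,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
        return {"spec": self.spec.to_json_dict(), "parameters": rows}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1))


@dataclass(frozen=True)
class ModIndexRow:
    param: ParamId
    mi: float
    epc: float


@dataclass(frozen=True)
class ModIndexTable:
    rows: tuple[ModIndexRow, ...]

    def significant(self, crit: float = MI_CRIT_05) -> list[ModIndexRow]:
        return [r for r in self.rows if r.mi > crit]

    def best(self) -> ModIndexRow | None:
        """Largest MI; ties broken by lowest (lag, target, source) order."""
        if not self.rows:
            return None
        return max(self.rows, key=lambda r: (r.mi, tuple(-np.array(_sort_key(r.param)))))

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)


def _sort_key(pid: ParamId) -> tuple:
    kind = pid[0]
    if kind == "A":
        return (0, pid[1], pid[2], 0)
    if kind == "Phi":
        return (pid[1], pid[2], pid[3], 0)
    if kind == "gamma":
        return (pid[1], pid[2], 0, 1)
    if kind == "tau":
        return (pid[1], pid[3], pid[4], 2 + pid[2])
    return (99,) + tuple(pid[1:]) + (9,)


# ---------------------------------------------------------------------------
# Degrees of freedom and fit indices
# ---------------------------------------------------------------------------


def model_df(p: int, a: int, k_free: int, extra_exog: int = 0) -> int:
    """df of a uSEM-family model on an order-``a`` block-Toeplitz matrix.

    Distinct fitted moments m(m+1)/2, minus the saturated exogenous-block
    covariance, minus the p innovation variances, minus the freed
    regression parameters.
    """
    if min(p, a, k_free, extra_exog) < 0:
        raise ValueError("arguments must be non-negative")
    m = p * (a + 1) + extra_exog
    n_x = m - p
    df = m * (m + 1) // 2 - n_x * (n_x + 1) // 2 - p - k_free
    if df < 0:
        raise ValueError(f"over-parameterized model: df = {df}")
    return df


def fit_indices(
    chi2: float,
    df: int,
    baseline_chi2: float,
    baseline_df: int,
    n_eff: int,
    S: np.ndarray,
    Sigma: np.ndarray,
    converged: bool = True,
) -> FitResult:
    """Absolute and incremental fit indices of a covariance-structure fit.

    RMSEA from the non-centrality per df; SRMR as the RMS standardized
    residual over the lower triangle; CFI clipped to [0, 1]; NNFI (TLI)
    reported unclipped and undefined (None) when df = 0.
    """
    chi2 = max(float(chi2), 0.0)
    excess = max(chi2 - df, 0.0)
    rmsea = 0.0 if df == 0 else float(np.sqrt(excess / (df * (n_eff - 1))))
    d = np.sqrt(np.outer(np.diag(S), np.diag(S)))
    resid = (S - Sigma) / d
    iu = np.triu_indices(S.shape[0])
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))
    denom = max(baseline_chi2 - baseline_df, excess, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - excess / denom
    cfi = float(min(max(cfi, 0.0), 1.0))
    if df == 0 or baseline_df == 0:
        nnfi = None
    else:
        b_ratio = baseline_chi2 / baseline_df
        nnfi = float((b_ratio - chi2 / df) / (b_ratio - 1.0)) if b_ratio != 1.0 else None
    p_value = float(_chi2_dist.sf(chi2, df)) if df > 0 else 1.0
    return FitResult(
        chi2=chi2,
        df=df,
        p_value=p_value,
        rmsea=rmsea,
        srmr=srmr,
        cfi=cfi,
        nnfi=nnfi,
        baseline_chi2=float(baseline_chi2),
        baseline_df=int(baseline_df),
        converged=converged,
        n_eff=int(n_eff),
    )


# ---------------------------------------------------------------------------
# Implied covariance
# ---------------------------------------------------------------------------


def _regression_matrices(spec: ModelSpec, params: "ParamMatrixSet", cov: LaggedCovariance) -> tuple[np.ndarray, np.ndarray]:
    """(A, B): contemporaneous matrix and the p x n_x matrix of regressions
    on the stacked exogenous variables, in the covariance's column order."""
    p, m = spec.p, cov.m
    A = params.A
    B = np.zeros((p, m - p))
    for pid in spec.free_params():
        k, c = cov.exog_position(pid)
        if c >= p:
            B[k, c - p] = params.estimate(pid)
    return A, B


def implied_sigma(spec: ModelSpec, params: "ParamMatrixSet", sigma_xx: np.ndarray, cov: LaggedCovariance | None = None) -> np.ndarray:
    """Model-implied covariance of [endogenous; exogenous] variables.

    Sigma_ee = (I-A)^-1 (B Sigma_xx B' + Psi) (I-A)^-T and
    Sigma_xe = Sigma_xx B' (I-A)^-T, with the exogenous block saturated.
    """
    p = spec.p
    n_x = sigma_xx.shape[0]
    if cov is None:
        cov = _layout_cov(spec, n_x)
    A, B = _regression_matrices(spec, params, cov)
    ImA = np.eye(p) - A
    try:
        ImA_inv = np.linalg.inv(ImA)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular I - A for contemporaneous matrix:\n{A}") from exc
    See = ImA_inv @ (B @ sigma_xx @ B.T + np.diag(params.psi)) @ ImA_inv.T
    Sxe = sigma_xx @ B.T @ ImA_inv.T
    m = p + n_x
    Sigma = np.empty((m, m))
    Sigma[:p, :p] = See
    Sigma[p:, :p] = Sxe
    Sigma[:p, p:] = Sxe.T
    Sigma[p:, p:] = sigma_xx
    return (Sigma + Sigma.T) / 2.0


def _layout_cov(spec: ModelSpec, n_x: int) -> LaggedCovariance:
    """A dummy LaggedCovariance used only for its column layout."""
    p = spec.p
    m = p + n_x
    return LaggedCovariance(
        S=np.eye(m),
        order=spec.order,
        n_eff=m + 2,
        p=p,
        var_names=tuple(f"v{i}" for i in range(m)),
        block_labels=("lag0",) * p + ("x",) * n_x,
        f=spec.f,
        g=spec.g,
        h=spec.h,
    )


# ---------------------------------------------------------------------------
# ML fit
# ---------------------------------------------------------------------------


def _safe_logdet(S: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(S)
    if sign <= 0 or not np.isfinite(ld):
        ev = np.linalg.eigvalsh(S)
        ev = np.clip(ev, 1e-12 * max(ev.max(), 1.0), None)
        return float(np.sum(np.log(ev)))
    return float(ld)


class _FitState:
    """Internal fitted state shared by SEs, MIs and Wald tests."""

    def __init__(self, cov: LaggedCovariance, spec: ModelSpec, reg_ids: list[ParamId], theta: np.ndarray):
        self.cov = cov
        self.spec = spec
        self.reg_ids = reg_ids
        self.theta = theta  # [regressions..., psi...]

    def matrices(self) -> tuple[np.ndarray, np.ndarray]:
        m, p = self.cov.m, self.cov.p
        k = len(self.reg_ids)
        Atil = np.zeros((m, m))
        for pid, val in zip(self.reg_ids, self.theta[:k]):
            r, c = self.cov.exog_position(pid)
            Atil[r, c] = val
        Psit = np.zeros((m, m))
        Psit[:p, :p] = np.diag(self.theta[k:])
        Psit[p:, p:] = self.cov.S[p:, p:]
        return Atil, Psit


def _f_and_grad(theta: np.ndarray, cov: LaggedCovariance, reg_pos: list[tuple[int, int]], logdetS: float):
    m, p = cov.m, cov.p
    k = len(reg_pos)
    Atil = np.zeros((m, m))
    for (r, c), val in zip(reg_pos, theta[:k]):
        Atil[r, c] = val
    psi = theta[k:]
    Psit = np.zeros((m, m))
    Psit[:p, :p] = np.diag(psi)
    Psit[p:, p:] = cov.S[p:, p:]
    I = np.eye(m)
    try:
        M = np.linalg.solve(I - Atil, I)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(theta)
    Sigma = M @ Psit @ M.T
    try:
        cf = cho_factor((Sigma + Sigma.T) / 2.0, lower=True)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(theta)
    logdetSig = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    Sig_inv = cho_solve(cf, I)
    F = logdetSig + float(np.sum(Sig_inv * cov.S)) - logdetS - m
    G = Sig_inv - Sig_inv @ cov.S @ Sig_inv
    grad = np.empty_like(theta)
    if k:
        R = Sigma @ G @ M
        for i, (r, c) in enumerate(reg_pos):
            grad[i] = 2.0 * R[c, r]
    P = M.T @ G @ M
    grad[k:] = np.diag(P)[:p]
    return F, grad


def fit_ml(
    S: LaggedCovariance,
    spec: ModelSpec,
    start: ParamMatrixSet | None = None,
    config: EngineConfig = EngineConfig(),
) -> tuple[ParamMatrixSet, FitResult]:
    """Fit the model by minimizing the ML discrepancy on ``S``.

    Returns estimates with SEs/CIs and a FitResult with
    ``chi2 = (n_eff - 1) F_ML`` and bookkept degrees of freedom.
    """
    cov, p, m = S, S.p, S.m
    reg_ids = spec.free_params()
    reg_pos = [cov.exog_position(pid) for pid in reg_ids]
    k = len(reg_ids)
    df = model_df(p, spec.order, k, extra_exog=cov.n_exog_extra)

    theta0 = np.zeros(k + p)
    theta0[k:] = np.clip(np.diag(cov.S)[:p], 1e-6, None)
    if start is not None:
        for i, pid in enumerate(reg_ids):
            try:
                theta0[i] = start.estimate(pid)
            except (KeyError, IndexError, TypeError):
                pass
        theta0[k:] = np.clip(start.psi, 1e-6, None)

    logdetS = _safe_logdet(cov.S)
    bounds = [(None, None)] * k + [(config.psi_floor, None)] * p
    res = optimize.minimize(
        _f_and_grad,
        theta0,
        args=(cov, reg_pos, logdetS),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": config.max_iter, "ftol": 1e-14, "gtol": 1e-9},
    )
    theta = res.x
    F, grad = _f_and_grad(theta, cov, reg_pos, logdetS)
    converged = bool(np.isfinite(F) and np.linalg.norm(grad) < max(config.grad_tol, 1e-6 * (1 + abs(F))))
    psi = theta[k:]
    if np.any(psi <= config.heywood_tol):
        warnings.warn("Heywood case: an innovation variance was driven to its floor")

    state = _FitState(cov, spec, reg_ids, theta)
    Atil, Psit = state.matrices()
    M = np.linalg.solve(np.eye(m) - Atil, np.eye(m))
    Sigma = M @ Psit @ M.T

    chi2 = max((cov.n_eff - 1) * F, 0.0)
    base_F = float(np.sum(np.log(np.clip(np.diag(cov.S), 1e-300, None)))) - logdetS
    baseline_chi2 = max((cov.n_eff - 1) * base_F, 0.0)
    baseline_df = m * (m - 1) // 2

    fr = fit_indices(chi2, df, baseline_chi2, baseline_df, cov.n_eff, cov.S, Sigma, converged=converged)

    se = _standard_errors(state, M, Sigma, config)
    params = _build_params(spec, reg_ids, theta, se)
    return params, fr


def _build_params(spec: ModelSpec, reg_ids: list[ParamId], theta: np.ndarray, se: dict) -> ParamMatrixSet:
    p = spec.p
    A = np.zeros((p, p))
    phi = np.zeros((spec.order, p, p))
    gamma = np.zeros((spec.f + 1, p)) if spec.f is not None else None
    tau = np.zeros((spec.g, spec.h, p, p)) if spec.tau_free is not None else None
    for pid, val in zip(reg_ids, theta[: len(reg_ids)]):
        kind = pid[0]
        if kind == "A":
            A[pid[1], pid[2]] = val
        elif kind == "Phi":
            phi[pid[1] - 1, pid[2], pid[3]] = val
        elif kind == "gamma":
            gamma[pid[1], pid[2]] = val
        elif kind == "tau":
            tau[pid[1] - 1, pid[2] - 1, pid[3], pid[4]] = val
    return ParamMatrixSet(spec=spec, A=A, phi=phi, psi=theta[len(reg_ids):].copy(), gamma=gamma, tau=tau, se=se)


# ---------------------------------------------------------------------------
# Expected information, SEs, modification indices, Wald pruning
# ---------------------------------------------------------------------------


def _dsigma_reg(M: np.ndarray, Sigma: np.ndarray, r: int, c: int) -> np.ndarray:
    D = np.outer(M[:, r], Sigma[c, :])
    return D + D.T


def _dsigma_cov(M: np.ndarray, positions: Iterable[tuple[int, int]]) -> np.ndarray:
    out = np.zeros_like(M)
    for i, j in positions:
        if i == j:
            out += np.outer(M[:, i], M[:, i])
        else:
            D = np.outer(M[:, i], M[:, j])
            out += D + D.T
    return out


def _free_dsigmas(state: _FitState, M: np.ndarray, Sigma: np.ndarray) -> list[np.ndarray]:
    """dSigma/dtheta for every free parameter: regressions, psi, and the
    saturated exogenous covariance elements."""
    cov, p = state.cov, state.cov.p
    out = [_dsigma_reg(M, Sigma, *cov.exog_position(pid)) for pid in state.reg_ids]
    out += [_dsigma_cov(M, [(i, i)]) for i in range(p)]
    for i in range(p, cov.m):
        for j in range(i, cov.m):
            out.append(_dsigma_cov(M, [(i, j)]))
    return out


def _information(Sig_inv: np.ndarray, dsigmas: Sequence[np.ndarray]) -> np.ndarray:
    K = np.stack([Sig_inv @ D for D in dsigmas])
    return np.einsum("aij,bji->ab", K, K)


def _standard_errors(state: _FitState, M: np.ndarray, Sigma: np.ndarray, config: EngineConfig) -> dict:
    cov = state.cov
    Sig_inv = np.linalg.inv(Sigma)
    ds = _free_dsigmas(state, M, Sigma)
    H = _information(Sig_inv, ds)
    n_scale = 2.0 / max(cov.n_eff - 1, 1)
    try:
        Cth = n_scale * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        Cth = n_scale * np.linalg.pinv(H)
    diag = np.clip(np.diag(Cth), 0.0, None)
    se: dict = {}
    ids = list(state.reg_ids) + [("Psi", i) for i in range(cov.p)]
    for pid, v in zip(ids, diag[: len(ids)]):
        se[pid] = float(np.sqrt(v))
    return se


def _state_from_params(cov: LaggedCovariance, spec: ModelSpec, params: ParamMatrixSet) -> _FitState:
    reg_ids = spec.free_params()
    theta = np.concatenate([[params.estimate(pid) for pid in reg_ids], params.psi])
    return _FitState(cov, spec, reg_ids, np.asarray(theta, dtype=float))


def score_tests(
    cov: LaggedCovariance,
    state: _FitState,
    candidates: Sequence[tuple[ParamId, tuple[int, int]]],
    extra_free_dsigmas: list[np.ndarray] | None = None,
    M_Sigma: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[ModIndexRow]:
    """Lagrange-multiplier statistics for fixed candidate regressions.

    For each candidate, MI = (n_eff - 1)/2 * g^2 / h where g is the
    fit-function gradient at the fitted model and h the candidate's
    expected information conditioned on all free parameters.
    """
    if M_Sigma is None:
        Atil, Psit = state.matrices()
        M = np.linalg.solve(np.eye(cov.m) - Atil, np.eye(cov.m))
        Sigma = M @ Psit @ M.T
    else:
        M, Sigma = M_Sigma
    Sig_inv = np.linalg.inv(Sigma)
    G = Sig_inv - Sig_inv @ cov.S @ Sig_inv
    free_ds = extra_free_dsigmas if extra_free_dsigmas is not None else _free_dsigmas(state, M, Sigma)
    cand_ds = [_dsigma_reg(M, Sigma, r, c) for _, (r, c) in candidates]
    all_ds = free_ds + cand_ds
    K = np.stack([Sig_inv @ D for D in all_ds])
    H = np.einsum("aij,bji->ab", K, K)
    nf = len(free_ds)
    Hff = H[:nf, :nf]
    try:
        Hff_inv = np.linalg.inv(Hff)
    except np.linalg.LinAlgError:
        Hff_inv = np.linalg.pinv(Hff)
    n1 = max(cov.n_eff - 1, 1)
    rows: list[ModIndexRow] = []
    scale = np.abs(H).max() if H.size else 1.0
    for idx, (pid, _) in enumerate(candidates):
        c = nf + idx
        g = float(np.sum(G * cand_ds[idx]))
        h_cond = float(H[c, c] - H[c, :nf] @ Hff_inv @ H[:nf, c])
        if h_cond <= 1e-12 * max(scale, 1.0):
            continue  # candidate not identified (e.g. degenerate input column)
        mi = max(n1 / 2.0 * g * g / h_cond, 0.0)
        epc = -g / h_cond
        rows.append(ModIndexRow(param=pid, mi=mi, epc=epc))
    return rows


def modification_indices(
    S: LaggedCovariance,
    spec: ModelSpec,
    params: ParamMatrixSet,
    candidates: Sequence[ParamId],
    config: EngineConfig = EngineConfig(),
) -> ModIndexTable:
    """MI table for currently-fixed candidate regression parameters."""
    free = set(spec.free_params())
    cands: list[tuple[ParamId, tuple[int, int]]] = []
    for pid in candidates:
        if pid in free:
            warnings.warn(f"candidate {pid} is already free; excluded")
            continue
        cands.append((pid, S.exog_position(pid)))
    state = _state_from_params(S, spec, params)
    rows = score_tests(S, state, cands)
    rows.sort(key=lambda r: (-r.mi,) + _sort_key(r.param))
    return ModIndexTable(rows=tuple(rows))


def wald_prune(
    S: LaggedCovariance,
    spec: ModelSpec,
    params: ParamMatrixSet,
    alpha: float = 0.05,
    protected: Iterable[ParamId] = (),
    config: EngineConfig = EngineConfig(),
) -> tuple[ModelSpec, ParamMatrixSet, FitResult]:
    """Iteratively fix the least-significant free regression (Wald p >= alpha).

    Innovation variances and the exogenous covariance are never pruned;
    ``protected`` parameters (e.g. group-level paths) are kept free.
    """
    protected = set(protected)
    cur_spec, cur_params = spec, params
    _, cur_fit = fit_ml(S, cur_spec, start=cur_params, config=config)
    while True:
        candidates = [pid for pid in cur_spec.free_params() if pid not in protected]
        if not candidates:
            break
        pvals = [(cur_params.wald_p(pid), pid) for pid in candidates]
        worst_p, worst = max(pvals, key=lambda t: (t[0], _sort_key(t[1])))
        if worst_p < alpha:
            break
        new_spec = cur_spec.with_fixed(worst)
        new_params, new_fit = fit_ml(S, new_spec, start=cur_params, config=config)
        if not new_fit.converged:
            warnings.warn("pruning produced a non-convergent model; reverting last removal")
            break
        cur_spec, cur_params, cur_fit = new_spec, new_params, new_fit
    return cur_spec, cur_params, cur_fit
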