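"""Generative simulators for uSEM/euSEM and group-structured data.

Data are generated from the structural recursion
``y(t) = (I - A)^{-1} (sum_q Phi_q y(t-q) + input terms + z(t))`` with
serially independent Gaussian innovations (identity covariance by
default).  Stationarity is enforced up front via the spectral radius of
the reduced-form companion matrix, and a burn-in stretch is discarded so
the retained samples are draws from the stationary law.  A fixed seed
pins the numpy Generator stream, making every simulated series
bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .data_model import HrfKernel, InputSeries, RoiTimeSeries, convolve_input, hrf_double_gamma
from .sem_engine import ParamId

__all__ = [
    "SimulationSpec",
    "GroupSimulationSpec",
    "TaskProtocol",
    "simulate_usem",
    "second_order_scenario",
    "SECOND_ORDER_SCENARIO_BETAS",
    "simulate_eusem",
    "simulate_group",
]


@dataclass(frozen=True)
class SimulationSpec:
    """True parameters of a generating uSEM/euSEM."""

    p: int
    T: int
    order: int
    A: np.ndarray
    phi: np.ndarray                      # (order, p, p)
    gamma: np.ndarray | None = None      # (f+1, p)
    tau: np.ndarray | None = None        # (g, h, p, p)
    innovation_cov: np.ndarray | None = None
    burn_in: int = 500
    seed: int = 0
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        phi = np.asarray(self.phi, dtype=float).reshape(self.order, self.p, self.p)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "phi", phi)
        if A.shape != (self.p, self.p):
            raise ValueError("A has wrong shape")
        cov = np.eye(self.p) if self.innovation_cov is None else np.asarray(self.innovation_cov, dtype=float)
        if cov.shape != (self.p, self.p) or not np.allclose(cov, cov.T):
            raise ValueError("innovation covariance must be p x p symmetric")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError("innovation covariance must be positive definite")
        object.__setattr__(self, "innovation_cov", cov)
        if abs(np.linalg.det(np.eye(self.p) - A)) < 1e-12:
            raise ValueError("I - A is singular")
        rho = self.spectral_radius()
        if rho >= 1.0:
            raise ValueError(f"non-stationary specification: spectral radius {rho:.3f} >= 1")

    def spectral_radius(self) -> float:
        """Spectral radius of the reduced-form companion matrix."""
        if self.order == 0:
            return 0.0
        p, a = self.p, self.order
        ImA_inv = np.linalg.inv(np.eye(p) - self.A)
        comp = np.zeros((a * p, a * p))
        for q in range(a):
            comp[:p, q * p : (q + 1) * p] = ImA_inv @ self.phi[q]
        if a > 1:
            comp[p:, : (a - 1) * p] = np.eye((a - 1) * p)
        return float(np.abs(np.linalg.eigvals(comp)).max())

    def nonzero_coefficients(self) -> list[tuple[ParamId, float]]:
        out: list[tuple[ParamId, float]] = []
        for k in range(self.p):
            for j in range(self.p):
                if self.A[k, j] != 0.0:
                    out.append((("A", k, j), float(self.A[k, j])))
        for q in range(1, self.order + 1):
            for k in range(self.p):
                for j in range(self.p):
                    if self.phi[q - 1, k, j] != 0.0:
                        out.append((("Phi", q, k, j), float(self.phi[q - 1, k, j])))
        if self.gamma is not None:
            for r in range(self.gamma.shape[0]):
                for k in range(self.p):
                    if self.gamma[r, k] != 0.0:
                        out.append((("gamma", r, k), float(self.gamma[r, k])))
        if self.tau is not None:
            g, h = self.tau.shape[:2]
            for q in range(1, g + 1):
                for r in range(1, h + 1):
                    for k in range(self.p):
                        for j in range(self.p):
                            if self.tau[q - 1, r - 1, k, j] != 0.0:
                                out.append((("tau", q, r, k, j), float(self.tau[q - 1, r - 1, k, j])))
        return out


def _iterate(spec: SimulationSpec, u_conv: np.ndarray | None) -> np.ndarray:
    p, T, a = spec.p, spec.T, spec.order
    total = T + spec.burn_in
    rng = np.random.default_rng(spec.seed)
    L = np.linalg.cholesky(spec.innovation_cov)
    Z = L @ rng.standard_normal((p, total))
    ImA_inv = np.linalg.inv(np.eye(p) - spec.A)
    u_full = np.zeros(total)
    if u_conv is not None:
        u_full[spec.burn_in :] = u_conv[:T]
    Y = np.zeros((p, total))
    f = spec.gamma.shape[0] - 1 if spec.gamma is not None else -1
    g, h = (spec.tau.shape[:2] if spec.tau is not None else (0, 0))
    for t in range(total):
        rhs = Z[:, t].copy()
        for q in range(1, a + 1):
            if t - q >= 0:
                rhs += spec.phi[q - 1] @ Y[:, t - q]
        if spec.gamma is not None:
            for r in range(f + 1):
                if t - r >= 0:
                    rhs += spec.gamma[r] * u_full[t - r]
        if spec.tau is not None:
            for q in range(1, g + 1):
                for r in range(1, h + 1):
                    if t - max(q, r) >= 0:
                        rhs += spec.tau[q - 1, r - 1] @ Y[:, t - q] * u_full[t - r]
        Y[:, t] = ImA_inv @ rhs
    return Y[:, spec.burn_in :]


def simulate_usem(spec: SimulationSpec) -> RoiTimeSeries:
    """Simulate a stationary uSEM realization of length T (burn-in dropped)."""
    Y = _iterate(spec, None)
    return RoiTimeSeries(
        values=Y,
        labels=tuple(f"ROI{i + 1}" for i in range(spec.p)),
        tr_seconds=spec.tr_seconds,
    )


#: Stand-in magnitudes for the three-ROI second-order scenario: first-order
#: autoregression 0.4 on every ROI, an extra 0.3 second-order autoregression
#: on ROI 3, a 0.5 contemporaneous path ROI3 -> ROI1, and a 0.4 cross-lag
#: ROI1 -> ROI2.  Overridable; chosen (and documented) as package defaults.
SECOND_ORDER_SCENARIO_BETAS: Mapping[ParamId, float] = {
    ("Phi", 1, 0, 0): 0.4,
    ("Phi", 1, 1, 1): 0.4,
    ("Phi", 1, 2, 2): 0.4,
    ("Phi", 2, 2, 2): 0.3,
    ("A", 0, 2): 0.5,
    ("Phi", 1, 1, 0): 0.4,
}


def second_order_scenario(
    betas: Mapping[ParamId, float] | None = None,
    T: int = 200,
    seed: int = 0,
) -> SimulationSpec:
    """The canonical single-subject scenario: 3 ROIs, 200 time points,
    second-order generating uSEM with identity innovation covariance and
    six nonzero coefficients."""
    coeffs = dict(SECOND_ORDER_SCENARIO_BETAS)
    if betas:
        coeffs.update(betas)
    p, a = 3, 2
    A = np.zeros((p, p))
    phi = np.zeros((a, p, p))
    for pid, val in coeffs.items():
        if pid[0] == "A":
            A[pid[1], pid[2]] = val
        elif pid[0] == "Phi":
            phi[pid[1] - 1, pid[2], pid[3]] = val
        else:
            raise ValueError(f"scenario accepts only A/Phi overrides, got {pid}")
    return SimulationSpec(p=p, T=T, order=a, A=A, phi=phi, seed=seed)


@dataclass(frozen=True)
class TaskProtocol:
    """A block design: alternating task and rest blocks, in seconds."""

    n_task_blocks: int = 3
    block_seconds: float = 36.0
    rest_seconds: float = 36.0
    initial_rest_seconds: float = 0.0

    def boxcar(self, T: int, tr_seconds: float) -> np.ndarray:
        u = np.zeros(T)
        t = self.initial_rest_seconds
        for _ in range(self.n_task_blocks):
            lo = int(round(t / tr_seconds))
            hi = int(round((t + self.block_seconds) / tr_seconds))
            u[lo:min(hi, T)] = 1.0
            t += self.block_seconds + self.rest_seconds
        return u


def simulate_eusem(
    spec: SimulationSpec,
    protocol: TaskProtocol,
    kernel: HrfKernel | None = None,
) -> tuple[RoiTimeSeries, InputSeries]:
    """Simulate an euSEM: a boxcar condition vector built from the block
    protocol, HRF-convolved, driving direct (gamma) and bilinear (tau)
    effects inside the recursion."""
    if spec.gamma is None and spec.tau is None:
        raise ValueError("euSEM simulation requires gamma and/or tau in the spec")
    kernel = kernel or hrf_double_gamma(spec.tr_seconds)
    raw = protocol.boxcar(spec.T, spec.tr_seconds)
    u = convolve_input(InputSeries(raw=raw[None, :]), kernel)
    Y = _iterate(spec, u.effective[0])
    ts = RoiTimeSeries(
        values=Y,
        labels=tuple(f"ROI{i + 1}" for i in range(spec.p)),
        tr_seconds=spec.tr_seconds,
    )
    return ts, u


# ---------------------------------------------------------------------------
# Multi-subject group simulation
# ---------------------------------------------------------------------------

_DEFAULT_GROUP_EDGES: tuple[tuple[ParamId, float], ...] = (
    (("Phi", 1, 0, 0), 0.4),
    (("Phi", 1, 1, 1), 0.4),
    (("Phi", 1, 2, 2), 0.4),
    (("Phi", 1, 3, 3), 0.4),
    (("A", 1, 0), 0.35),
    (("A", 2, 0), 0.35),
    (("A", 3, 0), 0.35),
    (("A", 2, 3), 0.3),
)

_DEFAULT_INDIVIDUAL_POOL: tuple[ParamId, ...] = (
    ("A", 0, 1),
    ("A", 1, 2),
    ("A", 3, 1),
    ("Phi", 1, 0, 1),
    ("Phi", 1, 2, 1),
    ("Phi", 1, 1, 3),
)


@dataclass(frozen=True)
class GroupSimulationSpec:
    """Resting-state-like multi-subject design: a shared group structure
    (per-ROI lag-1 autoregressions plus four contemporaneous paths among
    four ROIs), subject-specific extra connections, and a designated
    fraction of subjects carrying an additional lag-2 autoregression."""

    n_subjects: int = 32
    p: int = 4
    T: int = 160
    group_edges: tuple[tuple[ParamId, float], ...] = _DEFAULT_GROUP_EDGES
    jitter: float = 0.1
    individual_pool: tuple[ParamId, ...] = _DEFAULT_INDIVIDUAL_POOL
    n_individual: int = 2
    individual_coeff: float = 0.3
    fraction_lag2: float = 0.5
    lag2_coeff: float = 0.4
    seed: int = 0
    burn_in: int = 500
    max_redraws: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_lag2 <= 1.0:
            raise ValueError("fraction_lag2 must be in [0, 1]")


def simulate_group(gspec: GroupSimulationSpec) -> tuple[list[RoiTimeSeries], list[dict]]:
    """Simulate every subject and return the series plus a truth ledger.

    Per subject, group-edge coefficients are the group mean plus uniform
    jitter, ``n_individual`` extra edges are drawn from the pool, and the
    first ``round(fraction_lag2 * n)`` subjects (in a seed-shuffled
    order) receive one lag-2 autoregressive edge.
    """
    rng = np.random.default_rng(gspec.seed)
    n, p = gspec.n_subjects, gspec.p
    n_lag2 = int(round(gspec.fraction_lag2 * n))
    lag2_subjects = set(rng.permutation(n)[:n_lag2].tolist())
    series: list[RoiTimeSeries] = []
    ledger: list[dict] = []
    for i in range(n):
        has_lag2 = i in lag2_subjects
        for attempt in range(gspec.max_redraws + 1):
            edges: list[tuple[ParamId, float, str]] = []
            for pid, mean in gspec.group_edges:
                val = mean + rng.uniform(-gspec.jitter, gspec.jitter)
                edges.append((pid, float(val), "group"))
            pool = [pid for pid in gspec.individual_pool]
            chosen = rng.choice(len(pool), size=min(gspec.n_individual, len(pool)), replace=False)
            for c in chosen:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                val = sign * (gspec.individual_coeff + rng.uniform(-gspec.jitter, gspec.jitter))
                edges.append((pool[c], float(val), "individual"))
            if has_lag2:
                roi = int(rng.integers(p))
                edges.append((("Phi", 2, roi, roi), float(gspec.lag2_coeff), "individual"))
            order = max([pid[1] if pid[0] == "Phi" else 0 for pid, _, _ in edges] + [1])
            A = np.zeros((p, p))
            phi = np.zeros((order, p, p))
            for pid, val, _ in edges:
                if pid[0] == "A":
                    A[pid[1], pid[2]] = val
                else:
                    phi[pid[1] - 1, pid[2], pid[3]] = val
            try:
                spec = SimulationSpec(
                    p=p,
                    T=gspec.T,
                    order=order,
                    A=A,
                    phi=phi,
                    burn_in=gspec.burn_in,
                    seed=int(rng.integers(2**31 - 1)),
                )
                break
            except ValueError:
                if attempt == gspec.max_redraws:
                    raise ValueError(f"could not draw a stationary spec for subject {i + 1}")
        series.append(simulate_usem(spec))
        ledger.append(
            {
                "subject": f"subj{i + 1}",
                "has_lag2": has_lag2,
                "edges": [
                    {
                        "matrix": pid[0],
                        "lag": 0 if pid[0] == "A" else pid[1],
                        "target": pid[1] if pid[0] == "A" else pid[2],
                        "source": pid[2] if pid[0] == "A" else pid[3],
                        "value": val,
                        "level": level,
                    }
                    for pid, val, level in edges
                ],
            }
        )
    return series, ledger


def write_truth_ledger(ledger: Sequence[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(list(ledger), indent=1))
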