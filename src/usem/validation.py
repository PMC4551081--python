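"""A posteriori validation of the temporal order of connectivity maps.

A fitted map is validated by testing whether its one-step-ahead
prediction errors are white noise: a lag-3 VAR is laid out on the
block-Toeplitz covariance of the residuals and the null model fixing
every lagged regression coefficient at zero (with one repeated free
contemporaneous covariance) is fitted; the map passes when that null
model fits excellently by the same 2-of-4 rule used for model
acceptance.  When the test fails, modification indices over the lagged
residual dependencies drive the revision: a few interpretable indices
are freed confirmatorily at the indicated lags (option a), a diffuse
pattern triggers a data-driven search one order higher (option b), and
subdividing a long non-stationary series (option c) is available only as
an explicit user request.  The loop repeats until the residuals are
white or the maximum order is exhausted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_model import InputSeries, RoiTimeSeries, center
from .sem_engine import (
    MI_CRIT_05,
    EngineConfig,
    FitResult,
    ModIndexRow,
    ModIndexTable,
    ModelSpec,
    ParamId,
    ParamMatrixSet,
    _FitState,
    _dsigma_cov,
    block_toeplitz_cov,
    fit_indices,
    fit_ml,
    score_tests,
)
from .usem_family import GroupModel, SearchConfig, excellent_fit, usem_search, eusem_search

__all__ = [
    "ResidualSeries",
    "WhiteNoiseResult",
    "DecisionPolicy",
    "Decision",
    "ValidationTrace",
    "TraceRecord",
    "GroupValidationResult",
    "prediction_errors",
    "white_noise_df",
    "white_noise_test",
    "decide_option",
    "validate",
    "validate_group",
]


@dataclass(frozen=True)
class ResidualSeries:
    """One-step-ahead prediction errors of a fitted model (p x (T - a))."""

    values: np.ndarray
    parent_model_id: str
    a_used: int
    model_order: int = 0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("residuals contain non-finite values")
        object.__setattr__(self, "values", vals)

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def length(self) -> int:
        return self.values.shape[1]


def prediction_errors(
    ts: RoiTimeSeries,
    params: ParamMatrixSet,
    u: InputSeries | None = None,
) -> ResidualSeries:
    """Realized innovations: the observation minus every fitted
    contemporaneous, lagged, direct-input and bilinear term; the first
    ``a`` (or input-lag, if larger) time points are dropped."""
    if not ts.centered:
        ts = center(ts)
    spec = params.spec
    p, T = ts.p, ts.T
    if p != spec.p:
        raise ValueError("series and model dimension mismatch")
    a = spec.order
    t0 = a
    u_eff = None
    if spec.f is not None:
        if u is None:
            raise ValueError("model has input terms but no input series was given")
        u_eff = u.effective[0]
        if u_eff.shape[0] != T:
            raise ValueError("input length must match the time series")
        t0 = max(t0, spec.f, spec.g, spec.h)
    if t0 >= T:
        raise ValueError("model order exceeds the available history")
    Y = ts.values
    idx = np.arange(t0, T)
    Z = (np.eye(p) - params.A) @ Y[:, idx]
    for q in range(1, a + 1):
        Z -= params.phi[q - 1] @ Y[:, idx - q]
    if u_eff is not None and params.gamma is not None:
        for r in range(spec.f + 1):
            Z -= np.outer(params.gamma[r], u_eff[idx - r])
    if u_eff is not None and params.tau is not None:
        for q in range(1, spec.g + 1):
            for r in range(1, spec.h + 1):
                W = Y[:, idx - q] * u_eff[idx - r]
                W = W - W.mean(axis=1, keepdims=True)  # products enter centered
                Z -= params.tau[q - 1, r - 1] @ W
    return ResidualSeries(values=Z, parent_model_id=f"order{a}", a_used=t0, model_order=a)


def white_noise_df(p: int, L: int = 3) -> int:
    """df of the white-noise null on an order-L block-Toeplitz matrix:
    all lagged blocks fixed at zero and the L+1 diagonal blocks tied to a
    single free contemporaneous covariance."""
    if p < 1 or L < 0:
        raise ValueError("need p >= 1 and L >= 0")
    m = p * (L + 1)
    return m * (m + 1) // 2 - p * (p + 1) // 2


@dataclass(frozen=True)
class WhiteNoiseResult:
    fit: FitResult
    mi: ModIndexTable
    passed: bool
    L: int
    p: int
    model_order: int = 0  # order of the model whose residuals were tested

    def significant(self, crit: float = MI_CRIT_05) -> list[ModIndexRow]:
        return self.mi.significant(crit)


def white_noise_test(
    res: ResidualSeries,
    L: int = 3,
    cfg: SearchConfig | None = None,
) -> WhiteNoiseResult:
    """White-noise test of prediction errors via the block-Toeplitz method.

    The null model's implied covariance is block-diagonal with one
    repeated free p x p contemporaneous covariance; its ML solution is
    closed-form (the lag-0 block), and the chi-square measures every
    lagged moment.  The MI table reports, per (target, source, lag), the
    Lagrange-multiplier statistic for the corresponding lagged
    regression coefficient.
    """
    cfg = cfg or SearchConfig()
    p = res.p
    if res.length <= p * (L + 1):
        raise ValueError(f"residual series too short for a lag-{L} white-noise test")
    ts = center(
        RoiTimeSeries(
            values=res.values,
            labels=tuple(f"e{i + 1}" for i in range(p)),
        )
    )
    cov = block_toeplitz_cov(ts, L)
    m = cov.m
    C0 = cov.S[:p, :p]
    sign0, logdetC0 = np.linalg.slogdet(C0)
    signS, logdetS = np.linalg.slogdet(cov.S)
    if sign0 <= 0 or signS <= 0:
        raise ValueError("degenerate residual covariance in white-noise test")
    F = (L + 1) * logdetC0 - logdetS
    n_eff = cov.n_eff
    chi2 = max((n_eff - 1) * F, 0.0)
    df = white_noise_df(p, L)
    base_F = float(np.sum(np.log(np.diag(cov.S)))) - logdetS
    baseline_chi2 = max((n_eff - 1) * base_F, 0.0)
    fr = fit_indices(
        chi2,
        df,
        baseline_chi2,
        m * (m - 1) // 2,
        n_eff,
        cov.S,
        np.kron(np.eye(L + 1), C0),
        converged=True,
    )
    assert fr.df == white_noise_df(p, L)

    # Score tests for the lagged regression coefficients, conditioned on
    # the tied free contemporaneous covariance.
    I_m = np.eye(m)
    Sigma = np.kron(np.eye(L + 1), C0)
    free_ds = []
    for i in range(p):
        for j in range(i, p):
            positions = [(b * p + i, b * p + j) for b in range(L + 1)]
            free_ds.append(_dsigma_cov(I_m, positions))
    cands: list[tuple[ParamId, tuple[int, int]]] = [
        (("Phi", l, k, j), (k, l * p + j))
        for l in range(1, L + 1)
        for k in range(p)
        for j in range(p)
    ]
    state = _FitState(cov, ModelSpec.null(p, L), [], np.concatenate([[ ], np.diag(C0)]).astype(float))
    rows = score_tests(cov, state, cands, extra_free_dsigmas=free_ds, M_Sigma=(I_m, Sigma))
    rows.sort(key=lambda r: -r.mi)
    table = ModIndexTable(rows=tuple(rows))
    return WhiteNoiseResult(
        fit=fr, mi=table, passed=excellent_fit(fr, cfg), L=L, p=p, model_order=res.model_order
    )


# ---------------------------------------------------------------------------
# Decision criteria
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DecisionPolicy:
    """How white-noise failures are turned into map revisions.

    ``few_threshold``: at most this many significant residual MIs counts
    as "a few" interpretable parameters (confirmatory freeing, option a);
    anything else is treated as "no clear pattern" (option b).
    Subdividing the series (option c) is never chosen automatically.
    """

    few_threshold: int = 5
    mi_crit: float = MI_CRIT_05
    max_lag_step: int = 1     # confirmatory freeing reaches at most one lag higher
    allow_subdivision: bool = False
    segment_boundaries: tuple[int, ...] = ()


@dataclass(frozen=True)
class Decision:
    action: str  # option_a | option_b | option_c
    mapped_params: tuple[ParamId, ...] = ()


def decide_option(
    wn: WhiteNoiseResult,
    policy: DecisionPolicy | None = None,
    current_spec: ModelSpec | None = None,
) -> Decision:
    """Map a failed white-noise test to a revision option.

    A residual dependency at lag l from source j to target k maps to the
    model parameter Phi_l[k, j] (lag 0 maps to A[k, j]).  When that
    parameter is already free in the current model, the dependency
    signals that the modelled lag is too shallow for those indices and
    the next-lag term Phi_{l+1}[k, j] is freed instead.  Mapped lags
    reach at most ``max_lag_step`` above the current order; deeper
    indices are revisited once the order has grown.
    """
    policy = policy or DecisionPolicy()
    if wn.passed:
        raise ValueError("decide_option requires a failed white-noise test")
    if policy.allow_subdivision:
        return Decision(action="option_c")
    lag_cap = wn.model_order + policy.max_lag_step
    sig = wn.significant(policy.mi_crit)
    if 0 < len(sig) <= policy.few_threshold:
        mapped: list[ParamId] = []
        for row in sig:
            _, l, k, j = row.param
            pid: ParamId = ("A", k, j) if l == 0 else ("Phi", l, k, j)
            if current_spec is not None and current_spec.is_free(pid):
                nxt = 1 if l == 0 else l + 1
                pid = ("Phi", nxt, k, j)
                if current_spec.is_free(pid):
                    continue
                l = nxt
            if l > lag_cap:
                continue
            if pid not in mapped:
                mapped.append(pid)
        if mapped:
            return Decision(action="option_a", mapped_params=tuple(mapped))
    return Decision(action="option_b")


# ---------------------------------------------------------------------------
# The validation loop
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraceRecord:
    spec: ModelSpec
    fit: FitResult
    white_noise: WhiteNoiseResult
    action: str  # accept | option_a | option_b | option_c | give_up


@dataclass(frozen=True)
class ValidationTrace:
    records: tuple[TraceRecord, ...]
    final_spec: ModelSpec
    final_params: ParamMatrixSet
    final_fit: FitResult
    accepted: bool

    @property
    def final_order(self) -> int:
        return self.final_spec.order

    def to_json_dict(self) -> dict:
        return {
            "accepted": self.accepted,
            "final_order": self.final_order,
            "iterations": [
                {
                    "order": r.spec.order,
                    "free": [list(pid) for pid in r.spec.free_params()],
                    "fit": r.fit.indices(),
                    "white_noise": {
                        "passed": r.white_noise.passed,
                        "fit": r.white_noise.fit.indices(),
                        "mi": [
                            {"param": list(row.param), "mi": row.mi, "epc": row.epc}
                            for row in r.white_noise.mi
                        ],
                    },
                    "action": r.action,
                }
                for r in self.records
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1))

    def report(self) -> str:
        """Human-readable report: a model-fit block and a white-noise block
        per iteration, mirroring the usual fit-table layout."""
        lines = []
        for i, r in enumerate(self.records, 1):
            lines.append(f"== Iteration {i}: order-{r.spec.order} model, {r.spec.k_free} freed ==")
            lines.append("MODEL FIT")
            lines.append(_fmt_fit(r.fit))
            lines.append("WHITE NOISE TEST")
            lines.append(_fmt_fit(r.white_noise.fit))
            lines.append(f"white noise: {'passed' if r.white_noise.passed else 'FAILED'}; action: {r.action}")
        lines.append(
            f"final order: {self.final_order} ({'accepted' if self.accepted else 'gave up'})"
        )
        return "\n".join(lines)


def _fmt_fit(fr: FitResult) -> str:
    nnfi = "--" if fr.nnfi is None else f"{fr.nnfi:.2f}"
    return (
        f"  chi2({fr.df}) = {fr.chi2:.2f} (p = {fr.p_value:.3f}), RMSEA = {fr.rmsea:.2f}, "
        f"SRMR = {fr.srmr:.2f}, CFI = {fr.cfi:.2f}, NNFI = {nnfi}"
    )


def validate(
    ts: RoiTimeSeries,
    params: ParamMatrixSet,
    cfg: SearchConfig | None = None,
    policy: DecisionPolicy | None = None,
    max_order: int = 3,
    L: int = 3,
    base: ModelSpec | None = None,
    u: InputSeries | None = None,
    fit: FitResult | None = None,
) -> ValidationTrace:
    """Iterate white-noise testing and map revision until residuals are
    white or the order budget is exhausted.

    ``base`` (e.g. a GIMME group structure) is held as the permanent
    starting structure of any option-b re-search.  Option a re-fits the
    current structure confirmatorily with the mapped parameters added,
    raising the order when a mapped lag exceeds it.
    """
    cfg = cfg or SearchConfig()
    policy = policy or DecisionPolicy()
    ts = ts if ts.centered else center(ts)
    cur_spec = params.spec
    cur_params = params
    if fit is None:
        from .usem_family import usem_confirmatory

        cur_params, fit = usem_confirmatory(ts, cur_spec, cfg, inputs=u)
    cur_fit = fit
    records: list[TraceRecord] = []
    seen = {cur_spec.key()}
    while True:
        res = prediction_errors(ts, cur_params, u)
        wn = white_noise_test(res, L, cfg)
        if wn.passed:
            records.append(TraceRecord(cur_spec, cur_fit, wn, "accept"))
            return ValidationTrace(tuple(records), cur_spec, cur_params, cur_fit, accepted=True)
        decision = decide_option(wn, policy, current_spec=cur_spec)
        new_state = None
        if decision.action == "option_a":
            max_lag = max([pid[1] if pid[0] == "Phi" else 0 for pid in decision.mapped_params])
            new_order = max(cur_spec.order, max_lag)
            if new_order <= max_order:
                new_spec = cur_spec.expanded_to_order(new_order)
                for pid in decision.mapped_params:
                    if not new_spec.is_free(pid):
                        new_spec = new_spec.with_freed(pid)
                if new_spec.key() not in seen:
                    from .sem_engine import wald_prune
                    from .usem_family import _cov_for_spec, usem_confirmatory

                    try:
                        new_params, new_fit = usem_confirmatory(ts, new_spec, cfg, inputs=u)
                        if new_fit.converged:
                            # the family protocol ends every refit with Wald
                            # trimming; the base (group) structure is kept
                            cov = _cov_for_spec(ts, new_spec, u, cfg)
                            new_spec, new_params, new_fit = wald_prune(
                                cov,
                                new_spec,
                                new_params,
                                alpha=cfg.mi_alpha,
                                protected=(base.free_params() if base is not None else ()),
                                config=cfg.engine,
                            )
                            # trimming may undo the additions and revisit a
                            # spec already on the trace; fall through to b
                            if new_spec.key() not in seen:
                                new_state = (new_spec, new_params, new_fit)
                    except ValueError:
                        new_state = None
        if decision.action == "option_b" or (decision.action == "option_a" and new_state is None):
            new_order = cur_spec.order + 1
            if new_order <= max_order:
                search_cfg = replace(cfg, order=new_order)
                base_spec = (base or ModelSpec.null(ts.p, new_order, f=cur_spec.f, g=cur_spec.g, h=cur_spec.h)).expanded_to_order(new_order)
                if u is None:
                    new_spec, new_params, new_fit = usem_search(ts, search_cfg, base=base_spec)
                else:
                    new_spec, new_params, new_fit = eusem_search(ts, u, search_cfg, base=base_spec)
                if new_spec.key() in seen or not new_fit.converged:
                    new_state = None
                else:
                    new_state = (new_spec, new_params, new_fit)
                decision = replace(decision) if decision.action == "option_b" else Decision("option_b")
        if new_state is None:
            records.append(TraceRecord(cur_spec, cur_fit, wn, "give_up"))
            return ValidationTrace(tuple(records), cur_spec, cur_params, cur_fit, accepted=False)
        records.append(TraceRecord(cur_spec, cur_fit, wn, decision.action))
        cur_spec, cur_params, cur_fit = new_state
        seen.add(cur_spec.key())


@dataclass(frozen=True)
class GroupValidationResult:
    traces: tuple[ValidationTrace, ...]
    subject_ids: tuple[str, ...]

    @property
    def n_above_first_order(self) -> int:
        return sum(1 for t in self.traces if t.accepted and t.final_order > 1)

    @property
    def fraction_above_first_order(self) -> float:
        return self.n_above_first_order / len(self.traces)


def validate_group(
    gm: GroupModel,
    ts_list: Sequence[RoiTimeSeries],
    cfg: SearchConfig | None = None,
    policy: DecisionPolicy | None = None,
    max_order: int = 3,
    L: int = 3,
) -> GroupValidationResult:
    """Per-subject validation with the group structure as the permanent
    base of every revision, so the group-level map is maintained while
    individual-level connections absorb higher-order dependencies."""
    cfg = cfg or SearchConfig()
    if len(ts_list) != gm.n_subjects:
        raise ValueError("one series per subject is required")
    traces = []
    for sr, ts in zip(gm.subjects, ts_list):
        trace = validate(
            ts,
            sr.params,
            cfg,
            policy,
            max_order=max_order,
            L=L,
            base=gm.group_spec,
            fit=sr.fit,
        )
        traces.append(trace)
    return GroupValidationResult(
        traces=tuple(traces), subject_ids=tuple(s.subject_id for s in gm.subjects)
    )
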