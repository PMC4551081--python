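"""Data-driven and confirmatory uSEM/euSEM fitting and the two-stage
GIMME group/individual search.

The data-driven search starts from the null model (empty ``A`` and
``Phi_q``), repeatedly frees the candidate connection with the largest
significant modification index, and stops once the 2-of-4 excellent-fit
rule passes or no candidate is significant; non-significant freed
parameters are then trimmed with Wald tests.  GIMME first builds a
group-level connection structure shared by all subjects (a candidate is
freed when its modification index is significant for at least the
grouping criterion's share of the sample, conventionally 75%) and then
runs the individual-level search per subject on top of that structure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import chi2 as _chi2_dist

from .data_model import InputSeries, RoiTimeSeries, center
from .sem_engine import (
    EngineConfig,
    FitResult,
    LaggedCovariance,
    ModelSpec,
    ParamId,
    ParamMatrixSet,
    block_toeplitz_cov,
    fit_ml,
    modification_indices,
    wald_prune,
)

__all__ = [
    "SearchConfig",
    "GroupModel",
    "SubjectResult",
    "excellent_fit",
    "usem_confirmatory",
    "usem_search",
    "eusem_search",
    "gimme_group_search",
    "group_threshold_count",
    "candidate_set",
    "edge_rows",
]


@dataclass(frozen=True)
class SearchConfig:
    """Search and acceptance settings for the uSEM family.

    The excellent-fit thresholds and the 2-of-4 rule are the conventional
    alternative-fit-index cutoffs; ``criterion`` is the GIMME grouping
    criterion (share of subjects for which a candidate must be
    significant to enter the group model).
    """

    order: int = 1
    f: int = 1
    g: int = 1
    h: int = 1
    mi_alpha: float = 0.05
    rmsea_max: float = 0.05
    srmr_max: float = 0.05
    cfi_min: float = 0.95
    nnfi_min: float = 0.95
    n_pass: int = 2
    max_free: int | None = None
    criterion: float = 0.75
    engine: EngineConfig = field(default_factory=EngineConfig)

    def __post_init__(self) -> None:
        if not 0 < self.criterion <= 1:
            raise ValueError("criterion must be in (0, 1]")
        if not 1 <= self.n_pass <= 4:
            raise ValueError("n_pass must be in 1..4")

    @property
    def mi_crit(self) -> float:
        return float(_chi2_dist.ppf(1.0 - self.mi_alpha, 1))


def excellent_fit(fr: FitResult, cfg: SearchConfig) -> bool:
    """True iff at least ``n_pass`` of the four index thresholds pass
    (boundary equality passes; a missing index counts as a fail)."""
    checks = [
        fr.rmsea is not None and fr.rmsea <= cfg.rmsea_max,
        fr.srmr is not None and fr.srmr <= cfg.srmr_max,
        fr.cfi is not None and fr.cfi >= cfg.cfi_min,
        fr.nnfi is not None and fr.nnfi >= cfg.nnfi_min,
    ]
    return sum(checks) >= cfg.n_pass


def group_threshold_count(n: int, criterion: float) -> int:
    """Smallest integer >= criterion * n (e.g. 24 of 32 at 75%)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return int(math.ceil(criterion * n - 1e-9))


def candidate_set(spec: ModelSpec) -> list[ParamId]:
    """All free-able regressions for a spec's shape: off-diagonal A, every
    Phi_q entry, and (for input models) every gamma_r and tau_{q,r}."""
    p = spec.p
    out: list[ParamId] = [("A", k, j) for k in range(p) for j in range(p) if k != j]
    out += [("Phi", q, k, j) for q in range(1, spec.order + 1) for k in range(p) for j in range(p)]
    if spec.f is not None:
        out += [("gamma", r, k) for r in range(spec.f + 1) for k in range(p)]
    if spec.g and spec.h:
        out += [
            ("tau", q, r, k, j)
            for q in range(1, spec.g + 1)
            for r in range(1, spec.h + 1)
            for k in range(p)
            for j in range(p)
        ]
    return out


def _ensure_centered(ts: RoiTimeSeries) -> RoiTimeSeries:
    return ts if ts.centered else center(ts)


def usem_confirmatory(
    ts: RoiTimeSeries,
    spec: ModelSpec,
    cfg: SearchConfig | None = None,
    inputs: InputSeries | None = None,
) -> tuple[ParamMatrixSet, FitResult]:
    """Single ML fit of a pre-specified connection structure (no search)."""
    cfg = cfg or SearchConfig(order=spec.order)
    ts = _ensure_centered(ts)
    cov = _cov_for_spec(ts, spec, inputs, cfg)
    return fit_ml(cov, spec, config=cfg.engine)


def _cov_for_spec(
    ts: RoiTimeSeries, spec: ModelSpec, inputs: InputSeries | None, cfg: SearchConfig
) -> LaggedCovariance:
    if spec.f is not None and inputs is None:
        raise ValueError("spec includes input terms but no input series was given")
    if inputs is None:
        return block_toeplitz_cov(ts, spec.order)
    return block_toeplitz_cov(
        ts,
        spec.order,
        inputs=inputs,
        bilinear=bool(spec.g and spec.h),
        f=spec.f if spec.f is not None else 1,
        g=spec.g or 1,
        h=spec.h or 1,
    )


def _search(
    cov: LaggedCovariance,
    cfg: SearchConfig,
    base: ModelSpec,
    protected: Sequence[ParamId] = (),
) -> tuple[ModelSpec, ParamMatrixSet, FitResult]:
    """The shared modification-index freeing loop followed by Wald trimming
    and a contemporaneous-orientation sweep.

    Direction of a contemporaneous path is only weakly identified at the
    moment it is freed (its MI is symmetric in orientation), so after
    trimming, each freed A path is re-checked against its reversed
    orientation under the full lagged structure; the better-fitting
    orientation is kept and the model re-trimmed.
    """
    protected_set = set(protected) | set(base.free_params())
    spec, params, fit = _free_loop(cov, cfg, base)
    for _ in range(3):
        spec, params, fit = wald_prune(
            cov, spec, params, alpha=cfg.mi_alpha, protected=tuple(protected_set), config=cfg.engine
        )
        spec, params, fit, swapped = _orientation_sweep(cov, cfg, spec, params, fit, protected_set)
        if not swapped:
            break
        spec, params, fit = _free_loop(cov, cfg, spec, start=params)
    return spec, params, fit


def _orientation_sweep(cov, cfg, spec, params, fit, protected_set):
    swapped = False
    for pid in list(spec.free_params()):
        if pid[0] != "A" or pid in protected_set:
            continue
        mirror = ("A", pid[2], pid[1])
        if spec.is_free(mirror) or mirror in protected_set:
            continue
        trial_spec = spec.with_fixed(pid).with_freed(mirror)
        try:
            trial_params, trial_fit = fit_ml(cov, trial_spec, start=params, config=cfg.engine)
        except ValueError:
            continue
        if trial_fit.converged and trial_fit.chi2 < fit.chi2 - 1e-6:
            spec, params, fit = trial_spec, trial_params, trial_fit
            swapped = True
    return spec, params, fit, swapped


def _free_loop(
    cov: LaggedCovariance,
    cfg: SearchConfig,
    base: ModelSpec,
    start: ParamMatrixSet | None = None,
) -> tuple[ModelSpec, ParamMatrixSet, FitResult]:
    spec = base
    params, fit = fit_ml(cov, spec, start=start, config=cfg.engine)
    all_cands = candidate_set(spec)
    excluded: set[ParamId] = set()
    # an excellent 2-of-4 fit stops the search only when no candidate's MI
    # survives a Bonferroni correction over the candidate set; a strongly
    # significant index overrides apparently good global fit
    strong_crit = float(_chi2_dist.ppf(1.0 - cfg.mi_alpha / max(len(all_cands), 1), 1))
    freed = 0
    while True:
        free = set(spec.free_params())
        cands = [c for c in all_cands if c not in free and c not in excluded]
        if not cands:
            break
        table = modification_indices(cov, spec, params, cands, config=cfg.engine)
        best = table.best()
        if best is None or best.mi <= cfg.mi_crit:
            break
        if excellent_fit(fit, cfg) and best.mi <= strong_crit:
            break
        choices = [best.param]
        if best.param[0] == "A":
            # the MI of a contemporaneous path is nearly direction-blind;
            # orientation is resolved by the realized fit of each direction
            _, k, j = best.param
            mirror = ("A", j, k)
            if mirror in cands:
                choices.append(mirror)
        fitted = []
        for pid in choices:
            trial_spec = spec.with_freed(pid)
            try:
                trial = fit_ml(cov, trial_spec, start=params, config=cfg.engine)
            except ValueError:
                excluded.add(pid)
                continue
            if trial[1].converged:
                fitted.append((trial[1].chi2, pid, trial_spec, trial))
        if not fitted:
            # revert-and-skip (e.g. a reciprocal pair making I - A singular)
            excluded.add(best.param)
            continue
        _, _, spec, (params, fit) = min(fitted, key=lambda t: t[0])
        freed += 1
        if cfg.max_free is not None and freed >= cfg.max_free:
            break
    return spec, params, fit


def usem_search(
    ts: RoiTimeSeries,
    cfg: SearchConfig | None = None,
    base: ModelSpec | None = None,
) -> tuple[ModelSpec, ParamMatrixSet, FitResult]:
    """Data-driven uSEM: modification-index search over A and Phi_q."""
    cfg = cfg or SearchConfig()
    ts = _ensure_centered(ts)
    base = base or ModelSpec.null(ts.p, cfg.order)
    if base.order != cfg.order:
        base = base.expanded_to_order(cfg.order)
    cov = block_toeplitz_cov(ts, cfg.order)
    return _search(cov, cfg, base)


def eusem_search(
    ts: RoiTimeSeries,
    u: InputSeries,
    cfg: SearchConfig | None = None,
    base: ModelSpec | None = None,
) -> tuple[ModelSpec, ParamMatrixSet, FitResult]:
    """Data-driven euSEM: the uSEM search over a candidate set enlarged
    with direct (gamma) and bilinear (tau) input effects."""
    cfg = cfg or SearchConfig()
    ts = _ensure_centered(ts)
    if u.convolved is None:
        raise ValueError("input series must be HRF-convolved before euSEM fitting")
    if np.allclose(u.effective, 0.0):
        warnings.warn("input is constant zero; gamma/tau candidates excluded")
        spec, params, fit = usem_search(ts, cfg, base=base)
        return spec, params, fit
    base = base or ModelSpec.null(ts.p, cfg.order, f=cfg.f, g=cfg.g, h=cfg.h)
    if base.order != cfg.order:
        base = base.expanded_to_order(cfg.order)
    cov = block_toeplitz_cov(ts, cfg.order, inputs=u, bilinear=True, f=cfg.f, g=cfg.g, h=cfg.h)
    return _search(cov, cfg, base)


# ---------------------------------------------------------------------------
# GIMME
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectResult:
    subject_id: str
    spec: ModelSpec
    params: ParamMatrixSet
    fit: FitResult


@dataclass(frozen=True)
class GroupModel:
    """Group-level connection structure plus per-subject final models.

    The group spec is a subset of every subject's spec; group parameters
    are freely estimated per subject, so connection magnitudes (and
    signs) vary across subjects.
    """

    group_spec: ModelSpec
    subjects: tuple[SubjectResult, ...]

    def __post_init__(self) -> None:
        gset = set(self.group_spec.free_params())
        for s in self.subjects:
            if not gset <= set(s.spec.free_params()):
                raise ValueError(f"group mask not contained in subject {s.subject_id} mask")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def to_json_dict(self) -> dict:
        return {
            "group_spec": self.group_spec.to_json_dict(),
            "subjects": [
                {
                    "id": s.subject_id,
                    "spec": s.spec.to_json_dict(),
                    "parameters": s.params.to_json_dict()["parameters"],
                    "fit": s.fit.indices(),
                }
                for s in self.subjects
            ],
        }


def gimme_group_search(
    ts_list: Sequence[RoiTimeSeries],
    cfg: SearchConfig | None = None,
    subject_ids: Sequence[str] | None = None,
) -> GroupModel:
    """Two-stage GIMME search.

    Stage 1 frees, for all subjects at once, the candidate whose
    modification index is significant for at least
    ``group_threshold_count(n, criterion)`` subjects, choosing the
    candidate with the highest such count (ties: largest summed MI).
    Group paths not Wald-significant for enough subjects are then
    dropped.  Stage 2 runs the individual-level search per subject with
    the group structure as its base; group paths are never pruned there.
    """
    cfg = cfg or SearchConfig()
    if not ts_list:
        raise ValueError("need at least one subject")
    series = [_ensure_centered(ts) for ts in ts_list]
    p = series[0].p
    labels = series[0].labels
    for ts in series[1:]:
        if ts.p != p or ts.labels != labels:
            raise ValueError("all subjects must share p and ROI labels")
    n = len(series)
    ids = list(subject_ids) if subject_ids is not None else [f"subj{i + 1}" for i in range(n)]
    threshold = group_threshold_count(n, cfg.criterion)

    covs = [block_toeplitz_cov(ts, cfg.order) for ts in series]
    group = ModelSpec.null(p, cfg.order)
    fits: list[tuple[ParamMatrixSet, FitResult]] = [
        fit_ml(cov, group, config=cfg.engine) for cov in covs
    ]
    all_cands = candidate_set(group)

    def _refit_all(trial_group, cur_fits):
        return [
            fit_ml(cov, trial_group, start=params, config=cfg.engine)
            for cov, (params, _) in zip(covs, cur_fits)
        ]

    def _stage1_grow(group, fits):
        # Grow the group structure by MI counting; stop once the criterion
        # share of subjects fits excellently (mirrors the individual-level
        # stop rule) or no candidate is significant for enough subjects.
        while True:
            n_excellent = sum(1 for _, fit in fits if excellent_fit(fit, cfg))
            if n_excellent >= threshold:
                break
            free = set(group.free_params())
            cands = [c for c in all_cands if c not in free]
            if not cands:
                break
            counts: dict[ParamId, int] = {c: 0 for c in cands}
            mi_sums: dict[ParamId, float] = {c: 0.0 for c in cands}
            for cov, (params, fit) in zip(covs, fits):
                if not fit.converged:
                    continue  # flagged subject: excluded from counts this iteration
                table = modification_indices(cov, group, params, cands, config=cfg.engine)
                for row in table:
                    mi_sums[row.param] += row.mi
                    if row.mi > cfg.mi_crit:
                        counts[row.param] += 1
            best = max(cands, key=lambda c: (counts[c], mi_sums[c]))
            if counts[best] < threshold:
                break
            choices = [best]
            if best[0] == "A":
                mirror = ("A", best[2], best[1])
                if mirror in cands:
                    choices.append(mirror)
            scored = []
            for cand in choices:
                trial_group = group.with_freed(cand)
                trial_fits = _refit_all(trial_group, fits)
                scored.append((sum(f.chi2 for _, f in trial_fits), cand, trial_group, trial_fits))
            _, _, group, fits = min(scored, key=lambda t: t[0])
        return group, fits

    def _stage1_prune(group, fits):
        # Drop group paths Wald-significant for too few subjects.
        while True:
            gparams = group.free_params()
            if not gparams:
                break
            sig_counts = {
                pid: sum(
                    1
                    for (params, fit) in fits
                    if fit.converged and params.wald_p(pid) < cfg.mi_alpha
                )
                for pid in gparams
            }
            worst = min(gparams, key=lambda pid: sig_counts[pid])
            if sig_counts[worst] >= threshold:
                break
            group = group.with_fixed(worst)
            fits = _refit_all(group, fits)
        return group, fits

    def _stage1_sweep(group, fits):
        # Orientation sweep over group-level contemporaneous paths: a
        # path's direction is identified only through the lagged structure,
        # which may not have been present when the path was first freed.
        # Each path is tested against its reverse, alone and together with
        # the new source's first-order autoregression (whose absence makes
        # a reversed "sink" configuration self-consistent); alternatives
        # with different sizes are compared by an AIC-style penalty.
        def score(g, f):
            return sum(fr.chi2 for _, fr in f) + 2.0 * n * g.k_free

        swapped_any = False
        for pid in list(group.free_params()):
            if pid[0] != "A" or not group.is_free(pid):
                continue
            mirror = ("A", pid[2], pid[1])
            if group.is_free(mirror):
                continue
            trials = [group.with_fixed(pid).with_freed(mirror)]
            src_ar = ("Phi", 1, pid[1], pid[1])
            if cfg.order >= 1 and not group.is_free(src_ar):
                trials.append(trials[0].with_freed(src_ar))
            cur_score = score(group, fits)
            for trial_group in trials:
                trial_fits = _refit_all(trial_group, fits)
                if score(trial_group, trial_fits) < cur_score - 1e-6:
                    group, fits = trial_group, trial_fits
                    cur_score = score(group, fits)
                    swapped_any = True
        return group, fits, swapped_any

    for _ in range(3):
        group, fits = _stage1_grow(group, fits)
        group, fits = _stage1_prune(group, fits)
        group, fits, swapped = _stage1_sweep(group, fits)
        if not swapped:
            break

    # Stage 2: individual-level search on top of the group structure.
    subjects = []
    gparams = tuple(group.free_params())
    for sid, cov in zip(ids, covs):
        spec_i, params_i, fit_i = _search(cov, cfg, group, protected=gparams)
        subjects.append(SubjectResult(subject_id=sid, spec=spec_i, params=params_i, fit=fit_i))
    return GroupModel(group_spec=group, subjects=tuple(subjects))


# ---------------------------------------------------------------------------
# Edge-list export
# ---------------------------------------------------------------------------


def edge_rows(
    spec: ModelSpec,
    params: ParamMatrixSet,
    labels: Sequence[str],
    group_mask: set | None = None,
) -> list[dict]:
    """Canonical edge-list rows: source, target, lag, type, level, estimate,
    se, ci bounds.  ``type`` is roi/direct/modulating; ``level`` is
    group/individual when a group mask is supplied."""
    rows = []
    for pid in spec.free_params():
        kind = pid[0]
        if kind == "A":
            lag, target, source, etype = 0, pid[1], pid[2], "roi"
            src = labels[source]
        elif kind == "Phi":
            lag, target, source, etype = pid[1], pid[2], pid[3], "roi"
            src = labels[source]
        elif kind == "gamma":
            lag, target, etype = pid[1], pid[2], "direct"
            src = "input"
        else:  # tau
            lag, target, etype = pid[1], pid[3], "modulating"
            src = f"{labels[pid[4]]}*input[t-{pid[2]}]"
        est = params.estimate(pid)
        se = params.se.get(pid)
        lo, hi = params.ci(pid) if pid in params.se else (None, None)
        rows.append(
            {
                "source": src,
                "target": labels[target],
                "lag": lag,
                "type": etype,
                "level": ("group" if group_mask and pid in group_mask else "individual")
                if group_mask is not None
                else "individual",
                "estimate": est,
                "se": se,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return rows
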