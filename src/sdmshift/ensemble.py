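"""Member selection, committee averaging, importance, and response curves.

An ensemble is built from the per-fold models of every algorithm whose
mean cross-validated TSS strictly exceeds a threshold (0.70 by default).
Committee averaging binarizes each member at its own TSS-optimal
threshold and averages the votes, so the ensemble score at a cell is the
fraction of members calling it suitable — a value on the lattice
{0, 1/M, ..., 1}.

Variable importance follows the randomization convention: a predictor's
contribution is 1 minus the Pearson correlation between a member's
predictions on intact data and on data with that predictor's column
shuffled, floored at zero, averaged over shuffles and members, and
normalized to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GridSpec
from .models import FittedModel, ModelEvaluation, TrainingData, auc, encode_predictors, optimize_tss
from .predictors import EnvStack


@dataclass
class SuitabilityMap:
    """Per-cell suitability scores in [0, 1] on a masked grid."""

    grid: GridSpec
    values: np.ndarray  # NaN outside mask
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.grid.shape or self.mask.shape != self.grid.shape:
            raise ValueError("values/mask shape does not match grid")
        inside = self.values[self.mask]
        if inside.size and (np.nanmin(inside) < -1e-9 or np.nanmax(inside) > 1 + 1e-9):
            raise ValueError("suitability values must lie in [0, 1]")

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class EnsembleModel:
    """Committee of fold-level models from the TSS-selected algorithms."""

    members: list[tuple[FittedModel | None, float]]  # (model, its threshold)
    selected: list[str]
    excluded: list[dict]
    tss_min: float = 0.70

    @property
    def M(self) -> int:
        return len(self.members)


@dataclass
class VariableImportance:
    table: pd.DataFrame  # index variable; columns mean, sd (mean sums to 1)
    constant_members: int = 0  # members flagged for zero-variance predictions

    def top(self) -> str:
        return str(self.table["mean"].idxmax())


@dataclass
class ResponseCurve:
    variable: str
    probes: np.ndarray
    scores: np.ndarray


def mean_tss_by_algorithm(evaluations: list[ModelEvaluation]) -> dict[str, float]:
    by_alg: dict[str, list[float]] = {}
    for ev in evaluations:
        by_alg.setdefault(ev.algorithm, []).append(ev.tss)
    return {a: float(np.mean(v)) for a, v in by_alg.items()}


def select_members(
    evaluations: list[ModelEvaluation], tss_min: float = 0.70
) -> EnsembleModel:
    """Keep every fold-model of algorithms with mean TSS strictly above tss_min."""
    if not evaluations:
        raise ValueError("no evaluations supplied")
    means = mean_tss_by_algorithm(evaluations)
    selected = [a for a in means if means[a] > tss_min]
    excluded = [
        {"algorithm": a, "mean_tss": means[a], "reason": f"mean TSS <= {tss_min}"}
        for a in means
        if means[a] <= tss_min
    ]
    if not selected:
        raise ValueError(
            f"no algorithm exceeds mean TSS {tss_min}; review the threshold "
            f"(best was {max(means.values()):.3f})"
        )
    members = [
        (ev.model, ev.threshold) for ev in evaluations if ev.algorithm in selected
    ]
    return EnsembleModel(
        members=members, selected=sorted(selected), excluded=excluded, tss_min=tss_min
    )


def committee_average(
    member_maps: list[tuple[SuitabilityMap, float]], provenance: dict | None = None
) -> SuitabilityMap:
    """Fraction of members voting 'suitable' per cell.

    Each member map is binarized at its own threshold (score >= tau) and
    the votes averaged; all maps must share grid and mask.
    """
    if not member_maps:
        raise ValueError("no member maps")
    ref, _ = member_maps[0]
    votes = np.zeros(ref.grid.shape, dtype=float)
    for m, tau in member_maps:
        if m.grid != ref.grid or not np.array_equal(m.mask, ref.mask):
            raise ValueError("member maps must share grid and mask")
        votes += (m.values >= tau).astype(float)
    ca = votes / len(member_maps)
    ca[~ref.mask] = np.nan
    prov = dict(provenance or {})
    prov["members"] = len(member_maps)
    return SuitabilityMap(grid=ref.grid, values=ca, mask=ref.mask.copy(), provenance=prov)


def predict_ensemble_map(
    ensemble: EnsembleModel, stack: EnvStack, period: str | None = None
) -> SuitabilityMap:
    """Project every member onto a stack and committee-average the votes."""
    from .models import predict_map

    member_maps = [(predict_map(m, stack), tau) for m, tau in ensemble.members]
    prov = {"period": period} if period else {}
    return committee_average(member_maps, provenance=prov)


def score_ensemble(ensemble: EnsembleModel, X: pd.DataFrame, members=None) -> np.ndarray:
    """Committee-average score for encoded predictor rows."""
    members = members if members is not None else ensemble.members
    votes = np.zeros(len(X), dtype=float)
    for m, tau in members:
        votes += (m.score(X) >= tau).astype(float)
    return votes / len(members)


def evaluate_ensemble(ensemble: EnsembleModel, data: TrainingData) -> dict:
    """Cross-validated skill of the committee itself.

    For each fold, the committee is restricted to members trained with
    that fold held out and scored on the fold's test rows; TSS (threshold
    re-optimized on the committee score) and AUC are averaged across
    folds; SDs are sample standard deviations.
    """
    tsss, aucs = [], []
    for f in range(1, data.k + 1):
        members = [(m, tau) for m, tau in ensemble.members if m is not None and m.fold == f]
        if not members:
            raise ValueError(f"no members available for fold {f}")
        _, _, X_te, y_te = data.split(f)
        s = score_ensemble(ensemble, X_te, members=members)
        aucs.append(auc(s[y_te == 1], s[y_te == 0]))
        _, tss, _, _ = optimize_tss(s, y_te)
        tsss.append(tss)
    ddof = 1 if len(tsss) > 1 else 0
    return {
        "tss_mean": float(np.mean(tsss)),
        "tss_sd": float(np.std(tsss, ddof=ddof)),
        "auc_mean": float(np.mean(aucs)),
        "auc_sd": float(np.std(aucs, ddof=ddof)),
        "per_fold": {"tss": tsss, "auc": aucs},
    }


def variable_importance(
    ensemble: EnsembleModel,
    table: pd.DataFrame,
    variables: list[str] | None = None,
    n_perm: int = 10,
    seed: int = 0,
) -> VariableImportance:
    """Randomization importance over members and shuffles.

    ``table`` holds raw (unencoded) predictor rows. For each member and
    variable, the variable's column is shuffled ``n_perm`` times; the
    importance sample is 1 - Pearson r(intact predictions, shuffled
    predictions), floored at 0. Means are normalized to sum to one; SDs
    are scaled by the same constant.
    """
    rng = np.random.default_rng(seed)
    if variables is None:
        variables = [
            c
            for c in table.columns
            if c not in ("lon", "lat", "row", "col", "grid_row", "grid_col", "masked")
        ]
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise KeyError(f"data rows missing variable(s): {missing}")

    samples: dict[str, list[float]] = {v: [] for v in variables}
    constant_members = 0
    for m, _tau in ensemble.members:
        enc = encode_predictors(table[variables], m.categorical_levels)
        intact = m.score(enc)
        if np.std(intact) == 0:
            constant_members += 1
            for v in variables:
                samples[v].extend([0.0] * n_perm)
            continue
        for v in variables:
            for _ in range(n_perm):
                shuffled = table[variables].copy()
                shuffled[v] = rng.permutation(shuffled[v].to_numpy())
                enc_s = encode_predictors(shuffled, m.categorical_levels)
                pred = m.score(enc_s)
                if np.std(pred) == 0:
                    r = 0.0
                else:
                    r = float(np.corrcoef(intact, pred)[0, 1])
                samples[v].append(max(0.0, 1.0 - r))

    mean = np.array([np.mean(samples[v]) for v in variables])
    sd = np.array([np.std(samples[v], ddof=1 if len(samples[v]) > 1 else 0) for v in variables])
    total = mean.sum()
    if total == 0:
        norm_mean = np.zeros_like(mean)
        norm_sd = sd
    else:
        norm_mean = mean / total
        norm_sd = sd / total
    tab = pd.DataFrame({"mean": norm_mean, "sd": norm_sd}, index=pd.Index(variables, name="variable"))
    return VariableImportance(table=tab, constant_members=constant_members)


def response_curve(
    ensemble: EnsembleModel,
    stack: EnvStack,
    variable: str,
    n_probes: int = 100,
) -> ResponseCurve:
    """Median-profile (evaluation strip) response of the committee score.

    Probes span the variable's observed range over unmasked cells; every
    other continuous variable is fixed at its median, categoricals at
    their mode.
    """
    if variable not in stack.layers:
        raise KeyError(f"variable {variable!r} not in stack")
    if stack.layers[variable].kind != "continuous":
        raise ValueError("response curves are defined for continuous variables only")
    vals = stack.layers[variable].values[stack.mask]
    probes = np.linspace(float(vals.min()), float(vals.max()), n_probes)
    profile: dict[str, np.ndarray] = {}
    for name, layer in stack.layers.items():
        cell_vals = layer.values[stack.mask]
        if name == variable:
            profile[name] = probes
        elif layer.kind == "continuous":
            profile[name] = np.full(n_probes, float(np.median(cell_vals)))
        else:
            levels, counts = np.unique(cell_vals, return_counts=True)
            profile[name] = np.full(n_probes, float(levels[np.argmax(counts)]))
    table = pd.DataFrame(profile)
    votes = np.zeros(n_probes)
    for m, tau in ensemble.members:
        enc = encode_predictors(table, m.categorical_levels)
        votes += (m.score(enc) >= tau).astype(float)
    return ResponseCurve(variable=variable, probes=probes, scores=votes / ensemble.M)
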