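"""Variable screening, collinearity filtering, AICc subset scoring and CV-AUC.

The candidate pool is reduced in three stages before exhaustive subset
scoring: a jackknife screen retains variables with high gain in isolation
or whose omission from the full model costs the most gain; a pairwise
Pearson filter removes one member of every |r| > 0.8 pair (the one with
the lower isolation gain); every non-empty subset of the survivors is then
fit and scored by small-sample AICc, with Akaike weights over the scored
set, plus k-fold cross-validated AUC for ranking confirmation.

AICc log-likelihoods follow the presence-only convention of renormalizing
the raw Gibbs mass over all unmasked landscape cells, with k counted as
the number of non-zero coefficients.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .maxent_core import FeatureConfig, FeatureExpansion, MaxentModel, fit_maxent
from .occurrence_prep import OccurrenceSet
from .raster_stack import RasterStack, extract_values

__all__ = [
    "SelectionConfig",
    "ScreenReport",
    "ModelScore",
    "build_design",
    "jackknife_screen",
    "collinearity_filter",
    "score_subsets",
    "rank_models",
    "cv_auc",
    "auc_mann_whitney",
    "scores_to_frame",
]

MAX_FULL_BACKGROUND = 50_000
BACKGROUND_SAMPLE = 10_000


@dataclass(frozen=True)
class SelectionConfig:
    feature_config: FeatureConfig = FeatureConfig()
    r: float = 1.0
    tol: float = 1e-6
    top_isolation: int = 4  # g: variables kept for isolation gain
    top_omission: int = 4  # d: variables kept for omission gain drop
    collinearity_threshold: float = 0.8
    max_subset_variables: int = 12
    cv_folds: int = 10
    background_seed: int = 0


@dataclass
class ScreenReport:
    table: pd.DataFrame  # variable, gain_isolation, gain_drop, retained, reason
    retained: list[str]
    note: str = ""


@dataclass
class ModelScore:
    variables: tuple[str, ...]
    log_likelihood: float
    k: int
    n: int
    aicc: float
    delta_aicc: float = math.nan
    weight: float = math.nan
    auc_mean: float = math.nan
    auc_sd: float = math.nan
    valid: bool = True
    note: str = ""


def background_matrix(
    stack: RasterStack, variables: list[str] | None = None, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Background environment rows (cells × variables) and their flat indices.

    All unmasked cells when there are at most 50,000; otherwise a seeded
    uniform sample of 10,000 cells.
    """
    env, idx = stack.env_matrix(variables)
    if env.shape[0] > MAX_FULL_BACKGROUND:
        rng = np.random.default_rng(seed)
        pick = rng.choice(env.shape[0], size=BACKGROUND_SAMPLE, replace=False)
        pick.sort()
        env, idx = env[pick], idx[pick]
    return env, idx


def presence_matrix(stack: RasterStack, occ: OccurrenceSet, variables: list[str] | None = None) -> np.ndarray:
    values, _, _, outside, masked = extract_values(
        stack.subset(variables) if variables else stack, occ.points
    )
    bad = outside | masked
    if bad.any():
        raise ValueError(f"{int(bad.sum())} presence records fall outside usable cells; clean first")
    return values


def build_design(
    stack: RasterStack,
    occ: OccurrenceSet,
    variables: list[str],
    config: SelectionConfig = SelectionConfig(),
):
    """Expansion + presence/background feature matrices for one variable set."""
    env_bg, _ = background_matrix(stack, variables, config.background_seed)
    env_p = presence_matrix(stack, occ, variables)
    expansion = FeatureExpansion.from_background(env_bg, variables, config.feature_config)
    F_b = expansion.transform(env_bg)
    F_p = expansion.transform(env_p, clamp=True)
    return expansion, F_p, F_b


def _fit_gain(stack, occ, variables, config) -> float:
    expansion, F_p, F_b = build_design(stack, occ, variables, config)
    model = fit_maxent(F_p, F_b, expansion, r=config.r, tol=config.tol)
    return model.gain(F_p)


def jackknife_screen(
    stack: RasterStack,
    occ: OccurrenceSet,
    config: SelectionConfig = SelectionConfig(),
    candidates: list[str] | None = None,
) -> ScreenReport:
    """Gain in isolation and gain drop on omission, per candidate variable.

    Retains the union of the top ``g`` isolation-gain variables and the top
    ``d`` omission-drop variables.  A failed sub-fit flags the variable but
    never aborts the screen.
    """
    variables = candidates if candidates is not None else stack.names
    if len(variables) < 2:
        table = pd.DataFrame(
            {
                "variable": variables,
                "gain_isolation": [math.nan] * len(variables),
                "gain_drop": [math.nan] * len(variables),
                "retained": [True] * len(variables),
                "reason": ["single candidate"] * len(variables),
            }
        )
        return ScreenReport(table, list(variables), note="screening skipped: <2 candidates")

    try:
        full_gain = _fit_gain(stack, occ, variables, config)
    except Exception as exc:  # pragma: no cover - defensive
        full_gain = math.nan

    iso: dict[str, float] = {}
    drop: dict[str, float] = {}
    failed: set[str] = set()
    for v in variables:
        try:
            iso[v] = _fit_gain(stack, occ, [v], config)
        except Exception:
            iso[v] = math.nan
            failed.add(v)
        rest = [w for w in variables if w != v]
        try:
            drop[v] = full_gain - _fit_gain(stack, occ, rest, config)
        except Exception:
            drop[v] = math.nan
            failed.add(v)

    ok = [v for v in variables if v not in failed]
    by_iso = sorted(ok, key=lambda v: (-iso[v], v))[: config.top_isolation]
    by_drop = sorted(ok, key=lambda v: (-drop[v], v))[: config.top_omission]
    retained = sorted(set(by_iso) | set(by_drop), key=variables.index)

    rows = []
    for v in variables:
        if v in failed:
            reason = "fit failed"
        elif v in by_iso and v in by_drop:
            reason = "top isolation gain; top omission drop"
        elif v in by_iso:
            reason = "top isolation gain"
        elif v in by_drop:
            reason = "top omission drop"
        else:
            reason = "screened out"
        rows.append(
            {
                "variable": v,
                "gain_isolation": iso[v],
                "gain_drop": drop[v],
                "retained": v in retained,
                "reason": reason,
            }
        )
    return ScreenReport(pd.DataFrame(rows), retained)


def collinearity_filter(
    env: np.ndarray | pd.DataFrame,
    variables: list[str],
    threshold: float = 0.8,
    isolation_gain: dict[str, float] | None = None,
) -> list[str]:
    """Greedy elimination of highly correlated variable pairs.

    While any pair has |Pearson r| strictly above ``threshold`` (pairs
    visited in descending |r|, ties broken by variable name), the member
    with the lower isolation gain is dropped.  Constant variables are
    removed first with reason "zero variance".
    """
    if isinstance(env, pd.DataFrame):
        env = env[variables].to_numpy(float)
    env = np.asarray(env, float)
    if env.shape[1] != len(variables):
        raise ValueError("environment matrix width must match the variable list")
    gains = isolation_gain or {}

    keep = [v for j, v in enumerate(variables) if env[:, j].std() > 0]
    col = {v: j for j, v in enumerate(variables)}
    while len(keep) > 1:
        sub = env[:, [col[v] for v in keep]]
        r = np.corrcoef(sub, rowvar=False)
        np.fill_diagonal(r, 0.0)
        pairs = [
            (abs(r[i, j]), tuple(sorted((keep[i], keep[j]))))
            for i in range(len(keep))
            for j in range(i + 1, len(keep))
            if abs(r[i, j]) > threshold
        ]
        if not pairs:
            break
        pairs.sort(key=lambda t: (-t[0], t[1]))
        a, b = pairs[0][1]
        ga, gb = gains.get(a, 0.0), gains.get(b, 0.0)
        # lower isolation gain loses; equal gains drop the later name
        if ga < gb:
            victim = a
        elif gb < ga:
            victim = b
        else:
            victim = max(a, b)
        keep.remove(victim)
    return keep


def landscape_log_likelihood(model: MaxentModel, stack: RasterStack, occ: OccurrenceSet) -> float:
    """sum_i ln q_hat(x_i) with q_hat renormalized over all unmasked cells."""
    env_all, _ = stack.env_matrix(model.expansion.variables)
    F_all = model.expansion.transform(env_all)
    eta = F_all @ model.lam
    from scipy.special import logsumexp

    log_Z_land = logsumexp(eta)
    env_p = presence_matrix(stack, occ, model.expansion.variables)
    F_p = model.expansion.transform(env_p, clamp=True)
    return float(np.sum(F_p @ model.lam - log_Z_land))


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: 2k − 2LL + 2k(k+1)/(n−k−1)."""
    if n - k - 1 <= 0:
        return math.inf
    return 2 * k - 2 * log_likelihood + 2 * k * (k + 1) / (n - k - 1)


def score_subsets(
    variables: list[str],
    occ: OccurrenceSet,
    stack: RasterStack,
    config: SelectionConfig = SelectionConfig(),
    with_auc: bool = False,
    seed: int = 0,
) -> list[ModelScore]:
    """Fit and AICc-score every non-empty subset of ``variables``.

    Subsets with k ≥ n − 1 are flagged invalid (the correction term blows
    up); a subset whose fit fails is flagged and the rest continue.
    """
    if not 1 <= len(variables) <= config.max_subset_variables:
        raise ValueError(
            f"need between 1 and {config.max_subset_variables} variables, got {len(variables)}"
        )
    n = len(occ)
    scores: list[ModelScore] = []
    for size in range(1, len(variables) + 1):
        for subset in itertools.combinations(variables, size):
            try:
                expansion, F_p, F_b = build_design(stack, occ, list(subset), config)
                model = fit_maxent(F_p, F_b, expansion, r=config.r, tol=config.tol)
                ll = landscape_log_likelihood(model, stack, occ)
                k = int(np.sum(np.abs(model.lam) > 1e-9))
                score = ModelScore(
                    variables=subset,
                    log_likelihood=ll,
                    k=k,
                    n=n,
                    aicc=aicc(ll, k, n),
                    valid=(n - k - 1) > 0,
                    note="" if (n - k - 1) > 0 else "k >= n - 1",
                )
                if with_auc and score.valid:
                    score.auc_mean, score.auc_sd = cv_auc(
                        list(subset), occ, stack, folds=config.cv_folds, seed=seed, config=config
                    )
            except Exception as exc:
                score = ModelScore(
                    variables=subset,
                    log_likelihood=math.nan,
                    k=0,
                    n=n,
                    aicc=math.inf,
                    valid=False,
                    note=f"fit failed: {exc}",
                )
            scores.append(score)
    return rank_models(scores)


def rank_models(scores: list[ModelScore]) -> list[ModelScore]:
    """Attach ΔAICc and Akaike weights over all valid models; sort ascending.

    w_i = exp(−Δ_i/2) / Σ exp(−Δ_k/2); ties sort by fewer variables, then
    lexicographic subset.
    """
    valid = [s for s in scores if s.valid and math.isfinite(s.aicc)]
    if not valid:
        raise ValueError("no valid model scores to rank")
    best = min(s.aicc for s in valid)
    rel = {}
    for s in valid:
        s.delta_aicc = s.aicc - best
        rel[s.variables] = math.exp(-s.delta_aicc / 2.0)
    total = sum(rel.values())
    for s in valid:
        s.weight = rel[s.variables] / total
    for s in scores:
        if not s.valid:
            s.delta_aicc = math.nan
            s.weight = 0.0
    return sorted(
        scores,
        key=lambda s: (not s.valid, s.aicc, len(s.variables), s.variables),
    )


def auc_mann_whitney(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """AUC as the normalized Mann–Whitney U statistic; ties count 0.5."""
    pos = np.asarray(pos_scores, float)
    neg = np.asarray(neg_scores, float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need scores for both classes")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def cv_auc(
    variables: list[str],
    occ: OccurrenceSet,
    stack: RasterStack,
    folds: int = 10,
    seed: int = 0,
    config: SelectionConfig = SelectionConfig(),
) -> tuple[float, float]:
    """k-fold cross-validated AUC of held-out presences vs the background.

    Presences are shuffled with the seed and dealt round-robin into folds;
    the background sample is shared across folds.
    """
    m = len(occ)
    if m < folds:
        raise ValueError(f"only {m} presences; use at most {m} folds")
    expansion, F_p, F_b = build_design(stack, occ, variables, config)
    rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    fold_of = np.empty(m, dtype=int)
    fold_of[order] = np.arange(m) % folds
    aucs = []
    for fold in range(folds):
        test = fold_of == fold
        model = fit_maxent(F_p[~test], F_b, expansion, r=config.r, tol=config.tol)
        pos = model.raw_output(F_p[test])
        neg = model.raw_output(F_b)
        aucs.append(auc_mann_whitney(pos, neg))
    aucs = np.asarray(aucs)
    return float(aucs.mean()), float(aucs.std(ddof=1))


def scores_to_frame(scores: list[ModelScore]) -> pd.DataFrame:
    """Model-comparison report with one row per scored subset."""
    return pd.DataFrame(
        {
            "variables": ["+".join(s.variables) for s in scores],
            "log_likelihood": [s.log_likelihood for s in scores],
            "k": [s.k for s in scores],
            "n": [s.n for s in scores],
            "aicc": [s.aicc for s in scores],
            "delta_aicc": [s.delta_aicc for s in scores],
            "weight": [s.weight for s in scores],
            "auc_mean": [s.auc_mean for s in scores],
            "auc_sd": [s.auc_sd for s in scores],
            "valid": [s.valid for s in scores],
            "note": [s.note for s in scores],
        }
    )
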