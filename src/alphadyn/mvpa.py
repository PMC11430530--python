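"""Class-balanced leave-one-subject-out SVM decoding with permutation nulls.

For every held-out subject, an equal number of subjects per class is drawn at
random from the remainder, channels are z-scored on that training draw, a
linear SVM (C = 1 by default) is fitted and the held-out decision value
recorded.  Decision values are pooled within a repetition into one AUC
(midrank handling of ties) and the observed statistic is the mean AUC over
repetitions.  Significance comes from a permutation null: subject labels are
shuffled once per permutation and the whole procedure re-run (optionally with
fewer repetitions); the p-value uses the add-one estimator.  Classifier
weights are made interpretable through the Haufe transform — the training
covariance matrix times the weight vector, averaged over all folds.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import _svmcore
from .features import CONTROL_FEATURES, MAIN_FEATURES, FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "DecodingConfig",
    "DecodingResult",
    "auc_from_decisions",
    "balanced_loocv_auc",
    "permutation_test",
    "bonferroni_adjust",
    "decode_all_features",
]


@dataclass(frozen=True)
class DecodingConfig:
    n_per_class_train: int = 15
    n_repetitions: int = 10
    n_permutations: int = 1000
    perm_repetitions: int = 1  # repetitions per permutation (tractability)
    alpha: float = 0.05  # one-tailed
    n_tests_bonferroni: int = len(MAIN_FEATURES)
    svm_c: float = 1.0
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_per_class_train", "n_repetitions", "n_permutations",
                     "perm_repetitions"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class DecodingResult:
    feature_name: str
    condition_tag: str
    auc_observed: float
    per_repetition_aucs: np.ndarray
    null_aucs: np.ndarray
    p_value: float
    significant_raw: bool
    significant_bonferroni: bool
    haufe_pattern: np.ndarray
    channel_names: List[str] = field(default_factory=list)


def auc_from_decisions(decisions: np.ndarray, y: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney with midranks) of decision values."""
    y = np.asarray(y)
    n_pos = int(np.sum(y == 1))
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(decisions)
    return float(
        (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def _training_draws(
    y: np.ndarray, n_per_class: int, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Random balanced training-index draws for every repetition x held-out.

    Shape (n_reps, n, 2*n_per_class); the held-out subject never appears in
    its own draw.
    """
    n = y.size
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    if min(idx_pos.size, idx_neg.size) - 1 < n_per_class:
        raise ValueError(
            f"cannot draw {n_per_class} training subjects per class after "
            f"leaving one out (class sizes {idx_pos.size}/{idx_neg.size})"
        )
    draws = np.empty((n_reps, n, 2 * n_per_class), dtype=np.int64)
    for r in range(n_reps):
        for hold in range(n):
            pos = idx_pos[idx_pos != hold]
            neg = idx_neg[idx_neg != hold]
            draws[r, hold, :n_per_class] = rng.choice(pos, n_per_class, replace=False)
            draws[r, hold, n_per_class:] = rng.choice(neg, n_per_class, replace=False)
    return draws


def _run_loocv(
    X: np.ndarray,
    y: np.ndarray,
    cfg: DecodingConfig,
    n_reps: int,
    rng: np.random.Generator,
) -> Tuple[float, np.ndarray, np.ndarray]:
    draws = _training_draws(y, cfg.n_per_class_train, n_reps, rng)
    decisions, haufe_sum, _wsum, count = _svmcore.loocv_decisions(
        np.ascontiguousarray(X, dtype=np.float64),
        np.ascontiguousarray(y, dtype=np.int64),
        draws,
        float(cfg.svm_c),
        cfg.standardize,
    )
    rep_aucs = np.array([auc_from_decisions(decisions[r], y) for r in range(n_reps)])
    return float(rep_aucs.mean()), rep_aucs, haufe_sum / count


def balanced_loocv_auc(
    table: FeatureTable,
    cfg: DecodingConfig = DecodingConfig(),
    rng: Optional[np.random.Generator] = None,
) -> Tuple[float, np.ndarray, np.ndarray]:
    """Observed decoding statistic for one feature table.

    Returns (auc_observed, per-repetition AUCs, averaged Haufe pattern).
    """
    X, y = table.as_arrays()
    if np.isnan(X).any():
        raise ValueError("feature table contains missing cells")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    return _run_loocv(X, y, cfg, cfg.n_repetitions, rng)


def permutation_test(
    table: FeatureTable, cfg: DecodingConfig = DecodingConfig()
) -> DecodingResult:
    """Observed AUC against a shuffled-label null distribution.

    Labels are permuted once per permutation at the subject level before the
    entire balanced-LOOCV procedure; p-value is the add-one estimator
    ``(1 + #{null >= observed}) / (1 + n_permutations)`` and the raw decision
    compares the observed AUC with the null's 95th percentile.
    """
    X, y = table.as_arrays()
    if np.isnan(X).any():
        raise ValueError("feature table contains missing cells")
    rng = np.random.default_rng(cfg.seed)
    auc_obs, rep_aucs, haufe = _run_loocv(X, y, cfg, cfg.n_repetitions, rng)
    null = np.empty(cfg.n_permutations)
    for p in range(cfg.n_permutations):
        y_perm = rng.permutation(y)
        null[p], _, _ = _run_loocv(X, y_perm, cfg, cfg.perm_repetitions, rng)
    p_value = (1.0 + np.sum(null >= auc_obs)) / (1.0 + cfg.n_permutations)
    thresh = np.percentile(null, 100.0 * (1.0 - cfg.alpha))
    return DecodingResult(
        feature_name=table.feature_name,
        condition_tag=table.condition_tag,
        auc_observed=auc_obs,
        per_repetition_aucs=rep_aucs,
        null_aucs=null,
        p_value=float(p_value),
        significant_raw=bool(auc_obs > thresh),
        significant_bonferroni=bool(p_value <= cfg.alpha / cfg.n_tests_bonferroni),
        haufe_pattern=haufe,
        channel_names=list(table.values.columns),
    )


def bonferroni_adjust(
    p_values: Iterable[float], n_tests: int, alpha: float = 0.05
) -> np.ndarray:
    """Familywise significance flags: p <= alpha / n_tests."""
    p = np.asarray(list(p_values), dtype=float)
    if n_tests < p.size:
        raise ValueError("n_tests must be at least the number of p-values")
    return p <= alpha / n_tests


def decode_all_features(
    tables: Mapping[Tuple[str, str], FeatureTable],
    cfg: DecodingConfig = DecodingConfig(),
) -> Tuple[Dict[Tuple[str, str], DecodingResult], pd.DataFrame]:
    """One permutation-tested decoding per feature x contrast.

    The Bonferroni family is the main spectral-variability features within a
    contrast; control (MSE) and complexity features are corrected within
    their own families.  Returns the per-table results and a tidy summary.
    """
    families: Dict[str, List[Tuple[str, str]]] = {"main": [], "control": [], "lz": []}
    for key in tables:
        feat = key[0]
        if feat in MAIN_FEATURES:
            families["main"].append(key)
        elif feat in CONTROL_FEATURES:
            families["control"].append(key)
        else:
            families["lz"].append(key)

    results: Dict[Tuple[str, str], DecodingResult] = {}
    for fam, keys in families.items():
        if not keys:
            continue
        # family size counts features within one contrast
        n_tests = max(len({k[0] for k in keys}), 1)
        fam_cfg = replace(cfg, n_tests_bonferroni=n_tests)
        for key in sorted(keys):
            feat, tag = key
            sub_cfg = replace(
                fam_cfg, seed=int(np.random.SeedSequence(
                    entropy=cfg.seed,
                    spawn_key=(zlib.crc32(feat.encode()), 0 if tag == "pre" else 1),
                ).generate_state(1)[0] % (2**31))
            )
            results[key] = permutation_test(tables[key], sub_cfg)
            logger.info(
                "decoded %s/%s: AUC=%.3f p=%.4g", feat, tag,
                results[key].auc_observed, results[key].p_value,
            )

    rows = [
        {
            "feature": r.feature_name,
            "contrast": r.condition_tag,
            "auc": r.auc_observed,
            "p_value": r.p_value,
            "null_mean": float(r.null_aucs.mean()),
            "significant_raw": r.significant_raw,
            "significant_bonferroni": r.significant_bonferroni,
        }
        for r in results.values()
    ]
    summary = (
        pd.DataFrame(rows)
        .sort_values(["contrast", "auc"], ascending=[True, False])
        .reset_index(drop=True)
    )
    return results, summary
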