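"""Ensembles of small feed-forward networks for phenotype prediction.

The modeling strategy is resampled cross-validation at very small n: each of
``n_models`` networks draws its own random 75/25 train/holdout split of the
samples, is trained on the 75%, and is scored on the held-out 25% to which
it is naive. Model fit and robustness are summarized as the mean (+/- SEM)
of per-model train and cross-validation R^2, where R^2 is the squared
Pearson correlation between observed and predicted phenotype (with 4-sample
holdouts a 1 - SS_res/SS_tot definition can go negative; the squared
correlation stays in [0, 1]).

Variable importance is measured by perturbation sensitivity: the mean
absolute change in model output when one input is displaced by +1 training
SD, averaged over training samples and models, normalized to shares summing
to one. Networks are deliberately tiny (one hidden layer of 3 tanh units,
L2-penalized, deterministic full-batch L-BFGS optimization) so that the
parameter count stays manageable even with 1469 inputs and 12 training
samples; ridge-like shrinkage spreads weight across correlated informative
inputs, which is exactly what makes sensitivity-based ranking of a
collectively predictive gene suite work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from eggprint._nn import TinyNet
from eggprint.dataio import ExpressionMatrix, GenotypeMatrix, PhenotypeTable
from eggprint.preprocess import ScreenResult

__all__ = [
    "AnnConfig",
    "EnsembleResult",
    "SensitivityTable",
    "train_ensemble",
    "compute_sensitivities",
    "nested_subset_run",
    "compare_probe_sets",
    "genotype_variance",
]


class ModelError(ValueError):
    pass


@dataclass
class AnnConfig:
    n_models: int = 20
    train_fraction: float = 0.75
    hidden_units: int = 3
    activation: str = "tanh"
    l2_penalty: float = 1.0
    max_iterations: int = 2000
    seed: int = 0
    # "train": standardization statistics from each model's training split
    # only (the correct, leakage-free contract). "global" exists solely so
    # tests can demonstrate that leakage changes the CV numbers.
    standardize: str = "train"
    # "per_model": average per-model holdout R^2 (default); "pooled": one
    # R^2 over all out-of-fold predictions.
    cv_aggregate: str = "per_model"

    def validate(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ModelError("train_fraction must be in (0, 1)")
        if self.n_models < 2:
            raise ModelError("need at least 2 models")
        if self.standardize not in ("train", "global"):
            raise ModelError(f"unknown standardize mode {self.standardize!r}")
        if self.activation != "tanh":
            raise ModelError("only tanh hidden units are supported")


@dataclass
class _FittedModel:
    """Opaque handle for one trained network: the estimator plus everything
    needed to reproduce its input/output scaling."""

    estimator: TinyNet
    train_idx: np.ndarray
    test_idx: np.ndarray
    feat_mean: np.ndarray
    feat_sd: np.ndarray
    y_lo: float
    y_span: float

    def predict(self, x_raw: np.ndarray) -> np.ndarray:
        z = (x_raw - self.feat_mean) / self.feat_sd
        return self.estimator.predict(z) * self.y_span + self.y_lo


@dataclass
class EnsembleResult:
    feature_ids: list[str]
    sample_ids: list[str]
    target_name: str
    train_r2: np.ndarray  # per model
    cv_r2: np.ndarray  # per model
    models: list[_FittedModel] = field(repr=False)
    X: np.ndarray = field(repr=False)  # samples x features, raw (unstandardized)
    y: np.ndarray = field(repr=False)
    oof_predictions: dict[str, list[float]] = field(default_factory=dict)
    all_samples_held_out: bool = True

    @property
    def mean_train_r2(self) -> float:
        return float(self.train_r2.mean())

    @property
    def mean_cv_r2(self) -> float:
        return float(self.cv_r2.mean())

    @property
    def sem_train_r2(self) -> float:
        return float(self.train_r2.std(ddof=1) / np.sqrt(len(self.train_r2)))

    @property
    def sem_cv_r2(self) -> float:
        return float(self.cv_r2.std(ddof=1) / np.sqrt(len(self.cv_r2)))

    def pooled_cv_r2(self) -> float:
        obs, pred = self._pooled_oof()
        return _r2(obs, pred)

    def predictive_cv_r2(self) -> float:
        """Pooled out-of-fold 1 - SS_res/SS_tot. Unlike the squared
        correlation this is ~0 (or negative) when holdout predictions carry
        no information, so it can express 'nothing explained'."""
        obs, pred = self._pooled_oof()
        ss_tot = ((obs - obs.mean()) ** 2).sum()
        if ss_tot == 0:
            return 0.0
        return float(1.0 - ((obs - pred) ** 2).sum() / ss_tot)

    def _pooled_oof(self) -> tuple[np.ndarray, np.ndarray]:
        obs, pred = [], []
        for s, preds in self.oof_predictions.items():
            i = self.sample_ids.index(s)
            obs.extend([self.y[i]] * len(preds))
            pred.extend(preds)
        return np.asarray(obs), np.asarray(pred)


@dataclass
class SensitivityTable:
    """Per-feature perturbation sensitivities, shares, ranks (1 = largest
    share; ties broken lexicographically by feature id)."""

    table: pd.DataFrame  # columns: probe_id, sensitivity, share, rank

    def top(self, k: int) -> list[str]:
        return self.table.nsmallest(k, "rank")["probe_id"].tolist()


def _r2(obs: np.ndarray, pred: np.ndarray) -> float:
    if obs.std() == 0 or pred.std() == 0:
        return 0.0
    r = np.corrcoef(obs, pred)[0, 1]
    return float(r * r)


def _derive_seeds(master: int, stage: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, stage])
    return ss.generate_state(n) & 0x7FFFFFFF


def train_ensemble(
    expr_subset: ExpressionMatrix | np.ndarray,
    target: np.ndarray | pd.Series,
    config: AnnConfig,
    feature_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
    target_name: str = "pct_4h_viable",
    stage: int = 0,
) -> EnsembleResult:
    """Train ``config.n_models`` networks on independent random splits.

    Inputs are standardized per feature using training-split statistics
    only; the target is affinely mapped to [0, 1] using training-split
    range. Deterministic for a fixed config and seed.
    """
    config.validate()
    if isinstance(expr_subset, ExpressionMatrix):
        X = expr_subset.values.T  # samples x features
        feature_ids = list(expr_subset.probe_ids)
        sample_ids = list(expr_subset.sample_ids)
    else:
        X = np.asarray(expr_subset, dtype=float)
        if feature_ids is None or sample_ids is None:
            raise ModelError("feature_ids and sample_ids required for array input")
    y = np.asarray(target, dtype=float)
    n = len(y)
    if n < 6:
        raise ModelError("need at least 6 samples")
    if not np.isfinite(y).all():
        raise ModelError("target contains non-finite values")
    if y.std() == 0:
        raise ModelError("R^2 undefined for a constant target")

    n_train = max(int(round(config.train_fraction * n)), 2)
    if n - n_train < 2:
        raise ModelError("holdout smaller than 2: CV correlation undefined")

    seeds = _derive_seeds(config.seed, stage, config.n_models)
    global_mean = X.mean(axis=0)
    global_sd = np.maximum(X.std(axis=0, ddof=0), 1e-12)

    train_r2 = np.empty(config.n_models)
    cv_r2 = np.empty(config.n_models)
    models: list[_FittedModel] = []
    oof: dict[str, list[float]] = {s: [] for s in sample_ids}

    for m, s in enumerate(seeds):
        rng = np.random.default_rng(int(s))
        perm = rng.permutation(n)
        tr, te = np.sort(perm[:n_train]), np.sort(perm[n_train:])
        if config.standardize == "train":
            mu = X[tr].mean(axis=0)
            sd = np.maximum(X[tr].std(axis=0, ddof=0), 1e-12)
        else:  # leaky variant, for contract tests only
            mu, sd = global_mean, global_sd
        y_lo, y_hi = y[tr].min(), y[tr].max()
        span = y_hi - y_lo
        if span == 0:
            raise ModelError("training split has a constant target")
        est = TinyNet(
            n_hidden=config.hidden_units,
            alpha=config.l2_penalty,
            seed=int(s),
            max_iter=config.max_iterations,
        )
        est.fit((X[tr] - mu) / sd, (y[tr] - y_lo) / span)
        fm = _FittedModel(est, tr, te, mu, sd, float(y_lo), float(span))
        models.append(fm)
        train_r2[m] = _r2(y[tr], fm.predict(X[tr]))
        pred_te = fm.predict(X[te])
        cv_r2[m] = _r2(y[te], pred_te)
        for i, p in zip(te, pred_te):
            oof[sample_ids[i]].append(float(p))

    covered = all(len(v) > 0 for v in oof.values())
    return EnsembleResult(
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        target_name=target_name,
        train_r2=train_r2,
        cv_r2=cv_r2,
        models=models,
        X=X,
        y=y,
        oof_predictions=oof,
        all_samples_held_out=covered,
    )


def compute_sensitivities(
    result: EnsembleResult,
    chunk: int = 256,
) -> SensitivityTable:
    """Finite-difference importance of each input feature.

    For model m, training sample i and feature j the response is
    ``|f_m(x_i with x_ij + sigma_j) - f_m(x_i)|`` where sigma_j is the
    model's training-split SD of feature j; the raw sensitivity is the mean
    over (m, i) and shares are normalized to sum to one.
    """
    p = len(result.feature_ids)
    total = np.zeros(p)
    count = 0
    for fm in result.models:
        Xtr = result.X[fm.train_idx]
        base = fm.predict(Xtr)
        n = len(fm.train_idx)
        count += n
        for start in range(0, p, chunk):
            idx = np.arange(start, min(start + chunk, p))
            stacked = np.repeat(Xtr[None, :, :], len(idx), axis=0)  # (k, n, p)
            for k, j in enumerate(idx):
                stacked[k, :, j] += fm.feat_sd[j]
            pred = fm.predict(stacked.reshape(-1, p)).reshape(len(idx), n)
            total[idx] += np.abs(pred - base[None, :]).sum(axis=1)
    raw = total / count
    denom = raw.sum()
    share = raw / denom if denom > 0 else np.zeros_like(raw)
    order = np.lexsort((result.feature_ids, -share))
    rank = np.empty(p, dtype=int)
    rank[order] = np.arange(1, p + 1)
    table = pd.DataFrame(
        {
            "probe_id": result.feature_ids,
            "sensitivity": raw,
            "share": share,
            "rank": rank,
        }
    ).sort_values("rank", kind="stable").reset_index(drop=True)
    return SensitivityTable(table)


def nested_subset_run(
    expr: ExpressionMatrix,
    pheno: PhenotypeTable,
    screen: ScreenResult,
    sizes: list[int] = (1469, 250, 100),
    config: AnnConfig | None = None,
    target: str = "pct_4h_viable",
) -> dict[int, tuple[EnsembleResult, SensitivityTable]]:
    """Cascade of ensembles over shrinking sensitivity-ranked probe sets.

    Stage 1 trains on the top ``sizes[0]`` probes of the screened set (by
    screen rank); each later stage keeps the top-k probes by the previous
    stage's sensitivity shares and trains a fresh ensemble with a derived
    seed.
    """
    config = config or AnnConfig()
    sizes = list(sizes)
    if sizes != sorted(sizes, reverse=True):
        raise ModelError("sizes must be descending")
    if not sizes or min(sizes) < 1:
        raise ModelError("sizes must be positive probe counts")
    if sizes[0] > len(screen.selected):
        raise ModelError(
            f"first size {sizes[0]} exceeds screened set ({len(screen.selected)})"
        )
    y = pheno.target(target).reindex(expr.sample_ids).to_numpy(dtype=float)

    out: dict[int, tuple[EnsembleResult, SensitivityTable]] = {}
    current = screen.selected[: sizes[0]]
    for stage, k in enumerate(sizes):
        if k > len(current):
            raise ModelError(f"size {k} exceeds {len(current)} available probes")
        sub = expr.subset_probes(current[:k])
        res = train_ensemble(sub, y, config, target_name=target, stage=stage)
        sens = compute_sensitivities(res)
        out[k] = (res, sens)
        current = sens.top(k)  # next stage slices the top of this ranking
    return out


# ---------------------------------------------------------------------------
# subset comparison: ANOVA + Duncan's new multiple range test


@dataclass
class SubsetComparison:
    anova_f: float
    anova_p: float
    group_means: dict[int, float]  # on the transformed scale
    letters: dict[int, str]
    transformed: bool = True


def _duncan_letters(
    means: np.ndarray, labels: list[int], mse: float, df_err: int, n_rep: int,
    alpha: float = 0.05,
) -> dict[int, str]:
    """Duncan's new multiple range test with protection levels
    alpha_p = 1 - (1 - alpha)^(p - 1) and studentized-range critical values;
    equal replicate counts assumed. Returns letter groupings (groups sharing
    a letter are not significantly different)."""
    k = len(means)
    order = np.argsort(means)[::-1]
    sorted_means = means[order]
    se = np.sqrt(mse / n_rep)

    def differ(i: int, j: int) -> bool:
        # i < j in sorted (descending) order; span p = j - i + 1
        p_span = j - i + 1
        alpha_p = 1.0 - (1.0 - alpha) ** (p_span - 1)
        crit = stats.studentized_range.ppf(1.0 - alpha_p, p_span, df_err) * se
        return (sorted_means[i] - sorted_means[j]) > crit

    # build maximal runs of mutually non-different groups (line algorithm)
    candidates: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and not differ(i, j + 1):
            j += 1
        candidates.append((i, j))
    runs = [
        iv
        for iv in candidates
        if not any(
            a <= iv[0] and iv[1] <= b and (a, b) != iv for a, b in candidates
        )
    ]
    runs = sorted(set(runs))
    letters_sorted = ["" for _ in range(k)]
    for run_idx, (a, b) in enumerate(runs):
        ch = chr(ord("a") + run_idx)
        for t in range(a, b + 1):
            letters_sorted[t] += ch
    out: dict[int, str] = {}
    for pos, orig in enumerate(order):
        out[labels[orig]] = letters_sorted[pos]
    return out


def compare_probe_sets(
    results: dict[int, EnsembleResult],
    which: str = "cv",
    alpha: float = 0.05,
) -> SubsetComparison:
    """One-way ANOVA across probe-set sizes on arcsin-sqrt transformed R^2
    replicates, followed by Duncan's new multiple range test.

    ``which`` selects the replicate series: ``"cv"`` (holdout R^2) or
    ``"train"`` (model R^2)."""
    if len(results) < 2:
        raise ModelError("need >= 2 probe-set sizes to compare")
    labels = sorted(results, reverse=True)
    series = []
    for k in labels:
        r2 = results[k].cv_r2 if which == "cv" else results[k].train_r2
        if np.any((r2 < 0) | (r2 > 1)):
            raise ModelError("R^2 outside [0, 1]; cannot arcsin-sqrt transform")
        series.append(np.arcsin(np.sqrt(r2)))
    n_rep = len(series[0])
    if any(len(s) != n_rep for s in series):
        raise ModelError("unequal replicate counts across sizes")

    grand = np.concatenate(series).mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in series)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in series)
    df_b = len(series) - 1
    df_w = sum(len(s) for s in series) - len(series)
    if ss_within == 0:
        if ss_between == 0:
            # all values identical everywhere: nothing to separate
            return SubsetComparison(
                anova_f=float("nan"),
                anova_p=float("nan"),
                group_means={k: float(s.mean()) for k, s in zip(labels, series)},
                letters={k: "a" for k in labels},
            )
        f = float("inf")
        p = 0.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f, df_b, df_w))
    mse = ss_within / df_w if df_w > 0 else 0.0
    means = np.array([s.mean() for s in series])
    if mse > 0:
        letters = _duncan_letters(means, labels, mse, df_w, n_rep, alpha)
    else:
        # zero within-group variance: any mean difference is exact
        distinct = {m: chr(ord("a") + i)
                    for i, m in enumerate(sorted(set(means), reverse=True))}
        letters = {k: distinct[m] for k, m in zip(labels, means)}
    return SubsetComparison(
        anova_f=float(f),
        anova_p=p,
        group_means={k: float(m) for k, m in zip(labels, means)},
        letters=letters,
    )


def genotype_variance(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    config: AnnConfig | None = None,
    target: str = "pct_4h_viable",
) -> float:
    """Share of phenotype variation explained by microsatellite genotype.

    An ensemble is trained on allele-dosage inputs and scored by pooled
    out-of-fold predictive R^2 (1 - SS_res/SS_tot), floored at 0: under a
    null pedigree the holdout predictions carry no information and the
    reported share is ~0, while a genotype tracking the phenotype scores
    high. Constant loci are dropped; an all-constant matrix reports 0.

    The default configuration uses mild shrinkage (l2_penalty=0.01): the
    dosage matrix has two orders of magnitude fewer inputs than the
    expression ensembles, and heavy L2 would shrink holdout predictions
    toward the training mean, biasing the predictive R^2 downward even for
    a truly informative pedigree."""
    config = config or AnnConfig(l2_penalty=0.01)
    X = geno.dosages.astype(float)
    keep = X.std(axis=0) > 0
    if not keep.any():
        return 0.0
    X = X[:, keep]
    ids = [a for a, k in zip(geno.allele_ids, keep) if k]
    y = pheno.target(target).reindex(geno.sample_ids).to_numpy(dtype=float)
    res = train_ensemble(
        X, y, config, feature_ids=ids, sample_ids=list(geno.sample_ids),
        target_name=target, stage=97,
    )
    return max(res.predictive_cv_r2(), 0.0)
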