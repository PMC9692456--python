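"""Repeated double cross-validation (DCV) for PLS-DA and KPLS models.

DCV nests two cross-validation loops: the outer loop mimics an external test
set (honest performance estimation), while the inner loop — run only on the
outer-training samples — selects model complexity (number of latent
variables for PLS-DA; kernel width and latent variables for KPLS). The whole
procedure is repeated with reshuffled fold assignments ("cancellation
groups"), which yields confidence intervals for accuracies, Q2, selected
complexity, and per-variable coefficients.

Variable significance is assessed from the stability of the composite PLS
coefficients across all outer-loop models: a marker contributes significantly
when the empirical central (1 - alpha) interval of its coefficient
distribution excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortTable, GROUP_LEVELS
from .kpls import fit_kpls, predict_kpls, q2_score, sigma_grid
from .pls import fit_plsda, fit_pls, fit_preprocessor, predict_pls

_POS = "PFS"


@dataclass
class DCVConfig:
    """Settings of the repeated double cross-validation procedure."""

    outer_folds: int = 10
    inner_folds: int = 8
    repetitions: int = 50
    lv_grid: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    sigma_points: int = 7
    sigma_span: float = 10.0
    stratified: bool = True
    seed: int = 0
    alpha: float = 0.05
    max_partition_attempts: int = 100
    #: analyze marker concentrations on the log scale (they are right-skewed)
    log_transform: bool = True


@dataclass
class DCVResult:
    """Aggregated output of one repeated-DCV run."""

    mode: str  # "classification" | "regression"
    marker_names: tuple[str, ...]
    config: DCVConfig
    per_rep_overall: np.ndarray  # accuracy or Q2, one entry per repetition
    per_rep_class_acc: dict  # class -> array over repetitions (classification)
    selected_complexity: np.ndarray  # (reps, outer_folds) of A, or object (sigma, A)
    coef_samples: np.ndarray | None  # (reps * outer_folds, p) composite coefficients
    sample_scores: np.ndarray | None  # (reps, n) canonical-variate outer scores
    sample_predictions: np.ndarray | None  # (reps, n) outer-loop predictions
    redraw_log: list = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(self.per_rep_overall.mean())

    @property
    def sd(self) -> float:
        return float(self.per_rep_overall.std(ddof=1)) if len(self.per_rep_overall) > 1 else 0.0

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        lo, hi = np.percentile(self.per_rep_overall, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
        return float(lo), float(hi)

    def mean_complexity(self) -> float:
        vals = [c[1] if isinstance(c, tuple) else c for c in np.ravel(self.selected_complexity)]
        return float(np.mean(vals))

    def sample_score_summary(self, level: float = 0.95):
        """Per-sample mean canonical-variate score with percentile CI across
        repetitions (outer-loop projections)."""
        if self.sample_scores is None:
            raise ValueError("no sample scores recorded")
        s = self.sample_scores
        lo, hi = np.percentile(s, [100 * (1 - level) / 2, 100 * (1 + level) / 2], axis=0)
        return s.mean(axis=0), lo, hi


def make_partitions(n: int, k: int, labels=None, seed=None, rng=None) -> list[np.ndarray]:
    """Split 0..n-1 into k disjoint groups with sizes differing by <= 1.

    With labels, each class is dealt (in shuffled order) to the currently
    smallest group, keeping per-group class counts within 1 of
    proportionality.
    """
    if k > n:
        raise ValueError(f"k={k} > n={n}")
    if k < 2:
        raise ValueError("need k >= 2")
    rng = rng if rng is not None else np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    if labels is None:
        idx = rng.permutation(n)
        sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
        start = 0
        for f, s in zip(folds, sizes):
            f.extend(idx[start : start + s].tolist())
            start += s
    else:
        labels = np.asarray(labels)
        for cls in sorted(set(labels.tolist())):
            members = rng.permutation(np.flatnonzero(labels == cls))
            for m in members:
                f = min(range(k), key=lambda i: (len(folds[i]), i))
                folds[f].append(int(m))
    return [np.array(sorted(f), dtype=int) for f in folds]


def _valid_partition(folds, labels) -> bool:
    classes = set(labels.tolist())
    return all(set(labels[f].tolist()) == classes for f in folds)


def _draw_partition(n, k, labels, rng, stratified, max_attempts, redraw_log):
    for attempt in range(max_attempts):
        folds = make_partitions(n, k, labels=labels if stratified else None, rng=rng)
        if labels is None or _valid_partition(folds, labels):
            return folds
        redraw_log.append(f"re-drew partition (attempt {attempt + 1}): single-class fold")
    raise RuntimeError(f"could not draw a valid partition in {max_attempts} attempts")


def _rep_rngs(seed: int, repetitions: int) -> list[np.random.Generator]:
    """One independent, individually reproducible stream per repetition."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(repetitions)]


def _select_lv_classification(X, y01, folds, lv_grid):
    """Inner CV: balanced accuracy per candidate A; returns the best A
    (ties toward the smallest)."""
    lv_grid = sorted(lv_grid)
    counts = {a: np.zeros(4) for a in lv_grid}  # tp, fn, tn, fp per A
    for i, val in enumerate(folds):
        tr = np.concatenate([f for j, f in enumerate(folds) if j != i])
        Xtr, ytr = X[tr], y01[tr]
        a_hi = min(max(lv_grid), len(tr) - 1, X.shape[1])
        prep = fit_preprocessor(Xtr)
        ym = ytr.mean()
        model = fit_pls(prep.transform(Xtr), ytr - ym, a_hi)
        model.preprocessor = prep
        model.y_mean = ym
        for a in lv_grid:
            aa = min(a, model.A)
            yhat_tr = predict_pls(model, Xtr, a=aa)
            m1 = yhat_tr[ytr == 1].mean()
            m0 = yhat_tr[ytr == 0].mean()
            thr, sgn = 0.5 * (m0 + m1), (1.0 if m1 >= m0 else -1.0)
            pred = (sgn * (predict_pls(model, X[val], a=aa) - thr) >= 0).astype(float)
            yv = y01[val]
            counts[a] += [
                np.sum((pred == 1) & (yv == 1)),
                np.sum((pred == 0) & (yv == 1)),
                np.sum((pred == 0) & (yv == 0)),
                np.sum((pred == 1) & (yv == 0)),
            ]
    best_a, best_bacc = lv_grid[0], -1.0
    for a in lv_grid:
        tp, fn, tn, fp = counts[a]
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        bacc = 0.5 * (sens + spec)
        if bacc > best_bacc + 1e-12:
            best_a, best_bacc = a, bacc
    return best_a


def run_dcv_classification(
    table: CohortTable, markers=None, config: DCVConfig | None = None
) -> DCVResult:
    """Repeated double cross-validation of a PLS-DA model.

    Per repetition the outer partition is reshuffled; per outer fold the
    inner loop picks the number of latent variables by balanced accuracy,
    the model is refit on all outer-training samples, and the held-out fold
    is predicted. Composite coefficients of every outer model are collected
    for variable-significance assessment.
    """
    cfg = config or DCVConfig()
    sub = table if markers is None else table.subset_markers(list(markers))
    X = sub.markers
    labels = sub.group
    if set(labels.tolist()) != set(GROUP_LEVELS):
        raise ValueError("both groups must be present")
    y01 = (labels == _POS).astype(float)
    n, p = X.shape
    Xl = np.log(X) if cfg.log_transform else X

    redraw_log: list[str] = []
    per_rep_overall = np.zeros(cfg.repetitions)
    per_rep_acc = {c: np.zeros(cfg.repetitions) for c in GROUP_LEVELS}
    selected = np.zeros((cfg.repetitions, cfg.outer_folds), dtype=int)
    coef_samples = np.zeros((cfg.repetitions * cfg.outer_folds, p))
    sample_scores = np.zeros((cfg.repetitions, n))
    sample_pred = np.zeros((cfg.repetitions, n))

    for r, rng in enumerate(_rep_rngs(cfg.seed, cfg.repetitions)):
        folds = _draw_partition(
            n, cfg.outer_folds, labels, rng, cfg.stratified, cfg.max_partition_attempts, redraw_log
        )
        correct = {c: 0 for c in GROUP_LEVELS}
        total = {c: 0 for c in GROUP_LEVELS}
        for i, test in enumerate(folds):
            train = np.concatenate([f for j, f in enumerate(folds) if j != i])
            inner = _draw_partition(
                len(train),
                cfg.inner_folds,
                labels[train],
                rng,
                cfg.stratified,
                cfg.max_partition_attempts,
                redraw_log,
            )
            # inner CV operates on the training block only
            a_sel = _select_lv_classification(
                Xl[train], y01[train], inner, [a for a in cfg.lv_grid if a <= min(len(train) - 1, p)]
            )
            model = fit_plsda(Xl[train], labels[train], a_sel, positive_class=_POS)
            yhat = predict_pls(model.pls, Xl[test])
            pred_pos = model.lda_sign * (yhat - model.threshold) >= 0
            for t_idx, is_pos in zip(test, pred_pos):
                truth = labels[t_idx]
                total[truth] += 1
                if (truth == _POS) == bool(is_pos):
                    correct[truth] += 1
            sample_scores[r, test] = model.orientation * (yhat - model.threshold)
            sample_pred[r, test] = yhat
            selected[r, i] = a_sel
            # orient coefficients to the fixed positive-class coding
            coef_samples[r * cfg.outer_folds + i] = model.pls.b
        per_rep_overall[r] = sum(correct.values()) / n
        for c in GROUP_LEVELS:
            per_rep_acc[c][r] = correct[c] / total[c] if total[c] else np.nan

    return DCVResult(
        mode="classification",
        marker_names=sub.marker_names,
        config=cfg,
        per_rep_overall=per_rep_overall,
        per_rep_class_acc=per_rep_acc,
        selected_complexity=selected,
        coef_samples=coef_samples,
        sample_scores=sample_scores,
        sample_predictions=sample_pred,
        redraw_log=redraw_log,
    )


@dataclass
class VariableVerdict:
    name: str
    significant: bool
    direction: str  # "higher in PFS" | "higher in CONTROL"
    median_coef: float
    ci: tuple[float, float]


def assess_variable_significance(result: DCVResult, alpha: float | None = None) -> list[VariableVerdict]:
    """Coefficient-stability significance with jackknife-calibrated intervals.

    Outer-fold coefficients are delete-d jackknife replicates of the
    composite coefficient, so the sampling variance of the full-data
    coefficient is the fold-to-fold spread scaled by (k-1)/k per the
    delete-d jackknife (the raw spread understates it roughly k-fold,
    because outer-training sets overlap by ~(k-2)/k). The spread also
    contains pure Monte-Carlo noise from reshuffling the cancellation
    groups; that component is estimated from the between-repetition
    variance of the per-repetition mean coefficients and removed (floored
    at 20% of the raw spread). A variable is significant when the central
    (1 - alpha) normal interval around the mean coefficient excludes zero.
    """
    if result.coef_samples is None:
        raise ValueError("result carries no coefficient samples")
    from scipy import stats as _stats

    alpha = result.config.alpha if alpha is None else alpha
    k = result.config.outer_folds
    reps = result.config.repetitions
    C = result.coef_samples.reshape(reps, k, -1)
    rep_means = C.mean(axis=1)  # (reps, p)
    spread = ((C - rep_means[:, None, :]) ** 2).sum(axis=1).mean(axis=0)  # (p,)
    if reps > 1:
        mc_noise = rep_means.var(axis=0, ddof=1)  # partition-reshuffle noise / k
        spread_corr = np.clip(spread - (k - 1) * k * mc_noise, 0.2 * spread, None)
    else:
        spread_corr = spread
    se = np.sqrt((k - 1) / k * spread_corr)
    est = C.mean(axis=(0, 1))
    z = _stats.norm.ppf(1 - alpha / 2)

    verdicts = []
    for j, name in enumerate(result.marker_names):
        lo, hi = est[j] - z * se[j], est[j] + z * se[j]
        med = float(np.median(C[:, :, j]))
        verdicts.append(
            VariableVerdict(
                name=name,
                significant=bool(lo > 0 or hi < 0),
                direction="higher in PFS" if med > 0 else "higher in CONTROL",
                median_coef=med,
                ci=(float(lo), float(hi)),
            )
        )
    return verdicts


def refit_reduced_model(table: CohortTable, selected_markers, config: DCVConfig | None = None) -> DCVResult:
    """Full DCV re-run restricted to the selected markers."""
    selected = list(selected_markers)
    if not selected:
        raise ValueError("empty marker selection")
    return run_dcv_classification(table, markers=selected, config=config)


def _select_kpls(X, y, folds, lv_grid, sigmas):
    """Inner CV over (sigma, A): minimize pooled RMSE; ties toward smaller A
    then smaller sigma."""
    sse = {(s, a): 0.0 for s in range(len(sigmas)) for a in lv_grid}
    for i, val in enumerate(folds):
        tr = np.concatenate([f for j, f in enumerate(folds) if j != i])
        a_hi = min(max(lv_grid), len(tr) - 1)
        for si, sig in enumerate(sigmas):
            model = fit_kpls(X[tr], y[tr], sig, a_hi)
            for a in lv_grid:
                aa = min(a, model.A) if model.A else None
                pred = predict_kpls(model, X[val], a=aa)
                sse[(si, a)] += float(np.sum((y[val] - pred) ** 2))
    best = min(sse.items(), key=lambda kv: (kv[1], kv[0][1], kv[0][0]))
    (si, a), _ = best
    return float(sigmas[si]), a


def run_dcv_regression(
    table: CohortTable, outcome: str, config: DCVConfig | None = None, markers=None
) -> DCVResult:
    """Repeated DCV of a Gaussian-kernel KPLS regression of one clinical
    outcome (age, bmi, alm, sppb) on the marker panel; reports per-repetition
    outer-loop Q2."""
    cfg = config or DCVConfig()
    sub = table if markers is None else table.subset_markers(list(markers))
    # outcome: clinical column name, or an explicit response vector
    y = (
        np.asarray(getattr(sub, outcome), dtype=float)
        if isinstance(outcome, str)
        else np.asarray(outcome, dtype=float)
    )
    if len(y) != sub.n_subjects:
        raise ValueError("outcome length does not match cohort size")
    if y.std() == 0:
        raise ValueError(f"outcome {outcome} has zero variance")
    Xl = np.log(sub.markers) if cfg.log_transform else sub.markers
    n = len(y)
    labels = sub.group

    redraw_log: list[str] = []
    per_rep_q2 = np.zeros(cfg.repetitions)
    selected = np.empty((cfg.repetitions, cfg.outer_folds), dtype=object)
    sample_pred = np.zeros((cfg.repetitions, n))

    for r, rng in enumerate(_rep_rngs(cfg.seed, cfg.repetitions)):
        folds = _draw_partition(
            n, cfg.outer_folds, labels, rng, cfg.stratified, cfg.max_partition_attempts, redraw_log
        )
        preds = np.zeros(n)
        for i, test in enumerate(folds):
            train = np.concatenate([f for j, f in enumerate(folds) if j != i])
            inner = _draw_partition(
                len(train), cfg.inner_folds, labels[train], rng, cfg.stratified,
                cfg.max_partition_attempts, redraw_log,
            )
            lv = [a for a in cfg.lv_grid if a <= len(train) - 2]
            prep = fit_preprocessor(Xl[train])
            sigmas = sigma_grid(prep.transform(Xl[train]), cfg.sigma_points, cfg.sigma_span)
            sig, a_sel = _select_kpls(Xl[train], y[train], inner, lv, sigmas)
            model = fit_kpls(Xl[train], y[train], sig, a_sel)
            preds[test] = predict_kpls(model, Xl[test])
            selected[r, i] = (sig, a_sel)
        per_rep_q2[r] = q2_score(y, preds)
        sample_pred[r] = preds

    return DCVResult(
        mode="regression",
        marker_names=sub.marker_names,
        config=cfg,
        per_rep_overall=per_rep_q2,
        per_rep_class_acc={},
        selected_complexity=selected,
        coef_samples=None,
        sample_scores=None,
        sample_predictions=sample_pred,
        redraw_log=redraw_log,
    )


def permutation_test_accuracy(
    table: CohortTable, markers=None, config: DCVConfig | None = None, n_perm: int = 19
) -> dict:
    """Permutation test of the DCV classification accuracy.

    Group labels are permuted (seeded); the full repeated-DCV mean accuracy
    is recomputed per permutation. p = (1 + #{perm >= observed}) / (n_perm + 1).
    """
    cfg = config or DCVConfig()
    if n_perm < 19:
        raise ValueError("need n_perm >= 19")
    if len(set(table.group.tolist())) < 2:
        raise ValueError("single-class cohort")
    observed = run_dcv_classification(table, markers=markers, config=cfg).mean
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1_000_003]))
    null = np.zeros(n_perm)
    for b in range(n_perm):
        perm_table = CohortTable(
            **{
                **{k: getattr(table, k) for k in (
                    "subject_id", "age", "sex", "bmi", "sppb", "alm", "alm_bmi",
                    "n_diseases", "n_medications", "markers",
                )},
                "group": rng.permutation(table.group),
                "marker_names": table.marker_names,
            }
        )
        null[b] = run_dcv_classification(perm_table, markers=markers, config=cfg).mean
    p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return {"observed": observed, "null": null, "p": p}
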