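"""Two-group linear discriminant training with stepwise Wilks'-lambda selection.

The training pipeline mirrors classical stepwise discriminant analysis:

1. Variable selection: at each step the candidate whose entry minimizes
   Wilks' lambda  Lambda = det(W)/det(T)  (W = pooled within-group scatter,
   T = total scatter) is entered if its partial F exceeds ``f_enter``; any
   entered variable whose partial F has dropped below ``f_remove`` is then
   removed.  Selection stops when no action qualifies or after ``max_steps``
   actions (default 20).
2. Canonical statistics: for two groups the single discriminant eigenvalue
   lambda (largest eigenvalue of W^-1 B) determines
   Lambda = 1/(1+lambda) and the canonical correlation R = sqrt(lambda/(1+lambda)).
   Significance uses Bartlett's chi-square
   chi2 = -(n - 1 - (p+g)/2) * ln(Lambda) with p(g-1) degrees of freedom.
3. Fisher classification functions: per class g, coefficients
   Sigma_pooled^-1 mu_g and constant -1/2 mu_g' Sigma_pooled^-1 mu_g + ln(prior_g);
   a case is assigned to the class with the larger score.
4. Leave-one-out accuracy: each case is classified by Fisher functions
   refitted on the remaining n-1 cases.

Priors default to equal (0.5/0.5); group-size ("proportional") priors are
available.  Equal priors make the Fisher rule identical to nearest-centroid
classification in Mahalanobis distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bank import AGE_GROUPS, FisherClassifier, assign_age_group
from .features import FEATURE_NAMES

DEFAULT_F_ENTER = 3.84
DEFAULT_F_REMOVE = 2.71
MAX_STEPS = 20
N_GROUPS = 2                       # binary sleep-quality judgment
_VAR_FLOOR = 1e-12                 # pooled-variance floor for candidate screening


class TrainError(Exception):
    """Training input is degenerate (singular scatter, single class, ...)."""


@dataclass(frozen=True)
class StepwiseStep:
    action: str                    # "enter" | "remove"
    variable: str
    wilks: float                   # Wilks' lambda after the action
    f_statistic: float


@dataclass
class StepwiseTrace:
    steps: list[StepwiseStep] = field(default_factory=list)

    @property
    def selected(self) -> list[str]:
        current: list[str] = []
        for s in self.steps:
            if s.action == "enter":
                current.append(s.variable)
            else:
                current.remove(s.variable)
        return current


@dataclass
class LdaModel:
    group_id: int | None
    variables: tuple[str, ...]
    canonical_coef: np.ndarray
    eigenvalue: float
    canonical_correlation: float
    wilks: float
    chi_square: float
    df: int
    p_value: float
    classifier: FisherClassifier | None
    loo_accuracy: float | None
    n: int
    trace: StepwiseTrace | None = None


def _as_matrix(X, variables=None):
    if isinstance(X, pd.DataFrame):
        if variables is None:
            variables = [c for c in X.columns if c in FEATURE_NAMES] or list(X.columns)
        return X.loc[:, list(variables)].to_numpy(dtype=float), tuple(variables)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if variables is None:
        variables = tuple(f"x{i}" for i in range(X.shape[1]))
    return X, tuple(variables)


def _scatter_matrices(X: np.ndarray, y: np.ndarray):
    """Pooled within-group scatter W, total scatter T and class stats."""
    classes = np.unique(y)
    if classes.size != N_GROUPS:
        raise TrainError(f"need exactly two classes, got {classes.tolist()}")
    mu = X.mean(axis=0)
    T = (X - mu).T @ (X - mu)
    W = np.zeros_like(T)
    means, counts = [], []
    for c in classes:
        Xc = X[y == c]
        mc = Xc.mean(axis=0)
        W += (Xc - mc).T @ (Xc - mc)
        means.append(mc)
        counts.append(len(Xc))
    return W, T, classes, np.array(means), np.array(counts)


def wilks_lambda(X, y, variables=None) -> float:
    """Lambda = det(W)/det(T) on the given columns; in (0, 1]."""
    X, _ = _as_matrix(X, variables)
    y = np.asarray(y)
    W, T, *_ = _scatter_matrices(X, y)
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_w <= 0 or sign_t <= 0:
        raise TrainError("singular scatter matrix; drop collinear/constant variables")
    return float(np.exp(logdet_w - logdet_t))


def _partial_f(lambda_small: float, lambda_big: float, n: int, p_small: int) -> float:
    """Partial F for the variable whose entry took Lambda from small-set value
    ``lambda_small`` (p_small variables) to ``lambda_big`` (p_small + 1)."""
    dof = n - N_GROUPS - p_small
    if dof <= 0 or lambda_big <= 0:
        return 0.0
    return dof / (N_GROUPS - 1) * (lambda_small / lambda_big - 1.0)


def stepwise_select(X, y, variables=None,
                    f_enter: float = DEFAULT_F_ENTER,
                    f_remove: float = DEFAULT_F_REMOVE,
                    max_steps: int = MAX_STEPS) -> StepwiseTrace:
    """Stepwise Wilks'-lambda variable selection; may select nothing.

    Variables with pooled within-group variance below a small floor are
    excluded from candidacy (they would make the scatter singular).
    """
    X, names = _as_matrix(X, variables)
    y = np.asarray(y)
    n = len(y)
    W, _, *_ = _scatter_matrices(X, y)
    usable = [i for i in range(len(names)) if W[i, i] > _VAR_FLOOR]

    def lam(cols) -> float | None:
        try:
            return wilks_lambda(X[:, cols], y)
        except TrainError:
            return None

    selected: list[int] = []
    trace = StepwiseTrace()
    current_lambda = 1.0
    while len(trace.steps) < max_steps:
        acted = False
        # entry: candidate minimizing Lambda
        candidates = [i for i in usable if i not in selected]
        best, best_lambda = None, None
        for i in candidates:
            li = lam(selected + [i])
            if li is not None and (best_lambda is None or li < best_lambda):
                best, best_lambda = i, li
        if best is not None:
            f = _partial_f(current_lambda, best_lambda, n, len(selected))
            if f >= f_enter:
                selected.append(best)
                current_lambda = best_lambda
                trace.steps.append(StepwiseStep("enter", names[best],
                                                current_lambda, f))
                acted = True
        # removal: any included variable whose partial F fell below f_remove
        while len(trace.steps) < max_steps and len(selected) > 1:
            worst, worst_f, worst_lambda = None, None, None
            for i in selected:
                rest = [j for j in selected if j != i]
                lr = lam(rest)
                if lr is None:
                    continue
                f = _partial_f(lr, current_lambda, n, len(rest))
                if worst_f is None or f < worst_f:
                    worst, worst_f, worst_lambda = i, f, lr
            if worst is None or worst_f >= f_remove:
                break
            selected.remove(worst)
            current_lambda = worst_lambda
            trace.steps.append(StepwiseStep("remove", names[worst],
                                            current_lambda, worst_f))
            acted = True
        if not acted:
            break
    return trace


def bartlett_chi_square(wilks: float, n: int, p: int,
                        g: int = N_GROUPS) -> tuple[float, int, float]:
    """Bartlett's chi-square test of the discriminant function."""
    if not (0.0 < wilks <= 1.0):
        raise TrainError(f"Wilks' lambda must be in (0, 1], got {wilks}")
    mult = n - 1 - (p + g) / 2.0
    if mult <= 0:
        raise TrainError(f"sample size n={n} too small for Bartlett's test with p={p}")
    chi2 = -mult * np.log(wilks)
    df = p * (g - 1)
    return float(chi2), int(df), float(stats.chi2.sf(chi2, df))


def _priors_vector(priors, counts: np.ndarray) -> np.ndarray:
    if priors is None or priors == "equal":
        return np.full(N_GROUPS, 1.0 / N_GROUPS)
    if priors == "proportional":
        return counts / counts.sum()
    pv = np.asarray(priors, dtype=float)
    if pv.shape != (N_GROUPS,) or not np.isclose(pv.sum(), 1.0):
        raise TrainError("priors must be 'equal', 'proportional' or two values summing to 1")
    return pv


def fisher_functions(X, y, variables=None, priors="equal",
                     group_id: int | None = None) -> FisherClassifier:
    """Fisher classification functions from pooled within-group covariance."""
    X, names = _as_matrix(X, variables)
    y = np.asarray(y)
    W, _, classes, means, counts = _scatter_matrices(X, y)
    n = len(y)
    cov = W / (n - N_GROUPS)
    try:
        coef = np.linalg.solve(cov, means.T).T       # rows: class 0, class 1
    except np.linalg.LinAlgError as exc:
        raise TrainError("singular pooled within-group covariance") from exc
    pv = _priors_vector(priors, counts)
    consts = -0.5 * np.einsum("ij,ij->i", coef, means) + np.log(pv)
    order = np.argsort(classes)                      # class 0 -> y0, class 1 -> y1
    i0, i1 = order[0], order[1]
    return FisherClassifier(
        group_id=group_id if group_id is not None else -1,
        variables=names,
        coef_y0=coef[i0], coef_y1=coef[i1],
        const_y0=float(consts[i0]), const_y1=float(consts[i1]))


def _classify_rows(clf: FisherClassifier, X: np.ndarray) -> np.ndarray:
    s0 = X @ clf.coef_y0 + clf.const_y0
    s1 = X @ clf.coef_y1 + clf.const_y1
    return (s1 > s0).astype(int)


def loo_accuracy(X, y, variables=None, priors="equal") -> float:
    """Leave-one-out accuracy of the Fisher rule."""
    X, names = _as_matrix(X, variables)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 4:
        raise TrainError("need at least 4 cases for leave-one-out")
    correct = 0
    idx = np.arange(n)
    for i in range(n):
        rest = idx != i
        if np.unique(y[rest]).size < N_GROUPS:
            raise TrainError("a leave-one-out fold has a single-class training set")
        clf = fisher_functions(X[rest], y[rest], names, priors)
        correct += int(_classify_rows(clf, X[i:i + 1])[0] == y[i])
    return correct / n


def fit_lda(X, y, variables=None, priors="equal",
            group_id: int | None = None,
            trace: StepwiseTrace | None = None,
            with_loo: bool = True) -> LdaModel:
    """Canonical statistics + Fisher functions (+ LOO) on the given variables."""
    X, names = _as_matrix(X, variables)
    y = np.asarray(y, dtype=int)
    n = len(y)
    W, T, classes, means, counts = _scatter_matrices(X, y)
    B = T - W
    try:
        eigval = float(np.trace(np.linalg.solve(W, B)))   # rank(B) = 1 for 2 groups
    except np.linalg.LinAlgError as exc:
        raise TrainError("singular within-group scatter") from exc
    if eigval < 0:
        eigval = 0.0
    wilks = 1.0 / (1.0 + eigval)
    can_r = float(np.sqrt(eigval / (1.0 + eigval)))
    chi2, df, p_value = bartlett_chi_square(wilks, n, len(names))

    # canonical discriminant direction, scaled to unit pooled within variance
    diff = means[np.argsort(classes)[1]] - means[np.argsort(classes)[0]]
    v = np.linalg.solve(W, diff)
    scale = float(np.sqrt(v @ (W / (n - N_GROUPS)) @ v))
    canonical = v / scale if scale > 0 else v

    clf = fisher_functions(X, y, names, priors, group_id)
    loo = loo_accuracy(X, y, names, priors) if with_loo else None
    return LdaModel(group_id=group_id, variables=names, canonical_coef=canonical,
                    eigenvalue=eigval, canonical_correlation=can_r, wilks=wilks,
                    chi_square=chi2, df=df, p_value=p_value, classifier=clf,
                    loo_accuracy=loo, n=n, trace=trace)


# ---------------------------------------------------------------------------
# Per-age-group bank training
# ---------------------------------------------------------------------------

@dataclass
class TrainReport:
    models: dict[int, LdaModel]
    skipped: dict[int, str]

    def bank(self) -> dict[int, FisherClassifier]:
        return {gid: m.classifier for gid, m in self.models.items()
                if m.classifier is not None}


def train_bank(features: pd.DataFrame, labels: dict[str, int] | pd.Series,
               f_enter: float = DEFAULT_F_ENTER,
               f_remove: float = DEFAULT_F_REMOVE,
               priors="equal") -> TrainReport:
    """Fit one stepwise discriminant per age group 1-8.

    ``features`` needs columns ``child_id``, ``age_months`` and the ten
    variables.  Groups missing a class (or group 0) are skipped with a reason.
    """
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    df = features.copy()
    df["_label"] = df["child_id"].map(labels)
    if df["_label"].isna().any():
        missing = df.loc[df["_label"].isna(), "child_id"].tolist()
        raise TrainError(f"no label for child(ren) {missing[:5]}")
    df["_group"] = df["age_months"].map(assign_age_group)

    models: dict[int, LdaModel] = {}
    skipped: dict[int, str] = {}
    for gid in sorted(AGE_GROUPS):
        sub = df[df["_group"] == gid]
        if gid == 0:
            if len(sub):
                skipped[gid] = f"group 0 not trained ({len(sub)} children set aside)"
            continue
        if len(sub) == 0:
            continue
        ys = sub["_label"].astype(int).to_numpy()
        if np.unique(ys).size < N_GROUPS:
            skipped[gid] = "only one class present"
            continue
        X = sub.loc[:, list(FEATURE_NAMES)]
        trace = stepwise_select(X, ys, list(FEATURE_NAMES), f_enter, f_remove)
        chosen = trace.selected
        if not chosen:
            skipped[gid] = "stepwise selection entered no variable"
            continue
        try:
            models[gid] = fit_lda(X, ys, chosen, priors, group_id=gid, trace=trace)
        except TrainError as exc:
            skipped[gid] = str(exc)
    return TrainReport(models=models, skipped=skipped)


def report_to_dict(report: TrainReport) -> dict:
    """JSON-serializable summary of a training run."""
    out = {"groups": {}, "skipped": report.skipped}
    for gid, m in report.models.items():
        out["groups"][str(gid)] = {
            "n": m.n,
            "variables": list(m.variables),
            "eigenvalue": m.eigenvalue,
            "canonical_correlation": m.canonical_correlation,
            "wilks_lambda": m.wilks,
            "chi_square": m.chi_square,
            "df": m.df,
            "p_value": m.p_value,
            "loo_accuracy": m.loo_accuracy,
            "stepwise_trace": [
                {"action": s.action, "variable": s.variable,
                 "wilks": s.wilks, "F": s.f_statistic}
                for s in (m.trace.steps if m.trace else [])],
        }
    return out
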