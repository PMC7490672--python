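"""Wrist cut-point derivation from hip-labeled epochs.

Three calibrators turn a training table of wrist cpm values (optionally
with hip-reference intensity labels) into a wrist :class:`CutPointSet`:

``roc_calibrate``
    Three cumulative dichotomies of the ordinal scale — SB vs above,
    (SB ∪ LPA) vs above, (SB ∪ LPA ∪ MPA) vs VPA — each scanned over
    the observed unique cpm values with the predicate ``cpm > t``
    ("positive" = the higher-intensity side).  The selected threshold
    minimizes |sensitivity − specificity| (ties toward the smallest t);
    the scan over observed values is exact because both rates are
    piecewise constant between them.

``olr_calibrate``
    Proportional-odds cumulative-logit model of the hip label on wrist
    cpm (three intercepts, one slope), fitted by maximum likelihood
    with an optional tiny ridge on the slope for quasi-separable data.
    Each epoch is assigned to its argmax-probability class; cut points
    come from the max/min observed cpm within assigned classes.

``kmeans_calibrate``
    Unsupervised univariate k-means with k = 4.  The default solver is
    an exact dynamic program over sorted unique values (optimal
    within-cluster sum of squares, deterministic, no seed); Lloyd
    iterations with k-means++ restarts are available as an option.
    Cluster upper bounds become the cut points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .cutpoints import LEVEL_NAMES, CutPointSet, label_series

__all__ = [
    "CalibrationError",
    "CrossingThresholdsError",
    "EmptyPredictedClassError",
    "CalibrationResult",
    "roc_calibrate",
    "olr_calibrate",
    "kmeans_calibrate",
    "summarize_classes",
]


class CalibrationError(ValueError):
    """Calibration could not produce a valid cut-point set."""


class CrossingThresholdsError(CalibrationError):
    """Independently fitted dichotomy thresholds are not strictly increasing."""


class EmptyPredictedClassError(CalibrationError):
    """A model assigned no epochs to one of the four intensity classes."""


@dataclass
class CalibrationResult:
    """A derived cut-point set plus its per-class summary and diagnostics."""

    method: str
    cuts: CutPointSet
    per_class: pd.DataFrame  # class, n, lower, upper, mean, sd
    diagnostics: dict = field(default_factory=dict)

    def check_valid(self, n_input: int) -> None:
        if int(self.per_class["n"].sum()) != n_input:
            raise CalibrationError("per-class n does not sum to the input length")
        means = self.per_class["mean"].to_numpy(dtype=float)
        present = self.per_class["n"].to_numpy() > 0
        m = means[present]
        if len(m) > 1 and not np.all(np.diff(m) > 0):
            raise CalibrationError("class mean cpm must strictly increase with intensity")


def _validate_labeled(wrist_cpm, hip_label, require_all_classes=True):
    w = np.asarray(wrist_cpm)
    y = np.asarray(hip_label, dtype=np.int64)
    if w.shape != y.shape or w.ndim != 1:
        raise ValueError("wrist_cpm and hip_label must be equal-length 1-D sequences")
    if w.size == 0:
        raise ValueError("empty calibration data")
    if w.min() < 0:
        raise ValueError("negative cpm values")
    if y.min() < 0 or y.max() > 3:
        raise ValueError("labels must be ordinal codes 0..3")
    if require_all_classes and len(np.unique(y)) < 4:
        missing = [LEVEL_NAMES[k] for k in range(4) if not np.any(y == k)]
        raise CalibrationError(
            f"supervised calibration needs all four classes; missing {missing}"
        )
    return w, y


def summarize_classes(
    values: Sequence[float], assignments: Sequence[int], n_classes: int = 4
) -> pd.DataFrame:
    """Per-class n, observed bounds, mean and sample SD (n−1 denominator).

    Empty classes are reported with ``n = 0`` and NaN statistics rather
    than raising; single-member classes get NaN SD.
    """
    v = np.asarray(values, dtype=np.float64)
    a = np.asarray(assignments, dtype=np.int64)
    if v.shape != a.shape:
        raise ValueError("values and assignments must be parallel")
    rows = []
    for k in range(n_classes):
        sel = v[a == k]
        rows.append(
            {
                "class": LEVEL_NAMES[k] if n_classes == 4 else str(k),
                "n": int(sel.size),
                "lower": float(sel.min()) if sel.size else np.nan,
                "upper": float(sel.max()) if sel.size else np.nan,
                "mean": float(sel.mean()) if sel.size else np.nan,
                "sd": float(sel.std(ddof=1)) if sel.size > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _result(method, t1, t2, t3, wrist_cpm, diagnostics) -> CalibrationResult:
    try:
        cuts = CutPointSet(f"{method}_wrist", "wrist", int(t1), int(t2), int(t3))
    except ValueError as exc:
        raise CrossingThresholdsError(
            f"{method} thresholds ({t1}, {t2}, {t3}) do not strictly increase: {exc}"
        ) from exc
    assigned = label_series(wrist_cpm, cuts)
    res = CalibrationResult(method, cuts, summarize_classes(wrist_cpm, assigned), diagnostics)
    res.check_valid(len(wrist_cpm))
    return res


# --------------------------------------------------------------------------
# ROC
# --------------------------------------------------------------------------

def roc_threshold(wrist_cpm: np.ndarray, positive: np.ndarray) -> tuple[int, float, float]:
    """Exact scan of one dichotomy over observed unique thresholds.

    Predicts positive when ``cpm > t``.  Returns ``(t, sensitivity,
    specificity)`` at the threshold minimizing |sens − spec|, tie broken
    toward the smallest t.
    """
    w = np.asarray(wrist_cpm)
    pos = np.asarray(positive, dtype=bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise CalibrationError("dichotomy needs examples on both sides")
    t_candidates, inv = np.unique(w, return_inverse=True)
    if t_candidates.size < 2:
        raise CalibrationError("all cpm values identical: no threshold separates anything")
    # counts of positives/negatives at each unique value
    pos_at = np.bincount(inv, weights=pos).astype(np.int64)
    neg_at = np.bincount(inv, weights=~pos).astype(np.int64)
    # predicate cpm > t  =>  TP(t) = positives strictly above t
    tp = n_pos - np.cumsum(pos_at)
    tn = np.cumsum(neg_at)
    sens = tp / n_pos
    spec = tn / n_neg
    d = np.abs(sens - spec)
    # tie broken toward the smallest t, with a float tolerance so that
    # rationally-equal |sens − spec| values at different thresholds tie
    k = int(np.flatnonzero(d <= d.min() + 1e-12)[0])
    return int(t_candidates[k]), float(sens[k]), float(spec[k])


def roc_calibrate(wrist_cpm, hip_label) -> CalibrationResult:
    """Three cumulative ROC dichotomies -> wrist cut points (t1, t2, t3)."""
    w, y = _validate_labeled(wrist_cpm, hip_label)
    thresholds, diag = [], {}
    for d in (1, 2, 3):
        t, sens, spec = roc_threshold(w, y >= d)
        thresholds.append(t)
        diag[f"boundary_{d}"] = {"t": t, "sensitivity": sens, "specificity": spec}
    t1, t2, t3 = thresholds
    if not (t1 < t2 < t3):
        raise CrossingThresholdsError(
            f"crossing thresholds: dichotomies selected ({t1}, {t2}, {t3})"
        )
    return _result("roc", t1, t2, t3, w, diag)


# --------------------------------------------------------------------------
# Ordinal (cumulative-logit / proportional-odds) regression
# --------------------------------------------------------------------------

def _cumlogit_nll_grad(params, x, y_onehot, ridge):
    """Negative log-likelihood and gradient; thresholds via (a1, log-increments).

    Model: P(Y <= k | x) = sigmoid(alpha_k − beta * x), k = 0, 1, 2.
    """
    a1, d2, d3, beta = params
    alphas = np.array([a1, a1 + np.exp(d2), a1 + np.exp(d2) + np.exp(d3)])
    eta = alphas[None, :] - beta * x[:, None]  # (n, 3)
    cdf = expit(eta)
    full = np.hstack([np.zeros((x.size, 1)), cdf, np.ones((x.size, 1))])  # (n, 5)
    probs = np.diff(full, axis=1)  # (n, 4)
    p_obs = np.clip((probs * y_onehot).sum(axis=1), 1e-300, None)
    nll = -np.log(p_obs).sum() + ridge * beta * beta

    # gradient wrt alphas and beta through p_obs
    pdf = cdf * (1 - cdf)  # sigmoid'(eta), (n, 3)
    # d p_k / d alpha_j = pdf_j * ([j == k] − [j == k−1])
    y_idx = np.argmax(y_onehot, axis=1)  # class index per row (y_onehot is exact)
    grad_alpha = np.zeros(3)
    grad_beta = 0.0
    inv_p = 1.0 / p_obs
    for j in range(3):
        contrib = np.zeros(x.size)
        contrib[y_idx == j] += pdf[y_idx == j, j]
        contrib[y_idx == j + 1] -= pdf[y_idx == j + 1, j]
        grad_alpha[j] = -(contrib * inv_p).sum()
        grad_beta += (contrib * inv_p * x).sum()  # d eta / d beta = −x
    grad_beta += 2 * ridge * beta
    # chain rule to (a1, d2, d3)
    g_a1 = grad_alpha.sum()
    g_d2 = (grad_alpha[1] + grad_alpha[2]) * np.exp(d2)
    g_d3 = grad_alpha[2] * np.exp(d3)
    return nll, np.array([g_a1, g_d2, g_d3, grad_beta])


def fit_cumulative_logit(
    x: np.ndarray,
    y: np.ndarray,
    ridge: float = 1e-6,
    max_iter: int = 500,
) -> dict:
    """MLE of the proportional-odds model with a single predictor.

    The predictor is standardized internally; returned ``alpha`` (length
    3, increasing) and ``beta`` are on the original scale.  ``ridge``
    penalizes beta^2 (on the standardized scale) so quasi-separable data
    yield a finite optimum.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if np.ptp(x) == 0:
        raise CalibrationError("wrist_cpm is constant: cumulative-logit fit undefined")
    mu, sd = x.mean(), x.std()
    xs = (x - mu) / sd
    y_onehot = np.eye(4)[y]
    # start from the empirical cumulative logits at beta = 0
    cum = np.cumsum(np.bincount(y, minlength=4) / y.size)[:3]
    cum = np.clip(cum, 1e-6, 1 - 1e-6)
    a = np.log(cum / (1 - cum))
    a = np.maximum.accumulate(a + np.arange(3) * 1e-6)
    x0 = np.array(
        [a[0], np.log(max(a[1] - a[0], 1e-6)), np.log(max(a[2] - a[1], 1e-6)), 1.0]
    )
    opt = minimize(
        _cumlogit_nll_grad,
        x0,
        args=(xs, y_onehot, ridge),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "maxfun": 10 * max_iter},
    )
    a1, d2, d3, beta_s = opt.x
    alphas_s = np.array([a1, a1 + np.exp(d2), a1 + np.exp(d2) + np.exp(d3)])
    beta = beta_s / sd
    alphas = alphas_s + beta_s * mu / sd
    if not np.isfinite(opt.fun):
        raise CalibrationError(f"cumulative-logit fit did not converge: {opt.message}")
    return {
        "alpha": alphas,
        "beta": float(beta),
        "alpha_std": alphas_s,
        "beta_std": float(beta_s),
        "nll": float(opt.fun),
        "n_iter": int(opt.nit),
        "converged": bool(opt.success),
        "x_mean": float(mu),
        "x_sd": float(sd),
    }


def predict_class_probs(x: np.ndarray, alpha: np.ndarray, beta: float) -> np.ndarray:
    """Class probabilities P(Y = k | x) of a cumulative-logit model, (n, 4)."""
    x = np.asarray(x, dtype=np.float64)
    eta = np.asarray(alpha)[None, :] - beta * x[:, None]
    cdf = expit(eta)
    full = np.hstack([np.zeros((x.size, 1)), cdf, np.ones((x.size, 1))])
    return np.diff(full, axis=1)


def olr_calibrate(wrist_cpm, hip_label, ridge: float = 1e-6) -> CalibrationResult:
    """Proportional-odds fit + argmax assignment -> wrist cut points.

    Cut points follow the max/min rule: t1 = max cpm assigned SB,
    t2 = min cpm assigned MPA − 1, t3 = min cpm assigned VPA − 1 (LPA
    spans in between).
    """
    w, y = _validate_labeled(wrist_cpm, hip_label)
    fit = fit_cumulative_logit(w.astype(np.float64), y, ridge=ridge)
    probs = predict_class_probs(w.astype(np.float64), fit["alpha"], fit["beta"])
    assigned = np.argmax(probs, axis=1)
    for k in range(4):
        if not np.any(assigned == k):
            raise EmptyPredictedClassError(
                f"empty predicted class {LEVEL_NAMES[k]}: no epoch attains "
                "argmax probability for it"
            )
    t1 = int(w[assigned == 0].max())
    t2 = int(w[assigned == 2].min()) - 1
    t3 = int(w[assigned == 3].min()) - 1
    return _result("olr", t1, t2, t3, w, {"fit": fit})


# --------------------------------------------------------------------------
# Exact univariate k-means (dynamic programming)
# --------------------------------------------------------------------------

def _dp_kmeans_unique(values: np.ndarray, weights: np.ndarray, k: int):
    """Optimal WCSS partition of weighted sorted unique values into k
    contiguous segments, via divide-and-conquer DP (O(k u log u))."""
    u = values.size
    w1 = np.concatenate([[0.0], np.cumsum(weights)])
    ws = np.concatenate([[0.0], np.cumsum(weights * values)])
    ws2 = np.concatenate([[0.0], np.cumsum(weights * values * values)])

    def seg_cost(j, i):  # inclusive j..i
        w = w1[i + 1] - w1[j]
        s = ws[i + 1] - ws[j]
        return (ws2[i + 1] - ws2[j]) - s * s / w

    prev = np.array([seg_cost(0, i) for i in range(u)])
    args = np.zeros((k, u), dtype=np.int64)
    for layer in range(1, k):
        cur = np.full(u, np.inf)
        arg = np.zeros(u, dtype=np.int64)

        # compute cur[i] for i in [lo, hi] with argmin j constrained to
        # [jlo, jhi]; the argmin is monotone in i for this cost
        stack = [(layer, u - 1, layer, u - 1)]
        while stack:
            lo, hi, jlo, jhi = stack.pop()
            if lo > hi:
                continue
            mid = (lo + hi) // 2
            best, bestj = np.inf, jlo
            for j in range(jlo, min(jhi, mid) + 1):
                c = prev[j - 1] + seg_cost(j, mid)
                if c < best - 1e-12:
                    best, bestj = c, j
            cur[mid], arg[mid] = best, bestj
            stack.append((lo, mid - 1, jlo, bestj))
            stack.append((mid + 1, hi, bestj, jhi))
        prev, args[layer] = cur, arg
    # backtrack segment starts
    bounds = np.zeros(k + 1, dtype=np.int64)
    bounds[k] = u
    i = u - 1
    for layer in range(k - 1, 0, -1):
        j = args[layer][i]
        bounds[layer] = j
        i = j - 1
    return bounds, float(prev[u - 1])


def kmeans_calibrate(
    wrist_cpm,
    k: int = 4,
    method: str = "dp",
    seed: int = 0,
    n_init: int = 10,
) -> CalibrationResult:
    """Univariate k-means clustering of pooled wrist cpm values.

    ``method="dp"`` (default) computes the exact WCSS-optimal partition
    — deterministic and seed-free; equal values always share a cluster.
    ``method="lloyd"`` runs scikit-learn k-means++ with ``n_init``
    seeded restarts.  Cut points are the observed maxima of the three
    lowest clusters (the max-within-category rule).
    """
    w = np.asarray(wrist_cpm)
    if w.ndim != 1 or w.size == 0:
        raise ValueError("wrist_cpm must be a non-empty 1-D sequence")
    if w.min() < 0:
        raise ValueError("negative cpm values")
    uniq, counts = np.unique(w, return_counts=True)
    if uniq.size < k:
        raise CalibrationError(
            f"k-means with k={k} needs >= {k} distinct values, got {uniq.size}"
        )
    if method == "dp":
        bounds, wcss = _dp_kmeans_unique(
            uniq.astype(np.float64), counts.astype(np.float64), k
        )
        uppers = [float(uniq[bounds[j] - 1]) for j in range(1, k + 1)]
        assigned = np.searchsorted(np.array(uppers), w, side="left").astype(np.int8)
        centroids = [float(w[assigned == j].mean()) for j in range(k)]
        diag = {"solver": "dp", "wcss": wcss, "centroids": centroids}
    elif method == "lloyd":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(
            w.reshape(-1, 1).astype(np.float64)
        )
        order = np.argsort(km.cluster_centers_.ravel())
        relabel = np.empty(k, dtype=np.int64)
        relabel[order] = np.arange(k)
        assigned = relabel[km.labels_].astype(np.int8)
        uppers = [float(w[assigned == j].max()) for j in range(k)]
        wcss = float(km.inertia_)
        centroids = sorted(km.cluster_centers_.ravel().tolist())
        diag = {"solver": "lloyd", "wcss": wcss, "centroids": centroids}
    else:
        raise ValueError(f"unknown k-means method {method!r}; use 'dp' or 'lloyd'")

    if k != 4:
        cuts = None
        res = CalibrationResult(
            "kmeans", cuts, summarize_classes(w, assigned, n_classes=k), diag
        )
        return res
    t1, t2, t3 = (int(u) for u in uppers[:3])
    return _result("kmeans", t1, t2, t3, w, diag)
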