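"""Benchmarking statistics for frustration-vs-B-factor comparisons.

All vectors follow the package-wide NaN-mask convention: a NaN entry is
an undefined position.  Every statistic here deletes undefined positions
pairwise and consistently, so adding a masked position never changes a
result.

The evaluation machinery mirrors how a frustration score is judged
against crystallographic B-factors: rank (or linear) correlation with a
significance test, quartile-based ground-truth labels for high- and
low-mobility residues, ROC / precision-recall classification restricted
to the top-and-bottom-quartile residues (so chance average precision is
0.5), paired comparisons of correlation coefficients across structures,
and a one-sided Wilcoxon signed-rank test against a chance baseline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import StatisticsError, ValidationError


@dataclass
class BenchmarkResult:
    rho: float
    p_value: float
    n_pairs: int
    auc_roc_high: float
    ap_high: float
    ap_low: float
    baseline_high: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class PairedComparison:
    """Per-protein differences between two sets of correlation coefficients."""

    differences: np.ndarray
    median: float
    mean: float


def _as_vector(values) -> np.ndarray:
    return np.asarray(values, dtype=np.float64)


def smooth(values, window: int) -> np.ndarray:
    """Centered moving average over defined neighbors only.

    The window shrinks at the edges (and around masked entries, which
    simply do not contribute); masked positions stay masked.  ``window``
    must be odd and positive; window 1 is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValidationError(f"smoothing window must be odd and positive, got {window}")
    v = _as_vector(values)
    if window == 1:
        return v.copy()
    defined = ~np.isnan(v)
    filled = np.where(defined, v, 0.0)
    kernel = np.ones(window)
    # mode="full" then center-slice: np.convolve's "same" returns max(n, window)
    # elements, which breaks for vectors shorter than the window
    lo = (window - 1) // 2
    sums = np.convolve(filled, kernel, mode="full")[lo : lo + v.shape[0]]
    counts = np.convolve(defined.astype(np.float64), kernel, mode="full")[lo : lo + v.shape[0]]
    out = np.full_like(v, np.nan)
    ok = defined & (counts > 0)
    out[ok] = sums[ok] / counts[ok]
    return out


def normalize(values, method: str = "zscore") -> np.ndarray:
    """Normalize defined entries: z-score (population sd) or min-max to [0, 1]."""
    v = _as_vector(values)
    d = v[~np.isnan(v)]
    if d.size < 2:
        raise StatisticsError("normalization needs at least 2 defined values")
    if method == "zscore":
        sd = d.std(ddof=0)
        if sd == 0.0:
            raise StatisticsError("zero variance: z-score normalization undefined")
        return (v - d.mean()) / sd
    if method == "minmax":
        lo, hi = d.min(), d.max()
        if hi == lo:
            raise StatisticsError("zero spread: min-max normalization undefined")
        return (v - lo) / (hi - lo)
    raise ValidationError(f"unknown normalization method {method!r}")


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x, y = _as_vector(x), _as_vector(y)
    if x.shape != y.shape:
        raise ValidationError(f"vector lengths differ: {x.shape[0]} vs {y.shape[0]}")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """Exact permutation p-value for Spearman rho, n <= 10."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = np.corrcoef(rx, ry)[0, 1]
    perms = np.array(list(itertools.permutations(ry)))
    rhos = np.corrcoef(np.vstack([rx, perms]))[0, 1:]
    tol = 1e-12
    if alternative == "greater":
        return float(np.mean(rhos >= obs - tol))
    if alternative == "less":
        return float(np.mean(rhos <= obs + tol))
    return float(np.mean(np.abs(rhos) >= abs(obs) - tol))


def correlation(
    x,
    y,
    method: str = "spearman",
    alternative: str = "two-sided",
    exact: bool = False,
) -> tuple[float, float, int]:
    """Correlation after pairwise deletion of masked entries.

    Spearman is Pearson on average ranks (ties averaged) with a p-value
    from the t-approximation on n-2 degrees of freedom; an exact
    permutation p-value is available for n <= 10.  Returns
    (coefficient, p_value, n_pairs).
    """
    xs, ys = _pairwise_complete(x, y)
    n = xs.size
    if n < 3:
        raise StatisticsError(f"need at least 3 jointly defined pairs, got {n}")
    if np.unique(xs).size == 1 or np.unique(ys).size == 1:
        raise StatisticsError("all-tied vector: correlation undefined")
    if method == "spearman":
        rho, p = stats.spearmanr(xs, ys, alternative=alternative)
        if exact:
            if n > 10:
                raise StatisticsError("exact permutation p-value limited to n <= 10")
            p = _exact_spearman_p(xs, ys, alternative)
    elif method == "pearson":
        res = stats.pearsonr(xs, ys, alternative=alternative)
        rho, p = res.statistic, res.pvalue
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    return float(rho), float(p), int(n)


def quartile_labels(bfactors) -> np.ndarray:
    """Label positions high / low / mid by the 25th and 75th percentiles.

    Ground truth for classification: strictly above the 75th percentile of
    the defined values -> "high", strictly below the 25th -> "low", else
    "mid".  Percentiles use linear interpolation.  Masked positions stay
    unlabeled (None).  Requires >= 8 defined values and nonzero spread.
    """
    v = _as_vector(bfactors)
    d = v[~np.isnan(v)]
    if d.size < 8:
        raise StatisticsError(f"quartile labelling needs >= 8 defined values, got {d.size}")
    if d.max() == d.min():
        raise StatisticsError("degenerate spread: all defined values equal")
    q25, q75 = np.percentile(d, [25.0, 75.0])
    labels = np.full(v.shape[0], None, dtype=object)
    for k in range(v.shape[0]):
        if np.isnan(v[k]):
            continue
        labels[k] = "high" if v[k] > q75 else ("low" if v[k] < q25 else "mid")
    return labels


def roc_pr(score, labels, target: str = "high") -> tuple[float, float, float]:
    """ROC AUC and average precision for predicting B-factor extremes.

    Evaluation is restricted to residues labeled high or low (mid and
    unlabeled excluded), which makes the chance average-precision baseline
    the positive prevalence, 0.5 for balanced quartile labels.  For
    ``target="high"`` the score is used as-is (higher frustration predicts
    higher B); for ``target="low"`` the negated score is used.  Returns
    (auc_roc, average_precision, baseline).
    """
    if target not in ("high", "low"):
        raise ValidationError(f"target must be 'high' or 'low', got {target!r}")
    s = _as_vector(score)
    lab = np.asarray(labels, dtype=object)
    if s.shape[0] != lab.shape[0]:
        raise ValidationError("score and label lengths differ")
    keep = np.array([l in ("high", "low") for l in lab]) & ~np.isnan(s)
    y = (lab[keep] == target).astype(int)
    sv = s[keep] if target == "high" else -s[keep]
    if y.size == 0 or y.min() == y.max():
        raise StatisticsError("ROC/PR needs at least one positive and one negative after restriction")
    auc = float(roc_auc_score(y, sv))
    ap = float(average_precision_score(y, sv))
    baseline = float(y.mean())
    return auc, ap, baseline


def paired_differences(rho_seq, rho_struct) -> PairedComparison:
    """Elementwise rho_seq - rho_struct across proteins, with median and mean.

    Positive values mean the sequence-based score tracks B-factor more
    strongly than the structure-based one for that protein/structure pair.
    """
    a, b = _as_vector(rho_seq), _as_vector(rho_struct)
    if a.shape != b.shape:
        raise ValidationError(f"coefficient vectors differ in length: {a.shape[0]} vs {b.shape[0]}")
    d = a - b
    return PairedComparison(differences=d, median=float(np.median(d)), mean=float(np.mean(d)))


def wilcoxon_greater(values, baseline: float) -> float:
    """One-sided Wilcoxon signed-rank p-value that values exceed a baseline.

    Zero differences are discarded; at least 5 nonzero differences are
    required.  For <= 15 nonzero differences the p-value is computed by
    exact enumeration of all sign patterns on the (tie-averaged) ranks of
    |d|; beyond that the normal approximation with tie correction is used.
    """
    d = _as_vector(values) - float(baseline)
    d = d[~np.isnan(d)]
    nz = d[d != 0.0]
    if nz.size == 0:
        raise StatisticsError("all differences are zero: signed-rank test undefined")
    if nz.size < 5:
        raise StatisticsError(f"need >= 5 nonzero differences, got {nz.size}")
    if nz.size <= 15:
        ranks = stats.rankdata(np.abs(nz))
        w_obs = ranks[nz > 0].sum()
        m = nz.size
        signs = (np.arange(2**m)[:, None] >> np.arange(m)) & 1
        w_all = signs @ ranks
        return float(np.mean(w_all >= w_obs - 1e-9))
    res = stats.wilcoxon(nz, alternative="greater", method="approx")
    return float(res.pvalue)


def benchmark_report(
    score,
    bfactors,
    method: str = "spearman",
    alternative: str = "two-sided",
    window: int = 1,
    normalization: str | None = None,
) -> dict:
    """Full evaluation of one frustration profile against one B-factor vector.

    Smoothing (default off: window 1) and normalization are applied to the
    B-factor vector for parity with plotted profiles; both are monotone or
    near-identity transforms and default to the raw signal, on which all
    statistics are computed unless opted in.  Returns a JSON-ready dict
    with the BenchmarkResult fields, masking counts, and the configuration
    used.
    """
    s = _as_vector(score)
    b = _as_vector(bfactors)
    if s.shape != b.shape:
        raise ValidationError(f"profile and B-factor lengths differ: {s.shape[0]} vs {b.shape[0]}")
    b_used = smooth(b, window)
    if normalization:
        b_used = normalize(b_used, normalization)
    # pairwise-complete everywhere: a position masked in either vector is
    # excluded from all statistics, including the quartile thresholds
    joint = ~(np.isnan(s) | np.isnan(b_used))
    s = np.where(joint, s, np.nan)
    b_used = np.where(joint, b_used, np.nan)
    rho, p, n_pairs = correlation(s, b_used, method=method, alternative=alternative)
    labels = quartile_labels(b_used)
    auc_high, ap_high, baseline_high = roc_pr(s, labels, target="high")
    _, ap_low, _ = roc_pr(s, labels, target="low")
    result = BenchmarkResult(
        rho=rho,
        p_value=p,
        n_pairs=n_pairs,
        auc_roc_high=auc_high,
        ap_high=ap_high,
        ap_low=ap_low,
        baseline_high=baseline_high,
    )
    return {
        **result.as_dict(),
        "masking": {
            "n_positions": int(s.shape[0]),
            "score_masked": int(np.isnan(s).sum()),
            "bfactor_masked": int(np.isnan(b).sum()),
        },
        "config": {
            "method": method,
            "alternative": alternative,
            "window": window,
            "normalization": normalization,
            "pr_restriction": "high-union-low quartiles (baseline = prevalence in restricted set)",
        },
    }


def plot_profiles(vectors: dict[str, np.ndarray], window: int = 5, ax=None):
    """Simple smoothed profile plot of named per-position vectors.

    Returns the matplotlib axis; masked positions appear as gaps.
    """
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    for name, vec in vectors.items():
        ax.plot(np.arange(1, len(vec) + 1), smooth(vec, window), label=name)
    ax.set_xlabel("sequence position")
    ax.set_ylabel("smoothed score")
    ax.legend()
    return ax
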