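"""Tissue-adjusted single-sample gene set scoring.

Given a tumor expression matrix X (n samples x p genes, linear-scale
normalized values), a matched normal-tissue mean profile t, and a
cross-tissue average profile t_bar, each sample is scored against each gene
set by a squared Mahalanobis-style distance with a diagonal covariance whose
per-gene variances are inflated or deflated by the tissue-specificity
fold-change t* = t / t_bar. Deviations X - t are split into nonnegative and
nonpositive parts, scored separately (up- and down-regulation) and jointly,
and calibrated against a column-permutation null via per-set gamma fits, so
that scores are gamma CDF values in [0, 1] and 1 - score is a valid p-value
under the null of uncorrelated expression.

All expression values are assumed linear-scale (TPM-like). t* is a linear
fold-change; feeding log-scale data silently changes its meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special, stats

from .gene_sets import GeneSetCollection, SetIndex, build_set_index

__all__ = [
    "TpacConfig",
    "ExpressionMatrix",
    "TissueReference",
    "DeviationPair",
    "WeightedVariances",
    "GammaFit",
    "GammaNull",
    "ScoreResult",
    "DIRECTIONS",
    "prepare_expression",
    "tissue_specificity",
    "split_deviations",
    "weighted_variances",
    "set_distances",
    "total_distances",
    "permute_columns",
    "fit_gamma_mle",
    "fit_gamma_null",
    "score_with_null",
    "bh_fdr",
    "tpac",
]

DIRECTIONS = ("total", "plus", "minus")


@dataclass(frozen=True)
class TpacConfig:
    """Run configuration.

    ``n_permutations`` defaults to 1 (a single permuted copy of X); larger
    values pool the permuted distances per set before the gamma fit, which
    stabilizes fits for small cohorts. ``clamp_lo``/``clamp_hi`` bound the
    tissue-specificity fold-change so one extreme ratio cannot dominate a
    set's distance.
    """

    seed: int = 0
    n_permutations: int = 1
    min_set_size: int = 5
    clamp_lo: float = 1e-4
    clamp_hi: float = 1e4
    min_fit_n: int = 10


@dataclass
class ExpressionMatrix:
    """n samples x p genes of nonnegative, linear-scale normalized expression."""

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D samples-by-genes matrix")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample_ids for {n} rows")
        if len(self.gene_ids) != p:
            raise ValueError(f"{len(self.gene_ids)} gene_ids for {p} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if len(set(self.gene_ids)) != p:
            raise ValueError("gene_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class TissueReference:
    """Normal-tissue mean t, cross-tissue mean t_bar, and specificity t*.

    ``no_tissue_info`` flags genes with t_bar == 0, whose t* is set to 1
    (the gene keeps its deviation signal but receives no tissue weighting).
    """

    t: np.ndarray
    t_bar: np.ndarray
    t_star: np.ndarray
    no_tissue_info: np.ndarray


@dataclass
class DeviationPair:
    """Signed split of X - t: delta_plus >= 0, delta_minus <= 0, and
    delta_plus + delta_minus == X - t exactly with disjoint support."""

    delta_plus: np.ndarray
    delta_minus: np.ndarray


@dataclass
class WeightedVariances:
    """Per-gene diagonal variances: var_plus = var * t*, var_minus = var / t*."""

    var_plus: np.ndarray
    var_minus: np.ndarray
    base: np.ndarray


@dataclass
class GammaFit:
    """Maximum-likelihood gamma fit (shape/rate parameterization) for one
    set and direction of the permutation null."""

    shape: float
    rate: float
    n_used: int
    fit_ok: bool
    message: str = ""


@dataclass
class GammaNull:
    """Per-direction, per-set gamma null parameters."""

    fits: dict[str, list[GammaFit]]
    set_names: list[str]

    def for_direction(self, direction: str) -> list[GammaFit]:
        if direction not in self.fits:
            raise KeyError(f"unknown direction {direction!r}; expected one of {DIRECTIONS}")
        return self.fits[direction]


@dataclass
class ScoreResult:
    """Scores, p-values and provenance for one run.

    S / S_plus / S_minus are n x m gamma CDF values in [0, 1]; P matrices
    are 1 - S. Columns whose gamma fit failed hold NaN.
    """

    sample_ids: list[str]
    set_names: list[str]
    S: np.ndarray
    S_plus: np.ndarray
    S_minus: np.ndarray
    P: np.ndarray
    P_plus: np.ndarray
    P_minus: np.ndarray
    gamma_null: GammaNull
    set_index: SetIndex
    config: TpacConfig
    dropped_genes: list[str] = field(default_factory=list)
    dropped_sets: list[str] = field(default_factory=list)
    no_tissue_info_genes: list[str] = field(default_factory=list)

    def scores(self, direction: str = "total") -> np.ndarray:
        return {"total": self.S, "plus": self.S_plus, "minus": self.S_minus}[direction]

    def pvalues(self, direction: str = "total") -> np.ndarray:
        return {"total": self.P, "plus": self.P_plus, "minus": self.P_minus}[direction]

    def to_frame(self, direction: str = "total", kind: str = "score") -> pd.DataFrame:
        matrix = self.scores(direction) if kind == "score" else self.pvalues(direction)
        return pd.DataFrame(matrix, index=self.sample_ids, columns=self.set_names)


def prepare_expression(values, sample_ids, gene_ids) -> tuple[ExpressionMatrix, list[str]]:
    """Validate raw expression and remove zero-variance gene columns.

    Returns the cleaned matrix (gene order otherwise preserved) and the list
    of removed gene identifiers.

    Raises
    ------
    ValueError
        On non-finite or negative values, fewer than 2 samples (variance
        undefined), or if every gene has zero variance.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expression values must be 2-D (samples x genes)")
    if values.shape[0] < 2:
        raise ValueError("at least 2 samples are required (gene variance is undefined otherwise)")
    if not np.all(np.isfinite(values)):
        raise ValueError("expression values must be finite; missing values are not supported")
    if np.any(values < 0):
        raise ValueError("expression values must be nonnegative (linear-scale normalized data)")
    # exact constancy check: summation rounding can leave a spurious ~1e-33
    # variance on an identically-valued column
    keep = values.max(axis=0) != values.min(axis=0)
    if not keep.any():
        raise ValueError("all genes have zero variance; nothing to score")
    dropped = [g for g, k in zip(gene_ids, keep) if not k]
    matrix = ExpressionMatrix(
        values=values[:, keep],
        sample_ids=list(sample_ids),
        gene_ids=[g for g, k in zip(gene_ids, keep) if k],
    )
    return matrix, dropped


def tissue_specificity(
    t, t_bar, clamp_lo: float = 1e-4, clamp_hi: float = 1e4
) -> TissueReference:
    """Compute tissue-specificity weights t* = t / t_bar (linear fold-change).

    Ratios are clamped to ``[clamp_lo, clamp_hi]``. Genes with t_bar == 0
    carry no tissue information: their t* is set to 1 and flagged.
    """
    t = np.asarray(t, dtype=float)
    t_bar = np.asarray(t_bar, dtype=float)
    if t.shape != t_bar.shape or t.ndim != 1:
        raise ValueError("t and t_bar must be 1-D arrays of equal length")
    if np.any(t < 0) or np.any(t_bar < 0):
        raise ValueError("reference profiles must be elementwise nonnegative")
    if not (0 < clamp_lo < clamp_hi):
        raise ValueError("require 0 < clamp_lo < clamp_hi")
    no_info = t_bar == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(no_info, 1.0, t / np.where(no_info, 1.0, t_bar))
    t_star = np.clip(ratio, clamp_lo, clamp_hi)
    return TissueReference(t=t, t_bar=t_bar, t_star=t_star, no_tissue_info=no_info)


def split_deviations(X, t) -> DeviationPair:
    """Split the row-wise deviations X - t into signed parts.

    delta >= 0 goes to ``delta_plus``, delta < 0 to ``delta_minus``; their
    sum reconstructs X - t exactly and their elementwise product is zero.
    """
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=float)
    if t.shape != (values.shape[1],):
        raise ValueError(
            f"reference length {t.shape} does not match the gene axis ({values.shape[1]})"
        )
    delta = values - t[np.newaxis, :]
    positive = delta >= 0
    return DeviationPair(
        delta_plus=np.where(positive, delta, 0.0),
        delta_minus=np.where(positive, 0.0, delta),
    )


def weighted_variances(X, t_star) -> WeightedVariances:
    """Tissue-weighted diagonal variances.

    The unbiased sample variance of each gene, computed on X itself, is
    multiplied by t* for the positive direction and divided by t* for the
    negative direction: genes enriched in the matched normal tissue
    (t* > 1) are down-weighted when over-expressed in the tumor and
    up-weighted when under-expressed, and vice versa.
    """
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    t_star = np.asarray(t_star, dtype=float)
    if t_star.shape != (values.shape[1],):
        raise ValueError("t_star length does not match the gene axis")
    if np.any(t_star <= 0):
        raise ValueError("t_star must be strictly positive")
    base = values.var(axis=0, ddof=1)
    if np.any(base <= 0):
        raise ValueError("zero-variance gene encountered; run prepare_expression first")
    return WeightedVariances(var_plus=base * t_star, var_minus=base / t_star, base=base)


def set_distances(dev: np.ndarray, variances: np.ndarray, index: SetIndex) -> np.ndarray:
    """Squared diagonal-covariance Mahalanobis distances per sample and set.

    With a diagonal covariance the quadratic form collapses to
    ``sum_j dev[:, j]**2 / variances[j]`` over each set's member columns.
    Returns an n x m matrix ordered by ``index.names``.
    """
    dev = np.asarray(dev, dtype=float)
    variances = np.asarray(variances, dtype=float)
    scaled = dev * dev / variances[np.newaxis, :]
    out = np.empty((dev.shape[0], len(index)), dtype=float)
    for k, name in enumerate(index.names):
        out[:, k] = scaled[:, index.indices[name]].sum(axis=1)
    return out


def total_distances(M_plus: np.ndarray, M_minus: np.ndarray) -> np.ndarray:
    """Elementwise sum of positive- and negative-direction distances."""
    M_plus = np.asarray(M_plus, dtype=float)
    M_minus = np.asarray(M_minus, dtype=float)
    if M_plus.shape != M_minus.shape:
        raise ValueError(f"shape mismatch: {M_plus.shape} vs {M_minus.shape}")
    return M_plus + M_minus


def permute_columns(X, rng, n_permutations: int = 1) -> list[np.ndarray]:
    """Independently shuffle each gene column across samples.

    Each returned matrix applies a fresh, independent permutation to every
    column, preserving per-gene value multisets while destroying inter-gene
    correlation and sample-level shifts. Deterministic given the generator
    state (an int seed is accepted).
    """
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 samples to permute")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n, p = values.shape
    out = []
    for _ in range(n_permutations):
        permuted = np.empty_like(values)
        for j in range(p):
            permuted[:, j] = values[rng.permutation(n), j]
        out.append(permuted)
    return out


def fit_gamma_mle(values, min_fit_n: int = 10) -> GammaFit:
    """Maximum-likelihood gamma fit (shape alpha, rate beta) on positive data.

    Uses the profiled likelihood: beta_hat = alpha_hat / mean, with the shape
    solving log(alpha) - digamma(alpha) = log(mean) - mean(log x) by Newton
    iteration from the method-of-moments start. Callers must pre-filter to
    strictly positive values (zeros violate the contract and raise).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size and np.any(x <= 0):
        raise ValueError("gamma fitting requires strictly positive values; filter zeros first")
    if x.size < min_fit_n:
        return GammaFit(
            shape=float("nan"), rate=float("nan"), n_used=int(x.size), fit_ok=False,
            message=f"only {x.size} positive values (< min_fit_n={min_fit_n})",
        )
    mean = x.mean()
    s = np.log(mean) - np.mean(np.log(x))  # > 0 unless x is constant (Jensen)
    if not np.isfinite(s) or s <= 0:
        return GammaFit(
            shape=float("nan"), rate=float("nan"), n_used=int(x.size), fit_ok=False,
            message="degenerate sample (zero log-dispersion); gamma MLE undefined",
        )
    var = x.var(ddof=1)
    alpha = mean * mean / var if var > 0 else 1.0  # method-of-moments start
    converged = False
    for _ in range(200):
        f = np.log(alpha) - special.digamma(alpha) - s
        fprime = 1.0 / alpha - special.polygamma(1, alpha)
        step = f / fprime
        alpha_new = alpha - step
        if alpha_new <= 0:
            alpha_new = alpha / 2.0
        if abs(alpha_new - alpha) <= 1e-12 * max(1.0, alpha):
            alpha = alpha_new
            converged = True
            break
        alpha = alpha_new
    if not converged or not np.isfinite(alpha) or alpha <= 0:
        return GammaFit(
            shape=float("nan"), rate=float("nan"), n_used=int(x.size), fit_ok=False,
            message="Newton iteration for the gamma shape did not converge",
        )
    return GammaFit(shape=float(alpha), rate=float(alpha / mean), n_used=int(x.size), fit_ok=True)


def fit_gamma_null(
    permuted_distances: dict[str, list[np.ndarray]],
    set_names: list[str],
    min_fit_n: int = 10,
) -> GammaNull:
    """Fit per-set gamma nulls for each direction.

    ``permuted_distances[direction]`` is a list (one entry per permuted copy
    of X) of n x m distance matrices; copies are pooled per set, zeros are
    discarded, and each set/direction gets its own MLE fit.
    """
    fits: dict[str, list[GammaFit]] = {}
    for direction in DIRECTIONS:
        stacked = np.vstack(permuted_distances[direction])
        per_set = []
        for k in range(len(set_names)):
            column = stacked[:, k]
            per_set.append(fit_gamma_mle(column[column > 0], min_fit_n=min_fit_n))
        fits[direction] = per_set
    return GammaNull(fits=fits, set_names=list(set_names))


def score_with_null(
    M: np.ndarray, null_params: GammaNull, direction: str
) -> tuple[np.ndarray, np.ndarray]:
    """Transform distances into gamma CDF scores and p-values.

    S[i, k] is the fitted null CDF at M[i, k]; P = 1 - S. Columns whose fit
    failed are filled with NaN rather than fabricated values.
    """
    M = np.asarray(M, dtype=float)
    fits = null_params.for_direction(direction)
    if M.shape[1] != len(fits):
        raise ValueError(f"{M.shape[1]} distance columns but {len(fits)} null fits")
    S = np.full_like(M, np.nan)
    for k, fit in enumerate(fits):
        if fit.fit_ok:
            S[:, k] = stats.gamma.cdf(M[:, k], a=fit.shape, scale=1.0 / fit.rate)
    P = 1.0 - S
    return S, P


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment over one family.

    NaN entries are excluded from the family and returned as NaN. Output has
    the input's shape; each adjusted value is >= its p-value and <= 1, and
    the adjusted values are monotone in the sorted order.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    flat = p.ravel()
    mask = ~np.isnan(flat)
    valid = flat[mask]
    if valid.size == 0:
        return out
    if np.any((valid < 0) | (valid > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = valid.size
    order = np.argsort(valid, kind="stable")
    ranked = valid[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(adjusted, 1.0)
    flat_out = out.ravel()
    flat_out[mask] = q
    return flat_out.reshape(p.shape)


def _align_reference(ref, gene_ids: list[str], label: str) -> np.ndarray:
    """Accept an array aligned to gene_ids, or a mapping/Series keyed by gene."""
    if isinstance(ref, pd.Series):
        missing = [g for g in gene_ids if g not in ref.index]
        if missing:
            raise ValueError(
                f"{label} is missing {len(missing)} expression genes (e.g. {missing[:5]})"
            )
        return ref.reindex(gene_ids).to_numpy(dtype=float)
    if isinstance(ref, dict):
        return _align_reference(pd.Series(ref), gene_ids, label)
    arr = np.asarray(ref, dtype=float)
    if arr.shape != (len(gene_ids),):
        raise ValueError(f"{label} has length {arr.shape}, expected {len(gene_ids)}")
    return arr


def tpac(
    values,
    sample_ids,
    gene_ids,
    t,
    t_bar,
    collection: GeneSetCollection,
    config: TpacConfig = TpacConfig(),
) -> ScoreResult:
    """Run the full scoring pipeline and return scores, p-values and provenance.

    Stages: zero-variance gene removal -> tissue specificity -> signed
    deviation split -> weighted variances -> per-set distances (plus, minus,
    total) -> distances on permuted copies of X -> per-set gamma MLE null
    fits (three directions) -> gamma CDF scores and p-values. Deterministic
    given ``config.seed``.

    ``t`` and ``t_bar`` may be arrays aligned with ``gene_ids`` or
    pandas Series / dicts keyed by gene identifier.
    """
    X, dropped_genes = prepare_expression(values, list(sample_ids), list(gene_ids))
    t_arr = _align_reference(t, X.gene_ids, "t")
    t_bar_arr = _align_reference(t_bar, X.gene_ids, "t_bar")

    reference = tissue_specificity(
        t_arr, t_bar_arr, clamp_lo=config.clamp_lo, clamp_hi=config.clamp_hi
    )
    index = build_set_index(collection, X.gene_ids, min_set_size=config.min_set_size)
    deviations = split_deviations(X, reference.t)
    variances = weighted_variances(X, reference.t_star)

    M_plus = set_distances(deviations.delta_plus, variances.var_plus, index)
    M_minus = set_distances(deviations.delta_minus, variances.var_minus, index)
    M = total_distances(M_plus, M_minus)

    rng = np.random.default_rng(config.seed)
    permuted = permute_columns(X, rng, n_permutations=config.n_permutations)
    null_distances: dict[str, list[np.ndarray]] = {d: [] for d in DIRECTIONS}
    for Xp in permuted:
        dev_p = split_deviations(Xp, reference.t)
        Mp_plus = set_distances(dev_p.delta_plus, variances.var_plus, index)
        Mp_minus = set_distances(dev_p.delta_minus, variances.var_minus, index)
        null_distances["plus"].append(Mp_plus)
        null_distances["minus"].append(Mp_minus)
        null_distances["total"].append(total_distances(Mp_plus, Mp_minus))

    gamma_null = fit_gamma_null(null_distances, index.names, min_fit_n=config.min_fit_n)
    S, P = score_with_null(M, gamma_null, "total")
    S_plus, P_plus = score_with_null(M_plus, gamma_null, "plus")
    S_minus, P_minus = score_with_null(M_minus, gamma_null, "minus")

    return ScoreResult(
        sample_ids=X.sample_ids,
        set_names=index.names,
        S=S,
        S_plus=S_plus,
        S_minus=S_minus,
        P=P,
        P_plus=P_plus,
        P_minus=P_minus,
        gamma_null=gamma_null,
        set_index=index,
        config=replace(config),
        dropped_genes=dropped_genes,
        dropped_sets=index.dropped,
        no_tissue_info_genes=[
            g for g, flag in zip(X.gene_ids, reference.no_tissue_info) if flag
        ],
    )
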