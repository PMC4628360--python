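"""Statistical kernel: depth normalisation, empirical-Bayes moderated t-test,
BH false-discovery control, and the auxiliary tests the analysis uses.

The moderated t-statistic shrinks each feature's sample variance toward a
prior variance ``s0_sq`` with weight ``d0`` prior degrees of freedom:

    s_tilde^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
    t_g       = (mean_treated - mean_control) / (s_tilde * sqrt(1/n1 + 1/n2))

with t_g referred to a t-distribution on d0 + d_g degrees of freedom.  The
hyperparameters are fitted by the method of moments on log sample variances
(Smyth-style): under the hierarchical model, z_g = log s_g^2 satisfies

    E[z_g]   = log s0^2 + psi(d0/2) - log(d0/2) + log(d_g/2) - psi(d_g/2)
    Var[z_g] = psi'(d_g/2) + psi'(d0/2)

so d0 is obtained by inverting the trigamma function on the excess spread of
z_g, and s0^2 from the mean.  When the observed spread does not exceed the
trigamma floor psi'(d_g/2), the variances are consistent with a single common
value and d0 = infinity (complete shrinkage) is returned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import special, stats

log = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "TestResult",
    "ModerationParams",
    "scale_normalize",
    "log_transform",
    "estimate_moderation",
    "moderated_t_test",
    "bh_fdr",
    "chisq_independence",
    "hypergeom_enrichment",
    "ranksum_compare",
]

CONTROL = "control"
TREATED = "treated"


def _check_conditions(condition: Sequence[str], min_per_group: int = 2) -> None:
    labels = set(condition)
    if labels != {CONTROL, TREATED}:
        raise ValueError(f"conditions must be {{control, treated}}, got {sorted(labels)}")
    for lab in (CONTROL, TREATED):
        n = sum(c == lab for c in condition)
        if n < min_per_group:
            raise ValueError(f"condition {lab!r} has {n} samples; >= {min_per_group} required")


@dataclass
class CountMatrix:
    """Raw per-feature tag counts with per-sample library sizes and condition labels."""

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_features, n_samples), non-negative
    library_sizes: np.ndarray  # (n_samples,), positive
    condition: list[str]  # per sample, {control, treated}

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        nf, ns = self.counts.shape
        if nf != len(self.feature_ids) or ns != len(self.sample_ids):
            raise ValueError("counts shape inconsistent with id lists")
        if len(self.library_sizes) != ns or len(self.condition) != ns:
            raise ValueError("per-sample metadata inconsistent with sample count")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.library_sizes <= 0):
            raise ValueError("library sizes must be positive")
        colsums = self.counts.sum(axis=0)
        if np.any(self.library_sizes < colsums):
            log.warning(
                "library sizes smaller than column sums for some samples; "
                "library_sizes should be total mapped tags"
            )


@dataclass
class NormalizedMatrix:
    """log2-scale normalised intensities, same layout as the count matrix."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # (n_features, n_samples), log2 scale
    condition: list[str]
    pseudocount: float
    target: float  # normalisation target in reads

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("normalised values must be finite")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")

    def subset(self, feature_ids: Sequence[str]) -> "NormalizedMatrix":
        want = set(feature_ids)
        keep = [i for i, f in enumerate(self.feature_ids) if f in want]
        return NormalizedMatrix(
            [self.feature_ids[i] for i in keep],
            list(self.sample_ids),
            self.values[keep, :],
            list(self.condition),
            self.pseudocount,
            self.target,
        )


@dataclass
class TestResult:
    """Per-feature differential test outcome."""

    __test__ = False  # not a pytest class, despite the name

    feature_id: str
    log_fc: float  # log2 treated vs control
    t_stat: float
    p_value: float
    q_value: float = math.nan
    direction: str = "ns"  # up | down | ns

    @property
    def fc(self) -> float:
        """Linear fold change, signed by convention 2**log_fc."""
        return float(2.0 ** self.log_fc)


@dataclass
class ModerationParams:
    """Empirical-Bayes prior: d0 prior degrees of freedom (may be inf), s0_sq prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("d0 must be >= 0")
        if self.s0_sq <= 0:
            raise ValueError("s0_sq must be > 0")


def scale_normalize(m: CountMatrix, target: float | None = None) -> tuple[np.ndarray, float]:
    """Rescale each sample's counts to a common effective depth.

    Each column is multiplied by ``target / library_size``.  ``target``
    defaults to the mean library size across samples, so the average sample
    is left near its raw scale.  Returns ``(scaled values, target)``.
    """
    if target is None:
        target = float(np.mean(m.library_sizes))
    if target <= 0:
        raise ValueError("normalisation target must be positive")
    factors = target / m.library_sizes
    return m.counts.astype(float) * factors[np.newaxis, :], target


def log_transform(
    scaled: np.ndarray,
    m: CountMatrix,
    pseudocount: float = 1.0,
    target: float = float("nan"),
) -> NormalizedMatrix:
    """``value -> log2(value + pseudocount)``; monotone in the input."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    scaled = np.asarray(scaled, dtype=float)
    if np.any(scaled < 0):
        raise ValueError("scaled values must be >= 0")
    return NormalizedMatrix(
        list(m.feature_ids),
        list(m.sample_ids),
        np.log2(scaled + pseudocount),
        list(m.condition),
        pseudocount,
        target,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve psi'(x) = y for x > 0 (Newton on the monotone decreasing trigamma)."""
    if y <= 0:
        return math.inf
    # Smyth's starting value; converges in a handful of iterations.
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_moderation(variances: Sequence[float], residual_df: int) -> ModerationParams:
    """Fit the variance prior (d0, s0_sq) by moments on log sample variances."""
    if residual_df < 1:
        raise ValueError("residual_df must be >= 1")
    s2 = np.asarray(variances, dtype=float)
    s2 = s2[np.isfinite(s2)]
    if s2.size == 0 or np.all(s2 == 0):
        raise ValueError(
            "all variances are zero or missing; add a pseudocount or jitter before fitting"
        )
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return ModerationParams(math.inf, float(s2[0]) if s2.size else 1.0)
    d_g = float(residual_df)
    z = np.log(s2)
    e = z - special.digamma(d_g / 2.0) + math.log(d_g / 2.0)
    mean_e = float(np.mean(e))
    var_e = float(np.var(e, ddof=1))
    excess = var_e - float(special.polygamma(1, d_g / 2.0))
    if excess <= 0:
        # spread no larger than sampling noise of s_g^2: one common variance,
        # estimated by the unbiased arithmetic mean of the sample variances
        return ModerationParams(math.inf, float(np.mean(s2)))
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s0_sq = math.exp(mean_e + special.digamma(half_d0) - math.log(half_d0))
    return ModerationParams(d0, s0_sq)


def moderated_t_test(nm: NormalizedMatrix, mod: ModerationParams) -> list[TestResult]:
    """Two-group moderated t-test per feature (treated minus control on log2 scale).

    With d0 = 0 this is the ordinary pooled two-sample t-test; with d0 = inf
    every feature shares the prior variance s0_sq.
    """
    _check_conditions(nm.condition)
    cond = np.asarray(nm.condition)
    ctrl = nm.values[:, cond == CONTROL]
    trt = nm.values[:, cond == TREATED]
    n1, n2 = ctrl.shape[1], trt.shape[1]
    d_g = n1 + n2 - 2
    log_fc = trt.mean(axis=1) - ctrl.mean(axis=1)
    # pooled within-group variance
    ss = ctrl.var(axis=1, ddof=1) * (n1 - 1) + trt.var(axis=1, ddof=1) * (n2 - 1)
    s2_g = ss / d_g
    if math.isinf(mod.d0):
        s_tilde2 = np.full_like(s2_g, mod.s0_sq)
        df_total = np.inf
    else:
        s_tilde2 = (mod.d0 * mod.s0_sq + d_g * s2_g) / (mod.d0 + d_g)
        df_total = mod.d0 + d_g
    se = np.sqrt(s_tilde2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log_fc / se
    # zero pooled variance: infinite t for a real shift, 0 for no shift
    t = np.where(se > 0, t, np.where(log_fc != 0, np.sign(log_fc) * np.inf, 0.0))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return [
        TestResult(fid, float(lfc), float(tt), float(pp))
        for fid, lfc, tt, pp in zip(nm.feature_ids, log_fc, t, p)
    ]


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def chisq_independence(table: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or np.any(obs < 0):
        raise ValueError("table must be a 2-D non-negative array")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("every row and column sum must be positive")
    stat, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    return float(stat), int(dof), float(p)


def hypergeom_enrichment(
    hits: set[str],
    universe: set[str],
    term_sets: Mapping[str, set[str]],
) -> list[dict]:
    """Upper-tail hypergeometric term enrichment with BH correction across terms.

    Returns one row per non-empty term: term, k (hits in term), K (term size in
    universe), n (number of hits), N (universe size), p, q.
    """
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    N, n = len(universe), len(hits)
    rows = []
    for term, members in term_sets.items():
        members = members & universe
        if not members:
            log.warning("term %r has no members in the universe; skipped", term)
            continue
        K = len(members)
        k = len(members & hits)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    if rows:
        qs = bh_fdr([r["p"] for r in rows])
        for r, q in zip(rows, qs):
            r["q"] = float(q)
    return rows


def ranksum_compare(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Mann-Whitney rank-sum comparison; returns (median_a, median_b, p).

    Normal approximation with tie correction (midranks), two-sided.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if a.size == 1 and b.size == 1:
        # degenerate: U in {0, 1}; the normal approximation is meaningless
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)
    return float(np.median(a)), float(np.median(b)), p
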