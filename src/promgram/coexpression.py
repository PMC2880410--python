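"""Coexpression validation: maxCC statistics, empirical null, enrichment.

Each probe's coexpression with a reference block (the histone probes) is
summarized by maxCC — the maximum centered Pearson correlation between
the probe's preprocessed tissue profile and any block member.  Observed
maxCC values are compared between probe groups by Welch's t-test, turned
into empirical p-values against a resampled random-group null, filtered
by Benjamini-Hochberg FDR, and the surviving probes are tested for
enrichment in a candidate set by an upper-tail hypergeometric test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pwm import ParameterError


@dataclass
class ExpressionMatrix:
    """Probe x array expression values with a replicate -> tissue map.

    After :func:`preprocess` there is one column per tissue, each column
    has median 0 and unit sum of squares (degenerate all-constant columns
    are left at 0 and listed in ``flagged_columns``).
    """

    values: pd.DataFrame
    replicate_map: dict[str, str] | None = None
    preprocessed: bool = False
    flagged_columns: tuple[str, ...] = ()

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def array_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class EnrichmentResult:
    """Upper-tail hypergeometric enrichment with Bonferroni correction."""

    N: int
    n: int
    K: int
    k: int
    p_value: float
    p_corrected: float


def preprocess(raw: ExpressionMatrix, log_floor: float = 1.0
               ) -> ExpressionMatrix:
    """Replicate-mean, log2, per-array median-centering, SS-normalization.

    Steps, in order: average technical replicates per tissue; log2
    transform (values below ``log_floor`` are clipped to it first);
    subtract each column's median; scale each column to unit sum of
    squares.  All-constant columns become zero vectors after centering
    and are left at 0 (flagged) rather than divided by a zero norm.
    """
    if raw.replicate_map is None:
        raise ParameterError("preprocess needs a replicate map")
    missing = set(raw.values.columns) - set(raw.replicate_map)
    if missing:
        raise ParameterError(f"arrays without a tissue assignment: {missing}")
    tissues: dict[str, list[str]] = {}
    for arr in raw.values.columns:
        tissues.setdefault(raw.replicate_map[arr], []).append(arr)
    for t, arrs in tissues.items():
        if not arrs:
            raise ParameterError(f"tissue {t} has no arrays")
    mono = pd.DataFrame(
        {t: raw.values[arrs].mean(axis=1) for t, arrs in tissues.items()}
    )
    logged = np.log2(mono.clip(lower=log_floor))
    centered = logged - logged.median(axis=0)
    norms = np.sqrt((centered ** 2).sum(axis=0))
    flagged = tuple(norms.index[norms == 0])
    safe = norms.replace(0, 1.0)
    return ExpressionMatrix(centered / safe, None, True, flagged)


def _standardize_rows(values: np.ndarray) -> np.ndarray:
    """Mean-center rows and scale to unit norm; zero-variance rows -> NaN."""
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = centered / norms
    z[np.repeat(norms == 0, values.shape[1], axis=1)] = np.nan
    return z


def max_cc(expr: ExpressionMatrix, probe: str,
           reference_set: Sequence[str]) -> float:
    """Maximum centered Pearson correlation of a probe against a block.

    The probe is excluded from its own reference comparison when it
    belongs to the set.  Zero-variance profiles yield NaN correlations;
    if every comparison is NaN the maxCC is NaN.
    """
    refs = [r for r in reference_set if r != probe]
    if not refs:
        raise ParameterError("reference set is empty after self-exclusion")
    sub = expr.values.loc[[probe] + refs].to_numpy()
    z = _standardize_rows(sub)
    ccs = z[1:] @ z[0]
    if np.all(np.isnan(ccs)):
        return float("nan")
    return float(np.nanmax(ccs))


def max_cc_all(expr: ExpressionMatrix, probes: Sequence[str],
               reference_set: Sequence[str]) -> pd.Series:
    """Vectorized maxCC for many probes against one reference block."""
    ref_z = _standardize_rows(expr.values.loc[list(reference_set)].to_numpy())
    probe_z = _standardize_rows(expr.values.loc[list(probes)].to_numpy())
    cc = probe_z @ ref_z.T                      # (n_probes, n_refs)
    ref_pos = {r: j for j, r in enumerate(reference_set)}
    for i, p in enumerate(probes):
        if p in ref_pos:
            cc[i, ref_pos[p]] = np.nan
    with np.errstate(all="ignore"):
        out = np.nanmax(cc, axis=1)
    return pd.Series(out, index=list(probes), name="maxCC")


def group_test(maxcc_predicted: Sequence[float],
               maxcc_other: Sequence[float]) -> dict:
    """Welch two-sample t-test between predicted and other maxCC values.

    The statistic is computed as (mean_other - mean_predicted) / SE, so a
    higher predicted mean yields a negative t.  Normal-approximation 95%
    confidence intervals accompany each mean.
    """
    a = np.asarray(maxcc_predicted, dtype=float)
    b = np.asarray(maxcc_other, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each group needs >= 2 finite values")
    t, p = stats.ttest_ind(b, a, equal_var=False)

    def ci(x: np.ndarray) -> tuple[float, float]:
        se = x.std(ddof=1) / math.sqrt(len(x))
        half = 1.959963984540054 * se
        return float(x.mean() - half), float(x.mean() + half)

    return {
        "mean_predicted": float(a.mean()),
        "ci_predicted": ci(a),
        "mean_other": float(b.mean()),
        "ci_other": ci(b),
        "t": float(t),
        "p_value": float(p),
        "n_predicted": len(a),
        "n_other": len(b),
    }


def empirical_null(
    expr: ExpressionMatrix,
    group_size: int = 94,
    n_groups: int = 10_000,
    seed: int | None = None,
    probes: Sequence[str] | None = None,
) -> np.ndarray:
    """Background maxCC sample from random probe groups.

    Each group draws ``group_size`` probes without replacement; all but
    one act as the reference block and the held-out probe's maxCC against
    them is recorded.  Zero-variance probes are excluded from sampling.
    """
    values = (expr.values if probes is None
              else expr.values.loc[list(probes)]).to_numpy()
    z = _standardize_rows(values)
    valid = ~np.isnan(z[:, 0])
    z = z[valid]
    if z.shape[0] < group_size:
        raise ParameterError(
            f"need >= {group_size} probes with variance, have {z.shape[0]}")
    rng = np.random.default_rng(seed)
    out = np.empty(n_groups)
    n = z.shape[0]
    for g in range(n_groups):
        idx = rng.choice(n, size=group_size, replace=False)
        test, refs = idx[-1], idx[:-1]
        out[g] = np.max(z[refs] @ z[test])
    return out


def empirical_fdr(
    observed: Sequence[float],
    background: np.ndarray,
    q: float = 0.05,
) -> pd.DataFrame:
    """Add-one empirical p-values and Benjamini-Hochberg FDR.

    p_i = (1 + #{background >= observed_i}) / (1 + |background|); the BH
    step-up runs over all finite observations; NaN observations get NaN
    p-values and never pass.
    """
    obs = np.asarray(observed, dtype=float)
    bg = np.sort(np.asarray(background, dtype=float))
    if bg.size == 0:
        raise ParameterError("empty background sample")
    n_ge = bg.size - np.searchsorted(bg, obs, side="left")
    p = (1.0 + n_ge) / (1.0 + bg.size)
    p[np.isnan(obs)] = np.nan
    finite = ~np.isnan(p)
    fdr = np.full_like(p, np.nan)
    passed = np.zeros(len(p), dtype=bool)
    if finite.any():
        rej, q_vals, _, _ = multipletests(p[finite], alpha=q,
                                          method="fdr_bh")
        fdr[finite] = q_vals
        passed[finite] = fdr[finite] <= q
    return pd.DataFrame({"maxCC": obs, "p_value": p, "fdr": fdr,
                         "pass": passed})


def hypergeometric_enrichment(N: int, n: int, K: int, k: int,
                              multiplier: int | None = None
                              ) -> EnrichmentResult:
    """Upper-tail hypergeometric test P(X >= k) with Bonferroni correction.

    X counts successes in ``n`` draws without replacement from a
    population of ``N`` containing ``K`` successes.  The tail probability
    is evaluated through log-gamma arithmetic (scipy's survival
    function), so values far below float-underflow of individual terms
    are still exact.  ``multiplier`` defaults to N.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ParameterError("require 0 <= k <= min(n, K), K <= N, n <= N")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    mult = N if multiplier is None else multiplier
    return EnrichmentResult(N=N, n=n, K=K, k=k, p_value=p,
                            p_corrected=min(1.0, p * mult))


def coexpression_analysis(
    raw: ExpressionMatrix,
    histone_probes: Sequence[str],
    predicted_probes: Sequence[str],
    group_size: int = 94,
    n_groups: int = 10_000,
    fdr_q: float = 0.05,
    seed: int | None = None,
    exclude_histone_from_other: bool = True,
) -> dict:
    """The full coexpression validation chain on one expression matrix.

    Preprocesses the matrix, computes every probe's maxCC against the
    histone block, compares predicted vs other probes by Welch's t-test,
    builds the random-group empirical null, applies BH-FDR at ``fdr_q``,
    and tests the FDR-passing probes for enrichment in the predicted set
    (population = non-histone probes, Bonferroni multiplier = its size).

    The null groups are drawn from the same non-histone population the
    p-values are assigned to, so the resampling null matches the tested
    population rather than including the reference block itself.
    """
    expr = preprocess(raw)
    histone = [p for p in histone_probes if p in expr.values.index]
    population = [p for p in expr.probe_ids if p not in set(histone)]
    maxcc = max_cc_all(expr, population, histone)
    predicted = [p for p in predicted_probes if p in maxcc.index]
    other = [p for p in population if p not in set(predicted)]
    if not exclude_histone_from_other:
        other_cc = max_cc_all(expr, histone, histone)
        maxcc_other = np.concatenate([maxcc.loc[other], other_cc])
    else:
        maxcc_other = maxcc.loc[other].to_numpy()
    ttest = group_test(maxcc.loc[predicted].to_numpy(), maxcc_other)
    background = empirical_null(expr, group_size, n_groups, seed=seed,
                                probes=population)
    fdr = empirical_fdr(maxcc.to_numpy(), background, q=fdr_q)
    fdr.index = maxcc.index
    passing = set(fdr.index[fdr["pass"]])
    enrichment = hypergeometric_enrichment(
        N=len(population), n=len(passing), K=len(predicted),
        k=len(passing & set(predicted)))
    return {"maxcc": maxcc, "ttest": ttest, "fdr": fdr,
            "background": background, "enrichment": enrichment}
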