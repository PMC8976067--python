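"""13C isotope-tracing metabolomics statistics.

Covers the tracer-metabolomics computations around glutamine labeling of
the TCA cycle: correction of measured isotopologue distributions for
naturally occurring 13C, total-ion-current normalization, fractional
contribution of a uniformly labeled tracer, the M4 (oxidative flux) versus
M5 (reductive carboxylation) readout on citrate/isocitrate and aconitate,
per-experiment differential statistics combined across experiments with
Fisher's method and Benjamini-Hochberg FDR, and rank-based metabolite set
enrichment (unweighted Kolmogorov-Smirnov running sum with label
permutation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls
from scipy.special import comb
from statsmodels.stats.multitest import multipletests

__all__ = [
    "natural_abundance_matrix",
    "convolve_natural_abundance",
    "na_correction",
    "correct_table",
    "tic_normalize",
    "fractional_contribution",
    "oxidative_reductive_readout",
    "differential_stats",
    "msea",
    "EnrichmentResult",
]

NATURAL_13C = 0.0107


def natural_abundance_matrix(n_carbons: int, p: float = NATURAL_13C) -> np.ndarray:
    """Binomial 13C natural-abundance convolution matrix.

    C[i, j] = Binom(n-j, i-j) * p^(i-j) * (1-p)^(n-i) for i >= j: the
    probability that a molecule with j tracer-derived heavy carbons is
    measured as M_i after natural 13C on the remaining n-j positions.
    Columns sum to 1 (probability conservation); C is lower-triangular and
    invertible for p < 0.5.
    """
    if not 0 <= p < 0.5:
        raise ValueError("natural abundance p must lie in [0, 0.5)")
    n = n_carbons
    i, j = np.indices((n + 1, n + 1))
    k = np.clip(i - j, 0, None)
    C = comb(n - j, k) * p**k * (1 - p) ** (n - i)
    C[i < j] = 0.0
    return C


def convolve_natural_abundance(x: np.ndarray, p: float = NATURAL_13C) -> np.ndarray:
    """Forward model: distribution observed after natural-abundance labeling."""
    x = np.asarray(x, dtype=float)
    return natural_abundance_matrix(x.size - 1, p) @ x


def na_correction(
    measured: np.ndarray, n_carbons: int, p: float = NATURAL_13C
) -> tuple[np.ndarray, float]:
    """Correct a measured isotopologue vector for natural 13C abundance.

    Solves C x = measured by nonnegative least squares and renormalizes x
    to sum to 1.  Returns (corrected distribution, residual norm).
    """
    measured = np.asarray(measured, dtype=float)
    if measured.shape != (n_carbons + 1,):
        raise ValueError("measured vector must have n_carbons + 1 entries")
    if np.any(measured < 0):
        raise ValueError("measured signals must be nonnegative")
    C = natural_abundance_matrix(n_carbons, p)
    if np.linalg.cond(C) > 1e12:
        raise ValueError("correction matrix near-singular; p too large")
    x, resid = nnls(C, measured)
    total = x.sum()
    if total <= 0:
        return np.zeros_like(x), float(resid)
    return x / total, float(resid)


def correct_table(table: pd.DataFrame, p: float = NATURAL_13C) -> pd.DataFrame:
    """Apply na_correction to every (sample, metabolite) series in a long table.

    Replaces ``signal`` with the corrected fractional distribution scaled by
    the measured total, preserving pool sizes.
    """
    out = table.copy()
    for (_, _), idx in out.groupby(["sample", "metabolite"]).groups.items():
        sub = out.loc[idx].sort_values("M")
        n = int(sub["n_carbons"].iloc[0])
        vec = sub["signal"].to_numpy()
        corrected, _ = na_correction(vec, n, p)
        out.loc[sub.index, "signal"] = corrected * vec.sum()
    return out


def tic_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize every signal to its sample's total signal.

    Idempotent up to the per-sample totals becoming 1.  Raises on samples
    with zero total signal.
    """
    out = table.copy()
    totals = out.groupby("sample")["signal"].transform("sum")
    zero = out.loc[totals <= 0, "sample"].unique()
    if zero.size:
        raise ValueError(f"zero total signal in sample(s): {', '.join(map(str, zero))}")
    out["signal"] = out["signal"] / totals
    return out


def fractional_contribution(distribution: np.ndarray, n_carbons: int) -> float:
    """Fraction of a metabolite's carbon derived from the tracer: sum(i*x_i)/n."""
    if n_carbons == 0:
        raise ValueError("fractional contribution undefined for 0 carbons")
    x = np.asarray(distribution, dtype=float)
    if x.shape != (n_carbons + 1,):
        raise ValueError("distribution must have n_carbons + 1 entries")
    return float(np.dot(np.arange(n_carbons + 1), x) / n_carbons)


def oxidative_reductive_readout(
    table: pd.DataFrame,
    conditions: tuple[str, str] = ("SP", "NSP"),
    metabolites: tuple[str, ...] = ("citrate/isocitrate", "aconitate"),
    p: float = NATURAL_13C,
    correct: bool = True,
) -> pd.DataFrame:
    """M4 vs M5 labeling readout under [U-13C]-glutamine.

    M4 reports oxidative TCA flux (alpha-ketoglutarate to succinyl-CoA,
    losing one heavy carbon); M5 reports reductive carboxylation (all five
    heavy carbons retained on citrate/isocitrate and aconitate).  Returns
    per metabolite and M in {4, 5}: replicate means per condition and the
    two-sample two-tailed t-test p-value between conditions.
    """
    if correct:
        table = correct_table(table, p)
    rows = []
    for met in metabolites:
        sub = table[table["metabolite"] == met]
        if sub.empty:
            raise ValueError(f"metabolite {met!r} missing from table")
        n = int(sub["n_carbons"].iloc[0])
        for m in (4, 5):
            if m > n:
                continue
            vals = {}
            for cond in conditions:
                cs = sub[sub["condition"] == cond]
                fracs = []
                for _, rep_df in cs.groupby("replicate"):
                    rep_df = rep_df.sort_values("M")
                    tot = rep_df["signal"].sum()
                    fracs.append(
                        float(rep_df.loc[rep_df["M"] == m, "signal"].iloc[0] / tot)
                    )
                vals[cond] = np.asarray(fracs)
            pval = _ttest(vals[conditions[0]], vals[conditions[1]])
            rows.append(
                {
                    "metabolite": met,
                    "M": m,
                    f"mean_{conditions[0]}": vals[conditions[0]].mean(),
                    f"mean_{conditions[1]}": vals[conditions[1]].mean(),
                    "p": pval,
                }
            )
    return pd.DataFrame(rows)


def _ttest(a: np.ndarray, b: np.ndarray) -> float:
    """Classic (pooled-variance) two-sample two-tailed t-test p-value.

    Degenerate zero-variance ties return p = 1.0 with a warning.
    """
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        warnings.warn("zero-variance identical groups; p set to 1.0")
        return 1.0
    res = stats.ttest_ind(a, b, equal_var=True)
    pval = float(res.pvalue)
    if not np.isfinite(pval):
        warnings.warn("degenerate t-test input; p set to 1.0")
        return 1.0
    return pval


def fisher_combine(pvalues: np.ndarray) -> float:
    """Fisher's method: X^2 = -2 sum(ln p) on 2k degrees of freedom."""
    pvalues = np.asarray(pvalues, dtype=float)
    x2 = -2.0 * np.log(np.clip(pvalues, 1e-300, 1.0)).sum()
    return float(stats.chi2.sf(x2, 2 * pvalues.size))


def differential_stats(
    tables: list[pd.DataFrame],
    conditions: tuple[str, str] = ("SP", "NSP"),
    weighting: str = "inverse_variance",
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-metabolite differential pool-size statistics across experiments.

    Each table is one independent experiment (long format with condition,
    replicate, metabolite, signal; isotopologue rows are summed into pool
    sizes).  Per experiment: TIC normalization, log2 fold change of
    condition means, and a classic two-tailed two-sample t-test.  Across
    experiments: Fisher-combined p, Benjamini-Hochberg q across
    metabolites, weighted average log2 fold change (inverse-variance or
    equal weights), and the signed log10 q used for enrichment ranking.
    """
    if weighting not in ("inverse_variance", "equal"):
        raise ValueError("weighting must be 'inverse_variance' or 'equal'")
    ca, cb = conditions
    per_exp: dict[str, list[tuple[float, float, float]]] = {}
    for tab in tables:
        t = tic_normalize(tab) if normalize else tab.copy()
        pools = (
            t.groupby(["condition", "replicate", "metabolite"], as_index=False)[
                "signal"
            ].sum()
        )
        for met, sub in pools.groupby("metabolite"):
            a = sub.loc[sub["condition"] == ca, "signal"].to_numpy()
            b = sub.loc[sub["condition"] == cb, "signal"].to_numpy()
            if a.size < 2 or b.size < 2:
                raise ValueError(
                    f"metabolite {met!r}: need >= 2 replicates per condition"
                )
            lfc = float(np.log2(a.mean() / b.mean()))
            # delta-method variance of log2(mean_a/mean_b)
            var = (
                a.var(ddof=1) / (a.size * a.mean() ** 2)
                + b.var(ddof=1) / (b.size * b.mean() ** 2)
            ) / np.log(2) ** 2
            per_exp.setdefault(met, []).append((lfc, var, _ttest(a, b)))
    rows = []
    for met, entries in sorted(per_exp.items()):
        lfcs = np.array([e[0] for e in entries])
        vars_ = np.array([e[1] for e in entries])
        ps = np.array([e[2] for e in entries])
        if weighting == "inverse_variance" and np.all(vars_ > 0):
            w = 1.0 / vars_
        else:
            w = np.ones_like(lfcs)
        rows.append(
            {
                "metabolite": met,
                "n_experiments": len(entries),
                "log2fc": float(np.average(lfcs, weights=w)),
                "p_fisher": fisher_combine(ps),
            }
        )
    result = pd.DataFrame(rows)
    result["q"] = multipletests(result["p_fisher"], method="fdr_bh")[1]
    result["signed_log10_q"] = np.sign(result["log2fc"]) * -np.log10(
        np.clip(result["q"], 1e-300, 1.0)
    )
    return result


# ---------------------------------------------------------------------------
# metabolite set enrichment


@dataclass
class EnrichmentResult:
    """Enrichment of one metabolite set against a ranked list."""

    pathway: str
    es: float
    p: float
    q: float = np.nan
    leading_edge: list[str] = field(default_factory=list)
    n_hits: int = 0


def _enrichment_score(hits: np.ndarray) -> tuple[float, int]:
    """Unweighted KS running-sum enrichment score of a boolean hit vector."""
    n = hits.size
    g = int(hits.sum())
    if g == 0 or g == n:
        raise ValueError("set must hit a strict subset of the ranked list")
    steps = np.where(hits, 1.0 / g, -1.0 / (n - g))
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), i


def _perm_scores(
    n: int, g: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null enrichment scores from random placement of g hits among n ranks."""
    out = np.empty(n_perm)
    steps = np.full(n, -1.0 / (n - g))
    for k in range(n_perm):
        s = steps.copy()
        s[rng.choice(n, size=g, replace=False)] = 1.0 / g
        run = np.cumsum(s)
        out[k] = run[np.argmax(np.abs(run))]
    return out


def msea(
    scores: pd.Series,
    pathway_sets: dict[str, list[str]],
    n_permutations: int = 1000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Metabolite set enrichment on a score-ranked metabolite list.

    Metabolites are ranked by decreasing score (ties broken by name for
    determinism); each set's unweighted KS running-sum enrichment score is
    tested by permuting metabolite labels ``n_permutations`` times; p-values
    use the add-one rule (minimum attainable 1/(n_permutations+1)) and are
    BH-corrected across sets.  Sets not intersecting the list (or swallowing
    it whole) get ES = NaN and are excluded from the correction.
    """
    # deterministic ranking: descending score, ties by metabolite name
    df = pd.DataFrame({"metabolite": scores.index, "score": scores.to_numpy()})
    if not np.all(np.isfinite(df["score"])):
        raise ValueError("ranking scores must be finite")
    df = df.sort_values(["score", "metabolite"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    order = df["metabolite"].tolist()
    index = {m: i for i, m in enumerate(order)}
    n = len(order)
    rng = np.random.default_rng(seed)
    results: list[EnrichmentResult] = []
    for name, members in pathway_sets.items():
        if len(set(members)) < 2:
            raise ValueError(f"set {name!r} has fewer than 2 members")
        hits = np.zeros(n, dtype=bool)
        for m in members:
            if m in index:
                hits[index[m]] = True
        g = int(hits.sum())
        if g == 0 or g == n:
            results.append(EnrichmentResult(name, np.nan, np.nan, n_hits=g))
            continue
        es, i_ext = _enrichment_score(hits)
        null = _perm_scores(n, g, n_permutations, rng)
        p = (1 + int(np.sum(np.abs(null) >= abs(es) - 1e-12))) / (n_permutations + 1)
        if es >= 0:
            leading = [order[k] for k in range(i_ext + 1) if hits[k]]
        else:
            leading = [order[k] for k in range(i_ext, n) if hits[k]]
        results.append(EnrichmentResult(name, es, p, leading_edge=leading, n_hits=g))
    testable = [r for r in results if np.isfinite(r.es)]
    if testable:
        qs = multipletests([r.p for r in testable], method="fdr_bh")[1]
        for r, q in zip(testable, qs):
            r.q = float(q)
    return results
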