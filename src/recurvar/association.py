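"""Exact genotype-phenotype association for recurrently mutated genes.

For each gene the cohort is cross-classified into a 2x2 table (carrier of a
retained variant vs not, against a binary clinical covariate) and tested
with Fisher's exact test. The two-sided p-value follows the
``probability <= observed`` convention (the rule used by R's ``fisher.test``):
the hypergeometric probabilities of all tables sharing the observed margins
are enumerated and those no more probable than the observed table are summed.

Two odds-ratio flavors are reported: the sample (cross-product) OR
``ad / bc``, and the conditional maximum-likelihood estimate (CMLE) — the
noncentrality parameter psi maximizing the Fisher noncentral hypergeometric
likelihood of the observed cell given the margins, the quantity
``fisher.test`` prints. Exact confidence intervals invert the one-sided
tail tests at (1 - level)/2 per tail; boundary tables give one-sided
intervals with 0 or +inf endpoints. For plotting, extreme ORs are capped
into [0.01, 100] (visualization only; raw values are preserved).

Usage follows the model/results idiom::

    model = CovariateAssociation(retained, clinical, covariate="very_early_onset")
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp

from .model import ClinicalRecord, GeneRegistry

#: relative tolerance when comparing table probabilities to the observed one,
#: so float noise cannot exclude genuinely tied tables
TIE_RELATIVE_TOLERANCE = 1e-7

OR_CAP_LOW = 0.01
OR_CAP_HIGH = 100.0


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: rows = gene mutated / not, columns = covariate 1 / 0."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in {self.cells()}")

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def row1(self) -> int:
        return self.a + self.b

    @property
    def col1(self) -> int:
        return self.a + self.c

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def degenerate(self) -> bool:
        """True when a row or column margin is zero (test uninformative)."""
        return 0 in (self.row1, self.n - self.row1, self.col1, self.n - self.col1)

    def transposed(self) -> "ContingencyTable":
        return ContingencyTable(self.b, self.a, self.d, self.c)


def _support_and_logweights(table: ContingencyTable) -> tuple[np.ndarray, np.ndarray]:
    """Support of cell ``a`` given the margins, and log C(r1,a)+C(r2,c1-a)."""
    r1, c1, n = table.row1, table.col1, table.n
    r2 = n - r1
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logw = (
        gammaln(r1 + 1) - gammaln(support + 1) - gammaln(r1 - support + 1)
        + gammaln(r2 + 1) - gammaln(c1 - support + 1) - gammaln(r2 - (c1 - support) + 1)
    )
    return support, logw


def fisher_exact_p(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p by full enumeration over the support.

    Degenerate margins give p = 1.
    """
    if table.degenerate:
        return 1.0
    support, logw = _support_and_logweights(table)
    pmf = np.exp(logw - logsumexp(logw))
    p_obs = pmf[np.searchsorted(support, table.a)]
    p = float(pmf[pmf <= p_obs * (1.0 + TIE_RELATIVE_TOLERANCE)].sum())
    return min(p, 1.0)


def sample_or(table: ContingencyTable) -> float:
    """Cross-product odds ratio ad/bc; 0 or +inf with single zero cells.

    Raises for the doubly-degenerate 0/0 pattern (zero cells on a diagonal).
    """
    num = table.a * table.d
    den = table.b * table.c
    if den == 0:
        if num == 0:
            raise ValueError(f"odds ratio undefined for table {table.cells()} (0/0)")
        return math.inf
    return num / den


def _conditional_mean(t: float, support: np.ndarray, logw: np.ndarray) -> float:
    """E[a] under the noncentral hypergeometric with log-odds parameter t."""
    logp = logw + support * t
    logp -= logsumexp(logp)
    return float(np.sum(support * np.exp(logp)))


def _upper_tail(t: float, a: int, support: np.ndarray, logw: np.ndarray) -> float:
    logp = logw + support * t
    logz = logsumexp(logp)
    return float(np.exp(logsumexp(logp[support >= a]) - logz))


def _lower_tail(t: float, a: int, support: np.ndarray, logw: np.ndarray) -> float:
    logp = logw + support * t
    logz = logsumexp(logp)
    return float(np.exp(logsumexp(logp[support <= a]) - logz))


def _solve_increasing(f: Callable[[float], float], target: float) -> float:
    """Root of f(t) = target for f increasing in t, with bracket expansion."""
    lo, hi = -1.0, 1.0
    for _ in range(200):
        if f(lo) <= target:
            break
        lo *= 2
    else:
        raise ArithmeticError("could not bracket root from below")
    for _ in range(200):
        if f(hi) >= target:
            break
        hi *= 2
    else:
        raise ArithmeticError("could not bracket root from above")
    return brentq(lambda t: f(t) - target, lo, hi, xtol=1e-12, rtol=1e-14)


def cmle_or(table: ContingencyTable, level: float = 0.95) -> tuple[float, float, float]:
    """Conditional-MLE odds ratio with the exact confidence interval.

    Returns (or_cmle, ci_low, ci_high). The estimate solves the score
    equation E_psi[a] = a_obs; the interval inverts one-sided exact tests at
    (1 - level)/2 per tail. Tables with ``a`` at the support boundary yield
    0 or +inf for the estimate and the corresponding one-sided interval.
    """
    if table.degenerate:
        raise ValueError(f"degenerate margins in {table.cells()}; CMLE undefined")
    if not (0 < level < 1):
        raise ValueError(f"level must be in (0, 1), got {level}")
    support, logw = _support_and_logweights(table)
    a = table.a
    alpha = (1.0 - level) / 2.0

    if a == support[0]:
        estimate = 0.0
    elif a == support[-1]:
        estimate = math.inf
    else:
        t_hat = _solve_increasing(lambda t: _conditional_mean(t, support, logw), float(a))
        estimate = math.exp(t_hat)

    if a == support[0]:
        ci_low = 0.0
    else:
        # P_psi(A >= a) increases with psi; lower limit where it equals alpha
        t_low = _solve_increasing(lambda t: _upper_tail(t, a, support, logw), alpha)
        ci_low = math.exp(t_low)
    if a == support[-1]:
        ci_high = math.inf
    else:
        # P_psi(A <= a) decreases with psi; upper limit where it equals alpha
        t_high = _solve_increasing(lambda t: -_lower_tail(t, a, support, logw), -alpha)
        ci_high = math.exp(t_high)
    return estimate, ci_low, ci_high


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.tolist()


def cap_or_for_plot(or_value: float) -> float:
    """Clamp an odds ratio into [0.01, 100] for log-scale plotting; zero and
    +inf map to the caps. Visualization only — raw values stay unmodified."""
    if math.isnan(or_value):
        return math.nan
    return min(max(or_value, OR_CAP_LOW), OR_CAP_HIGH)


# ---------------------------------------------------------------------------
# covariates

@dataclass(frozen=True)
class CovariateSpec:
    """Binary clinical covariate: rule maps a ClinicalRecord to 1/0, or None
    to exclude the patient from the table."""

    name: str
    rule: Callable[[ClinicalRecord], Optional[int]]


BUILTIN_COVARIATES = {
    "very_early_onset": CovariateSpec("very_early_onset", lambda r: 1 if r.onset_age <= 20 else 0),
    "female": CovariateSpec("female", lambda r: 1 if r.sex.value == "female" else 0),
    "cardiomyopathy_positive": CovariateSpec("cardiomyopathy_positive", lambda r: 1 if r.cardiomyopathy else 0),
}


def get_covariate(covariate) -> CovariateSpec:
    if isinstance(covariate, CovariateSpec):
        return covariate
    try:
        return BUILTIN_COVARIATES[covariate]
    except KeyError:
        raise ValueError(f"unknown covariate {covariate!r}; built-ins: {sorted(BUILTIN_COVARIATES)}") from None


def build_table(carriers: set, clinical: list[ClinicalRecord],
                covariate) -> ContingencyTable:
    """Cross-classify the cohort into the gene-by-covariate 2x2 table."""
    spec = get_covariate(covariate)
    a = b = c = d = 0
    for rec in clinical:
        level = spec.rule(rec)
        if level is None:
            continue
        is_carrier = rec.patient_id in carriers
        if is_carrier and level == 1:
            a += 1
        elif is_carrier:
            b += 1
        elif level == 1:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


# ---------------------------------------------------------------------------
# model / results

@dataclass
class AssociationResult:
    gene: str
    covariate: str
    table: ContingencyTable
    p_two_sided: float
    or_sample: float
    or_cmle: float
    ci_low: float
    ci_high: float
    q_bh: float = math.nan
    degenerate: bool = False

    @property
    def or_capped_for_plot(self) -> float:
        return cap_or_for_plot(self.or_cmle)


class CovariateAssociation:
    """Exact-test association model for a set of genes against one covariate.

    Parameters
    ----------
    retained : DataFrame
        Retained observations (columns ``gene`` and ``patient_id`` at least).
    clinical : list of ClinicalRecord
        The full cohort; patients without retained variants in a gene count
        as non-carriers.
    covariate : str or CovariateSpec
        Built-ins: ``very_early_onset`` (onset age <= 20), ``female``,
        ``cardiomyopathy_positive``.
    genes : sequence of str, optional
        Genes to test (typically the r.m. set); defaults to every gene with
        at least one retained observation.
    """

    def __init__(self, retained: pd.DataFrame, clinical: list[ClinicalRecord],
                 covariate, genes: Optional[Sequence[str]] = None):
        self.retained = retained
        self.clinical = list(clinical)
        self.covariate = get_covariate(covariate)
        if genes is None:
            genes = sorted(retained["gene"].unique()) if len(retained) else []
        self.genes = list(genes)
        self._carriers = {
            gene: set(grp["patient_id"])
            for gene, grp in retained.groupby("gene")
        } if len(retained) else {}

    def fit(self, level: float = 0.95) -> "AssociationResults":
        results = []
        for gene in self.genes:
            table = build_table(self._carriers.get(gene, set()), self.clinical, self.covariate)
            p = fisher_exact_p(table)
            degenerate = table.degenerate
            try:
                or_s = sample_or(table)
            except ValueError:
                or_s = math.nan
            if degenerate:
                or_c, lo, hi = math.nan, math.nan, math.nan
            else:
                or_c, lo, hi = cmle_or(table, level=level)
            results.append(AssociationResult(
                gene=gene, covariate=self.covariate.name, table=table,
                p_two_sided=p, or_sample=or_s, or_cmle=or_c,
                ci_low=lo, ci_high=hi, degenerate=degenerate,
            ))
        qs = bh_adjust([r.p_two_sided for r in results])
        for r, q in zip(results, qs):
            r.q_bh = q
        return AssociationResults(results, covariate=self.covariate.name, level=level)


class AssociationResults:
    """Fit results: per-gene exact tests with FDR and plot-ready exports."""

    def __init__(self, results: list[AssociationResult], covariate: str, level: float):
        self.results = results
        self.covariate = covariate
        self.level = level

    def frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            a, b, c, d = r.table.cells()
            rows.append({
                "gene": r.gene, "covariate": r.covariate,
                "a": a, "b": b, "c": c, "d": d,
                "p": r.p_two_sided, "q_bh": r.q_bh,
                "or_sample": r.or_sample, "or_cmle": r.or_cmle,
                "ci_low": r.ci_low, "ci_high": r.ci_high,
                "or_capped_for_plot": r.or_capped_for_plot,
                "degenerate": r.degenerate,
            })
        df = pd.DataFrame(rows, columns=["gene", "covariate", "a", "b", "c", "d", "p", "q_bh",
                                         "or_sample", "or_cmle", "ci_low", "ci_high",
                                         "or_capped_for_plot", "degenerate"])
        return df.sort_values(["p", "gene"], kind="stable").reset_index(drop=True)

    def summary(self, max_rows: int = 20) -> str:
        df = self.frame()
        lines = [
            f"Exact gene-covariate association: covariate={self.covariate}, "
            f"genes={len(df)}, CI level={self.level:.0%}",
            "=" * 78,
        ]
        show = df.head(max_rows).copy()
        for col in ("p", "q_bh", "or_sample", "or_cmle", "ci_low", "ci_high"):
            show[col] = show[col].map(lambda v: f"{v:.4g}" if pd.notna(v) else "NA")
        lines.append(show[["gene", "a", "b", "c", "d", "p", "q_bh", "or_cmle",
                           "ci_low", "ci_high"]].to_string(index=False))
        if len(df) > max_rows:
            lines.append(f"... ({len(df) - max_rows} more genes)")
        return "\n".join(lines)

    def manhattan_table(self, registry: Optional[GeneRegistry] = None,
                        gene_positions: Optional[dict] = None,
                        significance: float = 0.05) -> pd.DataFrame:
        """Per-gene (chrom, position, -log10 p) rows sorted by chromosome
        then position. Genes absent from the registry land in an ``unplaced``
        bin. ``gene_positions`` (gene -> genomic position) refines ordering;
        otherwise genes take their alphabetical rank within the chromosome.
        """
        rows = []
        for r in self.results:
            if registry is not None and r.gene in registry:
                chrom = registry.chrom_of(r.gene)
            else:
                chrom = "unplaced"
            pos = gene_positions.get(r.gene) if gene_positions else None
            rows.append({"gene": r.gene, "chrom": chrom, "position": pos,
                         "p": r.p_two_sided,
                         "neg_log10_p": -math.log10(r.p_two_sided)})
        df = pd.DataFrame(rows)
        if df.empty:
            df = pd.DataFrame(columns=["gene", "chrom", "position", "p", "neg_log10_p"])
        else:
            if df["position"].isna().any():
                ranks = df.sort_values("gene").groupby("chrom").cumcount() + 1
                df["position"] = df["position"].astype(float).fillna(ranks.astype(float))
            df["_chrom_order"] = df["chrom"].map(_chrom_sort_key)
            df = df.sort_values(["_chrom_order", "position", "gene"], kind="stable")
            df = df.drop(columns="_chrom_order").reset_index(drop=True)
        df.attrs["significance_line"] = significance
        return df

    def forest_table(self) -> pd.DataFrame:
        """Per-gene OR export with capped (log2-ready) and raw columns."""
        rows = []
        for r in self.results:
            rows.append({
                "gene": r.gene,
                "or_cmle": r.or_cmle,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "or_sample": r.or_sample,
                "or_capped_for_plot": r.or_capped_for_plot,
                "ci_low_capped": cap_or_for_plot(r.ci_low),
                "ci_high_capped": cap_or_for_plot(r.ci_high),
                "infinite_or": math.isinf(r.or_sample) or (not math.isnan(r.or_cmle) and math.isinf(r.or_cmle)),
                "label": f"{r.gene} ({r.covariate})",
            })
        columns = ["gene", "or_cmle", "ci_low", "ci_high", "or_sample",
                   "or_capped_for_plot", "ci_low_capped", "ci_high_capped",
                   "infinite_or", "label"]
        return pd.DataFrame(rows, columns=columns)


def _chrom_sort_key(chrom: str):
    base = chrom[3:] if chrom.startswith("chr") else chrom
    if base.isdigit():
        return (0, int(base), "")
    if base in ("X", "Y"):
        return (1, 23 if base == "X" else 24, "")
    return (2, 0, base)
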