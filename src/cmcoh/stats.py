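"""Structure–function inference: normality-gated correlations between
corticospinal-tract measures and CMC cells, with subgroup stratification,
Benjamini–Hochberg FDR within each 48-test family, and post hoc power.

The layer is organized statsmodels-style: :class:`CMCCorrelation` is a model
built from a cohort frame (one row per subject: covariates + 48 CMC cells);
``fit()`` returns :class:`CMCCorrelationResults` carrying the per-cell
correlation estimates, adjusted p-values, power annotations and a
``summary()`` table.  The module-level functions (:func:`stratify`,
:func:`normality_gate`, :func:`correlate`, :func:`bh_fdr`,
:func:`posthoc_power`, :func:`run_analysis`) are the primitive operations
the model composes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, asdict
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import integrate, stats as sps
from scipy.special import gammaln, hyp2f1

from .core_io import ValidationError

__all__ = [
    "CorrResult",
    "stratify",
    "normality_gate",
    "correlate",
    "bh_fdr",
    "posthoc_power",
    "CMCCorrelation",
    "CMCCorrelationResults",
    "run_analysis",
    "DEFAULT_FAMILIES",
]

logger = logging.getLogger(__name__)

#: (family label, subgroup, covariate column) for the standard analysis plan:
#: full cohort then median-split subgroups, for injury and integrity.
DEFAULT_FAMILIES: tuple[tuple[str, str | None, str], ...] = (
    ("cohort_injury", None, "cst_injury_pct"),
    ("cohort_integrity", None, "fa_cst"),
    ("mild_moderate_injury", "mild_moderate", "cst_injury_pct"),
    ("severe_injury", "severe", "cst_injury_pct"),
    ("high_integrity", "high", "fa_cst"),
    ("low_integrity", "low", "fa_cst"),
)


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def stratify(cohort: pd.DataFrame, key: str) -> dict[str, pd.DataFrame]:
    """Median-split the cohort on CST injury or integrity.

    ``key='injury'``: subjects at or below the median percent injury form
    the mild-moderate subgroup, above it the severe subgroup.
    ``key='integrity'``: subjects at or above the median FA form the
    high-integrity subgroup, below it the low-integrity subgroup.  The
    boundary conventions differ on purpose — they match how the thresholds
    are defined (≤ median injury is mild-moderate; ≥ median FA is high).
    """
    col = {"injury": "cst_injury_pct", "integrity": "fa_cst"}.get(key)
    if col is None:
        raise ValidationError(f"unknown stratification key {key!r}")
    vals = cohort[col]
    sub = cohort[vals.notna()]
    x = sub[col].to_numpy(dtype=float)
    if x.size == 0 or np.ptp(x) == 0:
        raise ValidationError(f"degenerate split: no spread in {col}")
    med = float(np.median(x))
    if key == "injury":
        return {
            "mild_moderate": sub[sub[col] <= med],
            "severe": sub[sub[col] > med],
        }
    return {
        "high": sub[sub[col] >= med],
        "low": sub[sub[col] < med],
    }


# ---------------------------------------------------------------------------
# normality gate
# ---------------------------------------------------------------------------

def normality_gate(x, alpha: float = 0.05):
    """Shapiro–Wilk gate deciding the correlation method's distributional arm.

    Returns ``(distribution, transformed)`` where distribution is
    ``"normal"`` (raw passes), ``"lognormal"`` (raw fails, log(x) passes;
    transformed = log(x)), or ``"nonnormal"`` (both fail, or log is
    infeasible because of non-positive values).
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 4:
        raise ValidationError("normality gate needs n ≥ 4")
    if np.ptp(x) == 0:
        raise ValidationError("zero-variance sample")
    if sps.shapiro(x).pvalue > alpha:
        return "normal", x
    if np.all(x > 0):
        lx = np.log(x)
        if np.ptp(lx) > 0 and sps.shapiro(lx).pvalue > alpha:
            return "lognormal", lx
    return "nonnormal", x


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrResult:
    """One covariate × CMC-cell correlation."""

    covariate: str
    cell: str
    method: str  # "pearson" | "spearman"
    estimate: float
    p: float
    n: int
    subgroup: str = "cohort"
    p_adj: float = float("nan")
    significant: bool = False
    power_exact: float = float("nan")
    power_fisher_z: float = float("nan")
    exploratory: bool = False

    def __post_init__(self) -> None:
        if np.isfinite(self.estimate) and abs(self.estimate) > 1 + 1e-12:
            raise ValidationError(f"|estimate| > 1: {self.estimate}")


@lru_cache(maxsize=8)
def _spearman_null(n: int) -> np.ndarray:
    """Exact null distribution of Spearman's ρ for untied samples of size n,
    by full enumeration of rank permutations (feasible for n ≤ 9)."""
    ranks = np.arange(1.0, n + 1)
    perms = np.array(list(itertools.permutations(range(n))))
    permuted = ranks[perms]
    rx = (ranks - ranks.mean()) / ranks.std()
    ry = (permuted - ranks.mean()) / ranks.std()
    return (rx * ry).mean(axis=1)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman ρ (midranks) with an exact permutation two-tailed p.

    Under ties the reference distribution enumerates permutations of the
    actual midrank vectors, so midrank handling is explicit.
    """
    n = x.size
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if len(set(rx)) == n and len(set(ry)) == n:
        null = _spearman_null(n)
    else:  # ties: enumerate permutations of the observed midranks
        perms = np.array(list(itertools.permutations(range(n))))
        ry_p = ry[perms]
        rxs = (rx - rx.mean()) / rx.std()
        rys = (ry_p - ry_p.mean(axis=1, keepdims=True)) / ry_p.std(axis=1, keepdims=True)
        null = (rxs * rys).mean(axis=1)
    p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    return rho, p


def correlate(
    x,
    y,
    covariate: str = "x",
    cell: str = "y",
    subgroup: str = "cohort",
    gate_alpha: float = 0.05,
    exact_spearman_max_n: int = 9,
) -> CorrResult:
    """Normality-gated correlation between two samples (pairwise-complete).

    Both samples normal (raw or after log) → Pearson r on the (possibly
    log-transformed) values with the two-tailed t-based p; otherwise
    Spearman ρ with an exact permutation p for n ≤ 9 and the t-approximation
    above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < 4:
        raise ValidationError(f"pairwise-complete n={n} < 4")
    gx, tx = normality_gate(x, alpha=gate_alpha)
    gy, ty = normality_gate(y, alpha=gate_alpha)
    if gx != "nonnormal" and gy != "nonnormal":
        r, p = sps.pearsonr(tx, ty)
        method = "pearson"
    else:
        if n <= exact_spearman_max_n:
            r, p = _spearman_exact_p(x, y)
        else:
            res = sps.spearmanr(x, y)
            r, p = float(res.statistic), float(res.pvalue)
        method = "spearman"
    return CorrResult(
        covariate=covariate,
        cell=cell,
        method=method,
        estimate=float(r),
        p=float(p),
        n=n,
        subgroup=subgroup,
    )


# ---------------------------------------------------------------------------
# Benjamini–Hochberg FDR
# ---------------------------------------------------------------------------

def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-up Benjamini–Hochberg: adjusted p-values and the rejection set.

    adjusted p_(i) = min_{j ≥ i} m·p_(j)/j (capped at 1); reject where the
    adjusted value is ≤ q.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj, adj <= q


# ---------------------------------------------------------------------------
# post hoc power
# ---------------------------------------------------------------------------

def _corr_density(r, rho, n):
    """Sampling density of the correlation coefficient of a bivariate-normal
    sample of size n with population correlation rho."""
    lognum = (
        np.log(n - 2)
        + gammaln(n - 1)
        + ((n - 1) / 2) * np.log1p(-(rho**2))
        + ((n - 4) / 2) * np.log1p(-(r**2))
    )
    logden = 0.5 * np.log(2 * np.pi) + gammaln(n - 0.5) + (n - 1.5) * np.log1p(-rho * r)
    return np.exp(lognum - logden) * hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2)


def posthoc_power(
    r_obs: float, n: int, alpha: float = 0.05, method: str = "exact"
) -> float:
    """Achieved power of the two-tailed test of zero correlation, taking the
    observed coefficient as the population value.

    ``exact`` integrates the bivariate-normal sampling density of the sample
    correlation over the rejection region |r| > r_crit (r_crit from the
    t distribution with n−2 df).  ``fisher_z`` uses the normal approximation
    on atanh(r) with standard error 1/√(n−3).
    """
    if n <= 3:
        raise ValidationError("power needs n ≥ 4")
    if abs(r_obs) >= 1:
        raise ValidationError("|r_obs| must be < 1")
    if method == "fisher_z":
        zc = sps.norm.ppf(1 - alpha / 2)
        z = np.arctanh(r_obs) * np.sqrt(n - 3)
        return float(sps.norm.cdf(z - zc) + sps.norm.cdf(-z - zc))
    if method != "exact":
        raise ValidationError(f"unknown power method {method!r}")
    tc = sps.t.ppf(1 - alpha / 2, n - 2)
    rc = tc / np.sqrt(n - 2 + tc**2)
    lo, _ = integrate.quad(_corr_density, -1, -rc, args=(r_obs, n))
    hi, _ = integrate.quad(_corr_density, rc, 1, args=(r_obs, n))
    return float(lo + hi)


# ---------------------------------------------------------------------------
# the model / results pair
# ---------------------------------------------------------------------------

class CMCCorrelation:
    """Correlation model between structural covariates and CMC cells.

    Parameters
    ----------
    cohort
        One row per subject; must contain ``cst_injury_pct`` and ``fa_cst``
        (NaN for missing FA) plus the CMC cell columns (any column named
        ``region:muscle:band``).
    families
        ``(label, subgroup, covariate)`` triples; ``subgroup`` of ``None``
        means the full cohort, otherwise a label produced by
        :func:`stratify` on the covariate's key.  FDR correction is applied
        *within* each family.
    q
        FDR level.
    min_n
        Families with fewer complete subjects are skipped with a log line.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        families=DEFAULT_FAMILIES,
        q: float = 0.05,
        min_n: int = 4,
        gate_alpha: float = 0.05,
    ) -> None:
        self.cohort = cohort.reset_index(drop=True)
        self.families = tuple(families)
        self.q = float(q)
        self.min_n = int(min_n)
        self.gate_alpha = float(gate_alpha)
        self.cells = [c for c in cohort.columns if c.count(":") == 2]
        if not self.cells:
            raise ValidationError("cohort frame has no CMC cell columns")

    @classmethod
    def from_tables(
        cls, cmc: pd.DataFrame, covariates: pd.DataFrame, **kwargs
    ) -> "CMCCorrelation":
        """Build from a tidy CMC table plus a per-subject covariate table."""
        wide = cmc.assign(
            cell=cmc["region"] + ":" + cmc["muscle"] + ":" + cmc["band"]
        ).pivot(index="subject_id", columns="cell", values="coherence")
        frame = covariates.merge(wide, on="subject_id", how="inner")
        return cls(frame, **kwargs)

    def _family_frame(self, subgroup: str | None, covariate: str) -> pd.DataFrame | None:
        if subgroup is None:
            return self.cohort
        key = "injury" if covariate == "cst_injury_pct" else "integrity"
        groups = stratify(self.cohort, key)
        return groups.get(subgroup)

    def fit(self) -> "CMCCorrelationResults":
        rows: list[CorrResult] = []
        skipped: list[str] = []
        for label, subgroup, covariate in self.families:
            frame = self._family_frame(subgroup, covariate)
            if frame is None:
                skipped.append(label)
                continue
            frame = frame[frame[covariate].notna()]
            if len(frame) < self.min_n:
                logger.warning(
                    "family %s skipped: n=%d below minimum %d",
                    label,
                    len(frame),
                    self.min_n,
                )
                skipped.append(label)
                continue
            fam: list[CorrResult] = []
            for cell in self.cells:
                try:
                    res = correlate(
                        frame[covariate],
                        frame[cell],
                        covariate=covariate,
                        cell=cell,
                        subgroup=label,
                        gate_alpha=self.gate_alpha,
                    )
                except ValidationError as exc:
                    logger.warning("family %s cell %s skipped: %s", label, cell, exc)
                    continue
                fam.append(res)
            if not fam:
                skipped.append(label)
                continue
            adj, reject = bh_fdr([r.p for r in fam], q=self.q)
            for r, a, rej in zip(fam, adj, reject):
                r.p_adj = float(a)
                r.significant = bool(rej)
                if rej:
                    r.power_exact = posthoc_power(r.estimate, r.n, method="exact")
                    r.power_fisher_z = posthoc_power(
                        r.estimate, r.n, method="fisher_z"
                    )
            rows.extend(fam)

        # exploratory behavioral correlations for significant cells (full
        # cohort, uncorrected)
        sig_cells = {r.cell for r in rows if r.significant}
        for cell in sorted(sig_cells):
            for behav in ("uefm", "arat"):
                if behav not in self.cohort.columns:
                    continue
                try:
                    res = correlate(
                        self.cohort[behav],
                        self.cohort[cell],
                        covariate=behav,
                        cell=cell,
                        subgroup="cohort",
                        gate_alpha=self.gate_alpha,
                    )
                except ValidationError:
                    continue
                res.exploratory = True
                rows.append(res)
        return CMCCorrelationResults(self, rows, skipped)


class CMCCorrelationResults:
    """Fitted correlation families with FDR and power annotations."""

    def __init__(
        self,
        model: CMCCorrelation,
        results: list[CorrResult],
        skipped_families: list[str],
    ) -> None:
        self.model = model
        self.results = results
        self.skipped_families = skipped_families

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.results])

    @property
    def significant(self) -> pd.DataFrame:
        t = self.table
        return t[t["significant"]].reset_index(drop=True)

    def summary(self) -> str:
        t = self.table
        lines = [
            "Structure-function correlation analysis",
            "=" * 55,
            f"families run: "
            f"{', '.join(sorted(set(t[~t.exploratory]['subgroup'])))}",
        ]
        if self.skipped_families:
            lines.append(f"families skipped: {', '.join(self.skipped_families)}")
        lines.append(f"FDR level q = {self.model.q}")
        sig = self.significant
        lines.append(f"tests: {len(t[~t.exploratory])}; significant after FDR: {len(sig)}")
        if len(sig):
            lines.append("")
            lines.append(
                f"{'family':<22}{'cell':<38}{'method':<10}"
                f"{'est':>7}{'p':>10}{'p_adj':>10}{'power':>7}"
            )
            lines.append("-" * 104)
            for _, r in sig.iterrows():
                lines.append(
                    f"{r.subgroup:<22}{r.cell:<38}{r.method:<10}"
                    f"{r.estimate:>7.2f}{r.p:>10.4g}{r.p_adj:>10.4g}"
                    f"{r.power_exact:>7.2f}"
                )
        expl = t[t.exploratory]
        if len(expl):
            lines.append("")
            lines.append("exploratory (uncorrected) behavioral correlations:")
            for _, r in expl.iterrows():
                lines.append(
                    f"  {r.cell} ~ {r.covariate}: {r.method} "
                    f"{r.estimate:.2f} (p = {r.p:.3g}, n = {r.n})"
                )
        return "\n".join(lines)

    def report(self) -> str:
        """Markdown report mirroring the cohort → subgroup analysis order."""
        out = ["# CMC structure-function report", ""]
        t = self.table
        for label in dict.fromkeys(t[~t.exploratory]["subgroup"]):
            fam = t[(t.subgroup == label) & (~t.exploratory)]
            sig = fam[fam.significant]
            out.append(f"## {label} (n = {int(fam['n'].max())})")
            if len(sig) == 0:
                rng = fam["estimate"].abs()
                out.append(
                    f"No associations survive FDR "
                    f"(|est| range {rng.min():.3f}-{rng.max():.2f}, "
                    f"min adjusted p = {fam['p_adj'].min():.3g})."
                )
            for _, r in sig.iterrows():
                out.append(
                    f"- **{r.cell}**: {r.method} = {r.estimate:.2f}, "
                    f"p = {r.p:.4g}, adjusted p = {r.p_adj:.4g}; post hoc power "
                    f"{r.power_exact:.2f} (exact) / {r.power_fisher_z:.2f} (Fisher z)."
                )
            out.append("")
        return "\n".join(out)


def run_analysis(
    cohort: pd.DataFrame,
    families=DEFAULT_FAMILIES,
    q: float = 0.05,
    min_n: int = 4,
    gate_alpha: float = 0.05,
) -> CMCCorrelationResults:
    """Functional entry point: fit the standard analysis plan on a cohort
    frame and return the results object."""
    return CMCCorrelation(
        cohort, families=families, q=q, min_n=min_n, gate_alpha=gate_alpha
    ).fit()
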