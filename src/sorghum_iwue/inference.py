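"""Classical inference: Pearson correlation, Tukey HSD with compact letter
displays, and the haplotype-group x treatment ANOVA.

The studentized-range CDF is computed by adaptive quadrature of its integral
definition (target accuracy ~1e-6), so no external statistical tables are
needed; Tukey-Kramer's harmonic-mean convention handles unequal group sizes.

The haplotype ANOVA compares genotype sets carrying the recurrent-parent (RP)
vs exotic (NRP) allele of one aquaporin across watering treatments. The
genotype, not the pot replicate, is the biological unit of replication for the
Population comparison: replicates of one genotype share its genotypic value,
and treating them (or even a genotype's two treatment cells) as independent is
anticonservative whenever genotypic variance is nonzero. The default analysis
therefore works on genotype-level summaries — Population is tested on
per-genotype averages across treatments (between-genotype error stratum), and
Treatment / Population x Treatment on per-genotype WS-WW differences
(within-genotype stratum), i.e. the collapsed split-plot analysis that a
random-genotype mixed model reduces to in a balanced design. A pooled
replicate-level two-way ANOVA is available via ``level="replicate"`` but warns
that it ignores genotype clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special, stats

from .schema import DataQualityWarning

__all__ = [
    "pearson",
    "CorrelationResult",
    "correlation_matrix",
    "studentized_range_cdf",
    "studentized_range_critical",
    "tukey_hsd",
    "TukeyGrouping",
    "HaplotypeAnova",
    "HaplotypeAnovaResults",
    "haplotype_anova",
]


# --------------------------------------------------------------------------
# Pearson correlation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r_squared: float
    n: int
    p: float
    slope: float
    intercept: float


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with two-sided p from the t transform.

    Missing values are removed pairwise; n >= 3 complete pairs required. A
    zero-variance series yields a missing r (degenerate, not an error).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    sx = x - x.mean()
    sy = y - y.mean()
    ssx = float(np.sum(sx**2))
    ssy = float(np.sum(sy**2))
    if ssx == 0 or ssy == 0:
        warnings.warn(
            "zero variance in a series: correlation undefined",
            DataQualityWarning,
            stacklevel=2,
        )
        return CorrelationResult(np.nan, np.nan, n, np.nan, np.nan, np.nan)
    sxy = float(np.sum(sx * sy))
    r = sxy / np.sqrt(ssx * ssy)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    slope = sxy / ssx
    intercept = float(y.mean() - slope * x.mean())
    return CorrelationResult(r, r * r, n, p, float(slope), intercept)


def correlation_matrix(means: pd.DataFrame, traits: list[str]) -> pd.DataFrame:
    """All pairwise trait correlations over genotype x treatment means."""
    rows = []
    for i, a in enumerate(traits):
        for b in traits[i + 1 :]:
            try:
                res = pearson(means[a], means[b])
            except ValueError:
                continue
            rows.append(
                {
                    "trait_x": a,
                    "trait_y": b,
                    "r": res.r,
                    "r_squared": res.r_squared,
                    "n": res.n,
                    "p": res.p,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Studentized range and Tukey HSD
# --------------------------------------------------------------------------


#: fixed high-order Gauss-Legendre rule for the (smooth) inner z-integral
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(160)


def _srange_cdf_inf(q, k: int):
    """P(Q < q) for known variance (df = inf):
    k * int phi(z) [Phi(z) - Phi(z - q)]^(k-1) dz, Gauss-Legendre over the
    effective support, vectorized over q."""
    q = np.atleast_1d(np.asarray(q, dtype=float))
    out = np.zeros_like(q)
    pos = q > 0
    if np.any(pos):
        qp = q[pos]
        lo, hi = -8.5 - qp, 8.5  # integrand negligible outside
        z = 0.5 * (hi + lo)[:, None] + 0.5 * (hi - lo)[:, None] * _GL_NODES[None, :]
        w = 0.5 * (hi - lo)[:, None] * _GL_WEIGHTS[None, :]
        f = stats.norm.pdf(z) * (stats.norm.cdf(z) - stats.norm.cdf(z - qp[:, None])) ** (
            k - 1
        )
        out[pos] = np.minimum(k * np.sum(w * f, axis=1), 1.0)
    return out if out.size > 1 else float(out[0])


@lru_cache(maxsize=4096)
def studentized_range_cdf(q: float, k: int, df: float) -> float:
    """CDF of the studentized range of k normal means with df error degrees
    of freedom, by adaptive quadrature of its integral definition."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if q <= 0:
        return 0.0
    if not np.isfinite(df):
        return _srange_cdf_inf(q, k)
    if df < 1:
        raise ValueError("df must be >= 1")
    # outer integral over s = chi_df / sqrt(df), density
    # f(s) = df^(df/2) s^(df-1) exp(-df s^2/2) / (2^(df/2-1) Gamma(df/2))
    ln_c = (
        (df / 2.0) * np.log(df)
        - (df / 2.0 - 1.0) * np.log(2.0)
        - special.gammaln(df / 2.0)
    )

    def outer(s):
        s = np.asarray(s, dtype=float)
        log_dens = ln_c + (df - 1.0) * np.log(s) - df * s * s / 2.0
        return np.exp(log_dens) * _srange_cdf_inf(q * s, k)

    hi = 1.0 + 10.0 / np.sqrt(df)
    val, _ = integrate.quad(outer, 1e-9, hi, epsabs=1e-8, limit=200)
    val2, _ = integrate.quad(
        outer, hi, hi + 20.0 / np.sqrt(df) + 1.0, epsabs=1e-8, limit=200
    )
    return min(val + val2, 1.0)


def studentized_range_sf(q: float, k: int, df: float) -> float:
    return max(1.0 - studentized_range_cdf(q, k, df), 0.0)


@lru_cache(maxsize=1024)
def studentized_range_critical(alpha: float, k: int, df: float) -> float:
    """Upper-alpha quantile q(alpha; k, df), by root-finding on the CDF."""
    target = 1.0 - alpha
    return float(
        optimize.brentq(
            lambda q: studentized_range_cdf(q, k, df) - target, 1e-3, 60.0, xtol=1e-8
        )
    )


def _compact_letter_display(names, means, significant) -> dict[str, str]:
    """Piepho-style insert-and-absorb compact letter display.

    ``significant[(i, j)]`` is True when groups i and j differ. Two groups
    share a letter iff they are not significantly different (transitively
    consistent columns).
    """
    k = len(names)
    columns = [frozenset(range(k))]  # start: one letter containing everything
    for i in range(k):
        for j in range(i + 1, k):
            if not significant[(i, j)]:
                continue
            expanded = []
            for col in columns:
                if i in col and j in col:
                    expanded.extend([col - {i}, col - {j}])
                else:
                    expanded.append(col)
            # absorb: drop columns contained in another column
            columns = []
            for col in sorted(set(expanded), key=len, reverse=True):
                if col and not any(col <= kept for kept in columns):
                    columns.append(col)
    # deterministic letter order: by descending best mean within each column
    ordered = sorted(columns, key=lambda col: (-max(means[g] for g in col), sorted(col)))
    letters = {name: "" for name in names}
    for rank, col in enumerate(ordered):
        letter = chr(ord("a") + rank)
        for g in sorted(col):
            letters[names[g]] += letter
    return letters


@dataclass
class TukeyGrouping:
    """Pairwise Tukey HSD results plus the compact letter display."""

    groups: pd.DataFrame  # group, mean, n, letters
    pairwise: pd.DataFrame  # group_a, group_b, diff, q, p, significant
    alpha: float

    def summary(self) -> str:
        return (
            f"Tukey HSD at family-wise alpha = {self.alpha:g}\n"
            + self.groups.to_string(index=False)
        )


def tukey_hsd(cell_means, cell_ns, ms_error: float, df_error: float, alpha: float = 0.05) -> TukeyGrouping:
    """Tukey honest-significant-difference comparisons with letter groups.

    Parameters
    ----------
    cell_means : mapping or Series
        Group name -> mean.
    cell_ns : mapping or Series
        Group name -> number of observations.
    ms_error, df_error : float
        Error mean square and its degrees of freedom from the ANOVA.
    alpha : float
        Family-wise error rate. Unequal n uses the Tukey-Kramer
        harmonic-mean standard error per pair.
    """
    means = pd.Series(cell_means, dtype=float)
    ns = pd.Series(cell_ns, dtype=float)
    names = list(means.index)
    k = len(names)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if df_error < 1:
        raise ValueError("df_error must be >= 1")
    if ms_error <= 0:
        raise ValueError("ms_error must be > 0")
    rows = []
    significant = {}
    for i in range(k):
        for j in range(i + 1, k):
            diff = means.iloc[i] - means.iloc[j]
            se = np.sqrt(ms_error / 2.0 * (1.0 / ns.iloc[i] + 1.0 / ns.iloc[j]))
            q = abs(diff) / se
            p = studentized_range_sf(q, k, df_error)
            sig = p < alpha
            significant[(i, j)] = sig
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "diff": float(diff),
                    "q": float(q),
                    "p": float(p),
                    "significant": sig,
                }
            )
    letters = _compact_letter_display(names, means.to_numpy(), significant)
    groups = pd.DataFrame(
        {
            "group": names,
            "mean": means.to_numpy(),
            "n": ns.to_numpy(),
            "letters": [letters[name] for name in names],
        }
    )
    return TukeyGrouping(groups=groups, pairwise=pd.DataFrame(rows), alpha=alpha)


# --------------------------------------------------------------------------
# Haplotype-group x treatment ANOVA
# --------------------------------------------------------------------------


class DesignError(ValueError):
    """The haplotype design is incomplete (e.g. a population is absent)."""


class HaplotypeAnova:
    """Population (RP/NRP) x treatment analysis for one aquaporin and trait.

    ``records`` are replicate-level rows; ``assignments`` maps genotype_id to
    an RP/NRP group per aquaporin_id. See the module docstring for why the
    default analysis operates on genotype-level summaries.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        trait: str,
        aquaporin_id: str,
        assignments: pd.DataFrame,
        level: str = "genotype",
    ):
        if level not in ("genotype", "replicate"):
            raise ValueError("level must be 'genotype' or 'replicate'")
        sub = assignments.loc[assignments["aquaporin_id"] == aquaporin_id]
        if sub.empty:
            raise DesignError(f"no assignments for aquaporin {aquaporin_id!r}")
        dup = sub.duplicated(subset=["genotype_id"])
        if dup.any():
            raise DesignError(
                f"genotypes mapped to more than one group for {aquaporin_id!r}"
            )
        data = records.merge(
            sub[["genotype_id", "group"]], on="genotype_id", how="inner"
        ).dropna(subset=[trait])
        present = set(data["group"].unique())
        for pop in ("RP", "NRP"):
            if pop not in present:
                raise DesignError(
                    f"population {pop!r} absent for aquaporin {aquaporin_id!r}"
                )
        for pop in ("RP", "NRP"):
            if data.loc[data["group"] == pop, "genotype_id"].nunique() < 2:
                raise DesignError(f"population {pop!r} has fewer than 2 genotypes")
        self.data = data
        self.trait = trait
        self.aquaporin_id = aquaporin_id
        self.level = level

    def fit(self) -> "HaplotypeAnovaResults":
        if self.level == "replicate":
            return self._fit_replicate()
        return self._fit_genotype()

    def _fit_replicate(self) -> "HaplotypeAnovaResults":
        from .quantgen import TwoWayAnova

        warnings.warn(
            "replicate-level haplotype ANOVA ignores genotype clustering and is "
            "anticonservative when genotypic variance is nonzero",
            DataQualityWarning,
            stacklevel=2,
        )
        res = TwoWayAnova(self.data, self.trait, factors=("group", "treatment")).fit()
        table = res.table.rename(
            index={
                "group": "Population",
                "treatment": "Treatment",
                "group:treatment": "Population:Treatment",
            }
        )
        cells = self.data.groupby(["group", "treatment"])[self.trait]
        return HaplotypeAnovaResults(
            model=self,
            table=table,
            cell_means=cells.mean(),
            cell_ns=cells.count().astype(float),
            ms_error=float(table.loc["residual", "mean_sq"]),
            df_error=float(table.loc["residual", "df"]),
        )

    def _fit_genotype(self) -> "HaplotypeAnovaResults":
        # genotype x treatment means, then genotype-level summaries
        gt = (
            self.data.groupby(["genotype_id", "group", "treatment"])[self.trait]
            .mean()
            .reset_index()
        )
        wide = gt.pivot_table(
            index=["genotype_id", "group"], columns="treatment", values=self.trait
        ).reset_index()
        # Population stratum: per-genotype average over available treatments
        trt_cols = [c for c in ("WW", "WS") if c in wide.columns]
        wide["avg"] = wide[trt_cols].mean(axis=1)
        pops = sorted(wide["group"].unique())
        rows = []
        # one-way ANOVA of genotype averages across populations
        y = wide["avg"].to_numpy(dtype=float)
        groups = [y[wide["group"] == p] for p in pops]
        grand = y.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
        df_b, df_w = len(pops) - 1, len(y) - len(pops)
        ms_w = ss_within / df_w if df_w > 0 else np.nan
        F_pop = (ss_between / df_b) / ms_w if df_w > 0 and ms_w > 0 else np.nan
        p_pop = float(stats.f.sf(F_pop, df_b, df_w)) if np.isfinite(F_pop) else np.nan
        rows.append(("Population", df_b, F_pop, p_pop))

        # within-genotype stratum: WS - WW differences
        if set(("WW", "WS")) <= set(wide.columns):
            diff = wide.dropna(subset=["WW", "WS"]).copy()
            diff["d"] = diff["WS"] - diff["WW"]
            d = diff["d"].to_numpy(dtype=float)
            dgroups = [d[diff["group"] == p] for p in pops]
            if all(len(g) >= 2 for g in dgroups):
                df_dw = len(d) - len(pops)
                ss_dwithin = sum(float(np.sum((g - g.mean()) ** 2)) for g in dgroups)
                ms_dw = ss_dwithin / df_dw
                # Treatment: unweighted mean of population difference-means
                est = float(np.mean([g.mean() for g in dgroups]))
                se = np.sqrt(ms_dw * sum(1.0 / len(g) for g in dgroups)) / len(pops)
                F_t = (est / se) ** 2 if se > 0 else np.nan
                p_t = float(stats.f.sf(F_t, 1, df_dw)) if np.isfinite(F_t) else np.nan
                rows.append(("Treatment", 1, F_t, p_t))
                # Interaction: population differences in d
                dgrand = d.mean()
                ss_dbetween = sum(
                    len(g) * (g.mean() - dgrand) ** 2 for g in dgroups
                )
                F_i = (ss_dbetween / df_b) / ms_dw if ms_dw > 0 else np.nan
                p_i = (
                    float(stats.f.sf(F_i, df_b, df_dw)) if np.isfinite(F_i) else np.nan
                )
                rows.append(("Population:Treatment", df_b, F_i, p_i))

        table = pd.DataFrame(rows, columns=["source", "df", "F", "p"]).set_index(
            "source"
        )
        # cell summaries over genotype x treatment means (for Tukey letters)
        cells = gt.groupby(["group", "treatment"])[self.trait]
        cell_means = cells.mean()
        cell_ns = cells.count().astype(float)
        pooled = gt.copy()
        pooled["cell_mean"] = pooled.groupby(["group", "treatment"])[
            self.trait
        ].transform("mean")
        resid = pooled[self.trait] - pooled["cell_mean"]
        df_err = len(pooled) - cell_means.size
        ms_err = float(np.sum(resid**2) / df_err) if df_err > 0 else np.nan
        return HaplotypeAnovaResults(
            model=self,
            table=table,
            cell_means=cell_means,
            cell_ns=cell_ns,
            ms_error=ms_err,
            df_error=float(df_err),
        )


@dataclass
class HaplotypeAnovaResults:
    """F tests for Population, Treatment and their interaction, plus the
    population x treatment cell summaries feeding the Tukey letters."""

    model: HaplotypeAnova
    table: pd.DataFrame
    cell_means: pd.Series
    cell_ns: pd.Series
    ms_error: float
    df_error: float

    def tukey(self, alpha: float = 0.05) -> TukeyGrouping:
        names = [f"{g}:{t}" for g, t in self.cell_means.index]
        return tukey_hsd(
            dict(zip(names, self.cell_means.to_numpy())),
            dict(zip(names, self.cell_ns.to_numpy())),
            self.ms_error,
            self.df_error,
            alpha=alpha,
        )

    def summary(self) -> str:
        return (
            f"Haplotype ANOVA: {self.model.trait} ~ Population * Treatment "
            f"({self.model.aquaporin_id}, {self.model.level}-level)\n"
            + self.table.to_string(float_format=lambda v: f"{v:.4g}")
        )


def haplotype_anova(
    records: pd.DataFrame,
    trait: str,
    aquaporin_id: str,
    assignments: pd.DataFrame,
    level: str = "genotype",
) -> HaplotypeAnovaResults:
    """Fit the Population x Treatment ANOVA (see :class:`HaplotypeAnova`)."""
    return HaplotypeAnova(records, trait, aquaporin_id, assignments, level=level).fit()
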