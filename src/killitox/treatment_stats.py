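"""Pos/Neg/NS trend calls across the ordered treatment comparisons.

Behavior endpoints are compared between treatment arms with a normal
mean-difference model under a noninformative normal-inverse-gamma reference
prior: the posterior of each arm mean is a scaled Student t, the posterior
of the difference is sampled by Monte Carlo, and a comparison is significant
when the central 95% credible interval excludes zero.  The direction of a
significant call (Pos/Neg) is taken from back-transformed treatment means:
Pos when the second treatment of the pair exceeds the first.

Gene expression trends come from per-gene negative-binomial GLMs (log link,
library-size offsets, Wald test) with Benjamini-Hochberg control of the
false discovery rate.

No multiplicity correction is applied across behavior endpoints: each is
tested at alpha = 0.05, and :func:`expected_false_positives` quantifies the
number of calls expected by chance under the global null (e.g. 0.05 x 83 =
4.15 endpoints).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("killitox")

#: The five treatment comparisons of the standard design: parental-mercury
#: effect in the reference population, PCB126 effect in each population, and
#: the two population contrasts (each pair is first-vs-second; calls are
#: signed second-minus-first).
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("SCO-Ctrl", "SCO-MeHg"),
    ("SCO-Ctrl", "SCO-PCB"),
    ("SCO-Ctrl", "NBH-Ctrl"),
    ("SCO-PCB", "NBH-PCB"),
    ("NBH-Ctrl", "NBH-PCB"),
)


@dataclass(frozen=True)
class ComparisonPlan:
    """Ordered treatment pairs to test; calls are signed second-minus-first."""

    treatments: tuple[str, ...]
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS

    def __post_init__(self) -> None:
        seen = set()
        for a, b in self.pairs:
            if a not in self.treatments or b not in self.treatments:
                raise ValueError(f"pair ({a}, {b}) references undeclared treatments")
            if (a, b) in seen:
                raise ValueError(f"duplicate pair ({a}, {b})")
            seen.add((a, b))

    @property
    def comparison_ids(self) -> list[str]:
        return [f"{a}_vs_{b}" for a, b in self.pairs]


def default_plan() -> ComparisonPlan:
    return ComparisonPlan(
        treatments=("SCO-Ctrl", "SCO-MeHg", "SCO-PCB", "NBH-Ctrl", "NBH-PCB")
    )


_TRANSFORMS = {
    "identity": (lambda x: x, lambda x: x),
    "log": (lambda x: np.log(x), lambda x: np.exp(x)),
    "logit": (special.logit, special.expit),
}


def _posterior_mean_draws(y: np.ndarray, rng: np.random.Generator, n_draws: int) -> np.ndarray:
    """Draws from the marginal posterior of the mean under the Jeffreys
    reference prior p(mu, sigma^2) ~ 1/sigma^2: t_{n-1}(ybar, s/sqrt(n))."""
    n = len(y)
    ybar = y.mean()
    s = y.std(ddof=1)
    if s == 0.0:
        return np.full(n_draws, ybar)
    return ybar + s / np.sqrt(n) * rng.standard_t(n - 1, size=n_draws)


def compare_behavior(
    values: pd.DataFrame,
    plan: ComparisonPlan,
    transform: str = "identity",
    method: str = "bayes",
    cred: float = 0.95,
    n_draws: int = 8000,
    seed: int = 0,
) -> pd.DataFrame:
    """Trend calls for every endpoint x comparison pair.

    ``values`` is long-format with columns ``endpoint``, ``treatment``,
    ``value`` (one row per larva).  Each pair needs >= 2 observations per
    arm.  ``method="bayes"`` uses the credible-interval decision;
    ``method="welch"`` is a fast frequentist fallback with the same call
    semantics (95% Welch confidence interval).

    Returns columns ``endpoint``, ``comparison``, ``estimate`` (second minus
    first on the analysis scale), ``lo``, ``hi``, ``call``.
    """
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    fwd, inv = _TRANSFORMS[transform]
    rng = np.random.default_rng(seed)
    alpha = 1.0 - cred
    rows = []
    for endpoint, df in values.groupby("endpoint", sort=True):
        for (a, b) in plan.pairs:
            ya = df.loc[df["treatment"] == a, "value"].dropna().to_numpy(dtype=float)
            yb = df.loc[df["treatment"] == b, "value"].dropna().to_numpy(dtype=float)
            if len(ya) < 2 or len(yb) < 2:
                raise ValueError(
                    f"endpoint {endpoint!r}, pair ({a}, {b}): need >= 2 observations per arm"
                )
            ta, tb = fwd(ya), fwd(yb)
            if ta.std(ddof=1) == 0.0 and tb.std(ddof=1) == 0.0 and ta.mean() == tb.mean():
                warnings.warn(
                    f"degenerate comparison for {endpoint!r} ({a} vs {b}): "
                    "zero variance in both arms with equal means; calling NS"
                )
                rows.append((endpoint, f"{a}_vs_{b}", 0.0, 0.0, 0.0, "NS"))
                continue
            if method == "bayes":
                diff = _posterior_mean_draws(tb, rng, n_draws) - _posterior_mean_draws(
                    ta, rng, n_draws
                )
                est = float(np.mean(diff))
                lo, hi = np.quantile(diff, [alpha / 2, 1 - alpha / 2])
            elif method == "welch":
                est = float(tb.mean() - ta.mean())
                se = np.sqrt(ta.var(ddof=1) / len(ta) + tb.var(ddof=1) / len(tb))
                df_w = se**4 / (
                    (ta.var(ddof=1) / len(ta)) ** 2 / (len(ta) - 1)
                    + (tb.var(ddof=1) / len(tb)) ** 2 / (len(tb) - 1)
                )
                tcrit = stats.t.ppf(1 - alpha / 2, df_w)
                lo, hi = est - tcrit * se, est + tcrit * se
            else:
                raise ValueError(f"unknown method {method!r}")
            significant = lo > 0.0 or hi < 0.0
            if significant:
                # direction from back-transformed treatment means
                call = "Pos" if inv(tb.mean()) > inv(ta.mean()) else "Neg"
            else:
                call = "NS"
            rows.append((endpoint, f"{a}_vs_{b}", est, float(lo), float(hi), call))
    return pd.DataFrame(rows, columns=["endpoint", "comparison", "estimate", "lo", "hi", "call"])


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def _size_factors(y: np.ndarray) -> np.ndarray:
    """Median-of-ratios library size factors (robust to asymmetric
    differential expression, unlike total counts).  Falls back to total-count
    factors if too few genes are expressed everywhere."""
    expressed = np.all(y > 0, axis=1)
    if expressed.sum() >= 10:
        logref = np.log(y[expressed]).mean(axis=1)
        sf = np.exp(np.median(np.log(y[expressed]) - logref[:, None], axis=0))
    else:
        tot = y.sum(axis=0)
        sf = tot / np.exp(np.mean(np.log(tot)))
    return sf / np.exp(np.mean(np.log(sf)))


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    r = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def _estimate_dispersion(y: np.ndarray, mu: np.ndarray, X: np.ndarray) -> float:
    """NB dispersion by Cox-Reid adjusted profile maximum likelihood.

    The adjustment ``-0.5 log det(X' W X)`` (W the NB working weights)
    compensates for the fitted mean parameters; without it the plug-in MLE
    is biased low and downstream Wald tests are anticonservative."""

    def neg_apl(la: float) -> float:
        alpha = np.exp(la)
        w = mu / (1.0 + alpha * mu)
        xtwx = X.T @ (w[:, None] * X)
        sign, logdet = np.linalg.slogdet(xtwx)
        if sign <= 0:
            return np.inf
        return -(_nb_loglik(y, mu, alpha) - 0.5 * logdet)

    res = optimize.minimize_scalar(neg_apl, bounds=(-12.0, 5.0), method="bounded")
    return float(np.exp(res.x))


def de_test(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    fdr: float = 0.05,
    min_count_mean: float = 1.0,
    reference: str | None = None,
) -> pd.DataFrame:
    """Per-gene negative-binomial differential expression between two groups.

    Fits, per gene, an NB GLM with log link and log library-size offsets,
    dispersion estimated by profile maximum likelihood, and a Wald test of
    the group coefficient.  P-values are Benjamini-Hochberg adjusted; a gene
    is called Pos/Neg by the sign of its log2 fold-change at ``q < fdr``,
    otherwise NS.  Genes with mean count below ``min_count_mean`` (including
    all-zero genes) are excluded from testing and reported with
    ``filtered=True``.

    ``design`` needs columns ``sample`` and ``treatment`` with exactly two
    levels; ``reference`` names the first (denominator) level, defaulting to
    the lexicographically first.
    """
    design = design.set_index("sample").loc[list(counts.columns)]
    levels = sorted(design["treatment"].unique())
    if len(levels) != 2:
        raise ValueError("de_test needs exactly two treatment levels")
    if reference is None:
        reference = levels[0]
    other = [l for l in levels if l != reference][0]
    group = (design["treatment"] == other).to_numpy(dtype=float)
    if group.sum() < 2 or (1 - group).sum() < 2:
        raise ValueError("need >= 2 samples per group")

    y_all = counts.to_numpy(dtype=float)
    if not np.allclose(y_all, np.round(y_all)):
        raise ValueError("counts must be integers")
    offset = np.log(_size_factors(y_all))
    X = sm.add_constant(group)

    keep = y_all.mean(axis=1) >= min_count_mean
    n_filtered = int((~keep).sum())
    if n_filtered:
        logger.info("de_test: %d genes below the minimum-count filter", n_filtered)

    log2fc = np.full(len(counts), np.nan)
    pvals = np.full(len(counts), np.nan)
    for i in np.where(keep)[0]:
        y = y_all[i]
        try:
            pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
            alpha = _estimate_dispersion(y, pois.fittedvalues, X)
            fit = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
            ).fit()
            beta = fit.params[1]
            se = fit.bse[1]
            log2fc[i] = beta / np.log(2.0)
            # t reference with residual df: the Wald z is anticonservative at
            # small n because both the coefficient SE and alpha are estimated
            pvals[i] = 2.0 * stats.t.sf(abs(beta / se), df=len(y) - X.shape[1])
        except Exception as exc:  # singular fits on degenerate genes
            logger.debug("de_test: gene %s failed to fit (%s)", counts.index[i], exc)

    qvals = bh_adjust(pvals)
    call = np.where(
        (qvals < fdr) & (log2fc > 0), "Pos", np.where((qvals < fdr) & (log2fc < 0), "Neg", "NS")
    )
    call = np.where(np.isnan(qvals), "NS", call)
    out = pd.DataFrame(
        {
            "gene": counts.index,
            "comparison": f"{reference}_vs_{other}",
            "log2_fold_change": log2fc,
            "p_value": pvals,
            "q_value": qvals,
            "call": call,
            "filtered": ~keep,
        }
    )
    return out


def bh_adjust(p) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted q-values.

    NaN entries propagate as NaN and are excluded from the number of tests.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if mask.sum() == 0:
        return q
    _, q_sub, _, _ = multipletests(p[mask], method="fdr_bh")
    q[mask] = q_sub
    return q


def expected_false_positives(alpha: float, m: int) -> float:
    """Expected number of chance significances among ``m`` independent tests
    at per-test level ``alpha`` under the global null: ``alpha * m``
    (e.g. 0.05 x 83 = 4.15)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha * m


# ---------------------------------------------------------------------------
# Gene-set over-representation
# ---------------------------------------------------------------------------

def read_gmt(path: str) -> dict[str, tuple[str, list[str]]]:
    """GMT gene-set file: tab-separated ``name, description, member...`` per
    line.  Returns name -> (description, members).  The description field is
    kept as the set's functional-category label (installed GMT readers drop
    it, which is why this reader exists)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = (parts[1], [g for g in parts[2:] if g])
    return sets


def gene_set_test(
    calls: pd.DataFrame,
    gene_sets: dict[str, tuple[str, list[str]]],
    universe: list[str] | None = None,
) -> pd.DataFrame:
    """Direction-aware hypergeometric over-representation.

    For each set and each direction (Pos, Neg separately), tests whether the
    genes called in that direction are over-represented in the set relative
    to the universe (default: all genes in ``calls``).  P-values are BH
    adjusted across sets within a direction.
    """
    if universe is None:
        universe = list(calls["gene"])
    uni = set(universe)
    M = len(uni)
    rows = []
    for direction in ("Pos", "Neg"):
        hits = set(calls.loc[calls["call"] == direction, "gene"]) & uni
        n_hits = len(hits)
        p_list, meta = [], []
        for name, (category, members) in gene_sets.items():
            mem = set(members) & uni
            if not mem:
                logger.info("gene_set_test: set %r empty after universe intersection", name)
                continue
            k = len(hits & mem)
            # P(X >= k) for X ~ Hypergeom(M, n_hits, |set|)
            p = float(stats.hypergeom.sf(k - 1, M, n_hits, len(mem)))
            p_list.append(p)
            meta.append((name, category, direction, len(mem), k, p))
        q = bh_adjust(p_list)
        for (name, category, direction_, sz, k, p), qv in zip(meta, q):
            rows.append((name, category, direction_, sz, k, p, qv))
    return pd.DataFrame(
        rows,
        columns=["set", "category", "direction", "set_size", "n_hits_in_set", "p_value", "q_value"],
    )
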