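"""Likelihood-ratio tests, Bonferroni correction, candidate classification.

The three nested pairs are compared with chi-square LRTs:

=============  ====================  ==
test           null vs alternative   df
=============  ====================  ==
branch         M0 vs two-ratios      1
site           M1a vs M2a            2
branch-site    model A null vs A     1
=============  ====================  ==

The branch-site null fixes omega2 on the boundary, where the LRT null
distribution is formally a 50:50 mix of chi2_0 and chi2_1; the plain
chi2_1 reference used here is the conservative choice.  A gene is a
candidate when the LRT p-value clears the (possibly Bonferroni-corrected)
significance level and, for branch and branch-site tests, the foreground
dN/dS exceeds one.  Positively selected codon positions are reported only
when the LRT is significant, at posterior probability > 0.9 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.stats import chi2

from .models import BRANCH_MODELS, SITE_CLASS_MODELS, FitResult


@dataclass
class TestOutcome:
    """Result of one gene x clade hypothesis test."""

    gene_id: str
    clade_id: int | None
    test: str  # branch | site | branch-site | custom
    lnL_null: float
    lnL_alt: float
    statistic: float
    df: int
    p_value: float
    alpha_used: float
    candidate: bool
    omega_foreground: float | None = None
    omega_background: float | None = None
    positive_sites: list[tuple[int, float]] = field(default_factory=list)


def lrt(lnL_null: float, lnL_alt: float, df: int) -> tuple[float, float]:
    """Chi-square likelihood-ratio test of nested fits.

    The statistic ``2 (lnL_alt - lnL_null)`` is clamped at zero (optimizer
    jitter can leave the alternative marginally below the null), giving
    p = 1 in that case.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    statistic = max(0.0, 2.0 * (lnL_alt - lnL_null))
    p_value = float(chi2.sf(statistic, df))
    return statistic, p_value


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected significance level alpha / n_tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def classify(
    gene_id: str,
    clade_id: int | None,
    test: str,
    fit_null: FitResult,
    fit_alt: FitResult,
    df: int,
    alpha_used: float = 0.05,
    site_threshold: float = 0.9,
    positive_site_probs=None,
) -> TestOutcome:
    """Assemble the test outcome and apply the candidate rules.

    ``positive_site_probs`` is the per-site posterior mass on positively
    selected classes from the alternative fit; sites above the threshold
    are attached (1-based alignment coordinates) only when the LRT is
    significant and the model has site classes.
    """
    statistic, p_value = lrt(fit_null.lnL, fit_alt.lnL, df)
    significant = p_value < alpha_used
    candidate = significant
    if fit_alt.model_id in BRANCH_MODELS:
        candidate = candidate and (
            fit_alt.omega_foreground is not None and fit_alt.omega_foreground > 1.0
        )
    positive_sites: list[tuple[int, float]] = []
    if (
        significant
        and fit_alt.model_id in SITE_CLASS_MODELS
        and positive_site_probs is not None
    ):
        positive_sites = [
            (i + 1, float(p))
            for i, p in enumerate(positive_site_probs)
            if p > site_threshold
        ]
    return TestOutcome(
        gene_id=gene_id,
        clade_id=clade_id,
        test=test,
        lnL_null=fit_null.lnL,
        lnL_alt=fit_alt.lnL,
        statistic=statistic,
        df=df,
        p_value=p_value,
        alpha_used=alpha_used,
        candidate=candidate,
        omega_foreground=fit_alt.omega_foreground,
        omega_background=fit_alt.omega_background,
        positive_sites=positive_sites,
    )
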