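"""Site-class mixtures for the nested codon models.

Six model configurations are supported, forming three nested test pairs:

* branch test: ``M0`` (one ratio) vs ``two_ratios`` (background/foreground);
* site test: ``M1a`` (nearly neutral) vs ``M2a`` (positive selection);
* branch-site test: ``MA_null`` (omega2 fixed at 1) vs ``MA`` (model A).

Each site class carries a proportion and a pair of dN/dS ratios — one for
background branches, one for foreground (marked) branches.  In model A the
proportions of the two selected classes 2a/2b are not free: they split the
remaining mass ``1 - p0 - p1`` in the ratio ``p0 : p1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MODEL_IDS = ("M0", "two_ratios", "M1a", "M2a", "MA_null", "MA")

#: Models whose alternative hypothesis distinguishes foreground branches.
BRANCH_MODELS = frozenset({"two_ratios", "MA", "MA_null"})
#: Models with more than one site class (posteriors are defined).
SITE_CLASS_MODELS = frozenset({"M1a", "M2a", "MA_null", "MA"})

#: Null/alternative pairs with their LRT degrees of freedom.
TEST_PAIRS = {
    "branch": ("M0", "two_ratios", 1),
    "site": ("M1a", "M2a", 2),
    "branch-site": ("MA_null", "MA", 1),
}


@dataclass(frozen=True)
class SiteClass:
    proportion: float
    omega_background: float
    omega_foreground: float


@dataclass(frozen=True)
class SiteClassMix:
    model_id: str
    classes: tuple[SiteClass, ...]

    def __post_init__(self):
        total = sum(c.proportion for c in self.classes)
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ValueError(f"class proportions sum to {total}, not 1")
        if any(not 0 <= c.proportion <= 1 for c in self.classes):
            raise ValueError("class proportion outside [0, 1]")

    @property
    def proportions(self) -> np.ndarray:
        return np.array([c.proportion for c in self.classes])

    @property
    def positive_classes(self) -> list[int]:
        """Indices of classes with foreground omega > 1 (selected classes)."""
        return [
            k for k, c in enumerate(self.classes) if c.omega_foreground > 1.0
        ]

    # ------------------------------------------------------------------
    @staticmethod
    def m0(omega: float) -> "SiteClassMix":
        return SiteClassMix("M0", (SiteClass(1.0, omega, omega),))

    @staticmethod
    def two_ratios(omega_background: float, omega_foreground: float) -> "SiteClassMix":
        return SiteClassMix(
            "two_ratios", (SiteClass(1.0, omega_background, omega_foreground),)
        )

    @staticmethod
    def m1a(p0: float, omega0: float) -> "SiteClassMix":
        return SiteClassMix(
            "M1a",
            (SiteClass(p0, omega0, omega0), SiteClass(1.0 - p0, 1.0, 1.0)),
        )

    @staticmethod
    def m2a(p0: float, p1: float, omega0: float, omega2: float) -> "SiteClassMix":
        return SiteClassMix(
            "M2a",
            (
                SiteClass(p0, omega0, omega0),
                SiteClass(p1, 1.0, 1.0),
                SiteClass(1.0 - p0 - p1, omega2, omega2),
            ),
        )

    @staticmethod
    def model_a(
        p0: float, p1: float, omega0: float, omega2: float, null: bool = False
    ) -> "SiteClassMix":
        if null:
            omega2 = 1.0
        rest = 1.0 - p0 - p1
        p2a = rest * p0 / (p0 + p1)
        p2b = rest * p1 / (p0 + p1)
        return SiteClassMix(
            "MA_null" if null else "MA",
            (
                SiteClass(p0, omega0, omega0),
                SiteClass(p1, 1.0, 1.0),
                SiteClass(p2a, omega0, omega2),
                SiteClass(p2b, 1.0, omega2),
            ),
        )


@dataclass
class CodonModelParams:
    """Full parameterization of one fitted (or simulated) model."""

    model_id: str
    kappa: float
    pi: np.ndarray
    mix: SiteClassMix
    branch_lengths: np.ndarray | None = None  # engine edge order

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-8) or (self.pi < 0).any():
            raise ValueError("pi must be a probability vector")


@dataclass
class FitResult:
    """Maximum-likelihood fit of one model to one gene."""

    model_id: str
    lnL: float
    params: CodonModelParams
    omega_foreground: float | None = None
    omega_background: float | None = None
    site_posteriors: np.ndarray | None = None  # (n_sites, n_classes)
    converged: bool = True
    at_boundary: dict = field(default_factory=dict)
    n_starts: int = 1

    @property
    def mix(self) -> SiteClassMix:
        return self.params.mix
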