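"""ACMG/AMP evidence combination: Bayesian posterior of pathogenicity.

Assigned ACMG/AMP criteria (PVS1, PS1-4, PM1-6, PP1-5, BA1, BS1-4, BP1-7)
are tallied by strength class and combined into a single odds of
pathogenicity by exponentiating the very-strong odds with a weighted sum of
the counts (the Tavtigian naive-Bayes reading of the guidelines):

    OddsPath = O_PVS ** (NPP/8 + NPM/4 + NPS/2 + NPVS/1 - NBP/8 - NBS/2)
    Post_P   = OddsPath * Prior_P / ((OddsPath - 1) * Prior_P + 1)

with Prior_P = 0.1 and O_PVS = 350 by default.  The posterior maps to the
five-tier classification (P / LP / VUS / LB / B); the stand-alone benign
criterion BA1 forces tier B regardless of the posterior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "ACMG_CRITERIA",
    "CriteriaAssignment",
    "BayesParams",
    "odds_path",
    "posterior",
    "classify_tier",
]

#: The 28 ACMG/AMP evidence codes.
ACMG_CRITERIA: frozenset[str] = frozenset(
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
    + ["BA1"]
    + [f"BS{i}" for i in range(1, 5)]
    + [f"BP{i}" for i in range(1, 8)]
)

# Strength classes ordered by code prefix (longest prefix wins).
_STRENGTH_PREFIXES = ("PVS", "PS", "PM", "PP", "BA", "BS", "BP")


def strength_class(code: str) -> str:
    """Return the default strength class encoded in a criterion code prefix."""
    for prefix in _STRENGTH_PREFIXES:
        if code.startswith(prefix):
            return prefix
    raise ValueError(f"not an ACMG criterion code: {code!r}")


@dataclass(frozen=True)
class CriteriaAssignment:
    """Counts of assigned ACMG criteria per strength category.

    ``ba1`` flags the stand-alone benign criterion, which does not enter the
    odds exponent; variants carrying it are excluded outright by the
    candidate filter and force-classified benign.
    """

    npvs: int = 0
    nps: int = 0
    npm: int = 0
    npp: int = 0
    nbs: int = 0
    nbp: int = 0
    ba1: bool = False
    codes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        for name in ("npvs", "nps", "npm", "npp", "nbs", "nbp"):
            if getattr(self, name) < 0:
                raise ValueError(f"criteria count {name} must be non-negative")

    @classmethod
    def from_codes(
        cls,
        codes: Iterable[str],
        strength_overrides: Mapping[str, str] | None = None,
    ) -> "CriteriaAssignment":
        """Tally criterion codes into strength-class counts.

        ``strength_overrides`` maps a code to a non-default strength class
        (e.g. ``{"PP3": "PS"}`` to apply PP3 at strong level), mirroring
        annotation pipelines that up- or down-weigh individual criteria.
        """
        codes = tuple(codes)
        counts = {p: 0 for p in _STRENGTH_PREFIXES}
        for code in codes:
            if code not in ACMG_CRITERIA:
                raise ValueError(f"unknown ACMG criterion code: {code!r}")
            cls_ = strength_class(code)
            if strength_overrides and code in strength_overrides:
                cls_ = strength_overrides[code]
                if cls_ not in _STRENGTH_PREFIXES:
                    raise ValueError(f"unknown strength class override: {cls_!r}")
            counts[cls_] += 1
        return cls(
            npvs=counts["PVS"],
            nps=counts["PS"],
            npm=counts["PM"],
            npp=counts["PP"],
            nbs=counts["BS"],
            nbp=counts["BP"],
            ba1=counts["BA"] > 0,
            codes=codes,
        )

    @property
    def exponent(self) -> float:
        """Signed exponent applied to the very-strong odds."""
        return (
            self.npp / 8.0
            + self.npm / 4.0
            + self.nps / 2.0
            + self.npvs / 1.0
            - self.nbp / 8.0
            - self.nbs / 2.0
        )


@dataclass(frozen=True)
class BayesParams:
    """Prior probability of pathogenicity and odds for very-strong evidence."""

    prior: float = 0.1
    odds_pvs: float = 350.0

    def __post_init__(self) -> None:
        if not 0.0 < self.prior < 1.0:
            raise ValueError("prior must lie in (0, 1)")
        if self.odds_pvs <= 1.0:
            raise ValueError("odds_pvs must exceed 1")


def odds_path(criteria: CriteriaAssignment, params: BayesParams = BayesParams()) -> float:
    """Combined odds of pathogenicity for an assignment of criteria."""
    return params.odds_pvs ** criteria.exponent


def posterior(criteria: CriteriaAssignment, params: BayesParams = BayesParams()) -> float:
    """Posterior probability of pathogenicity.

    Evaluated in log-odds space so that extreme criteria stacks neither
    overflow nor collapse to exactly 0 or 1.
    """
    if criteria.exponent == 0:
        # OddsPath = 1: the posterior collapses to the prior exactly
        return params.prior
    # log-odds form of Post_P = O*p / ((O-1)*p + 1) with O = odds_pvs**exponent
    log_odds = criteria.exponent * math.log(params.odds_pvs) + math.log(
        params.prior / (1.0 - params.prior)
    )
    if log_odds >= 0:
        return 1.0 / (1.0 + math.exp(-log_odds))
    e = math.exp(log_odds)
    return e / (1.0 + e)


@dataclass(frozen=True)
class TierThresholds:
    """Posterior cut-points of the five-tier classification."""

    pathogenic: float = 0.99
    likely_pathogenic: float = 0.90
    likely_benign: float = 0.10
    benign: float = 0.001


def classify_tier(
    post: float,
    ba1: bool = False,
    thresholds: TierThresholds = TierThresholds(),
) -> str:
    """Map a posterior to {P, LP, VUS, LB, B}; BA1 forces B."""
    if not 0.0 < post < 1.0:
        raise ValueError("posterior must lie in (0, 1)")
    if ba1:
        return "B"
    if post > thresholds.pathogenic:
        return "P"
    if post > thresholds.likely_pathogenic:
        return "LP"
    if post < thresholds.benign:
        return "B"
    if post < thresholds.likely_benign:
        return "LB"
    return "VUS"
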