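"""Tank-level lab exposure outcomes and the lethal-threshold derivation.

Northern shrimp were exposed in replicate tanks to short pulses of
deltamethrin at four doses (a clean-seawater control and three dilutions of
the treatment dose).  This module pools the tank counts per treatment,
compares each dose against the control with a two-sided exact test on the
pooled dead/alive 2x2 table, and derives the lethal-effect threshold as the
lowest dose with a significant positive excess mortality.

The exact test enumerates the full hypergeometric distribution of tables
with the observed margins (Fisher's exact test, two-sided by summing all
tables no more probable than the observed one).  Because the unit of
analysis (shrimp vs tank) is debatable, a tank-label randomization test on
the difference in pooled mortality is provided as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "ExposureOutcome",
    "TreatmentComparison",
    "mortality_proportion",
    "exact_test_2x2",
    "compare_to_control",
    "randomization_test",
    "lethal_threshold",
    "NO_EFFECT",
]

#: Sentinel returned when no tested dose shows a significant lethal effect.
NO_EFFECT = None


@dataclass(frozen=True)
class ExposureOutcome:
    """Counts for one tank on one observation day."""

    treatment: float  # dose, ng L^-1
    tank: str
    n: int  # shrimp in the tank
    dead: int
    swimming_observed: int = 0
    day: int = 4  # study day (end of the pulse exposure by default)

    def __post_init__(self):
        if not 0 <= self.dead <= self.n:
            raise ValueError(f"dead must be within [0, n], got {self.dead}/{self.n}")
        if not 0 <= self.swimming_observed <= self.n:
            raise ValueError("swimming_observed must be within [0, n]")


@dataclass(frozen=True)
class TreatmentComparison:
    """One dose pooled against the control."""

    dose: float  # ng L^-1
    mortality_prop: float
    excess_vs_control: float
    p_value: float

    def __post_init__(self):
        if not 0.0 <= self.mortality_prop <= 1.0:
            raise ValueError("mortality proportion must be in [0, 1]")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p-value must be in (0, 1]")


def _pool(outcomes: Iterable[ExposureOutcome]) -> tuple[int, int]:
    """(dead, n) pooled across tanks."""
    dead = n = 0
    for o in outcomes:
        dead += o.dead
        n += o.n
    return dead, n


def mortality_proportion(outcomes: Iterable[ExposureOutcome]) -> float:
    """Pooled dead / pooled n across the tanks of one treatment."""
    dead, n = _pool(outcomes)
    if n == 0:
        raise ValueError("no shrimp in the supplied outcomes")
    return dead / n


def exact_test_2x2(d1: int, n1: int, d2: int, n2: int) -> float:
    """Two-sided Fisher exact p for a dead/alive 2x2 table.

    Enumerates the hypergeometric distribution over all tables with the
    observed margins and sums the probabilities of tables no more likely
    than the observed one.  A degenerate table (all dead or all alive in
    both groups) has a single attainable configuration, so p = 1.
    """
    if not (0 <= d1 <= n1 and 0 <= d2 <= n2):
        raise ValueError("death counts must lie within group sizes")
    k = d1 + d2  # total dead, fixed margin
    lo, hi = max(0, k - n2), min(k, n1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n1 + n2, k, n1)
    p_obs = pmf[d1 - lo]
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    # the full support sums to 1 by construction; absorb rounding residue
    if p >= 1.0 - 1e-9:
        return 1.0
    return p


def compare_to_control(
    treatment: Iterable[ExposureOutcome], control: Iterable[ExposureOutcome]
) -> TreatmentComparison:
    """Pooled exact comparison of one dose group against the control."""
    treatment = list(treatment)
    control = list(control)
    if not treatment or not control:
        raise ValueError("both treatment and control outcomes are required")
    d_t, n_t = _pool(treatment)
    d_c, n_c = _pool(control)
    if n_t == 0 or n_c == 0:
        raise ValueError("empty group")
    doses = {o.treatment for o in treatment}
    if len(doses) != 1:
        raise ValueError(f"treatment outcomes span several doses: {doses}")
    (dose,) = doses
    return TreatmentComparison(
        dose=dose,
        mortality_prop=d_t / n_t,
        excess_vs_control=d_t / n_t - d_c / n_c,
        p_value=exact_test_2x2(d_t, n_t, d_c, n_c),
    )


def randomization_test(
    treatment: Sequence[ExposureOutcome],
    control: Sequence[ExposureOutcome],
    n_permutations: int = 9999,
    seed: int = 0,
) -> float:
    """Tank-level randomization p for the difference in pooled mortality.

    Tanks (not shrimp) are shuffled between the two groups; the two-sided
    p is the fraction of permutations with |difference| at least as large
    as observed, with the +1 correction for the observed arrangement.
    """
    tanks = [(o.dead, o.n) for o in treatment] + [(o.dead, o.n) for o in control]
    n_t = len(treatment)
    if n_t == 0 or len(control) == 0:
        raise ValueError("both groups need at least one tank")

    def stat(order):
        dt = sum(tanks[i][0] for i in order[:n_t])
        nt = sum(tanks[i][1] for i in order[:n_t])
        dc = sum(tanks[i][0] for i in order[n_t:])
        nc = sum(tanks[i][1] for i in order[n_t:])
        return abs(dt / nt - dc / nc)

    rng = np.random.default_rng(seed)
    observed = stat(range(len(tanks)))
    idx = np.arange(len(tanks))
    hits = 0
    for _ in range(n_permutations):
        rng.shuffle(idx)
        if stat(idx) >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def lethal_threshold(
    comparisons: Sequence[TreatmentComparison], alpha: float = 0.05
):
    """Lowest dose with p < alpha and positive excess mortality.

    Returns :data:`NO_EFFECT` (None) when no tested dose qualifies. The
    comparisons must include only dosed groups (the control enters through
    each comparison); doses are evaluated in ascending order.
    """
    if not comparisons:
        raise ValueError("no dose comparisons supplied; control missing?")
    for comp in sorted(comparisons, key=lambda c: c.dose):
        if comp.p_value < alpha and comp.excess_vs_control > 0:
            return comp.dose
    return NO_EFFECT
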