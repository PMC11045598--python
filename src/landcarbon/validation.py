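"""Map-agreement decomposition and the Kno / Klocation / Kquantity statistics.

The decomposition compares a simulated map against a reference map through the
observed proportion correct P0 and a family of expected proportions correct
under graded information about quantity (class proportions) and location:

* NQNL = 1/J                      (no quantity, no location)
* MQNL = sum_j p_j q_j            (medium quantity, no location)
* MQPL = sum_j min(p_j, q_j)      (medium quantity, perfect location)
* NQPL = sum_j min(1/J, q_j)      (no quantity, medium location ceiling)
* PQNL = sum_j q_j^2              (perfect quantity, no location)
* PQPL = 1
* location skill L = (P0 - MQNL) / (MQPL - MQNL)
* NQML = NQNL + L * (NQPL - NQNL)
* PQML = PQNL + L * (PQPL - PQNL)

with p the simulated-map class proportions and q the reference proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .change import CrossTab, crosstab
from .core import LulcMap
from .errors import ValidationError

_EPS = 1e-12


@dataclass
class AgreementComponents:
    P0: float
    J: int
    p: np.ndarray  # simulated-map class proportions (rows of the crosstab)
    q: np.ndarray  # reference-map class proportions (columns)
    NQNL: float
    MQNL: float
    MQPL: float
    NQPL: float
    PQNL: float
    PQPL: float
    location_skill: float  # NaN when MQPL == MQNL and P0 != MQPL
    NQML: float
    PQML: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "P0", "J", "NQNL", "MQNL", "MQPL", "NQPL", "PQNL", "PQPL",
                "location_skill", "NQML", "PQML", "degenerate",
            )
        }
        d["p"] = self.p.tolist()
        d["q"] = self.q.tolist()
        return d


def agreement_components(tab: CrossTab) -> AgreementComponents:
    """Compute the full agreement decomposition from a crosstab.

    Crosstab rows index the simulated map, columns the reference map.  A
    degenerate denominator MQPL == MQNL yields location skill 1 when
    P0 == MQPL (agreement is as good as the marginals allow) and NaN,
    flagged, otherwise.
    """
    counts = np.asarray(tab.counts, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValidationError("empty crosstab")
    J = counts.shape[0]
    P0 = float(np.trace(counts) / total)
    p = counts.sum(axis=1) / total
    q = counts.sum(axis=0) / total
    NQNL = 1.0 / J
    MQNL = float(p @ q)
    MQPL = float(np.minimum(p, q).sum())
    NQPL = float(np.minimum(NQNL, q).sum())
    PQNL = float(q @ q)
    PQPL = 1.0

    degenerate = False
    if MQPL - MQNL > _EPS:
        L = (P0 - MQNL) / (MQPL - MQNL)
    elif abs(P0 - MQPL) <= _EPS:
        L = 1.0
        degenerate = True
    else:
        L = float("nan")
        degenerate = True
    NQML = NQNL + L * (NQPL - NQNL)
    PQML = PQNL + L * (PQPL - PQNL)
    return AgreementComponents(
        P0, J, p, q, NQNL, MQNL, MQPL, NQPL, PQNL, PQPL, float(L), NQML, PQML,
        degenerate,
    )


def kno(c: AgreementComponents) -> float:
    """(P0 - NQNL) / (1 - NQNL); overall skill against an uninformed simulation."""
    if c.J < 2:
        raise ValidationError("Kno needs at least 2 classes")
    return (c.P0 - c.NQNL) / (1.0 - c.NQNL)


def klocation(c: AgreementComponents) -> float:
    """(P0 - MQNL) / (MQPL - MQNL); skill at placing the given quantities."""
    return c.location_skill


def kquantity(c: AgreementComponents) -> float:
    """(P0 - NQML) / (PQML - NQML); skill at specifying class quantities.

    When simulated and reference proportions coincide, PQML collapses onto P0
    and the ratio is 1 by the algebraic identity of the components; the
    0/0 case that arises there is therefore defined as 1.  A degenerate
    denominator with a nonzero numerator is NaN (flagged undefined).
    """
    num = c.P0 - c.NQML
    den = c.PQML - c.NQML
    if abs(den) <= _EPS:
        return 1.0 if abs(num) <= _EPS else float("nan")
    return num / den


def agreement_report(simulated: LulcMap, reference: LulcMap) -> dict:
    """All components plus the three statistics for a map pair, as a dict."""
    tab = crosstab(simulated, reference)
    comps = agreement_components(tab)
    return {
        "components": comps.to_dict(),
        "kno": kno(comps),
        "klocation": klocation(comps),
        "kquantity": kquantity(comps),
    }
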