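"""Group-level inference for the temperature-asymmetry analysis.

Two complementary tests, per group × phase × term (short/long):

* an exact two-sided binomial test of the number of asymmetric
  recordings against the null probability 0.5 (minimum-likelihood
  two-sided rule), and
* a Wilcoxon signed-rank test of the relative contributions.  Because
  the decrease and increase contributions of a recording sum to 1,
  comparing them pairwise is equivalent to testing the decrease (or
  increase) contribution against 0.5.

Short-term asymmetry counts recordings with SD1d > SD1i and tests C1d;
long-term asymmetry counts SD2i > SD2d and tests C2i.  Significance is
declared at α = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .poincare import PoincareDescriptors, classify_asymmetry

ALPHA = 0.05


def binomial_asymmetry_test(n_asymmetric: int, n_total: int) -> float:
    """Exact two-sided binomial p-value against success probability 0.5."""
    if n_total < 1 or not 0 <= n_asymmetric <= n_total:
        raise ValueError(f"invalid counts {n_asymmetric}/{n_total}")
    return float(stats.binomtest(n_asymmetric, n_total, 0.5).pvalue)


def wilcoxon_contribution_test(contributions: Sequence[float]) -> float:
    """Signed-rank test of relative contributions against 0.5.

    Exact null distribution for ≤ 25 non-zero differences without ties;
    otherwise the normal approximation with continuity correction.
    Returns 1.0 when every contribution equals 0.5 exactly.
    """
    c = np.asarray(contributions, dtype=float)
    if np.any((c < 0) | (c > 1)):
        raise ValueError("contributions must lie in [0, 1]")
    d = c - 0.5
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    exact_ok = d.size <= 25 and np.unique(np.abs(d)).size == d.size
    if exact_ok:
        res = stats.wilcoxon(d, method="exact")
    else:
        res = stats.wilcoxon(d, method="approx", correction=True)
    return float(res.pvalue)


@dataclass(frozen=True)
class GroupAsymmetrySummary:
    group: str
    phase: str
    term: str  # "short" or "long"
    n_total: int
    n_asymmetric: int
    fraction: float
    binomial_p: float
    mean_contribution: float  # mean C1d (short) or C2i (long)
    wilcoxon_p: float
    significant: bool  # both tests below alpha


def summarize_asymmetry(
    labelled_descriptors: Iterable[tuple[str, str, PoincareDescriptors]],
    alpha: float = ALPHA,
) -> list[GroupAsymmetrySummary]:
    """Asymmetry summary rows, one per group × phase × term.

    ``labelled_descriptors`` yields (group, phase, descriptors) per
    pooled recording.  Empty group × phase cells produce no row.
    """
    cells: dict[tuple[str, str], list[PoincareDescriptors]] = {}
    for group, phase, desc in labelled_descriptors:
        cells.setdefault((group, phase), []).append(desc)

    rows: list[GroupAsymmetrySummary] = []
    for (group, phase), descs in sorted(cells.items()):
        for term in ("short", "long"):
            if term == "short":
                flags = [classify_asymmetry(d).short_term_asymmetric for d in descs]
                contribs = [d.c1d for d in descs]
            else:
                flags = [classify_asymmetry(d).long_term_asymmetric for d in descs]
                contribs = [d.c2i for d in descs]
            contribs = [c for c in contribs if not math.isnan(c)]
            n_total = len(descs)
            n_asym = int(sum(flags))
            binom_p = binomial_asymmetry_test(n_asym, n_total)
            wilcox_p = wilcoxon_contribution_test(contribs) if contribs else math.nan
            rows.append(
                GroupAsymmetrySummary(
                    group=group,
                    phase=phase,
                    term=term,
                    n_total=n_total,
                    n_asymmetric=n_asym,
                    fraction=n_asym / n_total,
                    binomial_p=binom_p,
                    mean_contribution=float(np.mean(contribs)) if contribs else math.nan,
                    wilcoxon_p=wilcox_p,
                    significant=bool(binom_p < alpha and wilcox_p < alpha),
                )
            )
    return rows


def summaries_to_frame(rows: Sequence[GroupAsymmetrySummary]) -> pd.DataFrame:
    return pd.DataFrame([row.__dict__ for row in rows])
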