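"""Thermal coefficients, acclimation contrasts and species divergences.

Operates on tidy trait tables (one row per animal x experimental
temperature, one column per trait).  Q10 quantifies acute thermal
sensitivity — the factor by which a rate rises per 10 degC —

    Q10 = (R2 / R1) ** (10 / (T2 - T1))

and is computed from the two endpoint group means (14.0 and 21.5 degC
by default), not a log-linear fit.  Group summaries report mean and
t-distribution 95% confidence intervals; divergences and acclimation
contrasts are percentage comparisons of group means.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "q10",
    "q10_table",
    "group_summaries",
    "relative_divergence",
    "acclimation_contrast",
]


def q10(r1: float, r2: float, t1: float, t2: float) -> float:
    """Thermal coefficient between rates r1 at t1 and r2 at t2 (degC).

    Satisfies q10(r, r, .) == 1 and the reciprocal symmetry
    ``q10(r2, r1, t2, t1) == 1 / q10(r1, r2, t1, t2)``.
    """
    if r1 <= 0 or r2 <= 0:
        raise ValueError(f"rates must be > 0, got r1={r1}, r2={r2}")
    if t1 == t2:
        raise ValueError("t1 and t2 must differ")
    return float((r2 / r1) ** (10.0 / (t2 - t1)))


def q10_table(
    trait_table: pd.DataFrame,
    traits: Sequence[str],
    t_low: float = 14.0,
    t_high: float = 21.5,
    group_keys: Sequence[str] = ("species", "acclimation_temp_c"),
    temp_key: str = "experimental_temp_c",
) -> pd.DataFrame:
    """Q10 per group and trait from endpoint-temperature group means."""
    rows = []
    for keys, grp in trait_table.groupby(list(group_keys)):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for trait in traits:
            lo = grp.loc[np.isclose(grp[temp_key], t_low), trait].dropna()
            hi = grp.loc[np.isclose(grp[temp_key], t_high), trait].dropna()
            if len(lo) == 0 or len(hi) == 0:
                continue
            r1, r2 = float(lo.mean()), float(hi.mean())
            rows.append(
                dict(zip(group_keys, keys))
                | dict(
                    trait=trait,
                    r1=r1,
                    r2=r2,
                    t1=t_low,
                    t2=t_high,
                    q10=q10(r1, r2, t_low, t_high),
                )
            )
    return pd.DataFrame(rows)


def group_summaries(
    trait_table: pd.DataFrame,
    keys: Sequence[str],
    traits: Sequence[str],
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Mean and t-distribution CI per group and trait (long format).

    Single-observation groups get an undefined (NaN) CI and are
    flagged rather than dropped.
    """
    rows = []
    for group_keys, grp in trait_table.groupby(list(keys)):
        if not isinstance(group_keys, tuple):
            group_keys = (group_keys,)
        for trait in traits:
            vals = grp[trait].dropna().to_numpy(dtype=float)
            n = len(vals)
            if n == 0:
                continue
            mean = float(np.mean(vals))
            if n == 1:
                lo = hi = float("nan")
                flagged = True
            else:
                sem = float(np.std(vals, ddof=1) / np.sqrt(n))
                half = float(stats.t.ppf(0.5 + ci_level / 2.0, n - 1) * sem)
                lo, hi = mean - half, mean + half
                flagged = False
            rows.append(
                dict(zip(keys, group_keys))
                | dict(
                    trait=trait,
                    n=n,
                    mean=mean,
                    ci_low=lo,
                    ci_high=hi,
                    ci_undefined=flagged,
                )
            )
    return pd.DataFrame(rows)


def relative_divergence(
    trait_table: pd.DataFrame,
    reference_species: str,
    comparison_species: str,
    traits: Sequence[str],
    pooling_keys: Sequence[str] = ("acclimation_temp_c",),
    species_key: str = "species",
) -> pd.DataFrame:
    """Percent divergence of the comparison species from the reference.

    ``100 * (mean_comparison / mean_reference - 1)`` per trait per
    pooled cell.  Both species must be present in every cell; a
    non-positive reference mean is an error.
    """
    rows = []
    for cell_keys, grp in trait_table.groupby(list(pooling_keys)):
        if not isinstance(cell_keys, tuple):
            cell_keys = (cell_keys,)
        ref = grp[grp[species_key] == reference_species]
        comp = grp[grp[species_key] == comparison_species]
        if len(ref) == 0 or len(comp) == 0:
            raise ValueError(
                f"cell {dict(zip(pooling_keys, cell_keys))}: both species required"
            )
        for trait in traits:
            m_ref = float(ref[trait].dropna().mean())
            m_comp = float(comp[trait].dropna().mean())
            if not m_ref > 0:
                raise ValueError(
                    f"reference mean for {trait!r} must be > 0, got {m_ref}"
                )
            rows.append(
                dict(zip(pooling_keys, cell_keys))
                | dict(
                    trait=trait,
                    mean_reference=m_ref,
                    mean_comparison=m_comp,
                    divergence_pct=100.0 * (m_comp / m_ref - 1.0),
                )
            )
    return pd.DataFrame(rows)


def acclimation_contrast(
    trait_table: pd.DataFrame,
    trait: str,
    warm_temp: float,
    cold_temp: float,
    acclimation_key: str = "acclimation_temp_c",
) -> float:
    """Percent decrease of a trait mean from cold- to warm-acclimation.

    ``100 * (1 - mean_warm / mean_cold)``; positive when the warm group
    sits below the cold group.
    """
    cold = trait_table.loc[
        np.isclose(trait_table[acclimation_key], cold_temp), trait
    ].dropna()
    warm = trait_table.loc[
        np.isclose(trait_table[acclimation_key], warm_temp), trait
    ].dropna()
    if len(cold) == 0 or len(warm) == 0:
        raise ValueError("both acclimation groups must be present")
    m_cold = float(cold.mean())
    if not m_cold > 0:
        raise ValueError(f"cold-group mean must be > 0, got {m_cold}")
    return 100.0 * (1.0 - float(warm.mean()) / m_cold)
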