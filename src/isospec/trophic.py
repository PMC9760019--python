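"""Trophic-position estimation and the classical tests built on it.

Trophic position is estimated from muscle δ15N against a per-site baseline
(SPOM, predominantly phytoplankton, trophic level λ = 1) with a fixed
per-level enrichment of 3.04‰:

    TP = λ + (δ15N_consumer − δ15N_baseline) / enrichment

Between-site differences in TP are tested with a one-way ANOVA; equality of
variances between unbalanced tissue samples with a two-sided F ratio test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import IsotopeDataset, baselines_to_dict
from .errors import DomainError

DEFAULT_LAMBDA = 1.0
DEFAULT_ENRICHMENT = 3.04  # ‰ of δ15N per trophic level

TROPHIC_GROUPS = ("carnivores", "detritivores", "herbivores", "omnivores")


def trophic_position(
    d15N_consumer,
    d15N_base,
    lam: float = DEFAULT_LAMBDA,
    enrichment: float = DEFAULT_ENRICHMENT,
):
    """TP = λ + (δ15N_consumer − δ15N_baseline)/enrichment (vectorized)."""
    if enrichment <= 0:
        raise DomainError(f"enrichment must be positive, got {enrichment}")
    tp = lam + (np.asarray(d15N_consumer, dtype=float) - d15N_base) / enrichment
    return float(tp) if np.ndim(tp) == 0 else tp


def trophic_positions_table(
    dataset: IsotopeDataset,
    baselines,
    tissue: str = "muscle",
    lam: float = DEFAULT_LAMBDA,
    enrichment: float = DEFAULT_ENRICHMENT,
) -> pd.DataFrame:
    """Per-individual TP from one tissue's δ15N and per-site baselines.

    ``baselines`` is a mapping site → δ15N or a list of BaselineRecord.
    """
    base = baselines if isinstance(baselines, Mapping) else baselines_to_dict(baselines)
    t = dataset.subset(tissue=tissue).table
    missing = set(t["site"]) - set(base)
    if missing:
        raise DomainError(f"no baseline for site(s): {sorted(missing)}")
    d15n_base = t["site"].map(base).to_numpy(dtype=float)
    tp = trophic_position(t["d15N"].to_numpy(), d15n_base, lam, enrichment)
    return pd.DataFrame({
        "individual_id": t["individual_id"].to_numpy(),
        "site": t["site"].to_numpy(),
        "standard_length": t["standard_length"].to_numpy(),
        "d15N": t["d15N"].to_numpy(),
        "d15N_base": d15n_base,
        "tp": tp,
    })


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float


def one_way_anova(*groups: Sequence[float]) -> AnovaResult:
    """Classical one-way ANOVA F-test across ≥2 groups (each n ≥ 2)."""
    arrs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrs) < 2:
        raise DomainError("ANOVA needs at least two groups")
    if any(len(a) < 2 for a in arrs):
        raise DomainError("every group needs n ≥ 2")
    k = len(arrs)
    N = sum(len(a) for a in arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    grand = np.concatenate(arrs).mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrs)
    if ssw == 0.0:
        if ssb == 0.0:
            raise DomainError("F undefined: zero within-group variance and equal means")
        return AnovaResult(F=float("inf"), df1=k - 1, df2=N - k, p=0.0)
    F, p = stats.f_oneway(*arrs)
    return AnovaResult(F=float(F), df1=k - 1, df2=N - k, p=float(p))


@dataclass(frozen=True)
class VarianceRatioResult:
    F: float
    df1: int
    df2: int
    p: float  # two-sided


def variance_ratio_test(a: Sequence[float], b: Sequence[float]) -> VarianceRatioResult:
    """Two-sided F test of variance homogeneity, F = s_a²/s_b² (n−1 variances)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) < 2 or len(b) < 2:
        raise DomainError("both samples need n ≥ 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0.0:
        raise DomainError("degenerate denominator: zero variance")
    F = va / vb
    df1, df2 = len(a) - 1, len(b) - 1
    tail = stats.f.sf(F, df1, df2)
    p = 2.0 * min(tail, 1.0 - tail)
    return VarianceRatioResult(F=float(F), df1=df1, df2=df2, p=float(min(p, 1.0)))


def trophic_composition(species_table: pd.DataFrame) -> pd.DataFrame:
    """Per-site percentage of species in each trophic group.

    ``species_table`` needs columns (species, group, site); species with a
    missing/unknown group are excluded with a warning.  Percentages are
    computed at full precision and also reported rounded to 1 decimal.
    """
    required = {"species", "group", "site"}
    if not required.issubset(species_table.columns):
        raise DomainError(f"species table needs columns {sorted(required)}")
    t = species_table.copy()
    t["group"] = t["group"].astype(str).str.lower()
    bad = ~t["group"].isin(TROPHIC_GROUPS)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} species with missing/unknown trophic group excluded",
            stacklevel=2,
        )
        t = t[~bad]
    if t.empty:
        raise DomainError("no species with a known trophic group")
    rows = []
    for site, sub in t.groupby("site", sort=False):
        total = sub["species"].nunique()
        counts = sub.groupby("group")["species"].nunique()
        for group in TROPHIC_GROUPS:
            c = int(counts.get(group, 0))
            pct = 100.0 * c / total
            rows.append({"site": site, "group": group, "n_species": c,
                         "percent": pct, "percent_display": round(pct, 1)})
    return pd.DataFrame(rows)
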