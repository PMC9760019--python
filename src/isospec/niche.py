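"""Niche variance decomposition (TNW = WIC + BIC) and its bootstrap null test.

For a continuous diet proxy (here an isotope value) with repeated
observations per individual, the total niche width (TNW) — the population
variance of all observations — decomposes by the law of total variance into
a within-individual component (WIC, the sample-size-weighted mean of
individual variances) and a between-individual component (BIC, the weighted
variance of individual means).  The WIC/TNW ratio indexes individual
specialization: near 1, individuals are generalists sharing the population
niche; near 0, individuals each use a small subset of it.

All variances use the population (1/n) convention — the only convention
under which WIC + BIC reproduces TNW exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DegenerateNicheError, DomainError


@dataclass
class NicheDecomposition:
    """Variance decomposition of one site × isotope niche."""

    TNW: float
    WIC: float
    BIC: float
    ratio: float
    n_individuals: int
    n_observations: int
    isotope: str | None = None
    site: str | None = None
    p_value: float | None = None
    n_reps: int | None = None
    null_ratios: np.ndarray | None = field(default=None, repr=False)


def _as_groups(observations) -> list[np.ndarray]:
    if isinstance(observations, Mapping):
        groups = [np.asarray(v, dtype=float).ravel() for v in observations.values()]
    else:
        groups = [np.asarray(v, dtype=float).ravel() for v in observations]
    if any(len(g) == 0 for g in groups):
        raise DomainError("every individual needs at least one observation")
    return groups


def variance_components(
    observations: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    isotope: str | None = None,
    site: str | None = None,
) -> NicheDecomposition:
    """Decompose TNW into WIC and BIC from per-individual observations.

    With x_ij the j-th observation of individual i, n_i its count and
    N = Σ n_i::

        TNW = (1/N) Σ_ij (x_ij − x̄)²
        WIC = Σ_i (n_i/N) · Var_i          (Var_i with 1/n_i denominator)
        BIC = Σ_i (n_i/N) · (x̄_i − x̄)²
        ratio = WIC / TNW

    Individuals observed once contribute Var_i = 0 to WIC but full weight
    to BIC (this handles unbalanced tissue replication).
    """
    groups = _as_groups(observations)
    if len(groups) < 2:
        raise DomainError("need at least 2 individuals")
    N = sum(len(g) for g in groups)
    if N < 2:
        raise DomainError("need at least 2 observations in total")
    allx = np.concatenate(groups)
    grand = allx.mean()
    TNW = float(np.mean((allx - grand) ** 2))
    if TNW == 0.0:
        raise DegenerateNicheError("all observations identical; WIC/TNW undefined")
    WIC = float(sum(len(g) / N * np.var(g) for g in groups))
    BIC = float(sum(len(g) / N * (g.mean() - grand) ** 2 for g in groups))
    return NicheDecomposition(
        TNW=TNW, WIC=WIC, BIC=BIC, ratio=WIC / TNW,
        n_individuals=len(groups), n_observations=int(N),
        isotope=isotope, site=site,
    )


def _ratios_from_matrix(X: np.ndarray, starts: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """WIC/TNW ratio per row of X, with columns segmented by individual."""
    N = X.shape[1]
    grand = X.mean(axis=1)
    TNW = np.mean((X - grand[:, None]) ** 2, axis=1)
    sums = np.add.reduceat(X, starts, axis=1)
    sumsq = np.add.reduceat(X**2, starts, axis=1)
    means = sums / sizes
    vars_ = sumsq / sizes - means**2
    WIC = (vars_ * (sizes / N)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(TNW > 0, WIC / TNW, 1.0)


def wic_tnw_null_test(
    observations: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    n_reps: int = 1000,
    seed: int | None = None,
    isotope: str | None = None,
    site: str | None = None,
) -> NicheDecomposition:
    """Monte Carlo bootstrap test of WIC/TNW against the generalist null.

    Each replicate redraws, for every individual, its n_i observations with
    replacement from the pooled sample and recomputes the ratio.  The
    one-tailed, add-one-smoothed p-value

        p = (1 + #{null ratio ≤ observed ratio}) / (n_reps + 1)

    is small when individuals are more specialized (smaller ratio) than the
    generalist null predicts.
    """
    if n_reps < 100:
        raise DomainError("n_reps must be at least 100")
    obs = variance_components(observations, isotope=isotope, site=site)
    groups = _as_groups(observations)
    sizes = np.array([len(g) for g in groups])
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    pool = np.concatenate(groups)
    rng = np.random.default_rng(seed)
    X = rng.choice(pool, size=(n_reps, pool.size), replace=True)
    null_ratios = _ratios_from_matrix(X, starts, sizes)
    p = (1.0 + np.sum(null_ratios <= obs.ratio)) / (n_reps + 1.0)
    obs.p_value = float(p)
    obs.n_reps = int(n_reps)
    obs.null_ratios = null_ratios
    return obs


def decompose_dataset(
    dataset,
    isotope: str,
    site: str,
    n_reps: int | None = 1000,
    seed: int | None = None,
    center_tissues: bool = False,
) -> NicheDecomposition:
    """Decomposition for one site × isotope of an :class:`IsotopeDataset`.

    Each individual's repeated observations are its values across tissues
    (muscle and fin), entered uncorrected for tissue offset by default;
    ``center_tissues=True`` subtracts per-tissue means first, a sensitivity
    analysis for the offset's contribution to WIC.
    """
    sub = dataset.subset(site=site)
    if center_tissues:
        t = sub.table.copy()
        from .data import _isotope_column

        col = _isotope_column(isotope)
        t[col] = t[col] - t.groupby("tissue")[col].transform("mean") + t[col].mean()
        sub = type(sub)(t, metadata=sub.metadata)
    obs = sub.observations_by_individual(isotope)
    if n_reps is None:
        return variance_components(obs, isotope=isotope, site=site)
    return wic_tnw_null_test(obs, n_reps=n_reps, seed=seed, isotope=isotope, site=site)
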