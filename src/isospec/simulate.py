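"""Synthetic two-river, two-tissue isotope studies with known ground truth.

The generator emulates the sampling design of a two-site field study of a
piscivorous cichlid: two river sub-populations with unbalanced replication
(27 and 21 individuals by default), muscle plus caudal-fin tissue per
individual with a fin-dropout fraction at the second site (13 of 21 fins
retained by default), four prey functional groups (carnivores,
detritivores, herbivores, omnivores) with Gaussian isotopic signatures,
per-individual diet proportions on the 4-simplex, additive per-tissue
isotopic offsets, and Gaussian measurement noise at the analytical
precision of an isotope-ratio mass spectrometer (~0.12‰).

Every stochastic routine takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .compositions import check_simplex, ilr, ilr_inv
from .data import BaselineRecord, IsotopeDataset
from .errors import ConfigurationError

ISOTOPES = ("d13C", "d15N")

#: default prey functional-group signatures (muscle, ‰): rows are sources,
#: columns (δ13C, δ15N).  Chosen to sit around the consumer window of an
#: Amazonian blackwater food web (consumer muscle δ13C ≈ −36, δ15N ≈ 14).
DEFAULT_SOURCE_MEANS = {
    "carnivores": (-35.0, 12.0),
    "detritivores": (-38.0, 9.5),
    "herbivores": (-32.5, 8.5),
    "omnivores": (-36.5, 10.5),
}
DEFAULT_SOURCE_SDS = {
    "carnivores": (0.9, 0.7),
    "detritivores": (1.0, 0.8),
    "herbivores": (1.1, 0.8),
    "omnivores": (1.0, 0.7),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world of the synthetic study.

    Defaults mirror the field design: sites ("Uatuma", "Jatapu") with 27/21
    individuals, fin dropout 0 and 8/21 (giving 13 Jatapú fins), a ~5‰
    muscle-to-fin δ13C offset, trophic discrimination of (0.4, 3.04)‰ for
    (δ13C, δ15N), and measurement noise of 0.12‰.
    """

    sites: tuple[str, ...] = ("Uatuma", "Jatapu")
    n_individuals_per_site: tuple[int, ...] = (27, 21)
    fin_dropout: tuple[float, ...] = (0.0, 8.0 / 21.0)
    sources: tuple[str, ...] = tuple(DEFAULT_SOURCE_MEANS)
    source_means: dict = field(default_factory=lambda: dict(DEFAULT_SOURCE_MEANS))
    source_sds: dict = field(default_factory=lambda: dict(DEFAULT_SOURCE_SDS))
    source_n: int = 12
    tdf_mean: tuple[float, float] = (0.4, 3.04)
    tdf_sd: tuple[float, float] = (0.5, 0.5)
    #: additive tissue offsets (δ13C, δ15N) relative to muscle
    tissue_offset: dict = field(
        default_factory=lambda: {"muscle": (0.0, 0.0), "fin": (5.0, -0.3)}
    )
    #: population diet concentration; mean diet is the normalised vector
    dirichlet_population: tuple[float, ...] = (1.7, 2.6, 1.9, 3.8)
    #: "ilr": Gaussian individual effects in ILR space around the population
    #: mean diet (mirrors the fitting model); "dirichlet": draws from
    #: Dirichlet(dirichlet_population) for misspecification checks
    diet_mode: str = "ilr"
    re_sd: float = 0.5
    obs_sd: float = 0.12
    #: SPOM δ15N baselines per site (‰)
    baseline_d15N: tuple[float, ...] = (5.31, 3.06)
    #: trophic-position equation constants
    tp_lambda: float = 1.0
    tp_enrichment: float = 3.04
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if len(self.sources) < 1:
            raise ConfigurationError("at least one prey source required")
        if len(self.n_individuals_per_site) != len(self.sites):
            raise ConfigurationError("n_individuals_per_site must match sites")
        if len(self.fin_dropout) != len(self.sites):
            raise ConfigurationError("fin_dropout must match sites")
        if not all(0.0 <= f <= 1.0 for f in self.fin_dropout):
            raise ConfigurationError("fin_dropout fractions must lie in [0, 1]")
        alpha = np.asarray(self.dirichlet_population, dtype=float)
        if alpha.shape != (len(self.sources),) or np.any(alpha <= 0):
            raise ConfigurationError(
                "dirichlet_population must be strictly positive, one entry per source"
            )
        if self.re_sd < 0 or self.obs_sd < 0:
            raise ConfigurationError("re_sd and obs_sd must be >= 0")
        for name in self.sources:
            if name not in self.source_means or name not in self.source_sds:
                raise ConfigurationError(f"source {name!r} missing mean/sd entries")
            if any(s < 0 for s in self.source_sds[name]):
                raise ConfigurationError(f"source {name!r} has negative SD")
        if self.diet_mode not in ("ilr", "dirichlet"):
            raise ConfigurationError("diet_mode must be 'ilr' or 'dirichlet'")
        return self


def _source_arrays(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    mu = np.array([config.source_means[s] for s in config.sources], dtype=float)
    sd = np.array([config.source_sds[s] for s in config.sources], dtype=float)
    return mu, sd


def source_profile_table(config: SimulationConfig) -> pd.DataFrame:
    """Long-format source table (source, isotope, mean, sd, n)."""
    mu, sd = _source_arrays(config)
    rows = []
    for j, name in enumerate(config.sources):
        for k, iso in enumerate(ISOTOPES):
            rows.append(
                {"source": name, "isotope": iso, "mean": mu[j, k],
                 "sd": sd[j, k], "n": config.source_n}
            )
    return pd.DataFrame(rows)


def tdf_table(config: SimulationConfig) -> pd.DataFrame:
    """Trophic discrimination factors (isotope, mean, sd)."""
    return pd.DataFrame(
        {"isotope": list(ISOTOPES), "mean": list(config.tdf_mean),
         "sd": list(config.tdf_sd)}
    )


def _draw_diets(config: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    alpha = np.asarray(config.dirichlet_population, dtype=float)
    J = len(alpha)
    if J == 1:
        return np.ones((n, 1))
    if config.diet_mode == "dirichlet":
        return rng.dirichlet(alpha, size=n)
    mean_diet = alpha / alpha.sum()
    z0 = ilr(mean_diet)
    z = z0 + config.re_sd * rng.standard_normal((n, J - 1))
    return ilr_inv(z, J)


def generate_study(
    config: SimulationConfig | None = None,
) -> tuple[IsotopeDataset, pd.DataFrame, list[BaselineRecord], pd.DataFrame]:
    """Generate a full synthetic study.

    Returns
    -------
    dataset:
        Validated consumer :class:`~isospec.data.IsotopeDataset`.
    sources:
        Long-format source profile table (source, isotope, mean, sd, n).
    baselines:
        Per-site SPOM δ15N baseline records.
    truth:
        Per-individual ground truth: diet proportions ``p_<source>`` on the
        simplex and the true trophic position ``tp`` implied by the
        noise-free expected muscle δ15N.
    """
    config = (config or SimulationConfig()).validate()
    rng = np.random.default_rng(config.seed)
    mu, _sd = _source_arrays(config)
    tdf = np.asarray(config.tdf_mean, dtype=float)

    consumer_rows = []
    truth_rows = []
    for s_idx, site in enumerate(config.sites):
        n = config.n_individuals_per_site[s_idx]
        diets = check_simplex(_draw_diets(config, n, rng), tol=1e-9, what="generated diet")
        lengths = np.round(rng.normal(35.0, 5.0, size=n).clip(15.0, 60.0), 1)
        weights = np.round(0.025 * lengths**3 * np.exp(rng.normal(0, 0.08, size=n)), 1)
        n_drop = int(round(config.fin_dropout[s_idx] * n))
        dropped = set(rng.choice(n, size=n_drop, replace=False).tolist())
        base = config.baseline_d15N[s_idx]
        for i in range(n):
            ind = f"{site}_{i + 1:02d}"
            expected = diets[i] @ (mu + tdf)  # noise-free muscle signal, both isotopes
            tp = config.tp_lambda + (expected[1] - base) / config.tp_enrichment
            truth_rows.append(
                {"individual_id": ind, "site": site,
                 **{f"p_{src}": diets[i, j] for j, src in enumerate(config.sources)},
                 "tp": tp}
            )
            for tissue in ("muscle", "fin"):
                if tissue == "fin" and i in dropped:
                    continue
                offset = np.asarray(config.tissue_offset[tissue], dtype=float)
                noise = config.obs_sd * rng.standard_normal(2)
                vals = expected + offset + noise
                consumer_rows.append(
                    {"individual_id": ind, "site": site, "tissue": tissue,
                     "standard_length": lengths[i], "total_weight": weights[i],
                     "d13C": vals[0], "d15N": vals[1],
                     "cn_ratio": round(float(rng.uniform(2.9, 3.3)), 2)}
                )
    dataset = IsotopeDataset(
        pd.DataFrame(consumer_rows), metadata={"source": "synthetic", "seed": config.seed}
    )
    baselines = [
        BaselineRecord(site=s, d15N_base=float(b))
        for s, b in zip(config.sites, config.baseline_d15N)
    ]
    return dataset, source_profile_table(config), baselines, pd.DataFrame(truth_rows)


def generate_generalist_null(dataset: IsotopeDataset, seed: int) -> IsotopeDataset:
    """Resample a dataset under the all-generalists null.

    The output has exactly the input's shape (same individuals, sites,
    tissues), but every individual's δ values are i.i.d. draws with
    replacement from the pooled per-(site, tissue, isotope) empirical
    distribution, destroying any between-individual diet structure.
    """
    rng = np.random.default_rng(seed)
    t = dataset.table.copy()
    for (_site, _tissue), idx in t.groupby(["site", "tissue"], sort=True).groups.items():
        idx = np.asarray(idx)
        for col in ISOTOPES:
            pool = t.loc[idx, col].to_numpy()
            t.loc[idx, col] = rng.choice(pool, size=len(idx), replace=True)
    return IsotopeDataset(t, metadata={**dataset.metadata, "null": "generalist", "seed": seed})


def write_study(dataset, sources, baselines, truth, outdir) -> dict[str, str]:
    """Write the CSV bundle a downstream pipeline run reads."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "consumers": outdir / "consumers.csv",
        "sources": outdir / "sources.csv",
        "baseline": outdir / "baseline.csv",
        "truth": outdir / "truth.csv",
    }
    dataset.to_csv(paths["consumers"])
    sources.to_csv(paths["sources"], index=False)
    pd.DataFrame([{"site": b.site, "d15N_base": b.d15N_base} for b in baselines]).to_csv(
        paths["baseline"], index=False
    )
    truth.to_csv(paths["truth"], index=False)
    return {k: str(v) for k, v in paths.items()}
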