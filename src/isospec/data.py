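"""Consumer isotope data model, CSV I/O, screening, and population summaries.

The central container is :class:`IsotopeDataset`, a validated table of
per-individual, per-tissue stable isotope measurements (δ13C vs VPDB and
δ15N vs atmospheric N2, both in ‰).  One row corresponds to one tissue
sample of one individual; an individual may contribute up to one muscle and
one fin row.  Baseline δ15N values (suspended particulate organic matter,
predominantly phytoplankton) are carried separately per site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DomainError,
    IntegrityError,
    ParseError,
    SchemaError,
)

VALID_TISSUES = ("muscle", "fin")
#: plausibility windows for δ values in ‰
D13C_WINDOW = (-60.0, 0.0)
D15N_WINDOW = (-10.0, 30.0)
#: C:N ratio at or above which lipid content biases δ13C and a lipid model
#: (out of scope here) would be required
CN_THRESHOLD = 3.5

#: canonical column names of the consumer table
CANONICAL_COLUMNS = (
    "individual_id",
    "site",
    "tissue",
    "standard_length",
    "total_weight",
    "d13C",
    "d15N",
    "cn_ratio",
)
REQUIRED_COLUMNS = ("individual_id", "site", "tissue", "d13C", "d15N")


@dataclass(frozen=True)
class IsotopeMeasurement:
    """A single tissue sample of one individual.

    Optional morphometrics (standard length in cm, total weight in g) and
    the C:N ratio ride along when the source table provides them.
    """

    individual_id: str
    site: str
    tissue: str
    d13C: float
    d15N: float
    standard_length: float | None = None
    total_weight: float | None = None
    cn_ratio: float | None = None


@dataclass(frozen=True)
class BaselineRecord:
    """Aggregated SPOM δ15N baseline for one site (‰)."""

    site: str
    d15N_base: float


class IsotopeDataset:
    """Validated long-format consumer isotope table.

    Parameters
    ----------
    table:
        DataFrame with the canonical columns (one row per individual×tissue).
    metadata:
        Free-form provenance dict (source file, applied corrections, ...).
    """

    def __init__(self, table: pd.DataFrame, metadata: dict | None = None):
        self.table = _validate_table(table)
        self.metadata: dict = dict(metadata or {})

    # -- basic introspection -------------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    @property
    def individuals(self) -> list[str]:
        return list(pd.unique(self.table["individual_id"]))

    @property
    def sites(self) -> list[str]:
        return list(pd.unique(self.table["site"]))

    @property
    def tissues(self) -> list[str]:
        return list(pd.unique(self.table["tissue"]))

    def measurements(self) -> list[IsotopeMeasurement]:
        out = []
        for row in self.table.itertuples(index=False):
            out.append(
                IsotopeMeasurement(
                    individual_id=row.individual_id,
                    site=row.site,
                    tissue=row.tissue,
                    d13C=row.d13C,
                    d15N=row.d15N,
                    standard_length=_none_if_nan(row.standard_length),
                    total_weight=_none_if_nan(row.total_weight),
                    cn_ratio=_none_if_nan(row.cn_ratio),
                )
            )
        return out

    def subset(self, site: str | None = None, tissue: str | None = None) -> "IsotopeDataset":
        t = self.table
        if site is not None:
            t = t[t["site"] == site]
        if tissue is not None:
            t = t[t["tissue"] == tissue]
        if t.empty:
            raise DomainError(f"empty subset for site={site!r}, tissue={tissue!r}")
        return IsotopeDataset(t.reset_index(drop=True), metadata=self.metadata)

    def observations_by_individual(
        self, isotope: str, site: str | None = None
    ) -> dict[str, np.ndarray]:
        """Per-individual arrays of δ values, pooling tissues.

        This is the grouping the niche variance decomposition consumes: each
        individual's repeated observations are its values across tissues.
        """
        col = _isotope_column(isotope)
        t = self.table if site is None else self.table[self.table["site"] == site]
        if t.empty:
            raise DomainError(f"no rows for site={site!r}")
        return {
            ind: grp[col].to_numpy(dtype=float)
            for ind, grp in t.groupby("individual_id", sort=False)
        }

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# -- construction and validation ---------------------------------------------


def _none_if_nan(x):
    return None if x is None or (isinstance(x, float) and np.isnan(x)) else x


def _isotope_column(isotope: str) -> str:
    key = str(isotope).lower().replace("δ", "d").replace("13c", "13C").replace("15n", "15N")
    aliases = {"d13C": "d13C", "13C": "d13C", "c": "d13C",
               "d15N": "d15N", "15N": "d15N", "n": "d15N"}
    if key not in aliases:
        raise DomainError(f"unknown isotope {isotope!r}; expected d13C or d15N")
    return aliases[key]


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    t = table.copy()
    for col in CANONICAL_COLUMNS:
        if col not in t.columns:
            t[col] = np.nan
    t = t[list(CANONICAL_COLUMNS)].reset_index(drop=True)
    t["individual_id"] = t["individual_id"].astype(str)
    t["site"] = t["site"].astype(str)
    t["tissue"] = t["tissue"].astype(str).str.lower()

    problems: list[str] = []
    bad_tissue = ~t["tissue"].isin(VALID_TISSUES)
    for i in t.index[bad_tissue]:
        problems.append(f"row {i}: unknown tissue {t.at[i, 'tissue']!r}")

    for col, window in (("d13C", D13C_WINDOW), ("d15N", D15N_WINDOW)):
        vals = pd.to_numeric(t[col], errors="coerce")
        for i in t.index[vals.isna()]:
            raise ParseError(f"row {i}: non-numeric {col} value {t.at[i, col]!r}")
        t[col] = vals
        out = (vals < window[0]) | (vals > window[1])
        for i in t.index[out]:
            problems.append(
                f"row {i}: {col}={vals[i]:.2f}‰ outside plausibility window {window}"
            )
    for col in ("standard_length", "total_weight", "cn_ratio"):
        vals = pd.to_numeric(t[col], errors="coerce")
        nonnumeric = vals.isna() & t[col].notna() & (t[col].astype(str).str.strip() != "") \
            & (t[col].astype(str).str.upper() != "NA")
        for i in t.index[nonnumeric]:
            raise ParseError(f"row {i}: non-numeric {col} value {t.at[i, col]!r}")
        bad = vals.notna() & (vals <= 0)
        for i in t.index[bad]:
            problems.append(f"row {i}: {col} must be > 0, got {vals[i]}")
        t[col] = vals
    if problems:
        raise DomainError("invalid rows:\n" + "\n".join(problems))

    dup = t.duplicated(subset=["individual_id", "tissue"], keep=False)
    if dup.any():
        pairs = t.loc[dup, ["individual_id", "tissue"]].drop_duplicates()
        raise IntegrityError(
            "duplicate (individual, tissue) pairs: "
            + ", ".join(f"({r.individual_id}, {r.tissue})" for r in pairs.itertuples())
        )
    # one individual, one site
    nsites = t.groupby("individual_id")["site"].nunique()
    multi = nsites[nsites > 1]
    if len(multi):
        raise IntegrityError(f"individuals recorded at multiple sites: {list(multi.index)}")
    sl = t.groupby("individual_id")["standard_length"].nunique(dropna=True)
    if (sl > 1).any():
        raise IntegrityError(
            f"standard length not constant within individuals: {list(sl[sl > 1].index)}"
        )
    return t


def read_consumer_table(path, schema: Mapping[str, str] | None = None) -> IsotopeDataset:
    """Read a consumer CSV into a validated :class:`IsotopeDataset`.

    Parameters
    ----------
    path:
        CSV file with a header row; decimal point ``.``, UTF-8, missing
        values as empty cells or ``NA``.
    schema:
        Optional mapping from canonical names (``individual_id``, ``site``,
        ``tissue``, ``standard_length``, ``total_weight``, ``d13C``,
        ``d15N``, ``cn_ratio``) to the file's column names.  Canonical
        names are used directly when no mapping is given.
    """
    raw = pd.read_csv(path, na_values=["NA", ""], keep_default_na=True)
    if schema:
        unknown = set(schema) - set(CANONICAL_COLUMNS)
        if unknown:
            raise SchemaError(f"schema maps unknown canonical names: {sorted(unknown)}")
        missing = [src for src in schema.values() if src not in raw.columns]
        if missing:
            raise SchemaError(f"mapped columns absent from file: {missing}")
        raw = raw.rename(columns={src: canon for canon, src in schema.items()})
    return IsotopeDataset(raw, metadata={"source": str(path)})


def read_baseline_table(path, schema: Mapping[str, str] | None = None) -> list[BaselineRecord]:
    """Read per-site SPOM δ15N baselines, averaging replicate filter values."""
    raw = pd.read_csv(path, na_values=["NA", ""])
    cols = {"site": "site", "d15N_base": "d15N_base"}
    if schema:
        cols.update(schema)
    missing = [c for c in cols.values() if c not in raw.columns]
    if missing:
        raise SchemaError(f"baseline table missing columns: {missing}")
    vals = pd.to_numeric(raw[cols["d15N_base"]], errors="coerce")
    if vals.isna().any():
        raise ParseError("non-numeric baseline δ15N value")
    agg = raw.assign(_v=vals).groupby(cols["site"])["_v"].mean()
    return [BaselineRecord(site=str(s), d15N_base=float(v)) for s, v in agg.items()]


def baselines_to_dict(records: Iterable[BaselineRecord]) -> dict[str, float]:
    return {r.site: r.d15N_base for r in records}


# -- corrections and screening -------------------------------------------------


def correct_ethanol_preservation(
    values: Sequence[float] | np.ndarray,
    isotope: str,
    coeffs: tuple[float, float] | None,
) -> np.ndarray:
    """Affine correction ``a + b·δ`` for ethanol-preserved tissue.

    The correction equation is tissue- and taxon-specific and must be
    supplied explicitly as ``(a, b)``; requesting a correction without
    coefficients is a configuration error rather than a silent no-op.
    """
    _isotope_column(isotope)
    if coeffs is None:
        raise ConfigurationError(
            "ethanol correction requested but no (a, b) coefficients configured"
        )
    a, b = float(coeffs[0]), float(coeffs[1])
    return a + b * np.asarray(values, dtype=float)


def apply_ethanol_correction(
    dataset: IsotopeDataset,
    coeffs: Mapping[str, tuple[float, float]] | None,
    tissue: str = "fin",
) -> IsotopeDataset:
    """Apply per-isotope ethanol corrections to one tissue's rows.

    ``coeffs`` maps isotope name to ``(a, b)``.  When ``coeffs`` is None the
    dataset is returned unchanged with a logged warning, the default on the
    assumption that deposited values were corrected upstream.
    """
    if coeffs is None:
        warnings.warn(
            "no ethanol-correction coefficients configured; "
            "assuming values are already corrected",
            stacklevel=2,
        )
        out = IsotopeDataset(dataset.table, metadata=dataset.metadata)
        out.metadata.setdefault("corrections", []).append(
            {"type": "ethanol", "tissue": tissue, "applied": False}
        )
        return out
    t = dataset.table.copy()
    mask = t["tissue"] == tissue
    for isotope, ab in coeffs.items():
        col = _isotope_column(isotope)
        t.loc[mask, col] = correct_ethanol_preservation(
            t.loc[mask, col].to_numpy(), isotope, ab
        )
    out = IsotopeDataset(t, metadata=dataset.metadata)
    out.metadata.setdefault("corrections", []).append(
        {"type": "ethanol", "tissue": tissue, "applied": True,
         "coeffs": {k: tuple(v) for k, v in coeffs.items()}}
    )
    return out


def lipid_correction_needed(cn_ratio: float) -> bool:
    """True when the C:N ratio flags lipid bias (threshold 3.5, inclusive)."""
    r = np.asarray(cn_ratio, dtype=float)
    if np.any(r <= 0):
        raise DomainError(f"C:N ratio must be positive, got {cn_ratio}")
    flagged = r >= CN_THRESHOLD
    return bool(flagged) if np.ndim(cn_ratio) == 0 else flagged


def screen_lipids(dataset: IsotopeDataset, on_flag: str = "error") -> IsotopeDataset:
    """Refuse (or warn about) samples whose C:N ratio demands a lipid model."""
    cn = dataset.table["cn_ratio"]
    known = cn.dropna()
    flagged = known.index[lipid_correction_needed(known.to_numpy())] if len(known) else []
    if len(flagged):
        msg = (
            f"{len(flagged)} sample(s) with C:N ≥ {CN_THRESHOLD}; lipid "
            "normalisation is out of scope — δ13C values are biased"
        )
        if on_flag == "error":
            raise DomainError(msg + f" (rows {list(flagged)})")
        warnings.warn(msg, stacklevel=2)
    out = IsotopeDataset(dataset.table, metadata=dataset.metadata)
    out.metadata["lipid_screen"] = {"n_flagged": int(len(flagged))}
    return out


# -- summaries ------------------------------------------------------------------


def summarize_population(
    dataset: IsotopeDataset, by: tuple[str, ...] = ("site", "tissue")
) -> pd.DataFrame:
    """Per-group n, mean and sample SD of δ13C and δ15N.

    SD uses the n−1 denominator.  Groups with n < 2 are still reported, with
    SD set to NaN and ``sd_defined`` False.  Values are kept at full
    precision; round only for display.
    """
    rows = []
    for keys, grp in dataset.table.groupby(list(by), sort=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        rec = dict(zip(by, keys))
        rec["n"] = len(grp)
        rec["sd_defined"] = len(grp) >= 2
        for col in ("d13C", "d15N"):
            rec[f"{col}_mean"] = float(grp[col].mean())
            rec[f"{col}_sd"] = float(grp[col].std(ddof=1)) if len(grp) >= 2 else float("nan")
        rows.append(rec)
    return pd.DataFrame(rows)
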