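"""Length-for-age z-scores via the LMS growth-reference method.

A growth reference tabulates, for each sex and age in days, the Box-Cox
power ``L``, the median length ``M`` (cm) and the coefficient of variation
``S``. A measured length ``x`` converts to a z-score by

    z = ((x / M)^L - 1) / (L * S)      if L != 0
    z = ln(x / M) / S                  if L == 0

and the transform inverts exactly. Reference parameters at untabulated ages
are obtained by linear interpolation in age, separately for L, M and S.

The packaged table ``data/lms_synthetic.csv`` is a synthetic miniature
reference with the same schema as the WHO 2006 length-for-age tables
(sex, age_days, L, M, S; ages 0-730 days) so the pipeline and its tests run
self-contained; real WHO tables are drop-in replacements.
"""
from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["LMSReference", "compute_laz", "invert_laz", "load_synthetic_reference"]

_REQUIRED = ("sex", "age_days", "L", "M", "S")
_SEXES = ("male", "female")


class LMSReference:
    """Sex- and age-indexed LMS table with linear age interpolation."""

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in _REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"LMS table missing required columns: {missing}")
        table = table.copy()
        table["sex"] = table["sex"].astype(str).str.lower()
        bad_sex = set(table["sex"]) - set(_SEXES)
        if bad_sex:
            raise ValueError(f"unrecognized sex values in LMS table: {sorted(bad_sex)}")
        if (table["M"] <= 0).any() or (table["S"] <= 0).any():
            raise ValueError("LMS table requires M > 0 and S > 0")
        if table.duplicated(["sex", "age_days"]).any():
            raise ValueError("LMS table has duplicate (sex, age_days) rows")
        self._grids: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for sex, sub in table.groupby("sex"):
            sub = sub.sort_values("age_days")
            self._grids[sex] = (
                sub["age_days"].to_numpy(float),
                sub["L"].to_numpy(float),
                sub["M"].to_numpy(float),
                sub["S"].to_numpy(float),
            )
        self.table = table

    @classmethod
    def from_csv(cls, path: str | Path) -> "LMSReference":
        return cls(pd.read_csv(path))

    def age_range(self, sex: str) -> tuple[float, float]:
        ages = self._grids[self._check_sex(sex)][0]
        return float(ages[0]), float(ages[-1])

    def _check_sex(self, sex: str) -> str:
        s = str(sex).lower()
        if s not in self._grids:
            raise KeyError(f"sex {sex!r} not present in LMS reference")
        return s

    def params(self, age_days, sex: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Interpolated (L, M, S) at ``age_days`` for one sex."""
        ages, L, M, S = self._grids[self._check_sex(sex)]
        a = np.asarray(age_days, dtype=float)
        if np.any(a < ages[0]) or np.any(a > ages[-1]):
            raise ValueError(
                f"age outside LMS reference range [{ages[0]:g}, {ages[-1]:g}] days"
            )
        return np.interp(a, ages, L), np.interp(a, ages, M), np.interp(a, ages, S)

    def laz(self, length_cm, age_days, sex: str):
        """z-score of length(s) at age(s) for one sex."""
        L, M, S = self.params(age_days, sex)
        x = np.asarray(length_cm, dtype=float)
        with np.errstate(invalid="ignore"):
            z = np.where(
                L == 0.0,
                np.log(x / M) / S,
                (np.power(x / M, L) - 1.0) / (L * S),
            )
        return z if z.ndim else float(z)

    def length(self, z, age_days, sex: str):
        """Inverse transform: length (cm) at given z-score, age and sex."""
        L, M, S = self.params(age_days, sex)
        zz = np.asarray(z, dtype=float)
        L, M, S, zz = np.broadcast_arrays(L, M, S, zz)
        x = np.empty_like(zz, dtype=float)
        zero = L == 0.0
        x[zero] = M[zero] * np.exp(S[zero] * zz[zero])
        nz = ~zero
        x[nz] = M[nz] * np.power(1.0 + L[nz] * S[nz] * zz[nz], 1.0 / L[nz])
        return x if np.asarray(z).ndim else float(x)


def compute_laz(length_cm, age_days, sex, ref: LMSReference):
    """z-score of a length measurement against an LMS reference."""
    return ref.laz(length_cm, age_days, sex)


def invert_laz(z, age_days, sex, ref: LMSReference):
    """Length (cm) whose z-score equals ``z`` at the given age and sex."""
    return ref.length(z, age_days, sex)


def add_laz_column(df: pd.DataFrame, ref: LMSReference, overwrite: bool = False) -> pd.DataFrame:
    """Return a copy of a measurement table with the ``laz`` column filled.

    Rows with a precomputed ``laz`` are kept unless ``overwrite`` is set.
    """
    out = df.copy()
    if "laz" not in out.columns:
        out["laz"] = np.nan
    need = out["laz"].isna() if not overwrite else np.ones(len(out), bool)
    for sex in out.loc[need, "sex"].unique():
        m = need & (out["sex"] == sex)
        out.loc[m, "laz"] = ref.laz(
            out.loc[m, "length_cm"].to_numpy(), out.loc[m, "age_days"].to_numpy(), sex
        )
    return out


def load_synthetic_reference() -> LMSReference:
    """The packaged synthetic miniature LMS reference used by tests and the
    simulator. Schema-compatible with real WHO length-for-age tables."""
    with resources.files("growthfalter.data").joinpath("lms_synthetic.csv").open() as fh:
        return LMSReference(pd.read_csv(fh))
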