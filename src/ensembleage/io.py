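"""Readers, writers and validation for the package's tabular artifacts.

All on-disk formats are comma-separated UTF-8 text with a mandatory header
row and ``.`` as the decimal mark.  Methylation matrices are CpG-by-sample
tables of beta values in [0, 1]; missing cells are written empty and either
an empty cell or ``NA`` is accepted on read.  Clock models are a coefficient
CSV (term, coefficient) with an ``(Intercept)`` row plus a JSON metadata
sidecar carrying the age transform, per-CpG training means used for
imputation, and the training recipe provenance.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .agetransform import AgeTransformSpec
from .errors import (CoverageError, ConsistencyError, FormatError,
                     ValidationError)

logger = logging.getLogger(__name__)

SAMPLE_SHEET_REQUIRED = ("sample_id", "age", "species", "tissue",
                         "stratum_id", "role", "expected_direction")
ROLES = ("control", "treated")
DIRECTIONS = ("stress", "rejuvenation", "none")

#: Default maximum tolerated fraction of a clock's CpGs that may be missing
#: (absent rows and empty cells combined) before prediction is refused.
DEFAULT_MAX_MISSING_FRACTION = 0.5


@dataclass
class BetaMatrix:
    """CpG-by-sample matrix of methylation fractions.

    ``values`` is a float DataFrame indexed by CpG id with sample ids as
    columns; NaN marks missing.  Construction validates the [0, 1] range
    and id uniqueness.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate CpG ids: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        arr = v.to_numpy(dtype=float, copy=False)
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            i, j = np.argwhere(bad & ~np.isnan(arr))[0]
            raise ValidationError(
                f"beta value {arr[i, j]!r} outside [0, 1] at "
                f"CpG {v.index[i]!r}, sample {v.columns[j]!r}")
        self.values = v.astype(float)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())


@dataclass
class SampleSheet:
    """Per-sample metadata: age, tissue, stratum, role and expected
    perturbation direction, plus any numeric outcome columns (e.g.
    time-to-death) carried through from the input file.

    ``data`` is indexed by sample_id.
    """

    data: pd.DataFrame
    outcome_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        d = self.data
        for col in SAMPLE_SHEET_REQUIRED[1:]:
            if col not in d.columns:
                raise FormatError(f"sample sheet missing required column {col!r}")
        if d.index.has_duplicates:
            dups = d.index[d.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        ages = d["age"].astype(float)
        if (ages <= 0).any():
            bad = d.index[ages <= 0][0]
            raise ValidationError(f"age must be > 0 years (sample {bad!r})")
        bad_role = ~d["role"].isin(ROLES)
        if bad_role.any():
            raise ValidationError(
                f"role must be one of {ROLES} (sample {d.index[bad_role][0]!r})")
        bad_dir = ~d["expected_direction"].isin(DIRECTIONS)
        if bad_dir.any():
            raise ValidationError(
                "expected_direction must be one of "
                f"{DIRECTIONS} (sample {d.index[bad_dir][0]!r})")
        ndir = d.groupby("stratum_id")["expected_direction"].nunique()
        mixed = ndir[ndir > 1]
        if len(mixed):
            raise ValidationError(
                f"mixed expected_direction within stratum {mixed.index[0]!r}")
        self.data = d.assign(age=ages)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def strata(self) -> list[str]:
        return list(dict.fromkeys(self.data["stratum_id"]))

    def stratum_direction(self, stratum_id: str) -> str:
        sub = self.data[self.data["stratum_id"] == stratum_id]
        if sub.empty:
            raise ValidationError(f"unknown stratum {stratum_id!r}")
        return sub["expected_direction"].iloc[0]

    def stratum_samples(self, stratum_id: str) -> pd.DataFrame:
        sub = self.data[self.data["stratum_id"] == stratum_id]
        if sub.empty:
            raise ValidationError(f"unknown stratum {stratum_id!r}")
        return sub

    def outcomes(self, name: str) -> pd.Series:
        if name not in self.outcome_names:
            raise ValidationError(f"unknown outcome {name!r}")
        return self.data[name].astype(float)


@dataclass
class ClockModel:
    """A fitted epigenetic clock: intercept plus sparse CpG weights on the
    beta scale, the age transform its target used, and per-CpG training
    means for imputing absent probes at prediction time."""

    clock_id: str
    intercept: float
    weights: dict[str, float]
    transform: AgeTransformSpec
    train_means: dict[str, float]
    recipe: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in self.weights if c not in self.train_means]
        if missing:
            raise ValidationError(
                f"clock {self.clock_id!r}: weighted CpGs without a training "
                f"mean: {missing[:5]}")


def read_beta(path: str | Path) -> BetaMatrix:
    """Read a CpG-by-sample beta matrix from CSV.

    First column holds CpG ids, header row holds sample ids.  Empty cells
    and ``NA`` become missing values.  Raises :class:`FormatError` for
    malformed tables and :class:`ValidationError` for out-of-range values,
    naming the offending cell.
    """
    try:
        df = pd.read_csv(path, index_col=0, na_values=["NA"],
                         keep_default_na=False)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as e:
        raise FormatError(f"cannot parse beta matrix {path}: {e}") from e
    for col in df.columns:
        coerced = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
        raw_present = df[col].replace("", np.nan).notna()
        if (coerced.isna() & raw_present).any():
            bad = df.index[coerced.isna() & raw_present][0]
            raise FormatError(
                f"non-numeric beta cell at CpG {bad!r}, sample {col!r}")
        df[col] = coerced
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    return BetaMatrix(df)


def write_beta(m: BetaMatrix, path: str | Path) -> None:
    df = m.values.copy()
    df.index.name = "cpg_id"
    # str() of a Python float is shortest-round-trip, so read_beta recovers
    # every value bit-exactly.
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["cpg_id", *df.columns])
        arr = df.to_numpy()
        for i, cpg in enumerate(df.index):
            row = ["" if np.isnan(v) else repr(float(v)) for v in arr[i]]
            w.writerow([cpg, *row])


def read_samples(path: str | Path) -> SampleSheet:
    """Read a sample sheet from CSV.

    Requires columns sample_id, age, species, tissue, stratum_id, role,
    expected_direction.  Any additional column that parses as numeric for
    every non-empty cell is kept as an outcome; other extras are dropped
    with a log note.
    """
    try:
        df = pd.read_csv(path, dtype=str, na_values=["NA"],
                         keep_default_na=False)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as e:
        raise FormatError(f"cannot parse sample sheet {path}: {e}") from e
    for col in SAMPLE_SHEET_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"sample sheet missing required column {col!r}")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    extras = [c for c in df.columns if c not in SAMPLE_SHEET_REQUIRED]
    outcome_names: list[str] = []
    for col in extras:
        coerced = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
        present = df[col].replace("", np.nan).notna()
        if (coerced.isna() & present).any():
            logger.info("sample sheet column %r is non-numeric; dropped", col)
            df = df.drop(columns=[col])
        else:
            df[col] = coerced
            outcome_names.append(col)
    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    if df["age"].isna().any():
        bad = df.index[df["age"].isna()][0]
        raise FormatError(f"non-numeric age for sample {bad!r}")
    return SampleSheet(df, outcome_names)


def write_samples(sheet: SampleSheet, path: str | Path) -> None:
    df = sheet.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path)


def align_to_clock(m: BetaMatrix, c: ClockModel,
                   max_missing_fraction: float = DEFAULT_MAX_MISSING_FRACTION,
                   ) -> BetaMatrix:
    """Restrict ``m`` to the clock's weighted CpGs, in the clock's order.

    CpGs absent from ``m`` and missing cells are imputed with the clock's
    training means, so downstream prediction is total.  The imputed
    fraction is logged.  If more than ``max_missing_fraction`` of the
    clock's CpGs are entirely absent from ``m``, a :class:`CoverageError`
    is raised instead.
    """
    clock_cpgs = list(c.weights)
    if not clock_cpgs:
        return BetaMatrix(pd.DataFrame(
            np.empty((0, len(m.sample_ids))), index=[], columns=m.sample_ids))
    present = [g for g in clock_cpgs if g in m.values.index]
    absent = [g for g in clock_cpgs if g not in m.values.index]
    if len(absent) / len(clock_cpgs) > max_missing_fraction:
        raise CoverageError(
            f"clock {c.clock_id!r}: {len(absent)}/{len(clock_cpgs)} CpGs "
            f"absent from matrix (> {max_missing_fraction:.0%} allowed)")
    out = pd.DataFrame(np.nan, index=clock_cpgs, columns=m.sample_ids)
    if present:
        out.loc[present] = m.values.loc[present].to_numpy()
    n_imputed = int(out.isna().to_numpy().sum())
    means = pd.Series({g: c.train_means[g] for g in clock_cpgs})
    out = out.apply(lambda col: col.fillna(means))
    frac = n_imputed / out.size if out.size else 0.0
    if n_imputed:
        logger.info("align_to_clock %s: imputed %d cells (%.2f%%) with "
                    "training means", c.clock_id, n_imputed, 100 * frac)
    return BetaMatrix(out)


def write_clock(c: ClockModel, path: str | Path) -> None:
    """Write a clock as ``<path>`` (coefficient CSV) plus ``<path>.json``
    (metadata sidecar).  Round-trips exactly through :func:`read_clock`."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["term", "coefficient"])
        w.writerow(["(Intercept)", repr(float(c.intercept))])
        for cpg, wt in c.weights.items():
            w.writerow([cpg, repr(float(wt))])
    sidecar = {
        "clock_id": c.clock_id,
        "transform": c.transform.to_dict(),
        "train_means": {k: float(v) for k, v in c.train_means.items()},
        "recipe": c.recipe,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w",
              encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1)


def read_clock(path: str | Path) -> ClockModel:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing clock sidecar {sidecar_path}")
    with open(sidecar_path, encoding="utf-8") as fh:
        meta = json.load(fh)
    intercept = None
    weights: dict[str, float] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows or rows[0] != ["term", "coefficient"]:
        raise FormatError(f"clock file {path} lacks term,coefficient header")
    for term, coef in rows[1:]:
        if term == "(Intercept)":
            intercept = float(coef)
        else:
            weights[term] = float(coef)
    if intercept is None:
        raise FormatError(f"clock file {path} lacks an (Intercept) row")
    means = meta.get("train_means", {})
    mismatch = set(weights) - set(means)
    if mismatch:
        raise ConsistencyError(
            f"clock {path}: CpGs in coefficients but not sidecar "
            f"train_means: {sorted(mismatch)[:5]}")
    return ClockModel(
        clock_id=meta["clock_id"],
        intercept=intercept,
        weights=weights,
        transform=AgeTransformSpec.from_dict(meta["transform"]),
        train_means={k: float(v) for k, v in means.items()},
        recipe=meta.get("recipe", {}),
    )


def write_library(clocks: list[ClockModel], outdir: str | Path) -> None:
    """Write a clock library as one file per clock plus a manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for c in clocks:
        fname = f"{c.clock_id}.csv"
        write_clock(c, outdir / fname)
        manifest.append({"clock_id": c.clock_id, "file": fname,
                         "n_weights": len(c.weights)})
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)


def read_library(outdir: str | Path) -> dict[str, ClockModel]:
    outdir = Path(outdir)
    with open(outdir / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    return {e["clock_id"]: read_clock(outdir / e["file"]) for e in manifest}
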