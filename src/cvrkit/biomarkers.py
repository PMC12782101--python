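"""Composite value ratios (CVRs) and traditional volumetric biomarkers.

A CVR assigns every atlas region to the numerator composite, the
denominator composite, or neither; its value at a visit is the ratio of the
two composites' mean volumes. The genome form encodes the assignment as an
integer vector over atlas positions (0 = numerator, 1 = excluded,
2 = denominator) for use by the genetic-algorithm search.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .cohort import COVARIATE_COLUMNS

NUM, EXC, DEN = 0, 1, 2
_CODES = {NUM: "NUM", EXC: "EXC", DEN: "DEN"}


@dataclass(frozen=True)
class CVRSpec:
    """A composite value ratio: numerator and denominator region sets."""

    numerator: tuple[str, ...]
    denominator: tuple[str, ...]

    def __post_init__(self) -> None:
        num = tuple(sorted(set(self.numerator)))
        den = tuple(sorted(set(self.denominator)))
        object.__setattr__(self, "numerator", num)
        object.__setattr__(self, "denominator", den)
        if not num:
            raise ValueError("numerator composite is empty")
        if not den:
            raise ValueError("denominator composite is empty")
        # overlapping composites are representable as sets (the ratio is
        # well-defined) but have no genome form; encode() rejects them

    # -- assignment-mapping form -------------------------------------------

    @classmethod
    def from_assignment(cls, assignment: dict[str, str]) -> "CVRSpec":
        """Build from a mapping region -> 'NUM' | 'DEN' | 'EXC'."""
        num, den = [], []
        for region, code in assignment.items():
            if code == "NUM":
                num.append(region)
            elif code == "DEN":
                den.append(region)
            elif code != "EXC":
                raise ValueError(f"invalid assignment {code!r} for {region!r}")
        return cls(tuple(num), tuple(den))

    def assignment(self, atlas: RegionAtlas) -> dict[str, str]:
        out = {}
        for r in atlas.region_names:
            if r in self.numerator:
                out[r] = "NUM"
            elif r in self.denominator:
                out[r] = "DEN"
            else:
                out[r] = "EXC"
        return out

    # -- genome form --------------------------------------------------------

    def encode(self, atlas: RegionAtlas) -> np.ndarray:
        """Integer genome over atlas positions (0 NUM / 1 EXC / 2 DEN)."""
        unknown = (set(self.numerator) | set(self.denominator)) - set(
            atlas.region_names
        )
        if unknown:
            raise KeyError(f"regions not in atlas: {sorted(unknown)}")
        overlap = set(self.numerator) & set(self.denominator)
        if overlap:
            raise ValueError(
                f"regions in both composites have no genome code: "
                f"{sorted(overlap)}"
            )
        genome = np.full(len(atlas), EXC, dtype=np.int8)
        for r in self.numerator:
            genome[atlas.index(r)] = NUM
        for r in self.denominator:
            genome[atlas.index(r)] = DEN
        return genome

    @classmethod
    def decode(cls, genome, atlas: RegionAtlas) -> "CVRSpec":
        """Decode an integer genome; rejects wrong length or invalid codes."""
        genome = np.asarray(genome)
        if genome.shape != (len(atlas),):
            raise ValueError(
                f"genome length {genome.shape} does not match atlas size {len(atlas)}"
            )
        if not np.isin(genome, (NUM, EXC, DEN)).all():
            bad = sorted(set(genome.tolist()) - {NUM, EXC, DEN})
            raise ValueError(f"invalid genome codes: {bad}")
        names = np.asarray(atlas.region_names)
        return cls(
            tuple(names[genome == NUM]),
            tuple(names[genome == DEN]),
        )

    # -- JSON form -----------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {"numerator": list(self.numerator), "denominator": list(self.denominator)}
        )

    @classmethod
    def from_json(cls, text: str) -> "CVRSpec":
        d = json.loads(text)
        return cls(tuple(d["numerator"]), tuple(d["denominator"]))

    def __str__(self) -> str:
        return f"({'+'.join(self.numerator)}) / ({'+'.join(self.denominator)})"


def _series_frame(table: pd.DataFrame, value: np.ndarray, keep: np.ndarray,
                  n_dropped: int, name: str) -> pd.DataFrame:
    cols = ["subject_id", "visit_time"] + [
        c for c in COVARIATE_COLUMNS if c in table.columns
    ]
    out = table.loc[keep, cols].copy()
    out["value"] = value[keep]
    out.attrs["biomarker"] = name
    out.attrs["n_dropped"] = int(n_dropped)
    return out.reset_index(drop=True)


def compute_cvr(table: pd.DataFrame, spec: CVRSpec) -> pd.DataFrame:
    """Biomarker series ``mean(numerator volumes) / mean(denominator volumes)``.

    Rows where any member volume is missing or non-positive are excluded
    with a warning; the count is recorded in ``attrs['n_dropped']``.
    """
    regions = list(spec.numerator) + list(spec.denominator)
    missing = [r for r in regions if r not in table.columns]
    if missing:
        raise KeyError(f"table is missing regions: {missing}")
    vols = table[regions].to_numpy(dtype=float)
    ok = np.isfinite(vols).all(axis=1) & (vols > 0).all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(
            f"compute_cvr: excluded {n_dropped} rows with missing/non-positive "
            f"member volumes", stacklevel=2,
        )
    num = table[list(spec.numerator)].to_numpy(dtype=float).mean(axis=1)
    den = table[list(spec.denominator)].to_numpy(dtype=float).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        value = num / den
    return _series_frame(table, value, ok, n_dropped, str(spec))


STANDARD_BIOMARKERS = (
    "hippocampus_icv",
    "ventricles_icv",
    "whole_brain_icv",
    "entorhinal_icv",
    "ventricles_hippocampus",
)


def column_ratio(
    table: pd.DataFrame, num: str, den: str, name: str | None = None
) -> pd.DataFrame:
    """Simple single-column ratio biomarker (e.g. one region over ICV)."""
    for col in (num, den):
        if col not in table.columns:
            raise KeyError(f"table is missing column {col!r}")
    name = name or f"{num}_{den}"
    a = table[num].to_numpy(dtype=float)
    b = table[den].to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(b) & (a > 0) & (b > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(
            f"{name}: excluded {n_dropped} rows with missing/non-positive "
            f"volumes", stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        value = a / b
    return _series_frame(table, value, ok, n_dropped, name)


def standard_biomarkers(
    table: pd.DataFrame, icv_name: str = "icv"
) -> dict[str, pd.DataFrame]:
    """The traditional biomarker series used as baselines.

    Returns hippocampus/ICV, ventricles/ICV, whole-brain/ICV,
    entorhinal/ICV and ventricles/hippocampus ("ventricles" here is the
    lateral ventricles).
    """
    needed = ["hippocampus", "lateral_ventricle", "whole_brain", "entorhinal",
              icv_name]
    for col in needed:
        if col not in table.columns:
            raise KeyError(f"table is missing column {col!r}")
    return {
        "hippocampus_icv": column_ratio(table, "hippocampus", icv_name,
                                        "hippocampus_icv"),
        "ventricles_icv": column_ratio(table, "lateral_ventricle", icv_name,
                                       "ventricles_icv"),
        "whole_brain_icv": column_ratio(table, "whole_brain", icv_name,
                                        "whole_brain_icv"),
        "entorhinal_icv": column_ratio(table, "entorhinal", icv_name,
                                       "entorhinal_icv"),
        "ventricles_hippocampus": column_ratio(
            table, "lateral_ventricle", "hippocampus", "ventricles_hippocampus"
        ),
    }
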