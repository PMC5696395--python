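"""Compositional fatty-acid (FA) trait tables.

Handles FA nomenclature parsing, rare-FA filtering, renormalization to 100%,
the logit transform for compositional proportions, per-species summary
statistics (means and standard errors used downstream as measurement error),
diet/physiology FA indices, and merging of literature profiles into a
combined species-by-context dataset.

A "FA table" is a pandas DataFrame with metadata columns (``sample_id``,
``species``, ``site``, ``habitat`` and optionally ``n_individuals_pooled``,
``source``) plus one column per FA holding proportions in % of total.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "FADescriptor",
    "SpeciesStats",
    "METADATA_COLUMNS",
    "parse_fa_name",
    "canonical_fa_name",
    "fa_columns",
    "load_classification",
    "filter_rare",
    "renormalize",
    "logit_transform",
    "logit_table",
    "species_stats",
    "compute_indices",
    "combined_fa_subset",
    "merge_literature",
]

METADATA_COLUMNS = ("sample_id", "species", "site", "habitat", "n_individuals_pooled", "source")

#: Absolute bacterial biomarker FAs (synthesized only by prokaryotes).
BACTERIAL_FAS = frozenset(
    {"a15:0", "i15:0", "16:1w5", "16:1w7", "i16:0", "i17:0", "cy17:0", "18:1w7", "cy19:0"}
)
#: Relative biomarker of plant feeding.
PLANT_FA = "18:1w9"
#: Relative biomarker of fungal feeding.
FUNGAL_FA = "18:2w6,9"

_FA_RE = re.compile(
    r"^\s*(?P<prefix>2-?OH|i|a|cy)?[\s-]*"
    r"(?P<carbons>\d+):(?P<db>\d+)"
    r"(?:\s*[wω](?P<omega>\d+(?:\s*,\s*\d+)*))?\s*$"
)

_PREFIX_CANON = {None: "none", "i": "iso", "a": "anteiso", "cy": "cyclo", "2-OH": "2-OH", "2OH": "2-OH"}


@dataclass(frozen=True)
class FADescriptor:
    """Parsed fatty-acid name.

    ``canonical`` is the ASCII form used for all joins, e.g. ``"18:2w6,9"``.
    Branched (iso/anteiso) and cyclopropane FAs carry no double bond and are
    classed as saturated.
    """

    raw_name: str
    carbons: int
    double_bonds: int
    prefix: str  # none | iso | anteiso | cyclo | 2-OH
    omega_positions: tuple[int, ...]
    canonical: str

    @property
    def saturation_class(self) -> str:
        if self.double_bonds == 0:
            return "SFA"
        return "MUFA" if self.double_bonds == 1 else "PUFA"

    @property
    def biomarker_class(self) -> str:
        if self.canonical in BACTERIAL_FAS:
            return "bacterial"
        if self.canonical == PLANT_FA:
            return "plant_relative"
        if self.canonical == FUNGAL_FA:
            return "fungal_relative"
        return "none"


def parse_fa_name(name: str) -> FADescriptor:
    """Parse an FA name like ``16:0``, ``cy17:0``, ``18:2ω6,9`` or ``2-OH 10:0``.

    Unicode ω and ASCII ``w`` are both accepted; the canonical form is ASCII.
    """
    m = _FA_RE.match(str(name))
    if m is None:
        raise ValueError(f"cannot parse fatty-acid name: {name!r}")
    raw_prefix = m.group("prefix")
    if raw_prefix is not None:
        raw_prefix = raw_prefix.replace("2OH", "2-OH")
    prefix = _PREFIX_CANON[raw_prefix]
    carbons = int(m.group("carbons"))
    db = int(m.group("db"))
    omega = tuple(int(x) for x in m.group("omega").split(",")) if m.group("omega") else ()
    if carbons <= 0:
        raise ValueError(f"nonpositive carbon count in {name!r}")
    lead = {"none": "", "iso": "i", "anteiso": "a", "cyclo": "cy", "2-OH": "2-OH "}[prefix]
    canonical = f"{lead}{carbons}:{db}"
    if omega:
        canonical += "w" + ",".join(str(x) for x in omega)
    return FADescriptor(str(name), carbons, db, prefix, omega, canonical)


def canonical_fa_name(name: str) -> str:
    return parse_fa_name(name).canonical


def load_classification(path=None) -> dict[str, FADescriptor]:
    """FA classification table (canonical_name → descriptor).

    Ships as package data; pass ``path`` to override with a user CSV holding
    columns canonical_name, carbons, double_bonds, prefix, biomarker_class.
    Names absent from the table still parse on the fly via the grammar.
    """
    if path is None:
        src = resources.files("phylofa").joinpath("data/fa_classification.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    return {row["canonical_name"]: parse_fa_name(row["canonical_name"]) for _, row in df.iterrows()}


def fa_columns(table: pd.DataFrame) -> list[str]:
    """Columns of a FA table that hold proportions (everything non-metadata)."""
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def filter_rare(
    table: pd.DataFrame, min_pct: float = 1.0, min_occurrence: int = 2
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Drop rare FA columns; returns the filtered table and a drop log.

    A FA is dropped when it is detected (>0) in fewer than ``min_occurrence``
    measurements, or when its mean proportion across all measurements falls
    below ``min_pct`` percent. Both rules are evaluated on the input table
    simultaneously.
    """
    cols = fa_columns(table)
    if table.empty or not cols:
        raise ValueError("empty FA table")
    dropped: dict[str, str] = {}
    for c in cols:
        vals = table[c].to_numpy(dtype=float)
        occ = int((vals > 0).sum())
        mean = float(vals.mean())
        if occ < min_occurrence:
            dropped[c] = f"detected in {occ} < {min_occurrence} measurements"
        elif mean < min_pct:
            dropped[c] = f"mean {mean:.3g}% < {min_pct}%"
    keep = [c for c in table.columns if c not in dropped]
    return table[keep].copy(), dropped


def renormalize(table: pd.DataFrame) -> pd.DataFrame:
    """Rescale each row's FA proportions to sum to 100%. Idempotent."""
    out = table.copy()
    cols = fa_columns(table)
    totals = out[cols].sum(axis=1).to_numpy(dtype=float)
    if np.any(totals <= 0):
        bad = out.index[totals <= 0]
        ids = out.loc[bad, "sample_id"].tolist() if "sample_id" in out else list(bad)
        raise ValueError(f"all-zero FA profile for sample(s): {ids}")
    out[cols] = out[cols].to_numpy(dtype=float) * (100.0 / totals[:, None])
    return out


def logit_transform(p, eps: float = 0.025) -> np.ndarray:
    """Logit of proportions in [0, 1], with boundary remapping.

    If the input column contains any exact 0 or 1, every value is first
    remapped to ``eps + (1 - 2 eps) p`` (the adjusted-logit convention);
    otherwise values are used as-is. Strictly increasing in ``p``.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    if np.any((arr == 0) | (arr == 1)):
        arr = eps + (1 - 2 * eps) * arr
    return np.log(arr / (1 - arr))


def logit_table(table: pd.DataFrame, eps: float = 0.025) -> pd.DataFrame:
    """Column-wise logit of a renormalized %-scale FA table (values /100 first)."""
    out = table.copy()
    for c in fa_columns(table):
        out[c] = logit_transform(out[c].to_numpy(dtype=float) / 100.0, eps=eps)
    return out


@dataclass
class SpeciesStats:
    """Per-species trait means, standard errors of the mean, and counts.

    ``mean`` and ``se`` are species × trait DataFrames in identical layout;
    species with a single measurement get se = 0 (no within-species variance
    estimate exists, so the measurement-error model degrades to the plain one
    for those tips).
    """

    mean: pd.DataFrame
    se: pd.DataFrame
    n_obs: pd.Series


def species_stats(table: pd.DataFrame, value_columns=None) -> SpeciesStats:
    """Mean and SEM per species over all measurements, pooled across site/habitat."""
    cols = value_columns if value_columns is not None else fa_columns(table)
    g = table.groupby("species")[list(cols)]
    mean = g.mean()
    cnt = g.count()
    sd = g.std(ddof=1)
    se = (sd / np.sqrt(cnt.where(cnt > 0))).fillna(0.0)
    n = table.groupby("species").size()
    return SpeciesStats(mean=mean, se=se, n_obs=n)


def compute_indices(profile: pd.Series, descriptors: dict[str, FADescriptor] | None = None) -> pd.Series:
    """Diet and physiology indices of one renormalized FA profile (% scale).

    Returns fa_number, bacterial_sum, pf_ratio, bf_ratio, bp_ratio, UI,
    sfa_sum, mufa_sum, pufa_sum, c20pufa_sum, us_ratio. Ratios with a zero
    denominator are NaN (an explicit undefined marker, never silently 0).
    UI is the abundance-weighted mean double-bond count on unit fractions.
    """
    desc = {}
    for name in profile.index:
        if descriptors and name in descriptors:
            desc[name] = descriptors[name]
        else:
            desc[name] = parse_fa_name(name)
    vals = profile.astype(float)
    total_by_class = {"SFA": 0.0, "MUFA": 0.0, "PUFA": 0.0}
    bacterial = plant = fungal = c20pufa = ui = 0.0
    for name, v in vals.items():
        d = desc[name]
        total_by_class[d.saturation_class] += v
        if d.biomarker_class == "bacterial":
            bacterial += v
        elif d.biomarker_class == "plant_relative":
            plant += v
        elif d.biomarker_class == "fungal_relative":
            fungal += v
        if d.carbons == 20 and d.double_bonds >= 2:
            c20pufa += v
        ui += (v / 100.0) * d.double_bonds

    def ratio(num, den):
        return num / den if den > 0 else np.nan

    sfa, mufa, pufa = total_by_class["SFA"], total_by_class["MUFA"], total_by_class["PUFA"]
    return pd.Series(
        {
            "fa_number": float((vals > 0).sum()),
            "bacterial_sum": bacterial,
            "pf_ratio": ratio(plant, fungal),
            "bf_ratio": ratio(bacterial, fungal),
            "bp_ratio": ratio(bacterial, plant),
            "UI": ui,
            "sfa_sum": sfa,
            "mufa_sum": mufa,
            "pufa_sum": pufa,
            "c20pufa_sum": c20pufa,
            "us_ratio": ratio(mufa + pufa, sfa),
        }
    )


def combined_fa_subset(names) -> list[str]:
    """FA names retained in combined-dataset mode.

    Biomarker FAs, C20 unsaturated FAs, and the saturated FAs 16:0 and 18:0 —
    the set consistently reported across literature sources.
    """
    keep = []
    for name in names:
        d = parse_fa_name(name)
        if (
            d.biomarker_class != "none"
            or (d.carbons == 20 and d.double_bonds >= 1)
            or d.canonical in ("16:0", "18:0")
        ):
            keep.append(name)
    return keep


def merge_literature(
    own: pd.DataFrame,
    literature: list[pd.DataFrame],
    min_pct: float = 1.0,
    min_occurrence: int = 2,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Build the combined species-by-context dataset from own + literature tables.

    Own measurements are averaged per species at each site and habitat;
    each literature table is taken as already compiled per species per
    treatment/site (one row = one data point). Columns are restricted to the
    combined FA subset; FAs missing from a source are imputed as 0 (assumed
    present only in trace amounts). Rare-FA filtering and renormalization are
    then applied across the pooled data points.
    """
    own = own.copy()
    own_mean = (
        own.groupby(["species", "site", "habitat"], as_index=False)[fa_columns(own)].mean()
    )
    own_mean.insert(0, "source", "own")
    frames = [own_mean]
    for k, lit in enumerate(literature):
        lit = lit.copy()
        if "source" not in lit:
            lit.insert(0, "source", f"literature_{k + 1}")
        frames.append(lit)
    merged = pd.concat(frames, ignore_index=True, sort=False)
    meta = [c for c in merged.columns if c in METADATA_COLUMNS]
    fas = [c for c in merged.columns if c not in METADATA_COLUMNS]
    canon = {c: canonical_fa_name(c) for c in fas}
    merged = merged.rename(columns=canon)
    # collapse duplicate canonical columns from heterogeneous sources
    merged = merged.T.groupby(level=0).sum(min_count=1).T if merged.columns.duplicated().any() else merged
    fas = [c for c in merged.columns if c not in METADATA_COLUMNS]
    keep = combined_fa_subset(fas)
    merged = merged[meta + keep]
    merged[keep] = merged[keep].fillna(0.0)
    merged["sample_id"] = [
        f"{r.source}|{r.species}|{r.site}|{r.habitat}" for r in merged.itertuples()
    ]
    filtered, dropped = filter_rare(merged, min_pct=min_pct, min_occurrence=min_occurrence)
    return renormalize(filtered), dropped
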