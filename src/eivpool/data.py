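"""Reading indicator-value tables, occurrence lists and plot designs.

Ellenberg-style indicator values (EIVs) score each plant species on an
ordinal scale for one of five environmental axes: moisture (F), light (L),
soil nutrients (N), soil reaction/pH (R) and salt tolerance (S).  A
resurvey dataset consists of species-occurrence lists per plot per
time-period plus a design table mapping plots to habitats.  This module
assembles those three inputs into the long-format observation table the
hierarchical models consume: one row per scored species occurrence, with
the plot, the 0/1 period indicator and the habitat label attached.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Indicator indices supported, in canonical order.
INDICES = ("F", "L", "N", "R", "S")

#: Valid (inclusive) score range per index.  F runs to 12 in the UK/Irish
#: adaptation; S admits 0 for non-halophytes.
SCORE_BOUNDS = {
    "F": (1, 12),
    "L": (1, 9),
    "N": (1, 9),
    "R": (1, 9),
    "S": (0, 9),
}

_WS = re.compile(r"\s+")


def normalize_species_name(name: str) -> str:
    """Normalize a species name for joining: trim, collapse internal
    whitespace, case-fold.  Original spellings are kept for output."""
    return _WS.sub(" ", str(name).strip()).casefold()


@dataclass
class EIVTable:
    """Species -> per-index indicator scores.

    ``scores`` is indexed by the normalized species name; missing scores
    are NaN.  ``original_names`` maps normalized back to first-seen
    original spelling.  ``missing_counts`` counts rows with a missing
    score per index.
    """

    scores: pd.DataFrame
    original_names: dict[str, str]
    missing_counts: dict[str, int]

    @property
    def indices(self) -> tuple[str, ...]:
        return tuple(self.scores.columns)

    def __len__(self) -> int:
        return len(self.scores)

    def lookup(self, species: str, index: str) -> float:
        """Score of ``species`` on ``index``; NaN if absent or unscored."""
        key = normalize_species_name(species)
        if key not in self.scores.index:
            return float("nan")
        return float(self.scores.at[key, index])


def load_eiv_table(path, index_subset=None) -> EIVTable:
    """Read a ``species,F,L,N,R,S`` CSV into an :class:`EIVTable`.

    Duplicate species rows with conflicting scores are a hard error (the
    message names the species); duplicates that agree are collapsed.
    Scores outside the per-index bounds are a hard error naming the row.
    Empty cells become missing scores and are counted per index.
    """
    indices = tuple(index_subset) if index_subset is not None else INDICES
    for idx in indices:
        if idx not in INDICES:
            raise ValueError(f"unknown EIV index {idx!r}; expected subset of {INDICES}")
    raw = pd.read_csv(path, dtype={"species": str})
    if "species" not in raw.columns:
        raise ValueError("EIV table needs a 'species' column")
    for idx in indices:
        if idx not in raw.columns:
            raise ValueError(f"EIV table is missing a column for index {idx!r}")

    raw = raw.reset_index(drop=True)
    raw["_norm"] = raw["species"].map(normalize_species_name)
    for row_number, row in raw.iterrows():
        for idx in indices:
            val = row[idx]
            if pd.isna(val):
                continue
            lo, hi = SCORE_BOUNDS[idx]
            v = float(val)
            if not (v == int(v) and lo <= v <= hi):
                raise ValueError(
                    f"score {val!r} for index {idx} out of range [{lo}, {hi}] "
                    f"at row {row_number + 2} (species {row['species']!r})"
                )

    # Conflict detection before collapsing duplicates.
    for norm, grp in raw.groupby("_norm"):
        for idx in indices:
            vals = grp[idx].dropna().unique()
            if len(vals) > 1:
                raise ValueError(
                    f"conflicting {idx} scores {sorted(vals)} for species "
                    f"{grp['species'].iloc[0]!r}"
                )

    collapsed = raw.groupby("_norm", sort=True)[list(indices)].first().astype(float)
    originals = raw.groupby("_norm", sort=True)["species"].first().to_dict()
    missing = {idx: int(collapsed[idx].isna().sum()) for idx in indices}
    return EIVTable(scores=collapsed, original_names=originals, missing_counts=missing)


@dataclass
class OccurrenceSet:
    """Presence records: one row per (plot, period, species) triple.

    Duplicated triples are silently deduplicated (presence/absence
    semantics); the dropped count is recorded.
    """

    records: pd.DataFrame  # columns: plot, period, species, species_key
    n_duplicates_dropped: int = 0


def load_occurrences(path) -> OccurrenceSet:
    """Read a ``plot,period,species`` CSV of occurrence records."""
    raw = pd.read_csv(path, dtype={"plot": str, "species": str})
    for col in ("plot", "period", "species"):
        if col not in raw.columns:
            raise ValueError(f"occurrence file needs a {col!r} column")
    if not raw["period"].isin([1, 2]).all():
        bad = sorted(raw.loc[~raw["period"].isin([1, 2]), "period"].unique())
        raise ValueError(f"period must be 1 or 2; found {bad}")
    recs = raw[["plot", "period", "species"]].copy()
    recs["plot"] = recs["plot"].str.strip()
    recs["period"] = recs["period"].astype(int)
    recs["species_key"] = recs["species"].map(normalize_species_name)
    before = len(recs)
    recs = recs.drop_duplicates(subset=["plot", "period", "species_key"])
    recs = recs.reset_index(drop=True)
    return OccurrenceSet(records=recs, n_duplicates_dropped=before - len(recs))


@dataclass
class PlotDesign:
    """Plot id -> habitat label (plus optional area and coordinates)."""

    table: pd.DataFrame  # indexed by plot id; columns habitat[, area_m2, lat, lon]

    @property
    def plots(self) -> list[str]:
        return list(self.table.index)

    def habitat_of(self, plot: str) -> str:
        return str(self.table.at[plot, "habitat"])


def load_plot_design(path) -> PlotDesign:
    """Read a ``plot,habitat[,area_m2,lat,lon]`` CSV design table."""
    raw = pd.read_csv(path, dtype={"plot": str, "habitat": str})
    for col in ("plot", "habitat"):
        if col not in raw.columns:
            raise ValueError(f"design file needs a {col!r} column")
    raw["plot"] = raw["plot"].str.strip()
    if raw["plot"].duplicated().any():
        dup = sorted(raw.loc[raw["plot"].duplicated(), "plot"].unique())
        raise ValueError(f"duplicate plot ids in design table: {dup}")
    if "area_m2" in raw.columns and (raw["area_m2"].dropna() <= 0).any():
        raise ValueError("area_m2 must be positive where present")
    return PlotDesign(table=raw.set_index("plot"))


@dataclass
class ModelFrame:
    """Long-format species-level observations for one EIV index.

    ``df`` has one row per scored occurrence with columns
    ``y`` (the species' indicator score), ``plot``, ``period`` (1 or 2),
    ``habitat`` and ``species``; rows are ordered by (plot, period,
    species).  Integer codes for plots (j) and habitats (k) and the 0/1
    period regressor are derived lazily and cached.
    """

    df: pd.DataFrame
    index: str
    drop_report: dict[str, int] = field(default_factory=dict)
    _codes: dict | None = field(default=None, repr=False, compare=False)

    REQUIRED_COLUMNS = ("y", "plot", "period", "habitat", "species")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"ModelFrame missing columns {missing}")
        if len(self.df) == 0:
            raise ValueError("ModelFrame has no rows")
        if not self.df["period"].isin([1, 2]).all():
            raise ValueError("period must be 1 or 2")
        hab_per_plot = self.df.groupby("plot")["habitat"].nunique()
        if (hab_per_plot > 1).any():
            bad = list(hab_per_plot[hab_per_plot > 1].index)
            raise ValueError(f"plots mapped to multiple habitats: {bad}")
        self.df = self.df.reset_index(drop=True)

    # -- derived design vectors ------------------------------------------
    def _build_codes(self) -> dict:
        if self._codes is None:
            plot_ids = sorted(self.df["plot"].unique())
            habitats = sorted(self.df["habitat"].unique())
            plot_map = {p: j for j, p in enumerate(plot_ids)}
            hab_map = {h: k for k, h in enumerate(habitats)}
            j = self.df["plot"].map(plot_map).to_numpy(dtype=np.int64)
            hab_of_plot = (
                self.df.drop_duplicates("plot").set_index("plot")["habitat"].to_dict()
            )
            k_of_plot = np.array(
                [hab_map[hab_of_plot[p]] for p in plot_ids], dtype=np.int64
            )
            self._codes = {
                "plot_ids": plot_ids,
                "habitats": habitats,
                "plot_map": plot_map,
                "hab_map": hab_map,
                "j": j,
                "k_of_plot": k_of_plot,
            }
        return self._codes

    @property
    def plot_ids(self) -> list[str]:
        return self._build_codes()["plot_ids"]

    @property
    def habitats(self) -> list[str]:
        return self._build_codes()["habitats"]

    @property
    def n_plots(self) -> int:
        return len(self.plot_ids)

    @property
    def n_habitats(self) -> int:
        return len(self.habitats)

    @property
    def y(self) -> np.ndarray:
        return self.df["y"].to_numpy(dtype=float)

    @property
    def x(self) -> np.ndarray:
        """0/1 period regressor: 0 for period 1, 1 for period 2."""
        return (self.df["period"].to_numpy() == 2).astype(float)

    @property
    def j(self) -> np.ndarray:
        """Plot index of each observation (0-based)."""
        return self._build_codes()["j"]

    @property
    def k_of_plot(self) -> np.ndarray:
        """Habitat index of each plot (length ``n_plots``)."""
        return self._build_codes()["k_of_plot"]

    def __len__(self) -> int:
        return len(self.df)

    # -- I/O -------------------------------------------------------------
    def to_csv(self, path) -> None:
        out = self.df[["y", "plot", "period", "habitat", "species"]].copy()
        out["index"] = self.index
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "ModelFrame":
        raw = pd.read_csv(path, dtype={"plot": str, "habitat": str, "species": str})
        idx = raw["index"].unique()
        if len(idx) != 1:
            raise ValueError(f"frame CSV mixes EIV indices: {sorted(idx)}")
        df = raw[["y", "plot", "period", "habitat", "species"]].copy()
        df["period"] = df["period"].astype(int)
        return cls(df=df, index=str(idx[0]))


def build_model_frame(
    occurrences: OccurrenceSet,
    eiv: EIVTable,
    design: PlotDesign,
    index: str,
) -> ModelFrame:
    """Join occurrences to indicator scores and plot design for one index.

    One output row per occurrence whose species carries a score for the
    chosen index.  Occurrences of unscored (or unlisted) species are
    dropped, counted per species in ``frame.drop_report``.  A plot present
    in the occurrences but absent from the design is a hard error, as is
    an empty result.
    """
    if index not in INDICES:
        raise ValueError(f"unknown EIV index {index!r}")
    if index not in eiv.indices:
        raise ValueError(f"EIV table was loaded without index {index!r}")
    recs = occurrences.records
    unknown_plots = sorted(set(recs["plot"]) - set(design.plots))
    if unknown_plots:
        raise ValueError(f"plots missing from design table: {unknown_plots}")

    scores = eiv.scores[index]
    joined = recs.join(scores.rename("y"), on="species_key")
    dropped = joined[joined["y"].isna()]
    drop_report = {
        str(sp): int(n) for sp, n in dropped["species"].value_counts().items()
    }
    kept = joined.dropna(subset=["y"]).copy()
    if len(kept) == 0:
        raise ValueError(f"no occurrence has a score for index {index!r}")
    kept["habitat"] = kept["plot"].map(design.table["habitat"])
    kept = kept.sort_values(["plot", "period", "species_key"], kind="mergesort")
    df = kept[["y", "plot", "period", "habitat", "species"]].reset_index(drop=True)
    df["y"] = df["y"].astype(float)
    return ModelFrame(df=df, index=index, drop_report=drop_report)


def plot_raw_means(frame: ModelFrame) -> pd.DataFrame:
    """Unweighted per-(plot, period) mean score and species count.

    These are the "community mean" point estimates that traditional
    resurvey analyses treat as data.
    """
    out = (
        frame.df.groupby(["plot", "period"], sort=True)["y"]
        .agg(mean="mean", n="count")
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out
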