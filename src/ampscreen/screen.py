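"""Scoring of a 96-well arrayed knockout screen.

Each plate carries gene-target wells plus a fixed control complement:
nine neutral controls (sgRNAs against genes not expressed in the assayed
cells, defining the null phenotype), non-targeting controls, a positive
control for the readout cytokine, essential-gene controls, and column 12
reserved for no-pulse electroporation and media-only ELISA controls.

The per-donor scoring pipeline:

1. background-correct ELISA absorbances with the plate's media-only wells;
   non-positive corrected values are floored to the smallest strictly
   positive corrected value in the donor's dataset;
2. divide by the well's mean luminescence (cell-count proxy, two reads);
3. normalize each treatment replicate to the median cell-count-normalized
   value of the plate's neutral controls (strictly per plate, absorbing
   plate effects) and take log2;
4. average replicate log2 fold-changes per well;
5. call hits: wells (and genes) whose |mean log2FC| is at least twice the
   standard deviation of the neutral-control log2 fold-changes pooled
   across the donor's plates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, InputError, ValidationError

# Well roles
GENE_TARGET = "gene_target"
NEUTRAL_CONTROL = "neutral_control"
NONTARGETING_CONTROL = "nontargeting_control"
POSITIVE_CONTROL = "positive_control"
ESSENTIAL_CONTROL = "essential_control"
NO_PULSE = "no_pulse"
MEDIA_ONLY = "media_only"
EMPTY = "empty"

ALL_ROLES = (GENE_TARGET, NEUTRAL_CONTROL, NONTARGETING_CONTROL,
             POSITIVE_CONTROL, ESSENTIAL_CONTROL, NO_PULSE, MEDIA_ONLY, EMPTY)

#: Roles whose wells receive a phenotype (log2 fold-change).
SCORED_ROLES = frozenset({GENE_TARGET, NEUTRAL_CONTROL, NONTARGETING_CONTROL,
                          POSITIVE_CONTROL, ESSENTIAL_CONTROL})

LAYOUT_COLUMNS = ["plate", "well", "role", "gene"]
MEASUREMENT_COLUMNS = ["plate", "well", "assay", "replicate", "absorbance"]
LUMINESCENCE_COLUMNS = ["plate", "well", "replicate", "rlu"]


@dataclass(frozen=True)
class ScreenOptions:
    """Scoring conventions where the procedure admits more than one reading.

    sd_center
        "zero": hit when |log2FC| >= 2 * neutral SD (threshold about 0);
        "mean": band the threshold about the neutral mean instead.
    floor_scope
        Scope over which the smallest strictly positive background-corrected
        value is found when flooring non-positive values: the donor's whole
        dataset ("dataset") or each plate ("plate").
    gene_aggregation
        How multi-well genes are summarised; "mean" of their well means.
    luminescence_background
        "media_only": subtract the plate's media-only luminescence mean
        before averaging; "none": use raw luminescence.
    """

    sd_center: str = "zero"
    floor_scope: str = "dataset"
    gene_aggregation: str = "mean"
    luminescence_background: str = "media_only"

    def __post_init__(self) -> None:
        if self.sd_center not in ("zero", "mean"):
            raise InputError("sd_center must be 'zero' or 'mean'")
        if self.floor_scope not in ("dataset", "plate"):
            raise InputError("floor_scope must be 'dataset' or 'plate'")
        if self.gene_aggregation != "mean":
            raise InputError("only 'mean' gene aggregation is supported")
        if self.luminescence_background not in ("media_only", "none"):
            raise InputError("luminescence_background must be 'media_only' or 'none'")


@dataclass
class ScreenResult:
    """Scored screen: per-well and per-gene phenotypes plus hit calls."""

    per_well: pd.DataFrame
    per_gene: pd.DataFrame
    neutral_sd: float
    neutral_mean: float
    threshold: float
    n_neutral_wells: int
    control_summary: dict
    options: ScreenOptions

    def report(self) -> dict:
        """JSON-serialisable run report."""
        return {
            "neutral_sd": self.neutral_sd,
            "neutral_mean": self.neutral_mean,
            "threshold": self.threshold,
            "n_neutral_wells": self.n_neutral_wells,
            "n_gene_wells": int((self.per_well["role"] == GENE_TARGET).sum()),
            "n_genes": int(len(self.per_gene)),
            "n_hit_genes": int(self.per_gene["hit"].sum()),
            "control_summary": self.control_summary,
            "options": asdict(self.options),
        }


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputError(f"{what} table is missing columns {missing}")


def validate_screen_tables(layout: pd.DataFrame, measurements: pd.DataFrame,
                           luminescence: pd.DataFrame) -> None:
    """Cross-check layout, measurement and luminescence tables.

    Every measured well must exist in the layout; offending wells are listed
    in the error message.
    """
    _require_columns(layout, LAYOUT_COLUMNS, "layout")
    _require_columns(measurements, MEASUREMENT_COLUMNS, "measurements")
    _require_columns(luminescence, LUMINESCENCE_COLUMNS, "luminescence")
    bad_roles = set(layout["role"]) - set(ALL_ROLES)
    if bad_roles:
        raise InputError(f"unknown well roles {sorted(bad_roles)}")
    layout_wells = set(zip(layout["plate"], layout["well"]))
    for name, df in (("measurements", measurements),
                     ("luminescence", luminescence)):
        extra = sorted(set(zip(df["plate"], df["well"])) - layout_wells)
        if extra:
            raise ValidationError(
                f"{name} reference wells absent from the layout: {extra[:10]}"
                + ("..." if len(extra) > 10 else ""))


def background_correct(measurements: pd.DataFrame, layout: pd.DataFrame,
                       floor_scope: str = "dataset") -> pd.DataFrame:
    """Background-correct ELISA absorbances against media-only wells.

    The mean media-only absorbance of each plate (per assay) is subtracted
    from every sample replicate on that plate. Corrected values <= 0 are
    replaced by the smallest strictly positive corrected value within
    ``floor_scope`` so that downstream log-ratios stay defined.

    Returns the measurements table with a ``bg_corrected`` column.
    """
    roles = layout.set_index(["plate", "well"])["role"]
    df = measurements.copy()
    keys = pd.MultiIndex.from_arrays([df["plate"], df["well"]])
    missing = keys.difference(roles.index)
    if len(missing):
        raise ValidationError(f"measured wells missing from layout: "
                              f"{sorted(set(missing))[:10]}")
    df["role"] = roles.loc[keys].to_numpy()

    out = []
    for (plate, assay), sub in df.groupby(["plate", "assay"], sort=False):
        media = sub.loc[sub["role"] == MEDIA_ONLY, "absorbance"]
        if media.empty:
            raise ConfigurationError(
                f"plate {plate!r}, assay {assay!r}: no media-only wells for "
                "background correction")
        sub = sub.copy()
        sub["bg_corrected"] = sub["absorbance"] - media.mean()
        out.append(sub)
    res = pd.concat(out, ignore_index=True)

    samples = res["role"].isin(SCORED_ROLES) | (res["role"] == NO_PULSE)
    if floor_scope == "dataset":
        groups = [(None, res)]
    else:
        groups = list(res.groupby("plate", sort=False))
    for _, grp in groups:
        mask = samples.loc[grp.index]
        vals = grp.loc[mask, "bg_corrected"]
        nonpos = vals <= 0
        if not nonpos.any():
            continue
        positive = vals[vals > 0]
        if positive.empty:
            raise DataError("all background-corrected absorbances are <= 0")
        res.loc[vals.index[nonpos], "bg_corrected"] = positive.min()
    return res


# Backwards-compatible single-plate entry point.
def background_correct_plate(measurements: pd.DataFrame, layout: pd.DataFrame,
                             ) -> pd.DataFrame:
    """Background-correct one plate (flooring scoped to that plate)."""
    return background_correct(measurements, layout, floor_scope="plate")


def mean_luminescence(luminescence: pd.DataFrame, layout: pd.DataFrame,
                      background: str = "media_only") -> pd.DataFrame:
    """Average luminescence reads per well, optionally background-subtracted.

    Returns columns ``plate, well, mean_rlu``. Background subtraction uses
    the mean luminescence of the plate's media-only wells when present.
    """
    roles = layout.set_index(["plate", "well"])["role"]
    df = luminescence.copy()
    keys = pd.MultiIndex.from_arrays([df["plate"], df["well"]])
    df["role"] = roles.reindex(keys).to_numpy()
    if background == "media_only":
        bg = (df[df["role"] == MEDIA_ONLY].groupby("plate")["rlu"].mean())
        df["rlu"] = df["rlu"] - df["plate"].map(bg).fillna(0.0)
    per_well = (df.groupby(["plate", "well"], as_index=False)["rlu"].mean()
                .rename(columns={"rlu": "mean_rlu"}))
    return per_well


def normalize_to_cell_counts(corrected_absorbance, luminescence_replicates):
    """Divide a background-corrected absorbance by the mean luminescence."""
    lum = np.mean(np.asarray(luminescence_replicates, dtype=float))
    if lum <= 0:
        raise DataError("mean luminescence must be > 0")
    return corrected_absorbance / lum


def compute_log2fc(values: pd.DataFrame, layout: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate log2 fold-change against the plate's neutral median.

    ``values`` must carry columns ``plate, well, assay, replicate,
    normalized`` (cell-count-normalized absorbances). Within each
    (plate, assay, replicate) group, every value is divided by the median
    over the plate's neutral-control wells and log2-transformed.
    Normalization is strictly per plate, absorbing plate effects.
    """
    roles = layout.set_index(["plate", "well"])["role"]
    df = values.copy()
    keys = pd.MultiIndex.from_arrays([df["plate"], df["well"]])
    df["role"] = roles.reindex(keys).to_numpy()

    out = []
    for (plate, assay, rep), sub in df.groupby(["plate", "assay", "replicate"],
                                               sort=False):
        neutral = sub.loc[sub["role"] == NEUTRAL_CONTROL, "normalized"]
        neutral = neutral[neutral > 0]
        if neutral.empty:
            raise ConfigurationError(
                f"plate {plate!r}, assay {assay!r}, replicate {rep!r}: "
                "no valid neutral-control wells to normalize against")
        sub = sub.copy()
        sub["fold_change"] = sub["normalized"] / neutral.median()
        sub["log2_fold_change"] = np.log2(sub["fold_change"])
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def aggregate_replicates(log2fcs) -> float:
    """Average replicate log2 fold-changes (log2FCs are ~normal, so the
    arithmetic mean on the log scale is the natural summary)."""
    arr = np.asarray(log2fcs, dtype=float)
    if arr.size == 0:
        raise InputError("no replicates to aggregate")
    return float(arr.mean())


def call_hits(per_well: pd.DataFrame,
              options: ScreenOptions = ScreenOptions()) -> ScreenResult:
    """Derive the neutral-control threshold and flag hits.

    ``per_well`` needs columns ``plate, well, role, gene,
    mean_log2_fold_change``. The neutral SD is the sample standard
    deviation of all neutral-control well means pooled across plates;
    the hit threshold is twice that, applied to |mean log2FC| about 0
    (or about the neutral mean with ``sd_center='mean'``). The boundary
    is inclusive.
    """
    scored = per_well[per_well["role"].isin(SCORED_ROLES)].copy()
    neutral = scored.loc[scored["role"] == NEUTRAL_CONTROL,
                         "mean_log2_fold_change"].dropna()
    if len(neutral) < 2:
        raise ConfigurationError("need >= 2 neutral-control wells to form "
                                 "a hit threshold")
    neutral_sd = float(neutral.std(ddof=1))
    neutral_mean = float(neutral.mean())
    threshold = 2.0 * neutral_sd
    center = 0.0 if options.sd_center == "zero" else neutral_mean

    def _is_hit(values: pd.Series) -> pd.Series:
        # inclusive boundary; deviations at float-rounding scale (far below
        # any biological phenotype) never count as hits
        dev = (values - center).abs()
        return (dev >= threshold) & (dev > 1e-9)

    scored["hit"] = _is_hit(scored["mean_log2_fold_change"])

    genes = scored[scored["role"] == GENE_TARGET]
    per_gene = (genes.groupby("gene", as_index=False)
                .agg(mean_log2_fold_change=("mean_log2_fold_change", "mean"),
                     n_wells=("well", "size")))
    per_gene["hit"] = _is_hit(per_gene["mean_log2_fold_change"])
    per_gene["threshold"] = threshold

    control_summary = {}
    for role in (NEUTRAL_CONTROL, NONTARGETING_CONTROL, POSITIVE_CONTROL,
                 ESSENTIAL_CONTROL):
        sub = scored[scored["role"] == role]
        control_summary[role] = {"n_wells": int(len(sub)),
                                 "n_hit_wells": int(sub["hit"].sum())}
    return ScreenResult(scored.reset_index(drop=True), per_gene, neutral_sd,
                        neutral_mean, threshold, int(len(neutral)),
                        control_summary, options)


def score_screen(layout: pd.DataFrame, measurements: pd.DataFrame,
                 luminescence: pd.DataFrame, assay: str | None = None,
                 options: ScreenOptions = ScreenOptions()) -> ScreenResult:
    """Run the full scoring pipeline for one donor's plate set.

    ``assay`` selects one readout (e.g. "TNFa") when the measurements table
    holds several; by default a single-assay table is required.
    """
    validate_screen_tables(layout, measurements, luminescence)
    assays = sorted(set(measurements["assay"]))
    if assay is None:
        if len(assays) != 1:
            raise InputError(f"measurements hold several assays {assays}; "
                             "pass assay=...")
        assay = assays[0]
    meas = measurements[measurements["assay"] == assay]
    if meas.empty:
        raise InputError(f"no measurements for assay {assay!r}")

    corrected = background_correct(meas, layout, options.floor_scope)
    lum = mean_luminescence(luminescence, layout,
                            options.luminescence_background)
    merged = corrected.merge(lum, on=["plate", "well"], how="left",
                             validate="many_to_one")
    scored_mask = merged["role"].isin(SCORED_ROLES)
    no_lum = scored_mask & merged["mean_rlu"].isna()
    if no_lum.any():
        bad = merged.loc[no_lum, ["plate", "well"]].drop_duplicates()
        raise ValidationError("scored wells without luminescence: "
                              f"{list(bad.itertuples(index=False, name=None))[:10]}")
    merged = merged[scored_mask].copy()
    if (merged["mean_rlu"] <= 0).any():
        raise DataError("non-positive mean luminescence in scored wells")
    merged["normalized"] = merged["bg_corrected"] / merged["mean_rlu"]

    l2fc = compute_log2fc(merged, layout)
    per_well = (l2fc.groupby(["plate", "well", "role"], as_index=False)
                .agg(mean_log2_fold_change=("log2_fold_change", "mean"),
                     n_replicates=("log2_fold_change", "size")))
    gene_map = layout.set_index(["plate", "well"])["gene"]
    keys = pd.MultiIndex.from_arrays([per_well["plate"], per_well["well"]])
    per_well["gene"] = gene_map.reindex(keys).to_numpy()
    return call_hits(per_well, options)
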