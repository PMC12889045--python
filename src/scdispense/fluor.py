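"""Plate-reader fluorescence normalization, thresholding and well calling.

The two-fluorophore dispensing assay reads each well in a green (sfGFP-type)
and a red (mApple-type) channel. Readings are first normalized per plate and
channel by the mean intensity of the non-template control (NTC) wells, then
min-max standardized per channel across the whole experiment to account for
different brightness between the two fluorophores. A well is called positive
in a channel when its normalized reading exceeds the background mean plus two
background standard deviations; the four-way call (empty / green-only /
red-only / dual) follows from the two per-channel calls.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .layout import PlateLayout, default_layout

WELL_CLASSES = ("empty", "green_only", "red_only", "dual")


@dataclass(frozen=True)
class FluorescenceThresholds:
    """Per-channel positive thresholds on the normalized scale.

    ``threshold = bg_mean + 2 * bg_sd`` computed over background wells;
    the SD uses the n-1 denominator.
    """

    bg_mean: dict[str, float]
    bg_sd: dict[str, float]

    @property
    def threshold(self) -> dict[str, float]:
        return {c: self.bg_mean[c] + 2.0 * self.bg_sd[c] for c in self.bg_mean}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["threshold"] = self.threshold
        return d


@dataclass(frozen=True)
class SignalCounts:
    """Tallies of dispensed-well classes for an experiment."""

    n_green_only: int = 0
    n_red_only: int = 0
    n_dual: int = 0
    n_empty: int = 0

    def __post_init__(self):
        if min(self.n_green_only, self.n_red_only, self.n_dual, self.n_empty) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def n_nonempty(self) -> int:
        return self.n_green_only + self.n_red_only + self.n_dual

    @property
    def n_total(self) -> int:
        return self.n_nonempty + self.n_empty

    def to_dict(self) -> dict:
        return {
            "n_green_only": self.n_green_only,
            "n_red_only": self.n_red_only,
            "n_dual": self.n_dual,
            "n_empty": self.n_empty,
            "n_nonempty": self.n_nonempty,
        }


def _require_columns(readings: pd.DataFrame) -> None:
    needed = {"plate_id", "well", "channel", "intensity"}
    missing = needed - set(readings.columns)
    if missing:
        raise ValueError(f"readings table missing columns: {sorted(missing)}")


def normalize(
    readings: pd.DataFrame,
    layout: PlateLayout | None = None,
    per_plate_minmax: bool = False,
) -> pd.DataFrame:
    """Normalize raw plate-reader intensities.

    Step 1 divides each reading by the mean NTC intensity of its plate and
    channel; step 2 min-max standardizes each channel to [0, 1] across all
    plates of the experiment (or per plate with ``per_plate_minmax``).

    Returns a copy of ``readings`` with a ``norm`` column added.
    """
    _require_columns(readings)
    layout = layout or default_layout()
    ntc_wells = set(layout.ntc_wells)
    if not ntc_wells:
        raise ValueError("layout has no NTC wells; normalization undefined")

    out = readings.copy()
    ntc = out[out["well"].isin(ntc_wells)]
    if ntc.empty:
        raise ValueError("no NTC readings found; check layout and plate ids")
    ntc_means = ntc.groupby(["plate_id", "channel"])["intensity"].mean()
    missing = (
        set(map(tuple, out[["plate_id", "channel"]].drop_duplicates().values))
        - set(ntc_means.index)
    )
    if missing:
        raise ValueError(f"plates without NTC readings: {sorted(missing)}")

    keys = pd.MultiIndex.from_frame(out[["plate_id", "channel"]])
    out["norm"] = out["intensity"].to_numpy() / ntc_means.reindex(keys).to_numpy()

    group = ["channel", "plate_id"] if per_plate_minmax else ["channel"]
    lo = out.groupby(group)["norm"].transform("min")
    hi = out.groupby(group)["norm"].transform("max")
    span = hi - lo
    if (span <= 0).any():
        bad = out.loc[span <= 0, group].drop_duplicates()
        raise ValueError(f"constant channel, min-max scale degenerate: {bad.to_dict('records')}")
    out["norm"] = (out["norm"] - lo) / span
    return out


def compute_thresholds(
    normalized: pd.DataFrame,
    layout: PlateLayout | None = None,
    background_roles: tuple[str, ...] = ("ntc",),
) -> FluorescenceThresholds:
    """Positive threshold per channel: background mean + 2 background SDs.

    ``background_roles`` selects the wells pooled as background — the default
    is the NTC wells; pass ``("ntc", "blank")`` to pool blanks in as well.
    """
    layout = layout or default_layout()
    if "norm" not in normalized.columns:
        raise ValueError("expected normalized readings (run normalize first)")
    bg_wells = set(layout.background_wells(background_roles))
    bg = normalized[normalized["well"].isin(bg_wells)]
    bg_mean: dict[str, float] = {}
    bg_sd: dict[str, float] = {}
    for channel, sub in bg.groupby("channel"):
        if len(sub) < 2:
            raise ValueError(
                f"need >= 2 background wells per channel to compute an SD; "
                f"channel {channel!r} has {len(sub)}"
            )
        bg_mean[channel] = float(sub["norm"].mean())
        bg_sd[channel] = float(sub["norm"].std(ddof=1))
    if not bg_mean:
        raise ValueError("no background readings found")
    return FluorescenceThresholds(bg_mean=bg_mean, bg_sd=bg_sd)


def classify_wells(
    normalized: pd.DataFrame,
    thresholds: FluorescenceThresholds,
    layout: PlateLayout | None = None,
) -> pd.DataFrame:
    """Call each dispensed well empty / green_only / red_only / dual.

    A channel is positive when its normalized reading is strictly greater
    than the channel threshold (ties count as negative). Returns one row per
    dispensed well with columns ``plate_id, well, green_norm, red_norm,
    well_class``.
    """
    layout = layout or default_layout()
    dispensed = set(layout.dispensed_wells)
    sub = normalized[normalized["well"].isin(dispensed)]
    wide = sub.pivot_table(
        index=["plate_id", "well"], columns="channel", values="norm", aggfunc="first"
    )
    for channel in ("green", "red"):
        if channel not in wide.columns or wide[channel].isna().any():
            bad = (
                wide.index[wide[channel].isna()].tolist()
                if channel in wide.columns
                else "all"
            )
            raise ValueError(f"dispensed wells missing {channel} channel: {bad}")
    expected = len(dispensed) * normalized["plate_id"].nunique()
    if len(wide) != expected:
        raise ValueError(
            f"expected {expected} dispensed wells across plates, found {len(wide)}"
        )

    thr = thresholds.threshold
    green_pos = wide["green"].to_numpy() > thr["green"]
    red_pos = wide["red"].to_numpy() > thr["red"]
    cls = np.where(
        green_pos & red_pos,
        "dual",
        np.where(green_pos, "green_only", np.where(red_pos, "red_only", "empty")),
    )
    out = wide.reset_index().rename(columns={"green": "green_norm", "red": "red_norm"})
    out.columns.name = None
    out["well_class"] = cls
    return out[["plate_id", "well", "green_norm", "red_norm", "well_class"]]


def tally(classes) -> SignalCounts:
    """Count well classes into a :class:`SignalCounts`.

    Accepts the frame returned by :func:`classify_wells` or any iterable of
    class labels.
    """
    if isinstance(classes, pd.DataFrame):
        labels = classes["well_class"]
    else:
        labels = pd.Series(list(classes), dtype=object)
    unknown = set(labels) - set(WELL_CLASSES)
    if unknown:
        raise ValueError(f"unknown well classes: {sorted(unknown)}")
    counts = labels.value_counts()
    return SignalCounts(
        n_green_only=int(counts.get("green_only", 0)),
        n_red_only=int(counts.get("red_only", 0)),
        n_dual=int(counts.get("dual", 0)),
        n_empty=int(counts.get("empty", 0)),
    )


def classify_experiment(
    readings: pd.DataFrame,
    layout: PlateLayout | None = None,
    background_roles: tuple[str, ...] = ("ntc",),
    per_plate_minmax: bool = False,
) -> tuple[pd.DataFrame, FluorescenceThresholds, SignalCounts]:
    """Full pipeline: normalize -> thresholds -> classify -> tally."""
    layout = layout or default_layout()
    normalized = normalize(readings, layout, per_plate_minmax=per_plate_minmax)
    thresholds = compute_thresholds(normalized, layout, background_roles)
    classified = classify_wells(normalized, thresholds, layout)
    return classified, thresholds, tally(classified)
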