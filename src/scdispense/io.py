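"""Readers and writers for the pipeline's tabular formats.

Formats
-------
plate-reader CSV (long)
    ``plate_id, well, channel, intensity`` — one row per well per channel.
plate-reader CSV (wide, Tecan-style)
    ``plate_id, well, green, red`` — one row per well, two intensity
    columns. The dialect is auto-detected from the header.
truth sidecar TSV
    ``plate_id, well, n_cells, n_green, n_red``.
plate-map YAML/JSON
    mapping well id -> role; defaults to the standard dispensing layout.
ANI TSV (long)
    ``query, reference, ani_pct, aligned_fraction_pct``.
quality TSV
    ``genome_id, completeness, contamination``.
reference-ANI TSV
    ``genome_id, ref_id, ani_pct, aligned_fraction_pct``.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .layout import PlateLayout, default_layout, normalize_well_id

LONG_COLUMNS = ["plate_id", "well", "channel", "intensity"]


def write_plate_table(readings: pd.DataFrame, path: str | Path) -> None:
    """Write a long plate-reader CSV."""
    readings[LONG_COLUMNS].to_csv(path, index=False)


def read_plate_table(
    path: str | Path,
    layout: PlateLayout | None = None,
    dialect: str = "auto",
) -> pd.DataFrame:
    """Read a plate-reader CSV in either the long or wide dialect.

    Well ids are normalized to the A1..H12 form. Validates that every
    dispensed well of every plate is present in both channels; missing wells
    are listed in the error.
    """
    layout = layout or default_layout()
    df = pd.read_csv(path)
    cols = set(df.columns)
    if dialect == "auto":
        if {"channel", "intensity"} <= cols:
            dialect = "long"
        elif {"green", "red"} <= cols:
            dialect = "wide"
        else:
            raise ValueError(
                f"unrecognized plate-table header {sorted(cols)}; expected "
                f"long (channel,intensity) or wide (green,red) dialect"
            )
    if dialect == "wide":
        missing = {"plate_id", "well", "green", "red"} - cols
        if missing:
            raise ValueError(f"wide plate table missing columns: {sorted(missing)}")
        df = df.melt(
            id_vars=["plate_id", "well"],
            value_vars=["green", "red"],
            var_name="channel",
            value_name="intensity",
        )
    else:
        missing = set(LONG_COLUMNS) - cols
        if missing:
            raise ValueError(f"long plate table missing columns: {sorted(missing)}")
    df = df[LONG_COLUMNS].copy()
    df["well"] = df["well"].map(normalize_well_id)
    if (df["intensity"] < 0).any():
        raise ValueError("negative intensities in plate table")

    expected = {
        (p, w, c)
        for p in df["plate_id"].unique()
        for w in layout.dispensed_wells
        for c in ("green", "red")
    }
    present = set(map(tuple, df[["plate_id", "well", "channel"]].values))
    absent = sorted(expected - present)
    if absent:
        raise ValueError(
            f"{len(absent)} dispensed well readings missing, e.g. {absent[:6]}"
        )
    return df


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_layout(layout: PlateLayout, path: str | Path) -> None:
    """Write a plate-map YAML (role per well)."""
    doc = {"n_rows": layout.n_rows, "n_cols": layout.n_cols, "roles": dict(layout.role_map)}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_layout(path: str | Path) -> PlateLayout:
    """Read a plate-map YAML/JSON; missing file fields fall back to the
    standard layout geometry."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    roles = {normalize_well_id(w): r for w, r in doc["roles"].items()}
    return PlateLayout(
        n_rows=int(doc.get("n_rows", 8)), n_cols=int(doc.get("n_cols", 12)), role_map=roles
    )


def _check_percent(df: pd.DataFrame, col: str, what: str) -> None:
    bad = df[(df[col] < 0) | (df[col] > 100)]
    if len(bad):
        raise ValueError(f"{what}: {col} outside [0, 100] in rows {bad.index.tolist()[:5]}")


def write_ani_table(ani: pd.DataFrame, aligned_fraction: pd.DataFrame, path: str | Path) -> None:
    """Write a long ANI TSV from square matrices (all ordered pairs)."""
    rows = []
    for q in ani.index:
        for r in ani.columns:
            if q == r:
                continue
            rows.append(
                {
                    "query": q,
                    "reference": r,
                    "ani_pct": ani.loc[q, r],
                    "aligned_fraction_pct": aligned_fraction.loc[q, r],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ani_table(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a long ANI TSV into square (ani, aligned_fraction) matrices.

    Duplicate (query, reference) rows resolve last-wins with a warning.
    The diagonal is set to ANI 100 / aligned fraction 100.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"query", "reference", "ani_pct", "aligned_fraction_pct"} - set(df.columns)
    if missing:
        raise ValueError(f"ANI table missing columns: {sorted(missing)}")
    _check_percent(df, "ani_pct", "ANI table")
    _check_percent(df, "aligned_fraction_pct", "ANI table")
    dup = df.duplicated(subset=["query", "reference"], keep="last")
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicate (query, reference) ANI rows; keeping the last",
            stacklevel=2,
        )
        df = df[~dup]
    ids = sorted(set(df["query"]) | set(df["reference"]))
    ani = pd.DataFrame(np.nan, index=ids, columns=ids)
    af = pd.DataFrame(np.nan, index=ids, columns=ids)
    for row in df.itertuples(index=False):
        ani.loc[row.query, row.reference] = row.ani_pct
        af.loc[row.query, row.reference] = row.aligned_fraction_pct
    # fill the missing direction symmetrically before downstream averaging
    ani = ani.where(~ani.isna(), ani.T)
    af = af.where(~af.isna(), af.T)
    np.fill_diagonal(ani.values, 100.0)
    np.fill_diagonal(af.values, 100.0)
    return ani, af


def read_quality_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"genome_id", "completeness", "contamination"} - set(df.columns)
    if missing:
        raise ValueError(f"quality table missing columns: {sorted(missing)}")
    _check_percent(df, "completeness", "quality table")
    if (df["contamination"] < 0).any():
        raise ValueError("negative contamination values")
    return df


def read_reference_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"genome_id", "ref_id", "ani_pct", "aligned_fraction_pct"} - set(df.columns)
    if missing:
        raise ValueError(f"reference-ANI table missing columns: {sorted(missing)}")
    _check_percent(df, "ani_pct", "reference table")
    _check_percent(df, "aligned_fraction_pct", "reference table")
    return df


def read_ani_tables(
    ani_path: str | Path,
    quality_path: str | Path | None = None,
    refs_path: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None, pd.DataFrame | None]:
    """Read the clustering inputs and cross-validate genome ids.

    Returns ``(ani, aligned_fraction, quality, references)``; genomes present
    in the ANI matrix but absent from the quality table pass through with a
    warning.
    """
    ani, af = read_ani_table(ani_path)
    quality = read_quality_table(quality_path) if quality_path else None
    refs = read_reference_table(refs_path) if refs_path else None
    if quality is not None:
        unknown = set(ani.index) - set(quality["genome_id"])
        if unknown:
            warnings.warn(
                f"{len(unknown)} genomes in ANI matrix without quality rows "
                f"(pass through unfiltered): {sorted(unknown)[:5]}",
                stacklevel=2,
            )
    return ani, af, quality, refs


def read_wash_series_table(path: str | Path):
    """Read a wash-series CSV (``sample_id, original_rate, wash_index,
    leftover_rate``) into one :class:`~scdispense.simulate.WashSeries` per
    sample."""
    from .simulate import WashSeries

    df = pd.read_csv(path)
    missing = {"sample_id", "original_rate", "wash_index", "leftover_rate"} - set(df.columns)
    if missing:
        raise ValueError(f"wash series table missing columns: {sorted(missing)}")
    out = []
    for sample_id, sub in df.groupby("sample_id"):
        sub = sub.sort_values("wash_index")
        expected = list(range(1, len(sub) + 1))
        if sub["wash_index"].tolist() != expected:
            raise ValueError(
                f"sample {sample_id}: wash_index must be 1..n without gaps"
            )
        originals = sub["original_rate"].unique()
        if len(originals) != 1:
            raise ValueError(f"sample {sample_id}: original_rate must be constant")
        out.append(
            WashSeries(
                original_rate=float(originals[0]),
                leftover_rates=tuple(sub["leftover_rate"].astype(float)),
                sample_id=str(sample_id),
            )
        )
    return out


def _jsonable(obj):
    """Recursively convert numpy scalars and NaN to JSON-safe values."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")
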