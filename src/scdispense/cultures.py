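"""Culture-success summaries and mock-community abundance shifts.

A dispensing run fills 88 wells of a 96-well plate; its culture success rate
is the percentage of those wells that grew a viable culture. Runs are keyed
by sample, dilution (1:10^k), enrichment time (hours) and medium, and
summarized as a sample x dilution x enrichment grid.

For mock-community experiments, per-species relative abundances before and
after dispensing are compared replicate-by-replicate; the shift is the mean
post-minus-pre difference in percentage points with a one-sample t-test of
the replicate deltas against zero (a paired-permutation variant is offered;
neither is claimed to reproduce any particular published p-value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_WELLS_PER_PLATE = 88


def success_rate(n_viable: int, n_dispensed: int = DEFAULT_WELLS_PER_PLATE) -> float:
    """Culture success rate, percent of dispensed wells that grew.

    Full-precision value; round to one decimal only for display.
    """
    if n_dispensed <= 0:
        raise ValueError("n_dispensed must be > 0")
    if not (0 <= n_viable <= n_dispensed):
        raise ValueError(f"n_viable must be in [0, {n_dispensed}], got {n_viable}")
    return 100.0 * n_viable / n_dispensed


@dataclass(frozen=True)
class CultureRateRecord:
    """Viable-well count for one dispensing run."""

    sample_id: str
    dilution_exponent: int
    enrichment_h: float
    medium: str
    n_viable: int
    n_dispensed: int = DEFAULT_WELLS_PER_PLATE

    def __post_init__(self):
        if not (0 <= self.n_viable <= self.n_dispensed):
            raise ValueError("0 <= n_viable <= n_dispensed required")

    @property
    def rate(self) -> float:
        return success_rate(self.n_viable, self.n_dispensed)


def summarize_runs(records: list[CultureRateRecord] | pd.DataFrame) -> pd.DataFrame:
    """Pivot culture success rates into a sample x dilution x enrichment grid.

    Returns a frame indexed by (sample_id, dilution_exponent, medium) with one
    column per enrichment time holding the rate in percent (NaN where a
    combination was not run), plus ``total_viable`` per row and a ``TOTAL``
    row carrying the grand total of viable cultures.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        needed = {"sample_id", "dilution_exponent", "enrichment_h", "medium", "n_viable"}
        missing = needed - set(df.columns)
        if missing:
            raise ValueError(f"records table missing columns: {sorted(missing)}")
        if "n_dispensed" not in df.columns:
            df["n_dispensed"] = DEFAULT_WELLS_PER_PLATE
    else:
        if not records:
            return pd.DataFrame()
        df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        return pd.DataFrame()

    key = ["sample_id", "dilution_exponent", "enrichment_h", "medium"]
    if df.duplicated(subset=key).any():
        dupes = df.loc[df.duplicated(subset=key), key].to_dict("records")
        raise ValueError(f"duplicate run keys: {dupes}")

    df["rate"] = 100.0 * df["n_viable"] / df["n_dispensed"]
    grid = df.pivot_table(
        index=["sample_id", "dilution_exponent", "medium"],
        columns="enrichment_h",
        values="rate",
        aggfunc="first",
    )
    grid.columns = [f"{h:g}h" for h in grid.columns]
    totals = df.groupby(["sample_id", "dilution_exponent", "medium"])["n_viable"].sum()
    grid["total_viable"] = totals
    total_row = pd.DataFrame(
        {c: [np.nan] for c in grid.columns}, index=pd.MultiIndex.from_tuples(
            [("TOTAL", 0, "")], names=grid.index.names
        )
    )
    total_row["total_viable"] = df["n_viable"].sum()
    return pd.concat([grid, total_row])


def total_cultures(records: list[CultureRateRecord] | pd.DataFrame) -> int:
    """Grand total of viable cultures across runs."""
    if isinstance(records, pd.DataFrame):
        return int(records["n_viable"].sum())
    return int(sum(r.n_viable for r in records))


@dataclass(frozen=True)
class AbundanceShiftResults:
    """Per-species pre-to-post abundance shifts with a paired test.

    ``table`` has one row per species with the mean delta in percentage
    points and the test p-value.
    """

    table: pd.DataFrame
    n_replicates: int
    test: str

    def summary(self) -> str:
        lines = [
            f"Mock-community abundance shift ({self.test}, n = {self.n_replicates})",
            "=" * 56,
        ]
        for _, row in self.table.iterrows():
            star = " *" if row["p_value"] < 0.05 else ""
            lines.append(
                f"{row['species']:<28s} {row['mean_delta_pp']:+7.1f} pp"
                f"  (p = {row['p_value']:.3f}){star}"
            )
        return "\n".join(lines)


class AbundanceShiftModel:
    """Paired pre/post comparison of mock-community relative abundances.

    Parameters
    ----------
    table
        Tidy frame with columns ``species, replicate, condition, abundance``
        where condition is ``pre`` or ``post`` and each (replicate,
        condition) profile sums to 1.
    """

    def __init__(self, table: pd.DataFrame):
        needed = {"species", "replicate", "condition", "abundance"}
        missing = needed - set(table.columns)
        if missing:
            raise ValueError(f"abundance table missing columns: {sorted(missing)}")
        bad = set(table["condition"]) - {"pre", "post"}
        if bad:
            raise ValueError(f"condition must be pre/post, got {sorted(bad)}")
        sums = table.groupby(["replicate", "condition"])["abundance"].sum()
        off = sums[(sums - 1.0).abs() > 1e-6]
        if len(off):
            raise ValueError(
                f"relative-abundance profiles must sum to 1: {off.to_dict()}"
            )
        pre_reps = set(table.loc[table["condition"] == "pre", "replicate"])
        post_reps = set(table.loc[table["condition"] == "post", "replicate"])
        if pre_reps != post_reps:
            raise ValueError(
                f"mismatched replicate sets: pre={sorted(pre_reps)} post={sorted(post_reps)}"
            )
        if len(pre_reps) < 2:
            raise ValueError("need >= 2 replicates with both conditions")
        self.table = table
        self.replicates = sorted(pre_reps)

    def fit(
        self, test: str = "ttest", n_permutations: int = 9999, seed: int | None = None
    ) -> AbundanceShiftResults:
        """Mean per-species delta (pp) and two-sided test of delta == 0.

        ``test`` is ``"ttest"`` (one-sample t on replicate deltas) or
        ``"permutation"`` (paired sign-flip permutation of the deltas).
        Zero-variance deltas at zero mean give p = 1 by convention.
        """
        wide = self.table.pivot_table(
            index=["species", "replicate"], columns="condition", values="abundance",
            aggfunc="first",
        )
        wide["delta"] = wide["post"] - wide["pre"]
        rows = []
        rng = np.random.default_rng(seed)
        for species, sub in wide.groupby(level="species", sort=False):
            deltas = sub["delta"].to_numpy()
            mean_pp = 100.0 * float(np.mean(deltas))
            if np.ptp(deltas) == 0.0:
                # zero variance: p = 1 at zero mean, else the shift is exact
                p = 1.0 if deltas[0] == 0.0 else 0.0
            elif test == "ttest":
                p = float(stats.ttest_1samp(deltas, 0.0).pvalue)
            elif test == "permutation":
                obs = abs(np.mean(deltas))
                signs = rng.choice([-1.0, 1.0], size=(n_permutations, len(deltas)))
                perm = np.abs((signs * deltas).mean(axis=1))
                p = float((1 + np.sum(perm >= obs - 1e-15)) / (1 + n_permutations))
            else:
                raise ValueError(f"unknown test {test!r}")
            rows.append({"species": species, "mean_delta_pp": mean_pp, "p_value": p})
        out = pd.DataFrame(rows)
        return AbundanceShiftResults(
            table=out, n_replicates=len(self.replicates), test=test
        )


def abundance_shift(table: pd.DataFrame, test: str = "ttest", seed: int | None = None) -> pd.DataFrame:
    """Per-species mean pre-to-post delta (pp) and p-value (shorthand)."""
    return AbundanceShiftModel(table).fit(test=test, seed=seed).table
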