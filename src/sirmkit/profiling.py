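"""GC-MS profiling normalization and group summaries.

Raw quantitation-ion intensities are normalized to the internal standard and
to sample protein; missing cells are back-filled with a per-metabolite floor
so every metabolite has a value in every sample; group means are expressed
as percentages of a reference cell line with delta-method SEM, matching the
percent-of-control convention used for pool-size comparisons.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "STUDY_LINES",
    "normalize_abundance",
    "normalize_table",
    "backfill_matrix",
    "percent_of_reference",
]

STUDY_LINES = ("NSC-34", "WT-NSC", "G93A-NSC")

logger = logging.getLogger(__name__)


def normalize_abundance(raw: float, is_intensity: float, protein_mg: float) -> float:
    """raw / internal standard / protein."""
    if is_intensity <= 0:
        raise ValueError("internal-standard intensity must be positive")
    if protein_mg <= 0:
        raise ValueError("protein must be positive")
    return raw / is_intensity / protein_mg


def normalize_table(df: pd.DataFrame) -> pd.DataFrame:
    """Normalize a profiling table (sample_id, metabolite,
    quant_ion_intensity, is_intensity, protein_mg) to a long StudyTable with
    kind='pool'."""
    required = {"sample_id", "metabolite", "quant_ion_intensity", "is_intensity", "protein_mg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profiling table missing columns: {sorted(missing)}")
    out = df.copy()
    if (out["is_intensity"] <= 0).any() or (out["protein_mg"] <= 0).any():
        raise ValueError("internal standard and protein must be positive")
    out["value"] = (
        out["quant_ion_intensity"] / out["is_intensity"] / out["protein_mg"]
    )
    out["kind"] = "pool"
    out["units"] = "au/mg"
    return out.drop(columns=["quant_ion_intensity", "is_intensity", "protein_mg"])


def backfill_matrix(table: pd.DataFrame, floor_fraction: float = 0.5) -> pd.DataFrame:
    """Fill missing (sample, metabolite) cells with a per-metabolite floor.

    The floor is ``floor_fraction`` (default half) of the minimum observed
    value for that metabolite.  A metabolite with no observed value at all is
    an error.  Filled cells are logged and flagged in a ``backfilled``
    column.
    """
    df = table.copy()
    samples = df["sample_id"].unique()
    full = pd.MultiIndex.from_product(
        [samples, df["metabolite"].unique()], names=["sample_id", "metabolite"]
    )
    wide = df.set_index(["sample_id", "metabolite"])["value"].reindex(full)
    missing = wide[wide.isna()]
    if missing.empty and not df["value"].isna().any():
        df["backfilled"] = False
        return df
    floors = df.groupby("metabolite")["value"].min() * floor_fraction
    dead = floors[floors.isna()].index.tolist()
    if dead:
        raise ValueError(f"metabolites with no observed value at all: {dead}")
    meta_cols = [c for c in df.columns if c not in ("sample_id", "metabolite", "value")]
    # sample-level metadata (cell line etc.) comes from the sample being filled
    sample_meta = df.drop_duplicates("sample_id").set_index("sample_id")[meta_cols]
    rows = []
    for (sample, met), _ in missing.items():
        logger.info("back-filling %s / %s with %.4g", sample, met, floors[met])
        row = {"sample_id": sample, "metabolite": met, "value": floors[met]}
        for col in meta_cols:
            row[col] = sample_meta.loc[sample, col]
        rows.append(row)
    df = df.dropna(subset=["value"]).copy()
    df["backfilled"] = False
    add = pd.DataFrame(rows)
    add["backfilled"] = True
    return pd.concat([df, add], ignore_index=True)


def percent_of_reference(
    table: pd.DataFrame, reference: str = "NSC-34", line_col: str = "line"
) -> pd.DataFrame:
    """Per-metabolite group means as percent of the reference line.

    Returns one row per (metabolite, line) with ``percent`` =
    mean(line)/mean(reference)*100 and ``sem`` propagated by the delta
    method for the ratio of two independent means.
    """
    if line_col not in table.columns:
        raise ValueError(f"table has no {line_col!r} column")
    if reference not in set(table[line_col]):
        raise ValueError(f"reference line {reference!r} not in table")
    stats = (
        table.groupby(["metabolite", line_col])["value"]
        .agg(["mean", "sem", "count"])
        .reset_index()
    )
    ref = stats[stats[line_col] == reference].set_index("metabolite")
    if (ref["count"] < 2).any():
        raise ValueError("reference line needs >= 2 samples per metabolite")
    rows = []
    for _, r in stats.iterrows():
        met = r["metabolite"]
        if met not in ref.index:
            continue
        rm, rs = ref.loc[met, "mean"], ref.loc[met, "sem"]
        if rm == 0:
            raise ValueError(f"zero reference mean for {met}")
        pct = r["mean"] / rm * 100.0
        if r[line_col] == reference:
            # reference vs itself is exactly 100; SEM reflects its own spread
            sem = rs / rm * 100.0 if np.isfinite(rs) else np.nan
            pct = 100.0
        else:
            sem = 100.0 * np.sqrt(
                (r["sem"] / rm) ** 2 + (r["mean"] * rs / rm**2) ** 2
            )
        rows.append(
            {
                "metabolite": met,
                "line": r[line_col],
                "percent": pct,
                "sem": sem,
                "n": int(r["count"]),
            }
        )
    return pd.DataFrame(rows)
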