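"""Bundled reference data: the published validation assay table and enzymes.

The validation table records, for 16 variant x accession assays, each
caller's pooled-sequencing VAF prediction and the allele frequency observed
by genotyping individual plants (CAPS digestion or Sanger sequencing).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .caps import (GenotypeCounts, RestrictionEnzyme, compare_predicted_observed,
                   observed_frequency)

__all__ = [
    "load_validation_table",
    "load_enzymes",
    "recompute_observed",
    "closest_caller_tally",
]

CALLERS = ("gatk", "snver", "crisp")


def _data_path(name: str):
    return resources.files("poolvar.data").joinpath(name)


def load_validation_table() -> pd.DataFrame:
    with resources.as_file(_data_path("table2_validation.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_enzymes() -> dict[str, RestrictionEnzyme]:
    with resources.as_file(_data_path("enzymes.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    return {r["name"]: RestrictionEnzyme(r["name"], r["site"])
            for _, r in df.iterrows()}


def recompute_observed(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Observed allele frequency recomputed from per-plant genotype counts.

    Rows whose homozygous-variant count is unavailable keep NaN.  Adds
    ``vaf_obs_recomputed`` (full precision) and ``vaf_obs_rounded``.
    """
    df = (table if table is not None else load_validation_table()).copy()
    full, rounded = [], []
    for _, r in df.iterrows():
        if pd.isna(r["n_homalt"]):
            full.append(np.nan)
            rounded.append(np.nan)
            continue
        counts = GenotypeCounts(
            ref_ref=int(r["n_plants"] - r["n_het"] - r["n_homalt"]),
            ref_alt=int(r["n_het"]),
            alt_alt=int(r["n_homalt"]),
        )
        f = observed_frequency(counts)
        full.append(f)
        rounded.append(observed_frequency(counts, rounded=True))
    df["vaf_obs_recomputed"] = full
    df["vaf_obs_rounded"] = rounded
    return df


def closest_caller_tally(table: pd.DataFrame | None = None) -> pd.Series:
    """Per-caller count of recovered assays where that caller's prediction
    was closest to the observed frequency.

    Assays where no plant carried the variant (observed frequency 0) are
    excluded, as the variant was not recovered.
    """
    df = table if table is not None else load_validation_table()
    tally = {c: 0 for c in CALLERS}
    for _, r in df.iterrows():
        if r["vaf_obs"] <= 0:
            continue
        predicted = {c: float(r[f"vaf_{c}"]) for c in CALLERS}
        closest, _ = compare_predicted_observed(predicted, float(r["vaf_obs"]))
        for c in closest:
            tally[c] += 1 / len(closest)
    return pd.Series(tally, name="n_closest")
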