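"""Packaged transcriptions of the published summary tables and the
arithmetic that recomputes the headline statistics from them.

The fixtures transcribe, cell for cell, the published per-sample summary
tables for twelve paired DNA/RNA pyrosequencing samples (four sites:
a coastal oxygen-minimum zone, two open-ocean time-series stations, and a
forest soil): mean percent amino-acid identities by detection fraction,
database-independent cluster identities, read GC percentages, and
proportional amino-acid usage changes.  The summary operations reproduce
the headline numbers (e.g. the mean paired RNA-DNA identity difference and
the expressed/non-expressed identity gap) by plain arithmetic over the
printed cells.
"""

from __future__ import annotations

import importlib.resources
import math
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "load_table2",
    "load_table6",
    "load_table7",
    "load_table8",
    "summarize_table2",
    "summarize_table6",
    "summarize_table7",
    "round_half_away",
    "TABLE6_OCEAN_ROWS",
]

#: the four representative ocean samples of the cluster-identity summary
TABLE6_OCEAN_ROWS = ("OMZ 50 m", "OMZ 200 m", "HOT 75 m", "HOT 500 m")


def _load(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("metaconserve.data") / name
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", na_values=["NA"])


def load_table2() -> pd.DataFrame:
    """Mean percent amino-acid identity by detection fraction and pool."""
    return _load("table2_identity.tsv")


def load_table6() -> pd.DataFrame:
    """Cluster counts and mean percent identity per cluster type."""
    return _load("table6_clusters.tsv")


def load_table7() -> pd.DataFrame:
    """Read GC percentages in ORFs by pool and detection fraction."""
    return _load("table7_gc.tsv")


def load_table8() -> pd.DataFrame:
    """Proportional amino-acid usage change (DNA->RNA) per sample, with the
    synonymous-codon GC content column."""
    return _load("table8_usage.tsv")


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero at the printed precision."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def summarize_table2(table: Optional[pd.DataFrame] = None) -> dict[str, float]:
    """Headline identity differences recomputed from the printed cells.

    * ``rna_dna_mean`` / ``rna_dna_min`` / ``rna_dna_max``: per-sample
      difference between the RNA and DNA rows' "All" identity, then mean and
      range over the 12 sample pairs.
    * ``expressed_nonexpressed_mean``: within the DNA rows, the mean of
      (shared - DNA-only) identity, i.e. expressed versus non-expressed.
    All values rounded half-away at one decimal.
    """
    t = table if table is not None else load_table2()
    dna = t[t["pool"] == "DNA"].set_index(["site", "depth"])
    rna = t[t["pool"] == "RNA"].set_index(["site", "depth"])
    if len(dna) != len(rna):
        raise ValueError("unpaired sample rows")
    paired = rna["all_genes"] - dna["all_genes"]
    gap = dna["shared"] - dna["dna_only"]
    return dict(
        rna_dna_mean=round_half_away(paired.mean(), 1),
        rna_dna_min=round_half_away(paired.min(), 1),
        rna_dna_max=round_half_away(paired.max(), 1),
        expressed_nonexpressed_mean=round_half_away(gap.mean(), 1),
        n_samples=len(paired),
    )


def summarize_table6(
    table: Optional[pd.DataFrame] = None,
    rows: Sequence[str] = TABLE6_OCEAN_ROWS,
) -> float:
    """Mean (DNA-only minus mixed) cluster identity over the selected rows.

    The default subset holds the four representative ocean samples; passing
    all five rows (including soil) is supported.  Rounded to one decimal.
    """
    t = table if table is not None else load_table6()
    t = t.set_index("sample")
    missing = [r for r in rows if r not in t.index]
    if missing:
        raise KeyError(f"unknown sample rows: {missing}")
    sel = t.loc[list(rows)]
    return round_half_away((sel["ident_dna_only"] - sel["ident_mixed"]).mean(), 1)


def summarize_table7(table: Optional[pd.DataFrame] = None) -> dict[str, float]:
    """GC differences over the 11 ocean samples (soil excluded).

    * ``rna_dna_mean``: mean of (RNA all - DNA all), rounded to the nearest
      integer as printed.
    * ``dnaonly_shared_mean``: mean of (DNA-only - shared), one decimal.
    * ``soil_rna_dna``: the soil sample's RNA-DNA difference, one decimal.
    """
    t = table if table is not None else load_table7()
    ocean = t[t["site"] != "Soil"]
    soil = t[t["site"] == "Soil"].iloc[0]
    return dict(
        rna_dna_mean=round_half_away((ocean["rna_all"] - ocean["dna_all"]).mean(), 0),
        dnaonly_shared_mean=round_half_away(
            (ocean["dna_only"] - ocean["dna_shared"]).mean(), 1
        ),
        soil_rna_dna=round_half_away(soil["rna_all"] - soil["dna_all"], 1),
        n_ocean=len(ocean),
    )
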