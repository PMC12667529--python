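"""Aggregate categorization and donor-level profile assembly.

Each aggregate is flagged against inclusive thresholds — long (length >=
100 nm), fibrillar (eccentricity >= 0.9), dense (>= 0.01 localizations per
nm^2, complement "sparse") and bright (scaled intensity >= 0.9 A.U.) — and
the population tabulated over the eight long x fibrillar x dense paths for
Sankey-style visualization. Donor profiles average technical-replicate
means and carry the fifteen features the disease-signature analysis uses,
plus the six radar measures (count normalized by the maximum donor count in
the panel, pSER colabelling, long, fibrillar, dense, bright proportions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class Thresholds:
    long_nm: float = 100.0
    fibrillar_ecc: float = 0.9
    dense_loc_per_nm2: float = 0.01
    bright_au: float = 0.9

    def __post_init__(self) -> None:
        if not 0 < self.fibrillar_ecc < 1:
            raise ValueError("eccentricity threshold must lie in (0, 1)")
        if min(self.long_nm, self.dense_loc_per_nm2, self.bright_au) <= 0:
            raise ValueError("thresholds must be positive")


#: the feature set feeding the discriminant analysis, in canonical order
LDA_FEATURES = [
    "mean_count", "mean_area_nm2", "mean_eccentricity", "mean_perimeter_nm",
    "mean_minor_axis_nm", "mean_major_axis_nm", "mean_n_localizations",
    "mean_length_nm", "mean_density", "mean_scaled_intensity",
    "prop_bright", "prop_pser", "prop_fibrillar", "prop_long", "prop_sparse",
]

RADAR_FEATURES = ["count_norm", "prop_pser", "prop_long", "prop_fibrillar",
                  "prop_dense", "prop_bright"]


def classify_aggregate(records: pd.DataFrame,
                       t: Thresholds | None = None) -> pd.DataFrame:
    """Append boolean category flags (inclusive thresholds) to a record table.

    Expects columns length_nm (or skeleton_length_nm), eccentricity,
    density_loc_per_nm2 and, when available, scaled_intensity.
    """
    t = t or Thresholds()
    out = records.copy()
    length = out["length_nm"] if "length_nm" in out else out["skeleton_length_nm"]
    out["long"] = length >= t.long_nm
    out["fibrillar"] = out["eccentricity"] >= t.fibrillar_ecc
    out["dense"] = out["density_loc_per_nm2"] >= t.dense_loc_per_nm2
    out["sparse"] = ~out["dense"]
    if "scaled_intensity" in out:
        out["bright"] = out["scaled_intensity"] >= t.bright_au
    return out


def tabulate_subpopulations(records: pd.DataFrame) -> pd.DataFrame:
    """Counts and proportions over the 2^3 long x fibrillar x dense paths."""
    cells = []
    n = len(records)
    for lng in (False, True):
        for fib in (False, True):
            for den in (False, True):
                if n:
                    count = int(((records["long"] == lng) &
                                 (records["fibrillar"] == fib) &
                                 (records["dense"] == den)).sum())
                else:
                    count = 0
                cells.append({"long": lng, "fibrillar": fib, "dense": den,
                              "count": count,
                              "proportion": count / n if n else 0.0})
    return pd.DataFrame(cells)


def scale_intensity(spots: pd.DataFrame, by: list[str] | None = None,
                    column: str = "intensity") -> pd.DataFrame:
    """Min-max scale spot intensities to [0, 1] by the batch maximum.

    ``by`` defines the batch (e.g. region x extract); None scales globally.
    """
    out = spots.copy()
    if by:
        grouped = out.groupby(by)[column]
        lo, hi = grouped.transform("min"), grouped.transform("max")
    else:
        lo, hi = out[column].min(), out[column].max()
    span = hi - lo
    out["scaled_intensity"] = np.where(span > 0, (out[column] - lo) / span, 0.0)
    return out


def _donor_profile_row(agg: pd.DataFrame, spots: pd.DataFrame,
                       t: Thresholds) -> dict:
    """One donor x region profile: replicate means averaged to donor level."""
    agg = classify_aggregate(agg, t)
    rep_counts = spots.groupby("replicate").size() if len(spots) else pd.Series(dtype=float)
    row = {
        "n_replicates": int(agg["replicate"].nunique()),
        "mean_count": float(rep_counts.mean()) if len(rep_counts) else 0.0,
    }
    # replicate means of continuous measures, then averaged across replicates
    measures = {
        "mean_area_nm2": "area_nm2", "mean_eccentricity": "eccentricity",
        "mean_perimeter_nm": "perimeter_nm", "mean_minor_axis_nm": "minor_axis_nm",
        "mean_major_axis_nm": "major_axis_nm",
        "mean_n_localizations": "n_localizations",
        "mean_length_nm": "length_nm" if "length_nm" in agg else "skeleton_length_nm",
        "mean_density": "density_loc_per_nm2",
        "mean_scaled_intensity": "scaled_intensity",
    }
    for name, col in measures.items():
        row[name] = float(agg.groupby("replicate")[col].mean().mean())
    # proportions over all of the donor's aggregates
    flags = {"prop_bright": "bright", "prop_fibrillar": "fibrillar",
             "prop_long": "long", "prop_sparse": "sparse", "prop_dense": "dense"}
    for name, col in flags.items():
        row[name] = float(agg[col].mean())
    if "colabel_pser" in agg:
        row["prop_pser"] = float(agg["colabel_pser"].mean())
    elif "colabel" in spots:
        row["prop_pser"] = float(spots["colabel"].mean())
    else:
        row["prop_pser"] = 0.0
    return row


def build_donor_profiles(aggregates: pd.DataFrame, spots: pd.DataFrame,
                         t: Thresholds | None = None,
                         normalize_count_by: tuple[str, ...] = ("region",)
                         ) -> pd.DataFrame:
    """Assemble one profile per donor x region from classified aggregates.

    ``aggregates`` and ``spots`` are tidy tables with donor/cohort/region/
    replicate columns (the cohort generator's output, or the measurement
    pipeline's). The radar ``count_norm`` feature is each donor's mean spot
    count as a proportion of the maximum donor count within the
    ``normalize_count_by`` panel, so exactly one donor per panel scores 1.
    """
    t = t or Thresholds()
    if "scaled_intensity" not in aggregates:
        raise ValueError("aggregates need a scaled_intensity column "
                         "(run scale_intensity first)")
    rows = []
    for (donor, region), agg in aggregates.groupby(["donor", "region"]):
        if agg.empty:
            continue
        sp = spots[(spots["donor"] == donor) & (spots["region"] == region)]
        row = _donor_profile_row(agg, sp, t)
        row.update({"donor": donor, "region": region,
                    "cohort": agg["cohort"].iloc[0]})
        rows.append(row)
    profiles = pd.DataFrame(rows)
    if profiles.empty:
        raise ValueError("no donor profiles could be built")
    key = [k for k in normalize_count_by if k in profiles]
    if key:
        max_count = profiles.groupby(key)["mean_count"].transform("max")
    else:
        max_count = profiles["mean_count"].max()
    profiles["count_norm"] = profiles["mean_count"] / max_count
    lead = ["donor", "cohort", "region", "n_replicates"]
    return profiles[lead + [c for c in profiles.columns if c not in lead]]
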