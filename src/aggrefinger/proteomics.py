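"""Aggregate-fraction proteomics downstream of peptide search.

TMT reporter abundances for an affinity-captured aggregate fraction and the
matched total proteome are filtered (contaminants out; quantified = at
least two peptides, one unique), normalized to a reference sample's summed
abundance, and turned into per-case ratios against the mean control
abundance. The aggregate-fraction ratio is then divided by the same
protein's total-proteome ratio, cancelling proteome-wide disease effects
and isolating aggregate-specific enrichment. Corrected ratios are tested
against the no-change mean (one-sample t on log2 ratios vs 0, equivalent in
orientation to testing the ratio against 1 but symmetric in variance) and
classified on the volcano plane (|log2| > 1, -log10 p > 1.3).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

META_COLUMNS = ["accession", "peptides", "unique_peptides", "contaminant"]


def _channels(table: pd.DataFrame) -> list[str]:
    ch = table.attrs.get("channels")
    if ch is None:
        raise ValueError("table.attrs['channels'] missing")
    return list(ch)


def filter_quantified(table: pd.DataFrame,
                      min_peptides: int = 2,
                      min_unique: int = 1,
                      contaminant_prefixes: tuple[str, ...] = ("CON_", "REV_", "KRT")
                      ) -> pd.DataFrame:
    """Keep quantifiable proteins: non-contaminant, >=2 peptides, >=1 unique.

    Contaminants are recognized by the flag column or by accession prefix
    (keratins and common database contaminant tags).
    """
    for col in ("peptides", "unique_peptides"):
        if col not in table.columns:
            raise ValueError(f"missing peptide-count column {col!r}")
    is_contaminant = table.get("contaminant", pd.Series(False, index=table.index))
    is_contaminant = is_contaminant.astype(bool) | table["accession"].str.startswith(
        tuple(contaminant_prefixes))
    keep = (~is_contaminant &
            (table["peptides"] >= min_peptides) &
            (table["unique_peptides"] >= min_unique))
    out = table.loc[keep].reset_index(drop=True)
    out.attrs = dict(table.attrs)
    return out


def reference_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each channel by its reference's summed abundance, rescaled so the
    grand mean of reference sums is the unit.

    ``table.attrs['reference_map']`` maps each sample channel to its
    reference column: total-proteome runs share a pooled per-run reference,
    aggregate-fraction channels each carry their own.
    """
    ref_map = table.attrs.get("reference_map")
    if not ref_map:
        raise ValueError("table.attrs['reference_map'] missing")
    out = table.copy()
    ref_sums = {ref: float(table[ref].sum()) for ref in set(ref_map.values())}
    for ref, s in ref_sums.items():
        if s <= 0:
            raise ValueError(f"reference column {ref!r} has non-positive sum")
    grand = float(np.mean(list(ref_sums.values())))
    for ch, ref in ref_map.items():
        out[ch] = table[ch] / (ref_sums[ref] / grand)
    out.attrs = dict(table.attrs)
    return out


def _case_ratios(table: pd.DataFrame, controls: list[str],
                 cases: list[str]) -> pd.DataFrame:
    """Per-case abundance ratio against the mean control abundance.

    Rows whose control mean is zero get NaN ratios (dropped downstream with
    a reason code).
    """
    ctrl_mean = table[controls].replace(0, np.nan).mean(axis=1)
    ratios = table[cases].div(ctrl_mean, axis=0)
    ratios.insert(0, "accession", table["accession"].to_numpy())
    return ratios


def compute_corrected_ratios(total: pd.DataFrame, aggregate: pd.DataFrame,
                             controls: list[str], cases: list[str],
                             min_present: int = 1) -> pd.DataFrame:
    """Total-proteome-corrected aggregate-fraction ratios per protein.

    For each case channel, corrected = (aggregate ratio) / (total ratio) for
    the same protein; proteins must be quantified (nonzero) in at least
    ``min_present`` case extracts in BOTH fractions and have a nonzero
    control mean, otherwise they are dropped with a reason code. Each
    protein's corrected ratios are tested by a one-sample t of log2 ratios
    against 0.

    Returns a volcano table: accession, n (cases contributing),
    mean_log2_corrected, t, p, neg_log10_p, reason (for dropped proteins
    see attrs['dropped']).
    """
    merged = pd.merge(total[["accession"] + controls + cases],
                      aggregate[["accession"] + controls + cases],
                      on="accession", suffixes=("_tot", "_agg"))
    tot = merged[["accession"] + [c + "_tot" for c in controls + cases]].rename(
        columns=lambda c: c.removesuffix("_tot"))
    agg = merged[["accession"] + [c + "_agg" for c in controls + cases]].rename(
        columns=lambda c: c.removesuffix("_agg"))

    r_tot = _case_ratios(tot, controls, cases).set_index("accession")
    r_agg = _case_ratios(agg, controls, cases).set_index("accession")
    corrected = r_agg / r_tot
    tot_idx = tot.set_index("accession")
    agg_idx = agg.set_index("accession")

    rows, dropped = [], []
    for acc, row in corrected.iterrows():
        vals = row.to_numpy(dtype=float)
        vals = vals[np.isfinite(vals) & (vals > 0)]
        present_tot = int((tot_idx.loc[acc, cases] > 0).sum())
        present_agg = int((agg_idx.loc[acc, cases] > 0).sum())
        if present_tot < min_present or present_agg < min_present:
            dropped.append({"accession": acc, "reason": "presence"})
            continue
        if vals.size == 0:
            dropped.append({"accession": acc, "reason": "zero_control_mean"})
            continue
        log2 = np.log2(vals)
        if vals.size >= 2 and log2.std(ddof=1) > 0:
            t, p = sps.ttest_1samp(log2, 0.0)
            t, p = float(t), float(p)
        elif vals.size >= 2:
            t, p = 0.0 if np.allclose(log2, 0) else np.inf, 1.0 if np.allclose(log2, 0) else 0.0
        else:
            t, p = np.nan, np.nan
        rows.append({"accession": acc, "n": int(vals.size),
                     "mean_log2_corrected": float(log2.mean()),
                     "t": t, "p": p,
                     "neg_log10_p": -np.log10(p) if p and np.isfinite(p) else np.nan})
    out = pd.DataFrame(rows)
    out.attrs["dropped"] = pd.DataFrame(dropped)
    return out


def volcano_classify(records: pd.DataFrame,
                     log2_threshold: float = 1.0,
                     neg_log10p_threshold: float = 1.3) -> pd.DataFrame:
    """Partition corrected ratios into enriched / depleted / ns calls."""
    out = records.copy()
    sig = out["neg_log10_p"] > neg_log10p_threshold
    out["call"] = "ns"
    out.loc[sig & (out["mean_log2_corrected"] > log2_threshold), "call"] = "enriched"
    out.loc[sig & (out["mean_log2_corrected"] < -log2_threshold), "call"] = "depleted"
    out.attrs = dict(records.attrs)
    return out
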