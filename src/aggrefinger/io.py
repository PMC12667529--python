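"""Readers, writers and end-to-end orchestration.

Localization tables travel as HDF5 (dataset ``locs``, one field per column)
or CSV with the columns frame, x, y, photons, sx, sy, bg, lpx, lpy —
coordinates in camera pixels, per-axis precision in pixels, following
common SMLM localization-table conventions. Image stacks are multi-frame
TIFF. ``run_profile`` drives the whole synthetic workflow (cohort
simulation -> classification -> donor profiles -> cohort statistics ->
discriminant signature -> proteomics volcano) and writes a manifest with
the seed and config hash so any run is reproducible.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from . import lda as lda_mod
from . import proteomics as prot_mod
from . import stats as stats_mod
from . import subpopulations as subpop_mod
from . import synthetic
from .config import PipelineConfig

logger = logging.getLogger(__name__)

LOC_COLUMNS = synthetic.LOC_COLUMNS


def write_localizations(table: pd.DataFrame, path: str | Path) -> None:
    """Write a localization table to .hdf5/.h5 or .csv by extension."""
    path = Path(path)
    if path.suffix in (".hdf5", ".h5"):
        rec = table[LOC_COLUMNS].to_records(index=False)
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("locs", data=rec)
            ds.attrs["pixel_size_nm"] = table.attrs.get("pixel_size_nm", 107.0)
    elif path.suffix == ".csv":
        table[LOC_COLUMNS].to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported extension {path.suffix!r}")


def read_localization_table(path: str | Path,
                            pixel_size_nm: float | None = None) -> pd.DataFrame:
    """Read and validate a localization table (HDF5 or CSV)."""
    path = Path(path)
    if path.suffix in (".hdf5", ".h5"):
        with h5py.File(path, "r") as f:
            if "locs" not in f:
                raise ValueError(f"{path}: no 'locs' dataset")
            rec = f["locs"][()]
            table = pd.DataFrame(rec)
            meta_px = f["locs"].attrs.get("pixel_size_nm")
    elif path.suffix == ".csv":
        if path.stat().st_size == 0:
            warnings.warn(f"{path}: empty file; returning empty table")
            table = pd.DataFrame(columns=LOC_COLUMNS)
            table.attrs["pixel_size_nm"] = pixel_size_nm or 107.0
            return table
        table = pd.read_csv(path)
        meta_px = None
    else:
        raise ValueError(f"unsupported extension {path.suffix!r}")

    missing = [c for c in LOC_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing} "
                         "(per-axis precision must be provided as lpx/lpy)")
    if len(table) and not np.all(np.isfinite(table[["x", "y"]].to_numpy())):
        raise ValueError(f"{path}: non-finite coordinates")
    table.attrs["pixel_size_nm"] = pixel_size_nm or meta_px or 107.0
    return table


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), np.asarray(stack, dtype=np.float32))


def read_stack(path: str | Path) -> np.ndarray:
    """Multi-frame TIFF -> (frames, h, w) array; single pages gain a frame axis."""
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 2-D or 3-D TIFF, got shape {arr.shape}")
    return arr


def write_ground_truth(truth: dict, path: str | Path) -> None:
    """JSON sidecar with the generator's ground truth."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if hasattr(o, "__dict__"):
            return o.__dict__
        raise TypeError(type(o).__name__)
    Path(path).write_text(json.dumps(truth, default=default, indent=1))


def run_profile(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Synthetic end-to-end run: all stage outputs written under ``out_dir``.

    Stages: cohort simulation, aggregate classification, Sankey tabulation,
    donor profiles, Welch cohort comparisons, LDA signature, proteomics
    volcano. Returns the in-memory results; every output carries the config
    hash in the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("simulate_cohort")
        cohort = synthetic.simulate_cohort(
            synthetic.SyntheticCohortSpec(seed=config.seed))
        aggregates, spots = cohort["aggregates"], cohort["spots"]

        stage("classify")
        t = subpop_mod.Thresholds(config.long_nm, config.fibrillar_ecc,
                                  config.dense_loc_per_nm2, config.bright_au)
        classified = subpop_mod.classify_aggregate(aggregates, t)
        classified.to_csv(out_dir / "aggregates.csv", index=False)
        sankey = classified.groupby(["cohort", "region"]).apply(
            subpop_mod.tabulate_subpopulations, include_groups=False).reset_index()
        sankey.to_csv(out_dir / "sankey_counts.csv", index=False)

        stage("profiles")
        profiles = subpop_mod.build_donor_profiles(aggregates, spots, t)
        profiles.to_csv(out_dir / "donor_profiles.csv", index=False)

        stage("cohort_stats")
        comparisons = pd.concat([
            stats_mod.compare_cohorts(profiles, f)
            for f in ("mean_length_nm", "mean_eccentricity", "mean_density",
                      "mean_count")], ignore_index=True)
        if len(comparisons):
            comparisons["p_holm"] = stats_mod.adjust_pvalues(
                comparisons["p"], "holm")
        comparisons.to_csv(out_dir / "cohort_comparisons.csv", index=False)

        stage("lda")
        x, labels, feats = lda_mod.build_feature_matrix(profiles)
        fit = lda_mod.fit_lda(x, labels, feats)
        proj = pd.DataFrame(fit.projection[:, :2], columns=["LD1", "LD2"])
        proj.insert(0, "label", fit.labels)
        proj.insert(0, "donor", profiles["donor"].to_numpy())
        proj.to_csv(out_dir / "lda_projection.csv", index=False)
        fit.coefficients.to_csv(out_dir / "lda_contributions.csv")

        stage("proteomics")
        enriched = {"P00100": (4.0, 1.0), "P00101": (0.25, 1.0)}
        total, agg_tab, _ = synthetic.simulate_proteomics(
            n_proteins=300, enriched=enriched, seed=config.seed)
        total = prot_mod.reference_normalize(prot_mod.filter_quantified(
            total, config.min_peptides, config.min_unique_peptides,
            config.contaminant_prefixes))
        agg_tab = prot_mod.reference_normalize(prot_mod.filter_quantified(
            agg_tab, config.min_peptides, config.min_unique_peptides,
            config.contaminant_prefixes))
        volcano = prot_mod.volcano_classify(
            prot_mod.compute_corrected_ratios(
                total, agg_tab, total.attrs["control_channels"],
                total.attrs["case_channels"]),
            config.volcano_log2_threshold, config.volcano_neglog10p_threshold)
        volcano.to_csv(out_dir / "volcano.csv", index=False)
    except Exception as err:  # noqa: BLE001 - re-raise with the failing stage
        raise RuntimeError(f"pipeline stage failed: {err}") from err

    manifest = {"seed": config.seed, "config_hash": config.config_hash(),
                "config": config.to_dict(),
                "outputs": sorted(p.name for p in out_dir.glob("*.csv"))}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    results.update({"profiles": profiles, "comparisons": comparisons,
                    "lda": fit, "volcano": volcano, "sankey": sankey,
                    "manifest": manifest})
    return results
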