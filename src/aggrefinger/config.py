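"""Pipeline configuration.

Every tunable threshold of the fingerprinting pipeline lives here, with the
published defaults: 107 nm camera pixels, mean projection over the last 40
frames, a 4 px colocalization radius, a strict <30 nm localization-precision
cut after discarding the first 300 frames, DBSCAN at eps 0.5 px / 5 points,
the long/fibrillar/dense/bright category thresholds (100 nm, 0.9, 0.01
loc/nm^2, 0.9 A.U.), the 101-point cumulative-distribution grid, matched-1000
KS subsampling and the |log2| > 1 / -log10 p > 1.3 volcano cuts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # acquisition geometry
    pixel_size_nm: float = 107.0
    image_width_px: int = 512
    image_height_px: int = 512

    # diffraction-limited detection
    projection_last_n: int = 40
    detect_smooth_sigma_px: float = 1.0
    detect_threshold_k: float = 5.0
    detect_min_separation_px: int = 3
    intensity_window_px: int = 7
    border_policy: str = "exclude"  # exclude | flag

    # colocalization
    coloc_radius_px: float = 4.0
    chance_mode: str = "mirror_x"  # mirror_x | swap_xy

    # super-resolution
    max_precision_nm: float = 30.0
    discard_first_frames: int = 300
    dbscan_eps_px: float = 0.5
    dbscan_min_samples: int = 5
    render_px_nm: float = 5.35  # camera pixel / 20
    morph_dilation_r: int = 1
    morph_closing_r: int = 2
    morph_erosion_r: int = 3
    drift_blocks: int = 10

    # subpopulation thresholds (inclusive boundaries)
    long_nm: float = 100.0
    fibrillar_ecc: float = 0.9
    dense_loc_per_nm2: float = 0.01
    bright_au: float = 0.9

    # cohort statistics
    cdf_grid_points: int = 101
    ks_subsample_n: int = 1000
    ks_n_boot: int = 100
    alpha: float = 0.05

    # proteomics
    min_peptides: int = 2
    min_unique_peptides: int = 1
    volcano_log2_threshold: float = 1.0
    volcano_neglog10p_threshold: float = 1.3
    contaminant_prefixes: tuple[str, ...] = ("CON_", "REV_", "KRT")

    # reproducibility
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["contaminant_prefixes"] = list(d["contaminant_prefixes"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "contaminant_prefixes" in d:
            d = {**d, "contaminant_prefixes": tuple(d["contaminant_prefixes"])}
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Stable short hash recorded in every pipeline output manifest."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0 or self.render_px_nm <= 0:
            raise ValueError("pixel sizes must be positive")
        if not (0 < self.fibrillar_ecc < 1):
            raise ValueError("eccentricity threshold must lie in (0, 1)")
        for name in ("long_nm", "dense_loc_per_nm2", "bright_au",
                     "coloc_radius_px", "max_precision_nm", "dbscan_eps_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def field_of_view_um(width_px: int = 512, pixel_size_nm: float = 107.0) -> float:
    """Side length of the field of view in micrometres (512 px x 107 nm = 54.784)."""
    return width_px * pixel_size_nm / 1000.0
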